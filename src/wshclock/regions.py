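"""Genome segmentation into window sets and per-window methylation features.

Coordinates: windows are 0-based half-open (BED); CpG positions are 1-based
(Bismark coverage convention). A CpG at position p lies in window [s, e)
iff p - 1 is in [s, e).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicWindow",
    "SEX_CHROMS",
    "default_schemes",
    "scheme_label",
    "segment_genome",
    "window_average_methylation",
    "deduplicate_windows",
]

logger = logging.getLogger(__name__)

SEX_CHROMS = frozenset(
    {"chrX", "chrY", "chrM", "chrMT", "X", "Y", "M", "MT"}
)

#: the default segmentation configuration: thirteen fixed bin sizes plus the
#: 100 bp / 20 bp sliding scheme (14 window sets in total)
DEFAULT_FIXED_SIZES = (9000, 8000, 7000, 6000, 5000, 4000, 3000, 2000, 1000, 500, 250, 150, 100)


@dataclass(frozen=True)
class GenomicWindow:
    """A labelled genomic interval, 0-based half-open, autosomal only."""

    chrom: str
    start: int
    end: int
    set_label: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid window {self.chrom}:{self.start}-{self.end}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def default_schemes() -> list[tuple]:
    """The 14 default segmentation schemes."""
    schemes: list[tuple] = [("fixed", size) for size in DEFAULT_FIXED_SIZES]
    schemes.append(("sliding", 100, 20))
    return schemes


def scheme_label(scheme: tuple) -> str:
    kind = scheme[0]
    if kind == "fixed":
        return f"{scheme[1]}bp"
    if kind == "sliding":
        return f"{scheme[1]}_{scheme[2]}"
    raise ValueError(f"unknown scheme {scheme!r}")


def segment_genome(chrom_sizes: Mapping[str, int], scheme: tuple) -> list[GenomicWindow]:
    """Tile every autosome with one window scheme.

    ``scheme`` is ``("fixed", size)`` (consecutive non-overlapping bins,
    trailing partial bin kept) or ``("sliding", width, step)`` (starts at
    0, step, 2*step, ... while start < chrom length; trailing windows
    truncated at the chromosome end). X/Y/M are excluded.
    """
    kind = scheme[0]
    if kind == "fixed":
        width = step = int(scheme[1])
    elif kind == "sliding":
        width, step = int(scheme[1]), int(scheme[2])
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if width < 1 or step < 1:
        raise ValueError(f"degenerate scheme {scheme!r}")
    label = scheme_label(scheme)
    windows: list[GenomicWindow] = []
    for chrom in chrom_sizes:
        if chrom in SEX_CHROMS:
            continue
        length = int(chrom_sizes[chrom])
        if length < 1:
            raise ValueError(f"chromosome {chrom} has non-positive length")
        for start in range(0, length, step):
            windows.append(GenomicWindow(chrom, start, min(start + width, length), label))
    return windows


def _regular_layout(chrom_windows: list[tuple[int, GenomicWindow]]):
    """Detect an arithmetic start grid with a common nominal width; returns
    (step, width) or None. Truncated trailing windows are tolerated."""
    starts = [w.start for _, w in chrom_windows]
    if starts != sorted(starts):
        return None
    width = max(w.end - w.start for _, w in chrom_windows)
    if len(starts) == 1:
        return max(width, 1), width
    steps = {b - a for a, b in zip(starts, starts[1:])}
    if len(steps) != 1:
        return None
    step = steps.pop()
    if step < 1:
        return None
    if starts[0] != 0:
        return None
    # all windows except possibly chromosome-end-truncated ones share width
    for _, w in chrom_windows[:-max(1, width // step)]:
        if w.end - w.start != width:
            return None
    return step, width


def window_average_methylation(
    coverage_by_sample: Mapping[str, Sequence],
    windows: Sequence[GenomicWindow],
    min_cov: int = 5,
    per_cpg_mean: bool = False,
) -> pd.DataFrame:
    """Mean methylation per window and sample from per-CpG coverage records.

    CpGs with total count < ``min_cov`` are dropped. The window value is
    call-weighted (sum of methylated counts over sum of all counts) unless
    ``per_cpg_mean`` is set, in which case it is the unweighted mean of
    per-CpG methylated fractions. Windows with no surviving CpG in at least
    one sample (including CpG-free windows) are removed; every remaining
    cell lies in [0, 1].
    """
    if not windows:
        raise ValueError("empty window set")
    sample_ids = list(coverage_by_sample)
    if not sample_ids:
        raise ValueError("no samples provided")

    by_chrom: dict[str, list[tuple[int, GenomicWindow]]] = {}
    for gi, w in enumerate(windows):
        by_chrom.setdefault(w.chrom, []).append((gi, w))

    n_win, n_samp = len(windows), len(sample_ids)
    meth_sum = np.zeros((n_win, n_samp))
    call_sum = np.zeros((n_win, n_samp))
    frac_sum = np.zeros((n_win, n_samp))
    cpg_count = np.zeros((n_win, n_samp), dtype=np.int64)

    layouts = {chrom: _regular_layout(group) for chrom, group in by_chrom.items()}

    for si, sample_id in enumerate(sample_ids):
        per_chrom: dict[str, list] = {}
        for rec in coverage_by_sample[sample_id]:
            if rec.total < min_cov:
                continue
            per_chrom.setdefault(rec.chrom, []).append(rec)
        for chrom, recs in per_chrom.items():
            group = by_chrom.get(chrom)
            if not group:
                continue
            pos0 = np.array([r.pos - 1 for r in recs])  # 0-based
            mc = np.array([r.count_meth for r in recs], dtype=float)
            tc = np.array([r.total for r in recs], dtype=float)
            layout = layouts[chrom]
            if layout is not None:
                step, width = layout
                j_hi = pos0 // step
                j_lo = np.maximum(0, (pos0 - width) // step + 1)
                j_hi = np.minimum(j_hi, len(group) - 1)
                valid = j_hi >= j_lo
                j_lo, j_hi = j_lo[valid], j_hi[valid]
                mc_v, tc_v = mc[valid], tc[valid]
                counts = (j_hi - j_lo + 1).astype(np.int64)
                total = int(counts.sum())
                if total == 0:
                    continue
                offsets = np.arange(total) - np.repeat(
                    np.concatenate(([0], np.cumsum(counts)[:-1])), counts
                )
                local = np.repeat(j_lo, counts) + offsets
                rep_m = np.repeat(mc_v, counts)
                rep_t = np.repeat(tc_v, counts)
                rep_p = np.repeat(pos0[valid], counts)
                w_starts = np.array([w.start for _, w in group])[local]
                w_ends = np.array([w.end for _, w in group])[local]
                ok = (w_starts <= rep_p) & (rep_p < w_ends)
                local, rep_m, rep_t = local[ok], rep_m[ok], rep_t[ok]
                gidx = np.array([gi for gi, _ in group])[local]
                np.add.at(meth_sum[:, si], gidx, rep_m)
                np.add.at(call_sum[:, si], gidx, rep_t)
                np.add.at(frac_sum[:, si], gidx, rep_m / rep_t)
                np.add.at(cpg_count[:, si], gidx, 1)
            else:
                starts = [w.start for _, w in group]
                max_width = max(w.end - w.start for _, w in group)
                import bisect

                for p, m_val, t_val in zip(pos0, mc, tc):
                    j = bisect.bisect_right(starts, p) - 1
                    while j >= 0 and starts[j] > p - max_width:
                        gi, w = group[j]
                        if w.start <= p < w.end:
                            meth_sum[gi, si] += m_val
                            call_sum[gi, si] += t_val
                            frac_sum[gi, si] += m_val / t_val
                            cpg_count[gi, si] += 1
                        j -= 1

    determined = (cpg_count > 0).all(axis=1)
    n_dropped = int((~determined).sum())
    if n_dropped:
        logger.info(
            "window_average_methylation: dropped %d/%d windows undetermined in >= 1 sample",
            n_dropped,
            n_win,
        )
    keep = np.nonzero(determined)[0]
    if per_cpg_mean:
        values = frac_sum[keep] / cpg_count[keep]
    else:
        values = meth_sum[keep] / call_sum[keep]
    index = pd.Index([windows[i].key for i in keep], name="window")
    matrix = pd.DataFrame(values, index=index, columns=sample_ids)
    if len(windows):
        matrix.attrs["set_label"] = windows[0].set_label
    return matrix


def deduplicate_windows(matrix: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, str]]:
    """Drop rows whose value vectors duplicate an earlier row.

    Among identical rows the first in genomic (input) order is kept; the
    returned mapping lists removed key -> kept key.
    """
    values = np.ascontiguousarray(matrix.to_numpy())
    seen: dict[bytes, str] = {}
    keep_mask = np.ones(len(matrix), dtype=bool)
    mapping: dict[str, str] = {}
    for i, key in enumerate(matrix.index):
        digest = values[i].tobytes()
        if digest in seen:
            keep_mask[i] = False
            mapping[key] = seen[digest]
        else:
            seen[digest] = key
    return matrix.loc[keep_mask], mapping
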