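"""Within-sample heterogeneity (WSH) scores from read-level methylation calls.

Five scores are implemented, all bounded in [0, 1]:

* ``pdr``   — proportion of reads carrying both methylated and unmethylated
  calls, among reads with enough CpGs to judge concordance.
* ``pm``    — epipolymorphism: one minus the sum of squared frequencies of
  the 16 possible patterns over a window of four CpGs.
* ``mhl``   — methylation haplotype load: length-weighted fraction of fully
  methylated contiguous substrings across reads.
* ``fdrp``  — fraction of read pairs that disagree at one or more shared
  CpGs near the anchor.
* ``qfdrp`` — mean normalized Hamming distance over shared CpGs, averaged
  across read pairs.

The anchor unit is a single CpG for ``pdr``/``mhl``/``fdrp``/``qfdrp`` and a
run of four consecutive covered CpGs for ``pm``. Kernels return ``None``
(not 0) when fewer than ``min_depth`` informative reads are available.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import MethylationRead, SampleMethylome

__all__ = [
    "METRICS",
    "MetricParams",
    "HeterogeneityLocus",
    "SampleScores",
    "compute_pdr",
    "compute_pm",
    "compute_mhl",
    "compute_fdrp",
    "compute_qfdrp",
    "score_sample",
    "assemble_score_matrix",
    "parse_locus_key",
]

METRICS = ("pdr", "pm", "mhl", "fdrp", "qfdrp")

PAIR_METRICS = ("fdrp", "qfdrp")


@dataclass(frozen=True)
class MetricParams:
    """Tuning knobs shared by the five score kernels.

    ``fdrp_max_reads=None`` disables pair subsampling; ``fdrp_window_bp=None``
    disables the distance restriction around the anchor CpG.
    """

    min_depth: int = 10
    pdr_min_cpgs_per_read: int = 4
    fdrp_max_reads: Optional[int] = 40
    fdrp_window_bp: Optional[int] = 50
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.fdrp_max_reads is not None and self.fdrp_max_reads < 2:
            raise ValueError("fdrp_max_reads must be >= 2")


@dataclass(frozen=True)
class HeterogeneityLocus:
    """Anchor of one score: a CpG position, or a 4-tuple of positions for pm."""

    metric: str
    chrom: str
    anchor: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        n_expected = 4 if self.metric == "pm" else 1
        if len(self.anchor) != n_expected:
            raise ValueError(
                f"{self.metric} anchor needs {n_expected} position(s), got {len(self.anchor)}"
            )
        if any(b <= a for a, b in zip(self.anchor, self.anchor[1:])):
            raise ValueError("anchor positions must be strictly increasing")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{'-'.join(str(p) for p in self.anchor)}"


def parse_locus_key(key: str) -> tuple[str, tuple[int, ...]]:
    """Invert :attr:`HeterogeneityLocus.key` (and window-free locus keys)."""
    chrom, _, tail = key.rpartition(":")
    return chrom, tuple(int(p) for p in tail.split("-"))


@dataclass
class SampleScores:
    """Scores of one metric for one sample, keyed by anchor locus."""

    sample_id: str
    metric: str
    scores: dict[HeterogeneityLocus, float]


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def compute_pdr(
    reads: Sequence[MethylationRead], params: MetricParams = MetricParams()
) -> Optional[float]:
    """Proportion of discordant reads among reads with enough CpG calls."""
    n_eligible = 0
    n_discordant = 0
    for read in reads:
        if read.n_calls < params.pdr_min_cpgs_per_read:
            continue
        n_eligible += 1
        if "M" in read.states and "U" in read.states:
            n_discordant += 1
    if n_eligible < params.min_depth:
        return None
    return n_discordant / n_eligible


def compute_pm(
    reads: Sequence[MethylationRead],
    quartet: Sequence[int],
    params: MetricParams = MetricParams(),
) -> Optional[float]:
    """Epipolymorphism over a 4-CpG window: 1 - sum of squared pattern freqs."""
    if len(quartet) != 4:
        raise ValueError("pm quartet must have exactly 4 positions")
    quartet = tuple(quartet)
    patterns: Counter[str] = Counter()
    for read in reads:
        lookup = dict(zip(read.positions, read.states))
        try:
            patterns["".join(lookup[p] for p in quartet)] += 1
        except KeyError:
            continue  # read does not cover all four CpGs
    n = sum(patterns.values())
    if n < params.min_depth:
        return None
    return 1.0 - sum((c / n) ** 2 for c in patterns.values())


def compute_mhl(
    reads: Sequence[MethylationRead], params: MetricParams = MetricParams()
) -> Optional[float]:
    """Length-weighted fraction of fully methylated substrings across reads.

    For each substring length l (1..longest read), M_l is the count of
    contiguous all-M substrings of length l over all reads divided by the
    number of length-l substrings offered; the score is sum(l * M_l) /
    sum(l) over lengths with at least one observed substring (weights
    w_l = l).
    """
    if len(reads) < params.min_depth:
        return None
    max_len = max(read.n_calls for read in reads)
    total = np.zeros(max_len + 1, dtype=np.int64)
    meth = np.zeros(max_len + 1, dtype=np.int64)
    for read in reads:
        n = read.n_calls
        lengths = np.arange(1, n + 1)
        total[1 : n + 1] += n - lengths + 1
        # contiguous all-M substrings of length l inside a maximal M-run of
        # length r: max(0, r - l + 1)
        for run_len in _m_run_lengths(read.states):
            ls = np.arange(1, run_len + 1)
            meth[1:run_len + 1] += run_len - ls + 1
    lengths = np.nonzero(total)[0]
    weights = lengths.astype(float)
    fractions = meth[lengths] / total[lengths]
    return float(np.dot(weights, fractions) / weights.sum())


def _m_run_lengths(states: str) -> list[int]:
    runs = []
    current = 0
    for s in states:
        if s == "M":
            current += 1
        elif current:
            runs.append(current)
            current = 0
    if current:
        runs.append(current)
    return runs


def _pair_fractions(
    reads: Sequence[MethylationRead],
    anchor_pos: int,
    params: MetricParams,
) -> Optional[list[float]]:
    """Per-pair fraction of discordant shared CpGs (pairs without shared
    CpGs are dropped). Returns None when depth is insufficient."""
    if len(reads) < params.min_depth:
        return None
    if params.fdrp_max_reads is not None and len(reads) > params.fdrp_max_reads:
        rng = np.random.default_rng(params.rng_seed)
        keep = np.sort(rng.choice(len(reads), size=params.fdrp_max_reads, replace=False))
        reads = [reads[i] for i in keep]
    window = params.fdrp_window_bp
    filtered: list[dict[int, str]] = []
    for read in reads:
        if window is None:
            filtered.append(dict(zip(read.positions, read.states)))
        else:
            filtered.append(
                {
                    p: s
                    for p, s in zip(read.positions, read.states)
                    if abs(p - anchor_pos) <= window
                }
            )
    fractions = []
    for i in range(len(filtered)):
        ci = filtered[i]
        for j in range(i + 1, len(filtered)):
            cj = filtered[j]
            shared = ci.keys() & cj.keys()
            if not shared:
                continue
            mismatched = sum(1 for p in shared if ci[p] != cj[p])
            fractions.append(mismatched / len(shared))
    if not fractions:
        return None
    return fractions


def compute_fdrp(
    reads: Sequence[MethylationRead],
    anchor_pos: int,
    params: MetricParams = MetricParams(),
) -> Optional[float]:
    """Fraction of read pairs discordant at >= 1 shared CpG near the anchor."""
    fractions = _pair_fractions(reads, anchor_pos, params)
    if fractions is None:
        return None
    return sum(1 for f in fractions if f > 0) / len(fractions)


def compute_qfdrp(
    reads: Sequence[MethylationRead],
    anchor_pos: int,
    params: MetricParams = MetricParams(),
) -> Optional[float]:
    """Mean normalized Hamming distance over shared CpGs across read pairs."""
    fractions = _pair_fractions(reads, anchor_pos, params)
    if fractions is None:
        return None
    return sum(fractions) / len(fractions)


# ---------------------------------------------------------------------------
# per-sample scoring
# ---------------------------------------------------------------------------

def _check_sorted(reads: Sequence[MethylationRead]) -> None:
    seen_chroms: dict[str, int] = {}
    prev_chrom = None
    prev_start = -1
    for read in reads:
        if read.chrom != prev_chrom:
            if read.chrom in seen_chroms:
                raise ValueError("reads are not sorted: chromosome groups interleaved")
            seen_chroms[read.chrom] = 1
            prev_chrom = read.chrom
            prev_start = read.start
        elif read.start < prev_start:
            raise ValueError(f"reads are not sorted by position on {read.chrom}")
        else:
            prev_start = read.start


def score_sample(
    sample: SampleMethylome,
    metric: str,
    params: MetricParams = MetricParams(),
) -> SampleScores:
    """Apply one metric kernel at every anchor locus of a sample.

    Anchors are every covered CpG (``pm``: every run of four consecutive
    covered CpGs, sliding by one). Loci whose kernel returns ``None`` are
    omitted.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    _check_sorted(sample.reads)

    by_pos: dict[str, dict[int, list[int]]] = {}
    for idx, read in enumerate(sample.reads):
        chrom_index = by_pos.setdefault(read.chrom, {})
        for pos in read.positions:
            chrom_index.setdefault(pos, []).append(idx)

    reads = sample.reads
    scores: dict[HeterogeneityLocus, float] = {}

    if metric == "pm":
        for chrom, chrom_index in by_pos.items():
            positions = sorted(chrom_index)
            for i in range(len(positions) - 3):
                quartet = tuple(positions[i : i + 4])
                candidates = set(chrom_index[quartet[0]])
                for p in quartet[1:]:
                    candidates &= set(chrom_index[p])
                value = compute_pm([reads[k] for k in sorted(candidates)], quartet, params)
                if value is not None:
                    scores[HeterogeneityLocus("pm", chrom, quartet)] = value
        return SampleScores(sample.sample_id, "pm", scores)

    for chrom, chrom_index in by_pos.items():
        for pos in sorted(chrom_index):
            covering = [reads[k] for k in chrom_index[pos]]
            if metric == "pdr":
                value = compute_pdr(covering, params)
            elif metric == "mhl":
                value = compute_mhl(covering, params)
            elif metric == "fdrp":
                value = compute_fdrp(covering, pos, params)
            else:
                value = compute_qfdrp(covering, pos, params)
            if value is not None:
                scores[HeterogeneityLocus(metric, chrom, (pos,))] = value
    return SampleScores(sample.sample_id, metric, scores)


def assemble_score_matrix(sample_scores: Iterable[SampleScores]) -> pd.DataFrame:
    """Union per-sample scores into a loci x samples matrix (NA = unscored).

    Rows are ordered genomically; the metric name is stored in
    ``DataFrame.attrs["metric"]``.
    """
    sample_scores = list(sample_scores)
    if not sample_scores:
        raise ValueError("need at least one scored sample")
    metrics_seen = {s.metric for s in sample_scores}
    if len(metrics_seen) != 1:
        raise ValueError(f"cannot mix metrics in one matrix: {sorted(metrics_seen)}")
    all_loci: set[HeterogeneityLocus] = set()
    for s in sample_scores:
        all_loci.update(s.scores)
    ordered = sorted(all_loci, key=lambda loc: (loc.chrom, loc.anchor))
    columns = {}
    for s in sample_scores:
        columns[s.sample_id] = [s.scores.get(loc, np.nan) for loc in ordered]
    matrix = pd.DataFrame(columns, index=[loc.key for loc in ordered], dtype=float)
    matrix.index.name = "locus"
    matrix.attrs["metric"] = metrics_seen.pop()
    return matrix
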