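"""Readers and writers for the plain-text formats used throughout the package.

Formats
-------
* Bismark-style coverage TSV: ``chrom  start  end  meth%  count_meth
  count_unmeth`` with 1-based point records (``start == end``); the 0-based
  dialect (``end == start + 1``) is accepted on input.
* Read-level methylation TSV: ``read_id  chrom  positions  states`` where
  ``positions`` is a comma-separated list of 1-based CpG coordinates and
  ``states`` a string over ``{M, U}`` of equal length.
* BED window tables (3 coordinate columns + window-set label).
* Score / feature matrices: TSV, loci as rows, samples as columns, ``NA``
  for missing cells.
* Sample metadata: TSV with ``sample_id`` and ``age`` columns.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "FormatError",
    "CpGSite",
    "MethylationRead",
    "CoverageRecord",
    "SampleMethylome",
    "read_bismark_coverage",
    "write_bismark_coverage",
    "read_readlevel_records",
    "write_readlevel_records",
    "read_bed_windows",
    "write_bed_windows",
    "read_score_matrix",
    "write_score_matrix",
    "read_metadata",
    "write_metadata",
    "aggregate_reads_to_coverage",
]

VALID_STATES = frozenset("MU")


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass(frozen=True)
class CpGSite:
    """A single CpG position (1-based, forward-strand-collapsed)."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class MethylationRead:
    """One sequenced molecule's ordered binary CpG calls on one chromosome."""

    chrom: str
    read_id: str
    positions: tuple[int, ...]
    states: str

    def __post_init__(self) -> None:
        if len(self.positions) < 1:
            raise ValueError("a read needs at least one CpG call")
        if len(self.positions) != len(self.states):
            raise ValueError(
                f"read {self.read_id}: {len(self.positions)} positions vs "
                f"{len(self.states)} states"
            )
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError(f"read {self.read_id}: positions not strictly increasing")
        if not VALID_STATES.issuperset(self.states):
            raise ValueError(f"read {self.read_id}: states outside {{M,U}}")

    @property
    def n_calls(self) -> int:
        return len(self.positions)

    @property
    def calls(self) -> tuple[tuple[int, str], ...]:
        return tuple(zip(self.positions, self.states))

    @property
    def start(self) -> int:
        return self.positions[0]

    @property
    def end(self) -> int:
        return self.positions[-1]


@dataclass(frozen=True)
class CoverageRecord:
    """Per-CpG methylated / unmethylated call counts (Bismark coverage row)."""

    chrom: str
    pos: int
    meth_percent: float
    count_meth: int
    count_unmeth: int

    def __post_init__(self) -> None:
        total = self.count_meth + self.count_unmeth
        if self.count_meth < 0 or self.count_unmeth < 0:
            raise ValueError("negative counts")
        if total < 1:
            raise ValueError("coverage record with zero total count")
        if not 0.0 <= self.meth_percent <= 100.0:
            raise ValueError(f"meth_percent outside [0,100]: {self.meth_percent}")
        expected = 100.0 * self.count_meth / total
        if abs(expected - self.meth_percent) > 0.51:
            raise ValueError(
                f"meth_percent {self.meth_percent} inconsistent with counts "
                f"{self.count_meth}/{self.count_unmeth}"
            )

    @property
    def total(self) -> int:
        return self.count_meth + self.count_unmeth


@dataclass
class SampleMethylome:
    """A sample's read-level calls and per-CpG coverage plus its metadata."""

    sample_id: str
    age: float
    reads: list[MethylationRead] = field(default_factory=list)
    coverage: list[CoverageRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be non-negative")


# ---------------------------------------------------------------------------
# coverage files
# ---------------------------------------------------------------------------

def read_bismark_coverage(path: str | os.PathLike) -> list[CoverageRecord]:
    """Parse a 6-column Bismark coverage file.

    Both the 1-based point dialect (start == end) and the half-open dialect
    (end == start + 1) are accepted; the reported position is ``end``.
    """
    records: list[CoverageRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise FormatError(
                    f"{path}:{lineno}: expected 6 tab-separated columns, got {len(parts)}"
                )
            chrom, start_s, end_s, pct_s, m_s, u_s = parts
            try:
                start, end = int(start_s), int(end_s)
                pct = float(pct_s)
                m, u = int(m_s), int(u_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field ({exc})") from exc
            if end - start not in (0, 1):
                raise FormatError(
                    f"{path}:{lineno}: not a point record (start={start}, end={end})"
                )
            if not 0.0 <= pct <= 100.0:
                raise FormatError(f"{path}:{lineno}: meth% outside [0,100]: {pct}")
            try:
                records.append(CoverageRecord(chrom, end, pct, m, u))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_bismark_coverage(records: Iterable[CoverageRecord], path: str | os.PathLike) -> None:
    """Write coverage records in the 1-based point dialect (start == end)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.pos}\t{rec.meth_percent:.10g}\t"
                f"{rec.count_meth}\t{rec.count_unmeth}\n"
            )


# ---------------------------------------------------------------------------
# read-level records
# ---------------------------------------------------------------------------

def read_readlevel_records(path: str | os.PathLike) -> list[MethylationRead]:
    """Parse the read-level TSV dialect (read_id, chrom, positions, states)."""
    reads: list[MethylationRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, got {len(parts)}"
                )
            read_id, chrom, pos_s, states = parts
            try:
                positions = tuple(int(p) for p in pos_s.split(","))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer position ({exc})") from exc
            try:
                reads.append(MethylationRead(chrom, read_id, positions, states))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return reads


def write_readlevel_records(reads: Iterable[MethylationRead], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for read in reads:
            pos_s = ",".join(str(p) for p in read.positions)
            fh.write(f"{read.read_id}\t{read.chrom}\t{pos_s}\t{read.states}\n")


# ---------------------------------------------------------------------------
# BED window sets
# ---------------------------------------------------------------------------

def write_bed_windows(windows: Sequence, path: str | os.PathLike) -> None:
    """Write windows (chrom/start/end/set_label, 0-based half-open) as BED3+1."""
    with open(path, "w") as fh:
        for w in windows:
            if w.start >= w.end:
                raise ValueError(f"invalid window {w.chrom}:{w.start}-{w.end} (start >= end)")
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.set_label}\n")


def read_bed_windows(path: str | os.PathLike) -> list:
    from .regions import GenomicWindow  # local import avoids a cycle

    windows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 BED columns")
            chrom, start_s, end_s, label = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            try:
                windows.append(GenomicWindow(chrom, start, end, label))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return windows


# ---------------------------------------------------------------------------
# score / feature matrices and metadata
# ---------------------------------------------------------------------------

def write_score_matrix(matrix: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a loci x samples matrix as TSV with an explicit ``locus`` column."""
    if matrix.index.duplicated().any():
        dups = matrix.index[matrix.index.duplicated()].tolist()
        raise ValueError(f"duplicate locus keys: {dups[:5]}")
    out = matrix.copy()
    out.index.name = "locus"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_score_matrix(path: str | os.PathLike) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if matrix.index.duplicated().any():
        dups = matrix.index[matrix.index.duplicated()].tolist()
        raise FormatError(f"{path}: duplicated locus rows: {dups[:5]}")
    matrix.index.name = "locus"
    return matrix


def write_metadata(ages: pd.Series, path: str | os.PathLike) -> None:
    """Write a sample metadata table from a series of ages indexed by sample id."""
    df = pd.DataFrame({"sample_id": ages.index, "age": ages.values})
    df.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | os.PathLike) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns or "age" not in df.columns:
        raise FormatError(f"{path}: metadata needs 'sample_id' and 'age' columns")
    ages = pd.Series(df["age"].astype(float).values, index=df["sample_id"].astype(str))
    ages.index.name = "sample_id"
    return ages


# ---------------------------------------------------------------------------
# read -> coverage aggregation
# ---------------------------------------------------------------------------

def aggregate_reads_to_coverage(reads: Iterable[MethylationRead]) -> list[CoverageRecord]:
    """Collapse read-level calls to per-CpG counts (sorted by chrom, pos)."""
    counts: dict[tuple[str, int], list[int]] = {}
    for read in reads:
        for pos, state in zip(read.positions, read.states):
            key = (read.chrom, pos)
            if key not in counts:
                counts[key] = [0, 0]
            counts[key][0 if state == "M" else 1] += 1
    records = []
    for (chrom, pos), (m, u) in sorted(counts.items()):
        pct = 100.0 * m / (m + u)
        records.append(CoverageRecord(chrom, pos, pct, m, u))
    return records
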