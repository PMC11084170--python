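"""Synthetic RRBS-like cohort generator with planted age-dependent loci.

The simulator lays loci on a toy two-chromosome genome (>= 1 kb apart so
window segmentation maps each locus to unambiguous windows) and draws, per
sample and locus, a negative-binomial number of reads. Four locus classes
are planted:

``het_pos`` / ``het_neg``
    Each read is a coherent haplotype (all-M with probability ``p_base``,
    else all-U) whose calls are then independently flipped with probability
    eps(age); eps increases (het_pos) or decreases (het_neg) with age, which
    raises pdr/pm/fdrp/qfdrp and lowers mhl in the same direction.
``mean_drift``
    Per-read, per-CpG Bernoulli calls with a logit-linear age-dependent
    methylation probability; the drift direction alternates between loci.
    The link is centred so that the methylation level crosses 0.5 mid-age,
    keeping read-level disorder approximately age-symmetric.
``null``
    Haplotype reads with age-constant flip noise.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .io import (
    MethylationRead,
    SampleMethylome,
    aggregate_reads_to_coverage,
    write_bismark_coverage,
    write_metadata,
    write_readlevel_records,
)

__all__ = ["SimulationConfig", "simulate_cohort", "iter_cohort", "simulate_ages", "export_cohort"]

LOCUS_CLASSES = ("het_pos", "het_neg", "mean_drift", "null")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort generator (all randomness from ``seed``)."""

    seed: int = 0
    n_samples: int = 180
    age_low: float = 19.0
    age_high: float = 56.0
    n_loci_het_pos: int = 50
    n_loci_het_neg: int = 50
    n_loci_mean: int = 50
    n_loci_null: int = 500
    cpgs_per_locus: int = 6
    cpg_spacing_bp: int = 15
    locus_spacing_bp: int = 1000
    coverage_mean: float = 24.0
    coverage_dispersion: float = 8.0
    read_span_min: int = 4
    read_span_max: int = 6
    #: eps(age) = clamp(eps0 + b1*a + b2*a^2, 0, 0.5), a = age normalized to [0,1]
    disorder_link: tuple[float, float, float] = (0.03, 0.22, 0.15)
    #: logit p(age) = mu0 + direction * gamma * (a - 0.5)
    mean_link: tuple[float, float] = (0.0, 2.8)
    p_base: float = 0.5

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.n_loci_total < 1:
            raise ValueError("at least one locus must be simulated")
        if not self.age_low < self.age_high:
            raise ValueError("age_low must be < age_high")
        if not 1 <= self.read_span_min <= self.read_span_max <= self.cpgs_per_locus:
            raise ValueError("need 1 <= read_span_min <= read_span_max <= cpgs_per_locus")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage parameters must be positive")
        eps0, b1, b2 = self.disorder_link
        for a in (0.0, 0.5, 1.0):
            if not 0.0 <= min(0.5, max(0.0, eps0 + b1 * a + b2 * a * a)) <= 0.5:
                raise ValueError("disorder link escapes [0, 0.5]")

    @property
    def n_loci_total(self) -> int:
        return self.n_loci_het_pos + self.n_loci_het_neg + self.n_loci_mean + self.n_loci_null

    def epsilon(self, a: float) -> float:
        """Flip probability at normalized age ``a`` in [0, 1]."""
        eps0, b1, b2 = self.disorder_link
        return min(0.5, max(0.0, eps0 + b1 * a + b2 * a * a))

    def normalize_age(self, age: float) -> float:
        return (age - self.age_low) / (self.age_high - self.age_low)


def _build_truth(config: SimulationConfig) -> pd.DataFrame:
    """Assign classes and coordinates to loci (classes shuffled over positions)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    classes = (
        ["het_pos"] * config.n_loci_het_pos
        + ["het_neg"] * config.n_loci_het_neg
        + ["mean_drift"] * config.n_loci_mean
        + ["null"] * config.n_loci_null
    )
    classes = [classes[i] for i in rng.permutation(len(classes))]
    n = len(classes)
    n_chr1 = (n + 1) // 2
    rows = []
    for i, cls in enumerate(classes):
        chrom = "chr1" if i < n_chr1 else "chr2"
        rank = i if i < n_chr1 else i - n_chr1
        start = config.locus_spacing_bp * (rank + 1) + 1  # 1-based first CpG
        positions = tuple(start + j * config.cpg_spacing_bp for j in range(config.cpgs_per_locus))
        direction = 1 if rng.random() < 0.5 else -1
        null_p = float(rng.uniform(0.2, 0.8))
        rows.append(
            {
                "locus_id": f"L{i:04d}",
                "class": cls,
                "chrom": chrom,
                "first_cpg": positions[0],
                "last_cpg": positions[-1],
                "p_base": config.p_base,
                "drift_direction": direction if cls == "mean_drift" else 0,
                "null_p": null_p if cls == "null" else math.nan,
            }
        )
    truth = pd.DataFrame(rows)
    truth = truth.sort_values(["chrom", "first_cpg"], kind="mergesort").reset_index(drop=True)
    return truth


def simulate_ages(config: SimulationConfig) -> pd.Series:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    ages = rng.uniform(config.age_low, config.age_high, size=config.n_samples)
    ids = [f"S{i:03d}" for i in range(config.n_samples)]
    return pd.Series(np.round(ages, 3), index=pd.Index(ids, name="sample_id"), name="age")


def _simulate_sample(
    config: SimulationConfig,
    truth_records: list[dict],
    sample_id: str,
    age: float,
    rng: np.random.Generator,
) -> SampleMethylome:
    a = config.normalize_age(age)
    sigmoid = lambda x: 1.0 / (1.0 + math.exp(-x))
    mu0, gamma = config.mean_link
    reads: list[MethylationRead] = []
    counter = 0
    nb_n = config.coverage_dispersion
    nb_p = nb_n / (nb_n + config.coverage_mean)
    for row in truth_records:
        m = int(rng.negative_binomial(nb_n, nb_p))
        if m == 0:
            continue
        positions = np.arange(
            row["first_cpg"],
            row["first_cpg"] + config.cpgs_per_locus * config.cpg_spacing_bp,
            config.cpg_spacing_bp,
        )
        spans = rng.integers(config.read_span_min, config.read_span_max + 1, size=m)
        starts = np.floor(rng.random(m) * (config.cpgs_per_locus - spans + 1)).astype(int)
        cls = row["class"]
        if cls in ("het_pos", "het_neg", "null"):
            if cls == "null":
                eps = config.epsilon(0.0)
                p_hap = row["null_p"]
            else:
                eps = config.epsilon(a if cls == "het_pos" else 1.0 - a)
                p_hap = row["p_base"]
            hap = rng.random(m) < p_hap  # True = all-M haplotype
            flips = rng.random((m, config.read_span_max)) < eps
            for k in range(m):
                span = int(spans[k])
                meth = np.full(span, hap[k]) ^ flips[k, :span]
                reads.append(_make_read(row["chrom"], counter + k, positions, starts[k], meth))
        else:  # mean_drift
            p = sigmoid(mu0 + row["drift_direction"] * gamma * (a - 0.5))
            draws = rng.random((m, config.read_span_max)) < p
            for k in range(m):
                span = int(spans[k])
                reads.append(
                    _make_read(row["chrom"], counter + k, positions, starts[k], draws[k, :span])
                )
        counter += m
    # sort within the sample so downstream scoring sees position-sorted input
    reads.sort(key=lambda r: (r.chrom, r.start))
    coverage = aggregate_reads_to_coverage(reads)
    return SampleMethylome(sample_id, float(age), reads, coverage)


def _make_read(chrom, number, positions, start, meth) -> MethylationRead:
    span = len(meth)
    pos = tuple(int(p) for p in positions[start : start + span])
    states = "".join("M" if x else "U" for x in meth)
    return MethylationRead(chrom, f"r{number}", pos, states)


def iter_cohort(config: SimulationConfig) -> Iterator[SampleMethylome]:
    """Yield simulated samples one at a time (memory-friendly order S000..)."""
    truth_records = _build_truth(config).to_dict("records")
    ages = simulate_ages(config)
    seeds = np.random.SeedSequence([config.seed, 303]).spawn(config.n_samples)
    for (sample_id, age), seed in zip(ages.items(), seeds):
        yield _simulate_sample(
            config, truth_records, sample_id, float(age), np.random.default_rng(seed)
        )


def simulate_cohort(config: SimulationConfig) -> tuple[list[SampleMethylome], pd.DataFrame]:
    """Simulate the full cohort; returns (samples, truth table).

    The truth table has one row per locus with its class and planted
    parameters; classes partition the loci.
    """
    samples = list(iter_cohort(config))
    return samples, _build_truth(config)


def export_cohort(samples: list[SampleMethylome], outdir: str | os.PathLike) -> dict[str, str]:
    """Write per-sample read-level and coverage files plus a metadata table.

    Returns a mapping of logical names to written paths.
    """
    if not samples:
        raise ValueError("cannot export an empty cohort")
    os.makedirs(outdir, exist_ok=True)
    written = {}
    ages = {}
    for sample in samples:
        reads_path = os.path.join(outdir, f"{sample.sample_id}.reads.tsv")
        cov_path = os.path.join(outdir, f"{sample.sample_id}.cov.tsv")
        write_readlevel_records(sample.reads, reads_path)
        write_bismark_coverage(sample.coverage, cov_path)
        written[f"{sample.sample_id}.reads"] = reads_path
        written[f"{sample.sample_id}.cov"] = cov_path
        ages[sample.sample_id] = sample.age
    meta_path = os.path.join(outdir, "metadata.tsv")
    write_metadata(pd.Series(ages, name="age"), meta_path)
    written["metadata"] = meta_path
    return written


def truth_locus_lookup(truth: pd.DataFrame):
    """Return a function mapping (chrom, pos) to the owning locus row index,
    or None if the position falls outside every locus."""
    spans: dict[str, list[tuple[int, int, int]]] = {}
    for idx, row in truth.iterrows():
        spans.setdefault(row["chrom"], []).append((row["first_cpg"], row["last_cpg"], idx))
    for v in spans.values():
        v.sort()

    def lookup(chrom: str, pos: int):
        import bisect

        entries = spans.get(chrom)
        if not entries:
            return None
        i = bisect.bisect_right(entries, (pos, float("inf"), float("inf"))) - 1
        if i >= 0 and entries[i][0] <= pos <= entries[i][1]:
            return entries[i][2]
        return None

    return lookup
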