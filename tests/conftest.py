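from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("ci", deadline=None, derandomize=True, database=None)
_hyp_settings.load_profile("ci")

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from wshclock.io import MethylationRead, SampleMethylome
from wshclock.simulate import SimulationConfig, simulate_cohort


def make_read(positions, states, chrom="chr1", read_id="r0"):
    return MethylationRead(chrom, read_id, tuple(positions), states)


def make_reads(pattern_list, positions=(10, 25, 40, 55), chrom="chr1"):
    """Build reads all covering the same positions from a list of state strings."""
    return [
        make_read(positions[: len(states)], states, chrom=chrom, read_id=f"r{i}")
        for i, states in enumerate(pattern_list)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_read_set(rng, max_reads=12, max_cpgs=8, chrom="chr1"):
    """A random set of overlapping reads on a shared CpG grid; every read
    covers the anchor (first grid position)."""
    n_cpgs = int(rng.integers(1, max_cpgs + 1))
    grid = np.sort(rng.choice(np.arange(1, 200), size=n_cpgs, replace=False))
    n_reads = int(rng.integers(2, max_reads + 1))
    reads = []
    for i in range(n_reads):
        hi = int(rng.integers(1, n_cpgs + 1))
        pos = tuple(int(p) for p in grid[:hi])
        states = "".join(rng.choice(["M", "U"], size=hi))
        reads.append(MethylationRead(chrom, f"r{i}", pos, states))
    return reads, int(grid[0])


@pytest.fixture(scope="session")
def small_cohort():
    """A small but informative cohort shared by the mid-weight tests."""
    config = SimulationConfig(
        seed=7,
        n_samples=40,
        n_loci_het_pos=10,
        n_loci_het_neg=10,
        n_loci_mean=10,
        n_loci_null=60,
    )
    samples, truth = simulate_cohort(config)
    return config, samples, truth


@pytest.fixture(scope="session")
def small_cohort_ages(small_cohort):
    _, samples, _ = small_cohort
    return pd.Series({s.sample_id: s.age for s in samples}, name="age")
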