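"""Per-locus age correlation, FDR adjustment, threshold selection, and the
quadratic global-trend summary of per-sample mean scores."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "correlate_with_age",
    "bh_adjust",
    "LociSubsets",
    "select_loci",
    "TrendFit",
    "mean_score_trend",
]

logger = logging.getLogger(__name__)

#: below this sample count the Spearman p-value is computed by exact
#: permutation enumeration rather than the t-approximation
EXACT_PERMUTATION_MAX_N = 8


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    target = abs(rho_obs) - 1e-12
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        r = np.corrcoef(rx, perm)[0, 1]
        if abs(r) >= target:
            count += 1
        total += 1
    return count / total


def correlate_with_age(
    matrix: pd.DataFrame,
    ages: pd.Series,
    method: str = "spearman",
    min_samples: int = 3,
    adjust: bool = True,
) -> pd.DataFrame:
    """Correlate each matrix row with age (pairwise-complete observations).

    Returns a frame indexed by locus with columns ``coef``, ``n``,
    ``p_value`` and (if ``adjust``) BH-adjusted ``p_adj``. Rows with fewer
    than ``min_samples`` complete pairs, or a constant score or age vector,
    are skipped with a log notice.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"method must be 'spearman' or 'pearson', got {method!r}")
    ages = ages.reindex(matrix.columns)
    if ages.isna().any():
        missing = ages.index[ages.isna()].tolist()
        raise ValueError(f"samples missing from metadata: {missing[:5]}")
    age_arr = ages.to_numpy(dtype=float)
    values = matrix.to_numpy(dtype=float)
    keys, coefs, ns, pvals = [], [], [], []
    n_skipped = 0
    for i, locus in enumerate(matrix.index):
        row = values[i]
        mask = ~np.isnan(row)
        n = int(mask.sum())
        if n < min_samples:
            n_skipped += 1
            continue
        x, y = row[mask], age_arr[mask]
        if np.all(x == x[0]) or np.all(y == y[0]):
            n_skipped += 1
            continue
        if method == "spearman":
            rho, p = stats.spearmanr(x, y)
            if n <= EXACT_PERMUTATION_MAX_N:
                p = _spearman_exact_p(x, y, rho)
            coef = float(rho)
        else:
            res = stats.pearsonr(x, y)
            coef, p = float(res.statistic), float(res.pvalue)
        keys.append(locus)
        coefs.append(coef)
        ns.append(n)
        pvals.append(float(p))
    if n_skipped:
        logger.info("correlate_with_age: skipped %d constant/underpowered loci", n_skipped)
    records = pd.DataFrame(
        {"coef": coefs, "n": ns, "p_value": pvals},
        index=pd.Index(keys, name=matrix.index.name or "locus"),
    )
    if adjust and len(records):
        records["p_adj"] = bh_adjust(records["p_value"].to_numpy())
    elif adjust:
        records["p_adj"] = np.array([], dtype=float)
    return records


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


@dataclass
class LociSubsets:
    """Age-correlated locus subsets at the standard thresholds."""

    negative: list[str] = field(default_factory=list)
    positive: list[str] = field(default_factory=list)
    high: list[str] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {
            "negative": len(self.negative),
            "positive": len(self.positive),
            "high": len(self.high),
        }


def select_loci(
    records: pd.DataFrame,
    cor_low: float = 0.25,
    cor_high: float = 0.5,
    alpha: float = 0.05,
) -> LociSubsets:
    """Partition correlation records into negative / positive / high subsets.

    negative: coef <= -cor_low, p_adj < alpha; positive: coef >= cor_low,
    p_adj < alpha; high: |coef| >= cor_high, p_adj < alpha.
    """
    if len(records) == 0:
        return LociSubsets()
    if "p_adj" not in records.columns:
        raise ValueError("records need a 'p_adj' column (run correlate_with_age with adjust=True)")
    sig = records["p_adj"] < alpha
    coef = records["coef"]
    return LociSubsets(
        negative=records.index[sig & (coef <= -cor_low)].tolist(),
        positive=records.index[sig & (coef >= cor_low)].tolist(),
        high=records.index[sig & (coef.abs() >= cor_high)].tolist(),
    )


@dataclass(frozen=True)
class TrendFit:
    """Least-squares quadratic fit of per-sample mean score against age."""

    intercept: float
    linear: float
    quadratic: float

    def predict(self, age: np.ndarray) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        return self.intercept + self.linear * age + self.quadratic * age**2


def mean_score_trend(
    matrix: pd.DataFrame,
    subset: Iterable[str],
    ages: pd.Series,
) -> tuple[pd.Series, TrendFit]:
    """Per-sample mean over a locus subset plus its quadratic age trend.

    Samples whose subset scores are all NA are omitted from the fit.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    sub = matrix.loc[subset]
    means = sub.mean(axis=0, skipna=True)
    means.name = "mean_score"
    valid = means.notna()
    x = ages.reindex(means.index[valid]).to_numpy(dtype=float)
    y = means[valid].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 samples with non-NA means for a quadratic fit")
    c2, c1, c0 = np.polyfit(x, y, deg=2)
    return means, TrendFit(intercept=float(c0), linear=float(c1), quadratic=float(c2))
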