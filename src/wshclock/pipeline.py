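"""End-to-end orchestration: score -> correlate -> select -> model, for the
heterogeneity route, the window route, and the two reciprocal-filtering
combinations. Reports are plain JSON-able dicts whose every count can be
re-derived from the emitted intermediates."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import association, metrics, models, regions
from .io import SampleMethylome
from .metrics import MetricParams, parse_locus_key

__all__ = [
    "AnalysisConfig",
    "run_wsh_pipeline",
    "run_region_pipeline",
    "run_combined_wsh_on_windows",
    "run_combined_region_on_loci",
]

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Thresholds, schemes, folds and seeds for the end-to-end runs."""

    cor_low: float = 0.25
    cor_high: float = 0.5
    alpha: float = 0.05
    schemes: list = field(default_factory=regions.default_schemes)
    min_cov: int = 5
    split_fraction: float = 0.8
    rf_cv_folds: int = 5
    rf_stability_iterations: int = 5
    rf_stability_folds: int = 10
    lasso_cv_folds: int = 10
    rfe_tol: float = 0.05
    seed: int = 0
    metric_params: MetricParams = field(default_factory=MetricParams)
    rf_param_grid: Optional[dict] = None
    wsh_metrics: tuple = metrics.METRICS

    def __post_init__(self) -> None:
        for name in ("cor_low", "cor_high", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        self.schemes = [tuple(s) for s in self.schemes]

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        mp = raw.pop("metric_params", None)
        cfg = cls(**raw)
        if mp:
            cfg.metric_params = MetricParams(**mp)
        return cfg

    def to_dict(self) -> dict:
        out = asdict(self)
        out["schemes"] = [list(s) for s in self.schemes]
        out["wsh_metrics"] = list(self.wsh_metrics)
        return out

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _ages_of(samples: Sequence[SampleMethylome]) -> pd.Series:
    return pd.Series(
        {s.sample_id: s.age for s in samples}, name="age"
    ).rename_axis("sample_id")


def _provenance(config: AnalysisConfig) -> dict:
    return {"config_hash": config.hash(), "seed": config.seed}


def score_metric_matrix(
    samples: Sequence[SampleMethylome],
    metric: str,
    params: MetricParams,
) -> pd.DataFrame:
    """Score every sample with one metric and assemble the locus matrix."""
    return metrics.assemble_score_matrix(
        metrics.score_sample(s, metric, params) for s in samples
    )


def run_wsh_pipeline(
    samples: Sequence[SampleMethylome],
    config: AnalysisConfig,
    score_matrices: Optional[Mapping[str, pd.DataFrame]] = None,
) -> dict:
    """For each metric: score, Spearman-correlate, select ``high``, RF clock.

    Metrics whose ``high`` subset is empty (or below 2 features) are skipped
    with a warning rather than failing the run. Precomputed score matrices
    may be passed to avoid rescoring.
    """
    ages = _ages_of(samples)
    report: dict = {"kind": "wsh", "metrics": {}, **_provenance(config)}
    split = models.split_train_test(ages.index, config.split_fraction, config.seed)
    report["train_samples"], report["test_samples"] = split
    for metric in config.wsh_metrics:
        if score_matrices is not None and metric in score_matrices:
            matrix = score_matrices[metric]
        else:
            matrix = score_metric_matrix(samples, metric, config.metric_params)
        records = association.correlate_with_age(matrix, ages, method="spearman")
        subsets = association.select_loci(records, config.cor_low, config.cor_high, config.alpha)
        section = {
            "n_loci": int(matrix.shape[0]),
            "n_correlated": int(len(records)),
            "subset_counts": subsets.counts(),
        }
        logger.info(
            "%s: %d loci -> neg %d / pos %d / high %d",
            metric, matrix.shape[0], *subsets.counts().values(),
        )
        if len(subsets.high) < 2:
            section["skipped"] = "fewer than 2 high-correlation loci"
            logger.warning("metric %s skipped: %s", metric, section["skipped"])
            report["metrics"][metric] = section
            continue
        fit = models.fit_wsh_rf_clock(
            matrix.loc[subsets.high],
            ages,
            seed=config.seed,
            param_grid=config.rf_param_grid,
            cv_folds=config.rf_cv_folds,
            stability_iterations=config.rf_stability_iterations,
            stability_folds=config.rf_stability_folds,
            split=split,
        )
        section["model"] = fit.model.to_dict()
        section["cv"] = fit.cv_evaluation.to_dict(include_predictions=False)
        section["test"] = fit.test_evaluation.to_dict(include_predictions=False)
        section["train_refit"] = fit.train_evaluation.to_dict(include_predictions=False)
        report["metrics"][metric] = section
    return report


def _region_chrom_sizes(samples: Sequence[SampleMethylome]) -> dict[str, int]:
    """Infer toy-genome chromosome sizes from the observed coverage."""
    sizes: dict[str, int] = {}
    for s in samples:
        for rec in s.coverage:
            if rec.pos > sizes.get(rec.chrom, 0):
                sizes[rec.chrom] = rec.pos
    return {c: p + 200 for c, p in sorted(sizes.items())}


def run_region_pipeline(
    samples: Sequence[SampleMethylome],
    config: AnalysisConfig,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> dict:
    """Segment, average, deduplicate, Pearson-filter and LASSO-fit every
    configured window scheme; emits a per-scheme summary with non-zero
    coefficient counts."""
    ages = _ages_of(samples)
    coverage = {s.sample_id: s.coverage for s in samples}
    if chrom_sizes is None:
        chrom_sizes = _region_chrom_sizes(samples)
    report: dict = {"kind": "region", "schemes": {}, **_provenance(config)}
    split = models.split_train_test(ages.index, config.split_fraction, config.seed)
    report["train_samples"], report["test_samples"] = split
    for scheme in config.schemes:
        label = regions.scheme_label(scheme)
        windows = regions.segment_genome(chrom_sizes, scheme)
        matrix = regions.window_average_methylation(coverage, windows, config.min_cov)
        matrix, dedup_map = regions.deduplicate_windows(matrix)
        section = {
            "n_windows": len(windows),
            "n_determined": int(matrix.shape[0] + len(dedup_map)),
            "n_deduplicated": int(matrix.shape[0]),
        }
        records = association.correlate_with_age(matrix, ages, method="pearson")
        subsets = association.select_loci(records, config.cor_high, config.cor_high, config.alpha)
        order = {k: i for i, k in enumerate(matrix.index)}
        selected = sorted(set(subsets.negative) | set(subsets.positive), key=order.__getitem__)
        section["n_age_correlated"] = len(selected)
        if len(selected) < 1:
            section["skipped"] = "no age-correlated windows survive the filter"
            logger.warning("scheme %s skipped: %s", label, section["skipped"])
            report["schemes"][label] = section
            continue
        try:
            fit = models.fit_region_lasso_clock(
                matrix.loc[selected],
                ages,
                seed=config.seed,
                cv_folds=config.lasso_cv_folds,
                split=split,
            )
        except ValueError as exc:
            section["skipped"] = str(exc)
            logger.warning("scheme %s skipped: %s", label, exc)
            report["schemes"][label] = section
            continue
        section["model"] = fit.model.to_dict()
        section["n_nonzero"] = fit.model.n_nonzero
        section["cv"] = fit.cv_evaluation.to_dict(include_predictions=False)
        section["test"] = fit.test_evaluation.to_dict(include_predictions=False)
        section["train_refit"] = fit.train_evaluation.to_dict(include_predictions=False)
        section["selected_windows"] = selected
        report["schemes"][label] = section
    return report


def _loci_in_windows(locus_keys: Sequence[str], window_keys: Sequence[str]) -> list[str]:
    """Locus keys whose anchor CpGs fall inside any of the given windows
    (1-based CpG p is inside 0-based half-open [s, e) iff s < p <= e)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for wkey in window_keys:
        chrom, _, span = wkey.rpartition(":")
        start_s, end_s = span.split("-")
        by_chrom.setdefault(chrom, []).append((int(start_s), int(end_s)))
    kept = []
    for lkey in locus_keys:
        chrom, anchor = parse_locus_key(lkey)
        intervals = by_chrom.get(chrom, ())
        if any(s < p <= e for p in anchor for (s, e) in intervals):
            kept.append(lkey)
    return kept


def run_combined_wsh_on_windows(
    samples: Sequence[SampleMethylome],
    config: AnalysisConfig,
    metric: str,
    selected_windows: Sequence[str],
    score_matrix: Optional[pd.DataFrame] = None,
) -> dict:
    """Heterogeneity clock restricted to loci inside age-correlated windows
    of a prior region run (any-overlap of the anchor CpGs)."""
    ages = _ages_of(samples)
    if score_matrix is None:
        score_matrix = score_metric_matrix(samples, metric, config.metric_params)
    report: dict = {"kind": "combined_wsh_on_windows", "metric": metric, **_provenance(config)}
    kept = _loci_in_windows(list(score_matrix.index), selected_windows)
    report["n_loci_in_windows"] = len(kept)
    if len(kept) < 2:
        report["skipped"] = "empty or singleton intersection of loci and windows"
        return report
    split = models.split_train_test(ages.index, config.split_fraction, config.seed)
    fit = models.fit_wsh_rf_clock(
        score_matrix.loc[kept],
        ages,
        seed=config.seed,
        param_grid=config.rf_param_grid,
        cv_folds=config.rf_cv_folds,
        stability_iterations=config.rf_stability_iterations,
        stability_folds=config.rf_stability_folds,
        split=split,
    )
    report["model"] = fit.model.to_dict()
    report["cv"] = fit.cv_evaluation.to_dict(include_predictions=False)
    report["test"] = fit.test_evaluation.to_dict(include_predictions=False)
    return report


def run_combined_region_on_loci(
    samples: Sequence[SampleMethylome],
    config: AnalysisConfig,
    scheme: tuple,
    high_loci: Sequence[str],
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> dict:
    """Window clock restricted to windows overlapping high-correlation
    heterogeneity loci (any anchor CpG inside the window)."""
    ages = _ages_of(samples)
    coverage = {s.sample_id: s.coverage for s in samples}
    if chrom_sizes is None:
        chrom_sizes = _region_chrom_sizes(samples)
    windows = regions.segment_genome(chrom_sizes, scheme)
    matrix = regions.window_average_methylation(coverage, windows, config.min_cov)
    matrix, _ = regions.deduplicate_windows(matrix)
    anchors: list[tuple[str, int]] = []
    for lkey in high_loci:
        chrom, pos = parse_locus_key(lkey)
        anchors.extend((chrom, p) for p in pos)
    kept = []
    for wkey in matrix.index:
        chrom, _, span = wkey.rpartition(":")
        start_s, end_s = span.split("-")
        s, e = int(start_s), int(end_s)
        if any(c == chrom and s < p <= e for c, p in anchors):
            kept.append(wkey)
    report: dict = {
        "kind": "combined_region_on_loci",
        "scheme": regions.scheme_label(scheme),
        "n_windows_on_loci": len(kept),
        **_provenance(config),
    }
    if len(kept) < 1:
        report["skipped"] = "no window overlaps the given loci"
        return report
    split = models.split_train_test(ages.index, config.split_fraction, config.seed)
    try:
        fit = models.fit_region_lasso_clock(
            matrix.loc[kept], ages, seed=config.seed, cv_folds=config.lasso_cv_folds, split=split
        )
    except ValueError as exc:
        report["skipped"] = str(exc)
        return report
    report["model"] = fit.model.to_dict()
    report["cv"] = fit.cv_evaluation.to_dict(include_predictions=False)
    report["test"] = fit.test_evaluation.to_dict(include_predictions=False)
    return report
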