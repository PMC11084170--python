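# wshclock

Tools for building age-prediction ("epigenetic clock") models from
read-level bisulfite sequencing data using within-sample methylation
heterogeneity (WSH) scores, with a synthetic RRBS-like cohort simulator
providing fully reproducible test inputs.

## What it does

* **Five WSH scores** computed per locus from read-level CpG calls:
  * `pdr` — proportion of discordant reads (reads carrying both methylated
    and unmethylated calls);
  * `pm` — epipolymorphism over 4-CpG windows (1 − Σ pattern-frequency²);
  * `mhl` — methylation haplotype load (length-weighted fraction of fully
    methylated substrings);
  * `fdrp` / `qfdrp` — fraction of discordant read pairs / mean normalized
    Hamming distance over shared CpGs.
* **Age association**: Spearman (scores) or Pearson (windows) correlation
  per locus with Benjamini–Hochberg adjustment, threshold subsets
  (|cor| ≥ 0.25 positive/negative, |cor| ≥ 0.5 "high"), and a quadratic
  global-trend fit of per-sample mean score against age.
* **Region features**: genome segmentation into 14 window sets (fixed bins
  9 kb…100 bp plus a 100 bp / 20 bp sliding scheme, sex chromosomes
  excluded), per-window mean methylation with a coverage ≥ 5 filter,
  missingness filtering and row deduplication.
* **Clock models**: random-forest clocks on high-correlation heterogeneity
  loci (grid-searched by 5-fold CV, stability via repeated 10-fold CV),
  LASSO clocks on window methylation (alpha by 10-fold CV, non-zero
  coefficient counts reported), and recursive feature elimination with a
  5 % MAE tolerance for the minimal feature set.
* **Simulator**: age-annotated cohorts with planted heterogeneity loci
  (haplotype reads with age-dependent flip noise), mean-drift loci
  (logit-linear age link), and null loci, under negative-binomial RRBS-like
  coverage; all outputs byte-reproducible from one seed.

## File formats

Plain text throughout: Bismark-style 6-column coverage TSV, a read-level
TSV (`read_id  chrom  comma-separated-positions  M/U-string`), BED3+label
window tables, TSV score/feature matrices (`NA` for missing), and a
`sample_id / age` metadata TSV.

## CLI

```bash
wshclock simulate --seed 1 --outdir data/                 # synthetic cohort
wshclock score --metric pdr --data-dir data/ --out pdr.tsv
wshclock correlate --matrix pdr.tsv --metadata data/metadata.tsv --out rec.tsv
wshclock windows --data-dir data/ --scheme 100_20 --out win.tsv
wshclock clock-wsh --matrix high.tsv --metadata data/metadata.tsv --out clock.json
wshclock clock-region --matrix win.tsv --metadata data/metadata.tsv --out clock.json
wshclock rfe --matrix win.tsv --metadata data/metadata.tsv --out rfe.tsv
wshclock run-all --data-dir data/ --outdir reports/       # both pipelines
```

Exit codes: 0 success, 2 configuration error, 3 data error. `run-all` and
the analysis subcommands accept a YAML config (thresholds, schemes, folds,
seeds); see `wshclock.pipeline.AnalysisConfig` for the fields.

## Layout

```
src/wshclock/
  io.py           readers/writers for all text formats
  simulate.py     synthetic cohort generator + truth table
  metrics.py      the five WSH score kernels and per-sample scoring
  association.py  correlation, BH adjustment, subsets, trend fit
  regions.py      window schemes and window methylation matrices
  models.py       RF / LASSO clocks, evaluation, RFE
  pipeline.py     end-to-end orchestrated runs and reports
  cli.py          click command group
tests/            pytest suite; tests/oracles.py holds independent
                  brute-force reference implementations of the kernels
scripts/acceptance.py
```
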