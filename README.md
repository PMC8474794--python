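# matrisig

Tools for deriving and evaluating prognostic RNA signatures from
two-condition expression arrays:

* **Rank-product differential expression** with permutation-based,
  two-sided min-p calibrated p-values and pfp estimates
  (`matrisig.rankprod`), including an exhaustive-permutation mode for
  small designs.
* **Gene-set filtering and ortholog mapping** with a bundled matrisome
  symbol list (`matrisig.genesets`).
* **Fold-change centroids** and two cohort stratification schemes —
  sign-of-Pearson-correlation against the transformed centroid, and a
  weighted median-split composite score (`matrisig.signature`).
* **Survival evaluation** — administrative follow-up truncation,
  Kaplan–Meier curves, a log-rank test exposing per-group
  observed/expected counts, and multivariate Cox proportional-hazards
  fits via lifelines (`matrisig.survival`).
* **Signature refinement** — per-gene median-split log-rank screening
  across configurable cohort subgroups, joint Benjamini–Hochberg
  correction, driver/suppressor concordance calls and a reversed-sign
  compact centroid (`matrisig.refinement`).
* **Synthetic data generators** for both regimes: small-replicate
  arrays with planted fold changes and survival cohorts with a latent
  centroid-like risk state (`matrisig.simulate`).
* An **end-to-end pipeline** (`matrisig.pipeline`) and a CLI tying the
  stages together.

## Test

```sh
python -m pytest tests/
```

The suite includes unit oracles (full-enumeration rank products,
hand-computed Kaplan–Meier / log-rank / BH values), hypothesis property
tests, simulation-based calibration checks and an acceptance suite
(`tests/test_acceptance.py`).

## CLI

Every stage is a subcommand; all randomness is seeded.

```sh
# differential expression (TSV matrix + sample->condition map)
matrisig de --expr expr.tsv --conditions cond.tsv --n-perm 1000 --seed 1 --out de.tsv

# significance + matrisome filter, centroid construction
matrisig filter --de de.tsv --out de_filtered.tsv
matrisig centroid --de de_filtered.tsv --out centroid.tsv

# cohort stratification and survival evaluation
matrisig stratify --cohort cohort.tsv --centroid centroid.tsv --method centroid --out strat.tsv
matrisig survive --clinical clinical.tsv --groups strat.tsv --endpoint DMFS \
    --cutoff-months 120 --covariates er,ln,grade,age,size --out cox.tsv

# per-gene subgroup screen and refinement
matrisig screen --cohort cohort.tsv --clinical clinical.tsv --centroid centroid.tsv --out screen.tsv
matrisig refine --screen screen.tsv --centroid centroid.tsv --out centroid_refined.tsv

# synthetic data
matrisig simulate fibroblast --spec spec.yaml --seed 1 --out-prefix sim
matrisig simulate cohort --spec cohort_spec.yaml --seed 1 --out-prefix sim

# full pipeline from a YAML config
matrisig run --config config.yaml
```

A fully synthetic pipeline config needs only simulation blocks:

```yaml
seed: 42
n_perm: 1000
out_dir: out
simulate_fibroblast:
  n_features: 200
  planted: [[0, 4.0], [1, -3.2]]
simulate_cohort:
  n_patients: 1500
  hr_true: 2.42
  frac_centroid_like: 0.4
```

## File formats

All I/O is plain TSV: expression matrices (first column feature id,
one column per sample), two-column condition and annotation maps,
centroids (gene, weight), clinical tables (`sample_id, time_months,
event, endpoint, er, ln, grade, age_gt50, size_gt20mm, subtype`), and
long-format screen matrices (`gene, subgroup, raw_p, adj_p,
direction`). Subgroup definitions and pipeline configs are YAML.
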