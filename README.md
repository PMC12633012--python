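# alveoniche

Analytical toolkit for early-postnatal lung transcriptomics: AT2 cell-state
signature construction and scoring, specimen stratification with
equal-weight composition analysis, spatial niche detection with
cross-section alignment, cell-type colocalization statistics, and
developmental maturation scoring — exercised end-to-end on a fully seeded
synthetic data generator with known ground truth.

## Modules

| module | what it does |
|---|---|
| `alveoniche.synthetic` | Seeded synthetic snRNA-seq cohorts (gamma-Poisson counts, three specimen classes with distinct FMO5+/CFTR+ AT2-state mixtures), staged fetal→postnatal series with on/off programs and disease-arrest specimens, and multi-section spatial maps with hard-core spacing and planted regions |
| `alveoniche.qc` | QC filtering (feature/molecule/mito/ribo thresholds with literal boundary semantics), log-CP10K normalization, specimen classification by AT2-state abundance, equal-weight-per-class composition, Wilcoxon rank-sum specimen tests, RT-qPCR normalization |
| `alveoniche.signatures` | Wilcoxon marker detection with pct/logFC filters, top-N signature construction, binned-control module scoring, AT2-state assignment (score and panel-count modes), maturation on/off sets and scoring, nearest-centroid label assignment |
| `alveoniche.niche` | k-NN neighborhood composition profiles, k-means niche detection (niches.k=4, neighbors.k=20 defaults; supervised K=2/k=10 mode), Pearson-correlation niche alignment across sections, Welch's t-test niche composition comparison |
| `alveoniche.spatial_stats` | Symmetric mean nearest-neighbor distances with one-way ANOVA + Tukey HSD, join-count self-association over 10–30 µm distance bands with analytic (random-labeling) and permutation nulls |
| `alveoniche.io` / `alveoniche.pipeline` / `alveoniche.cli` | Matrix Market / CSV / GMT I/O, YAML-configured pipeline orchestration with deterministic per-stage seeding and a reproducible JSON run report |

## CLI

Every subcommand takes `--config <yaml>` (all parameters have defaults),
`--out <dir>`, and `--seed <int>`:

```sh
alveoniche run --config config.yaml --out run/          # full pipeline
alveoniche simulate --out sim/ --seed 7                 # synthetic data only
alveoniche niche --config config.yaml --out run/        # prefix through niches
```

Stage subcommands (`simulate`, `qc`, `markers`, `signatures`, `score`,
`classify`, `composition`, `niche`, `distances`, `joincount`, `maturation`)
run the dependency-ordered pipeline prefix ending at that stage. A minimal
config:

```yaml
seed: 7
simulate:
  cohort: {n_specimens_per_class: 3, cells_per_specimen: 500}
  spatial: {n_sections: 5, cells_per_section: 3000}
niche: {neighbors_k: 20, niches_k: 4}
```

## Notes

- All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning; identical config + seed gives
  byte-identical outputs.
- QC boundary semantics are literal: features kept on the closed interval
  [500, 7500], molecules must exceed 1000 strictly, mito/ribo fractions
  strictly below 5% / 7.5%; spatial cells need ≥ 25 panel counts.
- Deliverables are text-only: Matrix Market triplets, TSV/CSV, GMT, JSON.
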