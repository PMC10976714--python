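# clubconv

Convergence-club analysis for country-year panels: the one-sided log-t
convergence test with Newey–West (HAC) inference, core-group club
clustering with adjacent-club merging, PCA composite indices, per-grouping
Gini inequality panels, and a two-level random-intercept mixed model with
intra-class correlation (ICC) — plus seeded synthetic-data generators so
the whole pipeline runs and is testable without any external data.

## Package layout

| module | contents |
| --- | --- |
| `clubconv.panel` | `PanelSeries` (balanced N×T panel), `Membership`, long-CSV I/O, log transform, balancing policies |
| `clubconv.logt` | relative transition paths `h_it`, cross-sectional variance `H_t`, the trimmed log-t regression with HAC one-sided inference |
| `clubconv.clubs` | unit ordering, core-group formation, membership sieve, full clustering recursion, adjacent-club merging |
| `clubconv.simulate` | `DGPSpec` loading-process panel simulator with planted clubs/divergent units; `RECDatasetSpec` two-level covariate/outcome generator |
| `clubconv.indices` | correlation screening, first-principal-component composite indices, affine rescaling |
| `clubconv.inequality` | Gini coefficient and grouping-by-year Gini panels |
| `clubconv.determinants` | random-intercept mixed model (REML/ML) with cluster-robust SEs and ICC; fixed-effects and pooled-OLS robustness fits |
| `clubconv.mcstudy` | Monte-Carlo size/power/slope-consistency/recovery studies |
| `clubconv.cli` | `clubconv` command-line entry point |
| `clubconv.datasets` | small bundled example correlation matrices |

## Command line

```bash
# simulate a 3-club panel, then run the full convergence workflow
clubconv simulate --kind panel --seed 7 --out scratch/sim/run
clubconv convergence --panel scratch/sim/run.csv --no-log-values --out scratch/conv

# two-level dataset and the determinants stage (ICC + mixed/FE/OLS)
clubconv simulate --kind rec --seed 7 --out scratch/rec
clubconv determinants --data scratch/rec.csv --covariates x1,x2,x3 --out scratch/det

# composite index, Gini panel, Monte-Carlo studies
clubconv indices --table indicators.csv --out scratch/idx
clubconv gini --panel panel.csv --membership members.csv --out scratch/gini.csv
clubconv study --kind size --reps 500 --seed 1 --out scratch/size.csv
```

Exit codes: 0 ok, 1 validation error, 2 runtime error.  Every run writes
a `manifest.json` (config echo, seed, versions); reruns with the same
inputs are byte-identical.

Analysis defaults follow the standard methodology: trimming fraction
`r = 0.3`, one-sided critical value `−1.65`, ordering by last
observation, automatic Bartlett-kernel bandwidth `⌊4(n/100)^{2/9}⌋`.
All are exposed as flags / YAML config keys.

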