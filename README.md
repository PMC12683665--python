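# germscreen

Interval-censored time-to-event analysis, germination indices and
multivariate screening for seed salinity-tolerance trials.

Germination trials record, at a few inspection days after sowing (DAS), how
many seeds in each petri dish have newly germinated, plus abnormal-seedling
counts at the final visit and, in a companion trial, seedling shoot/root
lengths. This package implements the full analysis chain used to screen a
panel of accessions for salinity tolerance at germination and early
seedling development:

1. **Time-to-event modelling** of interval-censored germination: the
   Turnbull nonparametric maximum-likelihood estimator (NPMLE) of the
   cumulative germination curve, fitted by self-consistency EM; T50 (time
   to 50% of germinated seeds) with a within-dish bootstrap SE; generalized
   Wilcoxon scores u = S(L) + S(R) − 1 against the pooled fit; and a
   permutation test of curve equality.
2. **Germination indices** per dish — total germination (TG), velocity
   coefficient (VC), germination index (GI), mean germination time (MGT),
   synchrony (GSI), normality rate (NR) — and **stress tolerance indices**
   STI_x = X_200mM / X_0mM, plus the seedling vigor index
   SVI = germinability × (shoot + main-root + lateral-root length).
3. **Multivariate screening**: PCA of the standardized STI matrix,
   hierarchical k-means (Ward initialization + Lloyd refinement) to split
   accessions into germination-strategy clusters, and cluster contrasts
   via Kruskal–Wallis + Dunn–Bonferroni or ANOVA + Sidak with compact
   letter displays.
4. A **synthetic-trial generator** with three accession archetypes
   (slow-but-complete, germination-susceptible, fast-but-frail) and ground
   truth tables, so every stage is testable by parameter recovery.

It is aimed at seed-biology and crop-screening groups who want the
censoring-aware analysis without hand-rolling it per trial.

## Worked example

```python
import numpy as np
from germscreen import (
    DishCounts, InspectionSchedule, compute_indices,
    counts_to_intervals, fit_npmle, quantile_time,
)

sched = InspectionSchedule((1, 2, 3, 6))
dish = DishCounts("CCE-X", 0.0, "r1", n_sown=50,
                  new_germ={1: 10, 2: 20, 3: 5, 6: 0}, n_abnormal=3)

fit = fit_npmle(counts_to_intervals(dish, sched))
print(fit.masses)                      # [0.2 0.4 0.1 0.3]
print(quantile_time(fit, 0.5).time)    # 1.75
```

The 15 never-germinating seeds are right-censored on (6, inf) and carry the
0.3 mass; F crosses 0.5 inside the (1, 2] interval, and linear
interpolation puts the absolute-scale median at 1 + (0.5−0.2)/0.4 = 1.75
DAS. Indices for the same kind of dish follow the printed formulas —
`compute_indices(dish, sched)` returns TG = 70, MGT = 1.3, and so on, with
the identity MGT × VC = G/Ntot holding exactly.

## The three-experiment analysis

The numbered drivers under `analysis/` run the whole study on synthetic
data (seed 42 by default) and write tidy CSVs under `results/`:

```bash
python analysis/01_simulate_trials.py      # gradient, panel, seedling data
python analysis/02_salinity_gradient.py    # NPMLE + Wilcoxon + T50 per dose
python analysis/03_sti_screening_clusters.py
python analysis/04_seedling_vigor.py
```

Sample output from the screening step:

```
PC1 41.6% + PC2 30.0% = 71.6% of STI variance
cluster 1: n=32, mean STI_TG=0.89, mean STI_MGT=1.26
cluster 2: n=14, mean STI_TG=0.92, mean STI_MGT=0.94
cluster 3: n=9,  mean STI_TG=0.60, mean STI_MGT=0.93
Rand index vs generator truth: 1.000
```

and from the seedling step:

```
mean trait STIs (least to most impacted): shoot=0.43, main_root=0.24, lateral_root=0.11
cluster 1: n=7, STI_SVI=0.30
```

i.e. the largest cluster keeps high final germination but is delayed under
salt, the small cluster loses germinability outright, shoots are the least
salt-impacted seedling trait and lateral roots the most — and only the
slow-but-complete cluster sustains seedling vigor.

The same stages are available as a CLI for real data
(`germscreen simulate|indices|sti|cluster|exp1|exp2|exp3`, long CSV
formats documented in `germscreen.io`), and as library functions
(`run_experiment1/2/3`).

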