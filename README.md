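# dendrotramp

Tools for asking a recreation-ecology question with dendrochronological
data: **does long-term trampling by pedestrian tourists suppress the
radial growth of trees beside tracks?** The package is aimed at
ecologists working in protected areas, where permits cap the number of
increment cores that can be taken, so every methodological choice —
sample size, trend family, split year — can move the answer.

It implements, as a tested pipeline that runs end to end on synthetic
data:

1. **Sample representativeness** — draw samples of size *n* without
   replacement from a pool of *N* cored trees of which *K* are "flawed"
   (rot, fungus, increment anomalies — cored but unusable) and track how
   the estimated flawed fraction behaves. The flawed count in a draw is
   Hypergeometric(*N*, *K*, *n*), so the simulation is checked against
   E = K/N and Var = (K/N)(1−K/N)/n · (N−n)/(N−1).
2. **Chronology statistics** — pooled TRW descriptives per plot × zone,
   Douglass mean sensitivity MS = mean |2(wₜ−wₜ₋₁)/(wₜ+wₜ₋₁)|,
   Gleichläufigkeit (sign-agreement of year-to-year changes), mean
   inter-series correlation r̄ and the expressed population signal
   EPS = n·r̄/(n·r̄ + (1−r̄)).
3. **Growth-trend models** — linear, negative exponential
   (a·e^(−b(x−x₀)) + k), logarithmic, 3rd-degree polynomial and a scaled
   Weibull-density shape, fitted by (multi-start) least squares; best
   fit by maximum R², a conservative line-first selection rule, paired-t
   comparison of absolute residuals, an extra-sum-of-squares F test of
   curve parallelism, and Welch t on residuals of a pooled fit to detect
   between-plot heterogeneity.
4. **Watershed-year sensitivity** — split the timeline at candidate
   onset years of mass tourism (default 1960/1970/1980), fit linear
   trends per zone and period, test zone-slope equality via the
   year × zone interaction, and tabulate how much the arbitrary split
   choice moves the slopes.
5. **Joint GLM** — tree-level ring width ~ year + plot + zone with
   normal errors and identity link; Wald χ² per term and a
   likelihood-ratio χ² for the whole model.
6. **Synthetic study generator** — two plots × (track, control) zones,
   per-tree negative-exponential age trend, shared AR(1) climate year
   effect, a ramped log-scale trampling suppression δ in track zones,
   lognormal noise, and flawed trees (90 bored, 15 flawed in the
   default preset).

Ring-width data are read/written in the Tucson decadal RWL format and a
wide year × tree CSV layout with columns named `Plot_Zone_TreeNr`
(zone `T` = trampled track zone, `C` = control; empty columns mark
flawed trees).

## Worked example

```python
import dendrotramp as dt

# a two-plot study design: 90 trees, 15 flawed
dataset, truth = dt.generate_dataset(dt.study_shape(), seed=1)
kept = dt.exclude_flawed(dataset)
print(len(dataset), sum(s.flawed for s in dataset), len(kept))
# 90 15 75

# how reliably would a 5-tree sample estimate the flawed fraction?
pool = dt.SamplingPool(90, 15)
res = dt.simulate_sampling(pool, sizes=[5, 45, 90], reps=5000, seed=1)
print(res.table[["size", "mean_pct", "sd_pct"]].round(2).to_string(index=False))
#  size  mean_pct  sd_pct
#     5     16.37   16.40
#    45     16.64    4.02
#    90     16.67    0.00
```

A 5-tree sample is unbiased on average but its flawed percentage swings
with SD ≈ 16 points — a single permit-limited sample can easily contain
0% or 40% unusable trees; at 45 trees the SD is about 4 points.

```python
z, params = dt.normalize_global(dataset)       # pooled z-scores
chron = dt.build_chronology(z)                  # plot/zone mean chronologies
y = chron["MW/track"].dropna()
fit = dt.conservative_select(y.index.to_numpy(float), y.to_numpy(), seed=1)
print(fit.family, round(fit.r_squared, 3))
# poly3 0.846

glm = dt.fit_glm(dataset, ref_plot="MW")
print(glm.table.round(4))
#                estimate      se  wald_chi2    p
# Intercept       18.9117  0.2484  5795.7805  0.0
# plot[K]          1.3193  0.0142  8612.0679  0.0
# zone[control]    0.0704  0.0138    25.9206  0.0
# year            -0.0094  0.0001  5245.8154  0.0
```

The positive `zone[control]` contrast says control trees grow wider
than track trees of the same plot and year — the trampling suppression
built into the generator (δ < 0) recovered with the correct sign.

The same pipeline is available from the shell:

```sh
dendrotramp --seed 1 --out-dir out all          # simulate + every stage
dendrotramp --seed 1 --out-dir out stats out/synthetic_rd.csv
```

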