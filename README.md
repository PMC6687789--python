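# vmclust

Two-step cluster analysis of knee valgus moment (VM) stance-phase
waveforms, for biomechanists studying ACL injury risk.

ACL injuries occur in the first ~50 ms after ground contact, but the knee
VM time series of a cutting trial does not always have a discrete peak in
that window, so extracting "the peak VM" mixes mechanically different
movements. `vmclust` instead classifies whole early-stance waveforms:

1. **Shape step.** Each trial is windowed to the first 30% of stance,
   linearly resampled to a common length (longest windowed series + 2
   frames), and reduced to the signs of its lagged differences,
   `s_k = sign(x_{k+1} - x_k) ∈ {-1, 0, +1}`. Euclidean distances between
   these signatures feed Ward.D2 agglomerative clustering
   (Lance–Williams recurrence on squared dissimilarities, heights on the
   original scale). The number of clusters is chosen from a C-Index scan,
   `C = (S_w - S_min) / (S_max - S_min)`, by a 0.05 cutoff or an elbow
   rule, and each cluster is named by quantitative rules on its aggregate
   curve: **early peak, peak, upslope, downslope, trough, early trough**
   (manual overrides supported).
2. **Magnitude step.** Within each shape, body-mass-normalized (Nm/kg)
   curves are clustered the same way into 2–4 sub-clusters (lowest
   C-Index wins) and ranked into **small / medium / large** magnitudes.

Group differences in label frequencies (e.g. sex × maturity phase) are
tested with a Pearson chi-square — with per-cell contributions
`(O-E)²/E` to localize effects — and, when expected counts fall below 5,
a fixed-margin Monte-Carlo significance test (Patefield sampling,
`p = (1 + #{sim ≥ obs}) / (n_sim + 1)`).

A synthetic generator (`vmclust.synthetic`) emulates the six waveform
families (Gaussian bumps, logistic ramps) with magnitude classes, smooth
autocorrelated noise, variable trial lengths and per-athlete body masses,
so the whole pipeline is testable without motion-capture data. Packaged
reference tables (`vmclust.datasets`) carry the observed shape and
shape-by-magnitude counts of a published two-phase youth-athlete cohort.

## Worked example

```python
from vmclust.datasets import load_shape_counts, load_shape_magnitude_counts
from vmclust import chi_square, frequency_report, monte_carlo_p

shape = load_shape_counts()                 # 4 groups x 6 shapes
res = chi_square(shape)
print(f"chi-square = {res.statistic:.1f}  (df = {res.df})")
print(frequency_report(shape)["early_peak"].round(1))
sub = load_shape_magnitude_counts()         # 4 groups x 14 sub-clusters
print(monte_carlo_p(sub, n_sim=9999, seed=1))
```

prints

```
chi-square = 400.1  (df = 15)
(boy, 1)     38.0
(girl, 1)    25.7
(boy, 2)     21.4
(girl, 2)    42.5
0.0001
```

i.e. shape frequencies differ strongly by sex and phase: 38% of
pre-adolescent boys' trials show an early peak against 25.7% for girls,
and the ratio reverses after adolescence (21.4% vs 42.5%) — the phase-2
girls' excess of the injury-relevant early-peak shape mirrors the 2–3×
higher ACL injury incidence of adult female athletes. The Monte-Carlo p
of 0.0001 is the smallest value 9999 simulated tables can resolve.

The command line mirrors the library:

```sh
vmclust simulate --config sim.yaml --seed 7 --out trials.csv --truth truth.csv
vmclust run --trials trials.csv --out labels.csv --json report.json
vmclust freqtest --trials trials.csv --labels labels.csv --monte-carlo 9999 --seed 7
```

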