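# Methods

## Model and procedure

`vmclust` treats each recorded trial as one observation: a stance-phase
knee valgus moment (VM) series in Nm with athlete metadata (sex, phase,
body mass). The analysis has two clustering passes over the same
preprocessed curves plus a frequency-testing stage.

**Preprocessing.** Trials are windowed to the leading
`stance_fraction` (default 0.30) of stance — the ACL-injury-relevant
weight-acceptance phase — with the window length rounded *up* so it
never undershoots the fraction. All windowed series are piecewise-
linearly resampled to a common length, by default the longest windowed
series plus two frames. Linear interpolation is deliberate: spline
overshoot would manufacture direction changes that the encoder, a
differencer, would mistake for shape features. The order is fixed:
window, then derive the common length, then resample, then divide by
body mass (Nm/kg). Windowing before resampling keeps the window a fixed
fraction of each trial's own stance.

**Shape encoding.** A curve of length L becomes the sign vector of its
lagged differences (length L−1, values −1/0/+1). Exact ties encode as 0
because interpolation can create exactly equal neighbours; a `ties="up"`
flag maps them to +1 for sensitivity analysis. The encoding is invariant
to positive scaling and offsets (this is what makes step 1 a pure shape
classification) and antisymmetric under curve negation. Pairwise
Euclidean distances over signatures are bounded by `2·sqrt(L−1)`.

**Ward.D2.** Agglomeration uses the minimum-variance criterion in the
Murtagh–Legendre formulation: the Lance–Williams recurrence applied to
squared input dissimilarities, with merge heights reported on the
square-rooted scale. It is implemented directly (rather than delegated)
so that exact merge ties can be broken deterministically — the
lexicographically smallest (smaller node id, larger node id) pair wins —
making results invariant to input order; an independent library
implementation serves as a cross-check in the tests. The implementation
is generic over any dissimilarity matrix and is reused by both steps.
Ward's criterion is reducible, so heights never invert, and tree cuts
are nested across k.

**Cluster count.** The Hubert–Levin C-Index
`C = (S_w − S_min)/(S_max − S_min)` is scanned over k = 2…50 (clamped to
n−1). Selection rules: *threshold* (default) takes the smallest k with
C ≤ 0.05, the cutoff used in the source methodology for a smooth scan;
*elbow* takes the k maximizing the discrete second difference of the
scan (first maximum, smaller k on ties); if no k meets the threshold the
scan argmin is returned and flagged `argmin-fallback`. The threshold
comparison is inclusive (≤). Undefined scan points (all-singleton cuts,
all-equal distances) are recorded as NaN, and float-summation dust is
clamped so C stays in [0, 1].

**Shape labels.** Visual cluster inspection is replaced by rules on the
cluster's mean curve: the apex is the sample deviating most from the
chord joining the endpoints; its deviation relative to the curve range
is the prominence. Prominent (≥ 0.2) positive apexes are peaks,
negative are troughs; the EARLY_ variant applies when the apex falls in
the first half of the window (i.e. the first 15% of stance, bracketing
the observation that injury-relevant early peaks fall within the first
quarter of stance). Non-prominent profiles are up/downslopes by net
change. Flat profiles raise an error directing the analyst to the
manual-override file (cluster_id → label), which always takes
precedence — inter-assessor reliability of visual labeling is exactly
why overrides are first-class.

**Magnitude labels.** Within each shape group, Nm/kg curves are
re-clustered; candidate sub-cluster counts 2–4 are scored by C-Index and
the lowest value wins. Exact C ties are broken toward the *finer*
partition: on clean data several sub-cluster counts can achieve exactly
C = 0 (a hierarchically clean magnitude structure has more than one
perfect separation), and the sub-clustering step exists to
differentiate magnitudes, so the more informative solution is kept.
Sub-clusters are ranked by mean |Nm/kg| (ties: peak value, then index)
and mapped small/large (k=2), small/medium/large (k=3), or
small/small/medium/large (k=4, a documented convention). Groups with
fewer than 3 members, or whose C-Index is undefined at every candidate
k, stay a single sub-cluster labeled medium.

**Frequency statistics.** Tables cross (sex, phase) groups with shape
or shape×magnitude categories, ordered by first appearance. The Pearson
statistic is uncorrected (no Yates continuity correction — the
published per-cell contributions reproduce only without it); per-cell
contributions `(O−E)²/E` sum to the statistic; the asymptotic p uses
the χ² upper tail with df = (r−1)(c−1). The Monte-Carlo p draws tables
from the conditional null with both margins fixed (Patefield sampling
via scipy) and uses the (1 + exceedances)/(n_sim + 1) estimator, which
never returns 0. An unconditional interpretation is not offered; the
conditional test is the standard reading of a simulated chi-square
significance test.

## Synthetic generator

The generator emulates the six empirical waveform families on the
stance-fraction axis: Gaussian bumps (early peak/trough centred at 10%
of stance, width 6%; peak/trough at 24%, width 8%) and logistic ramps
(up/downslopes centred at 15%, scale 5%). A trial is a template times a
magnitude multiplier (defaults: 0.5/1.0 Nm/kg for two-class families;
0.4/0.8/1.6 for the three-class trough families, mirroring the
reference cohort's 14 sub-clusters with ≥2× separation), plus smooth
noise — white noise filtered with a 5-frame moving average — at
`noise_sd` = 0.04 Nm/kg (10% of the smallest multiplier) by default.
Autocorrelated noise is essential: the encoder differences the curve,
and unfiltered noise would shred sign structure in a way filtered
inverse-dynamics signals never do. Raw lengths are uniform on 80–120
frames; body masses are drawn per athlete (blocks of 20 trials) from
normal distributions matching the reference cohort's descriptive
statistics, truncated at 25 kg; group sizes, shape frequencies and
per-shape magnitude splits default to the packaged reference tables.

What the generator does *not* emulate: kinematic coupling, ground
reaction force structure, within-athlete correlation of waveform shape,
asymmetric or composite waveforms, and the diffuse continuum of real
encodings (a real cohort of ~4900 trials produced over a thousand
distinct signatures; the generator's families are far crisper). Passing
recovery tests therefore show the pipeline machinery is sound, not that
real VM data contains six crisp families.

## Behaviour on idealized data: a documented limitation

On generator data the C-Index scan behaves qualitatively differently
from the published empirical scan, and this changes what cluster-count
selection does:

- The coarse k = 2 cut — mostly-rising versus mostly-falling
  signatures — is a *clean* separation of idealized families: every
  within-block pair distance sits below every between-block distance,
  so C(2) ≈ 0.004–0.017 at every noise level up to the default,
  including zero noise. The 0.05 threshold rule therefore accepts k = 2
  immediately, and the elbow and argmin rules land at k = 2–4. The
  empirical cutoff presupposes a diffuse scan with C(2) ≫ 0.05 (real
  data crossed 0.05 only at k = 39); idealized templates exclude that
  regime by construction. Consequently the default pipeline on
  synthetic data reports the binary split, and family-level recovery
  through automatic count selection does not reach high agreement. The
  test suite pins this behaviour rather than hiding it
  (`test_default_selection_prefers_coarse_split`), and the
  corresponding synthetic-recovery check is expected to fail until a
  selection rule suited to idealized data exists.
- Independently of selection, at the default noise (10% of the small
  amplitude) the differencer randomizes signs wherever the template
  derivative is small (bump tails), genuinely overlapping families:
  even a cut pinned at the true family count yields label agreement of
  ARI ≈ 0.7 (≈ 0.95 at 5% noise, 1.0 noiseless).

Analysts applying the pipeline to simulated or otherwise strongly
idealized data should pin the cluster count (`PipelineConfig.k_fixed`),
or inspect the exported C-Index scan, instead of relying on the 0.05
cutoff. The magnitude step is unaffected: per-family sub-clustering
recovers planted amplitude classes completely under the default regime.

## Numerical and design notes

- Windowing needs ≥ 3 samples and trials ≥ 4 frames, so differencing
  always leaves ≥ 2 encoded points.
- Resampling is exact on affine sequences and preserves endpoints.
- C-Index scans reuse one global sort of pairwise distances (prefix
  sums), so a 2…50 scan costs one sort plus O(n²) per k.
- The reference shape-by-magnitude table's printed expected counts and
  statistic are not mutually consistent with its own observed counts
  (recomputation from the printed observed counts gives ≈ 702); the
  package keeps the observed counts as printed and treats only
  quantities recomputable from them — margins, contributions, the
  Monte-Carlo bound — as reproduction targets.
- Printed relative frequencies in the reference analysis truncate
  rather than round (25.66% prints as 25%); comparisons against printed
  integers use truncation.
- Problem sizes in tests are desk-scale by design: recovery checks use
  300-trial cohorts (50 per family), cross-implementation checks use
  8–10-point configurations, and the Monte-Carlo test uses 9999 tables.

## Known limitations

- Event detection, signal filtering and C3D parsing are out of scope;
  trials are assumed to span exactly the stance phase.
- The shape-label rules are calibrated on the generator's template
  geometry; unusual empirical aggregates may need overrides.
- The C-Index is the only validity index offered; silhouette or gap
  statistics could be added as diagnostics.
- The Monte-Carlo test conditions on both margins; it does not address
  within-athlete correlation of trials (each trial is treated as the
  unit of observation, as in the source methodology).
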