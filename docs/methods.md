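# Methods

This note documents the statistical procedures, the generative model
behind the synthetic data, the numerical choices, and what the tests do
and do not establish.

## Cluster-based permutation testing

### Pointwise statistics

Every supported effect reduces to one contrast per subject, computed on
per-subject condition-average ERPs:

| design | contrast | F | df |
| --- | --- | --- | --- |
| `paired` | A − B | one-sample t² | (1, n−1) |
| `interaction_within` | (A₁−A₂) − (B₁−B₂) | one-sample t² | (1, n−1) |
| `interaction_mixed` | A − B, compared across groups | pooled two-sample t² | (1, n₁+n₂−2) |
| `three_way_mixed` | double difference, across groups | pooled two-sample t² | (1, n₁+n₂−2) |

Reducing the 2×2 interaction to a one-sample test on the double
difference is exact for 2-level factors and makes the within-subject
permutation scheme (sign flips) exact as well. A contrast with zero
sample variance and nonzero mean produces an infinite F; it is capped at
the sentinel `1e12` and flagged in `FMap.degenerate` rather than dropped,
so degenerate points remain visible in cluster masses.

### Cluster formation

1. Threshold the F map at the forming alpha (default .05 on the
   pointwise F distribution).
2. Per sensor, keep only supra-threshold runs of at least `min_run`
   consecutive samples (default 5; 20 ms at 250 Hz). The duration rule is
   deliberately a *per-sensor prefilter*: a sensor can only contribute
   points that are themselves temporally sustained on that sensor.
3. Link surviving sensor-time points — same sensor and adjacent samples,
   or spatially adjacent sensors and the same sample — and take connected
   components as clusters (mass = summed F). Components are found with
   `scipy.sparse.csgraph` on a Kronecker-structured grid adjacency.

Clusters are sorted by descending mass; ties break by earliest onset,
then lowest sensor ID. Reported windows are half-open
[first-sample time, last-sample time + Δt), with Δt = 1000/rate ms, so a
k-sample cluster spans exactly k·Δt ms.

### Permutation null and inference

Within-subject effects are permuted by independent per-subject sign
flips of the contrast (exact exchangeability under the null for 2-level
factors: flipping the sign is the same as swapping the subject's cell
labels). Between-subject factors are permuted by reassigning group
labels across subjects, preserving group sizes, with the within-subject
structure kept intact — the standard approximate-exchangeability choice
for interactions involving a group factor. The scheme used is recorded in
every result's metadata.

Each permutation re-runs the *identical* form-clusters pipeline and
contributes its **maximum** cluster mass (0 if nothing survives). The
critical mass is the 95th percentile of that sample (`numpy.percentile`,
linear interpolation); empirical clusters are significant if their mass
exceeds it, and each receives p = (1 + #{null max ≥ mass}) / (1 + n_perm)
— the +1 correction keeps p in (0, 1] with floor 1/(1+n_perm). Using the
per-permutation maximum, rather than pooling all permuted clusters, is
what gives family-wise control; the acceptance suite verifies an
empirical FWER at the nominal 5% over 200 null simulations.

Small instances (n ≤ ~20 subjects) can request exhaustive enumeration of
all 2ⁿ sign patterns instead of Monte-Carlo sampling; the test suite
checks the sampled null against full enumeration at n = 4.

### Follow-up statistics

Significant clusters are summarized by the per-subject mean amplitude
over the cluster's sensor set × time window (the rectangular hull, which
is what gets plotted and tabled in practice). Within-subject 2×2 designs
get a univariate repeated-measures ANOVA — every effect is F = t² of the
corresponding per-subject contrast, df (1, n−1), ηp² = F/(F + df_den) —
plus pairwise paired t-tests. Mixed designs get per-group paired t-tests
and between-group Welch t-tests (Welch–Satterthwaite fractional df).

## Recognition-memory indices

Hit rate = #(old trials answered "old") / #(old trials); false alarms
likewise over new trials. Two response dialects: an 11-anchor (0–10)
two-question format where the old/new response is explicit, and a
6-point combined scale where anchors 4–6 mean "old". Recollection is
operationalized as top-anchor "old" responses (10, resp. 6), familiarity
as sub-top "old" responses. Because split numerators share the overall
denominators, Pr_recollection + Pr_familiarity = Pr_overall holds as a
count identity — a deliberate convention, declared in output metadata
(split conventions differ across the literature and are not always
additive). Strata with fewer than 5 numerator trials are flagged
`unstable` but still computed.

New items are shared across stimulation conditions in these designs, so
false-alarm rates are matched to a stratum only on the columns that new
trials actually carry (e.g. affective category), and reused across the
levels of old-only factors.

d′ uses the 1/(2N) extreme-rate correction (rate 0 → 1/(2N), rate 1 →
1 − 1/(2N), N the relevant trial count) before the standard-normal
quantile, keeping d′ finite with perfect performance. Subjects whose
overall Pr (all trials pooled) is ≤ 0 are excluded before inferential
modeling; the exclusion report lists every subject's Pr.

## Random-intercept mixed models

Model: y = Xβ + Zb + e, b ~ N(0, σ²ₛ) per subject, e ~ N(0, σ²ₑ).
Factors are sum-to-zero coded (±1 for 2-level factors), so main effects
stay interpretable alongside interactions; default terms are the full
factorial.

Estimation profiles λ = σ²ₛ/σ²ₑ: for fixed λ the marginal covariance is
σ²ₑ(I + λZZ′) whose per-subject blocks invert in closed form
((I + λJ)⁻¹ = I − λ/(1+nλ)·J), giving GLS β̂ and a one-dimensional REML
(or ML) criterion minimized by bounded scalar search on log λ over
[−16, 16] with xatol 1e−12; the λ = 0 boundary is evaluated explicitly
and wins ties.

Satterthwaite df for a contrast c: f(θ) = c′(X′V⁻¹X)⁻¹c,
df = 2f²/(g′Ag), with g = ∇f over θ = (σ²ₛ, σ²ₑ) and A the inverse
expected REML information, Iⱼₖ = ½tr(PVⱼPVₖ),
P = V⁻¹ − V⁻¹X(X′V⁻¹X)⁻¹X′V⁻¹. For balanced designs the variance
strata are orthogonal and the df are exact integers — n subjects × 2×2
cells gives N − n − (p−1) = 87 at n = 30, and 203 for the 2×2×2 design —
because a within-subject contrast's variance depends only on σ²ₑ and the
delta method is parametrization-invariant. Two boundary/reference notes:

* When λ̂ = 0 the model degenerates to iid least squares and every
  fixed-effect t is assigned the full residual df N − rank(X), matching
  lme4/lmerTest's behavior on boundary (singular) fits.
* Off the boundary, on *unbalanced* data, the expected-information df
  differs from lmerTest's observed-information df by ~0.1 df in typical
  cases; balanced designs agree exactly (verified against lmerTest in the
  test suite). p-values are two-sided from the t distribution at the
  Satterthwaite df.

Bayes factors are the BIC approximation BF₁₀ = exp((BIC₀ − BIC₁)/2) on
maximum-likelihood refits of nested models (nesting is verified by a
column-span check; REML fits are refused). BIC counts p + 2 parameters.
This approximation is labelled in every output; it tracks the direction
and order of evidence but does **not** reproduce the values a JZS-prior
Bayesian ANOVA (e.g. JASP) would print. Evidence labels follow the
conventional decisive/very strong/strong/moderate/anecdotal bands at
100/30/10/3/1 (and their reciprocals for H₀).

## The synthetic studies

The generator emulates two designs end to end.

**Study 1** (within-subject crossover, default 30 subjects): two 60-trial
encoding sessions (30 unpleasant + 30 neutral scenes, 3000 ms each), one
under active stimulation and one under sham, order counterbalanced;
retrieval a week later shows the 120 encoded images intermixed with 120
new ones (240-image pool in four counterbalanced sets of 60), with an
old/new judgment plus 0–10 confidence. **Study 2** (mixed, default 65
subjects): stimulation is between subjects; a single 120-trial encoding
session presents images in alternating blocks of exactly four per on/off
stimulation half-cycle; retrieval uses a 6-point old/new-confidence
scale. Encoding orders are pseudorandom with no more than two
same-category scenes in a row, enforced by constrained sequential
sampling (restart on dead ends) under per-cell quotas.

**Behavior** comes from a dual-process model: an old item is recollected
with probability R (response "old" at the top anchor); otherwise a
familiarity strength x ~ N(d_fam, 1) is binned through strictly
increasing criteria into (response, confidence). New items draw from
N(0, 1); by default they can never be recollected (false-recollection
probability 0, configurable). The 11-anchor dialect cuts the strength
axis with 21 criteria into 22 bins (11 "new" folded down, 11 "old"
folded up; the old/new boundary is the middle criterion), the 6-point
dialect with 5 criteria. Closed forms used in tests: hit = R + (1−R)·
Φ(d − c), FA = 1 − Φ(c), with c the boundary criterion. Default per-cell
R values (≈ 0.26–0.49) and familiarity means (≈ 0.8–1.0) were set to the
recollection/familiarity performance levels typical of week-delayed
scene memory in these designs, with subject-level shifts on d_fam
(SD 0.35) and on logit R (SD 0.5) supplying the between-subject spread a
random intercept absorbs.

**ERPs** are generated directly at the per-subject condition-average
level (the statistics' input; no raw continuous EEG or artifacts — those
belong to upstream preprocessing, which is out of scope). Each average
is: injected rectangular sensor×time effect patches (per-condition mean
amplitude in µV, plus a subject-level amplitude deviation shared across
conditions so contrasts stay exact) + a per-subject constant offset +
structured noise. Noise is Gaussian with AR(1) temporal correlation
(default ρ = 0.5) mixed across sensors by a row-normalized lazy
graph-diffusion operator (default 2 passes); both operators are
variance-normalized so the marginal per-sample SD equals `noise_sd`
(default 1 µV) exactly. For between-subject designs patch amplitudes may
be keyed per group (`"group@condition"`). Default patches mirror the
emulated findings: a posterior emotion (LPP) main effect at 300–1000 ms,
an early emotion × stimulation interaction (416–548 ms or 476–600 ms),
and late retrieval old/new (+interaction) effects, at amplitudes of
1.2–1.5 µV — i.e. per-subject contrast-to-noise near 1, the regime where
detection is informative rather than trivial.

The packaged 129-sensor layout is a Fibonacci-spiral arrangement on the
upper hemisphere with distance-threshold adjacency tuned to a median of
~6 neighbors, and conventional posterior/anterior ROI masks (the most
negative / most positive y-coordinate 35% of sensors). It is synthetic —
a stand-in with realistic sensor count and neighbor density, not any
manufacturer's montage; all analyses take the layout as an input, so a
real montage in the same JSON format drops in.

What passing tests therefore show: the statistics are correct on data
satisfying their assumptions (Gaussian, stationary, exchangeable under
the null, rectangular effects), and the pipeline recovers known ground
truth at realistic contrast-to-noise. What they do not show: robustness
to real-EEG pathologies (artifacts, non-stationarity, sensor dropout,
reference choices) or the behavior of the forming threshold under heavy-
tailed noise.

## Numerical and convention choices

* Time is in ms relative to stimulus onset; all intervals are half-open
  [start, end); sample i covers [tᵢ, tᵢ + 4 ms) at 250 Hz.
* Analysis windows (encoding 200–600 and 600–1200 ms, retrieval
  400–1000 ms) and ROIs are tested independently, with no cross-window
  correction — mirroring common practice; reports state this.
* RNG: one root seed per run; each stage (design, behavior, encoding
  epochs, retrieval epochs, permutations) draws from a child stream at a
  fixed named offset, so stages are individually reproducible.
  Everything is deterministic given (config, seed); the test suite
  asserts byte-identical reports on repeated runs.
* Problem sizes in the validation suites — 200 null datasets × 500
  permutations at 16 subjects/32 sensors/64 samples for the FWER check,
  12 replicates at 26 subjects for patch recovery, 10,000 trials for
  generator-parameter recovery — were chosen to put Monte-Carlo error
  well inside the asserted tolerances while keeping the default test run
  in tens of seconds.

## Known limitations

* Only 2-level factors are supported in the cluster statistics (the
  designs here need nothing more); k-level effects would require true
  F-tests and a different permutation scheme.
* No TFCE, cluster-extent statistics, time-frequency analysis or source
  localization.
* The mixed model has a single random intercept: no random slopes and no
  crossed item effects.
* BIC Bayes factors are an approximation (see above), not JZS values.
* The behavior generator's criteria are fixed across subjects; only
  sensitivity and recollection vary by subject.
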