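# Methods

## Scope and data model

`phystate` analyzes a batch-culture stress test from three tabular
inputs: a genes × samples FPKM matrix, sample metadata (CO₂ condition,
stage = growth cycle between serial transfers, diurnal phase
light/dark, growth phase early/late, replicate), and time series of
cell counts and of dark-acclimated fluorescence yields Fm and Fo.
Missing expression values are a hard error (quantifiers emit 0, not
NA); all FPKM must be finite and non-negative. Metadata time is
optional — the state-space analysis needs only the categorical labels,
and growth fitting consumes its own time-series tables.

## Descriptor selection

Selection uses the reference stage (default: stage 1, the unstressed
cycle, pooled across CO₂ conditions — 24 transcriptomes under the
default design). On log10(FPKM + pseudocount) values, a gene is a
descriptor of an axis when all three criteria hold:

1. two-sided Mann–Whitney U rejects at α (default 0.05) after
   Benjamini–Hochberg adjustment across genes ("none" is available for
   a more literal, uncorrected reading);
2. |Q₂(φ_α) − Q₂(φ_β)| ≥ log10(fold_change_min), default twofold.
   Fold change is a difference of per-state medians in log10 space
   because the score geometry below is median-anchored;
3. |Q₂(φ_α) − Q₂(φ_β)| ≥ separation_sd_multiple × mean(SD(φ_α),
   SD(φ_β)), default 1; SDs are sample SDs (n−1) in log10 space.

The pseudocount (default 1.0) handles zero FPKM while preserving
ordering and bounding fold inflation for low counts. Genes passing for
both axes are assigned to the axis with the larger separation/SD ratio
so the two sets never overlap. Selection is symmetric under swapping
the two state labels (the profile orientation ε flips), and the
criteria are monotone: tightening any threshold never adds a
descriptor.

The choice of test and adjustment is a package decision: the selection
procedure's significance machinery is deliberately nonparametric to
match the rank-based statistics used everywhere else, and both are
exposed in `DescriptorCriteria`.

## The position-score map

Each descriptor's reference geometry is the pair of per-state log10
distributions: medians Q₂, extremes φ_min/φ_max per state, orientation
ε = +1 iff Q₂(φ_α) < Q₂(φ_β), gap θ = max(0, upper state's min − lower
state's max) with center θ_c. α = light on the diurnal axis and
α = early on the growth axis, so positive scores are light-like /
early-like; the polarity is arbitrary but fixed and documented.

For an observed κ the score λ is the piecewise map given in the
README: gap interpolation 2ε(θ_c − κ)/θ strictly inside the gap,
otherwise interpolation anchored at the δ-selected (closer-median)
state's distribution, ±1.5 at a state median, ±2 at that state's far
extreme, ±1 at a gap edge. Conventions where the equations leave
choices open:

- **Out-of-range κ** (below both minima or above both maxima): the
  anchored interpolation would extrapolate without bound on unseen
  data, so λ clamps to ±2, the value at the observed extreme.
- **Exact δ tie with no gap**: λ = 0, the value the gap interpolation
  takes at its center.
- **Degenerate profiles** (equal state medians) are rejected at
  profile construction, not at scoring.
- **Zero-width interpolation span** (an extreme equal to its median):
  κ beyond it clamps to ±2 like any out-of-range value.

**Continuity.** The map is continuous in κ across branch boundaries
(extremes, medians, gap edges, clamp points) with two provable
exceptions that are properties of the equations themselves, not of
this implementation: (i) for overlapping distributions (θ = 0) the
δ-switch at the equidistance point jumps between two unrelated
interpolations; (ii) for strongly asymmetric profiles a gap edge can
lie closer to the *opposite* state's median, in which case the
anchored interpolation on the out-of-gap side does not meet the gap
interpolation's ±1. Neither case arises for the near-symmetric
profiles that selection produces in practice; the test suite verifies
exact equivalence with an independently transcribed scalar oracle
everywhere and continuity at all boundaries outside these two cases.

Axis coordinates are convex combinations s_x = Σ ω_i λ_i (uniform
weights by default — nothing in the data motivates per-gene weights),
so |s_x|, |s_y| ≤ 2.

## Reference regions and classification

Per physiological state, stage-1 samples (conditions pooled by
default; a per-condition option exists) define a circular region:
centroid = mean position, radius = 1.96 × the standard deviation of
the observed positions about their centroid, i.e. √(var(s_x) +
var(s_y)) with n−1 variances — the RMS distance of the reference
scatter. Under Gaussian replicate scatter such a circle covers ~98% of
the position distribution asymptotically; we deliberately take the
total-SD reading of "1.96 standard deviations of the observed
positions" because the per-axis reading (≈1.96σ per axis) would cover
only ~85% of a two-dimensional Gaussian and make the circle
systematically too small as a state membership test. A sample is
classified to the nearest centroid's state if it lies within that
radius, otherwise to the non-distinctive area; exact ties are
non-distinctive.

Two finite-sample caveats, both measured by the acceptance script:
with only 6 reference samples per state the radius estimate is noisy
and expected held-out coverage drops to ~92% even for ideal Gaussian
scatter (an F(2,10) tail computation), and held-out samples carry a
small inward bias relative to in-sample reference positions (κ beyond
an observed extreme clamps, while κ beyond the gap-side range falls
down the steep gap interpolation). Observed held-out classification
accuracy on the default design is ~94%.

## Resilience statistics

- **Transcriptome similarity**: Spearman rank correlation (average
  ranks on ties) over genes with FPKM ≥ 5 in *every* sample of the
  comparison set, so one gene compendium enters each comparison;
  per-pair filtering is available as an option.
- **State-space dispersion**: Euclidean distances between all
  unordered replicate pairs per (condition, stage, diurnal, growth)
  sampling group; stage comparisons use a two-sided Mann–Whitney U
  test — exact p for small samples without ties, normal approximation
  with tie correction otherwise (scipy's `auto` policy, recorded in
  the result).
- **Fv/Fm variability**: Fv/Fm = (Fm − Fo)/Fm, valid for Fm > 0 and
  0 ≤ Fo ≤ Fm; CV = sample SD (n−1)/mean across replicates per
  time-point (the conservative convention at n = 2–3). Stage
  comparisons pair CVs by within-stage time index, truncate to the
  shorter series, drop zero differences, and apply a two-sided
  Wilcoxon signed-rank test, exact for n ≤ 25 without ties. Fewer
  than 5 usable pairs is an error with an explicit unpaired
  Mann–Whitney fallback option. The pairing unit (which stages, per
  condition or pooled) is exposed to the caller; the pipeline defaults
  to first-vs-last stage, pairing within condition and concatenating
  across conditions.

Both shift tests are calibrated: on identically generated groups they
reject at no more than 1.5× the nominal level over 1000 simulations
(checked in the test suite).

## Growth model

μ is the OLS slope of ln(count) vs time in days over the exponential
phase — a user-supplied window, or the maximal-slope 4-point run as a
documented auto-detection heuristic. Full curves are fitted by least
squares on ln(count) (multiplicative noise, consistent with the μ
definition) to the Zwietering-type lag-logistic

    ln N(t) = ln n₀ + A / (1 + exp(4μ(lag − t)/A + 2)),  A = ln(K/n₀),

the standard three-feature reparameterization in which A is the total
log growth, μ the maximum specific growth rate (the tangent slope at
the inflection), and lag the intercept of that tangent with the
baseline. The form is isolated behind `log_logistic_lag` so it can be
swapped. One consequence: N(0) sits slightly above n₀ (the sigmoid
floor is A/(1 + e^{4μ·lag/A + 2}), not zero), which is also true of the
synthetic generator since it inverts the same model. Initial values
are seeded from the data (n₀ from the first count, K from the maximum,
μ and lag from the steepest log-linear segment); non-convergence is
flagged, never silent, and a fit whose carrying capacity extrapolates
well beyond the observed range (observed maximum < 80% of K, or K >
5× the maximum) carries a plateau-not-identified warning.

Identifiability note: at 5% multiplicative noise on a twice-daily,
12-day design, K and μ recover to ~1–2%, but the lag estimate has a
sampling SD near 7% of its value — it trades off against μ and n₀ —
so single-run lag errors of 5–10% are expected rather than a fitting
defect; the acceptance script reports the measured errors.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
with defaults that mirror the reference design: 3 stages × 2 CO₂
conditions × 2 diurnal × 2 growth phases × 3 replicates (24 reference
transcriptomes in stage 1); 3000 genes of which 60 + 220 are planted
descriptors (direction fixed per gene) separated by effect = 0.6
log10-FPKM between states; descriptor base abundance log10 ~ N(1.5,
0.3) (descriptors are well-expressed transcripts); background genes
log10 ~ N(0.5, 0.8), a long-tailed abundance distribution so the
5-FPKM filter removes a realistic fraction of genes (~3/4 here).

Noise is normal in log10 space (log-normal FPKM) with two components:
an independent per-(gene, sample) SD of 0.12, and a replicate-level
"state depth" drawn per sample and axis with SD 0.25, which shifts all
of an axis's descriptors coherently — replicates sampled at nominally
the same phase sit at slightly different points of the light/dark or
early/late transition. The correlated component is what gives
replicate positions realistic scatter: with purely independent gene
noise, averaging over hundreds of descriptors would shrink position
spread toward zero and the reference circles to points, which real
replicate transcriptomes do not show.

Pre-collapse dysregulation has two stage-dependent knobs:

- **mixing** — the probability that a descriptor's state assignment is
  scrambled in a sample. The effective probability is drawn per
  sample from Beta(16m, 16(1 − m)) around the stage level m, so
  replicate cultures lose coherence to different degrees; this makes
  the dysregulated stage show both the drift toward the
  non-distinctive center and inflated inter-replicate dispersion, the
  paired pre-collapse signatures. m = 0 reproduces the pure four-state
  structure exactly; for any fixed gene the flips remain independent
  across samples, so at m = 0.5 a rank test on the state labels
  rejects at its nominal rate.
- **position_jitter_scale** — multiplies both noise components,
  inflating inter-replicate variability without moving state centers.

Defaults: mixing (0, 0, 0.4) and jitter (1, 1, 2) across the three
stages. Growth curves invert the fit's own lag-logistic (K = 2×10⁶
cells/mL, μ = 0.9/day, n₀ = 10⁵ cells/mL — an inoculum near the
reference experiment's seeding density — lag lengthening 0.5/1.5/3.0
days across stages as recovery slows, 5% multiplicative noise,
counts every 12 h for 12 days). Fv/Fm is drawn per replicate and
time-point around a healthy PSII yield of 0.65 with across-replicate
CV (0.02, 0.02, 0.06) over the stages — a threefold inflation in the
pre-collapse stage — and emitted as (Fm, Fo) pairs with log-normal Fm,
so Fv/Fm recovery from the pair is exact. All randomness flows from a
single `numpy.random.default_rng(seed)` per generator with a fixed,
documented draw order; the same seed reproduces identical studies
across platforms.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: the real transcriptome's gene catalog and
its correlation structure beyond the single per-axis depth factor;
library-level technical artifacts (depth, batch, lane); diel or
growth-phase expression *dynamics* within a state (samples are drawn
at state centers, not along trajectories); nutrient chemistry and UVR
dose-response; and mortality — collapse appears only through its
statistical precursors (scrambling, jitter, CV inflation), not as a
declining population.

## Statistical power of the small-replicate design

Two honest limits of triplicate cultures, both visible in the
acceptance script's measured rates: (i) a threefold Fv/Fm CV inflation
over 12 paired time-points clears exact Wilcoxon p < 0.005 in only
~78% of runs, because an n = 3 sample CV carries ~50% relative noise —
detecting at that stringency reliably needs either more replicates,
more time-points, or the larger inflation that real pre-collapse
cultures show; (ii) held-out pure-state classification plateaus near
94% under the 6-reference-samples-per-state design, for the coverage
reasons given above. The doubled-jitter dispersion signal, by
contrast, is detected at p < 0.01 in ~94% of simulations, and the
descriptor criteria recover planted descriptors essentially perfectly
at the default effect size.

## Problem sizes in the test suite

The suite runs the default 3000-gene study once, six 2-stage reference
builds for held-out classification, 100 simulations each for the two
detection-rate studies, and 1000 null simulations per calibration
check; the full suite completes in under a minute on one CPU, and
`scripts/acceptance.py` in about two. The pipeline demo config uses a
300-gene study purely to keep the end-to-end determinism check quick;
every statistical claim is made at the default sizes above.
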