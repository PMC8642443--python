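# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical conventions that affect results.

## Study design emulated

A within-subject crossover: every subject is measured in two sessions (real
and sham exposure), each session containing two baseline runs (Run1, Run2)
and four post-exposure runs (Run9–Run12), every run alternating 3-min
eyes-open (EO) and eyes-closed (EC) blocks sampled at 1000 Hz. The default
`ExperimentDesign` uses 29 subjects. Sensors are 102 triplet sites — one
radial magnetometer plus two orthogonal tangential planar gradiometers —
placed by a deterministic Fibonacci spiral on a spherical cap (head-model
sphere radius 0.09 m, sensor shell 0.102 m, cap half-angle 110°). Octant
region labels (left/right × frontal, temporal, parietal, occipital) are
assigned from the anterior–posterior angle; "posterior" means the parietal
and occipital octants.

## Synthetic band power

The central statistical object is per-cell log band power, generated
additively on the natural-log scale:

    log P = grand mean
          + subject intercept            ~ N(0, subject_sd)
          + eyes_ec_boost                (EC cells, posterior sensors)
          + log(effect_ratio)            (real session × post runs × target sensors)
          + residual                     ~ N(0, noise_sd)

Defaults: `subject_sd = 0.3`, `noise_sd = 0.2`, `eyes_ec_boost = 0.7`
(≈ doubling of posterior power with eyes closed, the characteristic
posterior alpha rise), `effect_ratio = 0.9` (a 10 % power decrease; the
validation studies below use 0.7 and 1.0). The field's literature reports
cluster masses rather than effect sizes, so `effect_ratio` is a free
generator parameter, documented here as the package's own choice — not an
estimate taken from any study. The target patch must be contiguous under
the layout adjacency (checked with connected components) and defaults to a
10-sensor posterior patch grown by breadth-first search.

The planted change is multiplicative on power (additive on log power)
because the statistics operate in the log domain. Effects apply to both
eyes conditions; the time×exposure structure makes the planted signal a
pure interaction in the omnibus ANOVA and a mean shift in the
baseline-corrected one-way test.

**What the generator does not emulate:** spatially correlated sensor noise,
per-sensor gain differences, run-order drifts, artifact residue, or any
dependence between the eyes boost and the exposure effect. Passing tests
therefore demonstrate the statistical machinery's correctness and
calibration under exchangeable Gaussian noise, not robustness to structured
real-world noise.

## Raw oscillatory signals

Each channel of `simulate_raw` is unit-variance 1/f^β-coloured Gaussian
noise (default β = 1, shaped in the frequency domain) plus a sinusoidal
alpha oscillation (default 10 Hz, channel-specific phase). EC blocks
multiply the alpha amplitude on posterior channels by
`ec_eo_amplitude_ratio` (default 2, i.e. a 4× band-power ratio). An
optional `EffectSpec` scales the alpha amplitude of target triplets by
√effect_ratio in real-session post runs, so the raw route plants the same
multiplicative band-power change at the oscillation peak. Per-run random
streams derive from `SeedSequence([seed, subject, session, run])`, making
every run independently regenerable.

## Spectral stage

* **FIR design.** Hamming window method; length `ceil(3.3 / (Δf/fs))`
  forced odd, on the narrower transition band (3301 taps at 1000 Hz). The
  −6 dB points sit at the transition-band midpoints — the only convention
  under which 1 Hz/1 Hz and 30 Hz/7.5 Hz edges give 0.50 Hz and 33.75 Hz.
  The residual DC gain of the window design (≈ −46 dB) is nulled exactly by
  subtracting the coefficient mean; this moves the −6 dB points by ~10⁻³ Hz
  and removes constant offsets completely.
* **Filtering** is single-pass linear-phase convolution with the group
  delay compensated and reflection padding, preserving −6 dB (not −12 dB)
  cut-off semantics; forward–backward filtering would square the response.
* **Welch PSD**: 512-sample Hamming windows, no overlap, per-segment mean
  removal, density normalisation (∫PSD df ≈ variance), trailing partial
  segments discarded.
* **Band power** is the *mean* (not sum) of PSD bins whose centre lies in
  the closed band interval — resolution-independent and determinate at band
  edges. On the 1000 Hz / 512-point grid (1.953125 Hz spacing) the 8–12 Hz
  band contains exactly the bins at 9.765625 and 11.71875 Hz, and 8–10 Hz
  exactly one bin. The alternatives (sum; open interval) are reasonable;
  mean + closed interval is this package's convention.
* **Log transform**: natural log in sensor space; 10·log₁₀ (dB) in source
  space with zero power floored at −300 dB. The downstream statistics are
  invariant to which monotone log is used within a stage.
* **Baseline correction** subtracts the mean of the two baseline runs from
  each post-exposure run per subject × session × eyes × sensor and drops
  the baseline rows.

## Source stage

The forward model is the closed-form field of a current dipole in a
spherically symmetric conductor: valid for any radial conductivity profile,
no surface meshing needed, and it preserves every mathematical property the
pipeline relies on (linearity, whitening, minimum-norm structure). Its
classic signature — radially oriented dipoles are externally silent — is a
correctness oracle in the tests. Magnetometer rows project the field on the
radial coil normal; planar-gradiometer rows are tangential finite
differences of that projection over a 16.8 mm baseline (typical planar
geometry; configurable).

The source grid is a recursively quadrisected octahedron projected to a
spherical shell (radius 0.07 m): depth d gives 2 + 4^(d+1) vertices, so
depth 5 yields the conventional 4098 dipoles per hemisphere; all synthetic
subjects share one grid, which is what template morphing achieves in real
group studies. Because a perfect sphere's outward normals are radial —
hence silent — `folded_normals` tilts each dipole normal by a smooth
sinusoidal "folding" pattern (tilt 1 ≈ 45°), emulating the non-radial
orientations of a convoluted cortical surface while keeping the vertex
grid spherical.

Whitening uses the inverse matrix square root of the (optionally
diagonally loaded) noise covariance; rank-deficient covariances are
rejected with a suggestion to pass a ridge. The minimum-norm kernel is
R Lᵂᵀ (Lᵂ R Lᵂᵀ + λ²I)⁻¹ with identity source covariance; by default R is
rescaled so trace(Lᵂ R Lᵂᵀ) equals the channel count, which makes
λ² = 1/9 the standard SNR-3 regularisation (λ², the gradiometer baseline,
depth weighting — absent here — and the covariance estimator are
package choices; they are configurable and not asserted to match any
specific study's unstated settings).

## Cluster permutation statistics

* **F maps.** For complete balanced within-subject designs the repeated-
  measures F for any effect is MS_effect / MS_(effect×subject), computed by
  inclusion–exclusion over marginal means (verified against statsmodels
  AnovaRM). For 2-level effects this equals the squared one-sample t of the
  per-subject contrast, which is what the vectorised permutation path uses.
* **Forming threshold**: the upper-tail F quantile at one-tail p = 0.05
  with df_effect = 1 and df_error = n_subjects − 1 for 2-level effects;
  membership requires F *strictly above* the threshold.
* **Permutation scheme.** Main effects: the factor's two levels are swapped
  independently per subject — a uniform draw over the 2ⁿ sign-flips of the
  per-subject contrasts; subjects are never exchanged with each other.
  Interactions: the full set of design-cell labels is permuted within each
  subject and the F map recomputed (the sign-flip subgroup is available via
  `interaction_scheme="sign_flip"`). When 2ⁿ ≤ n_permutations the test
  enumerates all sign patterns and the p value is exact.
* **p estimator**: add-one, p = (1 + #{perm max-mass ≥ observed}) /
  (1 + N) — never zero, valid by construction, and equivalent to the
  ">95 % of randomisations" decision rule at N = 1000 for any mass a real
  dataset produces. The strict percentile count/N is available via config.
* **Numerical detail**: the observed F map is computed as row 0 of the same
  sign-matrix product as the permuted maps; a separate 1-row product can
  differ in the last bit and silently exclude the identity relabelling from
  the null counts in exhaustive mode.
* **Degenerate inputs**: zero error variance with a non-zero effect is
  reported as the largest finite float (flag-like, still orderable); zero
  variance and zero effect give F = 0.

The per-run, per-eyes one-way tests are corrected for multiplicity across
space only (the cluster correction); no correction is applied across runs,
eyes conditions or bands, mirroring the per-run topographic reporting style
this pipeline reproduces — a known multiplicity limitation.

## HRV stage

RR series are stationary Gaussian AR(1): with marginal SD s and coefficient
φ, RMSSD = s√(2(1−φ)), so φ = 1 − RMSSD²/(2·SDNN²) hits both targets in
closed form; achievability requires 0 < RMSSD < 2·SDNN. Non-positive
intervals (possible in the Gaussian tail) are clipped to 1 ms with a
warning. Heart rate is the mean of per-beat 60/RRᵢ (the per-interval
formula; 60/mean RR is the obvious alternative and differs by Jensen's
inequality). SDNN uses the n−1 denominator. The R-peak detector is
Pan-Tompkins-style (5–15 Hz band-pass, squared derivative, 150 ms
integration, adaptive threshold, 0.2 s refractory period); its parameters
are package choices — what matters downstream is the exclusion contract:
a run is excluded when unlocatable-QRS segments individually shorter than
1.2 s total ≥ 30 s. The analysis window is 5 min per run.

## Pipeline orchestration and problem sizes

`run_experiment` executes, per band (8–12, 8–10, 10–12 Hz): dataset
generation, omnibus ANOVA cluster tests (time, eyes, exposure,
time×exposure by default), baseline correction, and per-run × per-eyes
real-vs-sham cluster tests — at the full study design (29 subjects,
102 triplets, 1000 permutations). The raw-signal source route runs at a
reduced scale chosen to keep the default run interactive (8 subjects,
16 s blocks, 250 Hz, depth-3 grid = 258 vertices); these sizes are config
fields, not limits of the method. Every stage's randomness derives from
`SeedSequence([master_seed, stage, ...])`, so a config reproduces its
report byte-identically; stage outputs (band-power TSVs, cluster JSON, HRV
TSV, report.json) are written eagerly for re-runnability.

The validation studies are likewise sized for a desk machine: the
family-wise-error study uses 500 global-null replicates at 200 permutations
each (the binomial bound 0.05 + 2√(0.05·0.95/500) ≈ 0.069 accounts for the
Monte-Carlo error of 500 replicates), and the recovery study uses 50
replicates of a 0.7-ratio effect at 1000 permutations, run on the EC
condition with post-exposure runs averaged — a single test per dataset, so
the measured rejection rate is a family-wise rate over space.

## Known limitations

* Sensor noise is exchangeable and Gaussian by construction; FWER control
  under heavy-tailed or spatially structured noise is not exercised.
* The spherical conductor and spherical cortical shell are geometric
  idealisations; absolute lead-field magnitudes are not anatomically
  calibrated, only their structure.
* The raw-route exposure effect scales a sinusoid's amplitude, so the
  realised band-power change is diluted by the 1/f background relative to
  the nominal ratio.
* Frequency-domain HRV, between-subject factors, threshold-free cluster
  enhancement and non-mass cluster statistics are out of scope.
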