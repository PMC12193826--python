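# Methods

This note records the models, parameter choices and numerical decisions
behind `uteqmt`, and what the synthetic data do and do not establish.

## Two-pool MT steady state

The MMF estimator inverts a continuous-wave power-equivalent (CWPE)
steady-state solution of the binary spin-bath model. Pools: free water (a)
and semisolid macromolecules (b), equilibrium magnetizations M0a = 1 − f,
M0b = f; exchange through a fundamental rate constant R with directional
rates k_ab = R·M0b, k_ba = R·M0a (detailed balance at equilibrium).
Saturation rates under an off-resonance irradiation of CW-equivalent
amplitude ω₁ at offset Δ:

* bound pool: W_b = π·ω₁²·g(Δ, T2mm), with g the absorption lineshape;
* water: W_a = ω₁²/((2πΔ)²·T2w), the far-offset limit of the Lorentzian
  lineshape. At the protocol's minimum offset (2 kHz) and T2w = 30 ms,
  2πΔT2w ≈ 377, so the full Lorentzian differs negligibly.

The two coupled longitudinal rate equations are linear in (Mza, Mzb); the
implementation evaluates their closed-form solution, and the test suite
checks it against an independent `numpy.linalg.solve` of the same system
(relative error < 1e-3 over 100 random parameter sets spanning the
invariant box).

Assumptions: pure steady state (no transient modeling of the 11-spoke
readout train), no slice profile or B0 inhomogeneity, magnitude signals
only. The observed water T1 from the VFA/AFI map is used directly as 1/R1a
without a free-pool correction, and R1b is pinned at 1 s⁻¹ (standard, not
identifiable from saturation data).

## Lineshape

The semisolid pool uses the super-Lorentzian

    g(Δ) = ∫₀¹ √(2/π) · T2mm/|3u²−1| · exp(−2(2πΔT2mm/(3u²−1))²) du,

normalized to unit integral over angular offset. The reference evaluator
uses adaptive quadrature split at the singular direction cosine u = 1/√3.
Because g(Δ, T2) = T2·φ(Δ·T2), the fitting and simulation hot path uses a
cached log-log cubic spline of φ on x ∈ [10⁻⁴·⁵, 10] (700 nodes), accurate
to ~1e-8 relative — validated against the quadrature in the tests. The
super-Lorentzian diverges on resonance; offsets below 1 kHz are clamped to
1 kHz. Protocol offsets start at 2 kHz, so the clamp is a robustness policy
only. Gaussian and Lorentzian lineshapes are retained for testing.

## Saturation power

The pulsed MT train is mapped to its CW power equivalent:
ω₁max = θ/(p₁·τp) and ω₁ = ω₁max·√(p₂·τp/TR), with p₁ (mean/peak) and p₂
(mean-square/peak²) the pulse-envelope factors. The exam does not fix the
pulse envelope, so the default is a Fermi-like pulse with p₁ = 0.7,
p₂ = 0.6, τp = 8 ms, averaged over the MT TR of 102 ms; all four values are
protocol-file configurable so alternative calibrations can be tested. Since
the same protocol object drives both simulation and fitting, biomarker
round trips are insensitive to this calibration; absolute in vivo accuracy
would not be.

## Fitting

All nonlinear fits are bounded trust-region least squares
(`scipy.optimize.least_squares`).

* **T2***: two-parameter magnitude model S0·exp(−TE/T2*) (the single
  component the six-echo protocol supports), log-linear initializer, bounds
  T2* ∈ (0.1, 200] ms; a constant-offset variant sits behind a flag.
  Estimates pinned at a bound (non-decaying input) are flagged, not
  silently returned.
* **T1 (VFA)**: linearized SPGR regression (S/sin α vs S/tan α) seeds a
  nonlinear refinement; bounds T1 ∈ (0.05, 5] s. Flip angles are scaled by
  the AFI B1 map; AFI ratios outside (TR1/TR2, 1) are masked as
  noise-dominated. AFI defaults (TR1 = 20 ms, TR2 = 100 ms, nominal 45°)
  are declared protocol parameters.
* **MMF**: free parameters {f, R, T2mm, M0} with T1 fixed from the measured
  map and T2w pinned at 30 ms (configurable) — the saturation grid barely
  constrains T2w. Bounds f ∈ [0, 0.5], R ∈ [1, 500] s⁻¹, T2mm ∈ [1, 50] µs.
  A deterministic four-point multi-start over f ∈ {0.05, 0.10, 0.15, 0.25}
  guards against local minima; ties break toward the smallest f. Fitting is
  seed-free and bit-reproducible.
* **Volume mode** maps the scalar fitters over masked voxels; non-converged
  voxels are dropped from the output mask and counted in the provenance
  log. MTR needs no fit and is computed vectorized, masking voxels whose
  MT-off signal falls below a configurable noise floor (default off for
  noiseless phantoms; recommended ≈ 3× background noise on noisy data,
  where Rician bias dominates).

Noiseless round trips recover f to < 1e-3 absolute and T2*/T1 to < 1e-6
relative; under Rician noise at SNR 50 the median MMF estimate stays within
10 % of truth (200 repeats), with the upward noise-floor bias growing as
SNR falls.

## Phantom and simulation

The digital phantom is a flat layered slab (default 64×64×8; tests and the
CLI use 16×16×4 to keep volume fits fast — all sizes are spec parameters):
background / superficial (deep-articular) cartilage / a 3-voxel OCJ band /
subchondral bone, stacked along axis 0. Default truths (f, R s⁻¹, T2mm µs,
T1 s, T2* ms): cartilage (0.11, 40, 12, 1.4, 24), OCJ (0.16, 60, 10, 1.0,
17), bone (0.18, 70, 9, 0.8, 15) — the OCJ band is more bound and
shorter-T2* than the cartilage above it, reflecting its low water content
and high collagen concentration. A linear B1 gradient (0.95–1.05) crosses
axis 1. Simulation evaluates the forward models on every protocol arm and
applies Rician noise (magnitude of a complex Gaussian perturbation); the
background therefore follows the Rayleigh limit, which the tests check.

What the phantom does *not* emulate: anatomical curvature, partial volume,
motion, registration error, B0 effects, or multi-component T2* decay.
Passing round trips therefore demonstrate estimator correctness and noise
behavior, not in vivo accuracy.

## Cohort model

Per-subject biomarkers are drawn independently per group from normal
distributions truncated at zero with the observed group means/SDs (MMF
15.8 ± 1.4 vs 13.6 ± 1.2 %, MTR 42.5 ± 2.5 vs 38.3 ± 2.9 %, T2* 19.7 ± 2.6
vs 21.6 ± 3.8 ms), group sizes 21/24 and KL composition 17/4/9/15. The true
in vivo MMF/MTR distributions are non-normal but unpublished; truncated
normal is the declared default and between-biomarker correlation defaults
to 0 because no joint distribution is reported (both configurable). The
reader-noise generator adds two readings per biomarker, each truth +
independent Gaussian noise with variance σ²·(1−ICC)/ICC relative to the
between-subject variance, which makes the population ICC(2,1) exactly the
target; simulation calibration recovers a 0.94 target within 0.02.

Within-subject (per-ROI) spread is not part of the cohort model — the study
table carries only whole-knee values — so the phantom pipeline and the
cohort generator are deliberately independent routes into the statistics
layer.

## Statistics layer

* Normality: the named KS test is applied with Lilliefors (estimated
  parameter) critical values per group; a biomarker is treated as normal
  iff both groups pass at α = 0.05. The naive KS variant is available.
* Group comparison: Welch t-test when normal (unequal variances is the
  safer default for an unspecified "independent t-test"), else two-sided
  Mann–Whitney U (exact for small tie-free samples via scipy).
* Correlation with KL: Spearman (average ranks on ties) for MMF/MTR,
  Pearson for T2* — fixed per biomarker to match how each was analyzed.
* ROC: empirical AUC (scikit-learn), equal by construction to the
  Mann–Whitney identity U/(n0·n1) with half-credit ties — the test suite
  asserts the identity against an exhaustive pair count. The p-value against
  AUC = 0.5 uses the large-sample normal approximation to U without tie
  correction. Direction is explicit: lower MMF/MTR indicates disease,
  higher T2* does.
* Youden cut-off: candidates are midpoints between adjacent distinct scores
  plus ±∞ sentinels; ties in J break toward higher specificity; thresholds
  are reported on the original scale.
* ICC: two-way random, absolute agreement, single measure (ICC(2,1)) from
  ANOVA mean squares, with ICC(3,1) selectable; cross-checked against
  pingouin in the tests.
* No multiplicity correction is applied (each biomarker at α = 0.05),
  stated in the report.

The simulation-reproduction routine draws 1000 seeded cohorts and averages
the per-cohort empirical AUCs; the closed-form binormal AUC
Φ(|μ₁−μ₂|/√(σ₁²+σ₂²)) gives 0.884 / 0.864 / 0.660 for MMF / MTR / T2* as an
independent cross-check of the simulated means.

## Degenerate inputs and tie-breaks

Flat multi-echo signals pin T2* at its upper bound and are flagged; AFI
ratio r = 1 (zero effective flip) is masked; constant inputs to correlation
or zero-variance inputs to normality/ICC raise errors; empty ROI regions
are excluded from the whole-knee mean with a warning; per-subject failures
in a cohort run are logged and skipped, with zero successes fatal. Whole-
knee aggregation is the unweighted mean of the four region means (equal
regional weighting; a voxel-count-weighted mode sits behind the aggregation
output, since per-region means and counts are both returned).

## Known limitations

* CWPE steady state ignores the transient spoke train; MMF accuracy on real
  data depends on the pulse-shape calibration the protocol file declares.
* The phantom's MTR (~78 % in the OCJ band) reflects the default saturation
  calibration, not the in vivo ~40 % range; the cohort generator, not the
  phantom, carries the study-level biomarker distributions.
* ROI drawing, registration and KL grading are upstream of this package;
  label masks must share the image grid exactly (affine tolerance 1e-4).
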