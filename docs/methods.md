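# Methods

## The model

Gene expression over one light–dark cycle is modelled as a fixed-period
single cosinor,

    f(t) = M + A·cos(ωt − φ),   ω = π/12 rad/h (24-h period),

with mesor M (rhythm-adjusted mean level), amplitude A (half the
peak-to-trough span, same units as M) and acrophase φ (phase of the
peak, radians). Because the period is fixed, the model is linear in the
basis {1, cos ωt, sin ωt}: f(t) = M + β cos ωt + γ sin ωt with
A = √(β²+γ²) and φ = atan2(γ, β), and is fitted by ordinary least
squares. The fitted curve peaks at ZT = 12φ/π hours (one radian of
phase = 12/π ≈ 3.8197 h); acrophases are wrapped to [0, 2π) and peak
times to [0, 24). Period estimation, multi-component cosinors and
zero-amplitude F-tests are deliberately out of scope.

Rhythm detection uses the amplitude noise/signal statistic
P = SE(A)/A with the strict rule *rhythmic ⇔ P < 0.3*. SE(A) is not
uniquely defined by that statement; this package uses the delta method
on the OLS covariance Σ of (β, γ):

    Var(A) = (β²Σ_ββ + γ²Σ_γγ + 2βγΣ_βγ) / A²,

the standard single-cosinor construction. A Monte-Carlo check (2000
seeded refits at the study design) confirms the delta-method SE agrees
with the empirical SD of A within 15% under multiplicative log-normal
noise of SD 0.1 log2 units. For A below 1e−12 the statistic is set to
+∞ (never rhythmic) rather than dividing by zero. Identifiability
requires ≥ 4 observations on ≥ 3 distinct phases (times mod 24);
degenerate designs raise an error, which batch fitting converts to a
flagged row rather than an abort.

Fits can be run on all replicate observations (default; 54 points on
the full design) or on per-timepoint means. On balanced noiseless data
the two coincide; on real data they weight residual variance
differently, and both are exposed because either reading of a
means-plotted cosinor analysis is defensible. ZT0 and ZT24 are distinct
samples at the same circadian phase and are both retained, so that
phase carries double weight in the design matrix — the reason
Var(β) ≠ Var(γ) on the 9-point grid and the reason two noiseless
cosinor profiles correlate at cos(Δφ) only approximately there (exactly
on a duplicate-free full cycle).

## Quantification and reference stability

Relative expression is R = 2^−ΔΔCt, where ΔCt = Ct_target − Ct_ref
(Ct_ref the arithmetic mean over the reference set, equivalent to the
geometric-mean normalisation of quantities) and ΔΔCt subtracts the
calibrator ΔCt. The calibrator only fixes the unit of the expression
scale: the default is the per-gene mean ΔCt over all samples
(mean-centring, privileging no timepoint), with `zt0_mean` and `min`
(most-expressed sample → R = 1) as options. P, acrophase, letter groups
and correlations are all invariant to this choice; only mesor and
amplitude scale with it. No amplification-efficiency correction is
applied (efficiency is assumed 2.0).

geNorm is implemented as published: pairwise variation
V_jk = SD_samples(log2 q_j/q_k), stability M_j = mean_{k≠j} V_jk,
iterative exclusion of the highest-M gene down to two survivors, and
V(n/n+1) computed between log-scale normalisation factors (geometric
means) of the top-n and top-(n+1) ranked genes. Selection returns the
single most stable gene by default (the usage the study design implies)
or the smallest top-n set with V(n/n+1) < 0.15. Stability is invariant
to rescaling any single sample, a property the tests assert.

## Group comparisons

Per-gene differences across the nine timepoints use classical one-way
ANOVA followed by Duncan's multiple range test at α = 0.05. The least
significant range for a stretch of p ordered means is
R_p = q(1−α_p; p, df_error)·√(MSE/n_h) with Duncan's protection level
α_p = 1−(1−α)^(p−1) (studentized-range quantiles from scipy) and n_h
the harmonic mean group size. The procedure tests stretches longest
first; a stretch whose range falls inside R_p is declared homogeneous
and protects all sub-stretches. Because homogeneity is then closed
under containment, the compact letter display reduces to the maximal
homogeneous intervals of the descending-mean order; letters are
assigned 'a', 'b', … from the highest mean. With zero within-group
variance, unequal means are always separated (F = +∞) and equal means
never are. Letters are invariant to group input order and to affine
transforms of the data.

## Correlation screening

Pairs are correlated on per-timepoint mean profiles (9 values ordered
by ZT) — replicates are distinct animals, so no within-sample pairing
exists and replicate-level correlation would mix biological rhythm with
fish-to-fish noise. A pair is retained when |r| > 0.5 and at least one
member is rhythmic; |r| ≥ 0.80 is labelled strong and 0.5 < |r| < 0.80
moderate (the published category note leaves [0.79, 0.80) unassigned;
it is resolved as moderate), with the sign reported as direction.
No correlation p-values are computed, matching the screening-only use
of the statistic.

## Synthetic data

The generator emulates the study design: 9 Zeitgeber times (0–24 h,
step 3), 6 replicates per time, ~26 target genes per tissue whose
(M, A, φ) default to the published table values, plus six candidate
reference genes. Noise is multiplicative log-normal on expression —
value = f(t)·2^ε, ε ~ N(0, σ²) on the log2 scale — i.e. additive
Gaussian on Ct, the natural qPCR error structure; the study reports
only mean ± SEM, so the default σ = 0.1 log2 units is a choice of
realistic replicate spread, not a calibrated one. Ct tables are derived
as ct = base_ct − log2(value) (default base 22 cycles), so a doubling
of expression is exactly one cycle. Each gene draws from a child random
stream keyed by (root seed, panel position), so appending genes never
perturbs earlier genes' draws and equal seeds give byte-identical
tables.

Six published rows print A ≥ M (e.g. fast-muscle mbnl1, A = 1.30 vs
M = 1.02), which would drive the noiseless trough negative and the
simulated Ct to infinity; in the default panels the amplitude is capped
at 0.95·M. The stable reference candidates are flat genes with σ
between 0.04 (rpl13, the quietest, mirroring the study's geNorm winner)
and 0.12; 18S rRNA is modelled as the unstable candidate with a
deterministic drift of 1 log2 unit across the day. The generator does
not model amplification-efficiency variation, plate effects or
between-tank differences, so passing tests demonstrate correctness of
the analysis chain under the assumed error model, not robustness to
those real-world artefacts. In particular, simulated P values need not
reproduce the published ones: several genes printed as arrhythmic have
large published A/M ratios and are detected as rhythmic under any
modest noise level, implying the real measurements were considerably
noisier for those genes than the mean ± SEM presentation suggests.

## Numerical choices and edge cases

- Acrophases within 1e−9 of 2π wrap to exactly 0 (atan2 roundoff).
- The rhythmic rule is strictly `P < threshold`; P = 0.3 is arrhythmic.
- The published fast-muscle crydash row prints a peak ZT (8.09 h)
  inconsistent with its own printed acrophase (2.13 rad → 8.14 h) at
  any tolerance derivable from two-decimal rounding
  (0.005·12/π + 0.005 ≈ 0.024 h); it is treated as a misprint and
  reported separately by the consistency checks. All other 51 rows are
  consistent within that rounding bound.
- Gene names are normalised on ingest (case-folding, 'rorα' → 'rora',
  'cry-dash' → 'crydash').
- Simulation sizes in the test suite (e.g. 500 recovery replicates,
  200 geNorm replicates, 1000 null ANOVA draws) were chosen to give
  stable Monte-Carlo estimates at interactive runtimes.

## Shape of the API

The three genuinely estimator-shaped operations follow the
scikit-learn protocol — `CosinorRegressor` (fit/predict on times and
values), `DeltaDeltaCt` (transformer from Ct tables to expression
tables) and `GeNormSelector` (fit/get_support/transform on quantity
tables) — with fitted attributes carrying trailing underscores, so they
compose with sklearn tooling. Duncan letters, correlation screening,
the simulator and the pipeline are procedures over tables rather than
fit/predict objects and are exposed as plain functions; module-level
functions mirror every estimator for script use.
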