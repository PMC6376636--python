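# Methods

## Model and hypotheses

Expression of gene *g* in sample *i* is modeled as a linear function of the
design row `x_i`: `E(y_gi) = x_iᵀ β_g`, with i.i.d. Gaussian errors within a
gene.  Time of day enters through the first harmonic of a Fourier series of
fixed period (default 24 h): `cos θ_i`, `sin θ_i` with `θ_i = 2π t_i / period`.
Higher harmonics may be added for non-sinusoidal waveforms, and a raw linear
time term for drift across several free-running cycles.  The design row is
ordered `[1, factor terms, other covariates, time terms, factor × time
terms]`; categorical variables use reference-level indicator coding with the
alphabetically first level as reference, and continuous covariates enter
unscaled (an optional centering flag exists purely for numerical
conditioning).

Three hypotheses map onto coefficient sets:

* **rhythmicity** — the time terms are all zero;
* **differential rhythmicity (DR)** — the factor × time interaction terms are
  all zero (a change in amplitude and/or phase between conditions);
* **differential expression (DE)** — the factor main effect is zero in the
  additive (no-interaction) model.

With exactly three distinct time points, the cosinor pair spans the same
column space as two time-category indicators, so the time test is identical
to a one-way ANOVA on time; with more time points the cosinor basis favors
sinusoidal variation, which ANOVA ignores.

The period and the alignment of time points across conditions are
assumptions, not estimates: the package does not detect period differences,
and results on free-running data with condition-dependent period should be
interpreted with caution.

## Empirical-Bayes moderation

Per-gene OLS gives `β̂_g`, residual variance `s_g²` on `d_g = n − p` df, and
average expression `A_g`.  The gene-wise variances are modeled as
`s_g² ~ s0² · F(d_g, d0)` (equivalently, true variances follow a scaled
inverse-chi-square prior with df `d0` and scale `s0²`).  Writing
`e_g = log s_g² − ψ(d_g/2) + log(d_g/2)` (ψ the digamma function):

* the excess of the empirical variance of `e` over `ψ′(d_g/2)` equals
  `ψ′(d0/2)`, solved for `d0` by inverting the trigamma function (Newton
  iteration from the asymptotic start `y ≈ 0.5 + 1/x`, relative tolerance
  1e-8);
* the mean of `e` equals `log s0² − ψ(d0/2) + log(d0/2)`, giving `s0²`.

If the observed spread does not exceed the pure sampling spread, `d0 = ∞`
(full shrinkage; the moderated F uses a chi-square reference).  If every
`s_g²` is *exactly* identical — a degenerate input arising only with
synthetic data — the prior is a point mass at the common value.  Genes with
`s_g² = 0` (perfect fits) enter prior estimation through a floor of 1e-10 in
log space and are flagged.

With the mean-variance trend enabled (the default in the workflow), the
location of `e` is a locally weighted linear regression on `A_g`
(statsmodels lowess, window fraction 0.5, 3 robustness iterations, delta
1% of the `A` range for speed), so `s0²(A_g)` varies smoothly with
expression level while `d0` comes from the spread about the curve.  The
smoother and its span are package choices — only the existence of a trend is
part of the model — and are configurable; agreement with other moderation
implementations is therefore exact in the untrended case and approximate in
the trended case.

Moderated statistics replace `s_g²` by the posterior
`s̃_g² = (d0 s0² + d_g s_g²)/(d0 + d_g)`:
`F = (β̂_Sᵀ V_S⁻¹ β̂_S / |S|) / s̃_g²` on `(|S|, d0 + d_g)` df for a tested set
`S` with unscaled covariance block `V_S`, and `t = β̂_j / (u_j s̃_g)` on
`d0 + d_g` df.  `d0 = 0` recovers classical per-gene OLS inference exactly;
`d0 = ∞` uses `s0²` with chi-square/normal references.

## The three-step workflow

1. **Rhythmicity.**  For two-condition designs the default detector fits the
   cosinor model separately within each condition (its own variance prior per
   condition, since each model has its own residual structure) and tests the
   time pair by moderated F.  The per-gene minimum p across conditions,
   BH-adjusted, is `q_rhy` (rhythmic in at least one condition); the maximum
   gives `q_rhy_max` (rhythmic in both — the prerequisite for interpreting a
   phase difference).  A per-gene, per-condition p-value table from any
   external rhythm detector can be substituted.  For continuous-moderator
   designs, step 1 is a moderated F on the time pair of the additive model,
   optionally gated by a rhythm-amplitude cutoff computed from a cosinor fit
   to covariate-adjusted residuals.
2. **Differential rhythmicity.**  The interaction model is fit to the
   rhythmic genes only (prior re-estimated on that subset), the interaction
   set tested by moderated F, and `q_dr` computed within the rhythmic set.
3. **Differential expression.**  The additive model is fit to the complement
   of the examined-and-DR set — genes with `q_dr` above cutoff *or* `q_rhy`
   above cutoff — and the factor main effect tested by moderated t, giving
   `q_de` and the log₂ fold-change (the coefficient itself, for an indicator
   factor).

Default cutoffs: `q_rhy ≤ 0.01` (suited to densely sampled designs; sparser
designs typically use 0.1), `q_dr ≤ 0.1`, `q_de ≤ 0.01`.  Each gene receives
exactly one class label (non-rhythmic, rhythmic-only, differentially-
rhythmic, differentially-expressed, rhythmic-and-DE), consistent with the
cutoffs by construction.  FDR control is Benjamini–Hochberg step-up; the
procedure name is recorded in run metadata, and the surface is pluggable
should a π0-adaptive variant be preferred.

## Rhythm parameters

From a first-harmonic fit, amplitude is the coefficient norm
`√(β_cos² + β_sin²)` — half the fitted peak-to-trough — and acrophase is
`(period/2π)·atan2(β_sin, β_cos)` wrapped to `[0, period)`.  Zero amplitude
leaves the acrophase undefined (flagged, reported as 0 by convention).
Δamplitude is the arithmetic difference (alternate − reference); Δacrophase
is the circular difference (reference − alternate) wrapped to
`(−period/2, +period/2]`, so a positive value means the alternate condition
peaks earlier (phase advance); the antipodal difference maps to +period/2.
These are descriptive post-hoc quantities, not tests: no confidence
intervals are attached, and for genes nearly arrhythmic in one condition the
phase difference is dominated by noise.

## Simulation

The generator emulates an entrained two-condition time course: 2 replicates
every 2 h over 24 h per condition (48 samples), 10,080 genes with 75%
non-rhythmic, sinusoidal rhythms of period 24 h, baselines of 0 (expression
centered around zero), and additive i.i.d. Gaussian noise with SD 1.  Rhythm
phases are uniform on [0, 24).  A DR gene set (default 504 genes; the
25%-of-rhythmic reading, 630, is one config field away) is parameterized by
mean amplitude, Δamp, and Δphase, each split symmetrically ±Δ/2 between
conditions so the nominal mean is exact; Δamp may reach at most twice the
mean amplitude, at which point one condition is arrhythmic and Δphase must
be undefined.  The default effect (Δamp = 1, Δphase = 6 h at mean amplitude
1) is a representative mid-grid point; the default evaluation grid holds the
mean amplitude at 1 and crosses Δamp {0, 0.25, …, 1.75} with Δphase
{0, 2, …, 12} h, dropping the null point and adding the arrhythmic boundary
(Δamp = 2, Δphase undefined) — 56 dataset configurations, one dataset each,
all fully overridable.

What the generator does **not** emulate: count-scale noise (RNA-seq
negative-binomial dispersion), mean-dependent variance, non-sinusoidal
waveforms, autocorrelated or heavy-tailed noise, and batch structure.
Passing tests therefore demonstrate correctness of the estimation and
testing machinery under the Gaussian sinusoid model, not robustness to every
property of real data.

## Evaluation and the permutation null

ROC/AUC uses the exact rank (Mann–Whitney) formulation with half-credit for
ties; positives are truth-DR genes and negatives default to rhythmic-but-
not-DR genes, isolating the DR test from the rhythm detector.  TPR is the
fraction of truth-DR genes with nominal `p ≤ 0.01` (unadjusted).

The permutation null fixes the rhythmic gene set from the true labels, then
repeatedly shuffles condition labels *within samples sharing a time point* —
preserving rhythmic structure while destroying genuine condition differences
— and recomputes step-2 q-values on the fixed set.  Permutations sample
uniformly among within-block arrangements without enforcing uniqueness
across permutations; single-sample blocks are left fixed with a warning.
Counts are summarized per dataset by the mean over permutations and across
datasets by the geometric mean; when a zero count makes the geometric mean
undefined, a +1 offset is applied and reported alongside the value.

## Numerical choices and degenerate inputs

* OLS via QR decomposition; `(XᵀX)⁻¹` from the triangular factor.
* Design rank is checked by SVD: smallest/largest singular value below
  1e-10 raises an error naming the collinear columns (pivoted-QR
  diagnosis).  A confounded design — e.g., a donor term when both of a
  donor's samples share age and time — fails here rather than silently.
* `β̂ = 0` yields statistic 0 and p = 1 exactly; singular tested-set
  covariance blocks raise a design error.
* Missing values are rejected, not imputed; duplicate gene/sample IDs are
  identity errors.
* Expression TSVs are written with `%.17g`, so write→read round-trips are
  bit-exact; all seeded runs are byte-reproducible.
* Abundance filtering keeps genes with TPM ≥ 0.5 in at least
  `ceil(fraction × n_samples)` samples (a literal "at least half"), and the
  log transform is `log2(TPM + 1)`.

## Problem sizes used in checks

The bundled acceptance script runs the full-size configurations (10,080
genes, 48 samples, 50 permutations, 56 grid datasets); the unit suite uses
scaled-down instances (hundreds of genes) chosen to keep each property
sharply testable.

## Known limitations

* No random-effects or duplicate-correlation modeling: subjects are fixed
  blocks.
* No count-based models (precision weights, negative-binomial GLMs); inputs
  are assumed approximately Gaussian on the log scale.
* No period estimation or cross-condition time realignment.
* No joint omnibus test of main effect plus interaction; the workflow's
  sequential gating means DE is only assessed for genes not classified DR.
* The amplitude cutoff in the continuous workflow uses residual-based
  amplitudes, which are biased downward when covariates absorb rhythmic
  variance.
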