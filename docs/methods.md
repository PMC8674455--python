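# Methods

## Model and estimation

The package operates on the usual two-stage summary-statistics approximation
to the hierarchical group model: subject-level contrast images are taken as
data, and the group effect at voxel *v* is estimated by OLS on the group
design, giving `θ̂_v = c(XᵀX)⁻¹XᵀY_v` with sampling variance
`u_v = λ̂_v · c(XᵀX)⁻¹cᵀ`, `λ̂_v = RSS_v/(N−p)`. Contrasts follow the
convention that the positive weights sum to one, so θ stays in percent
signal change. For the two-sample family the error variance is estimated
per group and `u_v = λ̂₁/n₁ + λ̂₂/n₂` with Welch–Satterthwaite degrees of
freedom; this closed-form heteroscedastic treatment replaces SPM-style
pooled non-sphericity ReML, which has no closed form at the voxel level and
is not needed for scalar contrasts. Paired designs are differenced upstream
and handled as one-sample. Degenerate voxels (zero residual variance) have
`u` floored at 1e-12 PSC² and a warning is logged.

Shrinkage is applied to the scalar contrast θ, not to the full β vector.
This makes the "prior SD of the effect" exact: the prior is literally
`θ ~ N(0, σ_p²)` and the default ROPE radius γ = 1 prior SD refers to that
same σ_p. SPM parameterises the prior on model parameters internally; for
the designs supported here the contrast-level convention is equivalent in
effect and easier to verify, and is documented as a deliberate choice.

σ_p² is estimated by EM on the pooled marginal model
`θ̂_v ~ N(0, σ_p² + u_v)` with the `u_v` plugged in as known — the standard
random-effects meta-analysis estimator. The EM update is
`σ_p² ← mean_v(m_v² + s_v²)` with the conjugate per-voxel posterior moments
computed under the current prior; it never decreases the marginal
likelihood and its fixed point matches an independent 1-D maximisation of
the marginal likelihood to 1e-6 in the tests. Initialisation is the moment
estimate `max(0, mean(θ̂²) − mean(u))`; convergence is a 1e-8 relative
change with a 500-iteration cap; the procedure is deterministic.
A boundary estimate σ_p² = 0 is legal and collapses every posterior to a
point mass at zero (the data show no map-wide effect variance beyond
sampling noise).

Posterior variance is computed in closed form,
`s² = σ_p² u/(σ_p² + u)`; the first-order Taylor reconstruction that SPM
uses to recover posterior variance from its noise hyperparameter image is
deliberately not replicated.

## Decision rules and numerical conventions

* Probabilities use exact Gaussian CDFs; `P_act + P_deact + P_null = 1`
  holds to 1e-12 by construction and is property-tested.
* Decisions threshold the probability at `p ≥ 0.95` (ties count as
  reaching the threshold). LPO maps are produced for visualisation; note
  LPO > 3 corresponds to p > 0.9526, slightly stricter than p ≥ 0.95 — the
  probability is primary here.
* Log posterior odds and log Bayes factors are capped at ±38 (the logit of
  probabilities at the edge of float64 resolution) so maps are finite and
  viewable; all odds are computed on the log scale with complementary
  normal CDFs, so the cap, not catastrophic cancellation, is the binding
  limit in deep tails.
* The Gaussian HDI equals the central interval and is computed that way; no
  general HDI search is implemented. An HDI endpoint exactly on the ROPE
  edge counts as overlap (low confidence); for ROPE-only, a probability
  exactly at threshold counts as a decision. Both tie-breaks are
  deterministic and stated.
* Zero-width posteriors (degenerate prior) are treated as point masses with
  the closed ROPE interval.
* ROPE maps use the closed forms `γ*_act = m − z·s`, `γ*_deact = −m − z·s`
  (reported only when positive) and solve `P_null(γ) = p_thr` by monotone
  bisection on `[0, |m| + 10s]` to 1e-6; the closed forms agree with a
  bisection oracle in the tests.
* Savage–Dickey Bayes factors use the standard orientation
  posterior(0)/prior(0): values below one favour a real effect. The
  interval Bayes factor satisfies
  `log BF(ROPE)_null = LPO_null + log prior-odds(θ∉ROPE)` identically and
  converges to the Savage–Dickey value as γ → 0; both identities are
  asserted numerically.
* Voxel-wise familywise control in the NHST comparator is Bonferroni (FDR
  is Benjamini–Hochberg via statsmodels). Random-field-theory FWE is out of
  scope: it requires smoothness estimation and is orthogonal to the
  Bayesian contribution, so published Dice-to-FWE values obtained with RFT
  are approximated, not reproduced, by the Bonferroni comparator.
* The Dice calibration grid defaults to γ ∈ [0, 0.4] PSC in 0.001 steps;
  ties at the maximum resolve to the smallest γ.

## Synthetic data

The phantom generator emulates a group analysis with known truth: 579
activated, 500 deactivated voxels (effect ±0.1, 0.2 or 0.3% PSC) and 3067
trivial voxels (±0.04% PSC, sign drawn once per layout per voxel), noise
SD 0.2–0.4% PSC, 1000 images per condition — contrast-to-noise 0.25–1.5.
The spatial layout is a contiguous-block 2-D grid: estimation is
voxel-wise, so geometry is irrelevant to decision rates, and synthetic
blobs replace meta-analysis-derived masks that would require an external
download. No smoothing is applied in the main simulation; the conceptual
two-glyph phantom (100 images, 50×50 voxels, 2-voxel-FWHM smoothing) is
the only smoothed dataset.

Noise is drawn from the Pearson distribution system, selected by the
standard κ criterion from the requested (Sk, Ku): normal at (0, 3),
symmetric or four-parameter beta for platykurtic/skewed cells, rescaled
Student t for (0, 7), and Pearson Type IV — sampled by inverse-CDF in the
arctan variable, where the density `cos^{2m−2}(u)e^{−νu}` is smooth and
bounded — for skewed leptokurtic cells such as (±0.7, 7). Note that
(0, 7) and (±0.7, 7) cannot be beta distributions; the full selection rule
is implemented instead of forcing one family. Types III/V/VI (gamma,
inverse-gamma, beta-prime) are included for completeness via moment
matching. Every sampler is standardised with theoretical moments, so
sample moments converge to specification (verified at n = 10⁶ with
tolerances 0.01/0.01/0.05/0.3 on mean/SD/skewness/kurtosis). Infeasible
moment pairs (Ku ≤ Sk² + 1) raise an error citing the bound.

What the phantom does **not** emulate: spatial autocorrelation, subject
heterogeneity of noise level, physiological confounds, or any subject-level
time-series structure. Passing decision-rate tests therefore demonstrates
the statistical behaviour of the inference machinery under controlled
violations of normality, not performance on real fMRI artefacts.

## Sweeps and scoring

Decision rates use true counts as denominators: correct = hits/true count,
incorrect = false alarms/count of non-members, low confidence =
undecided/total. A category absent from the truth yields *undefined* (null)
rates, never zero. Sample-size sweeps draw without-replacement subsamples
with one generator per repetition (`base_seed + repetition`), and the prior
SD — hence γ when expressed as a prior-SD multiple — is re-estimated on
every subsample, mirroring real use at each N. The default N grid is
10–100 in steps of 10 and 150–500 in steps of 50, ten repetitions per
point. The γ sweep reports the band where correct rates exceed 80% and
incorrect rates stay at or below 5% for both the activated and
not-activated categories.

## Validation scales and known limitations

The validation script and acceptance tests run the full protocol (1000
images, 4146 voxels, ten repetitions, all nine noise cells) in well under a
minute on one CPU, so no scaling down was needed. One known discrepancy is
documented: at the moderate-effect/medium-noise cell, the exact
Gaussian/EM pipeline puts the activated-correct-rate crossing of 80%
between N = 80 and N = 90 (analytically ≈ 76% at N = 80), slightly later
than the published crossing at N = 80 obtained with SPM's ReML machinery;
the corresponding test asserts the published bound and documents the gap
rather than adjusting any condition. Other limitations: no spatial priors
or cluster-level inference, no covariates at the group level, no
random-field-theory FWE, NIfTI-1 volumes only.
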