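# bpimap

Group-level **Bayesian parameter inference (BPI)** for mass-univariate
statistical brain maps.

Classical group fMRI analysis tests the point-null hypothesis voxel by voxel
and can only declare voxels "significant" — it cannot say that an effect is
*practically absent*, and it conflates statistical with practical
significance. `bpimap` implements the Bayesian alternative for stacks of
per-subject contrast images (BOLD percent signal change, PSC): every voxel
gets a posterior distribution of its effect, and decisions are made relative
to a **region of practical equivalence (ROPE)** `[-γ, γ]`, where γ is the
smallest effect considered practically meaningful. This yields a four-way
classification — *activated*, *deactivated*, *not activated* (practically
null), and *low confidence* (more data needed) — instead of the binary
significant/non-significant map.

## Model

Per-voxel group effects come from the two-stage summary-statistics GLM
`Y = Xβ + ε`: OLS gives the contrast estimate `θ̂_v` and its sampling
variance `u_v` (one-sample, Welch two-sample, and paired designs).
A **parametric empirical Bayes** step places a single zero-mean Gaussian
"global shrinkage" prior on the effect at every voxel,

    θ_v ~ N(0, σ_p²),        θ̂_v | θ_v ~ N(θ_v, u_v),

and estimates σ_p² by maximising the pooled marginal likelihood
`θ̂_v ~ N(0, σ_p² + u_v)` with EM. The conjugate posterior at each voxel is

    m_v = θ̂_v σ_p² / (σ_p² + u_v),      s_v² = σ_p² u_v / (σ_p² + u_v),

so noisy estimates shrink toward zero — an automatic multiplicity control.
From the Gaussian posterior, three probabilities

    P_act = P(θ > γ | D),  P_deact = P(θ < -γ | D),  P_null = P(-γ ≤ θ ≤ γ | D)

(summing to one) drive the **ROPE-only** rule (label when one reaches
P_thr = 95%) or the more conservative **HDI+ROPE** rule (position of the 95%
highest-density interval relative to the ROPE). The default effect-size
threshold is γ = 1 prior SD of the effect (`σ_p`). The toolbox also produces
log posterior odds (LPO) maps, interval (ROPE) and Savage–Dickey point-null
log Bayes factor maps, **ROPE maps** (per-voxel critical γ*), a classical
NHST comparator (t-maps with Bonferroni/FDR correction, Dice-overlap γ
calibration, Shapiro–Wilk normality diagnostics), and a fully synthetic
**Pearson-system phantom** harness with known ground truth for validating
decision rates under Gaussian and non-Gaussian noise.

## Worked example

```python
import bpimap as bp

phantom = bp.build_phantom(
    bp.PhantomSpec(effect_act=0.2, noise_sd=0.3, n_images=200, seed=1)
)
decisions = bp.run_pipeline(phantom.stack.data)   # OLS -> EB prior -> ROPE rule
rates = bp.decision_rates(decisions, phantom.truth)
print(decisions.posterior.prior.prior_sd, decisions.counts(), rates.low_confidence)
```

Running `python examples/01_classify_phantom.py` prints:

```
estimated prior SD of the effect: 0.1081 % PSC (5 EM iterations)
ROPE radius gamma = 1 prior SD = 0.1081 % PSC
label counts: {'activated': 574, 'deactivated': 497, 'not_activated': 2933, 'low_confidence': 142}
  correct     activated: 0.991   incorrect: 0.0000
  correct   deactivated: 0.994   incorrect: 0.0000
  correct not_activated: 0.956   incorrect: 0.0000
  low-confidence rate: 0.034
```

The phantom holds 579 truly activated, 500 deactivated and 3067 trivial
(±0.04% PSC) voxels; with 200 images the pipeline recovers over 99% of the
real effects and declares 95.6% of trivial voxels practically null, with no
incorrect decisions — only 3.4% of voxels remain undecided. The other
scripts in `examples/` demonstrate ROPE/Bayes-factor maps, Dice calibration
of γ against the classical FWE map, and sample-size planning curves.

Real NIfTI data flow through the same API (`bp.load_group_stack`,
`bp.estimate`, `bp.classify`, `bp.write_map`) or the `bpimap` command line
(`estimate`, `classify`, `ropemap`, `bayesfactor`, `nhst`, `dice-calibrate`,
`simulate`, `evaluate`, `sweep`).

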