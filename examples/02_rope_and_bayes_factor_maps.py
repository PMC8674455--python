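"""ROPE maps and Bayes factor maps for a handful of voxels.

Shows the reversed thresholding sequence: instead of fixing the effect-size
threshold gamma and classifying, each voxel reports its critical gamma*
(the largest ROPE still supporting an activation decision, or the smallest
ROPE that makes it practically null), plus interval and point-null Bayes
factors.
"""

import numpy as np

import bpimap as bp
from bpimap.design import fit_ols, make_design

rng = np.random.default_rng(7)
# five voxels: strong, moderate, weak, null-ish, negative effects
true_means = np.array([0.4, 0.2, 0.08, 0.0, -0.3])
data = true_means + rng.normal(0, 0.3, size=(60, 5))

summary = fit_ols(data, make_design("one_sample", 60))
posterior = bp.estimate(summary)
prior_sd = posterior.prior.prior_sd
rmap = bp.rope_map(posterior, rule="rope_only", p_thr=0.95)
log_bf = bp.bf_rope(posterior.post_mean, posterior.post_sd, prior_sd, gamma=0.1)
log_sdr = bp.bf_sdr(posterior.post_mean, posterior.post_sd, prior_sd)

print(f"prior SD = {prior_sd:.4f} % PSC")
print("voxel  post_mean  gamma*_act  gamma*_null  logBF_rope(0.1)  logBF_sdr")
for i in range(5):
    act = rmap.gamma_star_act[i]
    print(f"{i:>5}  {posterior.post_mean[i]:+9.4f}  "
          f"{act if np.isfinite(act) else float('nan'):10.4f}  "
          f"{rmap.gamma_star_null[i]:11.4f}  {log_bf[i]:15.3f}  {log_sdr[i]:9.3f}")
# gamma*_act is the largest ROPE radius at which the voxel is still declared
# activated (NaN if never); gamma*_null the smallest radius at which it
# becomes practically null.  Negative log Bayes factors favour a real effect.
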