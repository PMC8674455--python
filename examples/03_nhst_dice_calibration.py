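"""Compare Bayesian and classical maps and calibrate gamma by Dice overlap.

The classical comparator is a voxel-wise one-sided t-test with Bonferroni
familywise correction.  Sweeping the ROPE radius gamma and computing the
Dice overlap between the Bayesian 'activated' mask and the classical
significant mask finds the gamma at which the two analyses agree best.
"""

import bpimap as bp
from bpimap.design import fit_ols, make_design
from bpimap.nhst import NhstConfig, gamma_dice_search, nhst_map

phantom = bp.build_phantom(
    bp.PhantomSpec(effect_act=0.2, noise_sd=0.3, n_images=200, seed=3)
)
data = phantom.stack.data

summary = fit_ols(data, make_design("one_sample", data.shape[0]))
posterior = bp.estimate(summary)
classical = nhst_map(summary, NhstConfig(alpha=0.05, correction="bonferroni"))
result = gamma_dice_search(summary, posterior)

bayes_mask = bp.classify(
    posterior, bp.RopeConfig(gamma=result.gamma_dice_max)
).label == bp.ACTIVATED
print(f"classical FWE-significant positive voxels: {int(classical.positive.sum())}")
print(f"gamma(Dice_max) = {result.gamma_dice_max:.3f} % PSC, "
      f"Dice_max = {result.dice_max:.3f}")
print(f"Bayesian activated voxels at that gamma: {int(bayes_mask.sum())} "
      f"(true count {int((phantom.truth == bp.ACTIVATED).sum())})")
# A Dice near 1 means the Bayesian activation mask at this gamma almost
# coincides with the classical FWE-corrected map, while the Bayesian
# analysis additionally separates 'not activated' from 'low confidence'.
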