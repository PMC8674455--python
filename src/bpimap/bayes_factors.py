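"""Interval (ROPE) and point-null (Savage-Dickey) Bayes factors.

The interval Bayes factor compares the composite hypotheses
M_null: theta in [-gamma, gamma] versus M_alt: |theta| > gamma by the
ratio of posterior to prior odds of ROPE membership,

    BF_null = [P(ROPE | D) / (1 - P(ROPE | D))] / [P(ROPE) / (1 - P(ROPE))],

so log BF_null = LPO_null + log prior odds of lying outside the ROPE: the
log posterior odds map and the log BF map differ voxel-wise only by a
constant.  As gamma shrinks to zero the interval Bayes factor converges to
the Savage-Dickey density ratio, implemented here in the standard
orientation posterior(0)/prior(0): values below one mean the effect is less
likely to be exactly zero after seeing the data, i.e. evidence for M_alt.

All computation is on the log scale with complementary CDFs for tail
stability, capped at +/-38.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr, ndtr

from scipy.stats import norm

from .volumes import LPO_CAP


def _log_rope_odds(mean, sd, gamma):
    """log [P(|theta| <= gamma) / P(|theta| > gamma)] for N(mean, sd^2).

    The inside mass is evaluated in whichever complementary form keeps the
    CDF difference accurate; the outside mass sums two one-sided tails on
    the log scale, so deep-tail odds stay finite until the final cap.
    """
    mean = np.asarray(mean, dtype=float)
    z_hi = (gamma - mean) / sd
    z_lo = (-gamma - mean) / sd
    p_in = np.maximum(ndtr(z_hi) - ndtr(z_lo), ndtr(-z_lo) - ndtr(-z_hi))
    with np.errstate(divide="ignore"):
        log_in = np.log(np.clip(p_in, 0.0, 1.0))
    log_out = np.logaddexp(log_ndtr(-z_hi), log_ndtr(z_lo))
    return log_in - log_out


def bf_rope(posterior_mean, posterior_sd, prior_sd, gamma, cap: float = LPO_CAP):
    """Natural-log interval Bayes factor for the null (ROPE) model.

    Posterior is N(m, s^2), prior is the global shrinkage prior
    N(0, prior_sd^2); both ROPE masses come from Gaussian CDFs.
    """
    if np.any(np.asarray(gamma) <= 0):
        raise ValueError("bf_rope requires gamma > 0; use bf_sdr for a point null")
    if prior_sd <= 0:
        raise ValueError("bf_rope requires a nondegenerate prior (prior_sd > 0)")
    with np.errstate(invalid="ignore"):
        log_bf = _log_rope_odds(posterior_mean, posterior_sd, gamma) - _log_rope_odds(
            0.0, prior_sd, gamma
        )
    return np.clip(np.nan_to_num(log_bf, nan=0.0, posinf=np.inf, neginf=-np.inf), -cap, cap)


def bf_sdr(posterior_mean, posterior_sd, prior_sd, cap: float = LPO_CAP):
    """Natural-log Savage-Dickey point-null Bayes factor.

    Ratio of posterior to prior density at theta = 0.
    """
    if prior_sd <= 0:
        raise ValueError("bf_sdr requires prior_sd > 0")
    posterior_sd = np.asarray(posterior_sd, dtype=float)
    if np.any(posterior_sd <= 0):
        raise ValueError("bf_sdr requires posterior_sd > 0")
    log_bf = norm.logpdf(0.0, posterior_mean, posterior_sd) - norm.logpdf(
        0.0, 0.0, prior_sd
    )
    return np.clip(log_bf, -cap, cap)
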