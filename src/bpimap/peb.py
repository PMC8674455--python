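"""Parametric empirical Bayes with the global shrinkage prior.

The hierarchical model places a single zero-mean Gaussian prior on the
effect theta at every voxel,

    theta_v ~ N(0, sigma_p^2),        theta_hat_v | theta_v ~ N(theta_v, u_v),

where u_v is the (plug-in) sampling variance from the group-level OLS fit.
The prior variance sigma_p^2 is shared across all in-mask voxels and
estimated by maximising the marginal likelihood of the observed contrasts,
theta_hat_v ~ N(0, sigma_p^2 + u_v), via EM.  Pooling over voxels encodes
the physiological assumption of no global experimental effect: increases in
some regions are offset by decreases elsewhere, so the map-wide effect
distribution is centred on zero.

The per-voxel posterior is conjugate Gaussian,

    m_v = theta_hat_v * sigma_p^2 / (sigma_p^2 + u_v),
    s_v^2 = sigma_p^2 * u_v / (sigma_p^2 + u_v),

so noisy estimates shrink toward zero: the larger u_v, the stronger the
shrinkage.  As sigma_p^2 -> infinity the posterior reduces to the
frequentist estimate (m -> theta_hat, s^2 -> u).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import VoxelSummary
from .volumes import DataError

EM_TOL = 1e-8
EM_MAX_ITER = 500


@dataclass
class PriorModel:
    """Zero-mean Gaussian global shrinkage prior for the effect theta."""

    prior_var: float
    em_iterations: int = 0
    converged: bool = True
    prior_mean: float = 0.0

    def __post_init__(self) -> None:
        if self.prior_mean != 0.0:
            raise ValueError("the global shrinkage prior has mean zero")
        if self.prior_var < 0:
            raise ValueError("prior variance must be nonnegative")

    @property
    def prior_sd(self) -> float:
        return float(np.sqrt(self.prior_var))


@dataclass
class PosteriorMaps:
    """Per-voxel Gaussian posterior N(m, s^2) of the effect, plus the prior."""

    post_mean: np.ndarray
    post_sd: np.ndarray
    prior: PriorModel
    summary: VoxelSummary

    def __post_init__(self) -> None:
        self.post_mean = np.asarray(self.post_mean, dtype=float).ravel()
        self.post_sd = np.asarray(self.post_sd, dtype=float).ravel()
        if self.post_mean.shape != self.post_sd.shape:
            raise DataError("posterior mean/sd shapes differ")
        if np.any(self.post_sd < 0):
            raise DataError("posterior SD must be nonnegative")

    @property
    def n_voxels(self) -> int:
        return self.post_mean.size

    # geometry flows through from the OLS summary when it came from a stack
    @property
    def mask(self):
        return self.summary.mask

    @property
    def geometry(self):
        return self.summary.geometry


def marginal_loglik(prior_var: float, theta_hat: np.ndarray, u: np.ndarray) -> float:
    """Marginal log-likelihood of theta_hat under N(0, prior_var + u)."""
    w = prior_var + u
    return float(-0.5 * np.sum(np.log(2 * np.pi * w) + theta_hat**2 / w))


def estimate_prior_variance(summary: VoxelSummary) -> PriorModel:
    """EM estimate of the global shrinkage prior variance.

    Initialised at the moment estimate max(0, mean(theta_hat^2) - mean(u)).
    Each iteration computes the conjugate per-voxel posterior under the
    current prior and sets sigma_p^2 to the mean posterior second moment,
    mean(m^2 + s^2); this is the standard EM for a Gaussian random-effects
    model with known sampling variances and never decreases the marginal
    likelihood.  A zero prior variance (all observed spread explained by
    sampling noise) is a valid degenerate fixed point.
    """
    theta_hat, u = summary.theta_hat, summary.u
    if theta_hat.size < 2:
        raise DataError("need at least 2 voxels to pool a prior")
    if not (np.isfinite(theta_hat).all() and np.isfinite(u).all()):
        raise DataError("non-finite values in voxel summary")

    sigma2 = max(0.0, float(np.mean(theta_hat**2) - np.mean(u)))
    if sigma2 == 0.0:
        # moment estimate already at the boundary; EM would stay at 0
        return PriorModel(prior_var=0.0, em_iterations=0, converged=True)

    converged = False
    it = 0
    for it in range(1, EM_MAX_ITER + 1):
        v_post = 1.0 / (1.0 / u + 1.0 / sigma2)
        m_post = v_post * theta_hat / u
        new = float(np.mean(m_post**2 + v_post))
        if abs(new - sigma2) <= EM_TOL * max(sigma2, 1e-300):
            sigma2 = new
            converged = True
            break
        sigma2 = new
    return PriorModel(prior_var=sigma2, em_iterations=it, converged=converged)


def posterior_update(summary: VoxelSummary, prior: PriorModel) -> PosteriorMaps:
    """Conjugate Gaussian posterior of theta at every voxel.

    With a degenerate prior (sigma_p^2 = 0) every posterior collapses to a
    point mass at zero (m = 0, s = 0).
    """
    theta_hat, u = summary.theta_hat, summary.u
    if prior.prior_var == 0.0:
        m = np.zeros_like(theta_hat)
        s = np.zeros_like(theta_hat)
    else:
        shrink = prior.prior_var / (prior.prior_var + u)
        m = theta_hat * shrink
        s = np.sqrt(u * shrink)
    return PosteriorMaps(post_mean=m, post_sd=s, prior=prior, summary=summary)


def estimate(summary: VoxelSummary) -> PosteriorMaps:
    """Convenience: EM prior estimation followed by the posterior update."""
    return posterior_update(summary, estimate_prior_variance(summary))
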