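"""ROPE-based Bayesian parameter inference: probabilities, rules, ROPE maps.

Given the Gaussian posterior N(m, s^2) of the effect theta at a voxel and a
region of practical equivalence (ROPE) [-gamma, gamma], the three posterior
probabilities are

    p_act   = P(theta >  gamma | D)
    p_deact = P(theta < -gamma | D)
    p_null  = P(-gamma <= theta <= gamma | D)

which always sum to one.  A voxel is labelled by the ROPE-only rule when one
of them reaches the probability threshold (default 0.95), or by the more
conservative HDI+ROPE rule from the position of the 95% highest-density
interval relative to the ROPE.  Voxels where no criterion fires are
"low confidence": the data are insufficient to separate a practically
significant effect from a trivial one.

Log posterior odds LPO = ln(p / (1 - p)) are produced for visualisation
(LPO > 3 corresponds to p > 0.9526); decisions use the probabilities
directly, so thresholding at p >= 0.95 is very slightly more liberal than
LPO > 3.

ROPE maps reverse the thresholding sequence: instead of fixing gamma and
thresholding probabilities, each voxel reports the critical ROPE radius
gamma* — the largest gamma at which an (de)activation decision survives, or
the smallest gamma at which a not-activated decision appears.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_ndtr, ndtr
from scipy.stats import norm

from .peb import PosteriorMaps
from .volumes import LPO_CAP, DataError

# integer label codes (also used when writing label volumes)
ACTIVATED = 1
DEACTIVATED = -1
NOT_ACTIVATED = 2
LOW_CONFIDENCE = 0

LABEL_NAMES = {
    ACTIVATED: "activated",
    DEACTIVATED: "deactivated",
    NOT_ACTIVATED: "not_activated",
    LOW_CONFIDENCE: "low_confidence",
}

GAMMA_MODES = ("absolute", "prior_sd_multiple", "dice_max")
RULES = ("rope_only", "hdi_rope")


@dataclass
class RopeConfig:
    """Decision-rule settings: ROPE radius, rule, and thresholds."""

    gamma: float
    gamma_mode: str = "absolute"
    p_thr: float = 0.95
    rule: str = "rope_only"
    hdi_mass: float = 0.95

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if not 0.5 < self.p_thr < 1:
            raise ValueError("p_thr must lie in (0.5, 1)")
        if not 0 < self.hdi_mass < 1:
            raise ValueError("hdi_mass must lie in (0, 1)")
        if self.gamma_mode not in GAMMA_MODES:
            raise ValueError(f"gamma_mode must be one of {GAMMA_MODES}")
        if self.rule not in RULES:
            raise ValueError(f"rule must be one of {RULES}")


@dataclass
class ProbabilityMaps:
    """Per-voxel ROPE posterior probabilities and capped log posterior odds."""

    p_act: np.ndarray
    p_deact: np.ndarray
    p_null: np.ndarray
    lpo_act: np.ndarray
    lpo_deact: np.ndarray
    lpo_null: np.ndarray
    gamma: float = 0.0


@dataclass
class DecisionMaps:
    """Per-voxel four-way classification with the evidence behind it."""

    label: np.ndarray
    probs: ProbabilityMaps
    config: RopeConfig
    posterior: PosteriorMaps

    def counts(self) -> dict[str, int]:
        return {
            name: int((self.label == code).sum())
            for code, name in LABEL_NAMES.items()
        }


@dataclass
class RopeMap:
    """Critical ROPE radii gamma* per voxel.

    ``gamma_star_act``/``gamma_star_deact`` hold the maximum gamma at which
    the (de)activation decision survives (NaN when no positive radius
    exists); ``gamma_star_null`` holds the minimum gamma at which the voxel
    becomes not-activated.  ``category`` records the decisive map:
    activated/deactivated where a positive (de)activation radius exists,
    not_activated otherwise.
    """

    gamma_star_act: np.ndarray
    gamma_star_deact: np.ndarray
    gamma_star_null: np.ndarray
    category: np.ndarray = field(default=None)
    rule: str = "rope_only"


def lpo_from_probability(p, cap: float = LPO_CAP) -> np.ndarray:
    """Natural log posterior odds ln(p/(1-p)); endpoints map to +/- cap."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore"):
        lpo = np.log(p) - np.log1p(-p)
    return np.clip(lpo, -cap, cap)


def probability_from_lpo(lpo) -> np.ndarray:
    """Inverse of :func:`lpo_from_probability`."""
    return 1.0 / (1.0 + np.exp(-np.asarray(lpo, dtype=float)))


def posterior_probabilities(posterior: PosteriorMaps, gamma: float) -> ProbabilityMaps:
    """ROPE posterior probabilities for every voxel at a single gamma.

    Zero-width posteriors (s = 0, e.g. a degenerate prior) are treated as
    point masses: the ROPE interval is closed, so a point mass exactly at
    +/-gamma counts as inside.
    """
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    m = posterior.post_mean
    s = posterior.post_sd
    p_act = np.empty_like(m)
    p_deact = np.empty_like(m)
    p_null = np.empty_like(m)
    lpo_act = np.empty_like(m)
    lpo_deact = np.empty_like(m)

    pos = s > 0
    if pos.any():
        mp, sp = m[pos], s[pos]
        z_hi = (gamma - mp) / sp
        z_lo = (-gamma - mp) / sp
        p_act[pos] = ndtr(-z_hi)
        p_deact[pos] = ndtr(z_lo)
        p_null[pos] = np.clip(ndtr(z_hi) - ndtr(z_lo), 0.0, 1.0)
        # tail-stable log odds for the one-sided probabilities
        lpo_act[pos] = log_ndtr(-z_hi) - log_ndtr(z_hi)
        lpo_deact[pos] = log_ndtr(z_lo) - log_ndtr(-z_lo)
    if (~pos).any():
        m0 = m[~pos]
        p_act[~pos] = (m0 > gamma).astype(float)
        p_deact[~pos] = (m0 < -gamma).astype(float)
        p_null[~pos] = (np.abs(m0) <= gamma).astype(float)
        lpo_act[~pos] = lpo_from_probability(p_act[~pos])
        lpo_deact[~pos] = lpo_from_probability(p_deact[~pos])

    return ProbabilityMaps(
        p_act=p_act,
        p_deact=p_deact,
        p_null=p_null,
        lpo_act=np.clip(lpo_act, -LPO_CAP, LPO_CAP),
        lpo_deact=np.clip(lpo_deact, -LPO_CAP, LPO_CAP),
        lpo_null=lpo_from_probability(p_null),
        gamma=float(gamma),
    )


def classify_rope_only(
    probs: ProbabilityMaps,
    p_thr: float = 0.95,
    posterior: PosteriorMaps | None = None,
    config: RopeConfig | None = None,
) -> DecisionMaps:
    """Label voxels by thresholding the ROPE posterior probabilities.

    p_thr must exceed 0.5 so at most one criterion can fire per voxel;
    exact ties with the threshold count as reaching it.
    """
    if not 0.5 < p_thr < 1:
        raise ValueError("p_thr must lie in (0.5, 1) for mutually exclusive labels")
    label = np.full(probs.p_act.shape, LOW_CONFIDENCE, dtype=np.int8)
    label[probs.p_act >= p_thr] = ACTIVATED
    label[probs.p_deact >= p_thr] = DEACTIVATED
    label[probs.p_null >= p_thr] = NOT_ACTIVATED
    if config is None:
        config = RopeConfig(gamma=probs.gamma, p_thr=p_thr, rule="rope_only")
    return DecisionMaps(label=label, probs=probs, config=config, posterior=posterior)


def hdi(posterior_mean, posterior_sd, mass: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
    """Highest density interval of a Gaussian posterior (= central interval)."""
    if not 0 < mass < 1:
        raise ValueError("mass must lie in (0, 1)")
    m = np.asarray(posterior_mean, dtype=float)
    s = np.asarray(posterior_sd, dtype=float)
    z = norm.ppf(0.5 + mass / 2.0)
    return m - z * s, m + z * s


def classify_hdi_rope(
    posterior: PosteriorMaps,
    gamma: float,
    mass: float = 0.95,
    config: RopeConfig | None = None,
) -> DecisionMaps:
    """Label voxels by the position of the HDI relative to the ROPE.

    Activated when the HDI lies entirely above gamma, deactivated entirely
    below -gamma, not activated when contained in [-gamma, gamma]; an HDI
    endpoint exactly on a ROPE edge counts as overlap (low confidence).
    """
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    lo, hi = hdi(posterior.post_mean, posterior.post_sd, mass)
    label = np.full(lo.shape, LOW_CONFIDENCE, dtype=np.int8)
    label[lo > gamma] = ACTIVATED
    label[hi < -gamma] = DEACTIVATED
    inside = (lo >= -gamma) & (hi <= gamma)
    # degenerate intervals (s = 0) on the edge are genuinely inside
    strict = inside & ((lo > -gamma) & (hi < gamma) | (lo == hi))
    label[strict] = NOT_ACTIVATED
    probs = posterior_probabilities(posterior, gamma)
    if config is None:
        config = RopeConfig(gamma=gamma, rule="hdi_rope", hdi_mass=mass)
    return DecisionMaps(label=label, probs=probs, config=config, posterior=posterior)


def classify(posterior: PosteriorMaps, config: RopeConfig) -> DecisionMaps:
    """Apply the configured decision rule at the configured gamma."""
    if config.rule == "rope_only":
        probs = posterior_probabilities(posterior, config.gamma)
        return classify_rope_only(probs, config.p_thr, posterior, config)
    return classify_hdi_rope(posterior, config.gamma, config.hdi_mass, config)


def resolve_gamma(
    mode: str, posterior: PosteriorMaps | None = None, value: float | None = None
) -> float:
    """Resolve the effect-size threshold gamma in PSC units.

    ``absolute`` and ``dice_max`` take the supplied value as-is (the latter
    from a Dice calibration against the classical map);
    ``prior_sd_multiple`` scales the estimated prior SD of the effect — the
    field's default group-level threshold is one prior SD (multiplier 1).
    """
    if mode not in GAMMA_MODES:
        raise ValueError(f"gamma mode must be one of {GAMMA_MODES}")
    if mode in ("absolute", "dice_max"):
        if value is None:
            raise ValueError(f"gamma mode {mode!r} requires an explicit value")
        if value < 0:
            raise ValueError("gamma must be nonnegative")
        return float(value)
    if posterior is None:
        raise ValueError("prior_sd_multiple requires a posterior with its prior")
    mult = 1.0 if value is None else float(value)
    prior_sd = posterior.prior.prior_sd
    if prior_sd == 0.0:
        raise ValueError(
            "prior SD is zero, so a prior-SD multiple gives an empty ROPE; "
            "supply an absolute gamma instead"
        )
    return mult * prior_sd


def _bisect_gamma_null(m, s, p_thr, tol=1e-6):
    """Smallest gamma with p_null >= p_thr, by monotone bisection per voxel."""
    lo = np.zeros_like(m)
    hi = np.abs(m) + 10.0 * s
    # p_null is strictly increasing in gamma for s > 0, so the root is unique
    while np.max(hi - lo) > tol:
        mid = 0.5 * (lo + hi)
        p_null = ndtr((mid - m) / s) - ndtr((-mid - m) / s)
        ge = p_null >= p_thr
        hi = np.where(ge, mid, hi)
        lo = np.where(ge, lo, mid)
    return 0.5 * (lo + hi)


def rope_map(
    posterior: PosteriorMaps,
    rule: str = "rope_only",
    p_thr: float = 0.95,
    mass: float = 0.95,
) -> RopeMap:
    """Critical ROPE radii per voxel (thresholding sequence reversed).

    ROPE-only closed forms: an activation survives up to
    gamma* = m - z(p_thr) s (reported only when positive) and symmetrically
    for deactivations; the not-activated radius solves p_null(gamma) = p_thr
    by bisection.  HDI+ROPE uses the HDI endpoints directly.
    """
    if rule not in RULES:
        raise ValueError(f"rule must be one of {RULES}")
    m, s = posterior.post_mean, posterior.post_sd
    if rule == "rope_only":
        z = norm.ppf(p_thr)
        g_act = m - z * s
        g_deact = -m - z * s
        pos = s > 0
        g_null = np.abs(m).astype(float)  # point-mass limit for s = 0
        if pos.any():
            g_null[pos] = _bisect_gamma_null(m[pos], s[pos], p_thr)
    else:
        z = norm.ppf(0.5 + mass / 2.0)
        g_act = m - z * s
        g_deact = -m - z * s
        g_null = np.abs(m) + z * s
    g_act = np.where(g_act > 0, g_act, np.nan)
    g_deact = np.where(g_deact > 0, g_deact, np.nan)
    category = np.full(m.shape, NOT_ACTIVATED, dtype=np.int8)
    category[~np.isnan(g_act)] = ACTIVATED
    category[~np.isnan(g_deact)] = DEACTIVATED
    return RopeMap(
        gamma_star_act=g_act,
        gamma_star_deact=g_deact,
        gamma_star_null=g_null,
        category=category,
        rule=rule,
    )
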