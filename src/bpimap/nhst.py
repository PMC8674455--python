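"""Classical NHST comparator: t-maps, multiplicity control, Dice calibration.

The frequentist reference analysis computes per-voxel t statistics
t = theta_hat / sqrt(u) with the voxel's error degrees of freedom, and
controls multiplicity either voxel-wise familywise (Bonferroni) or by the
Benjamini-Hochberg false discovery rate.  The Dice overlap between the
classical activation mask and the Bayesian one, swept over the effect-size
threshold gamma, calibrates the gamma that makes the two analyses agree
most closely (gamma at maximum Dice).  Normality diagnostics (Shapiro-Wilk,
sample skewness/kurtosis) check the Gaussian assumption behind both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .decisions import ACTIVATED, classify_rope_only, posterior_probabilities
from .design import VoxelSummary
from .peb import PosteriorMaps
from .volumes import DataError, GroupStack

CORRECTIONS = ("bonferroni", "fdr", "none")
SIDES = ("positive", "negative", "two_sided")


@dataclass
class NhstConfig:
    alpha: float = 0.05
    correction: str = "bonferroni"
    sidedness: str = "positive"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.correction not in CORRECTIONS:
            raise ValueError(f"correction must be one of {CORRECTIONS}")
        if self.sidedness not in SIDES:
            raise ValueError(f"sidedness must be one of {SIDES}")


@dataclass
class NhstResult:
    t: np.ndarray
    p: np.ndarray
    positive: np.ndarray   # significant with theta_hat > 0
    negative: np.ndarray   # significant with theta_hat < 0
    config: NhstConfig


@dataclass
class DiceResult:
    gamma_grid: np.ndarray
    dice: np.ndarray
    gamma_dice_max: float
    dice_max: float


def nhst_map(summary: VoxelSummary, config: NhstConfig | None = None) -> NhstResult:
    """Per-voxel t-test with the configured sidedness and correction."""
    config = config or NhstConfig()
    t = summary.theta_hat / np.sqrt(summary.u)
    if config.sidedness == "positive":
        p = stats.t.sf(t, summary.dof)
    elif config.sidedness == "negative":
        p = stats.t.cdf(t, summary.dof)
    else:
        p = 2.0 * stats.t.sf(np.abs(t), summary.dof)

    if config.correction == "bonferroni":
        sig = p <= config.alpha / p.size
    elif config.correction == "fdr":
        sig = multipletests(p, alpha=config.alpha, method="fdr_bh")[0]
    else:
        sig = p <= config.alpha
    return NhstResult(
        t=t,
        p=p,
        positive=sig & (t > 0),
        negative=sig & (t < 0),
        config=config,
    )


def dice(mask_a, mask_b) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); two empty masks give 0."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise DataError("masks must have equal lengths")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return 2.0 * float((a & b).sum()) / float(denom)


def gamma_dice_search(
    summary: VoxelSummary,
    posterior: PosteriorMaps,
    rule: str = "rope_only",
    p_thr: float = 0.95,
    nhst_config: NhstConfig | None = None,
    grid: np.ndarray | None = None,
) -> DiceResult:
    """Sweep gamma and report Dice overlap of Bayesian vs classical activations.

    Default grid is 0 to 0.4 PSC in steps of 0.001 (401 points); ties at the
    maximum resolve to the smallest gamma.
    """
    from .decisions import classify_hdi_rope  # local to avoid cycle at import

    if grid is None:
        grid = np.arange(0.0, 0.4 + 1e-12, 0.001)
    grid = np.asarray(grid, dtype=float)
    classic = nhst_map(summary, nhst_config or NhstConfig()).positive
    scores = np.empty(grid.shape)
    for i, g in enumerate(grid):
        if rule == "rope_only":
            labels = classify_rope_only(
                posterior_probabilities(posterior, g), p_thr
            ).label
        else:
            labels = classify_hdi_rope(posterior, g, p_thr).label
        scores[i] = dice(labels == ACTIVATED, classic)
    best = int(np.argmax(scores))  # argmax returns the first (smallest gamma) tie
    return DiceResult(
        gamma_grid=grid,
        dice=scores,
        gamma_dice_max=float(grid[best]),
        dice_max=float(scores[best]),
    )


@dataclass
class NormalityReport:
    shapiro_p: np.ndarray
    frac_uncorrected: float       # p < alpha_uncorrected
    frac_bonferroni: float        # p < alpha_fwe / V
    median_kurtosis: float        # Pearson convention, normal = 3
    median_skewness: float
    n_degenerate: int
    alpha_uncorrected: float = 0.001
    alpha_fwe: float = 0.05


def normality_diagnostics(
    stack: GroupStack | np.ndarray,
    alpha_uncorrected: float = 0.001,
    alpha_fwe: float = 0.05,
) -> NormalityReport:
    """Shapiro-Wilk tests and moment diagnostics per voxel.

    Constant-across-subjects voxels are degenerate for the test and are
    flagged and excluded from the p-value fractions and the medians.
    """
    data = stack.data if isinstance(stack, GroupStack) else np.asarray(stack, float)
    n = data.shape[0]
    if not 3 <= n <= 5000:
        raise ValueError("Shapiro-Wilk needs 3 <= N <= 5000 subjects")
    degenerate = data.std(axis=0) == 0
    pvals = np.full(data.shape[1], np.nan)
    for j in np.nonzero(~degenerate)[0]:
        pvals[j] = stats.shapiro(data[:, j]).pvalue
    valid = ~degenerate
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise DataError("all voxels are degenerate")
    kurt = stats.kurtosis(data[:, valid], axis=0, fisher=False, bias=False)
    skew = stats.skew(data[:, valid], axis=0, bias=False)
    return NormalityReport(
        shapiro_p=pvals,
        frac_uncorrected=float((pvals[valid] < alpha_uncorrected).sum()) / n_valid,
        frac_bonferroni=float((pvals[valid] < alpha_fwe / n_valid).sum()) / n_valid,
        median_kurtosis=float(np.median(kurt)),
        median_skewness=float(np.median(skew)),
        n_degenerate=int(degenerate.sum()),
        alpha_uncorrected=alpha_uncorrected,
        alpha_fwe=alpha_fwe,
    )
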