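"""Scoring against ground truth and sample-size / effect-size-threshold sweeps.

Decision rates follow detection-theory conventions with true counts in the
denominators:

* correct rate (per category)  - correctly labelled voxels of that true
  category / number of voxels truly in the category ("hit rate");
* incorrect rate (per category) - voxels wrongly given that label / number
  of voxels truly NOT in that category ("false alarm rate");
* low-confidence rate - unclassified voxels / all voxels.

Sweeps rerun the full pipeline (OLS -> empirical-Bayes prior -> decision
rule) on random subsamples; when gamma is expressed as a prior-SD multiple
it is re-resolved on every subsample, because the prior SD itself depends
on the sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decisions import (
    ACTIVATED,
    DEACTIVATED,
    LOW_CONFIDENCE,
    NOT_ACTIVATED,
    DecisionMaps,
    RopeConfig,
    classify,
    resolve_gamma,
)
from .design import fit_ols, make_design
from .peb import estimate_prior_variance, posterior_update
from .volumes import DataError, GroupStack

CATEGORIES = {
    "activated": ACTIVATED,
    "deactivated": DEACTIVATED,
    "not_activated": NOT_ACTIVATED,
}

#: Default sample-size grid: 10..100 step 10, then 150..500 step 50.
DEFAULT_N_GRID = tuple(range(10, 101, 10)) + tuple(range(150, 501, 50))


@dataclass
class DecisionRates:
    """Correct/incorrect rates per category plus the low-confidence rate.

    Rates for a category with no true members are undefined and stored as
    None (serialised as null, never as 0).
    """

    correct: dict[str, float | None]
    incorrect: dict[str, float | None]
    low_confidence: float

    def as_flat_dict(self) -> dict[str, float | None]:
        out: dict[str, float | None] = {}
        for name in CATEGORIES:
            out[f"correct_{name}"] = self.correct[name]
            out[f"incorrect_{name}"] = self.incorrect[name]
        out["low_confidence"] = self.low_confidence
        return out


def decision_rates(labels: DecisionMaps | np.ndarray, truth: np.ndarray) -> DecisionRates:
    """Score a labelling against per-voxel ground-truth categories."""
    label = labels.label if isinstance(labels, DecisionMaps) else np.asarray(labels)
    truth = np.asarray(truth)
    if label.shape != truth.shape:
        raise DataError("labels and truth must have equal lengths")
    total = label.size
    correct: dict[str, float | None] = {}
    incorrect: dict[str, float | None] = {}
    for name, code in CATEGORIES.items():
        in_cat = truth == code
        n_true = int(in_cat.sum())
        n_not = total - n_true
        correct[name] = (
            float((label[in_cat] == code).sum()) / n_true if n_true else None
        )
        incorrect[name] = (
            float((label[~in_cat] == code).sum()) / n_not if n_not else None
        )
    low_conf = float((label == LOW_CONFIDENCE).sum()) / total
    return DecisionRates(correct=correct, incorrect=incorrect, low_confidence=low_conf)


@dataclass
class PipelineConfig:
    """How to turn a raw stack into voxel labels."""

    rule: str = "rope_only"
    p_thr: float = 0.95
    hdi_mass: float = 0.95
    gamma_mode: str = "prior_sd_multiple"
    gamma_value: float | None = None   # absolute gamma, or the SD multiplier


def run_pipeline(data: np.ndarray, config: PipelineConfig | None = None) -> DecisionMaps:
    """One-sample OLS, EM shrinkage prior, then the configured decision rule."""
    config = config or PipelineConfig()
    data = np.atleast_2d(np.asarray(data, dtype=float))
    design = make_design("one_sample", data.shape[0])
    summary = fit_ols(data, design)
    prior = estimate_prior_variance(summary)
    posterior = posterior_update(summary, prior)
    gamma = resolve_gamma(config.gamma_mode, posterior, config.gamma_value)
    rope = RopeConfig(
        gamma=gamma,
        gamma_mode=config.gamma_mode,
        p_thr=config.p_thr,
        rule=config.rule,
        hdi_mass=config.hdi_mass,
    )
    return classify(posterior, rope)


@dataclass
class SweepResult:
    """Decision rates (mean and SD over repetitions) along a swept axis."""

    axis: str
    grid: np.ndarray
    mean: list[dict[str, float | None]]
    sd: list[dict[str, float | None]] | None
    n_repetitions: int
    extra: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, g in enumerate(self.grid):
            row = {self.axis: g}
            row.update({f"mean_{k}": v for k, v in self.mean[i].items()})
            if self.sd is not None:
                row.update({f"sd_{k}": v for k, v in self.sd[i].items()})
            rows.append(row)
        return pd.DataFrame(rows)


def _aggregate(per_rep: list[DecisionRates]):
    """Mean and SD of flat rate dicts, propagating undefined (None) rates."""
    keys = per_rep[0].as_flat_dict().keys()
    mean: dict[str, float | None] = {}
    sd: dict[str, float | None] = {}
    for k in keys:
        vals = [r.as_flat_dict()[k] for r in per_rep]
        if any(v is None for v in vals):
            mean[k], sd[k] = None, None
        else:
            mean[k] = float(np.mean(vals))
            sd[k] = float(np.std(vals, ddof=1)) if len(vals) >= 2 else None
    return mean, sd


def sample_size_sweep(
    full_stack: GroupStack | np.ndarray,
    truth: np.ndarray | None,
    grid=DEFAULT_N_GRID,
    n_reps: int = 10,
    config: PipelineConfig | None = None,
    base_seed: int = 0,
) -> SweepResult:
    """Rates (or label counts, without truth) versus group size N.

    For each repetition a generator seeded at base_seed + repetition draws a
    without-replacement subsample at every N on the grid; the prior and
    (when gamma is a prior-SD multiple) the ROPE radius are re-estimated on
    each subsample.
    """
    data = full_stack.data if isinstance(full_stack, GroupStack) else np.asarray(full_stack)
    grid = np.asarray(sorted(grid), dtype=int)
    if grid[-1] > data.shape[0]:
        raise ValueError(
            f"grid maximum {grid[-1]} exceeds available images ({data.shape[0]})"
        )
    means, sds, counts = [], [], []
    rngs = [np.random.default_rng(base_seed + rep) for rep in range(n_reps)]
    subsets = {
        n: [rng.choice(data.shape[0], size=int(n), replace=False) for rng in rngs]
        for n in grid
    }
    for n in grid:
        per_rep_rates = []
        per_rep_counts = []
        for rep in range(n_reps):
            labels = run_pipeline(data[subsets[n][rep]], config)
            per_rep_counts.append(labels.counts())
            if truth is not None:
                per_rep_rates.append(decision_rates(labels, truth))
        counts.append(
            {
                k: float(np.mean([c[k] for c in per_rep_counts]))
                for k in per_rep_counts[0]
            }
        )
        if truth is not None:
            mean, sd = _aggregate(per_rep_rates)
        else:
            mean, sd = {}, {}
        means.append(mean)
        sds.append(sd)
    return SweepResult(
        axis="sample_size",
        grid=grid,
        mean=means,
        sd=sds if n_reps >= 2 else None,
        n_repetitions=n_reps,
        extra={"label_counts": counts},
    )


def gamma_sweep(
    stack: GroupStack | np.ndarray,
    truth: np.ndarray,
    gamma_grid: np.ndarray,
    config: PipelineConfig | None = None,
    correct_floor: float = 0.80,
    incorrect_ceiling: float = 0.05,
) -> SweepResult:
    """Decision rates versus the ROPE radius gamma at fixed N.

    Also reports the band of gamma values where, for both the activated and
    the not-activated categories, the correct rate reaches ``correct_floor``
    and the incorrect rate stays at or below ``incorrect_ceiling``.
    """
    data = stack.data if isinstance(stack, GroupStack) else np.asarray(stack)
    base = config or PipelineConfig()
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    means = []
    ok = np.ones(gamma_grid.shape, dtype=bool)
    for i, g in enumerate(gamma_grid):
        cfg = PipelineConfig(
            rule=base.rule,
            p_thr=base.p_thr,
            hdi_mass=base.hdi_mass,
            gamma_mode="absolute",
            gamma_value=float(g),
        )
        rates = decision_rates(run_pipeline(data, cfg), truth)
        flat = rates.as_flat_dict()
        means.append(flat)
        for name in ("activated", "not_activated"):
            c, w = flat[f"correct_{name}"], flat[f"incorrect_{name}"]
            if c is None or c < correct_floor or (w is not None and w > incorrect_ceiling):
                ok[i] = False
    band = gamma_grid[ok]
    optimal = (float(band.min()), float(band.max())) if band.size else None
    return SweepResult(
        axis="gamma",
        grid=gamma_grid,
        mean=means,
        sd=None,
        n_repetitions=1,
        extra={"optimal_band": optimal, "band_mask": ok},
    )
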