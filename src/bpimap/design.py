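"""Group-level design matrices and per-voxel OLS summary statistics.

Three test families cover the common group analyses of contrast maps:

* ``one_sample`` — mean effect across subjects (X is a column of ones);
* ``two_sample`` — group difference with unequal group variances
  (Welch-style standard error and Satterthwaite degrees of freedom);
* ``paired`` — reduced upstream to a one-sample test on within-pair
  differences.

The output per voxel is the contrast estimate theta_hat = c (X'X)^-1 X' y,
its sampling variance u, and the error degrees of freedom — the sufficient
statistics consumed by both the empirical-Bayes step and the classical
t-test comparator.  The contrast scaling convention is that the sum of
positive contrast weights equals one, so theta stays in percent-signal-change
units.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .volumes import DataError, GroupStack

logger = logging.getLogger(__name__)

FAMILIES = ("one_sample", "two_sample", "paired")

#: Floor applied to zero sampling variances (PSC^2) at degenerate voxels.
VARIANCE_FLOOR = 1e-12


class RankError(ValueError):
    """Design with too few rows or deficient column rank."""


@dataclass
class DesignSpec:
    """Design matrix X, contrast vector c and variance-group labels."""

    X: np.ndarray
    contrast: np.ndarray
    variance_groups: np.ndarray
    family: str

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.contrast = np.asarray(self.contrast, dtype=float).ravel()
        self.variance_groups = np.asarray(self.variance_groups, dtype=int).ravel()
        if self.family not in FAMILIES:
            raise ValueError(f"unsupported family {self.family!r}; use {FAMILIES}")
        n, p = self.X.shape
        if self.contrast.size != p:
            raise DataError("contrast length does not match design columns")
        if self.variance_groups.size != n:
            raise DataError("variance_groups length does not match design rows")
        if np.linalg.matrix_rank(self.X) < p:
            raise RankError("design matrix is rank deficient")
        pos = self.contrast[self.contrast > 0].sum()
        if pos > 0 and abs(pos - 1.0) > 1e-9:
            raise ValueError(
                "sum of positive contrast weights must equal 1 "
                f"(got {pos}); rescale the contrast"
            )

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]


@dataclass
class VoxelSummary:
    """Per-voxel OLS contrast estimate, its sampling variance, and dof."""

    theta_hat: np.ndarray
    u: np.ndarray
    dof: np.ndarray
    mask: np.ndarray | None = None
    geometry: object = None

    def __post_init__(self) -> None:
        self.theta_hat = np.asarray(self.theta_hat, dtype=float).ravel()
        self.u = np.asarray(self.u, dtype=float).ravel()
        self.dof = np.broadcast_to(
            np.asarray(self.dof, dtype=float), self.theta_hat.shape
        ).copy()
        if self.u.shape != self.theta_hat.shape:
            raise DataError("u and theta_hat shapes differ")
        if np.any(self.u <= 0):
            raise DataError("sampling variances must be positive")
        if np.any(self.dof < 1):
            raise DataError("degrees of freedom must be >= 1")

    @property
    def n_voxels(self) -> int:
        return self.theta_hat.size


def make_design(family: str, n1: int, n2: int | None = None) -> DesignSpec:
    """Build the design matrix and contrast for a test family.

    ``paired`` designs are definitionally a one-sample test on n1 within-pair
    difference rows; callers difference the data upstream.
    """
    if family not in FAMILIES:
        raise ValueError(f"unsupported family {family!r}; use {FAMILIES}")
    if n1 < 2:
        raise ValueError("need n1 >= 2")
    if family in ("one_sample", "paired"):
        X = np.ones((n1, 1))
        return DesignSpec(X, np.array([1.0]), np.ones(n1, dtype=int), family)
    if n2 is None or n2 < 2:
        raise ValueError("two_sample needs n2 >= 2")
    X = np.zeros((n1 + n2, 2))
    X[:n1, 0] = 1.0
    X[n1:, 1] = 1.0
    groups = np.r_[np.ones(n1, dtype=int), np.full(n2, 2, dtype=int)]
    return DesignSpec(X, np.array([1.0, -1.0]), groups, "two_sample")


def fit_ols(stack: GroupStack | np.ndarray, design: DesignSpec) -> VoxelSummary:
    """Per-voxel OLS contrast estimates with sampling variances.

    For ``two_sample`` the error variance is estimated per group and the
    contrast variance is lambda1/n1 + lambda2/n2 with Welch–Satterthwaite
    degrees of freedom; otherwise a single residual variance per voxel is
    used with dof = N - p.
    """
    if isinstance(stack, GroupStack):
        Y = stack.data
        mask, geometry = stack.mask, stack.geometry
    else:
        Y = np.atleast_2d(np.asarray(stack, dtype=float))
        mask, geometry = None, None
    n, p = design.X.shape
    if Y.shape[0] != n:
        raise DataError(f"stack has {Y.shape[0]} subjects but design has {n} rows")
    if n <= p:
        raise RankError(f"need more subjects ({n}) than design columns ({p})")

    X, c = design.X, design.contrast
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y                      # p x V
    theta_hat = c @ beta
    resid = Y - X @ beta

    if design.family == "two_sample":
        g = design.variance_groups
        n1, n2 = int((g == 1).sum()), int((g == 2).sum())
        lam1 = resid[g == 1].__pow__(2).sum(axis=0) / (n1 - 1)
        lam2 = resid[g == 2].__pow__(2).sum(axis=0) / (n2 - 1)
        u = lam1 / n1 + lam2 / n2
        # Welch-Satterthwaite effective dof, per voxel
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # 0/0 at degenerate voxels
            dof = u**2 / (
                (lam1 / n1) ** 2 / (n1 - 1) + (lam2 / n2) ** 2 / (n2 - 1)
            )
        dof = np.clip(np.nan_to_num(dof, nan=n1 + n2 - 2), 1.0, n1 + n2 - 2)
    else:
        lam = (resid**2).sum(axis=0) / (n - p)
        u = lam * float(c @ XtX_inv @ c)
        dof = np.full(theta_hat.shape, float(n - p))

    n_floored = int((u < VARIANCE_FLOOR).sum())
    if n_floored:
        logger.warning(
            "flooring %d degenerate voxel variance(s) at %g", n_floored, VARIANCE_FLOOR
        )
        u = np.maximum(u, VARIANCE_FLOOR)
    return VoxelSummary(theta_hat, u, dof, mask=mask, geometry=geometry)


def paired_differences(data_a: np.ndarray, data_b: np.ndarray) -> np.ndarray:
    """Within-pair differences, reducing a paired design to one-sample rows."""
    data_a, data_b = np.asarray(data_a, float), np.asarray(data_b, float)
    if data_a.shape != data_b.shape:
        raise DataError("paired stacks must have identical shapes")
    return data_a - data_b
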