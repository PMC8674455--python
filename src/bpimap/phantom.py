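"""Synthetic group datasets with Pearson-system noise and known ground truth.

The simulation harness emulates a group fMRI analysis where the truth is
known: each synthetic contrast image contains "activated" and "deactivated"
voxels carrying a practically significant mean effect (+/- 0.1, 0.2 or 0.3
PSC), surrounded by "trivial" voxels whose mean effect (+/- 0.04 PSC) is
inside any reasonable ROPE.  Voxel noise is drawn from the Pearson
distribution system, which realises any feasible (skewness, kurtosis) pair
(Ku > Sk^2 + 1) and therefore lets the same generator produce Gaussian and
controlled non-Gaussian noise:

* Type 0   - normal (Sk = 0, Ku = 3);
* Type I/II - (four-parameter) beta, the platykurtic and skewed cells;
* Type III - gamma (boundary case);
* Type IV  - the genuinely Pearson-only family (e.g. Sk = 0.7, Ku = 7),
  sampled by numerical CDF inversion in the arctan variable;
* Type V/VI - inverse-gamma / beta-prime;
* Type VII - rescaled Student t (Sk = 0, Ku > 3).

Every sampler is affinely standardised to the requested mean/SD using the
distribution's theoretical moments, so sample moments converge to the
specification as n grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, stats

from .decisions import ACTIVATED, DEACTIVATED, NOT_ACTIVATED
from .volumes import GroupStack, VolumeGeometry

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # approx 2.3548


class InfeasibleMomentsError(ValueError):
    """(Sk, Ku) outside the moment-feasibility region Ku > Sk^2 + 1."""


@dataclass(frozen=True)
class PearsonSpec:
    """Target first four moments; kurtosis in the Pearson convention (normal=3)."""

    mean: float = 0.0
    sd: float = 1.0
    skew: float = 0.0
    kurt: float = 3.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.kurt <= self.skew**2 + 1:
            raise InfeasibleMomentsError(
                f"no distribution has Sk={self.skew}, Ku={self.kurt}: "
                "kurtosis must exceed skewness^2 + 1"
            )


def pearson_type(skew: float, kurt: float) -> int:
    """Pearson family member (0-7) selected by the kappa criterion."""
    PearsonSpec(skew=skew, kurt=kurt)  # feasibility
    b1, b2 = skew**2, kurt
    if abs(skew) < 1e-12:
        if abs(b2 - 3.0) < 1e-12:
            return 0
        return 2 if b2 < 3 else 7
    c2 = 2 * b2 - 3 * b1 - 6
    if abs(c2) < 1e-12:
        return 3
    c0 = 4 * b2 - 3 * b1
    c1 = skew * (b2 + 3)
    kappa = c1**2 / (4 * c0 * c2)
    if kappa < 0:
        return 1
    if abs(kappa - 1) < 1e-12:
        return 5
    return 6 if kappa > 1 else 4


def _quadratic_roots(skew, kurt):
    """Roots of c0 + c1 x + c2 x^2 for the standardised Pearson ODE."""
    b1, b2 = skew**2, kurt
    denom = 10 * b2 - 12 * b1 - 18
    if abs(denom) < 1e-12:
        b2 += 1e-9
        denom = 10 * b2 - 12 * b1 - 18
    c0 = (4 * b2 - 3 * b1) / denom
    c1 = skew * (b2 + 3) / denom
    c2 = (2 * b2 - 3 * b1 - 6) / denom
    disc = c1**2 - 4 * c0 * c2
    a1 = (-c1 - np.sqrt(disc)) / (2 * c2)
    a2 = (-c1 + np.sqrt(disc)) / (2 * c2)
    if a1 > a2:
        a1, a2 = a2, a1
    return c0, c1, c2, a1, a2


def _sample_type1(skew, kurt, n, rng):
    """Four-parameter beta on the root interval [a1, a2]."""
    _, c1, c2, a1, a2 = _quadratic_roots(skew, kurt)
    p = (c1 + a1) / (c2 * (a2 - a1)) + 1.0
    q = -(c1 + a2) / (c2 * (a2 - a1)) + 1.0
    if p <= 0 or q <= 0:
        raise InfeasibleMomentsError(f"beta shapes non-positive for Sk={skew}, Ku={kurt}")
    x = a1 + (a2 - a1) * rng.beta(p, q, size=n)
    mu = a1 + (a2 - a1) * p / (p + q)
    var = (a2 - a1) ** 2 * p * q / ((p + q) ** 2 * (p + q + 1))
    x = (x - mu) / np.sqrt(var)
    beta_skew = 2 * (q - p) * np.sqrt(p + q + 1) / ((p + q + 2) * np.sqrt(p * q))
    if skew != 0 and np.sign(beta_skew) != np.sign(skew):
        x = -x
    return x


def _sample_type2(kurt, n, rng):
    """Symmetric beta; Ku = 3 - 6/(2p + 3) < 3."""
    p = (6.0 / (3.0 - kurt) - 3.0) / 2.0
    x = rng.beta(p, p, size=n) - 0.5
    return x / np.sqrt(1.0 / (4.0 * (2.0 * p + 1.0)))


def _sample_type3(skew, n, rng):
    """Gamma with shape 4/Sk^2, standardised; sign carries the skew."""
    k = 4.0 / skew**2
    x = (rng.gamma(k, 1.0, size=n) - k) / np.sqrt(k)
    return np.sign(skew) * x


def _sample_type4(skew, kurt, n, rng, grid_size=400_001):
    """Pearson Type IV via inverse-CDF sampling in u = arctan((x-lam)/a).

    Standardised parameterisation: with r = 6(Ku - Sk^2 - 1)/(2Ku - 3Sk^2 - 6),
    exponent m = (r+2)/2, asymmetry nu, scale a and location lam chosen so the
    distribution has mean 0 and variance 1.  In the arctan variable the
    density is proportional to cos(u)^(2m-2) exp(-nu u) on (-pi/2, pi/2),
    which is smooth and bounded, so a trapezoid CDF on a fine grid inverts
    accurately; x = lam + a tan(u) maps back with exact tail coverage.
    """
    b1 = skew**2
    r = 6.0 * (kurt - b1 - 1.0) / (2.0 * kurt - 3.0 * b1 - 6.0)
    disc = 16.0 * (r - 1.0) - b1 * (r - 2.0) ** 2
    if r <= 1 or disc <= 0:
        raise InfeasibleMomentsError(f"Type IV parameters infeasible for Sk={skew}, Ku={kurt}")
    m = (r + 2.0) / 2.0
    nu = -r * (r - 2.0) * skew / np.sqrt(disc)
    a = np.sqrt(disc) / 4.0
    lam = -(r - 2.0) * skew / 4.0

    u = np.linspace(-np.pi / 2, np.pi / 2, grid_size)
    with np.errstate(divide="ignore"):
        log_f = (2.0 * m - 2.0) * np.log(np.cos(u)) - nu * u
    f = np.exp(log_f - log_f.max())
    cdf = np.concatenate(([0.0], np.cumsum((f[1:] + f[:-1]) * 0.5 * np.diff(u))))
    cdf /= cdf[-1]
    draws = rng.uniform(0.0, 1.0, size=n)
    u_samp = np.interp(draws, cdf, u)
    return lam + a * np.tan(u_samp)


def _sample_type5(skew, n, rng):
    """Inverse gamma, shape solved from the skewness."""
    g = abs(skew)
    if g < 1e-12:
        raise InfeasibleMomentsError("Type V requires nonzero skewness")
    # g^2 (alpha-3)^2 = 16 (alpha-2)
    coef = [g**2, -(6 * g**2 + 16), 9 * g**2 + 32]
    alpha = max(np.roots(coef).real)
    dist = stats.invgamma(alpha)
    mu, var = dist.stats(moments="mv")
    x = (dist.rvs(size=n, random_state=rng) - mu) / np.sqrt(var)
    return np.sign(skew) * x


def _sample_type6(skew, kurt, n, rng):
    """Beta-prime with shapes numerically matched to (|Sk|, Ku)."""
    target = np.array([abs(skew), kurt])

    def resid(logab):
        a, b = np.exp(logab)
        if b <= 4.01:
            return np.array([1e3, 1e3])
        s, k = stats.betaprime.stats(a, b, moments="sk")
        return np.array([s, k + 3.0]) - target

    sol = optimize.fsolve(resid, x0=np.log([2.0, 8.0]), full_output=True)
    x0, info, ier, _ = sol
    if ier != 1 or np.max(np.abs(info["fvec"])) > 1e-8:
        raise InfeasibleMomentsError(
            f"could not match beta-prime moments for Sk={skew}, Ku={kurt}"
        )
    a, b = np.exp(x0)
    dist = stats.betaprime(a, b)
    mu, var = dist.stats(moments="mv")
    x = (dist.rvs(size=n, random_state=rng) - mu) / np.sqrt(var)
    return np.sign(skew) * x


def _sample_type7(kurt, n, rng):
    """Student t with dof from the kurtosis, rescaled to unit variance."""
    dof = 4.0 + 6.0 / (kurt - 3.0)
    return rng.standard_t(dof, size=n) * np.sqrt((dof - 2.0) / dof)


def pearson_sample(spec: PearsonSpec, n: int, seed=None) -> np.ndarray:
    """Draw n values from the Pearson family member matching spec's moments."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ptype = pearson_type(spec.skew, spec.kurt)
    if ptype == 0:
        x = rng.standard_normal(n)
    elif ptype == 1:
        x = _sample_type1(spec.skew, spec.kurt, n, rng)
    elif ptype == 2:
        x = _sample_type2(spec.kurt, n, rng)
    elif ptype == 3:
        x = _sample_type3(spec.skew, n, rng)
    elif ptype == 4:
        x = _sample_type4(spec.skew, spec.kurt, n, rng)
    elif ptype == 5:
        x = _sample_type5(spec.skew, n, rng)
    elif ptype == 6:
        x = _sample_type6(spec.skew, spec.kurt, n, rng)
    else:
        x = _sample_type7(spec.kurt, n, rng)
    return spec.mean + spec.sd * x


@dataclass
class PhantomSpec:
    """Ground-truth layout and noise model of a simulated group dataset.

    Defaults reproduce the reference simulation conditions: 579 activated,
    500 deactivated and 3067 trivial voxels; effect 0.2 PSC; trivial effects
    +/- 0.04 PSC with a per-voxel random sign fixed once per layout; noise
    SD 0.3 PSC; 1000 images.
    """

    counts: tuple[int, int, int] = (579, 500, 3067)
    effect_act: float = 0.2
    effect_trivial_magnitude: float = 0.04
    noise_sd: float = 0.3
    skew: float = 0.0
    kurt: float = 3.0
    n_images: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts) or sum(self.counts) == 0:
            raise ValueError("voxel counts must be nonnegative and not all zero")
        if not 0 <= self.effect_trivial_magnitude < self.effect_act:
            raise ValueError("trivial effect must be smaller than the true effect")
        PearsonSpec(sd=self.noise_sd, skew=self.skew, kurt=self.kurt)

    @property
    def n_voxels(self) -> int:
        return sum(self.counts)


@dataclass
class Phantom:
    """Simulated group stack together with its ground truth."""

    stack: GroupStack
    truth: np.ndarray          # per-voxel codes: ACTIVATED/DEACTIVATED/NOT_ACTIVATED
    true_means: np.ndarray     # per-voxel true effect (PSC)
    spec: PhantomSpec


def _phantom_geometry(n_voxels: int) -> tuple[np.ndarray, VolumeGeometry]:
    """Smallest near-square 2-D grid holding n_voxels, mask-trimmed."""
    side = int(np.ceil(np.sqrt(n_voxels)))
    rows = int(np.ceil(n_voxels / side))
    shape = (rows, side, 1)
    mask = np.zeros(shape, dtype=bool)
    mask.ravel()[:n_voxels] = True
    geom = VolumeGeometry(shape, np.diag([2.0, 2.0, 2.0, 1.0]))
    return mask, geom


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Generate a reproducible group stack with known voxel categories.

    Ground-truth categories occupy contiguous blocks of the flattened grid
    (estimation is voxel-wise, so the spatial arrangement is irrelevant to
    decision rates).  Trivial-voxel signs are drawn once per layout.
    """
    rng = np.random.default_rng(spec.seed)
    n_act, n_deact, n_triv = spec.counts
    total = spec.n_voxels
    truth = np.empty(total, dtype=np.int8)
    truth[:n_act] = ACTIVATED
    truth[n_act : n_act + n_deact] = DEACTIVATED
    truth[n_act + n_deact :] = NOT_ACTIVATED

    true_means = np.empty(total)
    true_means[:n_act] = spec.effect_act
    true_means[n_act : n_act + n_deact] = -spec.effect_act
    signs = rng.choice([-1.0, 1.0], size=n_triv)
    true_means[n_act + n_deact :] = signs * spec.effect_trivial_magnitude

    noise_spec = PearsonSpec(0.0, spec.noise_sd, spec.skew, spec.kurt)
    noise = pearson_sample(noise_spec, spec.n_images * total, rng).reshape(
        spec.n_images, total
    )
    data = true_means[None, :] + noise

    mask, geom = _phantom_geometry(total)
    stack = GroupStack(
        data=data,
        mask=mask,
        geometry=geom,
        subject_ids=[f"sim-{i:04d}" for i in range(spec.n_images)],
    )
    return Phantom(stack=stack, truth=truth, true_means=true_means, spec=spec)


def gaussian_smooth(image: np.ndarray, fwhm_voxels: float) -> np.ndarray:
    """Separable Gaussian smoothing parameterised by FWHM in voxels."""
    if fwhm_voxels < 0:
        raise ValueError("fwhm must be nonnegative")
    if fwhm_voxels == 0:
        return np.asarray(image, dtype=float).copy()
    sigma = fwhm_voxels / FWHM_TO_SIGMA
    return ndimage.gaussian_filter(np.asarray(image, dtype=float), sigma, mode="reflect")


@dataclass
class ConceptualPhantom:
    """Two-glyph illustration dataset: a '1' with a real but small effect,
    a '0' with a strictly zero effect, and a noisy low-confidence surround."""

    stack: GroupStack
    one_mask: np.ndarray     # flattened, in-mask order
    zero_mask: np.ndarray
    background_mask: np.ndarray


def _glyph_masks(size: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint 'one' and 'zero' glyphs on a size x size grid."""
    yy, xx = np.mgrid[0:size, 0:size]
    one = (np.abs(xx - 14) <= 1) & (yy >= 8) & (yy <= 41)
    one |= (yy - 8 >= (14 - xx)) & (yy - 8 <= (14 - xx) + 2) & (xx >= 9) & (xx <= 14)
    cx, cy = 34, 25
    r2 = ((xx - cx) / 6.5) ** 2 + ((yy - cy) / 11.0) ** 2
    zero = (r2 <= 1.0) & (r2 >= 0.45)
    return one, zero & ~one


def figure1_phantom(seed: int = 0, n_images: int = 100, size: int = 50) -> ConceptualPhantom:
    """Conceptual two-glyph phantom: 100 smoothed 50 x 50 images.

    The 'one' glyph has mean 0.1 and SD 0.37, the 'zero' glyph mean 0 and
    SD 0.6, the surround mean 0.01 and SD 0.37; each image is smoothed with
    a 2-voxel-FWHM Gaussian kernel.
    """
    rng = np.random.default_rng(seed)
    one, zero = _glyph_masks(size)
    background = ~(one | zero)
    mean_map = np.full((size, size), 0.01)
    sd_map = np.full((size, size), 0.37)
    mean_map[one] = 0.1
    mean_map[zero] = 0.0
    sd_map[zero] = 0.6
    images = np.empty((n_images, size, size))
    for i in range(n_images):
        raw = mean_map + sd_map * rng.standard_normal((size, size))
        images[i] = gaussian_smooth(raw, 2.0)

    mask = np.ones((size, size, 1), dtype=bool)
    geom = VolumeGeometry((size, size, 1), np.diag([2.0, 2.0, 2.0, 1.0]))
    stack = GroupStack(
        data=images.reshape(n_images, -1),
        mask=mask,
        geometry=geom,
        subject_ids=[f"sim-{i:04d}" for i in range(n_images)],
    )
    return ConceptualPhantom(
        stack=stack,
        one_mask=one.ravel(),
        zero_mask=zero.ravel(),
        background_mask=background.ravel(),
    )
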