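"""Stimulus generators and spike encoders.

Input classes:

* rotated Laplacian source mixtures (the classic two-source demixing
  problem), as raw 2-D samples, as rectified on/off rate vectors, and as
  Poisson spike trains with several synapses per channel;
* Foldiak bars: binary-OR superpositions of horizontal and vertical bars on
  a square grid, with independent-probability and exactly-k variants, rate
  encoding or a spike-spike correlation encoding;
* correlated Poisson trains with prescribed pairwise correlation, generated
  by thresholding equicorrelated (dichotomous) Gaussians;
* optional natural-image preprocessing (difference-of-Gaussians filtering,
  patch sampling, on/off rate maps) plus a synthetic grating image so the
  pipeline runs without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "DemixConfig",
    "BarsConfig",
    "CorrelationSpec",
    "sample_laplace_pair",
    "mix_rotate",
    "onoff_encode",
    "poisson_trains",
    "bar_templates",
    "bars_sample",
    "bars_to_rates",
    "solve_dichotomous_gaussian",
    "correlated_trains",
    "synthetic_grating_image",
    "preprocess_image_patches",
]


@dataclass
class DemixConfig:
    """Two-source Laplacian demixing task (spike encoding)."""

    theta: float = 0.5236            # rotation angle (rad)
    synapses_per_channel: int = 25
    rate_scale: float = 20.0         # Hz per unit rectified source amplitude
    sample_duration: float = 200.0   # ms

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta < np.pi / 2):
            raise ValueError("theta must lie in [0, pi/2)")
        if self.synapses_per_channel < 1:
            raise ValueError("synapses_per_channel must be >= 1")


@dataclass
class BarsConfig:
    """Foldiak bars task geometry and encoding."""

    grid: int = 5
    bar_width: int = 1
    mode: str = "independent_p"      # independent_p | exactly_k
    p: float = 0.1
    k: int = 4
    nu_bg: float = 2.0               # background pixel rate (Hz)
    nu_max: float = 40.0             # single-bar pixel rate (Hz)
    sample_duration: float = 200.0   # ms

    def __post_init__(self) -> None:
        if self.bar_width not in (1, 2):
            raise ValueError("bar_width must be 1 or 2")
        if self.grid % self.bar_width != 0:
            raise ValueError("grid must be a multiple of bar_width")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must be in [0, 1]")
        if self.mode not in ("independent_p", "exactly_k"):
            raise ValueError(f"unknown bars mode {self.mode!r}")
        if not (1 <= self.k <= self.n_bars):
            raise ValueError("k must be between 1 and the number of bars")

    @property
    def n_bars(self) -> int:
        return 2 * (self.grid // self.bar_width)

    @property
    def n_pixels(self) -> int:
        return self.grid * self.grid


@dataclass
class CorrelationSpec:
    """Equicorrelated spike-train specification (dichotomous Gaussian).

    All channels share the mean rate nu; channels inside each member set are
    pairwise correlated with coefficient c (of the per-bin spike
    indicators), background channels and channels of different sets are
    uncorrelated.  gamma (latent threshold) and lam (latent correlation) are
    derived by `solve_dichotomous_gaussian`.
    """

    nu: float = 20.0
    c: float = 0.5
    member_sets: list = field(default_factory=list)
    dt: float = 1.0
    gamma: float | None = None
    lam: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.c < 1.0):
            raise ValueError("c must be in [0, 1)")
        flat = [i for s in self.member_sets for i in s]
        if len(flat) != len(set(flat)):
            raise ValueError("member sets must not overlap")

    def solve(self) -> "CorrelationSpec":
        self.gamma, self.lam = solve_dichotomous_gaussian(self.nu, self.c, self.dt)
        return self


def sample_laplace_pair(rng: np.random.Generator, size: int | None = None) -> np.ndarray:
    """Two i.i.d. unit-variance Laplace sources (scale 1/sqrt(2))."""
    shape = (2,) if size is None else (size, 2)
    return rng.laplace(0.0, 1.0 / np.sqrt(2.0), size=shape)


def mix_rotate(s: np.ndarray, theta: float) -> np.ndarray:
    """Mix sources with the 2-D rotation matrix [[cos, -sin], [sin, cos]]."""
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    return np.asarray(s) @ R.T


def onoff_encode(x: np.ndarray) -> np.ndarray:
    """Rectify a signed 2-D input into 4 nonnegative channels
    (on1, off1, on2, off2); on_i * off_i = 0 and on - off reconstructs x."""
    x = np.asarray(x, dtype=float)
    on = np.maximum(x, 0.0)
    off = np.maximum(-x, 0.0)
    out = np.empty(x.shape[:-1] + (4,))
    out[..., 0::2] = on
    out[..., 1::2] = off
    return out


def poisson_trains(
    rates: np.ndarray,
    duration: float,
    dt: float,
    n_per_channel: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Independent Bernoulli-bin Poisson trains.

    Returns a boolean array of shape (n_bins, n_channels * n_per_channel);
    synapse j belongs to channel j // n_per_channel.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    p = np.repeat(rates, n_per_channel) * dt / 1000.0
    if np.any(p > 1):
        raise ValueError("rate * dt exceeds one spike per bin")
    n_bins = int(round(duration / dt))
    return rng.random((n_bins, p.size)) < p


def bar_templates(cfg: BarsConfig) -> np.ndarray:
    """All horizontal then vertical bars at non-overlapping offsets.

    Shape (n_bars, grid, grid), boolean.
    """
    n = cfg.grid // cfg.bar_width
    t = np.zeros((2 * n, cfg.grid, cfg.grid), dtype=bool)
    for i in range(n):
        rows = slice(i * cfg.bar_width, (i + 1) * cfg.bar_width)
        t[i, rows, :] = True
        t[n + i, :, rows] = True
    return t


def bars_sample(cfg: BarsConfig, rng: np.random.Generator):
    """Draw one bars stimulus: (binary grid, list of active bar ids).

    The grid is the pixelwise OR of the selected bar templates (nonlinear
    superposition: intersections are not brighter).
    """
    t = bar_templates(cfg)
    if cfg.mode == "independent_p":
        active = np.nonzero(rng.random(cfg.n_bars) < cfg.p)[0]
    else:
        active = rng.choice(cfg.n_bars, size=cfg.k, replace=False)
    grid = np.zeros((cfg.grid, cfg.grid), dtype=bool)
    for i in active:
        grid |= t[i]
    return grid, sorted(int(i) for i in active)


def bars_to_rates(grid: np.ndarray, cfg: BarsConfig) -> np.ndarray:
    """Encode a binary bars image as per-pixel firing rates (Hz).

    The image is L2-normalized and rescaled so that the bar pixels of a
    single-bar sample sit exactly at nu_max; background pixels at nu_bg.
    """
    grid = np.asarray(grid)
    x = grid.astype(float).ravel()
    nrm = np.linalg.norm(x)
    if nrm == 0:
        return np.full(x.size, cfg.nu_bg)
    m_bar = cfg.grid * cfg.bar_width  # pixels in one bar
    scaled = x / nrm * np.sqrt(m_bar)
    return cfg.nu_bg + scaled * (cfg.nu_max - cfg.nu_bg)


def _orthant_prob(gamma: float, lam: float) -> float:
    """P(Z1 > gamma, Z2 > gamma) for standard bivariate normal, corr lam.

    Plackett's identity: the orthant probability equals the independent
    value plus the integral of the bivariate density at (gamma, gamma) over
    the correlation path.
    """
    p = norm.sf(gamma)
    if lam == 0.0:
        return p * p

    def dens(rho):
        return np.exp(-gamma**2 / (1.0 + rho)) / (2.0 * np.pi * np.sqrt(1.0 - rho**2))

    val, _ = quad(dens, 0.0, lam, limit=200)
    return p * p + val


def solve_dichotomous_gaussian(nu: float, c: float, dt: float):
    """Latent threshold and correlation reproducing Bernoulli statistics.

    Finds gamma with P(z > gamma) = nu*dt/1000 and lam such that thresholded
    equicorrelated Gaussians have indicator correlation c.  Returns
    (gamma, lam).
    """
    p = nu * dt / 1000.0
    if not (0.0 < p < 1.0):
        raise ValueError("nu*dt/1000 must lie in (0, 1)")
    if not (0.0 <= c < 1.0):
        raise ValueError("c must be in [0, 1)")
    gamma = norm.isf(p)
    if c == 0.0:
        return float(gamma), 0.0
    target = p * p + c * p * (1.0 - p)

    def f(lam):
        return _orthant_prob(gamma, lam) - target

    hi = 1.0 - 1e-12
    if f(hi) < 0:
        raise ValueError(f"correlation c={c} unattainable at p={p}")
    lam = brentq(f, 0.0, hi, xtol=1e-12, rtol=8.9e-16)
    resid = abs(f(lam))
    if resid > 1e-8:
        raise RuntimeError(f"dichotomous-Gaussian solver residual {resid:.2e}")
    return float(gamma), float(lam)


def correlated_trains(
    spec: CorrelationSpec,
    duration: float,
    rng: np.random.Generator,
    n_channels: int | None = None,
) -> np.ndarray:
    """Spike trains with equicorrelated member sets (one-factor latents).

    Within each member set the latent Gaussian is
    z_i = sqrt(lam) * z_common + sqrt(1 - lam) * eps_i; background channels
    are independent.  Every channel's mean rate is nu.  Returns a boolean
    (n_bins, n_channels) array.
    """
    if spec.gamma is None or spec.lam is None:
        spec.solve()
    if n_channels is None:
        n_channels = max((max(s) for s in spec.member_sets if len(s)), default=-1) + 1
    n_bins = int(round(duration / spec.dt))
    z = rng.standard_normal((n_bins, n_channels))
    sq_l = np.sqrt(spec.lam)
    sq_r = np.sqrt(1.0 - spec.lam)
    for members in spec.member_sets:
        members = list(members)
        if not members:
            continue
        common = rng.standard_normal(n_bins)
        z[:, members] = sq_l * common[:, None] + sq_r * z[:, members]
    return z > spec.gamma


def synthetic_grating_image(
    size: int = 256,
    orientations=(0.0, np.pi / 3, 2 * np.pi / 3),
    freq: float = 0.08,
    noise: float = 0.2,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic stand-in image (sum of oriented gratings plus noise) so the
    natural-image pipeline runs without external data."""
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    img = np.zeros((size, size))
    for i, th in enumerate(orientations):
        phase = 2 * np.pi * freq * (xx * np.cos(th) + yy * np.sin(th))
        img += np.sin(phase + i)
    img += noise * rng.standard_normal(img.shape)
    return img


def preprocess_image_patches(
    image: np.ndarray,
    dog_center: float = 1.0,
    dog_surround: float = 3.0,
    patch_size: int = 10,
    contrast_floor: float = 0.1,
    rng: np.random.Generator | None = None,
    n_patches: int = 100,
    nu_bg: float = 2.0,
    nu_max: float = 40.0,
):
    """Whiten an intensity image and cut it into on/off rate maps.

    The image is convolved with a difference-of-Gaussians filter (center and
    surround widths in pixels), random patches are sampled, patches whose
    standard deviation falls below contrast_floor are discarded, survivors
    are z-scored, rectified into on/off maps and scaled linearly to
    [nu_bg, nu_max].  Returns (on_maps, off_maps) arrays of shape
    (n_kept, patch_size, patch_size).
    """
    rng = rng if rng is not None else np.random.default_rng()
    image = np.asarray(image, dtype=float)
    if image.shape[0] <= patch_size or image.shape[1] <= patch_size:
        raise ValueError("image must be larger than the patch size")
    filtered = (ndimage.gaussian_filter(image, dog_center)
                - ndimage.gaussian_filter(image, dog_surround))
    ons, offs = [], []
    for _ in range(n_patches):
        r = rng.integers(0, filtered.shape[0] - patch_size)
        c = rng.integers(0, filtered.shape[1] - patch_size)
        patch = filtered[r:r + patch_size, c:c + patch_size]
        sd = patch.std()
        if sd < contrast_floor:
            continue
        z = (patch - patch.mean()) / sd
        scale = np.abs(z).max()
        on = np.maximum(z, 0.0) / scale
        off = np.maximum(-z, 0.0) / scale
        ons.append(nu_bg + on * (nu_max - nu_bg))
        offs.append(nu_bg + off * (nu_max - nu_bg))
    if not ons:
        raise ValueError("no patch passed the contrast floor")
    return np.array(ons), np.array(offs)
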