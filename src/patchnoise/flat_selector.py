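"""Noise-calibrated threshold and flat-patch selection.

For a latent-flat patch the texture intensity is produced by noise alone, so
the largest intensity that pure noise at level sigma can plausibly produce is
a selection threshold: patches at or below it are declared flat.  The
threshold eps_delta is calibrated by Monte Carlo — draw many d x d patches of
N(0, sigma^2) noise, compute each one's texture intensity and take the
maximum (optionally a high quantile for users who prefer a statistic that
does not grow with the sample count).

Texture intensity is positively homogeneous in the pixel values, so the
calibration draws standard-normal patches once and scales: for a fixed seed,
eps_delta(alpha * sigma) == alpha * eps_delta(sigma) exactly.  The iterative
estimator exploits this to recalibrate at each new sigma without redrawing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .patch_engine import GradientKernels, PatchSet, TextureMap, texture_intensities

__all__ = [
    "ThresholdCalibration",
    "ThresholdCalibrator",
    "FlatPatchSet",
    "calibrate_threshold",
    "select_flat",
    "flat_pixel_mask",
]

logger = logging.getLogger(__name__)

DEFAULT_N_SAMPLES = 100_000
DEFAULT_C_MIN = 10


@dataclass(frozen=True)
class ThresholdCalibration:
    """Result of a Monte-Carlo threshold calibration."""

    eps_delta: float
    sigma_used: float
    n_samples: int
    seed: int
    quantile: float | None = None  # None means the maximum


@lru_cache(maxsize=64)
def _unit_noise_stat(
    d: int,
    n_samples: int,
    seed: int,
    quantile: float | None,
    hh_bytes: bytes,
    hh_shape: tuple[int, int],
) -> float:
    """Max (or quantile) texture intensity over unit-noise patch draws.

    Memoized: the iterative estimator and batch experiments recalibrate with
    identical draw parameters many times.
    """
    hh = np.frombuffer(hh_bytes, dtype=np.float64).reshape(hh_shape)
    kernels = GradientKernels(hh=hh, hv=hh.T.copy())
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((n_samples, d, d))
    eps_unit = texture_intensities(draws, kernels)
    if quantile is None:
        return float(eps_unit.max())
    return float(np.quantile(eps_unit, quantile))


@lru_cache(maxsize=64)
def _unit_bootstrap_bias(
    d: int,
    n_samples: int,
    seed: int,
    q0: float,
    hh_bytes: bytes,
    hh_shape: tuple[int, int],
) -> float:
    """Mean variance of the lowest-intensity q0 fraction of unit-noise patches.

    Conditioning on a small texture intensity shrinks a pure-noise patch's
    sample variance below sigma^2; this factor measures the shrinkage so the
    bootstrap estimate can be corrected.  Uses the same draw protocol (and
    seed) as the threshold calibration.
    """
    hh = np.frombuffer(hh_bytes, dtype=np.float64).reshape(hh_shape)
    kernels = GradientKernels(hh=hh, hv=hh.T.copy())
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((n_samples, d, d))
    eps = texture_intensities(draws, kernels)
    var = draws.var(axis=(1, 2), ddof=1)
    k = max(1, int(math.ceil(q0 * n_samples)))
    idx = np.argsort(eps, kind="stable")[:k]
    return float(var[idx].mean())


def bootstrap_variance_bias(
    d: int,
    kernels: GradientKernels,
    n_samples: int,
    seed: int,
    q0: float,
) -> float:
    """Shrinkage factor E[patch variance | lowest q0 texture] for unit noise."""
    hh = np.ascontiguousarray(kernels.hh, dtype=np.float64)
    return _unit_bootstrap_bias(
        int(d), int(n_samples), int(seed), float(q0), hh.tobytes(), hh.shape
    )


class ThresholdCalibrator:
    """Reusable calibrator: draws unit-noise patches once, scales by sigma.

    Keeping a single standard-normal draw per run makes the iterative
    threshold recalibration deterministic given the seed and cheap.
    """

    def __init__(
        self,
        d: int,
        kernels: GradientKernels,
        n_samples: int = DEFAULT_N_SAMPLES,
        seed: int = 0,
        quantile: float | None = None,
    ):
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if quantile is not None and not 0.0 < quantile <= 1.0:
            raise ValueError("quantile must be in (0, 1]")
        self.d = int(d)
        self.kernels = kernels
        self.n_samples = int(n_samples)
        self.seed = int(seed)
        self.quantile = quantile
        hh = np.ascontiguousarray(kernels.hh, dtype=np.float64)
        self._eps_unit_stat = _unit_noise_stat(
            self.d, self.n_samples, self.seed, quantile, hh.tobytes(), hh.shape
        )

    def threshold(self, sigma: float) -> float:
        if sigma < 0:
            raise ValueError("sigma must be non-negative")
        return sigma * self._eps_unit_stat

    def calibrate(self, sigma: float) -> ThresholdCalibration:
        return ThresholdCalibration(
            eps_delta=self.threshold(sigma),
            sigma_used=float(sigma),
            n_samples=self.n_samples,
            seed=self.seed,
            quantile=self.quantile,
        )


def calibrate_threshold(
    sigma: float,
    d: int,
    kernels: GradientKernels,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    quantile: float | None = None,
) -> ThresholdCalibration:
    """Monte-Carlo threshold: max texture intensity of pure noise at sigma.

    Deterministic given the seed.  ``quantile`` replaces the maximum by the
    given empirical quantile of the noise intensities (opt-in stability).
    """
    cal = ThresholdCalibrator(
        d=d, kernels=kernels, n_samples=n_samples, seed=seed, quantile=quantile
    )
    return cal.calibrate(sigma)


@dataclass(frozen=True, eq=False)
class FlatPatchSet:
    """Patches classified as flat, with their sample moments."""

    indices: np.ndarray  # flat indices into the PatchSet, ascending
    means: np.ndarray
    variances: np.ndarray  # unbiased, denominator w - 1
    eps_delta: float
    fallback: bool = False  # True when the C_min smallest-eps rule was used

    @property
    def C(self) -> int:
        return int(self.indices.size)


def select_flat(
    texture: TextureMap | np.ndarray,
    patches: PatchSet,
    eps_delta: float,
    c_min: int = DEFAULT_C_MIN,
) -> FlatPatchSet:
    """Patches with texture intensity <= eps_delta (inclusive), in order.

    If fewer than ``c_min`` patches pass, falls back to the ``c_min``
    smallest-intensity patches (ties broken by patch index) with a logged
    warning: a variance pool needs a minimum membership to be meaningful.
    """
    eps = texture.eps if isinstance(texture, TextureMap) else np.asarray(texture).ravel()
    if eps.size != patches.S:
        raise ValueError(
            f"texture map length {eps.size} does not match patch count {patches.S}"
        )
    mask = eps <= eps_delta
    indices = np.flatnonzero(mask)
    fallback = False
    if indices.size < min(c_min, patches.S):
        k = min(c_min, patches.S)
        indices = np.sort(np.argsort(eps, kind="stable")[:k])
        fallback = True
        logger.warning(
            "only %d patches under eps_delta=%.4g; falling back to the %d "
            "smallest-intensity patches",
            int(mask.sum()), eps_delta, k,
        )
    return FlatPatchSet(
        indices=indices,
        means=patches.means()[indices],
        variances=patches.variances()[indices],
        eps_delta=float(eps_delta),
        fallback=fallback,
    )


def flat_pixel_mask(patches: PatchSet, flat: FlatPatchSet) -> np.ndarray:
    """Boolean image marking pixels covered by any selected flat patch."""
    mask = np.zeros(patches.image.shape, dtype=bool)
    d = patches.d
    gc = patches.grid_shape[1]
    rows, cols = np.divmod(flat.indices, gc)
    for r, c in zip(rows, cols):
        mask[r : r + d, c : c + d] = True
    return mask
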