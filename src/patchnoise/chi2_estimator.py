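"""Chi-square pooling of flat-patch variances and the fixed-point iteration.

Each selected flat patch contributes an unbiased sample variance computed
from w = d^2 pixels.  For pure noise, (w-1) * var / sigma^2 is chi-square
with w-1 degrees of freedom, so the pooled sum over C patches is chi-square
with C*(w-1) degrees of freedom.  The noise level is estimated by dividing
the pooled sum by the chi-square quantile at confidence level T:

    sigma^2 = sum_l (w-1) * var_l / Q_chi2(T; C*(w-1))        (pooled, default)

A literal variant that pools raw variances against a quantile with C degrees
of freedom is retained behind ``df_convention="patch_count"``; only the
pooled form is near-unbiased for large C, which the flat-image recovery
experiments enforce.

The estimate is refined by a fixed-point loop: calibrate the selection
threshold at the current sigma, reselect flat patches, re-pool, and stop when
the squared relative change of sigma^2 falls below gamma.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .flat_selector import (
    DEFAULT_C_MIN,
    DEFAULT_N_SAMPLES,
    ThresholdCalibrator,
    bootstrap_variance_bias,
    select_flat,
)
from .patch_engine import (
    GradientKernels,
    PatchSet,
    TextureMap,
    decompose,
    texture_map,
    validate_image,
)

__all__ = [
    "DEFAULT_CONFIDENCE",
    "EstimatorConfig",
    "IterationRecord",
    "EstimationResult",
    "pooled_chi2_sigma",
    "initial_sigma",
    "convergence_phi",
    "estimate",
]

logger = logging.getLogger(__name__)

#: Default confidence level T = 1 - e^-6 (e = Euler's number).
DEFAULT_CONFIDENCE = 1.0 - math.exp(-6.0)


@dataclass(frozen=True)
class EstimatorConfig:
    """All tunables of the estimator.

    Parameters
    ----------
    d : patch side length; patches have w = d^2 pixels.
    confidence : chi-square confidence level T in (0, 1).
    gamma : convergence threshold on the squared relative change of sigma^2.
    max_iter : maximum number of refinement iterations.
    df_convention : "pooled" (df = C*(w-1), default) or "patch_count" (df = C).
    kernels : gradient kernel pair used for texture intensity.
    calib_samples : Monte-Carlo sample count for threshold calibration.
    calib_quantile : None for the max (default) or a quantile in (0, 1].
    seed : RNG seed for the calibration draws; fixes the whole run.
    q0 : fraction of smallest-intensity patches used for the initial sigma.
    c_min : minimum flat-patch count before the fallback rule kicks in.
    """

    d: int = 6
    confidence: float = DEFAULT_CONFIDENCE
    gamma: float = 1e-3
    max_iter: int = 10
    df_convention: str = "pooled"
    kernels: GradientKernels = field(default_factory=GradientKernels.first_difference)
    calib_samples: int = DEFAULT_N_SAMPLES
    calib_quantile: float | None = None
    seed: int = 0
    q0: float = 0.05
    c_min: int = DEFAULT_C_MIN

    def __post_init__(self):
        if self.d < 2:
            raise ValueError("patch size d must be >= 2")
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence T must lie in (0, 1)")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.df_convention not in ("pooled", "patch_count"):
            raise ValueError("df_convention must be 'pooled' or 'patch_count'")
        if not 0.0 < self.q0 <= 1.0:
            raise ValueError("q0 must lie in (0, 1]")

    @property
    def w(self) -> int:
        return self.d * self.d


@dataclass(frozen=True)
class IterationRecord:
    """One row of the estimation trace."""

    t: int
    sigma: float
    eps_delta: float | None  # threshold used to produce this sigma (None for t=0)
    n_flat: int
    phi: float | None  # convergence statistic vs the previous sigma


@dataclass(frozen=True)
class EstimationResult:
    sigma_end: float
    trace: tuple[IterationRecord, ...]
    converged: bool
    iterations_used: int

    def to_dict(self) -> dict:
        """JSON-serializable summary."""
        return {
            "sigma_end": self.sigma_end,
            "converged": self.converged,
            "iterations_used": self.iterations_used,
            "trace": [
                {
                    "t": r.t,
                    "sigma": r.sigma,
                    "eps_delta": r.eps_delta,
                    "n_flat": r.n_flat,
                    "phi": r.phi,
                }
                for r in self.trace
            ],
        }


def pooled_chi2_sigma(
    variances,
    w: int,
    T: float = DEFAULT_CONFIDENCE,
    df_convention: str = "pooled",
) -> float:
    """Noise level from a pool of per-patch variances via a chi-square quantile.

    ``variances`` are unbiased per-patch sample variances over w pixels each.
    """
    var = np.asarray(variances, dtype=np.float64)
    if var.size == 0:
        raise ValueError("no flat-patch variances to pool")
    if np.any(var < 0):
        raise ValueError("variances must be non-negative")
    if not 0.0 < T < 1.0:
        raise ValueError("confidence T must lie in (0, 1)")
    if w < 2:
        raise ValueError("patch pixel count w must be >= 2")
    C = var.size
    if df_convention == "pooled":
        num = (w - 1) * var.sum()
        df = C * (w - 1)
    elif df_convention == "patch_count":
        num = var.sum()
        df = C
    else:
        raise ValueError("df_convention must be 'pooled' or 'patch_count'")
    return float(np.sqrt(num / stats.chi2.ppf(T, df)))


def initial_sigma(
    texture: TextureMap,
    patches: PatchSet,
    config: EstimatorConfig,
) -> float:
    """Bootstrap estimate from the q0 fraction of smallest-intensity patches.

    Before any threshold exists, the patches most likely to be flat are simply
    those with the smallest texture intensity.  Conditioning on a low texture
    intensity also shrinks the sample variance of a pure-noise patch, so the
    pooled estimate is divided by a Monte-Carlo shrinkage factor computed on
    unit-noise patches with the same draw protocol (deterministic given the
    calibration seed).  The fixed-point loop then refines sigma_0.
    """
    eps = texture.eps
    k = max(int(math.ceil(config.q0 * patches.S)), min(config.c_min, patches.S))
    order = np.argsort(eps, kind="stable")[:k]
    variances = patches.variances()[np.sort(order)]
    sigma_raw = pooled_chi2_sigma(
        variances, config.w, config.confidence, config.df_convention
    )
    bias = bootstrap_variance_bias(
        config.d, config.kernels, config.calib_samples, config.seed, config.q0
    )
    return sigma_raw / math.sqrt(bias)


def convergence_phi(sigma_next: float, sigma_prev: float) -> float:
    """Squared relative change of sigma^2 between consecutive iterates."""
    if sigma_prev == 0.0:
        return 0.0 if sigma_next == 0.0 else math.inf
    v_next, v_prev = sigma_next**2, sigma_prev**2
    return (v_next - v_prev) ** 2 / v_prev**2


def estimate(image, config: EstimatorConfig | None = None) -> EstimationResult:
    """Blind noise-level estimate of a single grayscale image.

    Decomposes the image into overlapping patches, computes the texture map
    once, bootstraps sigma_0 from the flattest patches, then alternates
    threshold calibration at the current sigma with flat-patch reselection
    and chi-square re-pooling until the convergence statistic drops below
    gamma or ``max_iter`` is reached.  Deterministic given ``config.seed``.
    """
    if config is None:
        config = EstimatorConfig()
    image = validate_image(image)
    patches = decompose(image, config.d)
    if patches.S < 1:
        raise ValueError("image yields no patches")
    tmap = texture_map(image, config.d, config.kernels)

    calibrator = ThresholdCalibrator(
        d=config.d,
        kernels=config.kernels,
        n_samples=config.calib_samples,
        seed=config.seed,
        quantile=config.calib_quantile,
    )

    sigma_t = initial_sigma(tmap, patches, config)
    n0 = max(int(math.ceil(config.q0 * patches.S)), min(config.c_min, patches.S))
    trace = [IterationRecord(t=0, sigma=sigma_t, eps_delta=None,
                             n_flat=n0, phi=None)]
    converged = False
    prev_indices: np.ndarray | None = None

    for t in range(1, config.max_iter + 1):
        eps_delta = calibrator.threshold(sigma_t)
        flat = select_flat(tmap, patches, eps_delta, c_min=config.c_min)
        sigma_next = pooled_chi2_sigma(
            flat.variances, config.w, config.confidence, config.df_convention
        )
        phi = convergence_phi(sigma_next, sigma_t)
        trace.append(
            IterationRecord(t=t, sigma=sigma_next, eps_delta=eps_delta,
                            n_flat=flat.C, phi=phi)
        )
        logger.info(
            "iter %d: sigma=%.6g eps_delta=%.6g C=%d phi=%.3g",
            t, sigma_next, eps_delta, flat.C, phi,
        )
        same_set = prev_indices is not None and np.array_equal(
            prev_indices, flat.indices
        )
        sigma_t = sigma_next
        if phi <= config.gamma or same_set:
            converged = True
            break
        prev_indices = flat.indices

    if not converged:
        logger.warning(
            "no convergence within %d iterations (last phi=%.3g)",
            config.max_iter, trace[-1].phi,
        )
    return EstimationResult(
        sigma_end=sigma_t,
        trace=tuple(trace),
        converged=converged,
        iterations_used=trace[-1].t,
    )
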