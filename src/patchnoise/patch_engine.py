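"""Sliding-window patch decomposition and gradient texture intensity.

A noisy image ``Y = X + N`` (``N`` i.i.d. zero-mean Gaussian with standard
deviation sigma) is decomposed into all overlapping ``d x d`` patches.  For
each patch we compute a *gradient texture intensity* epsilon: the sum of the
absolute values of the horizontal and vertical gradient maps over the patch.
A latent-flat patch has epsilon driven only by noise, so epsilon separates
flat from structured patches once a noise-calibrated threshold is known.

All arithmetic is 64-bit float regardless of the input bit depth; inputs are
never clipped or rescaled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "GradientKernels",
    "Patch",
    "PatchSet",
    "TextureMap",
    "validate_image",
    "decompose",
    "gradient_maps",
    "texture_intensity",
    "texture_intensities",
    "texture_map",
    "sigma_flat_direct",
]

#: Rec. 601 luma weights used to collapse color inputs to grayscale.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def validate_image(image) -> np.ndarray:
    """Coerce *image* to a validated 2-D float64 array.

    Multi-channel input is reduced to luminance with the Rec. 601 weights
    (a warning is emitted).  Non-finite pixels raise ``ValueError``.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        warnings.warn(
            "multi-channel image reduced to luminance (Rec. 601 weights)",
            stacklevel=2,
        )
        arr = arr[:, :, :3] @ np.asarray(LUMA_WEIGHTS)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("image is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains NaN or Inf pixels")
    return arr


@dataclass(frozen=True, eq=False)
class GradientKernels:
    """A horizontal/vertical pair of zero-sum gradient kernels.

    ``hv`` must be the transpose of ``hh`` so the two directions are treated
    symmetrically, and both must sum to zero so a constant patch has zero
    gradient everywhere.
    """

    hh: np.ndarray
    hv: np.ndarray
    name: str = "custom"

    def __post_init__(self):
        hh = np.asarray(self.hh, dtype=np.float64)
        hv = np.asarray(self.hv, dtype=np.float64)
        if hh.ndim != 2 or hv.ndim != 2:
            raise ValueError("gradient kernels must be 2-D")
        if abs(hh.sum()) > 1e-12 or abs(hv.sum()) > 1e-12:
            raise ValueError("gradient kernel coefficients must sum to zero")
        if hh.T.shape != hv.shape or not np.array_equal(hh.T, hv):
            raise ValueError("hv must be the transpose of hh")
        object.__setattr__(self, "hh", hh)
        object.__setattr__(self, "hv", hv)

    @classmethod
    def first_difference(cls) -> "GradientKernels":
        """1x2 first-difference pair [-1, 1]; the default."""
        hh = np.array([[-1.0, 1.0]])
        return cls(hh=hh, hv=hh.T, name="diff")

    @classmethod
    def sobel(cls) -> "GradientKernels":
        hh = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
        return cls(hh=hh, hv=hh.T, name="sobel")

    @classmethod
    def from_name(cls, name: str) -> "GradientKernels":
        try:
            return {"diff": cls.first_difference, "sobel": cls.sobel}[name]()
        except KeyError:
            raise ValueError(f"unknown kernel set {name!r}; choose 'diff' or 'sobel'")


@dataclass(frozen=True, eq=False)
class Patch:
    """A single d x d window with its top-left image coordinate."""

    values: np.ndarray
    row: int
    col: int

    @property
    def d(self) -> int:
        return self.values.shape[0]

    @property
    def w(self) -> int:
        """Pixel count d**2."""
        return self.values.size


class PatchSet:
    """All stride-1 overlapping ``d x d`` patches of an image.

    Patches are stored as a zero-copy strided view with shape
    ``(P-d+1, Q-d+1, d, d)`` and enumerated in row-major order of their
    top-left corner.  Per-patch means and unbiased variances are computed
    lazily and cached.
    """

    def __init__(self, image: np.ndarray, d: int):
        image = validate_image(image)
        if d < 2:
            raise ValueError("patch size d must be >= 2")
        P, Q = image.shape
        if P < d or Q < d:
            raise ValueError(
                f"image {P}x{Q} is smaller than the patch size d={d}"
            )
        self.image = image
        self.d = int(d)
        self.grid = sliding_window_view(image, (d, d))
        self._means = None
        self._variances = None

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.grid.shape[:2]

    @property
    def S(self) -> int:
        gr, gc = self.grid_shape
        return gr * gc

    def __len__(self) -> int:
        return self.S

    def coords(self, k: int) -> tuple[int, int]:
        """Top-left (row, col) of the k-th patch in row-major order."""
        return divmod(int(k), self.grid_shape[1])

    def __getitem__(self, k: int) -> Patch:
        r, c = self.coords(k)
        return Patch(values=self.grid[r, c], row=r, col=c)

    def __iter__(self):
        for k in range(self.S):
            yield self[k]

    def values(self) -> np.ndarray:
        """All patches as an (S, d, d) array (copies the windows)."""
        return self.grid.reshape(self.S, self.d, self.d)

    def means(self) -> np.ndarray:
        """Per-patch sample means, flat (S,) array in patch order."""
        if self._means is None:
            self._means = self.grid.mean(axis=(2, 3)).ravel()
        return self._means

    def variances(self) -> np.ndarray:
        """Per-patch unbiased sample variances (denominator w - 1)."""
        if self._variances is None:
            w = self.d * self.d
            s1 = self.grid.sum(axis=(2, 3))
            s2 = np.square(self.grid).sum(axis=(2, 3))
            var = (s2 - np.square(s1) / w) / (w - 1)
            np.maximum(var, 0.0, out=var)  # guard tiny negatives from cancellation
            self._variances = var.ravel()
        return self._variances


def decompose(image, d: int) -> PatchSet:
    """All stride-1 overlapping d x d patches, row-major; S=(P-d+1)(Q-d+1)."""
    return PatchSet(image, d)


def _valid_correlate(arr: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Valid-region 2-D cross-correlation (no padding)."""
    kh, kw = kernel.shape
    if arr.shape[0] < kh or arr.shape[1] < kw:
        raise ValueError(
            f"kernel {kernel.shape} larger than array {arr.shape}"
        )
    windows = sliding_window_view(arr, (kh, kw))
    return np.einsum("rcij,ij->rc", windows, kernel)


def gradient_maps(patch, kernels: GradientKernels) -> tuple[np.ndarray, np.ndarray]:
    """Horizontal and vertical gradient maps of a patch.

    Valid-region cross-correlations with the kernel pair: no padding, so the
    output shrinks by the kernel extent minus one along each axis and no
    gradients are fabricated at patch borders.
    """
    values = patch.values if isinstance(patch, Patch) else np.asarray(patch, dtype=np.float64)
    gh = _valid_correlate(values, kernels.hh)
    gv = _valid_correlate(values, kernels.hv)
    return gh, gv


def texture_intensity(patch, kernels: GradientKernels) -> float:
    """Gradient texture intensity: sum of |Gh| + |Gv| over valid positions.

    Zero iff both gradient maps vanish identically, i.e. the patch is
    constant along both gradient directions.
    """
    gh, gv = gradient_maps(patch, kernels)
    return float(np.abs(gh).sum() + np.abs(gv).sum())


def texture_intensities(patches: np.ndarray, kernels: GradientKernels) -> np.ndarray:
    """Vectorized texture intensity for a batch of patches (n, d, d)."""
    patches = np.asarray(patches, dtype=np.float64)
    out = np.zeros(patches.shape[0])
    for kernel in (kernels.hh, kernels.hv):
        kh, kw = kernel.shape
        windows = sliding_window_view(patches, (kh, kw), axis=(1, 2))
        g = np.einsum("nrcij,ij->nrc", windows, kernel)
        out += np.abs(g).sum(axis=(1, 2))
    return out


@dataclass(frozen=True, eq=False)
class TextureMap:
    """Per-patch texture intensities aligned to the patch grid."""

    eps_grid: np.ndarray  # shape (P-d+1, Q-d+1)
    d: int

    @property
    def eps(self) -> np.ndarray:
        """Flat (S,) view in row-major patch order."""
        return self.eps_grid.ravel()

    @property
    def S(self) -> int:
        return self.eps_grid.size


def texture_map(image, d: int, kernels: GradientKernels) -> TextureMap:
    """Texture intensity of every patch of ``decompose(image, d)``.

    Exploits the overlap structure: each per-patch valid correlation value
    equals the full-image valid correlation at the corresponding offset, so
    the per-patch sum of |G| is a box sum over the full-image |G| map.
    """
    image = validate_image(image)
    P, Q = image.shape
    if d < 2 or P < d or Q < d:
        raise ValueError(f"image {P}x{Q} incompatible with patch size d={d}")
    gr, gc = P - d + 1, Q - d + 1
    eps = np.zeros((gr, gc))
    for kernel in (kernels.hh, kernels.hv):
        kh, kw = kernel.shape
        if d < kh or d < kw:
            raise ValueError(f"kernel {kernel.shape} larger than patch size d={d}")
        g_abs = np.abs(_valid_correlate(image, kernel))
        win = (d - kh + 1, d - kw + 1)
        eps += sliding_window_view(g_abs, win).sum(axis=(2, 3))
    return TextureMap(eps_grid=eps, d=d)


def sigma_flat_direct(image) -> float:
    """Population standard deviation of the whole image about its mean.

    A direct noise-level estimate valid only when the latent image is purely
    flat, in which case all variation is noise.
    """
    image = validate_image(image)
    return float(image.std())
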