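"""Image reading and writing (PNG, TIFF, PGM)."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .patch_engine import validate_image

__all__ = ["read_image", "write_mask", "write_phantom"]

SUPPORTED_SUFFIXES = {".png", ".tif", ".tiff", ".pgm"}


def read_image(path) -> np.ndarray:
    """Read a grayscale image as float64; color inputs reduced to luminance."""
    path = Path(path)
    if path.suffix.lower() not in SUPPORTED_SUFFIXES:
        raise ValueError(
            f"unsupported image format {path.suffix!r}; expected one of "
            f"{sorted(SUPPORTED_SUFFIXES)}"
        )
    arr = iio.imread(path)
    return validate_image(arr)


def write_mask(path, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit PNG (foreground = 255)."""
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def write_phantom(path, image: np.ndarray) -> None:
    """Write a float image losslessly enough for round-trip testing.

    PNG output is clipped to [0, 255] and quantized to 8 bits; TIFF output
    keeps 32-bit floats.
    """
    path = Path(path)
    image = validate_image(image)
    if path.suffix.lower() == ".png":
        iio.imwrite(path, np.clip(np.round(image), 0, 255).astype(np.uint8))
    elif path.suffix.lower() in (".tif", ".tiff"):
        iio.imwrite(path, image.astype(np.float32))
    else:
        raise ValueError(f"unsupported output format {path.suffix!r}")
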