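"""Image and disparity-map I/O.

Grayscale stereo images arrive as PNG/PGM/TIFF (color is collapsed to the
channel average).  Disparity maps are written as 32-bit float PFM (the
portable float map used by stereo benchmarks: little-endian, bottom-up
rows, NaN for invalid pixels) plus an optional 16-bit PNG preview.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np

from .pooling import DisparityMap


def read_image(path) -> np.ndarray:
    """Read a grayscale image as float; color inputs average their channels."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"image not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the path attached
        raise OSError(f"could not read image {path}: {exc}") from exc
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.ndim != 2:
        raise OSError(f"{path}: expected a 2D grayscale or color image")
    return arr


# ---------------------------------------------------------------------------
# PFM (portable float map)
# ---------------------------------------------------------------------------

def write_pfm(path, data: np.ndarray | DisparityMap) -> None:
    """Write a 32-bit float PFM; invalid pixels are encoded as NaN.

    Little-endian (negative scale header) with rows stored bottom-up, per
    the PFM convention.
    """
    if isinstance(data, DisparityMap):
        arr = np.where(data.valid_mask, data.disparity, np.nan)
    else:
        arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValueError("PFM output must be a 2D map")
    h, w = arr.shape
    with open(path, "wb") as fh:
        fh.write(b"Pf\n")
        fh.write(f"{w} {h}\n".encode())
        fh.write(b"-1.0\n")  # negative -> little-endian
        fh.write(arr[::-1].astype("<f4").tobytes())


def read_pfm(path) -> np.ndarray:
    """Read a grayscale PFM back into a float array (NaN = invalid)."""
    with open(path, "rb") as fh:
        header = fh.readline().strip()
        if header != b"Pf":
            raise OSError(f"{path}: not a grayscale PFM file (header {header!r})")
        dims = fh.readline().split()
        w, h = int(dims[0]), int(dims[1])
        scale = float(fh.readline())
        dtype = "<f4" if scale < 0 else ">f4"
        arr = np.frombuffer(fh.read(4 * w * h), dtype=dtype).reshape(h, w)
    return arr[::-1].astype(float)


def write_preview_png(path, data: np.ndarray | DisparityMap) -> None:
    """16-bit PNG preview scaling min..max to 0..65535; invalid pixels -> 0."""
    if isinstance(data, DisparityMap):
        arr = np.where(data.valid_mask, data.disparity, np.nan)
    else:
        arr = np.asarray(data, dtype=float)
    finite = np.isfinite(arr)
    out = np.zeros(arr.shape, dtype=np.uint16)
    if finite.any():
        lo, hi = arr[finite].min(), arr[finite].max()
        span = hi - lo if hi > lo else 1.0
        scaled = np.clip((arr - lo) / span, 0.0, 1.0) * 65535.0
        out[finite] = np.round(scaled[finite]).astype(np.uint16)
    iio.imwrite(path, out)


def write_image_png(path, image: np.ndarray) -> None:
    """8-bit PNG of a [0, 1] or arbitrary-range luminance image."""
    arr = np.asarray(image, dtype=float)
    lo, hi = arr.min(), arr.max()
    span = hi - lo if hi > lo else 1.0
    iio.imwrite(path, np.round((arr - lo) / span * 255.0).astype(np.uint8))
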