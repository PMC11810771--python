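"""Image input/output: TIFF (2D or multi-page stacks) and PNG (2D only).

Intensities are converted to 64-bit floats on load; writing converts PNG
output to 16-bit unsigned after rescaling, TIFF output is written as
float32 to keep files portable.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import InvalidParameterError


def imread(path) -> np.ndarray:
    """Load an image or stack as float64; TIFF stacks come back T×H×W."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        arr = iio.imread(path)
        if arr.ndim == 3:  # RGB(A) -> luminance by channel mean
            arr = arr[..., :3].mean(axis=-1)
    else:
        raise InvalidParameterError(f"unsupported image format: {path.name}")
    return np.asarray(arr, dtype=np.float64)


def imwrite(path, image) -> None:
    """Write a 2D image (PNG or TIFF) or a 3D stack (multi-page TIFF)."""
    path = Path(path)
    arr = np.asarray(image, dtype=np.float64)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, arr.astype(np.float32), photometric="minisblack")
    elif suffix == ".png":
        if arr.ndim != 2:
            raise InvalidParameterError("PNG supports 2D images only")
        lo, hi = float(arr.min()), float(arr.max())
        scale = 65535.0 / (hi - lo) if hi > lo else 0.0
        iio.imwrite(path, ((arr - lo) * scale).astype(np.uint16))
    else:
        raise InvalidParameterError(f"unsupported image format: {path.name}")
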