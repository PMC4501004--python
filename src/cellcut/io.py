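"""Image readers: 8/16-bit grayscale PNG and TIFF, RGB converted by the
standard luminance combination."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .preprocess import GrayImage


def read_gray_image(
    path: str | Path, pixel_size_um: tuple[float, float] | None = None
) -> GrayImage:
    """Read an image file as a :class:`GrayImage`.

    RGB(A) input is converted with the Rec. 709 luminance weights; the bit
    depth is inferred from the array dtype (16-bit for anything wider than
    8 bits).
    """
    import imageio.v3 as iio

    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as err:
        raise OSError(f"cannot read image {path}: {err}") from err
    if arr.ndim == 3:
        rgb = arr[..., :3].astype(np.float64)
        arr_max = 255 if arr.dtype == np.uint8 else 65535
        lum = rgb @ np.array([0.2126, 0.7152, 0.0722])
        arr = np.clip(np.round(lum), 0, arr_max).astype(arr.dtype)
    if arr.ndim != 2:
        raise OSError(f"unsupported image layout in {path}: shape {arr.shape}")
    if arr.dtype == np.uint8:
        return GrayImage(arr, bit_depth=8, pixel_size_um=pixel_size_um)
    if arr.dtype == np.bool_:
        return GrayImage(arr.astype(np.uint8) * 255, 8, pixel_size_um)
    arr = arr.astype(np.int64)
    if arr.min() < 0:
        raise OSError(f"negative intensities in {path}")
    if arr.max() <= 255:
        return GrayImage(arr.astype(np.uint8), 8, pixel_size_um)
    if arr.max() > 65535:
        raise OSError(f"{path}: intensities exceed 16-bit range")
    return GrayImage(arr.astype(np.uint16), 16, pixel_size_um)
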