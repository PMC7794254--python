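"""SHG image container and grayscale TIFF/PNG I/O.

A second-harmonic-generation (SHG) image is a single-channel intensity map
of fibrillar collagen; all feature operators consume this container so that
the physical pixel size travels with the pixel grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile

#: Default physical pixel size: a 500 μm field of view sampled at 512 px.
DEFAULT_PIXEL_SIZE_UM = 500.0 / 512.0

MIN_IMAGE_SIDE = 64


@dataclass(frozen=True)
class SHGImage:
    """A 2-D non-negative intensity grid with a physical pixel size.

    Parameters
    ----------
    intensities
        2-D float array of non-negative, finite intensities.
    pixel_size_um
        Edge length of one pixel in micrometres.
    """

    intensities: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"SHG image must be 2-D, got ndim={arr.ndim}")
        if min(arr.shape) < MIN_IMAGE_SIDE:
            raise ValueError(
                f"SHG image must be at least {MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE}, "
                f"got {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("SHG image intensities must be finite")
        if arr.min() < 0:
            raise ValueError("SHG image intensities must be non-negative")
        object.__setattr__(self, "intensities", arr)
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    @property
    def field_of_view_um(self) -> tuple[float, float]:
        return (
            self.shape[0] * self.pixel_size_um,
            self.shape[1] * self.pixel_size_um,
        )


def write_tiff(path: str | Path, image: SHGImage) -> None:
    """Write an image as 16-bit grayscale TIFF, clipping to [0, 65535]."""
    arr = np.clip(np.round(image.intensities), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def read_image(
    path: str | Path,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    channel: int | None = None,
) -> SHGImage:
    """Read an 8/16-bit grayscale TIFF or PNG as an :class:`SHGImage`.

    Multi-channel files require ``channel`` (the SHG channel index).
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(str(path))
    else:
        arr = iio.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if channel is None:
            raise ValueError(
                f"{path.name} is multi-channel; specify the SHG channel index"
            )
        arr = arr[..., channel] if arr.shape[-1] <= 4 else arr[channel]
    return SHGImage(arr.astype(float), pixel_size_um=pixel_size_um)
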