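"""Intensity-image containers with physical pixel size, and multichannel TIFF I/O.

All pixel data in the package travels as :class:`Image2D` (a single channel) or
:class:`MultiChannelImage` (named channels sharing one grid). Geometry is specified
in nanometres and converted to pixels through ``pixel_size`` (nm per pixel); the
coordinate convention is x = column, y = row, origin at the top-left pixel, with a
pixel's centre at ``(col + 0.5, row + 0.5) * pixel_size`` in nm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["Image2D", "MultiChannelImage", "read_tiff", "write_tiff"]


@dataclass
class Image2D:
    """A 2-D intensity grid with a physical pixel size.

    Parameters
    ----------
    pixels
        H×W array of finite, real intensities (converted to float64).
    pixel_size
        Physical size of one pixel in nm; must be positive.
    """

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D array, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")
        if not (self.pixel_size > 0):
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        self.pixel_size = float(self.pixel_size)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def extent_nm(self) -> tuple[float, float]:
        """Physical (height, width) of the field of view in nm."""
        h, w = self.pixels.shape
        return h * self.pixel_size, w * self.pixel_size

    def copy(self) -> "Image2D":
        return Image2D(self.pixels.copy(), self.pixel_size)


@dataclass
class MultiChannelImage:
    """Named channels sharing one pixel grid and pixel size."""

    channels: dict[str, Image2D] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {im.shape for im in self.channels.values()}
        sizes = {im.pixel_size for im in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels disagree on shape: {shapes}")
        if len(sizes) > 1:
            raise ValueError(f"channels disagree on pixel size: {sizes}")

    def __getitem__(self, name: str) -> Image2D:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    @property
    def pixel_size(self) -> float:
        return next(iter(self.channels.values())).pixel_size


def write_tiff(path, image: MultiChannelImage) -> None:
    """Write one page per channel; channel names and pixel size go into the
    image description as JSON so a round trip preserves physical units."""
    stack = np.stack([image[name].pixels for name in image.channel_names])
    meta = {"channels": image.channel_names, "pixel_size_nm": image.pixel_size}
    tifffile.imwrite(str(path), stack.astype(np.float32),
                     photometric="minisblack", description=json.dumps(meta))


def read_tiff(path, pixel_size: float | None = None,
              channel_names: list[str] | None = None) -> MultiChannelImage:
    """Read a multi-page TIFF into a :class:`MultiChannelImage`.

    Channel names and pixel size are recovered from the JSON image description
    written by :func:`write_tiff`; for third-party files they can be supplied
    explicitly (``pixel_size`` is then required).
    """
    with tifffile.TiffFile(str(path)) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].description
    if stack.ndim == 2:
        stack = stack[None]
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    names = channel_names or meta.get("channels") or [f"ch{i}" for i in range(len(stack))]
    px = pixel_size if pixel_size is not None else meta.get("pixel_size_nm")
    if px is None:
        raise ValueError(f"{path}: no pixel size in metadata; pass pixel_size=")
    if len(names) != len(stack):
        raise ValueError(f"{path}: {len(names)} channel names for {len(stack)} pages")
    return MultiChannelImage(
        {name: Image2D(page, px) for name, page in zip(names, stack)}
    )
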