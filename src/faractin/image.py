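"""Two-channel fluorescence image container and TIFF I/O."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

log = logging.getLogger(__name__)

DEFAULT_CHANNEL_MAP = {"dapi": 0, "actin": 1}


class ImageFormatError(ValueError):
    pass


@dataclass
class MultiChannelImage:
    """A (2, H, W) intensity raster: one DAPI and one F-actin channel."""

    pixels: np.ndarray
    channel_names: tuple[str, str] = ("dapi", "actin")
    pixel_size_um: float | None = None
    source_path: str | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[0] != 2:
            raise ImageFormatError(
                f"expected a (2, H, W) raster, got shape {self.pixels.shape}"
            )
        if np.issubdtype(self.pixels.dtype, np.floating) and (self.pixels < 0).any():
            raise ImageFormatError("negative intensities in image")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]

    @property
    def dapi(self) -> np.ndarray:
        return self.pixels[self.channel_names.index("dapi")]

    @property
    def actin(self) -> np.ndarray:
        return self.pixels[self.channel_names.index("actin")]


def _normalize_axes(arr: np.ndarray) -> np.ndarray:
    """Bring a 3-D TIFF array to channel-first (C, H, W) order."""
    if arr.ndim == 3 and arr.shape[-1] <= 8 < arr.shape[0]:
        return np.moveaxis(arr, -1, 0)
    return arr


def read_image(path: str | Path, channel_map: dict[str, int] | None = None) -> MultiChannelImage:
    """Read a multi-channel TIFF, mapping channels to (dapi, actin).

    ``channel_map`` gives the source index of each named channel, e.g.
    ``{"dapi": 2, "actin": 0}``; it defaults to the first two channels in
    (dapi, actin) order.  Unmapped extra channels are dropped with a notice.
    A single-channel file is rejected: both stains are required.
    """
    path = Path(path)
    channel_map = dict(channel_map or DEFAULT_CHANNEL_MAP)
    for key in ("dapi", "actin"):
        if key not in channel_map:
            raise ImageFormatError(f"channel_map is missing the '{key}' channel index")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # tifffile raises several types for non-TIFFs
        raise ImageFormatError(f"not a readable TIFF image: {path}") from exc
    arr = _normalize_axes(arr)
    if arr.ndim == 2:
        raise ImageFormatError(
            f"{path.name} has a single channel; a DAPI and an actin channel are required"
        )
    if arr.ndim != 3:
        raise ImageFormatError(f"unsupported TIFF dimensionality {arr.shape} in {path.name}")
    n_channels = arr.shape[0]
    for key, idx in channel_map.items():
        if not 0 <= idx < n_channels:
            raise ImageFormatError(
                f"channel_map['{key}'] = {idx} out of range for {n_channels}-channel {path.name}"
            )
    dropped = n_channels - 2
    if dropped > 0:
        log.info("dropping %d unmapped channel(s) from %s", dropped, path.name)
    pixels = np.stack([arr[channel_map["dapi"]], arr[channel_map["actin"]]])
    return MultiChannelImage(pixels, ("dapi", "actin"), source_path=str(path))


def write_image(image: MultiChannelImage, path: str | Path) -> None:
    """Write as a 16-bit two-channel TIFF (channel order dapi, actin)."""
    pixels = image.pixels
    if pixels.dtype != np.uint16:
        pixels = np.clip(np.round(pixels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        path,
        pixels,
        photometric="minisblack",
        metadata={"axes": "CYX", "channels": list(image.channel_names)},
    )
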