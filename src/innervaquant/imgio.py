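"""Image, mask and table I/O for fluorescence wound sections.

The quantification pipeline works on a single scalar intensity plane (the
antibody marker channel, conventionally the red plane of an RGB confocal
export). All intensities are held as floating point in [0, 1]; integer
inputs are rescaled by their dtype maximum so that threshold statistics are
independent of the original bit depth.

Coordinates are 0-based (row, column), row-major. Region and layer label
masks must share the image grid exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigurationError, ValidationError

__all__ = [
    "MarkerImage",
    "RegionLabelSet",
    "DensityRecord",
    "REGION_NAMES",
    "LAYER_NAMES",
    "read_image",
    "read_label_set",
    "label_set_from_arrays",
    "write_density_table",
    "read_density_table",
]

#: Default vocabulary for region label masks. Extensible via ``region_names``.
REGION_NAMES: dict[int, str] = {
    0: "outside",
    1: "wound_bed",
    2: "outer_edge_1",
    3: "wound_center",
    4: "outer_edge_2",
    5: "uninjured",
}

#: Default vocabulary for layer label masks.
LAYER_NAMES: dict[int, str] = {
    0: "neither",
    1: "epidermis",
    2: "dermis",
}

_RGB_CHANNELS = {"red": 0, "green": 1, "blue": 2, "alpha": 3}


@dataclass
class MarkerImage:
    """One 2-D marker-channel intensity plane, normalized to [0, 1]."""

    pixels: np.ndarray
    source_path: str = ""
    channel_name: str = "red"
    pixel_size_um: float | None = None
    bit_depth_origin: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValidationError(
                f"marker image must be 2-D, got shape {self.pixels.shape}"
            )
        if self.pixels.size < 1:
            raise ValidationError("marker image has zero pixels")
        if not np.issubdtype(self.pixels.dtype, np.floating):
            raise ValidationError("marker image pixels must be floating point")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0.0 or hi > 1.0:
            raise ValidationError(
                f"marker intensities must lie in [0, 1], got [{lo}, {hi}]"
            )
        if self.pixel_size_um is not None and not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um must be positive when present")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "MarkerImage":
        """Copy of this image with replaced pixel data, metadata preserved."""
        return replace(self, pixels=pixels)


@dataclass
class RegionLabelSet:
    """Paired region and layer label masks aligned to an image grid.

    Region labels partition the section laterally (wound bed, outer edges,
    wound center); layer labels partition the tissue vertically (epidermis
    over dermis, 0 for neither — glass, mounting medium, scab).
    """

    region_mask: np.ndarray
    layer_mask: np.ndarray
    region_names: Mapping[int, str] = field(default_factory=lambda: dict(REGION_NAMES))
    layer_names: Mapping[int, str] = field(default_factory=lambda: dict(LAYER_NAMES))

    def __post_init__(self) -> None:
        self.region_mask = np.asarray(self.region_mask)
        self.layer_mask = np.asarray(self.layer_mask)
        for name, mask in (("region", self.region_mask), ("layer", self.layer_mask)):
            if not np.issubdtype(mask.dtype, np.integer):
                raise ValidationError(f"{name} mask must hold integer labels")
            if mask.ndim != 2:
                raise ValidationError(f"{name} mask must be 2-D")
        if self.region_mask.shape != self.layer_mask.shape:
            raise ValidationError(
                "region mask shape "
                f"{self.region_mask.shape} != layer mask shape {self.layer_mask.shape}"
            )
        for name, mask, names in (
            ("region", self.region_mask, self.region_names),
            ("layer", self.layer_mask, self.layer_names),
        ):
            unknown = set(np.unique(mask).tolist()) - set(names)
            if unknown:
                raise ValidationError(
                    f"{name} mask contains unnamed labels {sorted(unknown)}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.region_mask.shape  # type: ignore[return-value]

    def regions_present(self) -> list[int]:
        """Region labels occurring in the mask, excluding 0 (outside)."""
        return [int(r) for r in np.unique(self.region_mask) if r != 0]

    def region_label_for(self, name: str) -> int:
        for label, label_name in self.region_names.items():
            if label_name == name:
                return int(label)
        raise ConfigurationError(f"unknown region name {name!r}")


@dataclass
class DensityRecord:
    """One (sample, day, region, layer) positive-pixel density measurement."""

    sample_id: str
    day: int
    region: str
    layer: str
    positive_pixels: int
    area_pixels: int
    density: float

    def __post_init__(self) -> None:
        if self.area_pixels <= 0:
            raise ValidationError("area_pixels must be positive")
        if self.positive_pixels < 0:
            raise ValidationError("positive_pixels must be non-negative")
        if not 0.0 <= self.density <= 1.0:
            raise ValidationError("density must lie in [0, 1]")


def _decode(path: str | os.PathLike) -> np.ndarray:
    p = Path(path)
    if not p.exists():
        raise IOError(f"cannot read image: no such file {p}")
    try:
        if p.suffix.lower() in {".tif", ".tiff"}:
            return tifffile.imread(p)
        return iio.imread(p)
    except IOError:
        raise
    except Exception as exc:  # decoder-specific failure
        raise IOError(f"cannot decode {p}: {exc}") from exc


def _extract_channel(arr: np.ndarray, channel: str, path: str) -> np.ndarray:
    """Pull one named plane out of a 2-D / RGB / multi-channel array."""
    if arr.ndim == 2:
        if channel in {"gray", "grey", "0"}:
            return arr
        raise ConfigurationError(
            f"{path}: single-channel image has no channel {channel!r}; "
            "use 'gray' or '0'"
        )
    if arr.ndim != 3:
        raise ValidationError(f"{path}: unsupported image dimensionality {arr.ndim}")
    # channel axis: trailing for interleaved RGB(A), leading for channel stacks
    if arr.shape[-1] in (3, 4):
        axis, n = -1, arr.shape[-1]
    elif arr.shape[0] < min(arr.shape[1:]):
        axis, n = 0, arr.shape[0]
    else:
        axis, n = -1, arr.shape[-1]
    if channel in _RGB_CHANNELS:
        idx = _RGB_CHANNELS[channel]
    elif channel.isdigit():
        idx = int(channel)
    else:
        raise ConfigurationError(f"{path}: unknown channel {channel!r}")
    if idx >= n:
        raise ConfigurationError(
            f"{path}: channel {channel!r} (index {idx}) not present in "
            f"{n}-channel image"
        )
    return np.take(arr, idx, axis=axis)


def read_image(
    path: str | os.PathLike,
    channel: str = "red",
    pixel_size_um: float | None = None,
) -> MarkerImage:
    """Read one marker channel from a TIFF/PNG file, rescaled to [0, 1].

    Integer data is divided by its dtype maximum (255 for 8-bit, 65535 for
    16-bit) so the stored maximum maps exactly to 1.0.
    """
    arr = _decode(path)
    plane = _extract_channel(arr, channel, str(path))
    if plane.size == 0:
        raise ValidationError(f"{path}: image has zero pixels")
    if plane.dtype == np.uint8:
        bit_depth = 8
        pixels = plane.astype(np.float64) / 255.0
    elif plane.dtype == np.uint16:
        bit_depth = 16
        pixels = plane.astype(np.float64) / 65535.0
    elif np.issubdtype(plane.dtype, np.floating):
        bit_depth = 32
        pixels = plane.astype(np.float64)
        if pixels.min() < 0 or pixels.max() > 1:
            raise ValidationError(
                f"{path}: floating-point image must already be scaled to [0, 1]"
            )
    else:
        raise ValidationError(f"{path}: unsupported pixel dtype {plane.dtype}")
    return MarkerImage(
        pixels=pixels,
        source_path=str(path),
        channel_name=channel,
        pixel_size_um=pixel_size_um,
        bit_depth_origin=bit_depth,
    )


def _read_mask(path: str | os.PathLike) -> np.ndarray:
    arr = _decode(path)
    if arr.ndim != 2:
        raise ValidationError(f"{path}: label mask must be single-channel 2-D")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValidationError(f"{path}: label mask must be integer, got {arr.dtype}")
    return arr.astype(np.int64)


def read_label_set(
    region_path: str | os.PathLike,
    layer_path: str | os.PathLike,
    image: MarkerImage,
    region_names: Mapping[int, str] | None = None,
    layer_names: Mapping[int, str] | None = None,
) -> RegionLabelSet:
    """Read and validate region + layer masks against an image's grid."""
    region = _read_mask(region_path)
    layer = _read_mask(layer_path)
    return label_set_from_arrays(region, layer, image, region_names, layer_names)


def label_set_from_arrays(
    region_mask: np.ndarray,
    layer_mask: np.ndarray,
    image: MarkerImage,
    region_names: Mapping[int, str] | None = None,
    layer_names: Mapping[int, str] | None = None,
) -> RegionLabelSet:
    if region_mask.shape != image.shape:
        raise ValidationError(
            f"region mask shape {region_mask.shape} != image shape {image.shape}"
        )
    if layer_mask.shape != image.shape:
        raise ValidationError(
            f"layer mask shape {layer_mask.shape} != image shape {image.shape}"
        )
    kwargs = {}
    if region_names is not None:
        kwargs["region_names"] = dict(region_names)
    if layer_names is not None:
        kwargs["layer_names"] = dict(layer_names)
    return RegionLabelSet(region_mask=region_mask, layer_mask=layer_mask, **kwargs)


_TABLE_COLUMNS = [
    "sample_id",
    "day",
    "region",
    "layer",
    "positive_pixels",
    "area_pixels",
    "density",
]


def write_density_table(
    records: Sequence[DensityRecord],
    path: str | os.PathLike,
    metadata: Mapping[str, str] | None = None,
) -> None:
    """Write density records as a UTF-8 CSV; a round-trip read is exact.

    ``metadata`` entries (e.g. config hash, seed) are emitted as leading
    ``# key=value`` comment lines so the tabular payload stays standard CSV.
    """
    if len(records) == 0:
        raise ValidationError("cannot write an empty density table")
    frame = pd.DataFrame([vars(r) for r in records], columns=_TABLE_COLUMNS)
    try:
        with open(path, "w", encoding="utf-8", newline="") as handle:
            for key, value in (metadata or {}).items():
                handle.write(f"# {key}={value}\n")
            frame.to_csv(handle, index=False)
    except OSError as exc:
        raise IOError(f"cannot write density table to {path}: {exc}") from exc


def read_density_table(path: str | os.PathLike) -> list[DensityRecord]:
    """Parse a density CSV written by :func:`write_density_table`."""
    try:
        frame = pd.read_csv(path, comment="#")
    except OSError as exc:
        raise IOError(f"cannot read density table from {path}: {exc}") from exc
    missing = set(_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: density table missing columns {sorted(missing)}")
    return [
        DensityRecord(
            sample_id=str(row.sample_id),
            day=int(row.day),
            region=str(row.region),
            layer=str(row.layer),
            positive_pixels=int(row.positive_pixels),
            area_pixels=int(row.area_pixels),
            density=float(row.density),
        )
        for row in frame.itertuples(index=False)
    ]
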