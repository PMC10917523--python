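"""TIFF z-stack input/output and the sum projection shared by all imaging assays.

Conventions binding for the whole package:

* voxel arrays are ordered ``(z, y, x)``, 0-based, pixel-centered;
* intensities are carried as ``float64`` in memory regardless of the on-disk
  integer type, so downstream sums and medians are exact in tests;
* the first (and only) spatial reduction applied to a stack is the per-pixel
  sum over z — every per-cell statistic downstream operates on that 2D
  projection.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

DEFAULT_Z_STEP_UM = 0.5
DEFAULT_PIXEL_SIZE_UM = 0.16


class FormatError(ValueError):
    """Raised when a TIFF file cannot be interpreted as a single-channel z-stack."""


@dataclass
class ImageStack:
    """A single-channel 3D fluorescence stack.

    Parameters
    ----------
    voxels:
        3D array ordered ``(z, y, x)``; finite and non-negative.
    z_step_um:
        Axial step between consecutive slices, micrometers.
    pixel_size_um:
        Lateral pixel size, micrometers.
    channel_name:
        Free-text channel label (e.g. ``"GFP"``, ``"mCherry"``).
    """

    voxels: np.ndarray
    z_step_um: float = DEFAULT_Z_STEP_UM
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D (z, y, x); got ndim={self.voxels.ndim}")
        if self.voxels.shape[0] < 1:
            raise ValueError("stack must contain at least one z slice")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("stack intensities must be finite")
        if np.any(self.voxels < 0):
            raise ValueError("stack intensities must be non-negative")
        if self.z_step_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("z_step_um and pixel_size_um must be positive")

    @property
    def n_z(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class Projection2D:
    """A 2D image derived from a stack, together with its provenance."""

    pixels: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("projection must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def sum_project(stack: ImageStack) -> Projection2D:
    """Sum a stack along z, pixel by pixel — no rescaling, no clipping.

    The result is the image every segmentation and per-cell statistic in this
    package operates on.
    """
    return Projection2D(
        pixels=stack.voxels.sum(axis=0),
        provenance=f"{stack.channel_name or 'stack'}|z-sum",
    )


def write_stack(path, stack: ImageStack, ome: bool = False) -> None:
    """Write a stack as a single-channel multi-page TIFF (ImageJ or OME dialect)."""
    data = stack.voxels.astype(np.float32)
    if ome:
        tifffile.imwrite(
            str(path),
            data,
            ome=True,
            metadata={
                "axes": "ZYX",
                "PhysicalSizeZ": stack.z_step_um,
                "PhysicalSizeZUnit": "µm",
                "PhysicalSizeX": stack.pixel_size_um,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeY": stack.pixel_size_um,
                "PhysicalSizeYUnit": "µm",
            },
        )
    else:
        tifffile.imwrite(
            str(path),
            data,
            imagej=True,
            resolution=(1.0 / stack.pixel_size_um, 1.0 / stack.pixel_size_um),
            metadata={"axes": "ZYX", "spacing": stack.z_step_um, "unit": "um"},
        )


def _ome_physical_size(xml: str, axis: str) -> float | None:
    m = re.search(rf'PhysicalSize{axis}="([0-9.eE+-]+)"', xml)
    return float(m.group(1)) if m else None


def read_stack(path, channel_name: str = "") -> ImageStack:
    """Read a single-channel multi-page TIFF into an :class:`ImageStack`.

    Page order maps to ascending z. Voxel sizes are populated from ImageJ or
    OME tags when present; otherwise package defaults are used and a note is
    logged.

    Raises
    ------
    FormatError
        If the file is unreadable, pages disagree in shape, or the series
        carries a channel/sample axis (multi-channel interleaving).
    """
    try:
        tf = tifffile.TiffFile(str(path))
    except Exception as exc:  # unreadable / not a TIFF
        raise FormatError(f"cannot read TIFF {path!r}: {exc}") from exc
    with tf:
        shapes = [p.shape for p in tf.pages]
        for i, shp in enumerate(shapes):
            if shp != shapes[0]:
                raise FormatError(
                    f"{path!r}: page {i} has shape {shp}, expected {shapes[0]}"
                )
        series = tf.series[0]
        axes = series.axes
        if any(ax in axes for ax in ("C", "S")):
            raise FormatError(
                f"{path!r}: series axes {axes!r} contain a channel/sample axis; "
                "expected a single-channel z-stack"
            )
        data = np.asarray(series.asarray(), dtype=np.float64)
        if data.ndim == 2:
            data = data[np.newaxis]
        if data.ndim != 3:
            raise FormatError(f"{path!r}: cannot interpret axes {axes!r} as (z, y, x)")

        z_step = None
        px_size = None
        if tf.is_imagej and tf.imagej_metadata:
            z_step = tf.imagej_metadata.get("spacing")
            page = tf.pages[0]
            if "XResolution" in page.tags:
                num, den = page.tags["XResolution"].value
                if num:
                    px_size = den / num
        elif tf.ome_metadata:
            z_step = _ome_physical_size(tf.ome_metadata, "Z")
            px_size = _ome_physical_size(tf.ome_metadata, "X")
        if z_step is None:
            logger.info("%s: no z-step metadata; using default %.2f um", path, DEFAULT_Z_STEP_UM)
            z_step = DEFAULT_Z_STEP_UM
        if px_size is None:
            logger.info(
                "%s: no pixel-size metadata; using default %.3f um", path, DEFAULT_PIXEL_SIZE_UM
            )
            px_size = DEFAULT_PIXEL_SIZE_UM

    return ImageStack(
        voxels=data,
        z_step_um=float(z_step),
        pixel_size_um=float(px_size),
        channel_name=channel_name,
    )
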