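"""Calibrated raster images and segmented regions.

The pipeline's in-memory image container is :class:`CalibratedImage`: a 2D
(or H×W×3 RGB) intensity array together with the physical pixel size in
micrometres per pixel and, optionally, the stage position of the image's
top-left corner so segmented regions can be mapped back to microscope stage
coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class CalibratedImage:
    """A fluorescence micrograph with physical calibration.

    Parameters
    ----------
    pixels : ndarray
        2D intensity raster, or an (H, W, 3) RGB stack.
    pixel_size_um : float
        Pixel edge length in micrometres per pixel; must be > 0.
    channel : str
        Channel tag: ``red``, ``green``, ``blue``, ``gray`` or ``rgb``.
    stage_origin_um : tuple of float, optional
        Stage-frame (x, y) of the image's top-left corner, in micrometres.
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel: str = "gray"
    stage_origin_um: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.size == 0:
            raise ValueError("image raster is empty")
        if self.pixels.ndim not in (2, 3):
            raise ValueError(f"expected 2D or RGB raster, got ndim={self.pixels.ndim}")
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise ValueError("3D input must be an (H, W, 3) RGB stack")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")

    @property
    def is_rgb(self) -> bool:
        return self.pixels.ndim == 3

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, channel: str | None = None) -> "CalibratedImage":
        """Copy of this image with a new raster, calibration preserved."""
        return replace(self, pixels=pixels, channel=channel or self.channel)


@dataclass
class Region:
    """One segmented connected component with calibrated shape descriptors.

    ``area_um2`` is pixel count × pixel_size²; ``perimeter_um`` comes from the
    crack-boundary polygon estimator (see :mod:`invadopipe.geometry`) and
    ``circularity`` is min(1, 4π·A/P²), clamped to absorb discretization
    overshoot on very round objects.
    """

    label: int
    mask: np.ndarray                      # boolean crop of the component
    bbox: tuple[int, int, int, int]       # (min_row, min_col, max_row, max_col), half-open
    area_um2: float
    perimeter_um: float
    circularity: float
    centroid_px: tuple[float, float]      # (x, y), pixel-centre frame
    boundary_px: np.ndarray               # (N, 2) pixel-corner polygon, image frame, (x, y)
    centroid_stage_um: tuple[float, float] | None = None
    # optional high-content shape descriptors (populated by hca.detect_objects)
    major_axis_um: float | None = None
    minor_axis_um: float | None = None
    solidity: float | None = None


def write_tiff(img: CalibratedImage, path: str | Path, sidecar: bool = True) -> None:
    """Write a TIFF with pixel size in the resolution tags (+ JSON sidecar).

    The resolution tags store pixels-per-micrometre (1 / pixel_size); the
    sidecar carries pixel size and stage origin explicitly.
    """
    path = Path(path)
    res = 1.0 / img.pixel_size_um
    data = img.pixels
    photometric = "rgb" if img.is_rgb else "minisblack"
    tifffile.imwrite(
        path,
        data,
        photometric=photometric,
        resolution=(res, res),
        metadata={"unit": "um", "channel": img.channel},
    )
    if sidecar:
        meta = {
            "pixel_size_um": img.pixel_size_um,
            "channel": img.channel,
            "width_px": int(img.pixels.shape[1]),
            "height_px": int(img.pixels.shape[0]),
        }
        if img.stage_origin_um is not None:
            meta["stage_origin_um"] = list(img.stage_origin_um)
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_tiff(path: str | Path, pixel_size_um: float | None = None) -> CalibratedImage:
    """Read a TIFF; pixel size from the sidecar JSON, TIFF resolution tags, or override.

    An explicit ``pixel_size_um`` argument wins over file metadata.
    """
    path = Path(path)
    channel = "gray"
    stage_origin = None
    sidecar = path.with_suffix(path.suffix + ".json")
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        channel = meta.get("channel", channel)
        if "stage_origin_um" in meta:
            stage_origin = tuple(meta["stage_origin_um"])
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = tf.asarray()
        if pixel_size_um is None:
            pixel_size_um = meta.get("pixel_size_um")
        if pixel_size_um is None:
            tag = page.tags.get("XResolution")
            if tag is not None:
                num, den = tag.value
                if num > 0 and den > 0:
                    pixel_size_um = den / num   # tag stores px per unit length
    if pixel_size_um is None:
        raise ValueError(
            f"{path}: no pixel size in sidecar or TIFF resolution tags; pass pixel_size_um"
        )
    if data.ndim == 3:
        channel = "rgb"
    return CalibratedImage(data, float(pixel_size_um), channel=channel, stage_origin_um=stage_origin)
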