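"""Microdissection planning: stage calibration, field tiling, element export.

A laser microdissector cuts regions specified in *stage* coordinates
(micrometres in the instrument frame), while segmentation delivers regions
in *pixel* coordinates of one acquired field. This module converts between
the two frames, lays out a matrix of adjacent field centres for scanning a
larger area, and serializes the resulting cut list.

Conventions
-----------
Image coordinates are 0-based with a pixel-centre convention: pixel (0, 0)
maps to the field's stage origin. Dissection polygons use pixel-*corner*
vertices (the crack boundary), so a 10×10 px square whose first pixel is
(100, 100) exports corners (100, 100)…(110, 110) µm at 1 µm/px. Stage y may
grow upward on some instruments; set ``y_axis_flip`` to mirror the y axis
about the field.

The true Zeiss "Element file" format is proprietary; the surrogate here is
an open XML schema (one ``<element>`` per region with ``<vertex>`` children,
one ``<point>`` per field centre, coordinates in µm at 0.01 µm precision)
plus flat CSV exports.
"""

from __future__ import annotations

import csv
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .image import Region

__all__ = [
    "CalibratedField",
    "DissectionPlan",
    "extract_calibration",
    "pixel_to_stage",
    "stage_to_pixel",
    "plan_tile_grid",
    "build_plan",
    "export_element_file",
    "parse_element_file",
    "export_plan_csv",
]


@dataclass
class CalibratedField:
    """Stage calibration of one acquired field."""

    stage_origin_um: tuple[float, float]
    pixel_size_um: float
    width_px: int
    height_px: int
    y_axis_flip: bool = False

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("field dimensions must be positive")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def width_um(self) -> float:
        return self.width_px * self.pixel_size_um

    @property
    def height_um(self) -> float:
        return self.height_px * self.pixel_size_um


@dataclass
class DissectionPlan:
    """Ordered field centres plus dissection polygons, all in stage µm."""

    field_centers_um: list[tuple[float, float]] = dc_field(default_factory=list)
    elements: list[tuple[int, np.ndarray]] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.field_centers_um)) != len(self.field_centers_um):
            raise ValueError("field centers must be unique")
        for rid, poly in self.elements:
            if len(poly) < 3:
                raise ValueError(f"element {rid}: polygon needs >= 3 vertices")


def extract_calibration(metadata: dict) -> CalibratedField:
    """Build a :class:`CalibratedField` from sidecar/TIFF metadata.

    Accepts ``pixel_size_um`` directly or a TIFF-style ``x_resolution``
    (pixels per µm), whose reciprocal is the pixel size. All missing or
    implausible fields are reported together.
    """
    problems: list[str] = []
    origin = metadata.get("stage_origin_um")
    if origin is None:
        problems.append("stage_origin_um missing")
    px = metadata.get("pixel_size_um")
    if px is None and "x_resolution" in metadata:
        res = metadata["x_resolution"]
        if res and res > 0:
            px = 1.0 / res
        else:
            problems.append("x_resolution must be > 0")
    if px is None:
        problems.append("pixel_size_um missing")
    elif px <= 0:
        problems.append(f"pixel_size_um must be > 0, got {px}")
    w = metadata.get("width_px")
    h = metadata.get("height_px")
    if not w or w <= 0:
        problems.append("width_px missing or non-positive")
    if not h or h <= 0:
        problems.append("height_px missing or non-positive")
    if problems:
        raise ValueError("invalid calibration metadata: " + "; ".join(problems))
    return CalibratedField(
        stage_origin_um=(float(origin[0]), float(origin[1])),
        pixel_size_um=float(px),
        width_px=int(w),
        height_px=int(h),
        y_axis_flip=bool(metadata.get("y_axis_flip", False)),
    )


def pixel_to_stage(p_px: tuple[float, float], field: CalibratedField) -> tuple[float, float]:
    """Map a pixel-centre coordinate to stage µm; pixel (0, 0) → stage origin."""
    x, y = p_px
    if not (0 <= x <= field.width_px - 1 and 0 <= y <= field.height_px - 1):
        raise ValueError(f"pixel {p_px} outside {field.width_px}x{field.height_px} image")
    ox, oy = field.stage_origin_um
    if field.y_axis_flip:
        y = field.height_px - 1 - y
    return (ox + x * field.pixel_size_um, oy + y * field.pixel_size_um)


def stage_to_pixel(p_um: tuple[float, float], field: CalibratedField) -> tuple[float, float]:
    """Inverse of :func:`pixel_to_stage`."""
    ox, oy = field.stage_origin_um
    x = (p_um[0] - ox) / field.pixel_size_um
    y = (p_um[1] - oy) / field.pixel_size_um
    if field.y_axis_flip:
        y = field.height_px - 1 - y
    if not (0 <= x <= field.width_px - 1 and 0 <= y <= field.height_px - 1):
        raise ValueError(f"stage point {p_um} maps outside the image")
    return (x, y)


def _corners_to_stage(poly_px: np.ndarray, field: CalibratedField) -> np.ndarray:
    """Map pixel-corner polygon vertices (0..W, 0..H) to stage µm."""
    poly = np.asarray(poly_px, dtype=float).copy()
    if field.y_axis_flip:
        poly[:, 1] = field.height_px - poly[:, 1]
    poly *= field.pixel_size_um
    poly[:, 0] += field.stage_origin_um[0]
    poly[:, 1] += field.stage_origin_um[1]
    return poly


def plan_tile_grid(
    start_center_um: tuple[float, float],
    field: CalibratedField,
    n_cols: int,
    n_rows: int,
    serpentine: bool = False,
) -> list[tuple[float, float]]:
    """Matrix of adjacent field centres for scanning a larger area.

    Centres are spaced exactly one field width horizontally and one field
    height vertically, so adjacent fields abut without gap or overlap.
    Row-major order by default; ``serpentine`` reverses every other row to
    mimic stage-efficient scanning.
    """
    if n_cols < 1 or n_rows < 1:
        raise ValueError("n_cols and n_rows must be >= 1")
    sx, sy = start_center_um
    centers = []
    for r in range(n_rows):
        cols = range(n_cols)
        if serpentine and r % 2 == 1:
            cols = reversed(cols)
        for c in cols:
            centers.append((sx + c * field.width_um, sy + r * field.height_um))
    return centers


def build_plan(regions: list[Region], field: CalibratedField) -> DissectionPlan:
    """Transform segmented regions into a stage-frame dissection plan."""
    elements = []
    for r in regions:
        if r.boundary_px is None or len(r.boundary_px) < 3:
            raise ValueError(f"region {r.label} lacks a boundary polygon")
        elements.append((r.label, _corners_to_stage(r.boundary_px, field)))
    ox, oy = field.stage_origin_um
    center = (ox + field.width_um / 2, oy + field.height_um / 2)
    return DissectionPlan(field_centers_um=[center], elements=elements)


def export_element_file(plan: DissectionPlan, path: str | Path) -> None:
    """Write the plan as surrogate element XML (coordinates at 0.01 µm)."""
    root = ET.Element("element_list", version="1.0", units="um")
    pts = ET.SubElement(root, "points")
    for i, (x, y) in enumerate(plan.field_centers_um, start=1):
        ET.SubElement(pts, "point", id=str(i), x=f"{x:.2f}", y=f"{y:.2f}")
    els = ET.SubElement(root, "elements")
    for rid, poly in plan.elements:
        el = ET.SubElement(els, "element", id=str(rid), type="dissection")
        for x, y in poly:
            ET.SubElement(el, "vertex", x=f"{x:.2f}", y=f"{y:.2f}")
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)


def parse_element_file(path: str | Path) -> DissectionPlan:
    """Read a surrogate element XML back into a :class:`DissectionPlan`."""
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:  # includes line/column info
        raise ValueError(f"{path}: malformed XML ({exc})") from exc
    root = tree.getroot()
    centers = []
    for pt in root.iter("point"):
        try:
            centers.append((float(pt.attrib["x"]), float(pt.attrib["y"])))
        except KeyError as exc:
            raise ValueError(f"{path}: <point> missing attribute {exc}") from exc
    elements = []
    for el in root.iter("element"):
        try:
            rid = int(el.attrib["id"])
        except KeyError as exc:
            raise ValueError(f"{path}: <element> missing attribute {exc}") from exc
        verts = []
        for v in el.iter("vertex"):
            try:
                verts.append((float(v.attrib["x"]), float(v.attrib["y"])))
            except KeyError as exc:
                raise ValueError(f"{path}: <vertex> missing attribute {exc}") from exc
        elements.append((rid, np.asarray(verts, dtype=float)))
    return DissectionPlan(field_centers_um=centers, elements=elements)


def export_plan_csv(plan: DissectionPlan, elements_path: str | Path, centers_path: str | Path) -> None:
    """Flat CSV exports: (element_id, vertex_index, x_um, y_um) and field centres."""
    with open(elements_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["element_id", "vertex_index", "x_um", "y_um"])
        for rid, poly in plan.elements:
            for i, (x, y) in enumerate(poly):
                w.writerow([rid, i, f"{x:.2f}", f"{y:.2f}"])
    with open(centers_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["center_index", "x_um", "y_um"])
        for i, (x, y) in enumerate(plan.field_centers_um):
            w.writerow([i, f"{x:.2f}", f"{y:.2f}"])
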