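"""Pipeline configuration: defaults, validation, YAML round-tripping.

Every published parameter keeps its printed value as the default (median
radius 2 px, rolling-ball radius 20 px, minimum area 10 µm², circularity
0.35–1, enrichment ratio ≥ 1.5, at least 2 specific peptides). Unknown keys
are rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .hca import HcaParams
from .segmentation import SegmentationParams
from .silac import LabelingScheme
from .synthetic import ImageSimParams, PeptideSimParams


@dataclass
class PlanningConfig:
    y_axis_flip: bool = False
    serpentine: bool = False
    grid_cols: int = 1
    grid_rows: int = 1


@dataclass
class QuantConfig:
    min_specific: int = 2
    ratio_threshold: float = 1.5
    overlap_mode: str = "overlap_coefficient"

    def __post_init__(self) -> None:
        if self.min_specific < 1:
            raise ValueError("min_specific must be >= 1")
        if self.ratio_threshold <= 0:
            raise ValueError("ratio_threshold must be > 0")


@dataclass
class PipelineConfig:
    """Aggregated configuration for the end-to-end pipeline."""

    seed: int = 0
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    hca: HcaParams = field(default_factory=HcaParams)
    labeling: LabelingScheme = field(default_factory=LabelingScheme)
    planning: PlanningConfig = field(default_factory=PlanningConfig)
    quant: QuantConfig = field(default_factory=QuantConfig)
    simulation_image: ImageSimParams = field(default_factory=ImageSimParams)
    simulation_peptides: PeptideSimParams = field(default_factory=PeptideSimParams)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["labeling"]["labeled_residues"] = sorted(self.labeling.labeled_residues)
        return d


_SECTION_TYPES = {
    "segmentation": SegmentationParams,
    "hca": HcaParams,
    "labeling": LabelingScheme,
    "planning": PlanningConfig,
    "quant": QuantConfig,
    "simulation_image": ImageSimParams,
    "simulation_peptides": PeptideSimParams,
}

# tuple-valued dataclass fields arrive from YAML as lists
_TUPLE_FIELDS = {
    ("segmentation", "circularity_range"),
    ("hca", "area_range_um2"),
    ("hca", "axis_length_range_um"),
    ("simulation_image", "rosette_diameter_range_um"),
    ("simulation_peptides", "peptides_per_protein"),
    ("simulation_peptides", "dilution_points_ng"),
}


def validate_config(raw: dict | None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a parsed document.

    Missing sections/keys take the published defaults; unknown sections or
    keys raise with every offending name listed.
    """
    raw = dict(raw or {})
    errors: list[str] = []
    kwargs: dict = {}
    if "seed" in raw:
        kwargs["seed"] = int(raw.pop("seed"))
    for section, cls in _SECTION_TYPES.items():
        if section not in raw:
            continue
        body = raw.pop(section)
        if body is None:
            continue
        if not isinstance(body, dict):
            errors.append(f"section {section!r} must be a mapping")
            continue
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(body) - valid
        if unknown:
            errors.append(f"unknown key(s) in {section!r}: {sorted(unknown)}")
            continue
        coerced = {}
        for k, v in body.items():
            if (section, k) in _TUPLE_FIELDS and isinstance(v, list):
                v = tuple(v)
            if section == "labeling" and k == "labeled_residues":
                v = frozenset(v)
            coerced[k] = v
        try:
            kwargs[section] = cls(**coerced)
        except (TypeError, ValueError) as exc:
            errors.append(f"invalid {section!r}: {exc}")
    if raw:
        errors.append(f"unknown top-level key(s): {sorted(raw)}")
    if errors:
        raise ValueError("configuration errors: " + "; ".join(errors))
    return PipelineConfig(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML (or JSON) configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
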