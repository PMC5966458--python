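"""End-to-end pipeline driver: simulate → segment → plan → quant.

``run_pipeline`` executes the requested stages on synthetic inputs (or
user-supplied files via the CLI), writes every artifact under one output
directory and records a run manifest (parameter hash, seeds, per-stage
record counts, output paths). Re-running with the same configuration and
seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import silac
from .config import PipelineConfig
from .image import CalibratedImage, write_tiff
from .planning import CalibratedField, build_plan, export_element_file, export_plan_csv, plan_tile_grid
from .segmentation import segment_rosettes
from .synthetic import generate_peptide_table, generate_rosette_field

log = logging.getLogger("invadopipe")

__all__ = ["run_pipeline", "regions_to_frame", "write_overlay_png"]


def regions_to_frame(regions) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                label=r.label,
                area_um2=r.area_um2,
                perimeter_um=r.perimeter_um,
                circularity=r.circularity,
                centroid_x_px=r.centroid_px[0],
                centroid_y_px=r.centroid_px[1],
            )
            for r in regions
        ],
        columns=["label", "area_um2", "perimeter_um", "circularity", "centroid_x_px", "centroid_y_px"],
    )


def write_overlay_png(img: CalibratedImage, regions, path: str | Path) -> None:
    """QC overlay: grayscale field with region boundaries burned in green."""
    import imageio.v3 as iio

    pix = img.pixels.astype(float)
    lo, hi = pix.min(), pix.max()
    norm = np.zeros_like(pix) if hi == lo else (pix - lo) / (hi - lo)
    rgb = np.stack([norm] * 3, axis=-1)
    for r in regions:
        minr, minc, _, _ = r.bbox
        for x, y in r.boundary_px.astype(int):
            yy = min(max(y, 0), pix.shape[0] - 1)
            xx = min(max(x, 0), pix.shape[1] - 1)
            rgb[yy, xx] = (0.0, 1.0, 0.0)
    iio.imwrite(path, (rgb * 255).astype(np.uint8))


def _config_hash(config: PipelineConfig) -> str:
    canon = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    stages: tuple[str, ...] = ("simulate", "segment", "plan", "quant"),
) -> dict:
    """Run the requested stages and return (and write) the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
        "outputs": [],
        "complete": False,
    }
    started = time.time()
    current = "setup"
    try:
        field_img = None
        regions = []
        if "simulate" in stages:
            current = "simulate"
            log.info("simulate: rendering rosette field (seed=%d)", config.seed)
            sim = config.simulation_image
            sim = type(sim)(**{**sim.__dict__, "seed": config.seed})
            field_img, truth = generate_rosette_field(sim)
            write_tiff(field_img, out / "field.tif")
            manifest["stages"]["simulate"] = {"rosettes_true": truth.rosette_count}
            manifest["outputs"].append("field.tif")

        if "segment" in stages:
            current = "segment"
            if field_img is None:
                raise ValueError("segment stage requires a simulated or loaded field image")
            regions = segment_rosettes(field_img, config.segmentation)
            df = regions_to_frame(regions)
            df.to_csv(out / "regions.csv", index=False)
            write_overlay_png(field_img, regions, out / "overlay.png")
            manifest["stages"]["segment"] = {"n_regions": len(regions)}
            manifest["outputs"] += ["regions.csv", "overlay.png"]
            log.info("segment: %d region(s) retained", len(regions))

        if "plan" in stages:
            current = "plan"
            if field_img is None:
                raise ValueError("plan stage requires a field image")
            cal = CalibratedField(
                stage_origin_um=field_img.stage_origin_um or (0.0, 0.0),
                pixel_size_um=field_img.pixel_size_um,
                width_px=field_img.pixels.shape[1],
                height_px=field_img.pixels.shape[0],
                y_axis_flip=config.planning.y_axis_flip,
            )
            plan = build_plan(regions, cal)
            start = plan.field_centers_um[0]
            plan.field_centers_um = plan_tile_grid(
                start, cal, config.planning.grid_cols, config.planning.grid_rows,
                serpentine=config.planning.serpentine,
            )
            export_element_file(plan, out / "plan.xml")
            export_plan_csv(plan, out / "plan_elements.csv", out / "plan_centers.csv")
            manifest["stages"]["plan"] = {
                "n_elements": len(plan.elements),
                "n_field_centers": len(plan.field_centers_um),
            }
            manifest["outputs"] += ["plan.xml", "plan_elements.csv", "plan_centers.csv"]
            log.info("plan: %d element(s), %d field centre(s)",
                     len(plan.elements), len(plan.field_centers_um))

        if "quant" in stages:
            current = "quant"
            sim = config.simulation_peptides
            sim = type(sim)(**{**sim.__dict__, "seed": config.seed})
            peptides, truth = generate_peptide_table(sim)
            classified = silac.classify_table(peptides, config.labeling)
            classified.to_csv(out / "peptides_classified.tsv", sep="\t", index=False)
            frac = silac.contamination_fraction(classified)
            ros = silac.normalize_abundances(
                silac.infer_proteins(classified, config.quant.min_specific, "ms1_area_rosette")
            )
            tot = silac.normalize_abundances(
                silac.infer_proteins(classified, config.quant.min_specific, "ms1_area_total")
            )
            enr = silac.enrichment_table(ros, tot, config.quant.ratio_threshold)
            enr.to_csv(out / "enrichment.csv", index=False)
            manifest["stages"]["quant"] = {
                "n_peptides": len(classified),
                "contamination_fraction": frac,
                "n_proteins": len(enr),
                "n_enriched": int(enr["enriched"].sum()),
            }
            manifest["outputs"] += ["peptides_classified.tsv", "enrichment.csv"]
            log.info("quant: %d peptide(s), %.1f%% contamination, %d/%d protein(s) enriched",
                     len(classified), 100 * frac, int(enr["enriched"].sum()), len(enr))
    except Exception as exc:
        manifest["failed_stage"] = current
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline failed in stage {current!r}: {exc}") from exc

    manifest["complete"] = True
    log.info("pipeline complete in %.1f s", time.time() - started)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
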