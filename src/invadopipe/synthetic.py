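"""Seeded synthetic data: rosette fields, zymography pairs, SILAC peptide tables.

Every generator draws all randomness from a single ``numpy`` Generator seeded
with the params' integer seed, so identical parameters give bit-identical
outputs. Ground truth is returned alongside each dataset so segmentation,
high-content scoring and enrichment calling can be validated by direct
comparison rather than by eye.

What is emulated — and what is not
----------------------------------
Rosette fields mimic fixed Src-transformed fibroblasts imaged in the
F-actin channel: bright annular rosettes 5–7 µm across (an F-actin ring
around a dimmer core) among elongated stress-fiber distractors, under a
multiplicative illumination gradient with additive Gaussian read noise.
No point-spread function, chromatic effects or cell-body context are
simulated; rosettes are placed non-overlapping by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .image import CalibratedImage

AMINO_ACIDS = "ACDEFGHILMNPQSTVWY"  # 18 residues; K/R appended as cleavage sites


@dataclass
class ImageSimParams:
    """Parameters for :func:`generate_rosette_field`.

    Intensities are arbitrary camera units: background level 10, ring
    amplitude 100 (so ``noise_sd=20`` corresponds to a signal-to-noise
    ratio of 5 on the ring).
    """

    field_width_px: int = 384
    field_height_px: int = 384
    pixel_size_um: float = 0.25
    n_rosettes: int = 5
    rosette_diameter_range_um: tuple[float, float] = (5.0, 7.0)
    ring_thickness_um: float = 1.0
    n_fibers: int = 5
    illumination_gradient_amplitude: float = 0.15
    noise_sd: float = 10.0
    seed: int = 0
    background_level: float = 10.0
    ring_amplitude: float = 100.0
    core_level_fraction: float = 0.35   # rosette core intensity / ring amplitude
    fiber_length_um: float = 20.0
    fiber_width_um: float = 1.0
    fiber_amplitude: float = 100.0
    min_separation_um: float = 2.0   # edge clearance beyond one diameter between rosettes
    fiber_clearance_um: float = 3.0  # minimum gap between a fiber and any rosette edge

    def __post_init__(self) -> None:
        lo, hi = self.rosette_diameter_range_um
        if not (0 < lo <= hi):
            raise ValueError(f"diameter range must be positive with lo <= hi, got ({lo}, {hi})")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.n_rosettes < 0 or self.n_fibers < 0:
            raise ValueError("n_rosettes and n_fibers must be >= 0")
        if self.ring_thickness_um <= 0:
            raise ValueError("ring_thickness_um must be > 0")


@dataclass
class ImageGroundTruth:
    """Per-field truth for a generated rosette image."""

    rosette_count: int
    centers_px: list[tuple[float, float]]       # (x, y)
    diameters_um: list[float]
    label_mask: np.ndarray                      # 0 background, 1..rosette_count filled disks

    def __post_init__(self) -> None:
        if self.rosette_count != len(self.centers_px) or self.rosette_count != len(self.diameters_um):
            raise ValueError("rosette_count does not match per-rosette lists")


def generate_rosette_field(params: ImageSimParams) -> tuple[CalibratedImage, ImageGroundTruth]:
    """Render a rosette-bearing field with ground truth.

    Rosettes are annuli (bright ring between r_in and r_out, dimmer core)
    with diameters drawn uniformly from the configured range and centers at
    least one diameter apart and clear of the field border. Fibers are
    rotated bright bars (aspect ratio ≥ 8 with the defaults) placed so they
    do not touch any rosette. A multiplicative linear gradient and additive
    Gaussian noise are applied last.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    H, W = p.field_height_px, p.field_width_px
    s = p.pixel_size_um
    yy, xx = np.mgrid[0:H, 0:W].astype(float)

    lo, hi = p.rosette_diameter_range_um
    margin_px = hi / 2 / s + 4
    if p.n_rosettes > 0 and (W <= 2 * margin_px or H <= 2 * margin_px):
        raise ValueError(
            f"field {W}x{H} px at {s} um/px is too small for rosettes of diameter up to {hi} um"
        )

    img = np.full((H, W), p.background_level, dtype=float)
    label_mask = np.zeros((H, W), dtype=np.int32)
    centers: list[tuple[float, float]] = []
    diameters: list[float] = []

    max_tries = 2000
    for i in range(p.n_rosettes):
        d = rng.uniform(lo, hi)
        for attempt in range(max_tries):
            cx = rng.uniform(margin_px, W - margin_px)
            cy = rng.uniform(margin_px, H - margin_px)
            ok = all(
                np.hypot(cx - ox, cy - oy) * s >= max(d, od) + p.min_separation_um
                for (ox, oy), od in zip(centers, diameters)
            )
            if ok:
                break
        else:
            raise ValueError(
                f"could not place rosette {i + 1}/{p.n_rosettes}: field too crowded"
            )
        r_out = d / 2 / s
        r_in = max(r_out - p.ring_thickness_um / s, 0.0)
        ring_cov, core_cov = _annulus_coverage(H, W, cx, cy, r_in, r_out)
        img += p.ring_amplitude * ring_cov
        img += p.core_level_fraction * p.ring_amplitude * core_cov
        rr = np.hypot(xx - cx, yy - cy)
        label_mask[rr <= r_out] = i + 1
        centers.append((cx, cy))
        diameters.append(float(d))

    # fiber distractors: rotated bars kept clear of every rosette and of each
    # other — crossing fibers would sum to a bright compact junction that no
    # longer fails the circularity filter by construction
    half_len = p.fiber_length_um / 2 / s
    half_wid = p.fiber_width_um / 2 / s
    clearance = p.fiber_clearance_um / s
    placed_fibers: list[tuple[float, float, float]] = []
    for i in range(p.n_fibers):
        for attempt in range(max_tries):
            cx = rng.uniform(half_len, W - half_len)
            cy = rng.uniform(half_len, H - half_len)
            theta = rng.uniform(0, np.pi)
            ok = all(
                _segment_clear(cx, cy, theta, half_len, ox, oy,
                               od / 2 / s + half_wid + clearance)
                for (ox, oy), od in zip(centers, diameters)
            ) and all(
                _segments_distance(cx, cy, theta, half_len, fx, fy, ft, half_len)
                >= 2 * half_wid + clearance
                for fx, fy, ft in placed_fibers
            )
            if ok:
                img += p.fiber_amplitude * _bar_coverage(H, W, cx, cy, theta, half_len, half_wid)
                placed_fibers.append((cx, cy, theta))
                break
        else:
            raise ValueError(f"could not place fiber {i + 1}/{p.n_fibers}: field too crowded")

    if p.illumination_gradient_amplitude:
        ramp = (xx / max(W - 1, 1) + yy / max(H - 1, 1)) / 2.0 - 0.5
        img *= 1.0 + p.illumination_gradient_amplitude * ramp
    if p.noise_sd > 0:
        img += rng.normal(0.0, p.noise_sd, size=img.shape)
    np.clip(img, 0, None, out=img)

    truth = ImageGroundTruth(
        rosette_count=len(centers),
        centers_px=centers,
        diameters_um=diameters,
        label_mask=label_mask,
    )
    return CalibratedImage(img, s, channel="red"), truth


_SUBPIX = 4  # linear supersampling factor for anti-aliased rendering


def _subpixel_offsets() -> np.ndarray:
    """Subpixel sample offsets relative to the pixel centre."""
    return (np.arange(_SUBPIX) + 0.5) / _SUBPIX - 0.5


def _annulus_coverage(
    H: int, W: int, cx: float, cy: float, r_in: float, r_out: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel area coverage of the ring [r_in, r_out] and the core (< r_in).

    Rendering a continuous annulus by subpixel coverage (4x4 samples) gives
    boundary pixels their correct partial intensity; hard thresholding the
    distance map instead would alias the thin ring wall.
    """
    x0 = max(int(np.floor(cx - r_out)) - 1, 0)
    x1 = min(int(np.ceil(cx + r_out)) + 2, W)
    y0 = max(int(np.floor(cy - r_out)) - 1, 0)
    y1 = min(int(np.ceil(cy + r_out)) + 2, H)
    off = _subpixel_offsets()
    ys = (np.arange(y0, y1)[:, None] + off[None, :]).ravel()
    xs = (np.arange(x0, x1)[:, None] + off[None, :]).ravel()
    rr = np.hypot(xs[None, :] - cx, ys[:, None] - cy)
    ring = ((rr <= r_out) & (rr >= r_in)).astype(float)
    core = (rr < r_in).astype(float)
    n = _SUBPIX
    ring_cov = ring.reshape(y1 - y0, n, x1 - x0, n).mean(axis=(1, 3))
    core_cov = core.reshape(y1 - y0, n, x1 - x0, n).mean(axis=(1, 3))
    full_ring = np.zeros((H, W))
    full_core = np.zeros((H, W))
    full_ring[y0:y1, x0:x1] = ring_cov
    full_core[y0:y1, x0:x1] = core_cov
    return full_ring, full_core


def _bar_coverage(
    H: int, W: int, cx: float, cy: float, theta: float, half_len: float, half_wid: float
) -> np.ndarray:
    """Per-pixel coverage of a rotated bar, anti-aliased like the annuli."""
    ext = half_len + 2
    x0 = max(int(np.floor(cx - ext)), 0)
    x1 = min(int(np.ceil(cx + ext)) + 1, W)
    y0 = max(int(np.floor(cy - ext)), 0)
    y1 = min(int(np.ceil(cy + ext)) + 1, H)
    off = _subpixel_offsets()
    ys = (np.arange(y0, y1)[:, None] + off[None, :]).ravel()
    xs = (np.arange(x0, x1)[:, None] + off[None, :]).ravel()
    dx = xs[None, :] - cx
    dy = ys[:, None] - cy
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    bar = ((np.abs(u) <= half_len) & (np.abs(v) <= half_wid)).astype(float)
    n = _SUBPIX
    cov = bar.reshape(y1 - y0, n, x1 - x0, n).mean(axis=(1, 3))
    full = np.zeros((H, W))
    full[y0:y1, x0:x1] = cov
    return full


def _segment_clear(cx: float, cy: float, theta: float, half_len: float,
                   px: float, py: float, min_dist: float) -> bool:
    """Distance from point (px, py) to the bar's axis segment >= min_dist."""
    ux, uy = np.cos(theta), np.sin(theta)
    t = np.clip((px - cx) * ux + (py - cy) * uy, -half_len, half_len)
    qx, qy = cx + t * ux, cy + t * uy
    return bool(np.hypot(px - qx, py - qy) >= min_dist)


def _segments_distance(ax: float, ay: float, atheta: float, ahalf: float,
                       bx: float, by: float, btheta: float, bhalf: float) -> float:
    """Minimum distance between two axis segments (sampled endpoints/points)."""
    ts = np.linspace(-1.0, 1.0, 17)
    aux, auy = np.cos(atheta), np.sin(atheta)
    bux, buy = np.cos(btheta), np.sin(btheta)
    pa = np.stack([ax + ts * ahalf * aux, ay + ts * ahalf * auy], axis=1)
    pb = np.stack([bx + ts * bhalf * bux, by + ts * bhalf * buy], axis=1)
    diff = pa[:, None, :] - pb[None, :, :]
    return float(np.hypot(diff[..., 0], diff[..., 1]).min())


@dataclass
class ZymographyTruth:
    degraded_area_um2: float
    nuclei_count: int
    hole_centers_px: list[tuple[int, int]]


def generate_zymography_pair(
    n_holes: int,
    hole_area_um2: float,
    n_nuclei: int,
    seed: int,
    field_px: int = 512,
    pixel_size_um: float = 1.0,
    noise_sd: float = 3.0,
) -> tuple[CalibratedImage, CalibratedImage, ZymographyTruth]:
    """Fluorescent-gelatin / nuclei image pair with exact degraded-area truth.

    Each hole is rendered as the ``round(hole_area_um2 / pixel_size²)``
    pixels closest to its centre (a digitized disk trimmed to exact count),
    so the recorded degraded area is exact by construction.
    """
    if n_holes < 0 or n_nuclei < 0:
        raise ValueError("n_holes and n_nuclei must be >= 0")
    if n_holes > 0 and hole_area_um2 <= 0:
        raise ValueError("hole_area_um2 must be > 0")
    rng = np.random.default_rng(seed)
    H = W = field_px
    s = pixel_size_um
    gelatin = np.full((H, W), 200.0)
    nuclei = np.full((H, W), 5.0)

    n_px = int(round(hole_area_um2 / s**2)) if n_holes else 0
    hole_r = int(np.ceil(np.sqrt(n_px / np.pi))) + 2
    margin = hole_r + 2
    if n_holes and 2 * margin >= min(H, W):
        raise ValueError("holes too large for the field")
    centers: list[tuple[int, int]] = []
    for i in range(n_holes):
        for attempt in range(2000):
            cx = int(rng.integers(margin, W - margin))
            cy = int(rng.integers(margin, H - margin))
            if all(np.hypot(cx - ox, cy - oy) >= 2 * hole_r + 2 for ox, oy in centers):
                break
        else:
            raise ValueError(f"could not place hole {i + 1}/{n_holes} without overlap")
        centers.append((cx, cy))
        yy, xx = np.mgrid[cy - hole_r:cy + hole_r + 1, cx - hole_r:cx + hole_r + 1]
        rr = np.hypot(xx - cx, yy - cy).ravel()
        order = np.argsort(rr, kind="stable")[:n_px]
        gelatin[yy.ravel()[order], xx.ravel()[order]] = 20.0

    nuc_r = 4.0 / s  # ~8 um nuclei
    nuc_margin = int(nuc_r) + 2
    nuc_centers: list[tuple[int, int]] = []
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    for i in range(n_nuclei):
        for attempt in range(2000):
            cx = int(rng.integers(nuc_margin, W - nuc_margin))
            cy = int(rng.integers(nuc_margin, H - nuc_margin))
            if all(np.hypot(cx - ox, cy - oy) >= 3 * nuc_r for ox, oy in nuc_centers):
                break
        else:
            raise ValueError(f"could not place nucleus {i + 1}/{n_nuclei}")
        nuc_centers.append((cx, cy))
        nuclei[np.hypot(xx - cx, yy - cy) <= nuc_r] = 150.0

    if noise_sd > 0:
        gelatin += rng.normal(0, noise_sd, gelatin.shape)
        nuclei += rng.normal(0, noise_sd, nuclei.shape)
        np.clip(gelatin, 0, None, out=gelatin)
        np.clip(nuclei, 0, None, out=nuclei)

    truth = ZymographyTruth(
        degraded_area_um2=n_holes * n_px * s**2,
        nuclei_count=n_nuclei,
        hole_centers_px=centers,
    )
    return (
        CalibratedImage(gelatin, s, channel="green"),
        CalibratedImage(nuclei, s, channel="blue"),
        truth,
    )


@dataclass
class PeptideSimParams:
    """Parameters for :func:`generate_peptide_table`.

    The enriched subset is spiked by ``enrichment_factor`` in the rosette
    channel; the remaining proteins are proportionally depleted so that both
    channels have equal total intensity. Under total-intensity normalization
    this makes the spiked proteins' normalized rosette/total ratio equal the
    enrichment factor exactly at zero noise (relative enrichment in a
    compartment necessarily comes at the expense of the other proteins'
    share, so the construction is also the physically consistent one).
    """

    n_proteins: int = 50
    peptides_per_protein: tuple[float, float] = (5.0, 2.0)   # (mean, dispersion sd)
    contaminant_fraction: float = 0.05
    enriched_subset_fraction: float = 0.25
    enrichment_factor: float = 3.0
    abundance_noise_cv: float = 0.0
    dilution_points_ng: tuple[float, ...] = (1.0, 5.0, 10.0, 25.0, 50.0, 100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("contaminant_fraction", "enriched_subset_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.enrichment_factor <= 0:
            raise ValueError("enrichment_factor must be > 0")
        pts = self.dilution_points_ng
        if any(b <= a for a, b in zip(pts, pts[1:])) or any(q <= 0 for q in pts):
            raise ValueError("dilution points must be strictly increasing and positive")
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be >= 0")


def _random_tryptic_sequence(rng: np.random.Generator, min_len: int = 7, max_len: int = 20) -> str:
    """Random tryptic peptide: interior non-K/R residues, C-terminal K or R."""
    n = int(rng.integers(min_len, max_len + 1))
    body = "".join(rng.choice(list(AMINO_ACIDS), size=n - 1))
    return body + rng.choice(["K", "R"])


def generate_peptide_table(params: PeptideSimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a peptide identification table plus per-protein ground truth.

    Returns
    -------
    peptides : DataFrame
        Columns ``peptide_id, sequence, protein_acc, is_specific,
        modifications, ms1_area_rosette, ms1_area_total, true_label_status``.
        Labeled rows carry a ¹³C6 modification on every K/R; contaminant rows
        carry none.
    proteins : DataFrame
        Columns ``protein_acc, n_peptides, true_ratio, enriched_truth``.
    """
    p = params
    rng = np.random.default_rng(p.seed)

    base = rng.lognormal(mean=10.0, sigma=1.0, size=p.n_proteins)
    n_enriched = int(round(p.enriched_subset_fraction * p.n_proteins))
    factors = np.ones(p.n_proteins)
    if n_enriched and n_enriched < p.n_proteins:
        # choose an enriched subset whose spike the remaining proteins can
        # absorb (depletion factor must stay positive); abundances are
        # heavy-tailed, so resample the subset if one giant protein lands in it
        for _ in range(200):
            enriched_idx = rng.choice(p.n_proteins, size=n_enriched, replace=False)
            sum_enriched = base[enriched_idx].sum()
            sum_rest = base.sum() - sum_enriched
            depletion = 1.0 - (p.enrichment_factor - 1.0) * sum_enriched / sum_rest
            if depletion > 0.01:
                break
        else:
            raise ValueError(
                "enrichment spike too large to balance channel totals; "
                "reduce enrichment_factor or enriched_subset_fraction"
            )
        factors[enriched_idx] = p.enrichment_factor
        rest = np.setdiff1d(np.arange(p.n_proteins), enriched_idx)
        factors[rest] = depletion
    elif n_enriched:
        factors[:] = p.enrichment_factor

    mean_k, sd_k = p.peptides_per_protein
    rows = []
    pid = 0
    for j in range(p.n_proteins):
        acc = f"PROT{j:04d}"
        k = max(1, int(round(rng.normal(mean_k, sd_k))))
        weights = rng.lognormal(0.0, 0.3, size=k)
        weights /= weights.sum()
        for w in weights:
            seq = _random_tryptic_sequence(rng)
            mods = ";".join(
                f"13C6@{res}{i + 1}" for i, res in enumerate(seq) if res in "KR"
            )
            a_ros = base[j] * factors[j] * w
            a_tot = base[j] * w
            if p.abundance_noise_cv > 0:
                sigma = np.sqrt(np.log(1 + p.abundance_noise_cv**2))
                a_ros *= rng.lognormal(-sigma**2 / 2, sigma)
                a_tot *= rng.lognormal(-sigma**2 / 2, sigma)
            rows.append((f"pep{pid:05d}", seq, acc, True, mods, a_ros, a_tot, "labeled"))
            pid += 1

    n_labeled = len(rows)
    f = p.contaminant_fraction
    n_cont = int(round(f / (1 - f) * n_labeled)) if f < 1 else 0
    if f == 1.0:
        n_cont, rows = n_labeled if n_labeled else 1, []
    for c in range(n_cont):
        seq = _random_tryptic_sequence(rng)
        area = rng.lognormal(8.0, 1.0)
        rows.append((f"cont{c:04d}", seq, f"CONT{c:03d}", True, "", area, area, "contaminant"))
        pid += 1

    peptides = pd.DataFrame(
        rows,
        columns=[
            "peptide_id", "sequence", "protein_acc", "is_specific", "modifications",
            "ms1_area_rosette", "ms1_area_total", "true_label_status",
        ],
    )
    proteins = pd.DataFrame(
        {
            "protein_acc": [f"PROT{j:04d}" for j in range(p.n_proteins)],
            "n_peptides": peptides[peptides.true_label_status == "labeled"]
            .groupby("protein_acc").size()
            .reindex([f"PROT{j:04d}" for j in range(p.n_proteins)], fill_value=0)
            .to_numpy() if len(peptides) else np.zeros(p.n_proteins, int),
            "true_ratio": factors,
            "enriched_truth": factors >= 1.5,
        }
    )
    return peptides, proteins


def generate_dilution_series(
    points_ng: Sequence[float],
    area_per_ng: float = 1.0e6,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Summed ¹³C-peptide MS1 area versus injected peptide quantity.

    Emulates the standard-curve series used to estimate how much peptide a
    dissected sample contains: area grows linearly with quantity at
    ``area_per_ng`` counts/ng, with optional multiplicative noise.
    """
    pts = list(points_ng)
    if any(b <= a for a, b in zip(pts, pts[1:])) or any(q <= 0 for q in pts):
        raise ValueError("dilution points must be strictly increasing and positive")
    rng = np.random.default_rng(seed)
    areas = np.asarray(pts, float) * area_per_ng
    if noise_cv > 0:
        sigma = np.sqrt(np.log(1 + noise_cv**2))
        areas = areas * rng.lognormal(-sigma**2 / 2, sigma, size=len(pts))
    return pd.DataFrame({"quantity_ng": pts, "summed_13c_area": areas})
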