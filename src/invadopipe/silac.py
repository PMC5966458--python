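"""SILAC specificity filtering and label-free enrichment quantification.

Cells are metabolically labeled with ¹³C6-lysine and ¹³C6-arginine
(+6.02013 Da per labeled residue), so every tryptic peptide that truly
originates from the labeled cells carries the heavy modification on all of
its K/R residues. Peptides identified without the label must come from
outside the sample (handling contamination) and are discarded before
quantification. Downstream, proteins are inferred from labeled specific
peptides, abundances are normalized by each sample's total intensity, and a
protein is called enriched in the dissected (rosette) sample when its
normalized rosette/total ratio is at least 1.5 (log2 ≈ 0.585, printed as
0.6 on log-scale plots).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LabelingScheme",
    "DilutionCurve",
    "QuantityEstimate",
    "classify_peptide_label",
    "classify_table",
    "contamination_fraction",
    "infer_proteins",
    "fit_dilution_curve",
    "estimate_quantity",
    "normalize_abundances",
    "enrichment_table",
    "replicate_overlap",
    "tabulate_annotations",
]

_MOD_RE = re.compile(r"^(?P<name>[\w+\-]+)@(?P<res>[A-Z])(?P<pos>\d+)$")

#: mass difference between six 13C and six 12C atoms, Da
C13_6_MASS_SHIFT_DA = 6 * (13.003355 - 12.000000)


@dataclass(frozen=True)
class LabelingScheme:
    """Which residues carry the heavy label and the mass shift per residue."""

    labeled_residues: frozenset = frozenset({"K", "R"})
    mass_shift_da: float = 6.02013
    label_name: str = "13C6"

    def __post_init__(self) -> None:
        if not self.mass_shift_da > 0:
            raise ValueError("mass_shift_da must be > 0")
        valid = set("ACDEFGHIKLMNPQRSTVWY")
        bad = set(self.labeled_residues) - valid
        if bad:
            raise ValueError(f"invalid residue letters: {sorted(bad)}")

    def expected_mass_shift(self, sequence: str) -> float:
        """Total mass shift if the peptide were fully labeled, in Da."""
        return self.mass_shift_da * sum(sequence.count(r) for r in self.labeled_residues)


def _parse_mods(modifications: str | None) -> list[tuple[str, str, int]]:
    """Parse 'name@X<pos>;...' into (name, residue, 1-based position) tuples."""
    if modifications is None or (isinstance(modifications, float) and math.isnan(modifications)):
        return []
    text = str(modifications).strip()
    if not text:
        return []
    out = []
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        m = _MOD_RE.match(token)
        if m is None:
            raise ValueError(f"unparseable modification token {token!r}")
        out.append((m["name"], m["res"], int(m["pos"])))
    return out


def classify_peptide_label(
    sequence: str, modifications: str | None, scheme: LabelingScheme | None = None
) -> str:
    """Classify one peptide as ``labeled``, ``contaminant`` or ``indeterminate``.

    Labeled: every labelable residue (K/R by default) carries the heavy
    modification. Contaminant: at least one labelable residue is unmodified
    (partial labels count as contaminant — metabolic incorporation is
    complete, so a half-labeled identification is an artifact). Indeterminate:
    the sequence contains no labelable residue, so the label carries no
    information.
    """
    if scheme is None:
        scheme = LabelingScheme()
    seq = str(sequence)
    mods = _parse_mods(modifications)
    label_positions = set()
    for name, res, pos in mods:
        if pos < 1 or pos > len(seq):
            raise ValueError(f"modification position {pos} outside sequence {seq!r}")
        if seq[pos - 1] != res:
            raise ValueError(
                f"modification {name}@{res}{pos} disagrees with residue {seq[pos - 1]!r}"
            )
        if name == scheme.label_name:
            if res not in scheme.labeled_residues:
                raise ValueError(
                    f"heavy label on residue {res!r} which is not in the labeling scheme"
                )
            label_positions.add(pos)
    sites = {i + 1 for i, r in enumerate(seq) if r in scheme.labeled_residues}
    if not sites:
        return "indeterminate"
    return "labeled" if sites <= label_positions else "contaminant"


def classify_table(table: pd.DataFrame, scheme: LabelingScheme | None = None) -> pd.DataFrame:
    """Return a copy of the peptide table with a ``label_status`` column."""
    out = table.copy()
    out["label_status"] = [
        classify_peptide_label(seq, mods, scheme)
        for seq, mods in zip(out["sequence"], out["modifications"])
    ]
    return out


def contamination_fraction(table: pd.DataFrame) -> float:
    """Fraction of classifiable peptides that are contaminants.

    Indeterminate peptides are excluded from numerator and denominator.
    """
    if "label_status" not in table.columns:
        raise ValueError("table is not classified; run classify_table first")
    n_lab = int((table["label_status"] == "labeled").sum())
    n_con = int((table["label_status"] == "contaminant").sum())
    if n_lab + n_con == 0:
        raise ValueError("no classifiable (labeled or contaminant) peptides in table")
    return n_con / (n_lab + n_con)


def infer_proteins(
    table: pd.DataFrame,
    min_specific: int = 2,
    area_column: str = "ms1_area_rosette",
) -> pd.DataFrame:
    """Group labeled peptides into proteins and apply the specific-peptide rule.

    Only labeled peptides contribute. A protein is retained when it has at
    least ``min_specific`` specific peptides (peptides assigned uniquely to
    it, per the table's ``is_specific`` flag); its abundance is the sum of
    its specific peptides' MS1 areas in ``area_column``.
    """
    if "label_status" not in table.columns:
        raise ValueError("table is not classified; run classify_table first")
    labeled = table[table["label_status"] == "labeled"]
    if labeled.empty:
        return pd.DataFrame(
            columns=["protein_acc", "n_specific_peptides", "abundance"]
        ).astype({"n_specific_peptides": int, "abundance": float})
    specific = labeled[labeled["is_specific"].astype(bool)]
    grouped = specific.groupby("protein_acc", sort=True).agg(
        n_specific_peptides=("peptide_id", "size"),
        abundance=(area_column, "sum"),
    )
    grouped = grouped[grouped["n_specific_peptides"] >= min_specific]
    return grouped.reset_index()


@dataclass
class DilutionCurve:
    """Least-squares line through (quantity, summed ¹³C area) points."""

    points: pd.DataFrame
    slope: float
    intercept: float
    r_squared: float


@dataclass
class QuantityEstimate:
    quantity_ng: float
    nearest_point_ng: float | None
    extrapolated: bool


def fit_dilution_curve(points: pd.DataFrame | list[tuple[float, float]]) -> DilutionCurve:
    """Fit the standard curve of summed ¹³C area vs injected quantity (ng)."""
    if not isinstance(points, pd.DataFrame):
        points = pd.DataFrame(points, columns=["quantity_ng", "summed_13c_area"])
    if len(points) < 2:
        raise ValueError("dilution curve needs at least 2 points")
    q = points["quantity_ng"].to_numpy(float)
    if np.any(np.diff(q) <= 0):
        raise ValueError("dilution quantities must be strictly increasing")
    a = points["summed_13c_area"].to_numpy(float)
    res = stats.linregress(q, a)
    if res.slope <= 0:
        raise ValueError("non-informative dilution curve: slope must be positive")
    return DilutionCurve(
        points=points.reset_index(drop=True),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def estimate_quantity(
    curve: DilutionCurve,
    summed_area: float,
    range_points_ng: "list[float] | None" = None,
) -> QuantityEstimate:
    """Invert the standard curve and pick the nearest reference point.

    The estimate is (area − intercept) / slope. When the estimate exceeds
    twice the largest fitted quantity a warning flags the extrapolation.
    ``range_points_ng`` is the menu of reference injections to choose from;
    it defaults to the fitted points themselves. Dilution series are
    logarithmic, so "closest" is measured on the log scale (72 ng is closer
    to 100 ng than to 50 ng), with ties resolved to the larger point.
    """
    est = (summed_area - curve.intercept) / curve.slope
    q_max = float(curve.points["quantity_ng"].max())
    extrapolated = est > 2 * q_max
    if extrapolated:
        warnings.warn(
            f"estimate {est:.1f} ng extrapolates beyond 2x the largest dilution point ({q_max} ng)"
        )
    menu = list(range_points_ng) if range_points_ng is not None else list(curve.points["quantity_ng"])
    nearest = None
    if menu:
        if est > 0:
            dist = lambda v: abs(math.log(v) - math.log(est))
        else:
            dist = lambda v: abs(v - est)
        nearest = max(menu, key=lambda v: (-dist(v), v))  # min distance, ties to larger
    return QuantityEstimate(quantity_ng=float(est), nearest_point_ng=nearest, extrapolated=extrapolated)


def normalize_abundances(proteins: pd.DataFrame, column: str = "abundance") -> pd.DataFrame:
    """Add ``normalized_abundance`` = abundance / sample total (sums to 1)."""
    total = proteins[column].sum()
    if not total > 0:
        raise ValueError("cannot normalize: total abundance is zero")
    out = proteins.copy()
    out["normalized_abundance"] = out[column] / total
    return out


def enrichment_table(
    rosette_proteins: pd.DataFrame,
    total_proteins: pd.DataFrame,
    ratio_threshold: float = 1.5,
) -> pd.DataFrame:
    """Per-protein enrichment calls from normalized rosette vs total abundances.

    Proteins detected in both samples get ratio = normalized_rosette /
    normalized_total and are enriched when ratio ≥ threshold (inclusive).
    Proteins seen in only one sample are reported with status
    ``rosette_only`` / ``total_only``, an undefined ratio, and are never
    flagged enriched.
    """
    for name, df in (("rosette", rosette_proteins), ("total", total_proteins)):
        if "normalized_abundance" not in df.columns:
            raise ValueError(f"{name} table lacks normalized_abundance; run normalize_abundances")
    ros = rosette_proteins.set_index("protein_acc")
    tot = total_proteins.set_index("protein_acc")
    accs = sorted(set(ros.index) | set(tot.index))
    rows = []
    for acc in accs:
        in_r, in_t = acc in ros.index, acc in tot.index
        if in_r and in_t:
            ratio = ros.at[acc, "normalized_abundance"] / tot.at[acc, "normalized_abundance"]
            rows.append(
                dict(
                    protein_acc=acc,
                    n_specific_rosette=int(ros.at[acc, "n_specific_peptides"]),
                    norm_rosette=ros.at[acc, "normalized_abundance"],
                    norm_total=tot.at[acc, "normalized_abundance"],
                    ratio=float(ratio),
                    log2_ratio=float(np.log2(ratio)),
                    enriched=bool(ratio >= ratio_threshold),
                    status="both_detected",
                )
            )
        else:
            rows.append(
                dict(
                    protein_acc=acc,
                    n_specific_rosette=int(ros.at[acc, "n_specific_peptides"]) if in_r else 0,
                    norm_rosette=ros.at[acc, "normalized_abundance"] if in_r else np.nan,
                    norm_total=tot.at[acc, "normalized_abundance"] if in_t else np.nan,
                    ratio=np.nan,
                    log2_ratio=np.nan,
                    enriched=False,
                    status="rosette_only" if in_r else "total_only",
                )
            )
    return pd.DataFrame(rows)


def replicate_overlap(set_a, set_b, mode: str = "overlap_coefficient") -> float:
    """Protein-list similarity between replicates, as a percentage.

    ``overlap_coefficient``: |A∩B| / min(|A|, |B|) × 100 (default);
    ``jaccard``: |A∩B| / |A∪B| × 100.
    """
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("replicate_overlap requires two non-empty sets")
    inter = len(a & b)
    if mode == "overlap_coefficient":
        return 100.0 * inter / min(len(a), len(b))
    if mode == "jaccard":
        return 100.0 * inter / len(a | b)
    raise ValueError(f"unknown overlap mode {mode!r}")


def tabulate_annotations(
    proteins, annotation_map: "dict[str, str] | pd.DataFrame"
) -> pd.DataFrame:
    """Per-class counts and percentages from a user-supplied protein→class map.

    Percentages are relative to the full protein list; proteins absent from
    the map are reported under the class ``unannotated``.
    """
    accs = list(proteins)
    if isinstance(annotation_map, pd.DataFrame):
        annotation_map = dict(
            zip(annotation_map["protein_acc"], annotation_map["annotation_class"])
        )
    classes: dict[str, int] = {}
    for acc in accs:
        cls = annotation_map.get(acc, "unannotated")
        classes[cls] = classes.get(cls, 0) + 1
    n = len(accs)
    rows = [
        dict(annotation_class=cls, count=cnt, percent=(100.0 * cnt / n) if n else 0.0)
        for cls, cnt in sorted(classes.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["annotation_class", "count", "percent"])
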