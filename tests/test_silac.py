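"""SILAC label classification, protein inference, enrichment and overlap."""

import numpy as np
import pandas as pd
import pytest

from invadopipe.silac import (
    C13_6_MASS_SHIFT_DA,
    LabelingScheme,
    classify_peptide_label,
    classify_table,
    contamination_fraction,
    enrichment_table,
    estimate_quantity,
    fit_dilution_curve,
    infer_proteins,
    normalize_abundances,
    replicate_overlap,
    tabulate_annotations,
)
from invadopipe.synthetic import PeptideSimParams, generate_peptide_table


class TestClassification:
    @pytest.mark.parametrize(
        "sequence, mods, expected",
        [
            ("ACDK", "13C6@K4", "labeled"),
            ("ACDK", "", "contaminant"),
            ("ACDEF", "", "indeterminate"),
            ("ACDKGR", "13C6@K4", "contaminant"),  # partially labeled -> artifact
            ("ACDKGR", "13C6@K4;13C6@R6", "labeled"),
        ],
    )
    def test_label_status(self, sequence, mods, expected):
        assert classify_peptide_label(sequence, mods) == expected

    def test_full_label_mass_shift_for_two_sites(self):
        scheme = LabelingScheme()
        assert scheme.expected_mass_shift("ACDKGR") == pytest.approx(2 * 6.02013)
        assert scheme.mass_shift_da == pytest.approx(C13_6_MASS_SHIFT_DA, abs=5e-5)

    def test_modification_on_wrong_residue_is_integrity_error(self):
        with pytest.raises(ValueError):
            classify_peptide_label("ACDK", "13C6@A1")  # heavy label on Ala

    def test_modification_position_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classify_peptide_label("ACDK", "13C6@K2")  # position 2 is C, not K

    def test_classification_exact_on_synthetic_table(self, noisefree_peptides):
        peptides, _ = noisefree_peptides
        classified = classify_table(peptides)
        assert (classified.label_status == classified.true_label_status).all()


class TestContaminationFraction:
    def test_all_labeled_is_zero(self):
        df = pd.DataFrame({"label_status": ["labeled"] * 10})
        assert contamination_fraction(df) == 0.0

    def test_ninety_five_five(self):
        df = pd.DataFrame({"label_status": ["labeled"] * 95 + ["contaminant"] * 5})
        assert contamination_fraction(df) == pytest.approx(0.05)

    def test_indeterminate_excluded_from_both_sides(self):
        df = pd.DataFrame(
            {"label_status": ["labeled"] * 10 + ["contaminant"] * 10 + ["indeterminate"] * 7}
        )
        assert contamination_fraction(df) == 0.5

    def test_no_classifiable_rows_rejected(self):
        with pytest.raises(ValueError):
            contamination_fraction(pd.DataFrame({"label_status": ["indeterminate"] * 3}))


class TestProteinInference:
    def _toy(self):
        return pd.DataFrame(
            {
                "peptide_id": ["p1", "p2", "p3"],
                "sequence": ["AAAK", "CCCK", "DDDK"],
                "protein_acc": ["P1", "P1", "P2"],
                "is_specific": [True, False, True],
                "ms1_area_rosette": [10.0, 5.0, 7.0],
                "label_status": ["labeled", "labeled", "labeled"],
            }
        )

    def test_empty_table(self):
        empty = pd.DataFrame(
            columns=["peptide_id", "protein_acc", "is_specific", "ms1_area_rosette", "label_status"]
        )
        assert infer_proteins(empty, 1).empty

    def test_min_specific_rule_and_shared_peptides_excluded(self):
        table = self._toy()
        two = infer_proteins(table, min_specific=2)
        assert "P1" not in set(two.protein_acc)
        one = infer_proteins(table, min_specific=1).set_index("protein_acc")
        assert one.at["P1", "abundance"] == 10.0  # shared peptide does not contribute
        assert one.at["P1", "n_specific_peptides"] == 1

    def test_contaminant_only_protein_never_reported(self):
        table = self._toy()
        table.loc[2, "label_status"] = "contaminant"
        assert "P2" not in set(infer_proteins(table, 1).protein_acc)


class TestDilutionCurve:
    def test_exact_line_inverts_exactly(self):
        curve = fit_dilution_curve([(0, 0.0), (50, 100.0), (100, 200.0)])
        est = estimate_quantity(curve, 144.0, range_points_ng=[25, 50, 100])
        assert est.quantity_ng == pytest.approx(72.0, abs=1e-9)
        assert est.nearest_point_ng == 100  # log-scale nearest on a dilution range

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            fit_dilution_curve([(50, 100.0)])

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError):
            fit_dilution_curve([(1, 100.0), (10, 50.0), (100, 10.0)])

    def test_noisy_slope_recovered_within_five_percent(self):
        rng = np.random.default_rng(11)
        q = np.array([1.0, 5.0, 10.0, 25.0, 50.0, 100.0])
        a = 2.0 * q * rng.lognormal(0, 0.01, size=q.size)
        curve = fit_dilution_curve(list(zip(q, a)))
        assert curve.slope == pytest.approx(2.0, rel=0.05)
        assert curve.r_squared > 0.99

    def test_extrapolation_warns(self):
        curve = fit_dilution_curve([(1, 10.0), (10, 100.0)])
        with pytest.warns(UserWarning, match="extrapolates"):
            est = estimate_quantity(curve, 500.0)
        assert est.extrapolated


class TestNormalizationAndEnrichment:
    def _quant(self, mapping):
        return pd.DataFrame(
            {
                "protein_acc": list(mapping),
                "n_specific_peptides": [2] * len(mapping),
                "abundance": list(mapping.values()),
            }
        )

    def test_normalization_fractions(self):
        out = normalize_abundances(self._quant({"A": 10.0, "B": 30.0}))
        assert list(out.normalized_abundance) == [0.25, 0.75]
        assert out.normalized_abundance.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_abundances(self._quant({"A": 0.0}))

    def test_scale_invariance(self):
        a = normalize_abundances(self._quant({"A": 10.0, "B": 30.0}))
        b = normalize_abundances(self._quant({"A": 1000.0, "B": 3000.0}))
        assert np.allclose(a.normalized_abundance, b.normalized_abundance)

    def test_worked_example(self):
        ros = normalize_abundances(self._quant({"A": 10.0, "B": 30.0}))
        tot = normalize_abundances(self._quant({"A": 5.0, "B": 35.0}))
        enr = enrichment_table(ros, tot).set_index("protein_acc")
        assert enr.at["A", "ratio"] == pytest.approx(2.0)
        assert bool(enr.at["A", "enriched"]) is True
        assert enr.at["B", "ratio"] == pytest.approx(0.857, abs=1e-3)
        assert bool(enr.at["B", "enriched"]) is False

    def test_identical_samples_none_enriched(self):
        ros = normalize_abundances(self._quant({"A": 10.0, "B": 30.0}))
        enr = enrichment_table(ros, ros)
        assert np.allclose(enr.ratio, 1.0) and not enr.enriched.any()

    def test_threshold_inclusive_at_exactly_1_5(self):
        ros = normalize_abundances(self._quant({"A": 3.0, "B": 1.0}))
        tot = normalize_abundances(self._quant({"A": 2.0, "B": 2.0}))
        enr = enrichment_table(ros, tot).set_index("protein_acc")
        assert enr.at["A", "ratio"] == pytest.approx(1.5, abs=1e-12)
        assert bool(enr.at["A", "enriched"]) is True

    def test_log2_threshold_rounds_to_published_value(self):
        assert np.log2(1.5) == pytest.approx(0.585, abs=1e-3)
        assert round(np.log2(1.5), 1) == 0.6

    def test_single_sample_proteins_reported_never_enriched(self):
        ros = normalize_abundances(self._quant({"A": 10.0, "B": 30.0}))
        tot = normalize_abundances(self._quant({"B": 5.0, "C": 5.0}))
        enr = enrichment_table(ros, tot).set_index("protein_acc")
        assert enr.at["A", "status"] == "rosette_only" and not bool(enr.at["A", "enriched"])
        assert enr.at["C", "status"] == "total_only" and not bool(enr.at["C", "enriched"])

    def test_enriched_set_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        ros = normalize_abundances(self._quant({f"P{i}": rng.uniform(1, 100) for i in range(30)}))
        tot = normalize_abundances(self._quant({f"P{i}": rng.uniform(1, 100) for i in range(30)}))
        sizes = [
            enrichment_table(ros, tot, ratio_threshold=t).enriched.sum()
            for t in (1.0, 1.5, 2.0, 3.0)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestParameterRecovery:
    def test_noise_free_spiked_ratios_recovered_exactly(self, noisefree_peptides):
        peptides, truth = noisefree_peptides
        classified = classify_table(peptides)
        ros = normalize_abundances(infer_proteins(classified, 1, "ms1_area_rosette"))
        tot = normalize_abundances(infer_proteins(classified, 1, "ms1_area_total"))
        enr = enrichment_table(ros, tot).merge(truth, on="protein_acc")
        spiked = enr[enr.true_ratio == 3.0]
        assert len(spiked) == 5
        assert np.allclose(spiked.ratio, 3.0, atol=1e-9)
        assert (enr.enriched == enr.enriched_truth).all()

    def test_median_ratio_error_under_ten_percent_at_ten_percent_cv(self):
        errors = []
        for seed in range(50):
            p = PeptideSimParams(
                n_proteins=30, peptides_per_protein=(5.0, 0.0), contaminant_fraction=0.0,
                abundance_noise_cv=0.10, enrichment_factor=3.0, seed=seed,
            )
            peptides, truth = generate_peptide_table(p)
            classified = classify_table(peptides)
            ros = normalize_abundances(infer_proteins(classified, 1, "ms1_area_rosette"))
            tot = normalize_abundances(infer_proteins(classified, 1, "ms1_area_total"))
            enr = enrichment_table(ros, tot).merge(truth, on="protein_acc")
            errors.extend(np.abs(enr.ratio - enr.true_ratio) / enr.true_ratio)
        assert np.median(errors) < 0.10


class TestOverlapAndAnnotations:
    def test_identical_sets_100(self):
        assert replicate_overlap({"a", "b"}, {"a", "b"}) == 100.0

    def test_worked_example_both_modes(self):
        a = {f"p{i}" for i in range(1, 11)}
        b = {f"p{i}" for i in range(6, 16)}
        assert replicate_overlap(a, b) == pytest.approx(50.0)
        assert replicate_overlap(a, b, mode="jaccard") == pytest.approx(100 * 5 / 15, abs=0.05)

    def test_disjoint_zero_and_empty_rejected(self):
        assert replicate_overlap({"a"}, {"b"}) == 0.0
        with pytest.raises(ValueError):
            replicate_overlap(set(), {"a"})

    def test_annotation_tabulation(self):
        prots = [f"P{i}" for i in range(312)]
        mapping = {f"P{i}": "RNA binding" for i in range(60)}
        out = tabulate_annotations(prots, mapping).set_index("annotation_class")
        assert out.at["RNA binding", "count"] == 60
        assert out.at["RNA binding", "percent"] == pytest.approx(19.2, abs=0.05)
        assert out["count"].sum() == 312

    def test_empty_map_all_unannotated(self):
        out = tabulate_annotations(["P1", "P2"], {}).set_index("annotation_class")
        assert out.at["unannotated", "count"] == 2
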