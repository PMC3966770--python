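"""Ratio computation and hierarchical median aggregation."""

import numpy as np
import pandas as pd
import pytest

import phosphoquant as pq

from conftest import make_record


def _ratios_from(design, *records):
    return pq.psm_log_ratios(list(records), design)


class TestPSMLogRatios:
    def test_twofold_and_unity(self, design1):
        intensities = {ch: 100.0 for ch in design1.channels("plex1")}
        intensities["126"] = 200.0
        ratios = _ratios_from(design1, make_record(design1, intensities=intensities))
        by_case = ratios.set_index("case")["log2_ratio"]
        assert by_case["case1"] == pytest.approx(1.0)
        assert by_case["case2"] == pytest.approx(0.0)
        assert len(ratios) == 4  # one ratio per case of the plex

    def test_swapping_tissue_labels_negates_ratios(self, design1, rng):
        rec = make_record(
            design1,
            intensities={ch: float(v) for ch, v in
                         zip(design1.channels("plex1"), rng.uniform(10, 1000, 8))},
        )
        fwd = _ratios_from(design1, rec).set_index("case")["log2_ratio"]
        rev = _ratios_from(design1.swap_tissues(), rec).set_index("case")["log2_ratio"]
        assert np.allclose(fwd, -rev)


class TestMedianAggregation:
    def _table(self, design, ratio_values, **kw):
        records = []
        for i, r in enumerate(ratio_values):
            intensities = {ch: 100.0 for ch in design.channels("plex1")}
            intensities["126"] = 100.0 * 2.0**r  # case1 log2 ratio = r
            records.append(make_record(design, psm_id=f"p{i}", intensities=intensities, **kw))
        return pq.aggregate_peptide(pq.psm_log_ratios(records, design))

    def test_single_psm_identity(self, design1):
        table = self._table(design1, [0.7])
        assert table.values.loc["LSESVKAR@3", ("case1", "imac")] == pytest.approx(0.7)

    def test_odd_count_median_robust_to_outlier(self, design1):
        table = self._table(design1, [0.5, 1.5, 9.0])
        assert table.values.loc["LSESVKAR@3", ("case1", "imac")] == pytest.approx(1.5)

    def test_even_count_median_is_mean_of_central_pair(self, design1):
        table = self._table(design1, [0.4, 0.8])
        expected = float(np.median([0.4, 0.8]))  # sorting oracle
        assert expected == pytest.approx(0.6)
        assert table.values.loc["LSESVKAR@3", ("case1", "imac")] == pytest.approx(expected)

    def test_aggregating_single_valued_table_is_idempotent(self, design1):
        table = self._table(design1, [0.3])
        again = pq.aggregate_peptide(
            pq.psm_log_ratios(
                [make_record(design1, intensities={
                    ch: 100.0 for ch in design1.channels("plex1")} | {"126": 100.0 * 2**0.3})],
                design1,
            )
        )
        pd.testing.assert_frame_equal(table.values, again.values)


class TestProteinAggregation:
    def _peptide_table(self, design, seq_acc_ratio):
        records = []
        for i, (seq, accs, r) in enumerate(seq_acc_ratio):
            intensities = {ch: 100.0 for ch in design.channels("plex1")}
            intensities["126"] = 100.0 * 2.0**r
            records.append(
                make_record(design, psm_id=f"p{i}", sequence=seq, phospho_positions=(),
                            accessions=accs, intensities=intensities)
            )
        return pq.aggregate_peptide(pq.psm_log_ratios(records, design))

    def test_median_over_unique_nonphospho_peptides(self, design1):
        table = self._peptide_table(
            design1,
            [("AAAAK", ("P1",), 0.2), ("CCCCK", ("P1",), 0.3), ("DDDDK", ("P1",), 0.4)],
        )
        protein = pq.aggregate_protein(table)
        assert protein.values.loc["P1", ("case1", "imac")] == pytest.approx(0.3)

    def test_shared_peptide_contributes_to_no_protein(self, design1):
        table = self._peptide_table(
            design1,
            [("AAAAK", ("P1",), 0.2), ("EEEEK", ("P1", "P2"), 5.0)],
        )
        protein = pq.aggregate_protein(table)
        assert protein.values.loc["P1", ("case1", "imac")] == pytest.approx(0.2)
        assert "P2" not in protein.features

    def test_phospho_only_protein_has_no_protein_ratio(self, design1):
        records = [make_record(design1, accessions=("P9",))]  # phospho PSM
        table = pq.aggregate_peptide(pq.psm_log_ratios(records, design1))
        protein = pq.aggregate_protein(table)
        assert "P9" not in protein.features


class TestMergeAndNormalize:
    def _arm_table(self, design, arm_ratios, **kw):
        records = []
        for i, (arm, r) in enumerate(arm_ratios):
            intensities = {ch: 100.0 for ch in design.channels("plex1")}
            intensities["126"] = 100.0 * 2.0**r
            records.append(make_record(design, psm_id=f"p{i}", arm=arm,
                                       intensities=intensities, **kw))
        return pq.aggregate_peptide(pq.psm_log_ratios(records, design))

    def test_merge_three_arms_median(self, design1):
        table = self._arm_table(design1, [("imac", 1.0), ("tio2", 1.2), ("non_enriched", 0.8)])
        merged = pq.merge_arms(table)
        assert merged.loc["LSESVKAR@3", "case1"] == pytest.approx(1.0)

    def test_merge_single_arm_passthrough(self, design1):
        table = self._arm_table(design1, [("tio2", 0.5)])
        assert pq.merge_arms(table).loc["LSESVKAR@3", "case1"] == pytest.approx(0.5)

    def test_merge_two_arms_even_median(self, design1):
        table = self._arm_table(design1, [("imac", 1.0), ("tio2", 2.0)])
        expected = float(np.median([1.0, 2.0]))
        assert pq.merge_arms(table).loc["LSESVKAR@3", "case1"] == pytest.approx(expected)

    def test_cross_arm_median_matches_row_recomputation(self, small_analysis):
        table = small_analysis.phospho_table
        merged = small_analysis.merged_phospho
        feat = merged.index[0]
        for case in merged.columns:
            arm_vals = [
                table.values.loc[feat, (case, arm)]
                for arm in table.arms
                if (case, arm) in table.values.columns
                and pd.notna(table.values.loc[feat, (case, arm)])
            ]
            if arm_vals:
                assert merged.loc[feat, case] == pytest.approx(float(np.median(arm_vals)))
            else:
                assert pd.isna(merged.loc[feat, case])

    def test_phospho_normalization_is_log_subtraction(self, design1):
        phospho_recs = []
        intensities = {ch: 100.0 for ch in design1.channels("plex1")}
        intensities["126"] = 100.0 * 2.0**1.5
        phospho_recs.append(make_record(design1, psm_id="ph", accessions=("P1",),
                                        intensities=intensities))
        nonphos = {ch: 100.0 for ch in design1.channels("plex1")}
        nonphos["126"] = 100.0 * 2.0**0.5
        phospho_recs.append(make_record(design1, psm_id="np", sequence="AAAAK",
                                        phospho_positions=(), accessions=("P1",),
                                        intensities=nonphos))
        table = pq.aggregate_peptide(pq.psm_log_ratios(phospho_recs, design1))
        phospho = table.subset_level("phosphopeptide")
        protein = pq.aggregate_protein(table)
        normalized = pq.normalize_phospho_to_protein(phospho, protein)
        assert normalized.loc["LSESVKAR@3", "case1"] == pytest.approx(1.0)
        assert normalized.loc["LSESVKAR@3", "case2"] == pytest.approx(0.0)

    def test_absent_protein_ratio_propagates_as_absent(self, design1):
        rec = make_record(design1, accessions=("P7",))
        table = pq.aggregate_peptide(pq.psm_log_ratios([rec], design1))
        normalized = pq.normalize_phospho_to_protein(
            table.subset_level("phosphopeptide"), pq.aggregate_protein(table)
        )
        assert normalized.loc["LSESVKAR@3"].isna().all()


class TestEndToEndInvariants:
    def test_channel_scaling_equivariance(self, design1, rng):
        """Multiplying one channel's raw intensities by a constant leaves
        every log2 T/NT ratio unchanged after sum-scaling."""
        records = [
            make_record(
                design1, psm_id=f"p{i}",
                intensities={ch: float(v) for ch, v in
                             zip(design1.channels("plex1"), rng.uniform(10, 1000, 8))},
            )
            for i in range(25)
        ]
        bumped = [
            rec.scaled({ch: (7.0 if ch == "127e" else 1.0) for ch in rec.intensities})
            for rec in records
        ]
        base, _ = pq.sum_scale(records, design1)
        alt, _ = pq.sum_scale(bumped, design1)
        r0 = pq.psm_log_ratios(base, design1)["log2_ratio"]
        r1 = pq.psm_log_ratios(alt, design1)["log2_ratio"]
        assert np.allclose(r0, r1, atol=1e-9)

    def test_noise_free_recovery_matches_truth_exactly(self):
        cfg = pq.SimConfig.noise_free(n_proteins=24, seed=7)
        sim = pq.generate_dataset(cfg)
        out = pq.analyze(sim.records, sim.design, pq.AnalysisOptions(pls=False))
        metrics = pq.truth_evaluation(out.merged_phospho, sim.truth.phospho_fc)
        assert metrics["max_abs_error"] < 1e-9
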