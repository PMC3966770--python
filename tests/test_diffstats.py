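"""Location tests, volcano calls, Venn accounting and enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import phosphoquant as pq
from phosphoquant.diffstats import MIN_P
from phosphoquant.errors import PhosphoQuantError


class TestOneSidedTTest:
    def test_symmetric_values_give_half(self):
        t, p = pq.one_sided_ttest([-1.0, 1.0, -2.0, 2.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "values",
        [
            [1.0, 1.2, 0.8, 1.1],
            [-0.5, -0.1, -0.9, -0.4, -0.2],
            [0.3, -0.2, 0.5, 0.1, 0.0, 0.4],
        ],
    )
    def test_matches_reference_implementation(self, values):
        """Auto-direction p equals half the two-sided p of the reference
        one-sample t-test (scipy) to 1e-10."""
        t, p = pq.one_sided_ttest(values)
        ref = stats.ttest_1samp(values, 0.0)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue / 2.0, abs=1e-10)

    def test_fixed_directions_match_reference(self, rng):
        values = rng.normal(0.2, 1.0, size=8)
        for direction in ("greater", "less"):
            _, p = pq.one_sided_ttest(values, direction=direction)
            ref = stats.ttest_1samp(values, 0.0, alternative=direction)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_single_value_yields_absent_p(self):
        t, p = pq.one_sided_ttest([0.7])
        assert np.isnan(t) and np.isnan(p)

    def test_zero_variance_nonzero_mean_flagged_minimal_p(self):
        t, p = pq.one_sided_ttest([0.5, 0.5, 0.5])
        assert np.isinf(t) and p == MIN_P

    def test_frame_variant_agrees_with_scalar(self, rng):
        matrix = pd.DataFrame(rng.normal(0, 1, size=(40, 6)))
        matrix.iloc[0, :4] = np.nan  # only 2 cases left
        matrix.iloc[1, :5] = np.nan  # single case -> absent statistics
        res = pq.ttest_frame(matrix)
        for i in range(40):
            t, p = pq.one_sided_ttest(matrix.iloc[i])
            assert res["t_stat"].iloc[i] == pytest.approx(t, nan_ok=True, abs=1e-12)
            assert res["p_one_sided"].iloc[i] == pytest.approx(p, nan_ok=True, abs=1e-12)
        assert np.isnan(res["p_one_sided"].iloc[1])

    def test_auto_direction_is_smaller_tail(self, rng):
        values = rng.normal(0.3, 1.0, 7)
        _, p_auto = pq.one_sided_ttest(values)
        _, p_g = pq.one_sided_ttest(values, "greater")
        _, p_l = pq.one_sided_ttest(values, "less")
        assert p_auto == pytest.approx(min(p_g, p_l), abs=1e-12)


class TestVolcano:
    def _frame(self, rows):
        return pd.DataFrame(
            rows, columns=["median_log2_ratio", "p_one_sided", "n_cases"]
        )

    def test_boundaries_are_inclusive(self):
        config = pq.VolcanoConfig(ratio_cut=0.3, p_cut=0.05)
        res = pq.volcano_classify(
            self._frame([(0.30, 0.05, 12), (0.29, 0.01, 12), (0.90, 0.06, 12),
                         (-0.30, 0.05, 12), (0.40, 0.04, 1)]),
            config,
        )
        assert list(res["significant"]) == [True, False, False, True, False]

    def test_thresholds_recorded(self):
        config = pq.VolcanoConfig(ratio_cut=0.75, p_cut=0.05)
        res = pq.volcano_classify(self._frame([(1.0, 0.001, 5)]), config)
        assert res.attrs["thresholds_used"] == (0.75, 0.05)

    def test_power_monotone_in_effect_size(self, rng):
        """Significant fraction is non-decreasing in the true |log2 FC|."""
        n_cases, n_feat, sd = 12, 400, 0.5
        config = pq.VolcanoConfig(ratio_cut=0.75, p_cut=0.05)
        fractions = []
        for fc in (0.0, 0.5, 1.0):
            mat = pd.DataFrame(rng.normal(fc, sd, size=(n_feat, n_cases)))
            res = pq.volcano_classify(pq.ttest_frame(mat), config)
            fractions.append(res["significant"].mean())
        assert fractions[0] <= fractions[1] <= fractions[2]
        assert fractions[2] > 0.9

    def test_union_rule_significant_in_any_arm(self, small_analysis):
        union = small_analysis.phospho_union
        per_arm = small_analysis.phospho_volcano
        expected = pd.Series(False, index=union.index)
        for res in per_arm.values():
            expected |= res["significant"].reindex(expected.index, fill_value=False)
        pd.testing.assert_series_equal(union, expected)


class TestOverlapCounts:
    def test_small_example_by_hand(self):
        counts = pq.overlap_counts({"A": {"x", "y"}, "B": {"y"}, "C": set()})
        assert counts["A"] == 1 and counts["A&B"] == 1
        assert counts["B"] == 0 and counts["C"] == 0
        assert counts["A&B&C"] == 0 and counts["union"] == 2

    def test_identical_sets_all_in_triple_overlap(self):
        s = {"a", "b", "c"}
        counts = pq.overlap_counts({"x": set(s), "y": set(s), "z": set(s)})
        assert counts["x&y&z"] == 3
        assert counts["x"] == counts["y"] == counts["z"] == 0

    def test_matches_brute_force_on_random_sets(self, rng):
        universe = [f"e{i}" for i in range(60)]
        for _ in range(20):
            sets = {
                label: {e for e in universe if rng.random() < 0.4}
                for label in ("A", "B", "C")
            }
            counts = pq.overlap_counts(sets)
            # brute force: classify every element by its membership pattern
            brute = {}
            for e in universe:
                member = tuple(sorted(l for l in sets if e in sets[l]))
                if member:
                    brute[member] = brute.get(member, 0) + 1
            for region, n in brute.items():
                assert counts["&".join(region)] == n
            region_total = sum(
                v for k, v in counts.items()
                if not k.startswith("total_") and k != "union"
            )
            assert region_total == counts["union"]


class TestEnrichment:
    def test_empty_hit_set_gives_unit_p(self):
        res = pq.enrichment_test(
            [], ["g1", "g2", "g3"], {"s1": ["g1"], "s2": ["g2", "g3"]}, ease=False
        )
        assert (res["p_raw"] == 1.0).all()

    def test_fisher_matches_hypergeometric_enumeration(self):
        """One-sided Fisher p equals the exhaustive hypergeometric tail."""
        background = [f"g{i}" for i in range(100)]
        in_set = background[:10]
        hits = background[:5] + background[50:55]  # 5 of 10 hits in the set
        res = pq.enrichment_test(hits, background, {"s": in_set}, ease=False)
        # enumerate P(X >= 5) for X ~ Hypergeom(N=100, K=10, n=10)
        expected = sum(
            stats.hypergeom.pmf(k, 100, 10, 10) for k in range(5, 11)
        )
        assert res["p_raw"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_ease_removes_one_hit(self):
        background = [f"g{i}" for i in range(100)]
        in_set = background[:10]
        hits = background[:5] + background[50:55]
        res = pq.enrichment_test(hits, background, {"s": in_set}, ease=True)
        expected = sum(stats.hypergeom.pmf(k, 100, 10, 10) for k in range(4, 11))
        assert res["p_raw"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_bh_adjustment_hand_example(self):
        background = [f"g{i}" for i in range(30)]
        res = pq.enrichment_test(
            background[:6], background,
            {"a": background[:5], "b": background[:12], "c": background},
            ease=False,
        )
        # BH: p_(i) * m / i, cummin from the largest rank
        raw = res.sort_values("p_raw")["p_raw"].to_numpy()
        m = len(raw)
        stepup = np.minimum.accumulate((raw * m / np.arange(1, m + 1))[::-1])[::-1]
        adj = res.sort_values("p_raw")["p_bh"].to_numpy()
        assert np.allclose(adj, np.minimum(stepup, 1.0))
        assert (res["p_bh"] >= res["p_raw"] - 1e-15).all()

    def test_bh_is_monotone_in_rank(self, rng):
        background = [f"g{i}" for i in range(200)]
        hits = list(rng.choice(background, size=40, replace=False))
        gene_sets = {
            f"s{j}": list(rng.choice(background, size=20, replace=False))
            for j in range(15)
        }
        res = pq.enrichment_test(hits, background, gene_sets)
        ordered = res.sort_values("p_raw")
        assert (ordered["p_bh"].diff().dropna() >= -1e-15).all()

    def test_counts_form_valid_table(self):
        background = [f"g{i}" for i in range(50)]
        res = pq.enrichment_test(background[:8], background, {"s": background[4:20]})
        row = res.iloc[0]
        assert row["n_hits_in_set"] <= row["n_hits"] <= row["n_background"]
        assert row["n_hits_in_set"] <= row["n_background_in_set"]

    def test_empty_background_raises(self):
        with pytest.raises(PhosphoQuantError):
            pq.enrichment_test([], [], {"s": ["g1"]})

    def test_hits_outside_background_raise(self):
        with pytest.raises(PhosphoQuantError):
            pq.enrichment_test(["x"], ["g1"], {"s": ["g1"]})

    def test_gmt_round_trip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("s1\tdesc\tg1\tg2\ns2\tdesc\tg3\n")
        assert pq.read_gmt(path) == {"s1": ["g1", "g2"], "s2": ["g3"]}


def test_null_type_one_error_calibrated(rng):
    """Fixed-direction one-sided p is uniform under the null: the rejection
    rate at 0.05 stays inside the binomial band, and the data-driven
    direction doubles it (half per direction)."""
    n_feat, n_cases = 3000, 12
    mat = pd.DataFrame(rng.normal(0.0, 0.5, size=(n_feat, n_cases)))
    p_fixed = pq.ttest_frame(mat, direction="greater")["p_one_sided"]
    rate = (p_fixed <= 0.05).mean()
    se = np.sqrt(0.05 * 0.95 / n_feat)
    assert abs(rate - 0.05) < 3 * se
    p_auto = pq.ttest_frame(mat, direction="auto")["p_one_sided"]
    rate_auto = (p_auto <= 0.05).mean()
    assert abs(rate_auto - 0.10) < 3 * np.sqrt(0.1 * 0.9 / n_feat)
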