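"""Reporter co-expression ratios, proportion CIs, and comparison tests."""

import numpy as np
import pandas as pd
import pytest

import oracles
from cisconserve import (
    ReporterCountTable,
    expression_ratio,
    fisher_exact_2x2,
    kruskal_wallis,
    proportion_with_ci,
    rank_sum_test,
)


def make_table(rows):
    return ReporterCountTable(
        pd.DataFrame(rows, columns=["animal", "construct", "cell_class", "gfp", "mcherry"])
    )


class TestExpressionRatio:
    @pytest.mark.parametrize("gfp,mch,expected", [(12, 12, 1.0), (0, 10, 0.0), (3, 12, 0.25)])
    def test_direct_division(self, gfp, mch, expected):
        assert expression_ratio(gfp, mch) == expected

    def test_zero_mcherry_not_scoreable(self):
        with pytest.raises(ValueError):
            expression_ratio(3, 0)

    def test_table_ratios_equal_per_row_division_and_exclude_zero_control(self, rng):
        rows = []
        for i in range(100):
            gfp = int(rng.integers(0, 14))
            mch = int(rng.integers(0, 14))
            rows.append((f"a{i}", "wt", "D-type", gfp, mch))
        table = make_table(rows)
        ratios = table.ratios()
        kept = [r for r in rows if r[4] > 0]
        assert len(ratios) == len(kept)
        assert list(ratios["ratio"]) == [g / m for (_, _, _, g, m) in kept]


class TestProportionCI:
    def test_boundaries(self):
        p, lo, hi = proportion_with_ci(50, 50)
        assert p == 1.0 and hi == 1.0
        p, lo, hi = proportion_with_ci(0, 50)
        assert p == 0.0 and lo == 0.0

    def test_matches_independent_wilson_formula(self):
        p, lo, hi = proportion_with_ci(40, 100)
        w_lo, w_hi = oracles.wilson_interval(40, 100)
        assert lo == pytest.approx(w_lo, abs=1e-6)
        assert hi == pytest.approx(w_hi, abs=1e-6)

    def test_wald_available_for_comparison(self):
        p, lo, hi = proportion_with_ci(40, 100, method="wald")
        se = np.sqrt(0.4 * 0.6 / 100)
        assert lo == pytest.approx(0.4 - 1.959963984540054 * se, abs=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            proportion_with_ci(5, 4)
        with pytest.raises(ValueError):
            proportion_with_ci(0, 0)


class TestFisherExact:
    def test_identical_proportions_give_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == 1.0

    @pytest.mark.parametrize(
        "table",
        [
            [[1, 9], [11, 3]],
            [[5, 0], [1, 4]],
            [[8, 2], [1, 5]],
            [[0, 2], [3, 0]],
            [[6, 6], [0, 12]],
            [[2, 3], [4, 2]],
        ],
    )
    def test_matches_hypergeometric_enumeration(self, table):
        assert fisher_exact_2x2(table) == pytest.approx(
            oracles.fisher_two_sided_enum(table), rel=1e-9
        )

    @pytest.mark.parametrize("n", [5, 7, 10])
    def test_perfect_separation_is_significant(self, n):
        table = [[0, n], [n, 0]]
        p = fisher_exact_2x2(table)
        assert p < 0.01
        assert p == pytest.approx(oracles.fisher_two_sided_enum(table), rel=1e-9)

    def test_invariant_under_transpose(self, rng):
        for _ in range(10):
            t = rng.integers(0, 12, size=(2, 2))
            assert fisher_exact_2x2(t) == pytest.approx(fisher_exact_2x2(t.T), rel=1e-9)

    def test_negative_or_fractional_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -2], [3, 4]])
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1.5, 2], [3, 4]])


class TestKruskalWallis:
    def test_identical_groups_give_zero_h(self):
        h, p = kruskal_wallis([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_fully_tied_data_gives_zero_h_by_convention(self):
        h, p = kruskal_wallis([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        assert (h, p) == (0.0, 1.0)

    def test_chi2_p_within_exact_permutation_bounds(self, rng):
        groups = [[0.1, 0.9, 0.4], [0.2, 0.8, 0.7], [1.0, 0.95, 0.95]]
        h_chi, p_chi = kruskal_wallis(groups)
        h_ex, p_ex = kruskal_wallis(groups, method="exact")
        assert h_ex == pytest.approx(h_chi)
        # chi-square approximation should land near the exact permutation p
        assert abs(p_chi - p_ex) < 0.1

    def test_matches_scipy_on_untied_data(self, rng):
        from scipy import stats

        groups = [rng.normal(size=8), rng.normal(1.0, size=8), rng.normal(size=8)]
        h, p = kruskal_wallis(groups)
        h_sp, p_sp = stats.kruskal(*groups)
        assert h == pytest.approx(h_sp)
        assert p == pytest.approx(p_sp)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])


class TestRankSum:
    def test_identical_samples_give_p_one_exactly(self):
        assert rank_sum_test([1, 2, 3], [1, 2, 3]) == 1.0

    def test_complete_separation_matches_enumeration(self):
        a, b = [5, 6, 7, 8], [1, 2, 3, 4]
        p = rank_sum_test(a, b, method="exact")
        assert p == pytest.approx(oracles.ranksum_two_sided_enum(a, b))
        assert p == pytest.approx(2 / 70)  # only the two extreme assignments

    def test_exact_matches_enumeration_with_ties(self, rng):
        a = list(rng.integers(0, 4, size=5))
        b = list(rng.integers(1, 5, size=6))
        assert rank_sum_test(a, b, method="exact") == pytest.approx(
            oracles.ranksum_two_sided_enum(a, b)
        )

    def test_large_shifted_normals_are_detected(self, rng):
        a = rng.normal(0.0, 1.0, size=60)
        b = rng.normal(1.5, 1.0, size=60)
        assert rank_sum_test(a, b) < 0.001

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestReporterCountTable:
    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing column"):
            ReporterCountTable(pd.DataFrame({"animal": [], "gfp": []}))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            make_table([("a1", "wt", "D-type", -1, 5)])

    def test_counts_over_max_cells_rejected(self):
        df = pd.DataFrame(
            [("a1", "wt", "D-type", 14, 5, 13)],
            columns=["animal", "construct", "cell_class", "gfp", "mcherry", "max_cells"],
        )
        with pytest.raises(ValueError, match="max_cells"):
            ReporterCountTable(df)

    def test_tsv_round_trip(self, tmp_path):
        table = make_table([("a1", "wt", "D-type", 10, 12), ("a2", "mut", "D-type", 2, 12)])
        path = tmp_path / "counts.tsv"
        table.to_tsv(path)
        back = ReporterCountTable.from_tsv(path)
        pd.testing.assert_frame_equal(back.data, table.data)
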