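import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from locusprox import (
    BindingMatrix,
    cochran_q,
    detection_binding_tables,
    expression_stratified_tests,
    locus_proportions,
    mcnemar_pairwise,
    simulate_binding_matrix,
    simulate_expression_detection,
)
from locusprox.design import TTestVariant


def _matrix(rows, loci=None):
    arr = np.asarray(rows, dtype=int)
    loci = loci or [f"L{j}" for j in range(arr.shape[1])]
    frame = pd.DataFrame(
        arr, columns=loci, index=pd.Index([f"T{i}" for i in range(len(arr))], name="tf")
    )
    return BindingMatrix(frame)


class TestLocusProportions:
    def test_reported_percentages(self):
        rows = [[1, 1]] * 97 + [[1, 0]] * 35 + [[0, 0]] * 86
        out = locus_proportions(_matrix(rows, ["TSS1", "e330"]))
        # 132/218 binders at the promoter, 97/218 at the distal region
        assert out.loc["TSS1", "count"] == 132
        assert out.loc["TSS1", "percentage"] == 60.6
        assert out.loc["e330", "count"] == 97
        assert out.loc["e330", "percentage"] == 44.5

    def test_all_zero_column(self):
        out = locus_proportions(_matrix([[0, 1], [0, 0]]))
        assert out.loc["L0", "count"] == 0
        assert out.loc["L0", "percentage"] == 0.0


class TestCochranQ:
    def test_identical_columns_no_variation(self):
        q, df, p = cochran_q(_matrix([[1, 1, 1], [0, 0, 0], [1, 1, 1]]))
        assert q == 0.0
        assert p == 1.0

    def test_hand_computed_three_by_three(self):
        q, df, p = cochran_q(_matrix([[1, 1, 0], [1, 0, 0], [1, 1, 1]]))
        assert q == pytest.approx(3.0)
        assert df == 2
        assert p == pytest.approx(np.exp(-1.5), abs=1e-4)  # chi2_2 tail = e^(-Q/2)

    def test_equals_mcnemar_statistic_at_two_loci(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            rows = rng.integers(0, 2, size=(30, 2))
            if not (rows.sum(axis=1) % 2).any():
                continue  # no discordant rows: both sides degenerate
            matrix = _matrix(rows)
            q, _, _ = cochran_q(matrix)
            mc = mcnemar_pairwise(matrix)[0]
            assert q == pytest.approx(mc.statistic, abs=1e-9)

    def test_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import cochrans_q

        rng = np.random.default_rng(13)
        rows = rng.integers(0, 2, size=(60, 4))
        q, df, p = cochran_q(_matrix(rows))
        ref = cochrans_q(rows, return_object=True)
        assert q == pytest.approx(ref.statistic, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_invariant_to_row_permutation_and_concordant_rows(self):
        rng = np.random.default_rng(14)
        rows = rng.integers(0, 2, size=(40, 3))
        base, _, _ = cochran_q(_matrix(rows))
        permuted, _, _ = cochran_q(_matrix(rows[rng.permutation(40)]))
        assert permuted == pytest.approx(base, abs=1e-9)
        padded = np.vstack([rows, np.zeros((5, 3), int), np.ones((5, 3), int)])
        with_concordant, _, _ = cochran_q(_matrix(padded))
        assert with_concordant == pytest.approx(base, abs=1e-9)

    def test_single_locus_rejected(self):
        with pytest.raises(ValueError):
            cochran_q(_matrix([[1], [0]]))


class TestMcNemar:
    def test_balanced_discordance_is_null(self):
        rows = [[1, 0]] * 5 + [[0, 1]] * 5 + [[1, 1]] * 10
        res = mcnemar_pairwise(_matrix(rows))[0]
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_hand_computed_statistic(self):
        rows = [[1, 0]] * 10 + [[0, 1]] * 2 + [[1, 1]] * 8
        res = mcnemar_pairwise(_matrix(rows))[0]
        assert (res.b, res.c) == (10, 2)
        assert res.statistic == pytest.approx(64 / 12)
        assert res.p == pytest.approx(0.02092, abs=5e-6)

    def test_matches_statsmodels_uncorrected(self):
        from statsmodels.stats.contingency_tables import mcnemar

        rows = [[1, 0]] * 7 + [[0, 1]] * 3 + [[1, 1]] * 5 + [[0, 0]] * 5
        res = mcnemar_pairwise(_matrix(rows))[0]
        table = [[5, 7], [3, 5]]
        ref = mcnemar(table, exact=False, correction=False)
        assert res.statistic == pytest.approx(float(ref.statistic), abs=1e-9)
        assert res.p == pytest.approx(float(ref.pvalue), abs=1e-9)

    def test_pair_count_and_bonferroni_family(self):
        rng = np.random.default_rng(15)
        matrix = _matrix(rng.integers(0, 2, size=(30, 6)))
        results = mcnemar_pairwise(matrix)
        assert len(results) == 15
        for res in results:
            assert res.p_bonf == pytest.approx(min(1.0, res.p * 15))

    def test_no_discordance_convention(self):
        res = mcnemar_pairwise(_matrix([[1, 1], [0, 0]]))[0]
        assert res.statistic == 0.0
        assert res.p == 1.0


def _fisher_enumeration(a, b, c, d):
    """Two-sided Fisher p by summing hypergeometric point probabilities
    not exceeding the observed table's, over all tables with the same
    margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def point(x):
        return (
            comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)
        )

    observed = point(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = point(x)
        if px <= observed * (1 + 1e-9):
            total += px
    return min(1.0, total)


class TestDetectionBindingTables:
    def _detection(self, tfs, statuses, expression=None):
        return pd.DataFrame(
            {
                "status": statuses,
                "expression": expression
                if expression is not None
                else np.ones(len(tfs)),
            },
            index=pd.Index(tfs, name="tf"),
        )

    def test_diagonal_table_exact_p(self):
        matrix = _matrix([[1]] * 5 + [[0]] * 5, ["L"])
        det = self._detection(
            [f"T{i}" for i in range(10)],
            ["quantified"] * 5 + ["undetected"] * 5,
        )
        table, expected, p = detection_binding_tables(matrix, det, "L")
        assert (table.a, table.b, table.c, table.d) == (5, 0, 0, 5)
        assert p == pytest.approx(2 / 252, abs=1e-9)
        assert expected == pytest.approx(2.5)

    def test_degenerate_margin_p_one(self):
        matrix = _matrix([[1]] * 4 + [[0]] * 4, ["L"])
        det = self._detection([f"T{i}" for i in range(8)], ["quantified"] * 8)
        _, _, p = detection_binding_tables(matrix, det, "L")
        assert p == 1.0

    def test_fisher_matches_enumeration_small_tables(self):
        rng = np.random.default_rng(16)
        for _ in range(40):
            counts = rng.integers(0, 8, size=4)
            if counts.sum() == 0 or counts.sum() > 30:
                continue
            a, b, c, d = (int(v) for v in counts)
            _, p_scipy = stats.fisher_exact([[a, b], [c, d]])
            assert p_scipy == pytest.approx(
                _fisher_enumeration(a, b, c, d), abs=1e-9
            )

    def test_independent_simulation_overlap_near_expected(self):
        rng = np.random.default_rng(17)
        matrix, _ = simulate_binding_matrix(500, [0.5], 0.0, seed=18)
        statuses = np.where(rng.random(500) < 0.4, "quantified", "undetected")
        det = self._detection(matrix.tfs, statuses)
        table, expected, p = detection_binding_tables(matrix, det, "locus1")
        # hypergeometric SE of the overlap count under independence
        n = table.grand_total
        r = table.a + table.b
        k = table.a + table.c
        var = r * k * (n - r) * (n - k) / (n**2 * (n - 1))
        assert abs(table.a - expected) < 3 * np.sqrt(var)
        assert p > 0.01

    def test_misaligned_tfs_rejected(self):
        matrix = _matrix([[1], [0]], ["L"])
        det = self._detection(["T0"], ["quantified"])
        with pytest.raises(ValueError, match="missing TF"):
            detection_binding_tables(matrix, det, "L")


class TestExpressionStratified:
    def test_identical_groups_null(self):
        matrix = _matrix([[1]] * 3 + [[0]] * 3, ["L"])
        det = pd.DataFrame(
            {
                "status": ["quantified"] * 6,
                "expression": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
            },
            index=pd.Index([f"T{i}" for i in range(6)], name="tf"),
        )
        strata, tests = expression_stratified_tests(det, matrix)
        pooled = tests[tests["scope"] == "pooled"]
        assert pooled["t"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert pooled["p"].iloc[0] == pytest.approx(1.0)

    def test_welch_hand_computed(self):
        t, p = stats.ttest_ind([1, 2, 3], [4, 5, 6], equal_var=False)
        assert t == pytest.approx(-3.674, abs=5e-4)
        assert p == pytest.approx(0.0214, abs=5e-4)
        # the module wires the same Welch variant through its surface
        matrix = _matrix([[1]] * 3 + [[0]] * 3, ["L"])
        det = pd.DataFrame(
            {
                "status": ["quantified"] * 6,
                "expression": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            },
            index=pd.Index([f"T{i}" for i in range(6)], name="tf"),
        )
        _, tests = expression_stratified_tests(det, matrix)
        row = tests[(tests["scope"] == "L")].iloc[0]
        assert abs(row["t"]) == pytest.approx(3.674, abs=5e-4)
        assert row["p"] == pytest.approx(0.0214, abs=5e-4)

    def test_detection_effect_recovered_in_sign_and_significance(self):
        matrix, _ = simulate_binding_matrix(600, [0.5], 0.3, seed=19)
        det = simulate_expression_detection(
            600, det_intercept=-2.0, det_slope=1.0, seed=20
        )
        det.index = matrix.tfs
        strata, tests = expression_stratified_tests(det, matrix)
        pooled = strata[strata["scope"] == "pooled"].set_index("stratum")
        det_mean = pooled.loc[
            ["detected/bound", "detected/unbound"], "mean"
        ].mean()
        und_mean = pooled.loc[
            ["undetected/bound", "undetected/unbound"], "mean"
        ].mean()
        assert und_mean < det_mean
        det_side = tests["group_a"].str.split("/").str[0]
        other_side = tests["group_b"].str.split("/").str[0]
        cross = tests[(tests["scope"] == "pooled") & (det_side != other_side)]
        assert (cross["p_bonf"] < 0.05).any()

    def test_small_stratum_skipped_with_warning(self, caplog):
        matrix = _matrix([[1]] * 1 + [[0]] * 5, ["L"])
        det = pd.DataFrame(
            {
                "status": ["quantified"] * 6,
                "expression": [1.0, 2.0, 1.5, 2.5, 3.0, 2.0],
            },
            index=pd.Index([f"T{i}" for i in range(6)], name="tf"),
        )
        with caplog.at_level("WARNING"):
            _, tests = expression_stratified_tests(det, matrix)
        assert any("smaller than 2" in r.message for r in caplog.records)


class TestNullCalibrationCochran:
    def test_type_i_error_small_panel(self):
        # quick exchangeable-locus null (the full 218 x 6 panel runs in
        # the acceptance suite): rejection rate 0.05 +/- 3 SE
        rng = np.random.default_rng(21)
        reps, rejections = 400, 0
        for _ in range(reps):
            rows = rng.random((100, 4)) < 0.4
            q, _, p = cochran_q(_matrix(rows.astype(int)))
            rejections += p < 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rejections / reps - 0.05) < 3 * se
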