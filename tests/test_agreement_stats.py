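"""Agreement/reliability statistics against independent oracles.

The ICC oracle codes the two-way ANOVA decomposition with explicit
Python loops (no shared code with the implementation); the paired-t
oracle integrates the Student t density numerically.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from romkin import (
    RaterMatrix,
    compare_methods,
    consensus,
    icc_two_way_random,
    interpret_cv,
    interpret_icc,
    mean_cv,
    mean_difference,
    paired_t_test,
    pearson,
    power_sample_size,
    rater_reliability,
    regression_r2,
)
from romkin.errors import InputError, UndefinedStatisticError


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def icc_agreement_oracle(values: np.ndarray) -> float:
    """ICC(2,1) by brute-force sums of squares, coded with plain loops."""
    n, k = values.shape
    grand = sum(values[i][j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(values[i][j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(values[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_tot = sum((values[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def t_sf_oracle(t: float, df: int) -> float:
    """P(T > t) by numerical integration of the Student t density."""
    from scipy.integrate import quad

    c = math.exp(math.lgamma((df + 1) / 2) - math.lgamma(df / 2)) / math.sqrt(df * math.pi)
    density = lambda u: c * (1 + u * u / df) ** (-(df + 1) / 2)
    tail, _ = quad(density, t, np.inf)
    return tail


class TestMeanDifference:
    def test_identical_vectors_give_zero(self):
        assert mean_difference([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_arithmetic(self):
        # |10-12| and |20-16| -> (2+4)/2 ; signed: (-2+4)/2
        assert mean_difference([10, 20], [12, 16], "absolute") == pytest.approx(3.0)
        assert mean_difference([10, 20], [12, 16], "signed") == pytest.approx(1.0)

    def test_length_mismatch_and_bad_mode(self):
        with pytest.raises(InputError):
            mean_difference([1, 2], [1])
        with pytest.raises(InputError):
            mean_difference([1], [1], mode="rms")

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(-180, 180), min_size=1, max_size=20))
    def test_absolute_dominates_signed(self, x):
        rng = np.random.default_rng(len(x))
        y = list(np.asarray(x) + rng.normal(size=len(x)))
        assert mean_difference(x, y, "absolute") >= abs(
            mean_difference(x, y, "signed")) - 1e-12


class TestPearsonAndRegression:
    def test_perfect_linear_relations(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
        assert pearson(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_textbook_value(self):
        assert pearson([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6, abs=1e-12)

    def test_constant_input_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            pearson([1, 1, 1], [1, 2, 3])
        with pytest.raises(InputError):
            pearson([1, 2], [3, 4])  # too short

    def test_r2_of_exact_line_is_one_and_of_constant_y_is_zero(self):
        x = [0.0, 1.0, 2.0, 3.0]
        assert regression_r2(x, [5 - 2 * v for v in x]) == pytest.approx(1.0)
        assert regression_r2(x, [4.0] * 4) == 0.0
        with pytest.raises(InputError):
            regression_r2([2, 2, 2], [1, 2, 3])

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_simple_regression_identity_r2_equals_pearson_squared(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = 2.0 * x + rng.normal(size=12)
        assert regression_r2(x, y) == pytest.approx(pearson(x, y) ** 2, abs=1e-12)


class TestIcc:
    def test_identical_columns_give_one(self):
        m = RaterMatrix(np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]]))
        assert icc_two_way_random(m) == pytest.approx(1.0)

    def test_fixed_offset_consistency_exceeds_agreement(self):
        base = np.array([10.0, 20.0, 35.0, 50.0, 80.0])
        m = RaterMatrix(np.column_stack([base, base + 7.0]))
        agreement = icc_two_way_random(m, form="agreement")
        consistency = icc_two_way_random(m, form="consistency")
        assert consistency == pytest.approx(1.0)
        assert consistency > agreement

    def test_fixed_matrix_matches_sums_of_squares_oracle(self):
        values = np.array([
            [70, 72, 75], [85, 80, 86], [92, 96, 90],
            [60, 65, 58], [110, 105, 112], [45, 50, 44],
        ], dtype=float)
        ours = icc_two_way_random(RaterMatrix(values))
        assert ours == pytest.approx(icc_agreement_oracle(values), abs=1e-10)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(2, 12), st.integers(2, 8), st.integers(0, 2**31 - 1))
    def test_random_matrices_match_oracle(self, n, k, seed):
        rng = np.random.default_rng(seed)
        subject = rng.normal(90, 25, size=(n, 1))
        rater = rng.normal(0, 5, size=(1, k))
        values = subject + rater + rng.normal(0, 8, size=(n, k))
        assert icc_two_way_random(RaterMatrix(values)) == pytest.approx(
            icc_agreement_oracle(values), abs=1e-10)

    def test_cross_check_against_pingouin(self):
        """ICC(2,1) and ICC(2,k) agree with the reference implementation."""
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(42)
        values = rng.normal(90, 20, size=(8, 8)).round(1)
        long = pd.DataFrame(
            [(i, j, values[i, j]) for i in range(8) for j in range(8)],
            columns=["subject", "rater", "score"],
        )
        table = pg.intraclass_corr(long, targets="subject", raters="rater",
                                   ratings="score")
        m = RaterMatrix(values)

        def lookup(*labels):
            rows = table.loc[table["Type"].isin(labels), "ICC"]
            assert len(rows) == 1
            return float(rows.iloc[0])

        icc21 = lookup("ICC2", "ICC(A,1)")   # two-way random, single, agreement
        icc2k = lookup("ICC2k", "ICC(A,k)")
        assert icc_two_way_random(m, "agreement", "single") == pytest.approx(icc21, abs=1e-9)
        assert icc_two_way_random(m, "agreement", "average") == pytest.approx(icc2k, abs=1e-9)

    def test_incomplete_or_tiny_matrix_rejected(self):
        with pytest.raises(InputError):
            RaterMatrix(np.array([[1.0, np.nan], [2.0, 3.0]]))
        with pytest.raises(InputError):
            icc_two_way_random(RaterMatrix(np.array([[1.0, 2.0]])))


class TestInterpretationBands:
    @pytest.mark.parametrize(
        "icc, label",
        [
            (0.85, "excellent"),
            (0.50, "good"),
            (0.805, "excellent"),  # the printed cutoffs leave 0.80-0.81 open
            (0.19, "unacceptable"),
            (0.20, "questionable"),
            (0.40, "good"),
            (0.60, "very good"),
            (0.80, "excellent"),
            (-0.3, "unacceptable"),
            (1.0, "excellent"),
        ],
    )
    def test_icc_bands(self, icc, label):
        assert interpret_icc(icc) == label

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(-5.0, 1.0, allow_nan=False))
    def test_icc_bands_total_over_domain(self, icc):
        assert interpret_icc(icc) in {
            "unacceptable", "questionable", "good", "very good", "excellent"}

    def test_icc_above_one_rejected(self):
        with pytest.raises(InputError):
            interpret_icc(1.1)

    @pytest.mark.parametrize(
        "cv, label",
        [(4.097, "low variability"), (9.999, "low variability"),
         (10.0, "moderate variability"), (19.9, "moderate variability"),
         (20.0, "high variability"), (55.0, "high variability")],
    )
    def test_cv_bands(self, cv, label):
        assert interpret_cv(cv) == label


class TestMeanCv:
    def test_identical_raters_give_zero(self):
        m = RaterMatrix(np.array([[90.0, 90.0, 90.0], [120.0, 120.0, 120.0]]))
        assert mean_cv(m) == 0.0

    def test_single_subject_hand_value(self):
        # sd([90,100,110]) = 10 (sample), mean = 100 -> CV 10%
        m = RaterMatrix(np.array([[90.0, 100.0, 110.0]]))
        assert mean_cv(m) == pytest.approx(10.0)

    def test_zero_mean_subject_is_undefined(self):
        m = RaterMatrix(np.array([[-5.0, 5.0], [10.0, 20.0]]))
        with pytest.raises(UndefinedStatisticError):
            mean_cv(m)


class TestPairedT:
    def test_zero_variance_differences_degenerate(self):
        with pytest.raises(UndefinedStatisticError):
            paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_symmetric_differences_give_t_zero_p_one(self):
        t, p = paired_t_test([0.0, 2.0], [1.0, 1.0])  # d = [-1, 1]
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_fixed_vectors_match_density_integration_oracle(self):
        x = np.array([171.0, 160.0, 155.0, 120.0, 99.0, 140.0, 162.0, 133.0])
        y = np.array([158.0, 155.0, 161.0, 105.0, 106.0, 131.0, 148.0, 130.0])
        t, p = paired_t_test(x, y)
        d = x - y
        t_hand = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        assert t == pytest.approx(t_hand, abs=1e-12)
        p_oracle = 2.0 * t_sf_oracle(abs(t_hand), len(d) - 1)
        assert p == pytest.approx(p_oracle, abs=1e-9)


class TestPowerSampleSize:
    def test_paired_design_normal_approximation(self):
        assert power_sample_size(5.0, 9.0, 0.05, 0.85) == 30

    def test_half_power_boundary(self):
        sd = 9.0
        z = 1.959964
        assert power_sample_size(z * sd, sd, 0.05, 0.5) == 1

    def test_t_method_is_slightly_conservative(self):
        n_norm = power_sample_size(5.0, 9.0, 0.05, 0.85)
        n_t = power_sample_size(5.0, 9.0, 0.05, 0.85, method="t")
        assert n_norm < n_t <= n_norm + 2

    def test_monotonicity_in_each_parameter(self):
        base = power_sample_size(5.0, 9.0, 0.05, 0.85)
        assert power_sample_size(10.0, 9.0, 0.05, 0.85) <= base  # larger delta
        assert power_sample_size(5.0, 18.0, 0.05, 0.85) >= base  # larger sd
        assert power_sample_size(5.0, 9.0, 0.05, 0.95) >= base  # more power
        assert power_sample_size(5.0, 9.0, 0.01, 0.85) >= base  # stricter alpha
        sds = [3.0, 6.0, 9.0, 12.0, 20.0]
        ns = [power_sample_size(5.0, sd, 0.05, 0.85) for sd in sds]
        assert ns == sorted(ns)

    @pytest.mark.parametrize(
        "kwargs",
        [{"delta": 0.0}, {"sd": -1.0}, {"alpha": 1.2}, {"power": 0.3},
         {"power": 1.0}, {"method": "bootstrap"}],
    )
    def test_domain_violations(self, kwargs):
        args = {"delta": 5.0, "sd": 9.0, "alpha": 0.05, "power": 0.85}
        args.update(kwargs)
        with pytest.raises(InputError):
            power_sample_size(**args)


class TestConsensusAndReports:
    def test_consensus_is_row_mean(self):
        m = RaterMatrix(np.array([[100.0, 110.0], [80.0, 90.0]]))
        assert list(consensus(m)) == [105.0, 85.0]
        single = RaterMatrix(np.array([[42.0], [37.0]]))
        assert list(consensus(single)) == [42.0, 37.0]

    def test_signed_difference_commutes_with_consensus(self):
        rng = np.random.default_rng(0)
        values = rng.normal(100, 15, size=(6, 4))
        ref = rng.normal(100, 15, size=6)
        m = RaterMatrix(values)
        via_consensus = mean_difference(consensus(m), ref, "signed")
        rater_wise = np.mean([
            mean_difference(values[:, j], ref, "signed") for j in range(4)])
        assert via_consensus == pytest.approx(rater_wise, abs=1e-12)
        # absolute differences do NOT commute in general
        abs_via = mean_difference(consensus(m), ref, "absolute")
        abs_rater = np.mean([
            mean_difference(values[:, j], ref, "absolute") for j in range(4)])
        assert abs_via <= abs_rater + 1e-12

    def test_compare_methods_report_is_consistent(self):
        rng = np.random.default_rng(1)
        x = rng.normal(100, 20, size=8)
        y = x + rng.normal(3, 5, size=8)
        rep = compare_methods(x, y)
        assert rep.icc_label == interpret_icc(rep.icc)
        assert rep.r_squared == pytest.approx(rep.pearson_r**2, abs=1e-12)
        assert rep.mean_difference >= abs(rep.mean_difference_signed)
        assert "ICC" in rep.summary()

    def test_identical_methods_degenerate_t_reported_as_none(self):
        x = np.array([10.0, 20.0, 30.0, 40.0])
        rep = compare_methods(x, x.copy())
        assert rep.icc == pytest.approx(1.0)
        assert rep.mean_difference == 0.0
        assert rep.t_statistic is None and rep.p_value is None

    def test_rater_reliability_recovers_generating_regime(self):
        """High subject variance + small rater noise -> high ICC, low CV."""
        rng = np.random.default_rng(2)
        values = rng.normal(100, 30, size=(8, 1)) + rng.normal(0, 3, size=(8, 8))
        rep = rater_reliability(RaterMatrix(values))
        assert rep.intraclass_cc > 0.9
        assert rep.icc_label == "excellent"
        assert rep.cv_label == "low variability"
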