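import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pocketgait as pg
from pocketgait.agreement import ICCType


def brute_force_passing_bablok_slope(x, y):
    """Independent oracle: explicit enumeration of all pairwise slopes with
    the shifted-median rule, written with plain loops."""
    slopes = []
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            if x[j] == x[i]:
                continue
            s = (y[j] - y[i]) / (x[j] - x[i])
            if s != -1.0:
                slopes.append(s)
    slopes.sort()
    n_s = len(slopes)
    k = sum(1 for s in slopes if s < -1.0)
    if n_s % 2 == 1:
        idx = (n_s + 1) // 2 + k - 1
        return slopes[min(max(idx, 0), n_s - 1)]
    lo = min(max(n_s // 2 + k - 1, 0), n_s - 1)
    hi = min(max(n_s // 2 + k, 0), n_s - 1)
    return 0.5 * (slopes[lo] + slopes[hi])


class TestPassingBablok:
    def test_identity_line(self):
        data = pg.PairedMeasurements(x=[1, 2, 3, 4], y=[1, 2, 3, 4])
        res = pg.passing_bablok(data)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0)

    def test_exact_proportionality(self):
        res = pg.passing_bablok(pg.PairedMeasurements(x=[1, 2, 3], y=[2, 4, 6]))
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 26)
        x = rng.uniform(0.8, 1.5, n)
        y = x + rng.normal(0, 0.05, n)
        data = pg.PairedMeasurements(x=x, y=y)
        res = pg.passing_bablok(data)
        oracle_slope = brute_force_passing_bablok_slope(list(x), list(y))
        assert res.slope == oracle_slope
        assert res.intercept == float(np.median(y - oracle_slope * x))

    def test_ci_brackets_point_estimates(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0.8, 1.5, 30)
        y = 1.1 * x + rng.normal(0, 0.03, 30)
        res = pg.passing_bablok(pg.PairedMeasurements(x=x, y=y))
        assert res.slope_ci[0] <= res.slope <= res.slope_ci[1]
        assert res.intercept_ci[0] <= res.intercept <= res.intercept_ci[1]

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.2, 5.0))
    def test_scale_equivariance(self, seed, c):
        # exact equivariance requires all pairwise slopes > -1 (so the
        # rank-shift K stays 0 on both scales); well-separated x with small
        # noise keeps every slope positive
        rng = np.random.default_rng(seed)
        x = np.linspace(1.0, 2.0, 15)
        y = x + rng.normal(0, 0.01, 15)
        base = pg.passing_bablok(pg.PairedMeasurements(x=x, y=y))
        scaled = pg.passing_bablok(pg.PairedMeasurements(x=x, y=c * y))
        assert scaled.slope == pytest.approx(c * base.slope, rel=1e-9)
        assert scaled.intercept == pytest.approx(c * base.intercept, rel=1e-9, abs=1e-12)

    def test_swap_property(self):
        # slope(y~x) * slope(x~y) = 1 when no slopes tie; needs an odd
        # slope count so the median is a single order statistic (n=22
        # gives C(22,2) = 231 pairwise slopes)
        rng = np.random.default_rng(8)
        x = rng.uniform(1.0, 2.0, 22)
        y = 1.3 * x + rng.normal(0, 0.08, 22)
        fwd = pg.passing_bablok(pg.PairedMeasurements(x=x, y=y)).slope
        rev = pg.passing_bablok(pg.PairedMeasurements(x=y, y=x)).slope
        assert fwd * rev == pytest.approx(1.0, rel=1e-9)

    def test_degenerate_x_rejected(self):
        with pytest.raises(pg.DegenerateInputError):
            pg.passing_bablok(pg.PairedMeasurements(x=[1.0, 1.0, 1.0], y=[1, 2, 3]))

    def test_too_few_pairs(self):
        with pytest.raises(pg.InsufficientDataError):
            pg.passing_bablok(pg.PairedMeasurements(x=[1.0, 2.0], y=[1.0, 2.0]))


class TestBlandAltman:
    def test_identical_methods_zero_bias(self):
        res = pg.bland_altman(pg.PairedMeasurements(x=[1.0, 2.0], y=[1.0, 2.0]))
        assert res.bias == 0.0
        assert res.loa_low == res.loa_high == 0.0

    def test_constant_offset(self):
        x = np.array([1.0, 1.1, 1.2, 1.3])
        res = pg.bland_altman(pg.PairedMeasurements(x=x, y=x + 0.1))
        assert res.bias == pytest.approx(0.1)
        assert res.sd == pytest.approx(0.0, abs=1e-12)
        assert res.loa_low == pytest.approx(0.1)
        assert res.loa_high == pytest.approx(0.1)

    def test_recovers_device_error_scale(self):
        # differences drawn at the validity-study error scale: 16.9 (SD 9.0) ms
        rng = np.random.default_rng(12)
        n = 50
        x = rng.uniform(0.9, 1.3, n)
        d = rng.normal(0.0169, 0.009, n)
        res = pg.bland_altman(pg.PairedMeasurements(x=x, y=x + d))
        se = 0.009 / np.sqrt(n)
        assert abs(res.bias - 0.0169) <= 3 * se
        assert res.loa_low <= res.bias <= res.loa_high

    def test_means_table_for_plot(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.1, 2.1, 2.9])
        res = pg.bland_altman(pg.PairedMeasurements(x=x, y=y))
        np.testing.assert_allclose(res.means, (x + y) / 2)
        np.testing.assert_allclose(res.diffs, y - x)

    def test_single_pair_insufficient(self):
        with pytest.raises(pg.InsufficientDataError):
            pg.bland_altman(pg.PairedMeasurements(x=[1.0], y=[1.0]))


def variance_components_icc(table):
    """Algebraic oracle: plug-in sigma_b^2 / (sigma_b^2 + sigma_w^2) from the
    same one-way ANOVA mean squares."""
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    row_means = table.mean(axis=1)
    msb = k * np.sum((row_means - table.mean()) ** 2) / (n - 1)
    msw = np.sum((table - row_means[:, None]) ** 2) / (n * (k - 1))
    sigma_b2 = (msb - msw) / k
    sigma_w2 = msw
    return sigma_b2 / (sigma_b2 + sigma_w2)


class TestICC:
    def test_perfect_agreement(self):
        table = np.array([[1, 1, 1], [2, 2, 2], [3, 3, 3]], dtype=float)
        res = pg.icc_oneway(table, ICCType.ICC_1_1)
        assert res.icc == 1.0
        assert res.ci_low == res.ci_high == 1.0
        assert res.p == 0.0

    def test_matches_variance_components_oracle(self):
        rng = np.random.default_rng(7)
        subjects = rng.normal(1.05, 0.15, 14)
        table = subjects[:, None] + rng.normal(0, 0.03, (14, 3))
        res = pg.icc_oneway(table, ICCType.ICC_1_1)
        assert res.icc == pytest.approx(variance_components_icc(table), abs=1e-12)

    def test_matches_pingouin(self):
        # independent published implementation as cross-check
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(17)
        subjects = rng.normal(1.05, 0.15, 12)
        table = subjects[:, None] + rng.normal(0, 0.04, (12, 3))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 3),
            "rater": np.tile(np.arange(3), 12),
            "score": table.ravel(),
        })
        ref = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                       ratings="score").set_index("Type")
        res11 = pg.icc_oneway(table, ICCType.ICC_1_1)
        res1k = pg.icc_oneway(table, ICCType.ICC_1_K)
        assert res11.icc == pytest.approx(ref.loc["ICC(1,1)", "ICC"], abs=1e-9)
        assert res1k.icc == pytest.approx(ref.loc["ICC(1,k)", "ICC"], abs=1e-9)
        assert res11.p == pytest.approx(ref.loc["ICC(1,1)", "pval"], rel=1e-6)
        # pingouin rounds its CI to 2 decimals
        np.testing.assert_allclose(
            [res11.ci_low, res11.ci_high], ref.loc["ICC(1,1)", "CI95"], atol=0.006)

    def test_null_simulation_unbiased(self):
        # iid noise columns: mean ICC(1,1) should sit within 3 SE of 0
        rng = np.random.default_rng(99)
        estimates = []
        for _ in range(1000):
            table = rng.normal(size=(8, 3))
            estimates.append(pg.icc_oneway(table, ICCType.ICC_1_1).icc)
        estimates = np.array(estimates)
        se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean()) <= 3 * se

    def test_icc1k_dominates_icc11_when_msb_exceeds_msw(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            table = rng.normal(0, 1, (10, 1))[:, [0] * 3] + rng.normal(0, 0.5, (10, 3))
            r11 = pg.icc_oneway(table, ICCType.ICC_1_1)
            r1k = pg.icc_oneway(table, ICCType.ICC_1_K)
            if r11.msb > r11.msw:
                assert r1k.icc >= r11.icc

    def test_all_identical_degenerate(self):
        with pytest.raises(pg.DegenerateInputError):
            pg.icc_oneway(np.full((5, 3), 2.0))

    def test_incomplete_table_rejected(self):
        table = np.ones((5, 3))
        table[4, 1] = 1.5
        table[2, 2] = np.nan
        with pytest.raises(pg.DegenerateInputError):
            pg.icc_oneway(table)


class TestCorrelationR2:
    def test_exact_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pg.correlation_r2(pg.PairedMeasurements(x=x, y=2 * x + 1)) \
            == pytest.approx(1.0)

    def test_anticorrelated_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pg.correlation_r2(pg.PairedMeasurements(x=x, y=-3 * x + 2)) \
            == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        x = np.array([1.0, 1.1, 0.9, 1.2, 1.05, 0.95, 1.15, 1.0, 1.3, 0.85])
        y = np.array([1.02, 1.09, 0.93, 1.18, 1.07, 0.97, 1.12, 1.01, 1.28, 0.88])
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        oracle = sxy ** 2 / (np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert pg.correlation_r2(pg.PairedMeasurements(x=x, y=y)) \
            == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_degenerate(self):
        with pytest.raises(pg.DegenerateInputError):
            pg.correlation_r2(pg.PairedMeasurements(x=[1.0, 1.0, 1.0], y=[1, 2, 3]))


class TestStrideMatching:
    def test_one_to_one_within_window(self):
        ref = np.array([1.0, 2.0, 3.0, 4.0])
        test = np.array([1.05, 2.1, 3.02, 5.5])
        pairs = pg.match_events(test, ref, window_s=0.25)
        assert pairs == [(0, 0), (1, 1), (2, 2)]

    def test_paired_stride_times_from_offset_stream(self):
        rng = np.random.default_rng(31)
        ref = 0.5 + np.cumsum(rng.uniform(0.95, 1.15, 20))
        test = ref + rng.normal(0.017, 0.009, 20)
        data = pg.paired_stride_times(hs_test=test, hs_ref=ref)
        assert len(data) == 19
        np.testing.assert_allclose(data.x, np.diff(ref))
        np.testing.assert_allclose(data.y, np.diff(test))

    def test_disjoint_streams_insufficient(self):
        with pytest.raises(pg.InsufficientDataError):
            pg.paired_stride_times(hs_test=np.arange(5.0),
                                   hs_ref=np.arange(5.0) + 100.0)


class TestReliabilityHarness:
    def test_study_design_recovers_excellent_reliability(self):
        # trial-level design: 14 subjects, between-SD 0.16 s, within-SD 0.04 s
        n_good = 0
        reps = 200
        for rep in range(reps):
            df = pg.simulate_study(n_subjects=14, visits=2, trials_per_visit=3,
                                   between_subject_sd=0.16, within_subject_sd=0.04,
                                   dtc_percent=12.0, seed=rep)
            one_visit = df[(df.visit == 1) & (df.condition == "normal")]
            table = one_visit.pivot_table(index="participant", columns="trial",
                                          values="mean_stride_time").to_numpy()
            if pg.icc_oneway(table, ICCType.ICC_1_1).icc > 0.80:
                n_good += 1
        assert n_good >= 0.95 * reps
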