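"""Statistical battery: t tests, Mann-Whitney, correlation, ICC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hepamri.stats import (
    DEFAULT_TEST_ROUTING,
    build_report,
    correlate,
    icc_two_way,
    independent_t,
    mann_whitney,
    mann_whitney_z_uncorrected,
    percent_change,
    t_from_summaries,
)


class TestTTests:
    def test_summary_t_matches_raw_t(self, rng):
        a = rng.normal(10, 2, 12)
        b = rng.normal(8, 3, 9)
        raw = independent_t(a, b)
        summ = t_from_summaries(
            a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
        )
        assert summ.statistic == pytest.approx(raw.statistic, rel=1e-12)
        assert summ.p_value == pytest.approx(raw.p_value, rel=1e-12)

    def test_group_summary_t_values(self):
        # pooled t from the default group summaries, n = 10 per group
        cases = [
            ((30.44, 2.80), (19.97, 3.39), 7.530),   # perfusion fraction
            ((32.33e-3, 8.87e-3), (22.99e-3, 1.59e-3), 3.278),
            ((88.89, 12.77), (119.34, 7.53), -6.495),
            ((2.06, 0.34), (3.44, 0.43), -7.961),    # MDA
        ]
        for (m1, s1), (m2, s2), expected in cases:
            res = t_from_summaries(m1, s1, 10, m2, s2, 10)
            assert res.statistic == pytest.approx(expected, abs=2e-3)
            assert res.p_value < 0.01

    def test_sign_convention(self):
        res = t_from_summaries(5.0, 1.0, 10, 3.0, 1.0, 10)
        assert res.statistic > 0

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            independent_t([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            t_from_summaries(1.0, 0.0, 10, 2.0, 1.0, 10)
        res = independent_t([2.0, 2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0


class TestMannWhitney:
    def test_u_convention_extremes(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.estimate == 0.0
        res = mann_whitney([4, 5, 6], [1, 2, 3])
        assert res.estimate == 9.0

    def test_identical_multisets_give_half_u(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.estimate == pytest.approx(4.5)
        assert res.statistic == 0.0

    def test_uncorrected_z_closed_form(self):
        # U = 0, n1 = n2 = 3: Z = (0 - 4.5) / sqrt(9*7/12) = -1.9640
        z = mann_whitney_z_uncorrected([1, 2, 3], [4, 5, 6])
        assert z == pytest.approx(-1.9640, abs=1e-4)

    def test_asymptotic_matches_scipy_with_corrections(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.8, 1, 12)
        res = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        # scipy reports U for the same group with the same corrections
        assert res.estimate == pytest.approx(float(ref.statistic))
        assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_exact_matches_scipy(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(1, 1, 7)
        res = mann_whitney(a, b, method="exact")
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-12)

    def test_tie_correction_applied(self):
        a = [1, 1, 2, 2, 3]
        b = [2, 3, 3, 4, 4]
        res = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_constant_pooled_sample(self):
        res = mann_whitney([5, 5], [5, 5, 5])
        assert res.p_value == 1.0


class TestCorrelation:
    def test_spearman_worked_example(self):
        # ranks x = (1..5), y = (2,1,4,3,5): sum d^2 = 4 -> rho = 0.8
        res = correlate([1, 2, 3, 4, 5], [2, 1, 4, 3, 5], "spearman")
        assert res.estimate == pytest.approx(0.8, abs=1e-12)

    def test_pearson_linear(self):
        x = np.arange(10.0)
        res = correlate(x, 3.0 * x + 1.0, "pearson")
        assert res.estimate == pytest.approx(1.0)

    def test_monotone_nonlinear_spearman_one(self):
        x = np.arange(1.0, 11.0)
        res = correlate(x, np.exp(x), "spearman")
        assert res.estimate == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        res = correlate([1, 1, 1], [1, 2, 3])
        assert np.isnan(res.estimate)


class TestICC:
    def test_perfect_agreement(self):
        r = icc_two_way([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert r.icc == 1.0

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.normal(30, 3, 20)
        y = x + rng.normal(0, 1.0, 20) + 0.5
        r = icc_two_way(x, y)
        n = x.size
        frame = pd.DataFrame({
            "subject": np.tile(np.arange(n), 2),
            "rater": np.repeat([1, 2], n),
            "score": np.concatenate([x, y]),
        })
        ref = pg.intraclass_corr(
            frame, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        # ICC(A,1) is the two-way absolute-agreement single-measure form
        assert r.icc == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-9)
        lo, hi = ref.loc["ICC(A,1)", "CI95"]
        # pingouin rounds its interval to two decimals
        assert r.ci_low == pytest.approx(lo, abs=5e-3)
        assert r.ci_high == pytest.approx(hi, abs=5e-3)

    def test_noise_lowers_icc(self, rng):
        x = rng.normal(0, 1, 30)
        near = icc_two_way(x, x + rng.normal(0, 0.05, 30))
        far = icc_two_way(x, x + rng.normal(0, 1.0, 30))
        assert near.icc > 0.95
        assert far.icc < near.icc

    def test_systematic_offset_penalized(self, rng):
        """Absolute-agreement ICC drops under a constant rater offset even
        with perfect consistency."""
        x = rng.normal(0, 1, 30)
        assert icc_two_way(x, x + 2.0).icc < 0.5

    def test_degenerate_constant_series(self):
        r = icc_two_way([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert r.degenerate

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            icc_two_way([1.0, 2.0], [1.0, 2.0])


class TestPercentChange:
    def test_worked_decrease(self):
        # control mean 30.44, model value 19.97 -> 34.40 % decrease
        m, s = percent_change([30.44, 30.44], [19.97, 19.97], "decrease")
        assert m == pytest.approx(34.40, abs=5e-3)
        assert s == pytest.approx(0.0, abs=1e-12)

    def test_increase_direction_flips_sign(self):
        m_dec, _ = percent_change([100.0, 100.0], [120.0, 130.0], "decrease")
        m_inc, _ = percent_change([100.0, 100.0], [120.0, 130.0], "increase")
        assert m_inc == pytest.approx(-m_dec) == pytest.approx(25.0)

    def test_zero_control_mean_rejected(self):
        with pytest.raises(ValueError):
            percent_change([1.0, -1.0], [2.0])


class TestReport:
    def _cohort(self, rng, n=10):
        rows = []
        for g, means in (("control", 1.0), ("model", 2.0)):
            for i in range(n):
                row = {"id": f"{g}-{i}", "group": g}
                for v in DEFAULT_TEST_ROUTING:
                    base = means if v != "I_score" else (0 if g == "control" else 1)
                    row[v] = float(base) + rng.normal(0, 0.1)
                row["I_score"] = 0 if g == "control" else int(rng.integers(3))
                row["F_score"] = 0 if g == "control" else int(rng.integers(3))
                for v in ("Dslow", "Dfast", "PF", "MD", "FA", "R2star"):
                    row[f"{v}_obs1"] = row[v]
                    row[f"{v}_obs2"] = row[v] + rng.normal(0, 0.02)
                rows.append(row)
        return pd.DataFrame(rows)

    def test_report_structure_and_routing(self, rng):
        report = build_report(self._cohort(rng), observer_cols=("_obs1", "_obs2"))
        comp = report["group_comparison"].set_index("variable")
        assert comp.loc["PF", "test"] == "t"
        assert comp.loc["ALT", "test"] == "mann_whitney"
        assert comp.loc["I_score", "test"] == "mann_whitney"
        assert set(report) == {
            "group_comparison", "correlations", "percent_change", "icc"
        }
        assert len(report["correlations"]) == 6 * 8
        assert list(report["percent_change"]["variable"]) == [
            "Dfast", "PF", "R2star"
        ]
        icc = report["icc"].set_index("variable")
        assert (icc["icc"] > 0.9).all()

    def test_routing_override(self, rng):
        report = build_report(self._cohort(rng), routing={"PF": "mann_whitney"})
        comp = report["group_comparison"].set_index("variable")
        assert comp.loc["PF", "test"] == "mann_whitney"
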