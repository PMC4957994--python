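"""Across-species statistics: t-tests, trend contrast, Holm, summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from winterniche import (
    holm_flags,
    meta_report,
    one_sample_t,
    paired_t,
    pearson_corr,
    per_species_tmean_tests,
    species_filter,
    summarize_table1,
    trend_contrast,
)
from winterniche.synthetic_data import SpeciesSurvey, TemperatureField


def make_survey(sid, detections, n_transects=60):
    det = np.asarray(detections, dtype=int)
    return SpeciesSurvey(sid, np.arange(det.size), det, n_transects)


class TestSpeciesFilter:
    def test_cell_count_threshold(self):
        sparse = make_survey("sparse", [30] * 49 + [0] * 51)  # 49 occupied cells
        dense = make_survey("dense", [30] * 50 + [0] * 50)
        kept = species_filter([sparse, dense])
        assert [s.species_id for s in kept] == ["dense"]

    def test_max_frequency_boundary(self):
        # max 3/60 = 0.05 is retained: only strictly lower frequencies drop out
        at_limit = make_survey("at_limit", [3] * 60)
        below = make_survey("below", [2] * 60)
        kept = species_filter([at_limit, below])
        assert [s.species_id for s in kept] == ["at_limit"]

    def test_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        surveys = [
            make_survey(f"sp{i}", rng.binomial(60, rng.uniform(0, 0.08), 120))
            for i in range(20)
        ]
        kept = {s.species_id for s in species_filter(surveys)}
        expected = {
            s.species_id
            for s in surveys
            if np.count_nonzero(s.detections) >= 50 and s.detections.max() >= 3
        }
        assert kept == expected


class TestTTests:
    def test_mean_equals_mu0(self):
        assert one_sample_t([1.0, 2.0, 3.0], 2.0).statistic == pytest.approx(0.0)

    def test_hand_formula(self):
        # mean 1, sd sqrt(2), se 1 -> t = 1
        r = one_sample_t([0.0, 2.0], 0.0)
        assert r.statistic == pytest.approx(1.0)
        assert r.df == 1

    def test_matches_scipy_on_random_instances(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            x = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(5, 60))
            mu0 = rng.uniform(-1, 1)
            mine = one_sample_t(x, mu0)
            ref = stats.ttest_1samp(x, mu0)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([1.0, 1.0, 1.0], 0.0)

    def test_paired_identity(self):
        rng = np.random.default_rng(29)
        x, y = rng.normal(size=40), rng.normal(size=40)
        assert paired_t(x, y).statistic == pytest.approx(
            one_sample_t(x - y, 0.0).statistic
        )
        assert paired_t(x, x.copy()).statistic == pytest.approx(0.0)

    def test_paired_constant_difference_degenerate(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])

    def test_type_one_error_calibrated(self):
        # under the null the test should reject ~alpha of the time
        rng = np.random.default_rng(31)
        rejections = sum(
            one_sample_t(rng.normal(0, 1, 20), 0.0).p_value < 0.05
            for _ in range(2000)
        )
        lo, hi = stats.binom.interval(0.999, 2000, 0.05)
        assert lo <= rejections <= hi


class TestTrendContrast:
    LEVELS = (0.50, 0.75, 0.90, 0.95)

    def test_constant_rows_give_zero(self):
        m = np.tile([[0.2, 0.2, 0.2, 0.2]], (10, 1)) + np.arange(10)[:, None] * 0.01
        r = trend_contrast(m, self.LEVELS)
        assert r.statistic == pytest.approx(0.0, abs=1e-20)

    def test_f_equals_t_squared(self):
        rng = np.random.default_rng(37)
        m = rng.uniform(0, 0.3, size=(25, 4))
        r = trend_contrast(m, self.LEVELS)
        scores = m @ (np.array(self.LEVELS) - np.mean(self.LEVELS))
        t = one_sample_t(scores, 0.0)
        assert r.statistic == pytest.approx(t.statistic**2, rel=1e-12)
        assert r.df == (1, 24)
        assert r.p_value == pytest.approx(t.p_value, rel=1e-9)

    def test_rising_pseudo_r2_detected(self):
        rng = np.random.default_rng(41)
        base = rng.uniform(0.0, 0.1, size=(30, 1))
        m = base + np.array([0.0, 0.02, 0.05, 0.08]) + rng.normal(0, 0.005, (30, 4))
        r = trend_contrast(m, self.LEVELS)
        assert r.p_value < 1e-6 and r.statistic > 0

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError):
            trend_contrast(np.ones((5, 4)), self.LEVELS, weights=[1, 0, 0, 0])


class TestHolm:
    def test_single_test(self):
        assert holm_flags([0.01]).tolist() == [True]

    def test_two_step_example(self):
        # 0.01 <= 0.05/2, then 0.04 <= 0.05/1: both significant
        assert holm_flags([0.01, 0.04]).tolist() == [True, True]
        # 0.03 > 0.05/2 stops immediately
        assert holm_flags([0.03, 0.04]).tolist() == [False, False]

    def test_monotone_flags(self):
        rng = np.random.default_rng(43)
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(2, 30))
            flags = holm_flags(p)
            if flags.any():
                assert flags[p <= p[flags].max()].all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(47)
        for _ in range(200):
            p = rng.uniform(0, 1, rng.integers(1, 40)) ** rng.uniform(0.5, 3)
            mine = holm_flags(p)
            ref = multipletests(p, alpha=0.05, method="holm")[0]
            np.testing.assert_array_equal(mine, ref)


class TestPerSpeciesTMean:
    def test_counts_partition(self):
        rng = np.random.default_rng(53)
        t = rng.uniform(-2, 10, 150)
        field = TemperatureField(np.arange(150), t)
        surveys = []
        for i in range(12):
            det = rng.binomial(60, rng.uniform(0.02, 0.4), 150)
            surveys.append(SpeciesSurvey(f"sp{i}", np.arange(150), det))
        surveys.append(SpeciesSurvey("empty", np.arange(150), np.zeros(150, int)))
        res = per_species_tmean_tests(surveys, field, regional_mean=t.mean())
        e = res.extra
        assert (
            e["n_colder"] + e["n_warmer"] + e["n_nonsignificant"] + len(e["skipped"])
            == res.n == 13
        )
        assert "empty" in e["skipped"]

    def test_null_calibration(self):
        # species occupying random cells have no thermal preference: after
        # Holm essentially none should be flagged
        rng = np.random.default_rng(59)
        t = rng.uniform(-2, 10, 400)
        field = TemperatureField(np.arange(400), t)
        flagged = 0
        total = 0
        for rep in range(10):
            surveys = [
                SpeciesSurvey(
                    f"r{rep}s{i}",
                    np.arange(400),
                    rng.binomial(60, np.full(400, 0.1)),
                )
                for i in range(10)
            ]
            res = per_species_tmean_tests(surveys, field, regional_mean=t.mean())
            flagged += res.extra["n_significant"]
            total += 10
        assert flagged / total <= 0.05

    def test_weighted_variant_runs(self):
        rng = np.random.default_rng(61)
        t = rng.uniform(-2, 10, 100)
        field = TemperatureField(np.arange(100), t)
        s = SpeciesSurvey("sp", np.arange(100), rng.binomial(60, 0.2, 100))
        res = per_species_tmean_tests([s], field, regional_mean=4.0, weighted=True)
        assert res.n == 1


class TestPearson:
    def test_perfect_line(self):
        x = np.arange(10.0)
        assert pearson_corr(x, 2 * x + 1).statistic == pytest.approx(1.0)

    def test_orthogonal(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])
        assert pearson_corr(x, y).statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(67)
        for _ in range(100):
            n = rng.integers(4, 50)
            x, y = rng.normal(size=n), rng.normal(size=n)
            mine = pearson_corr(x, y)
            ref = stats.pearsonr(x, y)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)


class TestSummaries:
    @staticmethod
    def toy_table():
        return pd.DataFrame(
            {
                "species_id": ["s1", "s2", "s3"],
                "b": [2.0, 4.0, -1.0],
                "c": [-1.0, -2.0, 0.5],
                "delta_aic": [-20.0, -15.0, -5.0],  # s3 not supported
                "pseudo_r2": [0.10, 0.20, 0.01],
                "t_pref": [6.0, 3.0, 4.0],
                "t_mean": [3.0, 2.0, 4.0],
                "t_breadth": [0.5, 0.4, 0.95],
            }
        )

    def test_hand_computed_summary(self):
        tab = summarize_table1(self.toy_table()).set_index("parameter")
        # b over the two supported species: mean 3, sd sqrt(2)
        assert tab.loc["b", "mean"] == pytest.approx(3.0)
        assert tab.loc["b", "sd"] == pytest.approx(np.sqrt(2.0))
        assert tab.loc["b", "n"] == 2
        # t_mean over all three species
        assert tab.loc["t_mean", "mean"] == pytest.approx(3.0)
        assert tab.loc["t_mean", "n"] == 3
        assert tab.loc["t_pref", "min"] == 3.0 and tab.loc["t_pref", "max"] == 6.0

    def test_single_species_sd_undefined(self):
        tab = summarize_table1(self.toy_table().iloc[:1]).set_index("parameter")
        assert np.isnan(tab.loc["b", "sd"])
        assert tab.loc["b", "mean"] == 2.0

    def test_meta_report_counts(self):
        rng = np.random.default_rng(71)
        n = 30
        table = pd.DataFrame(
            {
                "species_id": [f"s{i}" for i in range(n)],
                "b": rng.normal(3, 5, n),
                "c": rng.normal(-1, 3, n),
                "delta_aic": rng.uniform(-60, 5, n),
                "pseudo_r2": rng.uniform(0, 0.3, n),
                "t_pref": rng.uniform(-2, 10, n),
                "t_mean": rng.uniform(0, 5, n),
                "t_breadth": rng.uniform(0.26, 1.0, n),
            }
        )
        report = meta_report(table, regional_mean=2.55)
        counts = report["counts"]
        sig = table[table["delta_aic"] <= -13.82]
        assert counts["n_significant_models"] == len(sig)
        assert counts["n_tpref_cold"] == int((sig["t_pref"] < 0).sum())
        names = [t.name for t in report["tests"]]
        assert "r(T_PREF, T_MEAN)" in names
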