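"""Time-to-onset: date arithmetic, Weibull recovery, classification, rank test."""

import datetime as dt
import math

import numpy as np
import pytest
from scipy import stats

from conftest import make_record
from pvsignal.tto import (
    SmallSampleError,
    TTOSample,
    WeibullFit,
    WeibullFitError,
    classify_failure,
    compare_medians,
    compute_tto,
    cumulative_curves,
    fit_weibull,
)


def _sample(values, drug="aspirin"):
    return TTOSample(drug=drug, onsets_days=np.asarray(values, dtype=float))


def _weibull_draws(alpha, beta, n, seed):
    rng = np.random.default_rng(seed)
    return alpha * rng.weibull(beta, size=n)


class TestComputeTto:
    def test_whole_day_interval(self):
        rec = make_record("C1", start=dt.date(2020, 1, 1),
                          event=dt.date(2020, 1, 15))
        s = compute_tto([rec], "aspirin")
        assert list(s.onsets_days) == [14.0]

    def test_negative_interval_excluded_with_reason(self):
        rec = make_record("C1", start=dt.date(2020, 5, 1),
                          event=dt.date(2020, 1, 15))
        s = compute_tto([rec], "aspirin")
        assert s.n == 0 and s.exclusion_reasons == {"negative interval": 1}

    def test_missing_dates_tallied(self):
        recs = [make_record("C1", start=None, event=dt.date(2020, 1, 15)),
                make_record("C2", start=dt.date(2020, 1, 1), event=None)]
        s = compute_tto(recs, "aspirin")
        assert s.n == 0 and s.n_excluded == 2
        assert s.exclusion_reasons == {"missing start date": 1,
                                       "missing event date": 1}

    def test_zero_day_policy(self):
        rec = make_record("C1", start=dt.date(2020, 1, 1),
                          event=dt.date(2020, 1, 1))
        assert list(compute_tto([rec], "aspirin").onsets_days) == [0.5]
        excl = compute_tto([rec], "aspirin", zero_day_policy="exclude")
        assert excl.n == 0 and excl.exclusion_reasons == {"zero-day interval": 1}

    def test_generator_truth_roundtrip(self):
        from pvsignal.ingest import deduplicate, select_analysis_set
        from pvsignal.records import AnalysisConfig
        from pvsignal.synthetic import default_config, generate_corpus
        cfg = default_config(
            n_reports=5000, seed=21, dup_rate=0.0,
            missing_rates={"age": 0, "sex": 0, "event_date": 0, "start_date": 0})
        records, truth = generate_corpus(cfg, return_truth=True)
        sel = select_analysis_set(deduplicate(records), AnalysisConfig())
        s = compute_tto(sel.per_drug["aspirin"], "aspirin")
        expected = sorted(
            max(0.5, math.floor(truth[r.case_id]["onset_raw_days"] + 0.5))
            for r in sel.per_drug["aspirin"])
        assert sorted(s.onsets_days) == expected


class TestFitWeibull:
    def test_parameter_recovery(self):
        s = _sample(_weibull_draws(100.0, 0.6, 500, seed=30))
        fit = fit_weibull(s)
        assert 0.5 < fit.beta < 0.7
        assert 85 < fit.alpha < 115
        assert fit.beta_ci[0] < fit.beta < fit.beta_ci[1]
        assert fit.alpha_ci[0] < fit.alpha < fit.alpha_ci[1]

    def test_exponential_shape_ci_contains_one(self):
        s = _sample(_weibull_draws(50.0, 1.0, 1000, seed=31))
        fit = fit_weibull(s)
        assert fit.beta_ci[0] < 1.0 < fit.beta_ci[1]
        assert fit.failure_type == "random failure"

    def test_small_sample_refused(self):
        with pytest.raises(SmallSampleError):
            fit_weibull(_sample(range(1, 9)))

    def test_degenerate_sample_is_fit_error(self):
        with pytest.raises(WeibullFitError):
            fit_weibull(_sample([7.0] * 50))

    def test_median_identity_on_well_specified_data(self):
        s = _sample(_weibull_draws(200.0, 0.8, 2000, seed=32))
        fit = fit_weibull(s)
        model_median = fit.alpha * math.log(2) ** (1 / fit.beta)
        # bootstrap interval of the empirical median
        rng = np.random.default_rng(33)
        boots = [np.median(rng.choice(s.onsets_days, size=s.n))
                 for _ in range(500)]
        lo, hi = np.percentile(boots, [0.5, 99.5])
        assert lo < model_median < hi

    def test_agrees_with_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        s = _sample(_weibull_draws(120.0, 0.7, 400, seed=34))
        fit = fit_weibull(s)
        wf = lifelines.WeibullFitter().fit(s.onsets_days)
        assert fit.alpha == pytest.approx(wf.lambda_, rel=1e-3)
        assert fit.beta == pytest.approx(wf.rho_, rel=1e-3)

    def test_bootstrap_ci_close_to_asymptotic(self):
        s = _sample(_weibull_draws(80.0, 0.9, 300, seed=35))
        asym = fit_weibull(s)
        boot = fit_weibull(s, ci_method="bootstrap", n_boot=200, seed=1)
        assert boot.beta_ci[0] == pytest.approx(asym.beta_ci[0], rel=0.15)
        assert boot.beta_ci[1] == pytest.approx(asym.beta_ci[1], rel=0.15)


@pytest.mark.parametrize("beta, ci, expected", [
    (0.62, (0.54, 0.71), "early failure"),
    (1.02, (0.91, 1.14), "random failure"),
    (1.40, (1.21, 1.62), "wear-out failure"),
    (0.95, (0.88, 1.01), "random failure"),
])
def test_failure_classification_rules(beta, ci, expected):
    fit = WeibullFit(drug="x", alpha=100, alpha_ci=(80, 120), beta=beta,
                     beta_ci=ci, failure_type="", median_days=0,
                     iqr_days=(0, 0), n=100)
    assert classify_failure(fit) == expected


class TestCompareMedians:
    def test_identical_groups_no_separation(self):
        h, dof, p = compare_medians({"a": _sample([5, 5, 5]),
                                     "b": _sample([5, 5, 5], "b")})
        assert h == 0.0 and dof == 1 and p == 1.0

    def test_mirrored_groups_give_zero_h(self):
        h, _, p = compare_medians({"a": _sample([1, 2, 3]),
                                   "b": _sample([1, 2, 3], "b")})
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_three_groups_match_rank_brute_force(self):
        rng = np.random.default_rng(40)
        groups = [rng.integers(0, 30, size=m).astype(float)
                  for m in (17, 23, 11)]
        h, dof, p = compare_medians(
            {f"g{i}": _sample(g, f"g{i}") for i, g in enumerate(groups)})
        # rank-based brute force with tie correction
        pooled = np.concatenate(groups)
        ranks = stats.rankdata(pooled)
        n = len(pooled)
        start, h_bf = 0, 0.0
        for g in groups:
            r = ranks[start:start + len(g)]
            h_bf += r.sum() ** 2 / len(g)
            start += len(g)
        h_bf = 12 / (n * (n + 1)) * h_bf - 3 * (n + 1)
        _, counts = np.unique(pooled, return_counts=True)
        h_bf /= 1 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
        assert h == pytest.approx(h_bf, abs=1e-9)
        assert dof == 2
        assert p == pytest.approx(stats.chi2.sf(h_bf, 2), rel=1e-9)

    def test_separated_weibulls_highly_significant(self):
        short = _sample(_weibull_draws(66.32, 0.51, 100, seed=41), "ticagrelor")
        long = _sample(_weibull_draws(930.29, 0.62, 100, seed=42), "aspirin")
        _, _, p = compare_medians({"ticagrelor": short, "aspirin": long})
        assert p < 0.001

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_medians({"a": _sample([1, 2])})


class TestCumulativeCurves:
    def test_three_point_curve(self):
        df = cumulative_curves({"a": _sample([1, 2, 3])})
        assert list(zip(df.days, df.cum_prop)) == [
            (1.0, pytest.approx(1 / 3)), (2.0, pytest.approx(2 / 3)), (3.0, 1.0)]

    def test_monotone_and_terminal_one(self):
        draws = _weibull_draws(50.0, 0.7, 500, seed=43)
        df = cumulative_curves({"a": _sample(draws)})
        assert (df.cum_prop.diff().dropna() > 0).all()
        assert df.cum_prop.iloc[-1] == 1.0

    def test_ecdf_close_to_theoretical_cdf(self):
        alpha, beta = 75.0, 0.8
        draws = _weibull_draws(alpha, beta, 1000, seed=44)
        res = stats.kstest(draws, "weibull_min", args=(beta, 0, alpha))
        assert res.pvalue > 0.01
        # the exported curve is exactly the ECDF the KS statistic refers to
        df = cumulative_curves({"a": _sample(draws)})
        theo = 1 - np.exp(-(df.days / alpha) ** beta)
        assert np.max(np.abs(df.cum_prop - theo)) == pytest.approx(
            res.statistic, abs=1 / 1000)
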