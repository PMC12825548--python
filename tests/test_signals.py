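"""Four-grid statistics against independent oracles and structural properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from conftest import make_record
from pvsignal.records import AnalysisConfig
from pvsignal.signals import (
    ContingencyTable,
    GammaMixturePrior,
    bcpnn_ic,
    build_mgps_grid,
    build_table,
    ebgm_from_posterior,
    evaluate_signal,
    fit_gamma_mixture,
    ic_category,
    prr,
    pt_level_matrix,
    ror,
)
from pvsignal.ingest import deduplicate, select_analysis_set
from pvsignal.synthetic import default_config, generate_corpus


# --- independent closed-form oracle (plain-formula evaluation) -------------

def oracle_ror(a, b, c, d):
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    est = a * d / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    return est, est * math.exp(-z * se), est * math.exp(z * se)


def oracle_prr(a, b, c, d):
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    est = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    z = stats.norm.ppf(0.975)
    return est, est * math.exp(-z * se), est * math.exp(z * se)


def oracle_ic(a, b, c, d):
    n = a + b + c + d
    c1, k1 = a + b, a + c
    gamma = (n + 2.0) * (n + 2.0) / ((c1 + 1.0) * (k1 + 1.0))
    e_ic = math.log2((a + 1.0) * (n + 2.0) * (n + 2.0)
                     / ((n + gamma) * (c1 + 1.0) * (k1 + 1.0)))
    v_ic = ((n - a + gamma - 1.0) / ((a + 1.0) * (1 + n + gamma))
            + (n - c1 + 1.0) / ((c1 + 1.0) * (3 + n))
            + (n - k1 + 1.0) / ((k1 + 1.0) * (3 + n))) / math.log(2) ** 2
    return e_ic, e_ic - 2 * math.sqrt(v_ic)


# --- table construction ----------------------------------------------------

class TestBuildTable:
    def test_four_record_enumeration(self, tiny_corpus):
        t = build_table(tiny_corpus, "aspirin", {"Subdural hematoma"})
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_matches_brute_force_double_loop(self, analysis_config):
        corpus = deduplicate(generate_corpus(default_config(n_reports=2000, seed=2)))
        pts = analysis_config.target_pt_set
        for unit in ("case", "drug-event-pair"):
            t = build_table(corpus, "clopidogrel", pts, unit)
            a = b = c = d = 0
            for r in corpus:
                exposed = "clopidogrel" in r.primary_suspects()
                if unit == "case":
                    hit = bool(r.reactions & pts)
                    a += exposed and hit
                    b += exposed and not hit
                    c += (not exposed) and hit
                    d += (not exposed) and not hit
                else:
                    for pt in r.reactions:
                        hit = pt in pts
                        a += exposed and hit
                        b += exposed and not hit
                        c += (not exposed) and hit
                        d += (not exposed) and not hit
            assert (t.a, t.b, t.c, t.d) == (a, b, c, d)

    def test_per_pt_a_sums_dominate_full_set(self, analysis_config):
        """Records carrying several target PTs count once for the full set
        but once per PT in per-PT tables."""
        corpus = deduplicate(generate_corpus(default_config(n_reports=3000, seed=4)))
        full = build_table(corpus, "aspirin", analysis_config.target_pt_set)
        per_pt_sum = sum(
            build_table(corpus, "aspirin", {pt}).a
            for pt in analysis_config.target_pt_set)
        assert per_pt_sum >= full.a

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_table([], "aspirin", {"Subdural hematoma"})

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 5)


# --- ROR / PRR -------------------------------------------------------------

class TestRorPrr:
    def test_symmetric_table_gives_unity(self):
        t = ContingencyTable(10, 10, 10, 10)
        assert ror(t)[0] == pytest.approx(1.0)
        assert prr(t)[0] == pytest.approx(1.0)

    def test_worked_example_against_closed_form(self):
        t = ContingencyTable(25, 75, 100, 900)
        est, lo, hi = ror(t)
        assert est == pytest.approx(3.0)
        o = oracle_ror(25, 75, 100, 900)
        assert (est, lo, hi) == pytest.approx(o, rel=1e-12)
        assert (lo, hi) == pytest.approx((1.82, 4.94), abs=0.01)

        est, lo, hi = prr(t)
        assert est == pytest.approx(2.5)  # 0.25 / 0.10
        assert (est, lo, hi) == pytest.approx(oracle_prr(25, 75, 100, 900), rel=1e-12)

    def test_ror_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a, b, c, d = rng.integers(1, 1000, size=4)
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            assert ror(t)[0] * (b * c) == pytest.approx(a * d, rel=1e-9)

    def test_zero_cell_continuity_correction(self):
        est, lo, hi = ror(ContingencyTable(0, 10, 10, 100))
        assert 0 < est < 1 and lo > 0 and math.isfinite(hi)


# --- BCPNN -----------------------------------------------------------------

class TestBcpnn:
    def test_independence_limit(self):
        ic, _ = bcpnn_ic(ContingencyTable(100, 900, 900, 8100))
        assert abs(ic) < 0.05

    def test_closed_form_oracle(self):
        t = ContingencyTable(25, 75, 100, 900)
        assert bcpnn_ic(t) == pytest.approx(oracle_ic(25, 75, 100, 900), rel=1e-12)

    def test_monotone_in_a(self):
        ics = [bcpnn_ic(ContingencyTable(a, 50, 50, 1000))[0]
               for a in range(0, 40, 5)]
        assert all(x < y for x, y in zip(ics, ics[1:]))

    def test_defined_for_zero_cells(self):
        ic, ic025 = bcpnn_ic(ContingencyTable(0, 10, 0, 100))
        assert math.isfinite(ic) and math.isfinite(ic025)

    @given(st.integers(0, 500), st.integers(0, 500),
           st.integers(0, 500), st.integers(1, 500))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_ic025_below_ic_everywhere(self, a, b, c, d):
        ic, ic025 = bcpnn_ic(ContingencyTable(a, b, c, d))
        assert ic025 < ic

    @pytest.mark.parametrize("ic025, cat", [
        (-0.5, "none"), (0.0, "none"), (0.7, "weak"), (1.5, "weak"),
        (2.0, "medium"), (3.0, "medium"), (3.2, "strong")])
    def test_strength_bands(self, ic025, cat):
        assert ic_category(ic025) == cat


# --- MGPS ------------------------------------------------------------------

def oracle_ebgm_quad(prior, n, e):
    """Numerical-integration oracle: posterior is prior x Poisson likelihood."""
    def prior_pdf(lam):
        return (prior.p * stats.gamma.pdf(lam, prior.alpha1, scale=1 / prior.beta1)
                + (1 - prior.p) * stats.gamma.pdf(lam, prior.alpha2,
                                                  scale=1 / prior.beta2))

    def unnorm(lam):
        return prior_pdf(lam) * stats.poisson.pmf(n, lam * e)

    norm, _ = integrate.quad(unnorm, 0, np.inf, limit=200)
    mean_log, _ = integrate.quad(lambda lam: np.log(lam) * unnorm(lam) / norm,
                                 0, np.inf, limit=200)
    return math.exp(mean_log)


class TestMgps:
    def test_null_grid_shrinks_to_unity(self):
        rng = np.random.default_rng(1)
        e = rng.uniform(5, 50, size=400)
        n = rng.poisson(e)  # observed == expected in distribution
        prior = fit_gamma_mixture(n, e)
        for i in range(0, 400, 40):
            ebgm, _ = ebgm_from_posterior(prior, int(n[i]), float(e[i]))
            assert abs(ebgm - 1.0) < 0.35

    def test_shrinkage_below_raw_ratio(self):
        rng = np.random.default_rng(2)
        e = rng.uniform(1, 20, size=500)
        n = rng.poisson(e)
        e = np.append(e, 0.05)
        n = np.append(n, 1)  # raw relative ratio 20 in a mostly-null grid
        prior = fit_gamma_mixture(n, e)
        ebgm, _ = ebgm_from_posterior(prior, 1, 0.05)
        assert 1.0 < ebgm < 20.0

    def test_ebgm_matches_numerical_integration(self):
        prior = GammaMixturePrior(0.5, 0.4, 3.0, 2.0, 0.4)
        for n, e in [(0, 2.0), (3, 1.5), (10, 2.0), (50, 10.0), (5, 0.3)]:
            ebgm, eb05 = ebgm_from_posterior(prior, n, e)
            assert ebgm == pytest.approx(oracle_ebgm_quad(prior, n, e), rel=1e-6)
            assert eb05 < ebgm

    def test_eb05_is_fifth_posterior_percentile(self):
        prior = GammaMixturePrior(0.5, 0.4, 3.0, 2.0, 0.4)
        ebgm, eb05 = ebgm_from_posterior(prior, 8, 2.0)
        # CDF of the posterior mixture at eb05 must equal 0.05
        from pvsignal.signals import posterior_mixture
        q, (a1, b1), (a2, b2) = posterior_mixture(prior, 8, 2.0)
        cdf = (q * stats.gamma.cdf(eb05, a1, scale=1 / b1)
               + (1 - q) * stats.gamma.cdf(eb05, a2, scale=1 / b2))
        assert cdf == pytest.approx(0.05, abs=1e-8)


# --- joint evaluation and PT-level matrix ----------------------------------

class TestEvaluateSignal:
    def test_small_count_blocks_joint_signal(self):
        # a=2: disproportionality enormous but the a>=3 rule must veto
        res = evaluate_signal("x", ContingencyTable(2, 1, 1, 10000))
        assert res.ror > 100 and not res.ror_flag and not res.joint_signal

    def test_joint_signal_is_conjunction(self):
        res = evaluate_signal("x", ContingencyTable(60, 40, 100, 9800))
        assert res.joint_signal == (res.ror_flag and res.prr_flag
                                    and res.bcpnn_flag and res.mgps_flag)

    def test_strong_category_from_ic025(self):
        res = evaluate_signal("x", ContingencyTable(500, 100, 300, 90000))
        assert res.ic025 > 3 and res.ic_category == "strong"


class TestPtLevelMatrix:
    def test_counts_equal_brute_force(self, analysis_config):
        corpus = deduplicate(generate_corpus(default_config(n_reports=2000, seed=8)))
        sel = select_analysis_set(corpus, analysis_config)
        df = pt_level_matrix(sel)
        for row in df.itertuples():
            tally = sum(1 for r in corpus
                        if row.drug in r.primary_suspects() and row.pt in r.reactions)
            assert row.count == tally

    def test_absent_pt_has_zero_count_and_negative_ic025(self):
        cfg = AnalysisConfig(target_pt_set=frozenset({"Subdural hematoma",
                                                      "Never reported PT"}))
        corpus = [make_record("C1", drug="aspirin"),
                  make_record("C2", drug="other-drug", pts=("Nausea",))]
        sel = select_analysis_set(corpus, cfg)
        df = pt_level_matrix(sel)
        row = df[(df.drug == "aspirin") & (df.pt == "Never reported PT")].iloc[0]
        assert row["count"] == 0 and row["ic025"] < 0
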