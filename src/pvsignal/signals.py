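"""Four-algorithm disproportionality analysis on 2x2 report tables.

For a (drug, event-set) pair the corpus is collapsed into the four-grid
table::

              target event   other events
    drug           a              b
    other drugs    c              d

and four signal statistics are computed:

* **ROR** (reporting odds ratio) ``ad/(bc)`` with a Wald 95% CI on the log
  scale; signal when ``a >= 3`` and the CI lower bound exceeds 1.
* **PRR** (proportional reporting ratio) ``[a/(a+b)] / [c/(c+d)]`` with its
  log-scale Wald CI; same signal rule.
* **BCPNN information component** — the posterior expectation of
  ``log2 P(drug, event) / (P(drug) P(event))`` under the classic closed-form
  Bayesian model (Dirichlet/Beta priors); signal when the lower credible
  bound ``IC025 = E(IC) - 2 sqrt(V(IC))`` exceeds 0, with strength bands
  (0, 1.5] weak, (1.5, 3] medium, > 3 strong.
* **MGPS EBGM** — the empirical-Bayes geometric mean of the relative
  reporting rate under DuMouchel's two-component gamma mixture prior fitted
  to the whole drug x event grid; signal when the 5th posterior percentile
  EBGM05 exceeds 2 with ``a > 0``.

A joint signal requires all four criteria simultaneously.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .ingest import AnalysisSet
from .records import ReportRecord, ROLE_PRIMARY_SUSPECT

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class UndefinedResultError(ValueError):
    """The statistic is undefined for this table even after correction."""


class FitError(RuntimeError):
    """An empirical-Bayes prior fit failed to converge."""


@dataclass(frozen=True)
class ContingencyTable:
    """Four-grid counts for one (drug, event-set) pair against the rest."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")
        if self.n < 1:
            raise ValueError("table must contain at least one report")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def corrected(self) -> tuple[float, float, float, float]:
        """Haldane–Anscombe continuity correction: add 0.5 to every cell when
        any cell is zero (applied for ROR/PRR only; the Bayesian methods use
        their native smoothing)."""
        if min(self.a, self.b, self.c, self.d) == 0:
            return self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5
        return float(self.a), float(self.b), float(self.c), float(self.d)


@dataclass
class DisproportionalityResult:
    """All four statistics plus per-algorithm flags for one pair."""

    drug: str
    a: int
    table: ContingencyTable
    ror: float
    ror_low: float
    ror_high: float
    prr: float
    prr_low: float
    prr_high: float
    ic: float
    ic025: float
    ic_category: str
    ebgm: float
    ebgm05: float
    ror_flag: bool
    prr_flag: bool
    bcpnn_flag: bool
    mgps_flag: bool

    @property
    def joint_signal(self) -> bool:
        return self.ror_flag and self.prr_flag and self.bcpnn_flag and self.mgps_flag


# ---------------------------------------------------------------------------
# table construction
# ---------------------------------------------------------------------------

def _is_exposed(record: ReportRecord, drug: str) -> bool:
    return any(d.role == ROLE_PRIMARY_SUSPECT and d.drug_name == drug
               for d in record.drugs)


def build_table(corpus: Sequence[ReportRecord], drug: str,
                event_pts: Iterable[str],
                counting_unit: str = "case") -> ContingencyTable:
    """Collapse a deduplicated corpus into the four-grid table.

    Under ``case`` counting each report contributes once, classified by
    whether the drug is its primary suspect and whether any reaction falls in
    ``event_pts``.  Under ``drug-event-pair`` counting each (report, PT) pair
    contributes once.
    """
    if not corpus:
        raise ValueError("empty corpus")
    pts = frozenset(event_pts)
    a = b = c = d = 0
    if counting_unit == "case":
        for r in corpus:
            exposed = _is_exposed(r, drug)
            hit = bool(r.reactions & pts)
            if exposed and hit:
                a += 1
            elif exposed:
                b += 1
            elif hit:
                c += 1
            else:
                d += 1
    elif counting_unit == "drug-event-pair":
        for r in corpus:
            exposed = _is_exposed(r, drug)
            n_hit = len(r.reactions & pts)
            n_other = len(r.reactions) - n_hit
            if exposed:
                a += n_hit
                b += n_other
            else:
                c += n_hit
                d += n_other
    else:
        raise ValueError(f"unknown counting unit {counting_unit!r}")
    return ContingencyTable(a, b, c, d)


# ---------------------------------------------------------------------------
# frequentist statistics
# ---------------------------------------------------------------------------

def ror(table: ContingencyTable) -> tuple[float, float, float]:
    """Reporting odds ratio with its Wald 95% CI on the log scale."""
    a, b, c, d = table.corrected()
    if b * c == 0:
        raise UndefinedResultError("ROR undefined: b*c == 0 after correction")
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_est = math.log(est)
    return est, math.exp(log_est - Z95 * se), math.exp(log_est + Z95 * se)


def prr(table: ContingencyTable) -> tuple[float, float, float]:
    """Proportional reporting ratio with its Wald 95% CI."""
    a, b, c, d = table.corrected()
    if (a + b) == 0 or (c + d) == 0 or a == 0 or c == 0:
        raise UndefinedResultError("PRR undefined for this table")
    est = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    log_est = math.log(est)
    return est, math.exp(log_est - Z95 * se), math.exp(log_est + Z95 * se)


# ---------------------------------------------------------------------------
# BCPNN information component (closed-form Bayesian model)
# ---------------------------------------------------------------------------
#
# With a = c11, row total c1. = a+b, column total c.1 = a+c and N reports, the
# classic closed form uses Beta/Dirichlet priors with hyperparameters
# alpha1 = beta1 = 1, alpha = beta = 2, gamma11 = 1 and gamma chosen so the
# prior IC expectation is 0:
#
#   gamma  = gamma11 * (N + alpha)(N + beta) / ((c1. + alpha1)(c.1 + beta1))
#   E(IC)  = log2[ (c11 + gamma11)(N + alpha)(N + beta)
#                  / ((N + gamma)(c1. + alpha1)(c.1 + beta1)) ]
#   V(IC)  = (1/ln 2)^2 * [ (N - c11 + gamma - gamma11)
#                             / ((c11 + gamma11)(1 + N + gamma))
#                         + (N - c1. + alpha - alpha1)
#                             / ((c1. + alpha1)(1 + N + alpha))
#                         + (N - c.1 + beta - beta1)
#                             / ((c.1 + beta1)(1 + N + beta)) ]
#
# IC025 = E(IC) - 2 sqrt(V(IC)); finite for every non-negative table.

def bcpnn_ic(table: ContingencyTable) -> tuple[float, float]:
    """Information component expectation and its lower bound IC025."""
    c11 = table.a
    c1 = table.a + table.b
    cd1 = table.a + table.c
    n = table.n
    a1 = b1 = 1.0
    al = be = 2.0
    g11 = 1.0
    gamma = g11 * (n + al) * (n + be) / ((c1 + a1) * (cd1 + b1))
    e_ic = math.log2((c11 + g11) * (n + al) * (n + be)
                     / ((n + gamma) * (c1 + a1) * (cd1 + b1)))
    v_ic = ((n - c11 + gamma - g11) / ((c11 + g11) * (1 + n + gamma))
            + (n - c1 + al - a1) / ((c1 + a1) * (1 + n + al))
            + (n - cd1 + be - b1) / ((cd1 + b1) * (1 + n + be))) / math.log(2) ** 2
    return e_ic, e_ic - 2.0 * math.sqrt(v_ic)


def ic_variance(table: ContingencyTable) -> float:
    """V(IC) of the closed-form model (used for the EIC interval exports)."""
    e_ic, ic025 = bcpnn_ic(table)
    return ((e_ic - ic025) / 2.0) ** 2


def ic_category(ic025: float) -> str:
    """Signal-strength band from the IC lower bound."""
    if ic025 <= 0:
        return "none"
    if ic025 <= 1.5:
        return "weak"
    if ic025 <= 3.0:
        return "medium"
    return "strong"


# ---------------------------------------------------------------------------
# MGPS: DuMouchel's multi-item gamma Poisson shrinker
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaMixturePrior:
    """Two-component gamma mixture prior on the relative reporting rate."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p: float  # weight of component 1

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha1, self.beta1, self.alpha2, self.beta2, self.p])


DEFAULT_PRIOR_INIT = GammaMixturePrior(0.2, 0.1, 2.0, 4.0, 1 / 3)


def _nb_logpmf(n: np.ndarray, alpha: float, beta: float, e: np.ndarray) -> np.ndarray:
    # marginal of a Poisson(lambda*E) with lambda ~ Gamma(alpha, rate beta)
    return stats.nbinom.logpmf(n, alpha, beta / (beta + e))


def _mixture_loglik(theta: np.ndarray, n: np.ndarray, e: np.ndarray,
                    weights: Optional[np.ndarray] = None) -> float:
    la1, lb1, la2, lb2, logit_p = theta
    a1, b1, a2, b2 = np.exp([la1, lb1, la2, lb2])
    p = special.expit(logit_p)
    lp1 = _nb_logpmf(n, a1, b1, e) + np.log(p)
    lp2 = _nb_logpmf(n, a2, b2, e) + np.log1p(-p)
    ll = np.logaddexp(lp1, lp2)
    if weights is not None:
        ll = ll * weights
    return -float(np.sum(ll))


def fit_gamma_mixture(counts: np.ndarray, expected: np.ndarray,
                      init: GammaMixturePrior = DEFAULT_PRIOR_INIT) -> GammaMixturePrior:
    """Maximize the negative-binomial-mixture marginal likelihood over all
    grid cells."""
    n = np.asarray(counts, dtype=float)
    e = np.asarray(expected, dtype=float)
    if n.size < 2:
        raise ValueError("need at least 2 grid cells to fit the prior")
    theta0 = np.array([math.log(init.alpha1), math.log(init.beta1),
                       math.log(init.alpha2), math.log(init.beta2),
                       special.logit(init.p)])
    # box constraints keep the mixture proper on sparse or degenerate grids,
    # where the unconstrained MLE can drift to a point-mass corner
    log_bound = math.log(1e4)
    bounds = [(-log_bound, log_bound)] * 4 + [(-7.0, 7.0)]
    res = optimize.minimize(_mixture_loglik, theta0, args=(n, e),
                            method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 2000})
    if not res.success:
        # on sparse grids the line search can stall against a bound (a mixture
        # component collapsing toward a point mass); the clipped best point is
        # a valid bounded MLE as long as the objective improved and is finite
        if not (np.isfinite(res.fun)
                and res.fun <= _mixture_loglik(theta0, n, e) + 1e-9):
            raise FitError(f"gamma-mixture fit did not converge: {res.message}; "
                           f"objective={res.fun:.6g}, theta={res.x}")
        logger.warning("gamma-mixture fit stopped at a bound (%s); "
                       "using best bounded point", res.message)
    res.x = np.clip(res.x, [-log_bound] * 4 + [-7.0], [log_bound] * 4 + [7.0])
    a1, b1, a2, b2 = np.exp(res.x[:4])
    return GammaMixturePrior(a1, b1, a2, b2, float(special.expit(res.x[4])))


def posterior_mixture(prior: GammaMixturePrior, n: float, e: float
                      ) -> tuple[float, tuple[float, float], tuple[float, float]]:
    """Posterior of the relative reporting rate given observed n, expected E.

    Returns (q, (a1', b1'), (a2', b2')) where q is the posterior weight of
    the first gamma component and (a', b') its shape/rate parameters.
    """
    lp1 = _nb_logpmf(np.array(n), prior.alpha1, prior.beta1, np.array(e)) \
        + math.log(prior.p)
    lp2 = _nb_logpmf(np.array(n), prior.alpha2, prior.beta2, np.array(e)) \
        + math.log1p(-prior.p)
    q = float(np.exp(lp1 - np.logaddexp(lp1, lp2)))
    return q, (prior.alpha1 + n, prior.beta1 + e), (prior.alpha2 + n, prior.beta2 + e)


def ebgm_from_posterior(prior: GammaMixturePrior, n: float, e: float,
                        percentile: float = 0.05) -> tuple[float, float]:
    """EBGM (geometric mean of the posterior rate) and its lower percentile.

    The canonical MGPS lower bound EB05 is the 5th posterior percentile; the
    2.5th is available via ``percentile=0.025``.
    """
    q, (a1, b1), (a2, b2) = posterior_mixture(prior, n, e)
    mean_log = (q * (special.digamma(a1) - math.log(b1))
                + (1 - q) * (special.digamma(a2) - math.log(b2)))
    ebgm = math.exp(mean_log)

    def cdf(x: float) -> float:
        return (q * stats.gamma.cdf(x, a1, scale=1 / b1)
                + (1 - q) * stats.gamma.cdf(x, a2, scale=1 / b2))

    lo, hi = 1e-12, max(10.0, ebgm * 50)
    while cdf(hi) < percentile:
        hi *= 10
    while cdf(lo) > percentile:  # heavy prior mass near zero
        lo /= 1e3
        if lo < 1e-290:
            return ebgm, 0.0
    eb_lo = optimize.brentq(lambda x: cdf(x) - percentile, lo, hi, xtol=1e-10)
    return ebgm, eb_lo


@dataclass
class MgpsGrid:
    """Observed/expected counts over the full drug x event grid plus the
    fitted prior.  Shrinkage strength depends on the whole grid, so the prior
    is fitted once per corpus and reused for every pair."""

    drugs: list[str]
    pts: list[str]
    counts: np.ndarray       # shape (n_drugs, n_pts)
    expected: np.ndarray
    prior: GammaMixturePrior

    def cell(self, drug: str, pt_set: frozenset[str]) -> tuple[float, float]:
        if drug not in self.drugs:  # drug absent from the corpus: empty cell
            return 0.0, 0.0
        i = self.drugs.index(drug)
        cols = [j for j, p in enumerate(self.pts) if p in pt_set]
        n = float(self.counts[i, cols].sum())
        e = float(self.expected[i, cols].sum())
        return n, e


def build_mgps_grid(corpus: Sequence[ReportRecord],
                    init: GammaMixturePrior = DEFAULT_PRIOR_INIT) -> MgpsGrid:
    """Tally the drug x PT grid (primary-suspect pairs), compute independence
    expectations E_ij = row_i col_j / N, and fit the mixture prior."""
    drug_ix: dict[str, int] = {}
    pt_ix: dict[str, int] = {}
    for r in corpus:
        for d in r.primary_suspects():
            drug_ix.setdefault(d, len(drug_ix))
        for p in r.reactions:
            pt_ix.setdefault(p, len(pt_ix))
    drugs = sorted(drug_ix)
    pts = sorted(pt_ix)
    di = {d: i for i, d in enumerate(drugs)}
    pi = {p: j for j, p in enumerate(pts)}
    counts = np.zeros((len(drugs), len(pts)))
    for r in corpus:
        for d in set(r.primary_suspects()):
            for p in r.reactions:
                counts[di[d], pi[p]] += 1
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    total = counts.sum()
    expected = row @ col / total
    mask = expected.ravel() > 0
    if mask.sum() < 2:
        logger.warning("grid has %d usable cells; keeping the default prior",
                       int(mask.sum()))
        prior = init
    else:
        prior = fit_gamma_mixture(counts.ravel()[mask], expected.ravel()[mask], init)
    return MgpsGrid(drugs, pts, counts, expected, prior)


# ---------------------------------------------------------------------------
# joint evaluation
# ---------------------------------------------------------------------------

def evaluate_signal(drug: str, table: ContingencyTable,
                    mgps: Optional[MgpsGrid] = None,
                    event_pts: Optional[frozenset[str]] = None,
                    ebgm_percentile: float = 0.05) -> DisproportionalityResult:
    """Compute all four statistics for one table and apply the signal rules.

    ``mgps`` supplies the grid-fitted prior; if omitted, the MGPS statistics
    are computed from the table's own observed/expected cell (a degenerate
    grid), which is only appropriate in tests.
    """
    ror_est, ror_lo, ror_hi = ror(table)
    prr_est, prr_lo, prr_hi = prr(table)
    e_ic, ic025 = bcpnn_ic(table)

    if mgps is not None and event_pts is not None:
        n_cell, e_cell = mgps.cell(drug, event_pts)
        prior = mgps.prior
    else:
        n_cell = table.a
        e_cell = (table.a + table.b) * (table.a + table.c) / table.n
        prior = DEFAULT_PRIOR_INIT
    ebgm, ebgm05 = ebgm_from_posterior(prior, n_cell, max(e_cell, 1e-12),
                                       percentile=ebgm_percentile)

    a = table.a
    return DisproportionalityResult(
        drug=drug, a=a, table=table,
        ror=ror_est, ror_low=ror_lo, ror_high=ror_hi,
        prr=prr_est, prr_low=prr_lo, prr_high=prr_hi,
        ic=e_ic, ic025=ic025, ic_category=ic_category(ic025),
        ebgm=ebgm, ebgm05=ebgm05,
        ror_flag=(a >= 3 and ror_lo > 1.0),
        prr_flag=(a >= 3 and prr_lo > 1.0),
        bcpnn_flag=(ic025 > 0.0),
        mgps_flag=(ebgm05 > 2.0 and a > 0),
    )


def drug_signals(analysis: AnalysisSet,
                 counting_unit: Optional[str] = None,
                 ebgm_percentile: float = 0.05) -> dict[str, DisproportionalityResult]:
    """Four-algorithm results for every study/control drug against the full
    target PT set."""
    cfg = analysis.config
    unit = counting_unit or cfg.counting_unit
    mgps = build_mgps_grid(analysis.corpus)
    out = {}
    for drug in cfg.all_drugs:
        table = build_table(analysis.corpus, drug, cfg.target_pt_set, unit)
        out[drug] = evaluate_signal(drug, table, mgps=mgps,
                                    event_pts=frozenset(cfg.target_pt_set),
                                    ebgm_percentile=ebgm_percentile)
    return out


def pt_level_matrix(analysis: AnalysisSet,
                    counting_unit: str = "drug-event-pair") -> pd.DataFrame:
    """Per-(drug, PT) report counts and BCPNN IC/IC025, as a tidy table.

    The count column tallies drug-event pairs (one per report mentioning the
    PT with the drug as primary suspect); the IC columns come from the per-PT
    four-grid table under the same counting unit.
    """
    cfg = analysis.config
    rows = []
    for drug in cfg.all_drugs:
        for pt in sorted(cfg.target_pt_set):
            table = build_table(analysis.corpus, drug, {pt}, counting_unit)
            e_ic, ic025 = bcpnn_ic(table)
            rows.append({"drug": drug, "pt": pt, "count": table.a,
                         "ic": e_ic, "ic025": ic025,
                         "ic_category": ic_category(ic025)})
    return pd.DataFrame(rows)


def results_frame(results: dict[str, DisproportionalityResult]) -> pd.DataFrame:
    """Tidy one-row-per-drug table of all statistics and flags."""
    rows = []
    for drug, r in results.items():
        rows.append({
            "drug": drug, "a": r.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
            "ror": r.ror, "ror_low": r.ror_low, "ror_high": r.ror_high,
            "prr": r.prr, "prr_low": r.prr_low, "prr_high": r.prr_high,
            "ic": r.ic, "ic025": r.ic025, "ic_category": r.ic_category,
            "ebgm": r.ebgm, "ebgm05": r.ebgm05,
            "ror_flag": r.ror_flag, "prr_flag": r.prr_flag,
            "bcpnn_flag": r.bcpnn_flag, "mgps_flag": r.mgps_flag,
            "joint_signal": r.joint_signal,
        })
    return pd.DataFrame(rows)
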