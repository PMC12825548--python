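"""Synthetic spontaneous-reporting-system generator with known ground truth.

Emulates a FAERS-like corpus: each raw report carries one primary-suspect drug
drawn from a marginal distribution, a set of reaction PTs drawn per-PT
Bernoulli with probability ``base_pt * lambda(drug, pt) * stratum multiplier``
(capped at 1), demographics drawn from configurable age/sex mixtures, onset
times drawn from per-drug Weibull distributions, duplicate case versions, and
per-field missingness.  Because the joint model is an explicit product of
probabilities, every 2x2 contingency cell has a closed-form expectation
(:func:`ground_truth_tables`), which downstream modules use as simulation
oracles.

Reports whose Bernoulli PT draws all come up empty are redrawn (a report with
no reaction cannot exist), so cell expectations condition on a non-empty
reaction set; the conditioning term is carried exactly in the closed form.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .records import (
    DrugExposure,
    ReportRecord,
    ValidationError,
    ROLE_CONCOMITANT,
)

_SEXES = ("female", "male")
_REPORTERS = ("physician", "pharmacist", "other health-professional",
              "consumer", "lawyer", "unspecified")
_REPORTER_PROBS = (0.3615, 0.2188, 0.2058, 0.1792, 0.0050, 0.0297)
_COUNTRIES = ("United States", "France", "Italy", "United Kingdom", "Japan", "other")
_COUNTRY_PROBS = (0.3404, 0.1409, 0.0999, 0.0873, 0.0626, 0.2689)
_OUTCOME_PROBS = (("hospitalization", 0.6664), ("death", 0.2341),
                  ("life-threatening", 0.1612), ("other", 0.4592),
                  ("disability", 0.0603), ("required intervention", 0.0095))
_START_WINDOW = (dt.date(2004, 1, 1), dt.date(2024, 6, 30))


@dataclass
class SyntheticConfig:
    """Full parameterization of the simulated reporting system.

    Parameters
    ----------
    n_reports
        Number of raw cases before duplication inflates the corpus.
    drugs
        Drug label -> marginal probability of being the report's primary
        suspect; must sum to 1.
    events
        PT label -> baseline per-report inclusion probability; must sum to 1
        (so a report carries one PT on average under the null).
    target_pts
        The subset of ``events`` forming the target event set (the
        CNS-hematoma PTs in the default configuration).
    signal_multipliers
        (drug, PT) -> multiplier lambda on the joint reporting probability
        above independence; absent pairs default to 1 (no association).
    strata_effects
        (stratum label, drug) -> multiplier applied on top of lambda for
        reports in that stratum; stratum labels are sex labels or age-group
        labels.  Effects apply to pairs with an explicit lambda.
    age_distribution
        Sequence of (weight, low, high) age bands; weights sum to 1 and ages
        are uniform within a band.
    sex_distribution
        (p_female, p_male); sex missingness is governed by ``missing_rates``.
    onset_models
        Drug -> (alpha, beta): Weibull scale (days) and shape for the time
        from drug start to a target event.
    dup_rate
        Probability a case is emitted twice (a resubmitted version).
    missing_rates
        Per-field missingness probabilities for "age", "sex", "event_date",
        "start_date" (missing completely at random).
    seed
        Seed for the generator; a fixed seed makes the corpus byte-identical
        across runs.
    """

    n_reports: int = 20_000
    drugs: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_DRUGS))
    events: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_EVENTS))
    target_pts: frozenset[str] = frozenset(_t for _t in ())  # set in __post_init__
    signal_multipliers: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_LAMBDAS))
    strata_effects: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_STRATA))
    age_distribution: Sequence[tuple[float, float, float]] = (
        (0.006, 0.0, 18.0), (0.029, 18.0, 45.0), (0.174, 45.0, 65.0), (0.791, 65.0, 95.0))
    sex_distribution: tuple[float, float] = (0.36, 0.64)
    onset_models: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_ONSETS))
    background_onset: tuple[float, float] = (180.0, 1.0)
    dup_rate: float = 0.023
    missing_rates: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.134, "sex": 0.10,
                                 "event_date": 0.30, "start_date": 0.70})
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.target_pts:
            self.target_pts = frozenset(_DEFAULT_TARGET_PTS) & frozenset(self.events)
        self.target_pts = frozenset(self.target_pts)
        self.validate()

    def validate(self) -> None:
        if self.n_reports < 1:
            raise ValidationError("n_reports: must be >= 1")
        for name, mapping in (("drugs", self.drugs), ("events", self.events)):
            if not mapping:
                raise ValidationError(f"{name}: must be non-empty")
            vals = list(mapping.values())
            if any(not (0.0 <= v <= 1.0) for v in vals):
                raise ValidationError(f"{name}: probabilities must lie in [0, 1]")
            if abs(sum(vals) - 1.0) > 1e-9:
                raise ValidationError(f"{name}: marginal probabilities must sum to 1")
        if not self.target_pts <= frozenset(self.events):
            raise ValidationError("target_pts: not a subset of the event list")
        for (d, p), lam in self.signal_multipliers.items():
            if lam <= 0:
                raise ValidationError(f"signal_multipliers[{d!r},{p!r}]: must be > 0")
        for key, m in self.strata_effects.items():
            if m <= 0:
                raise ValidationError(f"strata_effects[{key!r}]: must be > 0")
        w = [b[0] for b in self.age_distribution]
        if abs(sum(w) - 1.0) > 1e-9 or any(x < 0 for x in w):
            raise ValidationError("age_distribution: band weights must sum to 1")
        for _, lo, hi in self.age_distribution:
            if not (0 <= lo < hi <= 130):
                raise ValidationError("age_distribution: bands must satisfy 0 <= lo < hi <= 130")
        if abs(sum(self.sex_distribution) - 1.0) > 1e-9:
            raise ValidationError("sex_distribution: proportions must sum to 1")
        for d, (a, b) in self.onset_models.items():
            if a <= 0 or b <= 0:
                raise ValidationError(f"onset_models[{d!r}]: Weibull alpha, beta must be > 0")
        if not (0.0 <= self.dup_rate < 1.0):
            raise ValidationError("dup_rate: must lie in [0, 1)")
        for f_, r in self.missing_rates.items():
            if not (0.0 <= r <= 1.0):
                raise ValidationError(f"missing_rates[{f_!r}]: must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Default study conditions: four antiplatelet agents with signal strengths in
# the ratio reported for CNS hematomas, warfarin as positive control,
# rosuvastatin as negative control, against a pooled background drug.  Target
# PT baselines are proportioned to the observed subtype mix (subdural
# dominating), and onset Weibulls use the per-drug fitted (alpha, beta).
# ---------------------------------------------------------------------------

_DEFAULT_DRUGS = {
    "aspirin": 0.030, "clopidogrel": 0.030, "ticagrelor": 0.010,
    "prasugrel": 0.005, "warfarin": 0.015, "rosuvastatin": 0.015,
    "other-drug": 0.895,
}

_DEFAULT_TARGET_PTS = ("Subdural hematoma", "Cerebral hematoma",
                       "Extradural hematoma", "Spinal epidural hematoma")

# target PT baselines proportioned to the observed subtype mix (subdural
# dominating at ~63%), scaled so target events are frequent enough to study
# at desk-scale corpus sizes
_DEFAULT_EVENTS = {
    "Subdural hematoma": 0.0063,
    "Cerebral hematoma": 0.00125,
    "Extradural hematoma": 0.00091,
    "Spinal epidural hematoma": 0.00153,
    "Nausea": 0.24501,
    "Headache": 0.190,
    "Dizziness": 0.158,
    "Fatigue": 0.140,
    "Rash": 0.130,
    "Diarrhoea": 0.127,
}

_DEFAULT_LAMBDAS = {
    (d, p): lam
    for d, lam in (("aspirin", 22.0), ("clopidogrel", 27.0), ("ticagrelor", 8.0),
                   ("prasugrel", 17.0), ("warfarin", 38.0), ("rosuvastatin", 0.4))
    for p in _DEFAULT_TARGET_PTS
}

_DEFAULT_STRATA = {
    ("female", "clopidogrel"): 1.6,
    ("female", "aspirin"): 1.3,
    ("female", "ticagrelor"): 1.3,
    ("female", "prasugrel"): 1.3,
    ("18-44", "prasugrel"): 8.0,
    (">=65", "aspirin"): 0.6,
    (">=65", "clopidogrel"): 0.6,
    (">=65", "ticagrelor"): 0.6,
    (">=65", "prasugrel"): 0.6,
}

_DEFAULT_ONSETS = {
    "aspirin": (930.29, 0.62), "clopidogrel": (396.90, 0.58),
    "ticagrelor": (66.32, 0.51), "prasugrel": (137.12, 0.65),
    "warfarin": (100.0, 0.80), "rosuvastatin": (180.0, 1.0),
    "other-drug": (180.0, 1.0),
}


def default_config(**overrides) -> SyntheticConfig:
    """The study-conditions configuration, with keyword overrides."""
    return SyntheticConfig(**overrides)


def null_config(**overrides) -> SyntheticConfig:
    """Default marginals but all signal multipliers and strata effects = 1."""
    overrides.setdefault("signal_multipliers", {})
    overrides.setdefault("strata_effects", {})
    return SyntheticConfig(**overrides)


@dataclass(frozen=True)
class ExpectedTable:
    """Real-valued expected 2x2 cell counts under the generative model."""

    a: float
    b: float
    c: float
    d: float

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def odds_ratio(self) -> float:
        return (self.a * self.d) / (self.b * self.c)


def _age_band_label(lo: float, hi: float) -> str:
    """Map an age band's range onto the analysis age-group labels."""
    from .ingest import derive_age_group
    return derive_age_group((lo + hi) / 2.0)


def _effective_probs(config: SyntheticConfig, drug: str,
                     sex: str, band_label: str) -> np.ndarray:
    """Per-PT inclusion probabilities for one (drug, stratum) combination."""
    pts = list(config.events)
    base = np.array([config.events[p] for p in pts])
    mult = np.ones(len(pts))
    strat = (config.strata_effects.get((sex, drug), 1.0)
             * config.strata_effects.get((band_label, drug), 1.0))
    for j, p in enumerate(pts):
        lam = config.signal_multipliers.get((drug, p))
        if lam is not None:
            mult[j] = lam * strat
    return np.minimum(1.0, base * mult)


def ground_truth_tables(config: SyntheticConfig) -> dict[str, ExpectedTable]:
    """Exact expected a/b/c/d per drug (case counting, deduplicated corpus).

    Marginalizes over the sex x age-band strata and conditions on a non-empty
    reaction set, exactly as the sampler does.
    """
    config.validate()
    pts = list(config.events)
    target_idx = np.array([p in config.target_pts for p in pts])
    strata: list[tuple[float, str, str]] = []
    for (w_band, lo, hi) in config.age_distribution:
        label = _age_band_label(lo, hi)
        for sex, w_sex in zip(_SEXES, config.sex_distribution):
            strata.append((w_band * w_sex, sex, label))

    n = config.n_reports
    p_target_by_drug: dict[str, float] = {}
    for drug in config.drugs:
        p_hit = 0.0
        for w, sex, label in strata:
            p_eff = _effective_probs(config, drug, sex, label)
            p_none_target = float(np.prod(1.0 - p_eff[target_idx]))
            p_empty = float(np.prod(1.0 - p_eff))
            p_hit += w * (1.0 - p_none_target) / (1.0 - p_empty)
        p_target_by_drug[drug] = p_hit

    tables: dict[str, ExpectedTable] = {}
    total_target = sum(config.drugs[d] * p_target_by_drug[d] for d in config.drugs)
    for drug, p_drug in config.drugs.items():
        a = n * p_drug * p_target_by_drug[drug]
        b = n * p_drug - a
        c = n * total_target - a
        d = n - a - b - c
        tables[drug] = ExpectedTable(a, b, c, d)
    return tables


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def generate_corpus(config: SyntheticConfig,
                    return_truth: bool = False):
    """Draw a synthetic report corpus.

    Returns the list of :class:`ReportRecord` (length ``n_reports`` plus any
    duplicate versions).  With ``return_truth=True`` also returns a per-case
    ground-truth dict: ``case_id -> {"drug", "onset_raw_days", "is_target"}``
    where ``onset_raw_days`` is the pre-rounding Weibull draw for
    target-event cases (None otherwise).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    drug_names = list(config.drugs)
    drug_probs = np.array([config.drugs[d] for d in drug_names])
    pts = list(config.events)
    n_pts = len(pts)
    target_mask = np.array([p in config.target_pts for p in pts])

    # demographics (true values; missingness applied at emission)
    sex_idx = rng.choice(2, size=n, p=np.asarray(config.sex_distribution))
    band_w = np.array([b[0] for b in config.age_distribution])
    band_idx = rng.choice(len(band_w), size=n, p=band_w)
    lo = np.array([b[1] for b in config.age_distribution])
    hi = np.array([b[2] for b in config.age_distribution])
    ages = rng.uniform(lo[band_idx], hi[band_idx])
    band_labels = [_age_band_label(l, h) for l, h in zip(lo, hi)]

    drug_idx = rng.choice(len(drug_names), size=n, p=drug_probs)

    # per-record effective PT probabilities via cached (drug, sex, band) rows
    cache: dict[tuple[int, int, int], np.ndarray] = {}
    p_eff = np.empty((n, n_pts))
    for i in range(n):
        key = (drug_idx[i], sex_idx[i], band_idx[i])
        row = cache.get(key)
        if row is None:
            row = _effective_probs(config, drug_names[key[0]],
                                   _SEXES[key[1]], band_labels[key[2]])
            cache[key] = row
        p_eff[i] = row

    hits = rng.random((n, n_pts)) < p_eff
    # a report must carry at least one reaction: redraw empty rows
    empty = ~hits.any(axis=1)
    while empty.any():
        idx = np.nonzero(empty)[0]
        hits[idx] = rng.random((len(idx), n_pts)) < p_eff[idx]
        empty[idx] = ~hits[idx].any(axis=1)

    is_target = hits[:, target_mask].any(axis=1)

    # onset: Weibull for target cases, background model otherwise
    alpha = np.empty(n)
    beta = np.empty(n)
    bg_a, bg_b = config.background_onset
    for i in range(n):
        a_, b_ = config.onset_models.get(drug_names[drug_idx[i]], (bg_a, bg_b))
        if is_target[i]:
            alpha[i], beta[i] = a_, b_
        else:
            alpha[i], beta[i] = bg_a, bg_b
    onset_raw = alpha * rng.standard_exponential(n) ** (1.0 / beta)
    onset_days = _round_half_up(onset_raw).astype(int)

    start_lo = _START_WINDOW[0].toordinal()
    start_hi = _START_WINDOW[1].toordinal()
    start_ord = rng.integers(start_lo, start_hi + 1, size=n)
    event_ord = start_ord + onset_days
    receipt_ord = event_ord + rng.integers(1, 60, size=n)

    reporter_idx = rng.choice(len(_REPORTERS), size=n, p=np.asarray(_REPORTER_PROBS))
    country_idx = rng.choice(len(_COUNTRIES), size=n, p=np.asarray(_COUNTRY_PROBS))
    serious = rng.random(n) < 0.9982
    outcome_draws = {name: rng.random(n) < p for name, p in _OUTCOME_PROBS}
    conc_mask = rng.random(n) < 0.3
    conc_idx = rng.choice(len(drug_names), size=n, p=drug_probs)

    miss = {f_: rng.random(n) < config.missing_rates.get(f_, 0.0)
            for f_ in ("age", "sex", "event_date", "start_date")}
    dup_mask = rng.random(n) < config.dup_rate

    records: list[ReportRecord] = []
    truth: dict[str, dict] = {}
    for i in range(n):
        case_id = f"C{i + 1:07d}"
        drug = drug_names[drug_idx[i]]
        start = (None if miss["start_date"][i]
                 else dt.date.fromordinal(int(start_ord[i])))
        exposures = [DrugExposure(drug, start_date=start)]
        if conc_mask[i] and drug_names[conc_idx[i]] != drug:
            exposures.append(DrugExposure(drug_names[conc_idx[i]],
                                          role=ROLE_CONCOMITANT))
        reactions = frozenset(pts[j] for j in np.nonzero(hits[i])[0])
        outcomes = frozenset(name for name in outcome_draws
                             if outcome_draws[name][i]) if serious[i] else frozenset()
        rec = ReportRecord(
            case_id=case_id,
            version_id=1,
            receipt_date=dt.date.fromordinal(int(receipt_ord[i])),
            drugs=exposures,
            reactions=reactions,
            event_date=None if miss["event_date"][i]
            else dt.date.fromordinal(int(event_ord[i])),
            sex="unspecified" if miss["sex"][i] else _SEXES[sex_idx[i]],
            age_years=None if miss["age"][i] else round(float(ages[i]), 1),
            reporter=_REPORTERS[reporter_idx[i]],
            country=_COUNTRIES[country_idx[i]],
            serious=bool(serious[i]),
            outcomes=outcomes,
            source="synthetic",
        )
        records.append(rec)
        if return_truth:
            truth[case_id] = {
                "drug": drug,
                "is_target": bool(is_target[i]),
                "onset_raw_days": float(onset_raw[i]) if is_target[i] else None,
            }
        if dup_mask[i]:
            records.append(_duplicate_version(rec))

    if return_truth:
        return records, truth
    return records


def _duplicate_version(rec: ReportRecord) -> ReportRecord:
    """Resubmitted case version: version+1, receipt +1 day, reporter perturbed."""
    order = list(_REPORTERS)
    perturbed = order[(order.index(rec.reporter) + 1) % len(order)]
    return ReportRecord(
        case_id=rec.case_id,
        version_id=rec.version_id + 1,
        receipt_date=rec.receipt_date + dt.timedelta(days=1),
        drugs=rec.drugs,
        reactions=rec.reactions,
        event_date=rec.event_date,
        sex=rec.sex,
        age_years=rec.age_years,
        reporter=perturbed,
        country=rec.country,
        serious=rec.serious,
        outcomes=rec.outcomes,
        source=rec.source,
    )


def write_ground_truth(path, config: SyntheticConfig,
                       truth: dict[str, dict]) -> None:
    """Write the ground-truth sidecar (expected tables + per-case truths)."""
    tables = ground_truth_tables(config)
    payload = {
        "seed": config.seed,
        "n_reports": config.n_reports,
        "expected_tables": {d: {"a": t.a, "b": t.b, "c": t.c, "d": t.d}
                            for d, t in tables.items()},
        "cases": truth,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
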