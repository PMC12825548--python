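"""Descriptive characteristic tables, PT shares, and pipeline orchestration.

Descriptive statistics count deduplicated *cases*; PT-level shares count
drug-event *pairs*.  Percentages are rounded half-up to two decimals for
presentation while machine-readable outputs keep full precision.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .ingest import AnalysisSet, deduplicate, select_analysis_set, write_report_tables
from .records import AnalysisConfig, ReportRecord
from .signals import drug_signals, pt_level_matrix, results_frame
from .stratify import stratum_signals
from .synthetic import SyntheticConfig, generate_corpus, write_ground_truth
from .tto import (
    SmallSampleError,
    compare_medians,
    compute_tto,
    cumulative_curves,
    fit_weibull,
    tto_table,
)

DEFAULT_YEAR_BANDS = ((2004, 2008), (2009, 2013), (2014, 2018), (2019, 2024))


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (1.005 -> 1.01), matching presentation rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, denominator: int) -> float:
    """count/denominator as a percentage, rounded half-up to 2 decimals."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * count / denominator)


@dataclass
class DescriptiveSummary:
    """One characteristic's category counts with percentages.

    ``multi_valued`` marks groupings (outcomes) where a case may occupy more
    than one category, so percentages may legitimately exceed 100 in total.
    """

    grouping: str
    rows: pd.DataFrame  # columns: category, count, pct
    denominator: int
    multi_valued: bool = False


def _count_summary(grouping: str, labels: Sequence[str],
                   values: Sequence[str], denom: int,
                   multi: bool = False) -> DescriptiveSummary:
    counts = {lab: 0 for lab in labels}
    for v in values:
        if v in counts:
            counts[v] += 1
    rows = pd.DataFrame(
        [{"category": lab, "count": n, "pct": percentage(n, denom)}
         for lab, n in counts.items()])
    return DescriptiveSummary(grouping, rows, denom, multi)


def _year_band(year: int, bands) -> Optional[str]:
    for lo, hi in bands:
        if lo <= year <= hi:
            return f"{lo}-{hi}"
    return None


def summarize_characteristics(per_drug: Mapping[str, Sequence[ReportRecord]],
                              top_k_countries: int = 5,
                              year_bands=DEFAULT_YEAR_BANDS
                              ) -> dict[str, dict[str, DescriptiveSummary]]:
    """Characteristic summaries per drug and overall (case counting).

    ``per_drug`` maps each study drug to its analysis-set records; the
    "total" group is the union of unique cases across the given drugs.
    """
    groups: dict[str, list[ReportRecord]] = {
        d: list(recs) for d, recs in per_drug.items()}
    seen: dict[str, ReportRecord] = {}
    for recs in per_drug.values():
        for r in recs:
            seen.setdefault(r.case_id, r)
    groups["total"] = list(seen.values())

    out: dict[str, dict[str, DescriptiveSummary]] = {}
    for name, recs in groups.items():
        denom = len(recs)
        summaries: dict[str, DescriptiveSummary] = {}
        summaries["sex"] = _count_summary(
            "sex", ["female", "male", "unspecified"],
            [r.sex for r in recs], denom)
        summaries["age_group"] = _count_summary(
            "age_group", ["<18", "18-44", "45-64", ">=65", "unspecified"],
            [r.age_group for r in recs], denom)
        summaries["reporter"] = _count_summary(
            "reporter", ["physician", "pharmacist", "other health-professional",
                         "consumer", "lawyer", "unspecified"],
            [r.reporter for r in recs], denom)
        country_counts = pd.Series([r.country or "unspecified" for r in recs])
        top = list(country_counts.value_counts().head(top_k_countries).index)
        summaries["country"] = _count_summary(
            "country", top + ["other"],
            [c if c in top else "other" for c in country_counts], denom)
        summaries["seriousness"] = _count_summary(
            "seriousness", ["serious", "non-serious"],
            ["serious" if r.serious else "non-serious" for r in recs], denom)
        outcome_vals = [oc for r in recs for oc in sorted(r.outcomes)]
        summaries["outcomes"] = _count_summary(
            "outcomes", ["life-threatening", "hospitalization", "disability",
                         "death", "congenital anomaly", "required intervention",
                         "other"],
            outcome_vals, denom, multi=True)
        year_labels = [f"{lo}-{hi}" for lo, hi in year_bands]
        summaries["reporting_year"] = _count_summary(
            "reporting_year", year_labels,
            [_year_band(r.receipt_date.year, year_bands) or "" for r in recs],
            denom)
        out[name] = summaries

    # drug mix within the total group
    denom = len(groups["total"])
    drug_of_case = []
    for d, recs in per_drug.items():
        drug_of_case.extend([d] * len(recs))
    out["total"]["drug"] = _count_summary(
        "drug", list(per_drug), drug_of_case, denom)
    return out


def pt_share(per_drug: Mapping[str, Sequence[ReportRecord]],
             target_pts: frozenset[str]) -> pd.DataFrame:
    """Per-PT drug-event-pair counts and shares of all target-event reports.

    Each (case, matching PT) pair counts once; shares use the total number of
    target pairs as denominator, so they sum to 100 within rounding.
    """
    counts: dict[str, int] = {pt: 0 for pt in sorted(target_pts)}
    seen: set[tuple[str, str]] = set()
    for recs in per_drug.values():
        for r in recs:
            for pt in r.reactions & target_pts:
                if (r.case_id, pt) not in seen:
                    seen.add((r.case_id, pt))
                    counts[pt] += 1
    return shares_from_counts(counts)


def shares_from_counts(counts: Mapping[str, int],
                       total: Optional[int] = None) -> pd.DataFrame:
    """Percentage shares (2-decimal, half-up) from category counts."""
    denom = total if total is not None else sum(counts.values())
    rows = [{"pt": k, "count": v, "pct": percentage(v, denom)}
            for k, v in counts.items()]
    return pd.DataFrame(rows).sort_values("count", ascending=False,
                                          kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _summaries_frame(all_summaries) -> pd.DataFrame:
    rows = []
    for group, summaries in all_summaries.items():
        for s in summaries.values():
            for rec in s.rows.to_dict("records"):
                rows.append({"group": group, "characteristic": s.grouping,
                             "category": rec["category"], "count": rec["count"],
                             "pct": rec["pct"], "denominator": s.denominator,
                             "multi_valued": s.multi_valued})
    return pd.DataFrame(rows)


def run_pipeline(out_dir,
                 synthetic_config: Optional[SyntheticConfig] = None,
                 records: Optional[Sequence[ReportRecord]] = None,
                 analysis_config: Optional[AnalysisConfig] = None,
                 zero_day_policy: str = "recode") -> dict:
    """Execute the full analysis on a synthetic or supplied corpus.

    Stages: simulate (if no records given) -> deduplicate -> select ->
    disproportionality -> PT-level matrix -> stratified (sex, age) -> TTO ->
    descriptives.  All tabular outputs are CSV; a JSON manifest records the
    seed, config hash, per-stage row counts and a content hash per file.
    Re-running with identical inputs reproduces byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = analysis_config or AnalysisConfig()

    manifest: dict = {"pvsignal_version": __version__, "stages": {}, "files": {}}
    if records is None:
        if synthetic_config is None:
            raise ValueError("either records or synthetic_config required")
        records, truth = generate_corpus(synthetic_config, return_truth=True)
        write_report_tables(records, out / "corpus")
        write_ground_truth(out / "ground_truth.json", synthetic_config, truth)
        manifest["seed"] = synthetic_config.seed
        manifest["config_hash"] = hashlib.sha256(
            repr(synthetic_config).encode()).hexdigest()
    manifest["stages"]["raw_reports"] = len(records)

    corpus = deduplicate(records)
    manifest["stages"]["deduplicated_cases"] = len(corpus)

    analysis = select_analysis_set(corpus, cfg)
    manifest["stages"]["analysis_sets"] = {
        d: len(v) for d, v in analysis.per_drug.items()}

    results = drug_signals(analysis)
    signals_df = results_frame(results)
    signals_df.to_csv(out / "signals.csv", index=False)

    pt_matrix = pt_level_matrix(analysis)
    pt_matrix.to_csv(out / "pt_level.csv", index=False)

    strat_frames = [stratum_signals(analysis, dim) for dim in ("sex", "age_group")]
    pd.concat(strat_frames, ignore_index=True).to_csv(
        out / "stratified.csv", index=False)

    study_sets = {d: analysis.per_drug[d] for d in cfg.study_drugs}
    samples = {d: compute_tto(recs, d, zero_day_policy)
               for d, recs in study_sets.items()}
    fits = {}
    for d, s in samples.items():
        try:
            fits[d] = fit_weibull(s)
        except SmallSampleError:
            pass
    if fits:
        tto_table(fits).to_csv(out / "tto_weibull.csv", index=False)
    curves = cumulative_curves(samples)
    curves.to_csv(out / "tto_curves.csv", index=False)
    nonempty = {d: s for d, s in samples.items() if s.n > 0}
    if len(nonempty) >= 2:
        h, dof, p = compare_medians(nonempty)
        manifest["kruskal_wallis"] = {"H": h, "dof": dof, "p": p}

    summaries = summarize_characteristics(study_sets)
    _summaries_frame(summaries).to_csv(out / "descriptives.csv", index=False)
    pt_share(study_sets, frozenset(cfg.target_pt_set)).to_csv(
        out / "pt_share.csv", index=False)

    manifest["joint_signals"] = {
        d: bool(results[d].joint_signal) for d in cfg.all_drugs}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][str(path.relative_to(out))] = _sha256(path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
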