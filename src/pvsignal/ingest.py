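"""Reading FAERS-style report tables, deduplication, and analysis-set selection.

Input layout mirrors the FAERS quarterly ASCII files: ``$``-delimited tables
named DEMO (demographics), DRUG (exposures with role codes), REAC (reaction
PTs), THER (therapy start dates) and OUTC (regulatory outcomes), joined on
(caseid, caseversion).  A compact single-table CSV dialect is also supported
for small fixtures (one row per report; list-valued fields ``;``-joined).

Deduplication follows the standard FAERS convention: for each case identifier
retain the report version with the greatest (receipt date, version id).
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .records import (
    AnalysisConfig,
    DrugExposure,
    ReportRecord,
    ValidationError,
    ROLE_PRIMARY_SUSPECT,
    VALID_OUTCOMES,
    VALID_REPORTERS,
    VALID_SEXES,
)

logger = logging.getLogger(__name__)

DELIM = "$"

_DEMO_COLS = ["caseid", "caseversion", "receipt_date", "event_date", "age_yrs",
              "sex", "reporter", "country", "serious", "source"]
_DRUG_COLS = ["caseid", "caseversion", "drug_seq", "drugname", "role_cod"]
_REAC_COLS = ["caseid", "caseversion", "pt"]
_THER_COLS = ["caseid", "caseversion", "drug_seq", "start_date"]
_OUTC_COLS = ["caseid", "caseversion", "outc_cod"]

_OUTC_CODES = {"DE": "death", "LT": "life-threatening", "HO": "hospitalization",
               "DS": "disability", "CA": "congenital anomaly",
               "RI": "required intervention", "OT": "other"}
_OUTC_CODES_INV = {v: k for k, v in _OUTC_CODES.items()}


class InputError(ValueError):
    """A mandatory input table is missing or structurally unusable."""


class DataIntegrityError(ValueError):
    """Conflicting rows within one (case, version) key."""


def derive_age_group(age_years: Optional[float]) -> str:
    """Map an age in years to the analysis bands, closed on the left.

    Bands: <18, 18-44, 45-64, >=65; missing age maps to "unspecified".
    """
    if age_years is None:
        return "unspecified"
    if age_years < 0:
        raise ValidationError(f"negative age {age_years}")
    if age_years < 18:
        return "<18"
    if age_years < 45:
        return "18-44"
    if age_years < 65:
        return "45-64"
    return ">=65"


def parse_date(value) -> Optional[dt.date]:
    """Parse an ISO-8601 date; FAERS partial dates (YYYY, YYYYMM) and
    unparseable strings map to missing (with a logged warning for the latter)."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if not s or s.lower() in ("nan", "none", "na"):
        return None
    digits = s.replace("-", "")
    if len(digits) in (4, 6) and digits.isdigit():  # partial date
        return None
    try:
        if len(digits) == 8 and digits.isdigit() and "-" not in s:
            return dt.date(int(digits[:4]), int(digits[4:6]), int(digits[6:8]))
        return dt.date.fromisoformat(s)
    except ValueError:
        logger.warning("unparseable date %r treated as missing", s)
        return None


def _fmt_date(d: Optional[dt.date]) -> str:
    return d.isoformat() if d is not None else ""


# ---------------------------------------------------------------------------
# FAERS-style multi-table I/O
# ---------------------------------------------------------------------------

def write_report_tables(records: Sequence[ReportRecord], out_dir) -> dict[str, Path]:
    """Write a corpus as $-delimited DEMO/DRUG/REAC/THER/OUTC tables.

    Row order is deterministic (sorted by case, version, then sequence), so a
    write -> read -> write cycle is byte-stable.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    demo, drug, reac, ther, outc = [], [], [], [], []
    for r in sorted(records, key=lambda r: (r.case_id, r.version_id)):
        demo.append((r.case_id, r.version_id, _fmt_date(r.receipt_date),
                     _fmt_date(r.event_date),
                     "" if r.age_years is None else r.age_years,
                     r.sex, r.reporter, r.country or "", int(r.serious), r.source))
        for seq, ex in enumerate(r.drugs, start=1):
            drug.append((r.case_id, r.version_id, seq, ex.drug_name, ex.role))
            if ex.start_date is not None:
                ther.append((r.case_id, r.version_id, seq, _fmt_date(ex.start_date)))
        for pt in sorted(r.reactions):
            reac.append((r.case_id, r.version_id, pt))
        for oc in sorted(r.outcomes):
            outc.append((r.case_id, r.version_id, _OUTC_CODES_INV[oc]))

    paths = {}
    for name, rows, cols in (("DEMO", demo, _DEMO_COLS), ("DRUG", drug, _DRUG_COLS),
                             ("REAC", reac, _REAC_COLS), ("THER", ther, _THER_COLS),
                             ("OUTC", outc, _OUTC_COLS)):
        path = out / f"{name}.txt"
        pd.DataFrame(rows, columns=cols).to_csv(path, sep=DELIM, index=False)
        paths[name] = path
    return paths


def read_report_tables(paths: Mapping[str, object]) -> list[ReportRecord]:
    """Read $-delimited report tables into records, joined on (case, version).

    ``paths`` maps table names (DEMO, DRUG, REAC; THER and OUTC optional) to
    file paths.  Unparseable dates become missing with a warning; rows whose
    case/version key conflicts within a table raise
    :class:`DataIntegrityError`.
    """
    for mandatory in ("DEMO", "DRUG", "REAC"):
        if mandatory not in paths:
            raise InputError(f"missing mandatory table {mandatory}")

    def load(name, cols):
        if name not in paths:
            return pd.DataFrame(columns=cols)
        df = pd.read_csv(paths[name], sep=DELIM, dtype=str, keep_default_na=False)
        missing = set(cols) - set(df.columns)
        if missing:
            raise InputError(f"table {name} lacks columns {sorted(missing)}")
        return df

    demo = load("DEMO", _DEMO_COLS)
    drug = load("DRUG", _DRUG_COLS)
    reac = load("REAC", _REAC_COLS)
    ther = load("THER", _THER_COLS)
    outc = load("OUTC", _OUTC_COLS)

    if demo.duplicated(subset=["caseid", "caseversion"]).any():
        raise DataIntegrityError("duplicate (caseid, caseversion) rows in DEMO")

    starts: dict[tuple, str] = {}
    for row in ther.itertuples(index=False):
        key = (row.caseid, row.caseversion, row.drug_seq)
        if key in starts and starts[key] != row.start_date:
            raise DataIntegrityError(f"conflicting THER start dates for {key}")
        starts[key] = row.start_date

    drugs_by_key: dict[tuple, list[DrugExposure]] = {}
    for row in drug.itertuples(index=False):
        key = (row.caseid, row.caseversion)
        start = parse_date(starts.get((row.caseid, row.caseversion, row.drug_seq)))
        drugs_by_key.setdefault(key, []).append(
            DrugExposure(row.drugname, role=row.role_cod, start_date=start))

    reac_by_key: dict[tuple, set[str]] = {}
    for row in reac.itertuples(index=False):
        reac_by_key.setdefault((row.caseid, row.caseversion), set()).add(row.pt)

    outc_by_key: dict[tuple, set[str]] = {}
    for row in outc.itertuples(index=False):
        code = row.outc_cod.strip()
        label = _OUTC_CODES.get(code, code.lower())
        if label not in VALID_OUTCOMES:
            raise InputError(f"unknown outcome code {code!r}")
        outc_by_key.setdefault((row.caseid, row.caseversion), set()).add(label)

    records: list[ReportRecord] = []
    rejected = 0
    for row in demo.itertuples(index=False):
        key = (row.caseid, row.caseversion)
        reactions = reac_by_key.get(key, set())
        if not reactions:
            rejected += 1
            logger.warning("case %s v%s rejected: no reactions", *key)
            continue
        age = None if row.age_yrs == "" else float(row.age_yrs)
        records.append(ReportRecord(
            case_id=row.caseid,
            version_id=int(row.caseversion),
            receipt_date=parse_date(row.receipt_date) or dt.date.min,
            drugs=drugs_by_key.get(key, []),
            reactions=frozenset(reactions),
            event_date=parse_date(row.event_date),
            sex=row.sex if row.sex in VALID_SEXES else "unspecified",
            age_years=age,
            reporter=row.reporter if row.reporter in VALID_REPORTERS else "unspecified",
            country=row.country or None,
            serious=str(row.serious).strip() in ("1", "True", "true", "Y"),
            outcomes=frozenset(outc_by_key.get(key, set())),
            source=row.source or "FAERS-like",
        ))
    if rejected:
        logger.warning("%d rows rejected during ingest", rejected)
    return records


# ---------------------------------------------------------------------------
# Compact single-table CSV dialect (fixtures)
# ---------------------------------------------------------------------------

def write_corpus_csv(records: Sequence[ReportRecord], path) -> None:
    """One row per report; drugs encoded ``name:role:start`` and ``;``-joined."""
    rows = []
    for r in sorted(records, key=lambda r: (r.case_id, r.version_id)):
        rows.append({
            "caseid": r.case_id, "caseversion": r.version_id,
            "receipt_date": _fmt_date(r.receipt_date),
            "event_date": _fmt_date(r.event_date),
            "drugs": ";".join(f"{d.drug_name}:{d.role}:{_fmt_date(d.start_date)}"
                              for d in r.drugs),
            "reactions": ";".join(sorted(r.reactions)),
            "sex": r.sex, "age_yrs": "" if r.age_years is None else r.age_years,
            "reporter": r.reporter, "country": r.country or "",
            "serious": int(r.serious),
            "outcomes": ";".join(sorted(r.outcomes)), "source": r.source,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_corpus_csv(path) -> list[ReportRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        drugs = []
        for spec_ in filter(None, row.drugs.split(";")):
            name, role, start = spec_.split(":")
            drugs.append(DrugExposure(name, role=role, start_date=parse_date(start)))
        records.append(ReportRecord(
            case_id=row.caseid, version_id=int(row.caseversion),
            receipt_date=parse_date(row.receipt_date) or dt.date.min,
            drugs=drugs,
            reactions=frozenset(filter(None, row.reactions.split(";"))),
            event_date=parse_date(row.event_date),
            sex=row.sex, age_years=None if row.age_yrs == "" else float(row.age_yrs),
            reporter=row.reporter, country=row.country or None,
            serious=row.serious in ("1", "True", "true"),
            outcomes=frozenset(filter(None, row.outcomes.split(";"))),
            source=row.source,
        ))
    return records


# ---------------------------------------------------------------------------
# Deduplication and analysis-set selection
# ---------------------------------------------------------------------------

def deduplicate(records: Iterable[ReportRecord]) -> list[ReportRecord]:
    """One record per case: the greatest (receipt_date, version_id) wins.

    Output is sorted by case_id, so the operation is deterministic and
    idempotent.
    """
    best: dict[str, ReportRecord] = {}
    for r in records:
        cur = best.get(r.case_id)
        if cur is None or (r.receipt_date, r.version_id) > (cur.receipt_date,
                                                            cur.version_id):
            best[r.case_id] = r
    return [best[cid] for cid in sorted(best)]


@dataclass
class AnalysisSet:
    """Per-drug analysis subsets plus the full deduplicated denominator corpus."""

    per_drug: dict[str, list[ReportRecord]]
    corpus: list[ReportRecord]
    multiplicity: int = 0  # records appearing under more than one drug
    config: AnalysisConfig = field(default_factory=AnalysisConfig)


def select_analysis_set(records: Sequence[ReportRecord],
                        config: AnalysisConfig) -> AnalysisSet:
    """Select, for each study/control drug, the reports where the drug is the
    primary suspect and at least one reaction falls in the target PT set.

    ``records`` must already be deduplicated; the full corpus is retained as
    the disproportionality denominator.  A record with two study drugs as
    primary suspects is counted under both (multiplicity reported).
    """
    if not config.target_pt_set:
        raise ValidationError("target_pt_set must be non-empty")
    if config.date_window is not None:
        lo, hi = config.date_window
        records = [r for r in records if lo <= r.receipt_date <= hi]
    per_drug: dict[str, list[ReportRecord]] = {d: [] for d in config.all_drugs}
    multi = 0
    for r in records:
        if not (r.reactions & config.target_pt_set):
            continue
        ps = {config.normalize_drug(n) for n in r.primary_suspects()}
        matched = [d for d in config.all_drugs if config.normalize_drug(d) in ps]
        if len(matched) > 1:
            multi += 1
        for d in matched:
            per_drug[d].append(r)
    if multi:
        logger.info("%d records matched multiple analysis drugs", multi)
    return AnalysisSet(per_drug=per_drug, corpus=list(records),
                       multiplicity=multi, config=config)
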