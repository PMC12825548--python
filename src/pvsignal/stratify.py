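"""Demographic stratification of disproportionality signals.

Disproportionality is recomputed inside each sex or age-band stratum, with
the stratum's own sub-corpus as the comparison denominator.  The stratum IC
expectation and its 95% interval (IC +/- 2 sqrt V) are exported as the EIC
columns; records without a specified value on the stratification dimension
form a separate pool that is reported but never enters a stratum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .ingest import AnalysisSet
from .records import AnalysisConfig, ReportRecord, ValidationError
from .signals import (
    ContingencyTable,
    DisproportionalityResult,
    build_mgps_grid,
    build_table,
    bcpnn_ic,
    evaluate_signal,
    ic_variance,
)

SEX_STRATA = ("female", "male")
AGE_STRATA = ("<18", "18-44", "45-64", ">=65")


@dataclass(frozen=True)
class Stratum:
    dimension: str  # "sex" or "age_group"
    label: str

    def __post_init__(self) -> None:
        valid = {"sex": SEX_STRATA, "age_group": AGE_STRATA}
        if self.dimension not in valid:
            raise ValidationError(f"unknown stratification dimension {self.dimension!r}")
        if self.label not in valid[self.dimension]:
            raise ValidationError(
                f"label {self.label!r} invalid for dimension {self.dimension!r}")


def stratify_corpus(corpus: Sequence[ReportRecord], dimension: str
                    ) -> tuple[dict[Stratum, list[ReportRecord]], list[ReportRecord]]:
    """Partition a corpus by sex or age group.

    Returns (strata sub-corpora, unspecified pool); the sub-corpora plus the
    pool partition the input exactly.
    """
    if dimension == "sex":
        labels = SEX_STRATA
        key = lambda r: r.sex  # noqa: E731
    elif dimension == "age_group":
        labels = AGE_STRATA
        key = lambda r: r.age_group  # noqa: E731
    else:
        raise ValidationError(f"unknown stratification dimension {dimension!r}")
    strata = {Stratum(dimension, lab): [] for lab in labels}
    unspecified: list[ReportRecord] = []
    for r in corpus:
        lab = key(r)
        if lab == "unspecified":
            unspecified.append(r)
        else:
            strata[Stratum(dimension, lab)].append(r)
    return strata, unspecified


@dataclass
class StratumResult:
    stratum: Stratum
    n_stratum: int
    result: Optional[DisproportionalityResult]
    table: ContingencyTable
    eic: float
    eic_low: float
    eic_high: float
    small_count: bool  # a < 3: flags forced false, marker set


def stratum_signals(analysis: AnalysisSet, dimension: str,
                    counting_unit: str = "case") -> pd.DataFrame:
    """Per-(drug, stratum) four-algorithm results with EIC intervals.

    Strata with a = 0 report NaN for the frequentist statistics (their CIs
    are not meaningful without events) while the Bayesian IC remains defined;
    strata with a < 3 carry a small-count marker and false flags.
    """
    cfg: AnalysisConfig = analysis.config
    strata, unspecified = stratify_corpus(analysis.corpus, dimension)
    rows = []
    for stratum, sub in strata.items():
        mgps = build_mgps_grid(sub) if sub else None
        for drug in cfg.all_drugs:
            if not sub:
                continue
            table = build_table(sub, drug, cfg.target_pt_set, counting_unit)
            e_ic, ic025 = bcpnn_ic(table)
            half = 2.0 * math.sqrt(ic_variance(table))
            row = {"drug": drug, "dimension": dimension, "stratum": stratum.label,
                   "n_stratum": len(sub), "a": table.a, "b": table.b,
                   "c": table.c, "d": table.d,
                   "eic": e_ic, "eic_low": e_ic - half, "eic_high": e_ic + half,
                   "small_count": table.a < 3}
            if table.a == 0:
                row.update(ror=float("nan"), ror_low=float("nan"),
                           ror_high=float("nan"), prr=float("nan"),
                           prr_low=float("nan"), prr_high=float("nan"),
                           ic=e_ic, ic025=ic025, ebgm=float("nan"),
                           ebgm05=float("nan"), ror_flag=False, prr_flag=False,
                           bcpnn_flag=False, mgps_flag=False, joint_signal=False)
            else:
                res = evaluate_signal(drug, table, mgps=mgps,
                                      event_pts=frozenset(cfg.target_pt_set))
                row.update(ror=res.ror, ror_low=res.ror_low, ror_high=res.ror_high,
                           prr=res.prr, prr_low=res.prr_low, prr_high=res.prr_high,
                           ic=res.ic, ic025=res.ic025,
                           ebgm=res.ebgm, ebgm05=res.ebgm05,
                           ror_flag=res.ror_flag and table.a >= 3,
                           prr_flag=res.prr_flag and table.a >= 3,
                           bcpnn_flag=res.bcpnn_flag if table.a >= 3 else False,
                           mgps_flag=res.mgps_flag if table.a >= 3 else False)
                row["joint_signal"] = (row["ror_flag"] and row["prr_flag"]
                                       and row["bcpnn_flag"] and row["mgps_flag"])
            rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["n_unspecified"] = len(unspecified)
    return df
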