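"""Core record types for spontaneous adverse-event reports.

A spontaneous reporting system (SRS) such as FAERS stores one report per
(case, version); a *case* is a patient-event episode that may be resubmitted
as successive versions.  Each report carries the drugs involved (with a role
code marking the primary suspect), the adverse reactions coded as MedDRA-style
preferred terms (PTs), event and receipt dates, and demographics.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace  # noqa: F401  (replace re-exported)
from typing import Optional, Sequence

#: drug role codes, FAERS convention
ROLE_PRIMARY_SUSPECT = "PS"
ROLE_SECONDARY_SUSPECT = "SS"
ROLE_CONCOMITANT = "C"
ROLE_INTERACTING = "I"
VALID_ROLES = frozenset({ROLE_PRIMARY_SUSPECT, ROLE_SECONDARY_SUSPECT,
                         ROLE_CONCOMITANT, ROLE_INTERACTING})

VALID_SEXES = frozenset({"female", "male", "unspecified"})
VALID_REPORTERS = frozenset({"physician", "pharmacist", "other health-professional",
                             "consumer", "lawyer", "unspecified"})
#: the seven regulatory seriousness outcome categories
VALID_OUTCOMES = frozenset({"death", "life-threatening", "hospitalization",
                            "disability", "congenital anomaly",
                            "required intervention", "other"})

AGE_GROUPS = ("<18", "18-44", "45-64", ">=65", "unspecified")


class ValidationError(ValueError):
    """A record or configuration violates a structural invariant."""


@dataclass(frozen=True)
class DrugExposure:
    """One drug mentioned on a report, with its role and start date."""

    drug_name: str
    role: str = ROLE_PRIMARY_SUSPECT
    start_date: Optional[dt.date] = None

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ValidationError(f"invalid drug role {self.role!r}; "
                                  f"expected one of {sorted(VALID_ROLES)}")


@dataclass
class ReportRecord:
    """One spontaneous adverse-event report (a single case version)."""

    case_id: str
    version_id: int
    receipt_date: dt.date
    drugs: Sequence[DrugExposure]
    reactions: frozenset[str]
    event_date: Optional[dt.date] = None
    sex: str = "unspecified"
    age_years: Optional[float] = None
    reporter: str = "unspecified"
    country: Optional[str] = None
    serious: bool = True
    outcomes: frozenset[str] = field(default_factory=frozenset)
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValidationError("case_id must be non-empty")
        if not self.reactions:
            raise ValidationError(f"case {self.case_id}: reactions must be non-empty")
        if self.sex not in VALID_SEXES:
            raise ValidationError(f"case {self.case_id}: invalid sex {self.sex!r}")
        if self.reporter not in VALID_REPORTERS:
            raise ValidationError(f"case {self.case_id}: invalid reporter {self.reporter!r}")
        bad = set(self.outcomes) - VALID_OUTCOMES
        if bad:
            raise ValidationError(f"case {self.case_id}: invalid outcomes {sorted(bad)}")
        if self.age_years is not None and not (0.0 <= self.age_years <= 130.0):
            raise ValidationError(f"case {self.case_id}: age {self.age_years} outside [0, 130]")
        self.reactions = frozenset(self.reactions)
        self.outcomes = frozenset(self.outcomes)
        self.drugs = tuple(self.drugs)

    @property
    def age_group(self) -> str:
        from .ingest import derive_age_group  # local import avoids cycle
        return derive_age_group(self.age_years)

    def primary_suspects(self) -> tuple[str, ...]:
        """Names of all drugs carrying the primary-suspect role."""
        return tuple(d.drug_name for d in self.drugs if d.role == ROLE_PRIMARY_SUSPECT)

    def primary_start_date(self, drug_name: str) -> Optional[dt.date]:
        for d in self.drugs:
            if d.role == ROLE_PRIMARY_SUSPECT and d.drug_name == drug_name:
                return d.start_date
        return None


#: PTs naming central-nervous-system hematomas; both English spellings so that
#: reports coded under either dialect match.  Fully overridable in AnalysisConfig.
DEFAULT_TARGET_PTS = frozenset({
    "Subdural hematoma", "Subdural haematoma",
    "Cerebral hematoma", "Cerebral haematoma",
    "Extradural hematoma", "Extradural haematoma",
    "Spinal epidural hematoma", "Spinal epidural haematoma",
})

DEFAULT_STUDY_DRUGS = ("aspirin", "clopidogrel", "ticagrelor", "prasugrel")


@dataclass
class AnalysisConfig:
    """Defines the drug/event scope of a disproportionality analysis.

    ``counting_unit`` selects the denominator semantics: ``"case"`` counts one
    deduplicated case per cell (descriptive-table semantics) while
    ``"drug-event-pair"`` counts each (case, matching PT) pair (PT-level
    semantics).  Warfarin is the conventional positive control for hemorrhagic
    events; rosuvastatin, widely co-prescribed but without documented
    hemorrhagic risk, serves as the negative control.
    """

    target_pt_set: frozenset[str] = DEFAULT_TARGET_PTS
    study_drugs: tuple[str, ...] = DEFAULT_STUDY_DRUGS
    positive_control: str = "warfarin"
    negative_control: str = "rosuvastatin"
    counting_unit: str = "case"
    date_window: Optional[tuple[dt.date, dt.date]] = None
    drug_synonyms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.target_pt_set = frozenset(self.target_pt_set)
        self.study_drugs = tuple(self.study_drugs)
        if not self.target_pt_set:
            raise ValidationError("target_pt_set must be non-empty")
        if not self.study_drugs:
            raise ValidationError("study_drugs must be non-empty")
        for ctrl in (self.positive_control, self.negative_control):
            if ctrl in self.study_drugs:
                raise ValidationError(f"control drug {ctrl!r} overlaps study drugs")
        if self.counting_unit not in ("case", "drug-event-pair"):
            raise ValidationError(f"invalid counting_unit {self.counting_unit!r}")

    @property
    def all_drugs(self) -> tuple[str, ...]:
        return self.study_drugs + (self.positive_control, self.negative_control)

    def normalize_drug(self, name: str) -> str:
        """Case-insensitive exact match against the synonym list (brand -> generic)."""
        key = name.strip().lower()
        return self.drug_synonyms.get(key, key)
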