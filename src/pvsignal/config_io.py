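"""YAML configuration loading for the command-line interface.

A config file may carry a ``synthetic:`` section (generator parameters; the
nested ``signal_multipliers`` and ``strata_effects`` mappings are written
``drug -> pt -> value`` and ``stratum -> drug -> value``) and an
``analysis:`` section mirroring :class:`pvsignal.records.AnalysisConfig`.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .records import AnalysisConfig
from .synthetic import SyntheticConfig


def _flatten(nested: dict) -> dict:
    return {(outer, inner): v
            for outer, sub in (nested or {}).items()
            for inner, v in sub.items()}


def load_config(path) -> tuple[SyntheticConfig | None, AnalysisConfig]:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    syn = None
    if "synthetic" in raw:
        s = dict(raw["synthetic"])
        if "signal_multipliers" in s:
            s["signal_multipliers"] = _flatten(s["signal_multipliers"])
        if "strata_effects" in s:
            s["strata_effects"] = _flatten(s["strata_effects"])
        if "age_distribution" in s:
            s["age_distribution"] = [tuple(b) for b in s["age_distribution"]]
        if "target_pts" in s:
            s["target_pts"] = frozenset(s["target_pts"])
        syn = SyntheticConfig(**s)
    a = dict(raw.get("analysis", {}))
    if "target_pt_set" in a:
        a["target_pt_set"] = frozenset(a["target_pt_set"])
    if "study_drugs" in a:
        a["study_drugs"] = tuple(a["study_drugs"])
    analysis = AnalysisConfig(**a)
    return syn, analysis
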