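"""ECG parameter schema.

A 12-lead resting ECG, after automatic measurement, is summarised by a fixed
table of scalar parameters: per-lead waveform amplitudes and durations plus a
handful of global intervals, axes and demographics.  The default schema used
throughout this package has 178 entries: 12 leads x 14 per-lead measurements
(168) plus 10 global entries.  Schemas are user-replaceable via JSON; only the
default is privileged.

Each parameter kind carries a *direction vocabulary*: the ECG finding word that
applies when the value is abnormally low or abnormally high (e.g. a low R-wave
amplitude reads as "low voltage", a long ventricular activation time as "VAT
prolongation").  The criteria module consumes this vocabulary when it turns
attribution-derived decision factors into human-readable decision criteria.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

LEADS = ["I", "II", "III", "aVR", "aVL", "aVF", "V1", "V2", "V3", "V4", "V5", "V6"]

#: per-lead measurement kinds (14 per lead)
LEAD_KINDS = [
    "R_amp", "S_amp", "Q_amp", "T_amp", "P_amp", "ST_level",
    "R_dur", "S_dur", "Q_dur", "P_dur", "T_dur",
    "VAT", "QTc_lead", "RR_lead",
]

#: global (whole-ECG) kinds (10)
GLOBAL_KINDS = [
    "HR", "PR_interval", "QRS_duration", "QT_interval", "QTc",
    "QRS_axis", "P_axis", "RR_interval", "age", "sex",
]

_UNITS = {
    "R_amp": "mV", "S_amp": "mV", "Q_amp": "mV", "T_amp": "mV", "P_amp": "mV",
    "ST_level": "mV",
    "R_dur": "ms", "S_dur": "ms", "Q_dur": "ms", "P_dur": "ms", "T_dur": "ms",
    "VAT": "ms", "QTc_lead": "ms", "RR_lead": "ms",
    "HR": "bpm", "PR_interval": "ms", "QRS_duration": "ms", "QT_interval": "ms",
    "QTc": "ms", "QRS_axis": "degrees", "P_axis": "degrees", "RR_interval": "ms",
    "age": "years", "sex": "binary",
}

# Finding word when the parameter is abnormally low / abnormally high.
# ``None`` means no finding is read in that direction.  T-wave amplitude is
# special-cased in the criteria module: "negative T-wave inversion" requires
# the cluster median to actually be negative, not merely below reference.
_DIRECTION_VOCAB = {
    "R_amp": ("low voltage", "high voltage"),
    "S_amp": ("low voltage", "deep S wave"),
    "Q_amp": (None, "Q wave"),            # deep (large-magnitude) Q wave
    "T_amp": ("negative T-wave inversion", "tall T wave"),
    "P_amp": (None, None),
    "ST_level": ("ST depression", "ST elevation"),
    "R_dur": (None, "R-wave prolongation"),
    "S_dur": (None, "S-wave prolongation"),
    "Q_dur": (None, "Q wave"),            # wide Q wave is still "Q wave"
    "P_dur": (None, "P-wave prolongation"),
    "T_dur": (None, "T-wave prolongation"),
    "VAT": (None, "VAT prolongation"),
    "QTc_lead": (None, "QTc prolongation"),
    "RR_lead": (None, None),
    # globals: only QTc yields a criterion within the six canonical categories
    "HR": (None, None),
    "PR_interval": (None, "PR prolongation"),
    "QRS_duration": (None, "QRS prolongation"),
    "QT_interval": (None, "QT prolongation"),
    "QTc": (None, "QTc prolongation"),
    "QRS_axis": (None, None),
    "P_axis": (None, None),
    "RR_interval": (None, None),
    "age": (None, None),                  # demographic, never a waveform finding
    "sex": (None, None),
}

#: kinds that describe the waveform itself (eligible to become decision criteria)
WAVEFORM_KINDS = frozenset(LEAD_KINDS) | {"QTc", "PR_interval", "QRS_duration", "QT_interval"}


@dataclass(frozen=True)
class SchemaEntry:
    name: str
    lead: str            # one of LEADS or "GLOBAL"
    kind: str
    units: str

    @property
    def vocab(self) -> tuple[Optional[str], Optional[str]]:
        """(finding-when-low, finding-when-high) for this parameter kind."""
        return _DIRECTION_VOCAB[self.kind]


@dataclass
class ParameterSchema:
    """Ordered collection of ECG parameter definitions."""

    entries: list[SchemaEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate parameter names in schema: {dup}")
        for e in self.entries:
            if e.lead != "GLOBAL" and e.lead not in LEADS:
                raise ValueError(f"unknown lead {e.lead!r} for parameter {e.name!r}")
            if e.kind not in _DIRECTION_VOCAB:
                raise ValueError(f"unknown parameter kind {e.kind!r} ({e.name!r})")
        self._index = {e.name: i for i, e in enumerate(self.entries)}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def index(self, name: str) -> int:
        return self._index[name]

    def entry(self, name: str) -> SchemaEntry:
        return self.entries[self._index[name]]

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    # ---- serialisation -------------------------------------------------
    def to_json(self, path) -> None:
        payload = [
            {"name": e.name, "lead": e.lead, "kind": e.kind, "units": e.units}
            for e in self.entries
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ParameterSchema":
        with open(path) as fh:
            payload = json.load(fh)
        return cls([SchemaEntry(d["name"], d["lead"], d["kind"], d["units"]) for d in payload])


def lead_param(kind: str, lead: str) -> str:
    """Canonical name of a per-lead parameter, e.g. ``R_amp_V5``."""
    return f"{kind}_{lead}"


def default_schema() -> ParameterSchema:
    """The 178-parameter default schema (12 leads x 14 kinds + 10 globals)."""
    entries = [
        SchemaEntry(lead_param(kind, lead), lead, kind, _UNITS[kind])
        for lead in LEADS
        for kind in LEAD_KINDS
    ]
    entries += [SchemaEntry(kind, "GLOBAL", kind, _UNITS[kind]) for kind in GLOBAL_KINDS]
    return ParameterSchema(entries)


# Lead families within which a shared finding is merged into one criterion.
# These mirror the canonical lead groupings of the six finding categories
# (lateral T inversion, broad low voltage, precordial Q waves, lateral VAT,
# right-precordial S prolongation).  QTc merges across any leads.
MERGE_GROUPS: dict[str, list[str]] = {
    "negative T-wave inversion": ["I", "II", "aVL", "V4", "V5", "V6"],
    "low voltage": ["I", "II", "aVL", "V4", "V5", "V6"],
    "Q wave": ["V3", "V4", "V5", "V6"],
    "VAT prolongation": ["I", "aVL", "V4", "V5", "V6"],
    "S-wave prolongation": ["V1", "V2", "V3"],
}


def lead_sort_key(lead: str) -> int:
    return (LEADS + ["GLOBAL"]).index(lead)


def sort_leads(leads: Iterable[str]) -> list[str]:
    return sorted(set(leads), key=lead_sort_key)
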