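"""Decision factors, decision criteria and the six finding categories.

Within each attribution cluster, a parameter is a *decision factor* when its
median Shapley value across the cluster's records exceeds the mean + 1 SD of
the per-parameter medians (population-SD convention).  Decision factors on
waveform parameters are then translated into signed ECG findings ("decision
criteria") by comparing the cluster's median parameter value against the
reference (whole test set) median: low amplitudes read as low voltage,
negative T amplitudes as T-wave inversion, long durations as prolongation,
and prominent Q waves as Q waves.  Non-waveform factors (age, sex, axes)
influence the model but yield no ECG finding.

Findings map onto six canonical categories; VAT prolongation and S-wave
prolongation are additionally flagged as one intraventricular-conduction-
delay super-group in reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .attribution import AttributionMatrix
from .geometry import ClusterAssignment
from .schema import MERGE_GROUPS, ParameterSchema, WAVEFORM_KINDS, sort_leads


class FindingCategory(str, Enum):
    """The six canonical ECG finding categories for reduced LVEF."""

    NEG_T_INVERSION_I_V56 = "NEG_T_INVERSION_I_V56"
    LOW_VOLTAGE_I_II_V46 = "LOW_VOLTAGE_I_II_V46"
    Q_WAVE_V36 = "Q_WAVE_V36"
    VAT_PROLONG_I_V56 = "VAT_PROLONG_I_V56"
    S_PROLONG_V23 = "S_PROLONG_V23"
    QTC_PROLONG = "QTC_PROLONG"


#: finding word -> (category, canonical lead family or None for any leads)
_CATEGORY_OF = {
    "negative T-wave inversion": (FindingCategory.NEG_T_INVERSION_I_V56,
                                  {"I", "II", "aVL", "V4", "V5", "V6"}),
    "low voltage": (FindingCategory.LOW_VOLTAGE_I_II_V46,
                    {"I", "II", "aVL", "V4", "V5", "V6"}),
    "Q wave": (FindingCategory.Q_WAVE_V36, {"V3", "V4", "V5", "V6"}),
    "VAT prolongation": (FindingCategory.VAT_PROLONG_I_V56,
                         {"I", "aVL", "V4", "V5", "V6"}),
    "S-wave prolongation": (FindingCategory.S_PROLONG_V23, {"V1", "V2", "V3"}),
    "QTc prolongation": (FindingCategory.QTC_PROLONG, None),
}

#: categories reported together as intraventricular conduction delay
IVCD_GROUP = {FindingCategory.VAT_PROLONG_I_V56, FindingCategory.S_PROLONG_V23}


@dataclass
class DecisionFactor:
    cluster: int
    parameter: str
    median_shap: float
    threshold_used: float

    def __post_init__(self) -> None:
        if not self.median_shap > self.threshold_used:
            raise ValueError("a decision factor must exceed its threshold")


@dataclass
class DecisionCriterion:
    cluster: int
    finding: str
    leads: list[str]
    direction: str          # low | high | negative | present

    def __post_init__(self) -> None:
        if not self.leads:
            raise ValueError("criterion needs at least one lead")
        if self.finding not in _CATEGORY_OF and self.direction not in (
                "low", "high", "negative", "present"):
            raise ValueError(f"invalid direction {self.direction!r}")

    def label(self) -> str:
        leads = "/".join(self.leads)
        return f"{self.finding} in {leads}"


def extract_decision_factors(attr: AttributionMatrix, ca: ClusterAssignment,
                             threshold_over: str = "medians",
                             include_unexplained: bool = False
                             ) -> list[DecisionFactor]:
    """Per-cluster decision factors from the attribution matrix.

    For each explained cluster: the median Shapley value of every parameter
    over the cluster's records is computed; the threshold is the mean + 1 SD
    (population convention) of those p medians, and parameters whose median
    strictly exceeds it become decision factors, sorted by decreasing median.
    ``threshold_over='entries'`` instead takes mean + SD over all n x p
    Shapley entries of the cluster (the alternative reading).
    """
    if threshold_over not in ("medians", "entries"):
        raise ValueError("threshold_over must be 'medians' or 'entries'")
    if len(ca.labels) != len(attr.record_ids):
        raise ValueError("cluster assignment does not cover the attribution rows")
    clusters = sorted(ca.sizes())
    if not include_unexplained:
        clusters = [c for c in clusters if c not in ca.unexplained]
    factors: list[DecisionFactor] = []
    for c in clusters:
        rows = attr.values[ca.labels == c]
        if rows.size == 0:
            warnings.warn(f"cluster {c} is empty; skipped")
            continue
        medians = np.median(rows, axis=0)
        pool = medians if threshold_over == "medians" else rows.ravel()
        thr = float(np.mean(pool) + np.std(pool, ddof=0))
        hits = np.flatnonzero(medians > thr)
        hits = hits[np.argsort(-medians[hits], kind="stable")]
        factors.extend(
            DecisionFactor(c, attr.feature_names[j], float(medians[j]), thr)
            for j in hits)
    return factors


def interpret_criteria(factors: Sequence[DecisionFactor],
                       cohort_values: np.ndarray,
                       cohort_labels: np.ndarray,
                       reference_values: np.ndarray,
                       schema: ParameterSchema,
                       min_effect_sd: float = 0.2) -> list[DecisionCriterion]:
    """Translate decision factors into signed ECG findings.

    For each factor on a waveform parameter the cluster's median parameter
    value is compared with the reference median; a finding is emitted only
    when the difference exceeds ``min_effect_sd`` reference SDs and the
    parameter's direction vocabulary names a finding for that direction.
    "Negative T-wave inversion" additionally requires the cluster median T
    amplitude to actually be negative.  Findings shared by several leads of
    one canonical lead family are merged into a single criterion.
    """
    cohort_values = np.asarray(cohort_values, dtype=float)
    reference_values = np.asarray(reference_values, dtype=float)
    if reference_values.size == 0:
        raise ValueError("reference table is empty")
    cohort_labels = np.asarray(cohort_labels)

    ref_median = np.median(reference_values, axis=0)
    ref_sd = np.std(reference_values, axis=0, ddof=0)

    # (cluster, finding) -> {lead: direction}
    partial: dict[tuple[int, str], dict[str, str]] = {}
    for fa in sorted(factors, key=lambda f: (f.cluster, f.parameter)):
        if fa.parameter not in schema:
            raise ValueError(f"decision factor on unknown parameter {fa.parameter!r}")
        ent = schema.entry(fa.parameter)
        if ent.kind not in WAVEFORM_KINDS:
            continue                        # demographics etc: no ECG finding
        j = schema.index(fa.parameter)
        members = cohort_values[cohort_labels == fa.cluster]
        if members.size == 0:
            continue
        cmed = float(np.median(members[:, j]))
        diff = cmed - float(ref_median[j])
        if abs(diff) < min_effect_sd * float(ref_sd[j]) or diff == 0.0:
            continue                        # no direction to report
        low, high = ent.vocab
        finding = low if diff < 0 else high
        if finding is None:
            continue
        if finding == "negative T-wave inversion":
            if cmed >= 0.0:
                continue                    # lowered but still upright T wave
            direction = "negative"
        elif finding in ("Q wave",):
            direction = "present"
        else:
            direction = "low" if diff < 0 else "high"
        partial.setdefault((fa.cluster, finding), {})[ent.lead] = direction

    criteria: list[DecisionCriterion] = []
    for (clu, finding), lead_dirs in sorted(partial.items(), key=lambda kv: kv[0]):
        leads = sort_leads(lead_dirs)
        family = MERGE_GROUPS.get(finding)
        direction = next(iter(set(lead_dirs.values())))
        if family is None:                  # QTc and global findings: merge all
            criteria.append(DecisionCriterion(clu, finding, leads, direction))
            continue
        merged = [ld for ld in leads if ld in family]
        rest = [ld for ld in leads if ld not in family]
        if merged:
            criteria.append(DecisionCriterion(clu, finding, merged, direction))
        for ld in rest:                     # outside the family: stand alone
            criteria.append(DecisionCriterion(clu, finding, [ld], lead_dirs[ld]))
    return criteria


@dataclass
class CategorySet:
    """Per-cluster decomposition into the six canonical categories."""

    cluster: int
    categories: set[FindingCategory] = field(default_factory=set)
    outside: list[str] = field(default_factory=list)    # findings beyond the six

    @property
    def conduction_delay(self) -> bool:
        """VAT and/or S-wave prolongation present (reported as one super-group)."""
        return bool(self.categories & IVCD_GROUP)

    def to_dict(self) -> dict:
        return {
            "cluster": self.cluster,
            "categories": sorted(c.value for c in self.categories),
            "outside_six_categories": sorted(self.outside),
            "intraventricular_conduction_delay": self.conduction_delay,
        }


def categorize(criteria: Sequence[DecisionCriterion]) -> dict[int, CategorySet]:
    """Map criteria onto the six canonical categories, per cluster.

    A finding outside the six categories (or a canonical finding in
    non-canonical leads) is reported under ``outside``, never dropped
    silently.  Deterministic and order-independent in the input.
    """
    out: dict[int, CategorySet] = {}
    for cr in criteria:
        cs = out.setdefault(cr.cluster, CategorySet(cr.cluster))
        entry = _CATEGORY_OF.get(cr.finding)
        if entry is None:
            cs.outside.append(cr.label())
            continue
        cat, family = entry
        if family is not None and not set(cr.leads) & family:
            cs.outside.append(cr.label())
            continue
        cs.categories.add(cat)
    return out
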