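"""The six rule-based metabolic-syndrome definitions and their classifier.

Each definition is declarative: a list of component predicates (sex-specific
cutoff + comparator + treatment/diagnosis substitution flags), an optional
mandatory component set or special gate, and a minimum component count.  A
participant is positive when the mandatory gate holds and at least
``min_components`` of the non-mandatory components are positive.

The five components are abdominal obesity (waist circumference), elevated
triglycerides, low HDL cholesterol, elevated blood pressure, and elevated
fasting glucose.  Comparator direction is taken literally from the published
cutoff tables (HDL uses ``<``; waist is strict ``>`` for the NCEP-ATPIII and
Barbosa 2006 waist cutoffs, ``>=`` elsewhere), so boundary values matter and
are unit-tested at each cutoff.

Built-in registry (all labs mg/dL, BP mmHg, WC cm):

================  ============================================================
IDF_AHA_NHLBI     harmonized gold standard — any >=3 of {WC >=90 M / >=80 F;
                  TG >=150; HDL <40 M / <50 F; BP >=130/85 or SAH treatment;
                  glucose >=100 or prior DM diagnosis/treatment}
NCEP_ATPIII       same five, WC >102 M / >88 F, >=3
BARBOSA2006       NCEP-ATPIII rules with Brazilian WC cutoffs >88 M / >84 F
IDF               WC >=90 M / >=80 F mandatory, plus >=2 of the other four
EGIR              insulin-resistance gate (proxy: glucose >=110 or DM
                  diagnosis/treatment — no insulin assay in the cohort), plus
                  >=2 of {WC >=94 M / >=80 F; TG >=150; HDL <39 both sexes;
                  BP >=140/90 or SAH treatment}
AACE              insulin-resistance *risk* gate (any one listed indicator),
                  plus >=2 of {TG >=150; HDL <40 M / <50 F; BP >=130/85};
                  no waist or glucose component
================  ============================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .accuracy import exact_ci
from .cohort import Cohort, ParticipantRecord

__all__ = [
    "COMPONENTS",
    "ComponentPredicate",
    "CriterionDefinition",
    "ComponentStatus",
    "PrevalenceEstimate",
    "builtin_criteria",
    "get_criterion",
    "evaluate_components",
    "classify",
    "classify_cohort",
    "prevalence",
]

COMPONENTS = ("waist", "triglycerides", "hdl", "blood_pressure", "glucose")

_FIELD_OF = {
    "waist": "waist_cm",
    "triglycerides": "tg_mgdl",
    "hdl": "hdl_mgdl",
    "glucose": "glucose_mgdl",
}

_CMP: dict[str, Callable[[float, float], bool]] = {
    ">=": lambda v, c: v >= c,
    ">": lambda v, c: v > c,
    "<": lambda v, c: v < c,
}


@dataclass(frozen=True)
class ComponentPredicate:
    """One component rule: sex-specific cutoff, comparator, substitutions.

    ``blood_pressure`` predicates interpret ``cutoff_*`` as the systolic
    threshold and ``dbp_cutoff`` as the diastolic one; the component is
    positive when either pressure crosses its threshold (the usual
    "130/85"-style reading) or a substitution flag is set.
    """

    component: str
    cutoff_female: float
    cutoff_male: float
    comparator: str = ">="
    dbp_cutoff: Optional[float] = None
    substitution_flags: frozenset = frozenset()

    def __post_init__(self):
        if self.component not in COMPONENTS:
            raise ValueError(f"unknown component {self.component!r}")
        if self.comparator not in _CMP:
            raise ValueError(f"unknown comparator {self.comparator!r}")
        if self.component == "hdl" and self.comparator != "<":
            raise ValueError("hdl comparator must be '<'")
        if self.component != "hdl" and self.comparator == "<":
            raise ValueError(f"{self.component} comparator cannot be '<'")
        if (self.component == "blood_pressure") != (self.dbp_cutoff is not None):
            raise ValueError("dbp_cutoff is required for (and only for) blood_pressure")

    def cutoff_for(self, sex: str) -> float:
        return self.cutoff_female if sex == "female" else self.cutoff_male

    def measured_positive(self, record: ParticipantRecord) -> bool:
        """Measurement-only evaluation (no substitution flags)."""
        cmp = _CMP[self.comparator]
        if self.component == "blood_pressure":
            return cmp(record.sbp_mmHg, self.cutoff_for(record.sex)) or cmp(
                record.dbp_mmHg, self.dbp_cutoff
            )
        return cmp(getattr(record, _FIELD_OF[self.component]), self.cutoff_for(record.sex))

    def __call__(self, record: ParticipantRecord) -> bool:
        if any(bool(getattr(record, f)) for f in self.substitution_flags):
            return True
        return self.measured_positive(record)


# -- special mandatory gates -------------------------------------------------

def egir_ir_proxy(record: ParticipantRecord) -> bool:
    """Insulin-resistance proxy gate for EGIR in a cohort with no insulin
    assays: fasting glucose >= 110 mg/dL or prior diabetes diagnosis/treatment."""
    return record.glucose_mgdl >= 110 or record.dm_diagnosis or record.dm_treatment


def aace_ir_risk(record: ParticipantRecord) -> bool:
    """AACE high-insulin-resistance-risk gate: any one of the listed
    indicators.  Unknown (None) history flags count as absent."""
    wc_cut = 80.0 if record.sex == "female" else 94.0
    return any(
        (
            record.cvd,
            record.sah_diagnosis,
            record.pcos,
            record.nafld,
            record.acanthosis,
            bool(record.family_history_t2dm_htn_cvd),
            bool(record.gestational_dm_history),
            record.nonwhite,
            record.sedentary,
            record.age_over_40,
            record.bmi is not None and record.bmi >= 25,
            record.waist_cm > wc_cut,
        )
    )


_GATES: dict[str, Callable[[ParticipantRecord], bool]] = {
    "egir_ir_proxy": egir_ir_proxy,
    "aace_ir_risk": aace_ir_risk,
}


@dataclass(frozen=True)
class CriterionDefinition:
    """A complete MetS definition.

    ``mandatory`` lists component names that must themselves be positive
    before the remaining components are counted; ``gate`` names a special
    non-component precondition (registered in ``_GATES``).  A definition has
    at most one of the two in the built-in registry, but both are honoured.
    """

    name: str
    predicates: tuple[ComponentPredicate, ...]
    min_components: int
    mandatory: frozenset = frozenset()
    gate: Optional[str] = None

    def __post_init__(self):
        comps = [p.component for p in self.predicates]
        if len(set(comps)) != len(comps):
            raise ValueError(f"{self.name}: duplicate component predicate")
        unknown = set(self.mandatory) - set(comps)
        if unknown:
            raise ValueError(f"{self.name}: mandatory components {sorted(unknown)} have no predicate")
        n_countable = len(comps) - len(self.mandatory)
        if self.min_components > n_countable:
            raise ValueError(f"{self.name}: min_components {self.min_components} > countable components {n_countable}")
        if self.gate is not None and self.gate not in _GATES:
            raise ValueError(f"{self.name}: unknown gate {self.gate!r}")

    def predicate_for(self, component: str) -> ComponentPredicate:
        for p in self.predicates:
            if p.component == component:
                return p
        raise KeyError(component)

    def to_dict(self) -> dict:
        """Serializable form (auditable / editable criteria config)."""
        return {
            "name": self.name,
            "min_components": self.min_components,
            "mandatory": sorted(self.mandatory),
            "gate": self.gate,
            "predicates": [
                {
                    "component": p.component,
                    "cutoff_female": p.cutoff_female,
                    "cutoff_male": p.cutoff_male,
                    "comparator": p.comparator,
                    "dbp_cutoff": p.dbp_cutoff,
                    "substitution_flags": sorted(p.substitution_flags),
                }
                for p in self.predicates
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CriterionDefinition":
        preds = tuple(
            ComponentPredicate(
                component=p["component"],
                cutoff_female=p["cutoff_female"],
                cutoff_male=p["cutoff_male"],
                comparator=p.get("comparator", ">="),
                dbp_cutoff=p.get("dbp_cutoff"),
                substitution_flags=frozenset(p.get("substitution_flags", ())),
            )
            for p in d["predicates"]
        )
        return cls(
            name=d["name"],
            predicates=preds,
            min_components=d["min_components"],
            mandatory=frozenset(d.get("mandatory", ())),
            gate=d.get("gate"),
        )


# -- built-in registry -------------------------------------------------------

_GLUCOSE_SUBS = frozenset({"dm_diagnosis", "dm_treatment"})
_BP_SUBS = frozenset({"sah_treatment"})


def _five(wc_f, wc_m, wc_cmp=">="):
    return (
        ComponentPredicate("waist", wc_f, wc_m, wc_cmp),
        ComponentPredicate("triglycerides", 150, 150),
        ComponentPredicate("hdl", 50, 40, "<"),
        ComponentPredicate("blood_pressure", 130, 130, ">=", dbp_cutoff=85, substitution_flags=_BP_SUBS),
        ComponentPredicate("glucose", 100, 100, ">=", substitution_flags=_GLUCOSE_SUBS),
    )


def builtin_criteria(aace_glucose_component: bool = False) -> dict[str, CriterionDefinition]:
    """The six built-in definitions, keyed by name, gold standard first.

    ``aace_glucose_component=True`` adds the canonical AACE impaired-fasting
    glucose component (110–125 mg/dL band approximated as >=110) which the
    source cohort's rule table omits for lack of glucose-tolerance testing.
    """
    crits = {
        "IDF_AHA_NHLBI": CriterionDefinition("IDF_AHA_NHLBI", _five(80, 90), 3),
        "EGIR": CriterionDefinition(
            "EGIR",
            (
                ComponentPredicate("waist", 80, 94),
                ComponentPredicate("triglycerides", 150, 150),
                ComponentPredicate("hdl", 39, 39, "<"),
                ComponentPredicate("blood_pressure", 140, 140, ">=", dbp_cutoff=90, substitution_flags=_BP_SUBS),
            ),
            2,
            gate="egir_ir_proxy",
        ),
        "NCEP_ATPIII": CriterionDefinition("NCEP_ATPIII", _five(88, 102, ">"), 3),
        "AACE": CriterionDefinition(
            "AACE",
            (
                ComponentPredicate("triglycerides", 150, 150),
                ComponentPredicate("hdl", 50, 40, "<"),
                ComponentPredicate("blood_pressure", 130, 130, ">=", dbp_cutoff=85, substitution_flags=_BP_SUBS),
            )
            + (
                (ComponentPredicate("glucose", 110, 110, ">=", substitution_flags=_GLUCOSE_SUBS),)
                if aace_glucose_component
                else ()
            ),
            2,
            gate="aace_ir_risk",
        ),
        "IDF": CriterionDefinition("IDF", _five(80, 90), 2, mandatory=frozenset({"waist"})),
        "BARBOSA2006": CriterionDefinition("BARBOSA2006", _five(84, 88, ">"), 3),
    }
    return crits


DEFAULT_CRITERIA_ORDER = ("IDF_AHA_NHLBI", "EGIR", "AACE", "NCEP_ATPIII", "BARBOSA2006", "IDF")


def get_criterion(name: str) -> CriterionDefinition:
    try:
        return builtin_criteria()[name]
    except KeyError:
        raise KeyError(f"unknown criterion {name!r}; built-ins: {sorted(builtin_criteria())}") from None


# -- evaluation --------------------------------------------------------------

@dataclass(frozen=True)
class ComponentStatus:
    """Per-component outcome of one record under one criterion."""

    components: dict
    mandatory_gate: bool

    @property
    def n_positive(self) -> int:
        return sum(bool(v) for v in self.components.values())


def _require_classifiable(record: ParticipantRecord) -> None:
    miss = record.missing_fields()
    if miss:
        raise ValueError(f"record {record.id!r} is not classifiable; missing: {miss}")


def evaluate_components(record: ParticipantRecord, criterion: CriterionDefinition) -> ComponentStatus:
    """Evaluate every component predicate (substitutions applied) plus the
    mandatory gate for one record."""
    _require_classifiable(record)
    comps = {p.component: p(record) for p in criterion.predicates}
    gate = True
    if criterion.gate is not None:
        gate = _GATES[criterion.gate](record)
    for m in criterion.mandatory:
        gate = gate and comps[m]
    return ComponentStatus(components=comps, mandatory_gate=gate)


def classify(record: ParticipantRecord, criterion: CriterionDefinition) -> bool:
    """True iff the mandatory gate holds and at least ``min_components`` of
    the non-mandatory components are positive."""
    status = evaluate_components(record, criterion)
    countable = sum(
        bool(v) for k, v in status.components.items() if k not in criterion.mandatory
    )
    return status.mandatory_gate and countable >= criterion.min_components


def classify_cohort(
    cohort: Cohort, criteria: Sequence[CriterionDefinition]
) -> pd.DataFrame:
    """Label matrix: one boolean column per criterion (input order), one row
    per record, indexed by record id."""
    data = {}
    for crit in criteria:
        col = []
        for r in cohort:
            try:
                col.append(classify(r, crit))
            except ValueError as exc:
                raise ValueError(f"{crit.name}: {exc}") from exc
        data[crit.name] = col
    return pd.DataFrame(data, index=pd.Index(cohort.ids, name="id"), dtype=bool)


@dataclass(frozen=True)
class PrevalenceEstimate:
    count: int
    n: int
    point: float  # proportion in [0, 1]
    ci_low: float
    ci_high: float

    @property
    def percent(self) -> float:
        return 100.0 * self.point


def prevalence(labels, stratum=None, level: float = 0.95) -> PrevalenceEstimate:
    """Proportion positive with an exact (Clopper-Pearson) confidence interval.

    ``stratum`` optionally masks the label vector to a subgroup (e.g. one sex).
    """
    lab = np.asarray(labels, dtype=bool)
    if stratum is not None:
        lab = lab[np.asarray(stratum, dtype=bool)]
    n = lab.size
    if n == 0:
        raise ValueError("empty stratum")
    k = int(lab.sum())
    lo, hi = exact_ci(k, n, level)
    return PrevalenceEstimate(count=k, n=n, point=k / n, ci_low=lo, ci_high=hi)
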