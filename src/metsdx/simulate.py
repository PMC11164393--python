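"""Seeded synthetic-cohort generator.

Emulates the statistical structure of the reference cohort (1,111 primary-
care nursing professionals, ~87.7% female): sex-specific location/scale of
each continuous measure, and — what downstream classification actually
depends on — the sex-specific *positivity fraction* of each of the five MetS
components at the harmonized cutoffs.

Mechanism: a Gaussian copula over five component latents (waist, TG, HDL,
blood pressure, glucose) with exchangeable correlation (default rho = 0.3),
each mapped to a location-shifted normal whose SD is the reference value and
whose location is chosen so the cutoff quantile equals the target positivity
(quantile matching).  The reference means/SDs alone cannot reproduce the
reference positivity fractions (real distributions are skewed), so the
positivity fraction wins; the published SDs keep the scale realistic.

Systolic and diastolic pressure share one latent (comonotone within
subject), both margins matched to the same target, so the "130/85-or-above"
union event hits the target exactly.  Treatment/diagnosis flags are drawn
conditionally on the raw component positivity so that the substitution code
paths of the classifier are exercised.  Calibration targets refer to the
measured predicate (value vs cutoff), not the flag-substituted component.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats

from .cohort import Cohort, ParticipantRecord
from .criteria import CriterionDefinition

__all__ = [
    "CohortSpec",
    "DEFAULT_CONTINUOUS_PARAMS",
    "DEFAULT_TARGETS",
    "generate",
    "plant_labels",
    "reference_classify",
]

#: (mean, SD) per sex for each continuous measure — reference cohort values.
DEFAULT_CONTINUOUS_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "female": {
        "glucose": (84.48, 18.04),
        "tg": (132.41, 55.24),
        "hdl": (58.80, 31.30),
        "waist": (86.33, 14.11),
        "bmi": (26.18, 8.64),
        "sbp": (116.58, 15.44),
        "dbp": (77.02, 10.61),
    },
    "male": {
        "glucose": (86.19, 16.08),
        "tg": (148.17, 67.27),
        "hdl": (57.72, 27.02),
        "waist": (89.60, 15.71),
        "bmi": (27.55, 4.50),
        "sbp": (123.70, 14.09),
        "dbp": (82.55, 9.41),
    },
}

#: Target positivity per component at the harmonized cutoffs, per sex —
#: the reference cohort's measured component positivity.
DEFAULT_TARGETS: dict[str, dict[str, float]] = {
    "female": {
        "glucose": 0.1631,   # glucose >= 100
        "triglycerides": 0.3231,   # TG >= 150
        "hdl": 0.4697,       # HDL < 50
        "waist": 0.6831,     # WC >= 80
        "blood_pressure": 0.1641,  # >= 130/85
    },
    "male": {
        "glucose": 0.1985,
        "triglycerides": 0.4118,
        "hdl": 0.2279,       # HDL < 40
        "waist": 0.5221,     # WC >= 90
        "blood_pressure": 0.2721,
    },
}

#: Calibration cutoffs (harmonized criterion), per sex where they differ.
_CAL_CUTOFFS = {
    "glucose": {"female": (100.0, ">="), "male": (100.0, ">=")},
    "triglycerides": {"female": (150.0, ">="), "male": (150.0, ">=")},
    "hdl": {"female": (50.0, "<"), "male": (40.0, "<")},
    "waist": {"female": (80.0, ">="), "male": (90.0, ">=")},
    # blood pressure handled specially: (SBP cutoff, DBP cutoff)
    "blood_pressure": {"female": ((130.0, 85.0), ">="), "male": ((130.0, 85.0), ">=")},
}

#: Conditional flag probabilities (see module docstring).  ``*_pos``/``*_neg``
#: condition on the raw glucose / blood-pressure component positivity.
DEFAULT_FLAG_PROBS: dict[str, float] = {
    "dm_treatment_given_pos": 0.5,
    "dm_treatment_given_neg": 0.02,
    "dm_diagnosis_given_pos": 0.3,
    "dm_diagnosis_given_neg": 0.01,
    "sah_treatment_given_pos": 0.5,
    "sah_treatment_given_neg": 0.02,
    "sah_diagnosis_given_pos": 0.3,
    "sah_diagnosis_given_neg": 0.02,
    "cvd": 0.05,
    "pcos_female": 0.08,
    "nafld": 0.05,
    "acanthosis": 0.03,
    "sedentary": 0.4329,
    "nonwhite": 0.7480,
}

_LATENT_ORDER = ("waist", "triglycerides", "hdl", "blood_pressure", "glucose")

#: Physiological floors applied after generation (far below every cutoff, so
#: they cannot disturb calibration; they keep records valid, i.e. positive).
_FLOORS = {"glucose": 40.0, "tg": 30.0, "hdl": 10.0, "waist": 50.0, "bmi": 13.0, "sbp": 70.0, "dbp": 40.0}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    Defaults are the reference study's conditions: n = 1111, 87.7% female,
    reference means/SDs, reference component positivity, exchangeable latent
    correlation 0.3 (an assumption — the study reports no component
    correlations), conditional treatment-flag probabilities.
    """

    n: int = 1111
    female_fraction: float = 0.877
    continuous_params: dict = field(default_factory=lambda: DEFAULT_CONTINUOUS_PARAMS)
    targets: dict = field(default_factory=lambda: DEFAULT_TARGETS)
    rho: float = 0.3
    correlation: Optional[np.ndarray] = None  # overrides rho when given (5x5)
    flag_probs: dict = field(default_factory=lambda: DEFAULT_FLAG_PROBS)
    age_mean: float = 34.52   # P(age <= 35) = 52.12%, the reference fraction
    age_sd: float = 9.0
    seed: int = 0

    def corr_matrix(self) -> np.ndarray:
        if self.correlation is not None:
            c = np.asarray(self.correlation, dtype=float)
        else:
            c = np.full((5, 5), self.rho)
            np.fill_diagonal(c, 1.0)
        if c.shape != (5, 5) or not np.allclose(c, c.T):
            raise ValueError("correlation must be a symmetric 5x5 matrix")
        if np.linalg.eigvalsh(c).min() <= 1e-10:
            raise ValueError("correlation matrix must be positive definite")
        return c

    def validate(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must be in [0, 1]")
        for sex in ("female", "male"):
            for comp, p in self.targets[sex].items():
                if not 0 <= p <= 1:
                    raise ValueError(f"target for {comp}/{sex} out of [0, 1]: {p}")
                _, cmp = _CAL_CUTOFFS[comp][sex]
                if p in (0.0, 1.0) and cmp in ("<", ">"):
                    raise ValueError(
                        f"target {p} for {comp}/{sex} is infeasible with strict comparator {cmp}"
                    )
        for p in self.flag_probs.values():
            if not 0 <= p <= 1:
                raise ValueError("flag probabilities must be in [0, 1]")
        self.corr_matrix()


def _shifted_mean(cutoff: float, sd: float, target: float, comparator: str) -> float:
    """Location of a normal with the given SD whose ``comparator cutoff``
    probability equals ``target`` (quantile matching)."""
    p = min(max(target, 1e-12), 1 - 1e-12)
    if comparator in (">=", ">"):
        return cutoff - sd * stats.norm.ppf(1 - p)
    return cutoff - sd * stats.norm.ppf(p)  # "<"


def generate(spec: CohortSpec) -> Cohort:
    """Draw a cohort; deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    female = rng.random(n) < spec.female_fraction
    sexes = np.where(female, "female", "male")

    chol = np.linalg.cholesky(spec.corr_matrix())
    z = rng.standard_normal((n, 5)) @ chol.T  # component risk latents
    lat = {comp: z[:, i] for i, comp in enumerate(_LATENT_ORDER)}

    vals = {k: np.empty(n) for k in ("glucose", "tg", "hdl", "waist", "sbp", "dbp")}
    for sex in ("female", "male"):
        m = sexes == sex
        if not m.any():
            continue
        cp = spec.continuous_params[sex]
        tg_ = spec.targets[sex]
        for comp, key in (("glucose", "glucose"), ("triglycerides", "tg"), ("waist", "waist")):
            cutoff, cmp = _CAL_CUTOFFS[comp][sex]
            mu = _shifted_mean(cutoff, cp[key][1], tg_[comp], cmp)
            vals[key][m] = mu + cp[key][1] * lat[comp][m]
        # HDL: low value is the risk direction -> value latent is -risk latent
        cutoff, cmp = _CAL_CUTOFFS["hdl"][sex]
        mu = _shifted_mean(cutoff, cp["hdl"][1], tg_["hdl"], cmp)
        vals["hdl"][m] = mu - cp["hdl"][1] * lat["hdl"][m]
        # blood pressure: SBP and DBP share the latent, both margins matched
        (sc, dc), cmp = _CAL_CUTOFFS["blood_pressure"][sex]
        mu_s = _shifted_mean(sc, cp["sbp"][1], tg_["blood_pressure"], cmp)
        mu_d = _shifted_mean(dc, cp["dbp"][1], tg_["blood_pressure"], cmp)
        vals["sbp"][m] = mu_s + cp["sbp"][1] * lat["blood_pressure"][m]
        vals["dbp"][m] = mu_d + cp["dbp"][1] * lat["blood_pressure"][m]

    # BMI rides on the waist latent; no positivity target of its own
    z_bmi = 0.8 * lat["waist"] + 0.6 * rng.standard_normal(n)
    bmi = np.empty(n)
    for sex in ("female", "male"):
        m = sexes == sex
        mu, sd = spec.continuous_params[sex]["bmi"]
        bmi[m] = mu + sd * z_bmi[m]
    vals["bmi"] = bmi

    for key, floor in _FLOORS.items():
        vals[key] = np.maximum(vals[key], floor)
    age = np.clip(spec.age_mean + spec.age_sd * rng.standard_normal(n), 20.0, 70.0)

    fp = spec.flag_probs
    p = lambda key: fp.get(key, 0.0)

    def conditional(prefix: str, positive: np.ndarray) -> np.ndarray:
        probs = np.where(positive, p(f"{prefix}_given_pos"), p(f"{prefix}_given_neg"))
        return rng.random(n) < probs

    glu_pos = vals["glucose"] >= 100
    bp_pos = (vals["sbp"] >= 130) | (vals["dbp"] >= 85)
    flags = {
        "dm_treatment": conditional("dm_treatment", glu_pos),
        "dm_diagnosis": conditional("dm_diagnosis", glu_pos),
        "sah_treatment": conditional("sah_treatment", bp_pos),
        "sah_diagnosis": conditional("sah_diagnosis", bp_pos),
        "cvd": rng.random(n) < p("cvd"),
        "pcos": (rng.random(n) < p("pcos_female")) & female,
        "nafld": rng.random(n) < p("nafld"),
        "acanthosis": rng.random(n) < p("acanthosis"),
        "sedentary": rng.random(n) < p("sedentary"),
        "nonwhite": rng.random(n) < p("nonwhite"),
    }

    width = len(str(n))
    records = [
        ParticipantRecord(
            id=f"S{i + 1:0{width}d}",
            sex=sexes[i],
            age_years=float(age[i]),
            waist_cm=float(vals["waist"][i]),
            bmi=float(vals["bmi"][i]),
            sbp_mmHg=float(vals["sbp"][i]),
            dbp_mmHg=float(vals["dbp"][i]),
            glucose_mgdl=float(vals["glucose"][i]),
            tg_mgdl=float(vals["tg"][i]),
            hdl_mgdl=float(vals["hdl"][i]),
            **{k: bool(v[i]) for k, v in flags.items()},
        )
        for i in range(n)
    ]
    return Cohort(records, provenance=f"synthetic(seed={spec.seed}, n={n})")


# -- independent straight-line rule evaluation (oracle path) -----------------

def reference_classify(r: ParticipantRecord, name: str) -> bool:
    """Straight-line re-statement of each definition, deliberately sharing no
    code with ``metsdx.criteria`` — the oracle side of the dual-implementation
    classification check."""
    f = r.sex == "female"
    bp130 = r.sbp_mmHg >= 130 or r.dbp_mmHg >= 85 or r.sah_treatment
    bp140 = r.sbp_mmHg >= 140 or r.dbp_mmHg >= 90 or r.sah_treatment
    dm = r.dm_diagnosis or r.dm_treatment
    glu100 = r.glucose_mgdl >= 100 or dm
    tg150 = r.tg_mgdl >= 150
    hdl_low = r.hdl_mgdl < (50 if f else 40)

    if name == "IDF_AHA_NHLBI":
        wc = r.waist_cm >= (80 if f else 90)
        return (wc + tg150 + hdl_low + bp130 + glu100) >= 3
    if name == "NCEP_ATPIII":
        wc = r.waist_cm > (88 if f else 102)
        return (wc + tg150 + hdl_low + bp130 + glu100) >= 3
    if name == "BARBOSA2006":
        wc = r.waist_cm > (84 if f else 88)
        return (wc + tg150 + hdl_low + bp130 + glu100) >= 3
    if name == "IDF":
        wc = r.waist_cm >= (80 if f else 90)
        return wc and (tg150 + hdl_low + bp130 + glu100) >= 2
    if name == "EGIR":
        gate = r.glucose_mgdl >= 110 or dm
        wc = r.waist_cm >= (80 if f else 94)
        return gate and (wc + tg150 + (r.hdl_mgdl < 39) + bp140) >= 2
    if name == "AACE":
        risk = (
            r.cvd or r.sah_diagnosis or r.pcos or r.nafld or r.acanthosis
            or bool(r.family_history_t2dm_htn_cvd) or bool(r.gestational_dm_history)
            or r.nonwhite or r.sedentary
            or (r.age_years is not None and r.age_years > 40)
            or (r.bmi is not None and r.bmi >= 25)
            or r.waist_cm > (80 if f else 94)
        )
        return risk and (tg150 + hdl_low + bp130) >= 2
    raise KeyError(name)


def plant_labels(spec: CohortSpec, criterion: CriterionDefinition) -> tuple[Cohort, np.ndarray]:
    """Generate a cohort together with labels computed by the independent
    straight-line evaluator, for oracle-testing the classifier."""
    cohort = generate(spec)
    labels = np.array([reference_classify(r, criterion.name) for r in cohort], dtype=bool)
    return cohort, labels
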