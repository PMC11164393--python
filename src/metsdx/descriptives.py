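"""Sex-stratified descriptive tables.

Categorical variables are compared across sexes with Pearson's chi-square
(no continuity correction).  Continuous variables are routed to Student's
t-test or the Mann-Whitney U test on a per-stratum Kolmogorov-Smirnov
normality check at alpha = 0.05 — the KS statistic is computed against a
normal with the sample's own mean/SD (a Lilliefors-style usage: the nominal
KS p-value is anti-conservative with estimated parameters, which is the
convention being reproduced, not corrected).

Component-positivity rows reuse the predicate objects of the criteria
registry — there is a single source of truth for every cutoff — and report
measurement-only positivity (treatment/diagnosis substitutions excluded),
the way clinical descriptive tables tabulate measured values against
cutoffs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .criteria import ComponentPredicate, CriterionDefinition

__all__ = [
    "categorical_compare",
    "continuous_compare",
    "ContinuousComparison",
    "summarize_cohort",
]


def categorical_compare(counts) -> tuple[float, float]:
    """Pearson chi-square (no Yates correction) on a 2xk / rxk count table.

    Returns ``(statistic, p_value)`` with (r-1)(k-1) degrees of freedom.
    Raises on zero row/column margins (expected counts must be positive).
    """
    tab = np.asarray(counts, dtype=float)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError(f"need an r x k table with r, k >= 2, got shape {tab.shape}")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("zero margin: every row and column must have positive total")
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return float(chi2), float(p)


@dataclass(frozen=True)
class ContinuousComparison:
    test: str  # "t" | "mann-whitney"
    p_value: float
    normal_a: bool
    normal_b: bool


def _ks_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    """KS normality check against N(sample mean, sample SD)."""
    sd = x.std(ddof=1)
    if sd == 0:
        return False
    return stats.kstest(x, "norm", args=(x.mean(), sd)).pvalue > alpha


def continuous_compare(values_a, values_b, alpha: float = 0.05) -> ContinuousComparison:
    """Compare two samples, routing on per-group KS normality.

    Both normal -> two-sample t-test; otherwise Mann-Whitney U (two-sided,
    normal approximation with tie correction for larger samples, exact for
    small tie-free ones — scipy's automatic policy).  Degenerate constant
    input falls to the Mann-Whitney path with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 observations per group")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("constant input; comparison is vacuous (p = 1)")
        return ContinuousComparison("mann-whitney", 1.0, False, False)
    na, nb = _ks_normal(a, alpha), _ks_normal(b, alpha)
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        warnings.warn("degenerate (constant) group; using Mann-Whitney")
        na = nb = False
    if na and nb:
        p = stats.ttest_ind(a, b, equal_var=True).pvalue
        return ContinuousComparison("t", float(p), na, nb)
    p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    return ContinuousComparison("mann-whitney", float(p), na, nb)


_CONTINUOUS_ROWS = (
    ("Fasting glucose (mg/dL)", "glucose_mgdl"),
    ("Triglycerides (mg/dL)", "tg_mgdl"),
    ("HDLc (mg/dL)", "hdl_mgdl"),
    ("Waist circumference (cm)", "waist_cm"),
    ("BMI (kg/m2)", "bmi"),
    ("Systolic blood pressure (mmHg)", "sbp_mmHg"),
    ("Diastolic blood pressure (mmHg)", "dbp_mmHg"),
)

_CATEGORICAL_ROWS = (
    ("Age > 40 years", "age_over_40"),
    ("Sedentary", "sedentary"),
    ("Non-white", "nonwhite"),
    ("Prior DM diagnosis", "dm_diagnosis"),
    ("DM treatment", "dm_treatment"),
    ("SAH diagnosis", "sah_diagnosis"),
    ("SAH treatment", "sah_treatment"),
)


def _pred_label(crit: str, p: ComponentPredicate) -> str:
    if p.component == "blood_pressure":
        core = f"BP {p.comparator}{p.cutoff_female:g}/{p.dbp_cutoff:g}"
    elif p.cutoff_female == p.cutoff_male:
        core = f"{p.component} {p.comparator}{p.cutoff_female:g}"
    else:
        core = f"{p.component} {p.comparator}{p.cutoff_male:g} (M) {p.comparator}{p.cutoff_female:g} (F)"
    return f"{core} [{crit}]"


def summarize_cohort(
    cohort: Cohort,
    criteria: Sequence[CriterionDefinition] = (),
) -> pd.DataFrame:
    """Sex-stratified descriptive table.

    One row per variable: categorical rows carry ``n (%)`` per stratum and a
    chi-square p; continuous rows carry ``mean (SD)`` and the routed
    t / Mann-Whitney p; component rows (one per distinct cutoff across the
    supplied criteria) carry measured positivity per stratum.  Strata with
    no records yield empty cells and no test.
    """
    df = cohort.to_dataframe()
    fem = df[df["sex"] == "female"]
    mal = df[df["sex"] == "male"]
    rows: list[dict] = []

    def cat_row(label: str, mask: pd.Series) -> None:
        mask = mask.fillna(False).astype(bool)
        total = f"{int(mask.sum())} ({100 * mask.mean():.2f})"
        cells = {}
        for name, sub in (("female", fem), ("male", mal)):
            m = mask.loc[sub.index]
            cells[name] = f"{int(m.sum())} ({100 * m.mean():.2f})" if len(sub) else ""
        p = None
        if len(fem) and len(mal):
            mf, mm = mask.loc[fem.index], mask.loc[mal.index]
            tab = [[int(mf.sum()), int(mm.sum())], [int((~mf).sum()), int((~mm).sum())]]
            if all(sum(r) for r in tab) and all(tab[0][j] + tab[1][j] for j in (0, 1)):
                _, p = categorical_compare(tab)
        rows.append(
            {"variable": label, "kind": "categorical", "total": total,
             "female": cells["female"], "male": cells["male"],
             "test": "chi-square" if p is not None else "", "p_value": p}
        )

    for label, col in _CATEGORICAL_ROWS:
        cat_row(label, df[col])

    seen: set = set()
    for crit in criteria:
        for pred in crit.predicates:
            key = (pred.component, pred.cutoff_female, pred.cutoff_male, pred.comparator, pred.dbp_cutoff)
            if key in seen:
                continue
            seen.add(key)
            mask = pd.Series(
                [pred.measured_positive(r) if r.classifiable else None for r in cohort],
                index=df.index,
            )
            cat_row(_pred_label(crit.name, pred), mask)

    for label, col in _CONTINUOUS_ROWS:
        vals = df[col].dropna()
        total = f"{vals.mean():.2f} ({vals.std(ddof=1):.2f})" if len(vals) > 1 else ""
        cells, groups = {}, {}
        for name, sub in (("female", fem), ("male", mal)):
            v = sub[col].dropna()
            groups[name] = v
            cells[name] = f"{v.mean():.2f} ({v.std(ddof=1):.2f})" if len(v) > 1 else ""
        test, p = "", None
        if len(groups["female"]) >= 3 and len(groups["male"]) >= 3:
            cmp_res = continuous_compare(groups["female"], groups["male"])
            test, p = cmp_res.test, cmp_res.p_value
        rows.append(
            {"variable": label, "kind": "continuous", "total": total,
             "female": cells["female"], "male": cells["male"], "test": test, "p_value": p}
        )

    return pd.DataFrame(rows, columns=["variable", "kind", "total", "female", "male", "test", "p_value"])
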