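"""Diagnostic accuracy against a gold standard: 2x2 tables, Se/Sp/PPV/NPV
with exact binomial confidence intervals, likelihood ratios with log-method
intervals, Cohen's kappa with agreement banding, and reconstruction of 2x2
tables from published summary counts.

Conventions follow the standard accuracy-study layout: a = true positive,
b = false positive, c = false negative, d = true negative, so

    Se = a/(a+c)        Sp = d/(b+d)
    PPV = a/(a+b)       NPV = d/(c+d)
    LR+ = Se/(1-Sp)     LR- = (1-Se)/Sp

A metric whose denominator is zero is *undefined*, rendered "-" in tables and
null in JSON (e.g. LR+ when there are no false positives).  Proportion CIs
are Clopper-Pearson exact; LR CIs use the Simel log method,

    ln LR+ +/- z * sqrt(1/a - 1/(a+c) + 1/b - 1/(b+d)),

(and the analogous c,d form for LR-), which guarantees nominal coverage for
the proportions and matches how accuracy studies conventionally report LRs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionTable",
    "Estimate",
    "AccuracyReport",
    "build_confusion",
    "exact_ci",
    "accuracy_metrics",
    "likelihood_ratios",
    "cohen_kappa",
    "kappa_band",
    "reconstruct_confusion",
    "compare",
]


@dataclass(frozen=True)
class ConfusionTable:
    """Counts versus the gold standard: a=TP, b=FP, c=FN, d=TN."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise ValueError("empty confusion table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def gold_positive(self) -> int:
        return self.a + self.c

    @property
    def test_positive(self) -> int:
        return self.a + self.b

    def summarize(self) -> tuple[int, int, int, Optional[float]]:
        """(n, gold positives, test positives, PPV) — the published-count
        form that :func:`reconstruct_confusion` inverts."""
        ppv = self.a / self.test_positive if self.test_positive else None
        return self.n, self.gold_positive, self.test_positive, ppv


@dataclass(frozen=True)
class Estimate:
    """Point estimate with a 95% CI; ``value is None`` means undefined."""

    value: Optional[float]
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    @property
    def defined(self) -> bool:
        return self.value is not None


UNDEFINED = Estimate(None)


def build_confusion(gold: Sequence, test: Sequence) -> ConfusionTable:
    """Tally a 2x2 table from parallel boolean vectors."""
    g = np.asarray(gold, dtype=bool)
    t = np.asarray(test, dtype=bool)
    if g.shape != t.shape or g.ndim != 1:
        raise ValueError(f"gold and test must be equal-length 1-d vectors, got {g.shape} vs {t.shape}")
    if g.size == 0:
        raise ValueError("empty label vectors")
    return ConfusionTable(
        a=int(np.sum(g & t)),
        b=int(np.sum(~g & t)),
        c=int(np.sum(g & ~t)),
        d=int(np.sum(~g & ~t)),
    )


def exact_ci(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact binomial interval (beta-quantile form).

    Lower bound is 0 when ``successes == 0``; upper bound 1 when
    ``successes == trials``.
    """
    if trials <= 0 or not (0 <= successes <= trials):
        raise ValueError(f"invalid counts: {successes}/{trials}")
    lo, hi = proportion_confint(successes, trials, alpha=1 - level, method="beta")
    # statsmodels returns NaN at the degenerate ends; the exact bounds there are 0/1
    lo = 0.0 if math.isnan(lo) else float(lo)
    hi = 1.0 if math.isnan(hi) else float(hi)
    return lo, hi


def _prop_estimate(successes: int, trials: int, level: float) -> Estimate:
    if trials == 0:
        return UNDEFINED
    lo, hi = exact_ci(successes, trials, level)
    return Estimate(successes / trials, lo, hi)


def accuracy_metrics(t: ConfusionTable, level: float = 0.95) -> dict[str, Estimate]:
    """Sensitivity, specificity and predictive values with exact CIs.

    The predictive values are the raw column proportions a/(a+b), d/(c+d) —
    i.e. computed at the cohort's own gold-standard prevalence.
    """
    return {
        "se": _prop_estimate(t.a, t.a + t.c, level),
        "sp": _prop_estimate(t.d, t.b + t.d, level),
        "ppv": _prop_estimate(t.a, t.a + t.b, level),
        "npv": _prop_estimate(t.d, t.c + t.d, level),
    }


def likelihood_ratios(t: ConfusionTable, level: float = 0.95) -> tuple[Estimate, Estimate]:
    """(LR+, LR-) with Simel log-method CIs.

    LR+ is undefined when there are no false positives (Sp = 1); LR- is
    undefined when there are no true negatives (Sp = 0); both are undefined
    when Se or Sp itself is undefined.  A CI is reported only when every
    count entering its variance term is positive.
    """
    z = stats.norm.ppf(0.5 + level / 2)
    if t.a + t.c == 0 or t.b + t.d == 0:
        return UNDEFINED, UNDEFINED
    se = t.a / (t.a + t.c)
    sp = t.d / (t.b + t.d)

    if t.b == 0:
        lr_pos = UNDEFINED
    else:
        val = se / (1 - sp)
        if t.a == 0:
            lr_pos = Estimate(0.0)
        else:
            var = 1 / t.a - 1 / (t.a + t.c) + 1 / t.b - 1 / (t.b + t.d)
            half = z * math.sqrt(max(var, 0.0))
            lr_pos = Estimate(val, val * math.exp(-half), val * math.exp(half))

    if t.d == 0:
        lr_neg = UNDEFINED
    else:
        val = (1 - se) / sp
        if t.c == 0:
            lr_neg = Estimate(0.0)
        else:
            var = 1 / t.c - 1 / (t.a + t.c) + 1 / t.d - 1 / (t.b + t.d)
            half = z * math.sqrt(max(var, 0.0))
            lr_neg = Estimate(val, val * math.exp(-half), val * math.exp(half))
    return lr_pos, lr_neg


#: Agreement bands (upper bound inclusive), from the slight/fair/moderate/
#: substantial/almost-perfect convention.
KAPPA_BANDS = (
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
)


def kappa_band(kappa: float) -> str:
    for upper, label in KAPPA_BANDS:
        if kappa <= upper:
            return label
    return "almost perfect"


def cohen_kappa(t: ConfusionTable) -> tuple[Optional[float], Optional[str]]:
    """Chance-corrected agreement between the two binary classifications.

    kappa = (Po - Pe)/(1 - Pe) with Po = (a+d)/n and
    Pe = [(a+b)(a+c) + (c+d)(b+d)] / n^2.  Undefined (None) when the
    marginals are degenerate (Pe = 1).
    """
    n = t.n
    po = (t.a + t.d) / n
    pe = ((t.a + t.b) * (t.a + t.c) + (t.c + t.d) * (t.b + t.d)) / n**2
    if pe == 1.0:
        return None, None
    k = (po - pe) / (1 - pe)
    return k, kappa_band(k)


def reconstruct_confusion(
    n: int, gold_pos: int, test_pos: int, ppv: Optional[float]
) -> ConfusionTable:
    """Rebuild a 2x2 table from published summary counts.

    Given the cohort size, the gold-standard positive count, the comparison
    criterion's positive count, and the published PPV (rounded is fine —
    ``a`` is recovered as round(ppv * test_pos)), returns the unique
    consistent table.  ``ppv`` may be None only when ``test_pos == 0``.
    """
    if not (0 <= gold_pos <= n and 0 <= test_pos <= n):
        raise ValueError("counts exceed cohort size")
    if test_pos == 0:
        a = 0
    else:
        if ppv is None or not (0 <= ppv <= 1):
            raise ValueError(f"ppv must be in [0, 1], got {ppv!r}")
        a = int(math.floor(ppv * test_pos + 0.5))
    b = test_pos - a
    c = gold_pos - a
    d = n - gold_pos - b
    for name, v in zip("abcd", (a, b, c, d)):
        if v < 0:
            raise ValueError(f"inconsistent summary counts: cell {name} = {v}")
    return ConfusionTable(a, b, c, d)


@dataclass(frozen=True)
class AccuracyReport:
    """Full accuracy profile of one comparison criterion vs the gold standard."""

    table: ConfusionTable
    se: Estimate
    sp: Estimate
    ppv: Estimate
    npv: Estimate
    lr_pos: Estimate
    lr_neg: Estimate
    kappa: Optional[float]
    kappa_band: Optional[str]

    def to_dict(self) -> dict:
        def est(e: Estimate):
            return None if not e.defined else {"value": e.value, "ci": [e.ci_low, e.ci_high]}

        return {
            "table": {"a": self.table.a, "b": self.table.b, "c": self.table.c, "d": self.table.d},
            "se": est(self.se),
            "sp": est(self.sp),
            "ppv": est(self.ppv),
            "npv": est(self.npv),
            "lr_pos": est(self.lr_pos),
            "lr_neg": est(self.lr_neg),
            "kappa": self.kappa,
            "kappa_band": self.kappa_band,
        }


def compare(t: ConfusionTable, level: float = 0.95) -> AccuracyReport:
    """All accuracy metrics for one 2x2 table."""
    m = accuracy_metrics(t, level)
    lr_pos, lr_neg = likelihood_ratios(t, level)
    k, band = cohen_kappa(t)
    return AccuracyReport(
        table=t,
        se=m["se"],
        sp=m["sp"],
        ppv=m["ppv"],
        npv=m["npv"],
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        kappa=k,
        kappa_band=band,
    )


# -- printed-table formatting ------------------------------------------------

def fmt_pct(e: Estimate) -> str:
    """Percentage with CI at 1 decimal place; '-' when undefined."""
    if not e.defined:
        return "-"
    return f"{100 * e.value:.1f} ({100 * e.ci_low:.1f}-{100 * e.ci_high:.1f})"


def _sig3(x: float) -> str:
    if x == 0:
        return "0"
    from decimal import Decimal

    d = Decimal(f"{x:.3g}")
    return f"{d.normalize():f}"


def fmt_lr(e: Estimate) -> str:
    """Likelihood ratio with CI at 3 significant figures; '-' when undefined."""
    if not e.defined:
        return "-"
    if e.ci_low is None:
        return _sig3(e.value)
    return f"{_sig3(e.value)} ({_sig3(e.ci_low)}-{_sig3(e.ci_high)})"
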