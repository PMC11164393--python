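"""Published summary counts of the reference accuracy study (a cohort of
1,111 primary-health-care nursing professionals, Bahia, Brazil).

These printed counts are *inputs* to the analysis: because every comparison
criterion produced (almost) no false positives, each criterion's full 2x2
table against the harmonized gold standard is exactly recoverable from the
cohort size, the gold-standard positive count, the criterion's positive
count and the published PPV (see ``accuracy.reconstruct_confusion``).  The
reconstructed tables reproduce every published sensitivity, specificity,
predictive value, likelihood ratio and kappa.
"""

from __future__ import annotations

from .accuracy import ConfusionTable, reconstruct_confusion

__all__ = [
    "REFERENCE_N",
    "GOLD_POSITIVE",
    "CRITERION_SUMMARY",
    "reconstructed_tables",
    "MARITAL_BY_SEX",
    "AGE_GROUP_BY_SEX",
]

#: Final analyzed cohort size after exclusion of incomplete records.
REFERENCE_N = 1111

#: Positives under the harmonized (IDF/AHA/NHLBI) gold standard: 31.23%.
GOLD_POSITIVE = 347

#: Per-criterion published positive count and PPV (proportion scale).
CRITERION_SUMMARY: dict[str, tuple[int, float]] = {
    "IDF": (330, 1.00),
    "NCEP_ATPIII": (290, 1.00),
    "BARBOSA2006": (323, 0.997),
    "EGIR": (52, 1.00),
    "AACE": (148, 0.973),
}


def reconstructed_tables() -> dict[str, ConfusionTable]:
    """The five comparison criteria's 2x2 tables vs the gold standard,
    reconstructed from the published summary counts."""
    return {
        name: reconstruct_confusion(REFERENCE_N, GOLD_POSITIVE, pos, ppv)
        for name, (pos, ppv) in CRITERION_SUMMARY.items()
    }


#: Marital status (with / without partner) by sex.  The published female
#: "without partner" cell (477) is inconsistent with the female column total
#: (975) and with its own printed percentage (45.85% of 975 = 447); the
#: percentage-consistent 447 is used, which reconciles the totals and
#: reproduces the published chi-square p-value 0.557.
MARITAL_BY_SEX = [[528, 70], [447, 66]]

#: Age group (up to 35 / 36+) by sex; reproduces the published p = 0.450.
AGE_GROUP_BY_SEX = [[504, 75], [471, 61]]
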