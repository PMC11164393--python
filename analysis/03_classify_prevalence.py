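"""Classify the cohort under the six MetS definitions and estimate
prevalence.

Reads results/cohort.csv, applies the declarative rule engine, checks the
label matrix against the straight-line oracle labels from step 01, and
writes per-criterion prevalence (overall and by sex, exact 95% CIs) to
results/prevalence.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from metsdx.cohort import filter_classifiable, identity_codebook, read_cohort
from metsdx.criteria import DEFAULT_CRITERIA_ORDER, builtin_criteria, classify_cohort, prevalence


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()
    out = Path(args.out_dir)

    cohort, _ = read_cohort(out / "cohort.csv", identity_codebook())
    cohort, excluded = filter_classifiable(cohort)
    print(f"{len(cohort)} classifiable records ({len(excluded)} excluded)")

    registry = builtin_criteria()
    labels = classify_cohort(cohort, [registry[n] for n in DEFAULT_CRITERIA_ORDER])
    labels.to_csv(out / "labels.csv")

    truth_path = out / "true_labels.csv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, index_col=0).astype(bool)
        mismatches = int((labels != truth.loc[labels.index, labels.columns]).sum().sum())
        print(f"agreement with straight-line oracle: {len(labels) * 6 - mismatches}"
              f"/{len(labels) * 6} labels ({mismatches} mismatches)")

    sexes = pd.Series([r.sex for r in cohort], index=labels.index)
    rows = []
    for crit in labels.columns:
        for stratum, mask in (("overall", None),
                              ("female", (sexes == "female").to_numpy()),
                              ("male", (sexes == "male").to_numpy())):
            est = prevalence(labels[crit].to_numpy(), stratum=mask)
            rows.append({"criterion": crit, "stratum": stratum, "positives": est.count,
                         "n": est.n, "prevalence_pct": round(est.percent, 2),
                         "ci_low_pct": round(100 * est.ci_low, 2),
                         "ci_high_pct": round(100 * est.ci_high, 2)})
    prev = pd.DataFrame(rows)
    prev.to_csv(out / "prevalence.csv", index=False)
    print(f"prevalence table -> {out/'prevalence.csv'}")
    print(prev[prev.stratum == "overall"].to_string(index=False))


if __name__ == "__main__":
    main()
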