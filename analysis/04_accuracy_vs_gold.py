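"""Diagnostic accuracy of the five comparison criteria against the
harmonized gold standard on the simulated cohort.

Reads results/labels.csv, builds each criterion's 2x2 table versus
IDF_AHA_NHLBI, and writes the validity-indicator and kappa-agreement tables
(results/validity_synthetic.csv, results/kappa_synthetic.csv).
"""

import argparse
from pathlib import Path

import pandas as pd

from metsdx.accuracy import build_confusion, compare, fmt_lr, fmt_pct


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", default="results")
    ap.add_argument("--gold", default="IDF_AHA_NHLBI")
    args = ap.parse_args()
    out = Path(args.out_dir)

    labels = pd.read_csv(out / "labels.csv", index_col=0).astype(bool)
    gold = labels[args.gold].to_numpy()
    vrows, krows = [], []
    for crit in labels.columns:
        if crit == args.gold:
            continue
        rep = compare(build_confusion(gold, labels[crit].to_numpy()))
        t = rep.table
        vrows.append({"criterion": crit, "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                      "sensitivity": fmt_pct(rep.se), "specificity": fmt_pct(rep.sp),
                      "ppv": fmt_pct(rep.ppv), "npv": fmt_pct(rep.npv),
                      "lr_pos": fmt_lr(rep.lr_pos), "lr_neg": fmt_lr(rep.lr_neg)})
        krows.append({"criterion": crit, "kappa": round(rep.kappa, 4),
                      "agreement": rep.kappa_band})
    pd.DataFrame(vrows).to_csv(out / "validity_synthetic.csv", index=False)
    pd.DataFrame(krows).to_csv(out / "kappa_synthetic.csv", index=False)
    print(f"validity vs {args.gold} -> {out/'validity_synthetic.csv'}")
    print(pd.DataFrame(vrows)[["criterion", "sensitivity", "specificity", "npv"]]
          .to_string(index=False))
    print(pd.DataFrame(krows).to_string(index=False))


if __name__ == "__main__":
    main()
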