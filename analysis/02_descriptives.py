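"""Sex-stratified descriptive table of the simulated cohort.

Reads results/cohort.csv (run 01_simulate_cohort.py first), assembles the
categorical, component-positivity and continuous rows with their chi-square
or t / Mann-Whitney comparisons, and writes results/descriptives.csv.
"""

import argparse
from pathlib import Path

from metsdx.cohort import identity_codebook, read_cohort
from metsdx.criteria import builtin_criteria
from metsdx.descriptives import summarize_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()

    out = Path(args.out_dir)
    cohort, issues = read_cohort(out / "cohort.csv", identity_codebook())
    assert issues.empty
    table = summarize_cohort(cohort, list(builtin_criteria().values()))
    table.to_csv(out / "descriptives.csv", index=False)
    print(f"descriptive table ({len(table)} rows) -> {out/'descriptives.csv'}")
    sig = table.dropna(subset=["p_value"]).query("p_value <= 0.05")
    print(f"  {len(sig)} of {table.p_value.notna().sum()} sex comparisons significant at 0.05:")
    for _, r in sig.iterrows():
        print(f"    {r.variable}: {r.test} p = {r.p_value:.3g}")


if __name__ == "__main__":
    main()
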