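"""End-to-end orchestration: ingest (or simulate) -> eligibility filter ->
classification under the six definitions -> prevalence, descriptive,
validity and agreement tables -> files.

Outputs mirror the reporting structure of a diagnostic-accuracy study:
``prevalence.csv`` (overall and by sex, exact CIs), ``validity.csv``
(Se/Sp/PPV/NPV/LR rows per comparison criterion), ``kappa.csv``,
``descriptives.csv``, ``exclusions.csv``, a machine-readable
``bundle.json`` and a plain-text run log.  Identical configuration and seed
produce byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .accuracy import build_confusion, compare, fmt_lr, fmt_pct
from .cohort import Codebook, Cohort, filter_classifiable, read_cohort
from .criteria import (
    DEFAULT_CRITERIA_ORDER,
    builtin_criteria,
    classify_cohort,
    prevalence,
)
from .descriptives import summarize_cohort
from .simulate import CohortSpec, generate

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    """One analysis run: either a file + codebook, or a simulation spec."""

    input_path: Optional[str] = None
    codebook: Optional[Codebook] = None
    sim_spec: Optional[CohortSpec] = None
    gold: str = "IDF_AHA_NHLBI"
    criteria: Sequence[str] = DEFAULT_CRITERIA_ORDER
    output_dir: str = "results"
    seed: int = 0

    def __post_init__(self):
        if (self.input_path is None) == (self.sim_spec is None):
            raise ValueError("exactly one of input_path or sim_spec must be given")
        if self.input_path is not None and self.codebook is None:
            raise ValueError("input_path requires a codebook")
        if self.gold not in self.criteria:
            raise ValueError(f"gold standard {self.gold!r} must be in the criteria list")
        unknown = set(self.criteria) - set(builtin_criteria())
        if unknown:
            raise ValueError(f"unknown criteria: {sorted(unknown)}")


def _prevalence_table(labels: pd.DataFrame, sexes: pd.Series) -> pd.DataFrame:
    rows = []
    for crit in labels.columns:
        for stratum, mask in (
            ("overall", None),
            ("female", (sexes == "female").to_numpy()),
            ("male", (sexes == "male").to_numpy()),
        ):
            if mask is not None and not mask.any():
                continue
            est = prevalence(labels[crit].to_numpy(), stratum=mask)
            rows.append(
                {
                    "criterion": crit,
                    "stratum": stratum,
                    "positives": est.count,
                    "n": est.n,
                    "prevalence_pct": round(est.percent, 2),
                    "ci_low_pct": round(100 * est.ci_low, 2),
                    "ci_high_pct": round(100 * est.ci_high, 2),
                }
            )
    return pd.DataFrame(rows)


def _validity_tables(labels: pd.DataFrame, gold: str) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    gold_vec = labels[gold].to_numpy()
    rows, krows, bundle = [], [], {}
    for crit in labels.columns:
        if crit == gold:
            continue
        t = build_confusion(gold_vec, labels[crit].to_numpy())
        rep = compare(t)
        rows.append(
            {
                "criterion": crit,
                "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                "sensitivity": fmt_pct(rep.se),
                "specificity": fmt_pct(rep.sp),
                "ppv": fmt_pct(rep.ppv),
                "npv": fmt_pct(rep.npv),
                "lr_pos": fmt_lr(rep.lr_pos),
                "lr_neg": fmt_lr(rep.lr_neg),
            }
        )
        krows.append(
            {
                "criterion": crit,
                "kappa": None if rep.kappa is None else round(rep.kappa, 4),
                "agreement": rep.kappa_band,
            }
        )
        bundle[crit] = rep.to_dict()
    return pd.DataFrame(rows), pd.DataFrame(krows), bundle


def run(config: RunConfig) -> dict:
    """Execute the full analysis; returns the report bundle (also written to
    ``output_dir``)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.sim_spec is not None:
        spec = config.sim_spec
        if spec.seed != config.seed:
            from dataclasses import replace

            spec = replace(spec, seed=config.seed)
        cohort = generate(spec)
        read_issues = pd.DataFrame(columns=["id", "field", "problem"])
    else:
        cohort, read_issues = read_cohort(config.input_path, config.codebook)

    n_input = len(cohort)
    cohort, exclusions = filter_classifiable(cohort)
    if len(cohort) == 0:
        raise ValueError("no classifiable records after eligibility filtering")

    registry = builtin_criteria()
    crits = [registry[name] for name in config.criteria]
    labels = classify_cohort(cohort, crits)
    sexes = pd.Series([r.sex for r in cohort], index=labels.index)

    prev = _prevalence_table(labels, sexes)
    validity, kappa_tab, acc_bundle = _validity_tables(labels, config.gold)
    desc = summarize_cohort(cohort, crits)

    prev.to_csv(out / "prevalence.csv", index=False)
    validity.to_csv(out / "validity.csv", index=False)
    kappa_tab.to_csv(out / "kappa.csv", index=False)
    desc.to_csv(out / "descriptives.csv", index=False)
    exclusions.to_csv(out / "exclusions.csv", index=False)
    labels.to_csv(out / "labels.csv")

    bundle = {
        "config": {
            "gold": config.gold,
            "criteria": list(config.criteria),
            "seed": config.seed,
            "input": config.input_path or repr(config.sim_spec and "synthetic"),
        },
        "counts": {
            "input_records": n_input,
            "excluded": int(len(exclusions)),
            "analyzed": int(len(cohort)),
            "read_issues": int(len(read_issues)),
        },
        "prevalence": prev.to_dict(orient="records"),
        "accuracy": acc_bundle,
        "kappa": kappa_tab.to_dict(orient="records"),
    }
    (out / "bundle.json").write_text(json.dumps(bundle, indent=2))

    log = [
        f"metsdx {__version__} | python {platform.python_version()} | numpy {np.__version__} | pandas {pd.__version__}",
        f"seed={config.seed} gold={config.gold} criteria={','.join(config.criteria)}",
        f"records: input={n_input} excluded={len(exclusions)} analyzed={len(cohort)}",
    ]
    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    return bundle
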