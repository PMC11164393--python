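"""Participant-level cohort model: record types, codebook-mapped ingest, and
eligibility filtering.

Canonical units are the ones every published cutoff is printed in — mg/dL for
fasting glucose, triglycerides and HDL cholesterol, mmHg for blood pressure,
cm for waist circumference, kg/m² for BMI.  Columns declared in mmol/L in the
codebook are converted once, at ingest, so downstream rule evaluation never
touches unit logic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterator, Optional

import pandas as pd
import yaml

__all__ = [
    "ParticipantRecord",
    "Cohort",
    "Codebook",
    "CodebookError",
    "MMOL_TO_MGDL",
    "read_cohort",
    "write_cohort",
    "filter_classifiable",
]

#: Multiplicative factors taking mmol/L to mg/dL.
MMOL_TO_MGDL = {
    "glucose_mgdl": 18.016,
    "tg_mgdl": 88.57,
    "hdl_mgdl": 38.67,
}

#: Continuous measurements carried by a record (canonical field names).
CONTINUOUS_FIELDS = (
    "age_years",
    "waist_cm",
    "bmi",
    "sbp_mmHg",
    "dbp_mmHg",
    "glucose_mgdl",
    "tg_mgdl",
    "hdl_mgdl",
)

#: Boolean clinical / treatment flags.  The two history flags are tri-state
#: (True/False/None); "unknown" (None) never satisfies a risk indicator.
REQUIRED_FLAGS = (
    "dm_diagnosis",
    "dm_treatment",
    "sah_treatment",
    "sah_diagnosis",
    "cvd",
    "pcos",
    "nafld",
    "acanthosis",
    "sedentary",
    "nonwhite",
)
OPTIONAL_FLAGS = ("family_history_t2dm_htn_cvd", "gestational_dm_history")

#: Fields without which a record cannot be run through any of the six rule
#: sets: sex plus the inputs of the five components (waist, BP pair, glucose,
#: triglycerides, HDL).  The treatment/diagnosis flags always carry a value
#: (they default to False), so they never gate classifiability on their own.
CLASSIFIABLE_FIELDS = (
    "sex",
    "waist_cm",
    "sbp_mmHg",
    "dbp_mmHg",
    "glucose_mgdl",
    "tg_mgdl",
    "hdl_mgdl",
)


@dataclass
class ParticipantRecord:
    """One study participant: measurements, flags, identifier.

    Continuous measures are ``None`` when missing; strictly positive
    otherwise.  ``pcos`` may be True only for females.
    """

    id: str
    sex: Optional[str] = None  # "female" | "male"
    age_years: Optional[float] = None
    waist_cm: Optional[float] = None
    bmi: Optional[float] = None
    sbp_mmHg: Optional[float] = None
    dbp_mmHg: Optional[float] = None
    glucose_mgdl: Optional[float] = None
    tg_mgdl: Optional[float] = None
    hdl_mgdl: Optional[float] = None
    dm_diagnosis: bool = False
    dm_treatment: bool = False
    sah_treatment: bool = False
    sah_diagnosis: bool = False
    cvd: bool = False
    pcos: bool = False
    nafld: bool = False
    acanthosis: bool = False
    sedentary: bool = False
    nonwhite: bool = False
    family_history_t2dm_htn_cvd: Optional[bool] = None
    gestational_dm_history: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.sex is not None and self.sex not in ("female", "male"):
            raise ValueError(f"record {self.id!r}: sex must be 'female' or 'male', got {self.sex!r}")
        if self.pcos and self.sex != "female":
            raise ValueError(f"record {self.id!r}: pcos flag requires sex='female'")
        for name in CONTINUOUS_FIELDS:
            v = getattr(self, name)
            if v is not None:
                v = float(v)
                if name != "age_years" and v <= 0:
                    raise ValueError(f"record {self.id!r}: {name} must be strictly positive, got {v}")
                if name == "age_years" and v < 0:
                    raise ValueError(f"record {self.id!r}: age_years must be non-negative, got {v}")
                object.__setattr__(self, name, v)

    @property
    def age_over_40(self) -> bool:
        """Derived flag: strictly older than 40 years (False when age unknown)."""
        return self.age_years is not None and self.age_years > 40

    def missing_fields(self) -> list[str]:
        """Names of required-for-classification fields that are absent."""
        return [f for f in CLASSIFIABLE_FIELDS if getattr(self, f) is None]

    @property
    def classifiable(self) -> bool:
        return not self.missing_fields()

    def to_mmol(self) -> "ParticipantRecord":
        """Copy with the three lab values expressed in mmol/L (for round-trip checks)."""
        kw = {
            k: (getattr(self, k) / MMOL_TO_MGDL[k] if getattr(self, k) is not None else None)
            for k in MMOL_TO_MGDL
        }
        return replace(self, **kw)

    def from_mmol(self) -> "ParticipantRecord":
        kw = {
            k: (getattr(self, k) * MMOL_TO_MGDL[k] if getattr(self, k) is not None else None)
            for k in MMOL_TO_MGDL
        }
        return replace(self, **kw)


@dataclass
class Cohort:
    """Ordered collection of participant records with unique ids."""

    records: list[ParticipantRecord]
    provenance: str = "in-memory"

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ParticipantRecord]:
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {f.name: getattr(r, f.name) for f in fields(r)}
            row["age_over_40"] = r.age_over_40
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "dataframe") -> "Cohort":
        recs = []
        valid = {f.name for f in fields(ParticipantRecord)}
        for _, row in df.iterrows():
            kw = {k: (None if pd.isna(v) else v) for k, v in row.items() if k in valid}
            kw["id"] = str(kw["id"])
            for fl in REQUIRED_FLAGS:
                if kw.get(fl) is None:
                    kw[fl] = False
                else:
                    kw[fl] = bool(kw[fl])
            for fl in OPTIONAL_FLAGS:
                if kw.get(fl) is not None:
                    kw[fl] = bool(kw[fl])
            recs.append(ParticipantRecord(**kw))
        return cls(recs, provenance=provenance)


class CodebookError(ValueError):
    """Configuration problem in the codebook / input file mapping."""


@dataclass
class Codebook:
    """User-supplied mapping from a deposited spreadsheet's columns to the
    canonical fields.

    The deposited data's exact layout is defined by its accompanying code
    book, not hard-coded here: ``columns`` maps canonical field -> source
    column name, ``values`` maps canonical field -> {raw cell value ->
    canonical value} (e.g. ``{"sex": {"F": "female", "M": "male"}}``), and
    ``units`` may declare ``glucose_mgdl``/``tg_mgdl``/``hdl_mgdl`` source
    columns as ``"mmol/L"`` for automatic conversion.
    """

    columns: dict[str, str]
    values: dict[str, dict] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for canon, src in self.columns.items():
            if src in seen:
                raise CodebookError(f"source column {src!r} mapped by both {seen[src]!r} and {canon!r}")
            seen[src] = canon
        for canon, unit in self.units.items():
            if unit not in ("mg/dL", "mmol/L"):
                raise CodebookError(f"unsupported unit {unit!r} for {canon!r}")
            if unit == "mmol/L" and canon not in MMOL_TO_MGDL:
                raise CodebookError(f"mmol/L conversion not defined for {canon!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "Codebook":
        """Load from a YAML or JSON mapping file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
        return cls(
            columns=data["columns"],
            values=data.get("values", {}),
            units=data.get("units", {}),
        )

    def to_file(self, path: str | Path) -> None:
        data = {"columns": self.columns, "values": self.values, "units": self.units}
        p = Path(path)
        if p.suffix in (".yaml", ".yml"):
            p.write_text(yaml.safe_dump(data, sort_keys=False))
        else:
            p.write_text(json.dumps(data, indent=2))


#: Canonical fields a codebook must map before ingest is attempted.
_REQUIRED_MAPPED = ("sex", "waist_cm", "sbp_mmHg", "dbp_mmHg", "glucose_mgdl", "tg_mgdl", "hdl_mgdl")

_TRUTHY = {"1", "yes", "y", "true", "t", "sim", "s"}
_FALSY = {"0", "no", "n", "false", "f", "nao", "não"}


def _coerce_bool(v):
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return None
    if isinstance(v, (bool,)):
        return v
    if isinstance(v, (int, float)):
        return bool(v)
    s = str(v).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"cannot interpret {v!r} as boolean")


def read_cohort(path: str | Path, codebook: Codebook) -> tuple[Cohort, pd.DataFrame]:
    """Read a cohort table (CSV or XLSX) through a codebook.

    Returns the cohort together with a row-level issue report (columns
    ``id``, ``field``, ``problem``).  Cells that fail coercion are reported
    and stored as missing — the row is retained, never silently dropped;
    whether it remains usable is decided later by :func:`filter_classifiable`.

    Raises
    ------
    CodebookError
        If a canonical field required for classification is unmapped, or a
        mapped source column is absent from the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)

    missing_map = [c for c in _REQUIRED_MAPPED if c not in codebook.columns]
    if missing_map:
        raise CodebookError(f"codebook does not map required field(s): {missing_map}")
    missing_src = [s for s in codebook.columns.values() if s not in df.columns]
    if missing_src:
        raise CodebookError(f"mapped column(s) not in {path.name}: {missing_src}")

    issues: list[dict] = []
    records: list[ParticipantRecord] = []
    valid = {f.name for f in fields(ParticipantRecord)}
    for i, (_, row) in enumerate(df.iterrows()):
        kw: dict = {}
        rid = str(row[codebook.columns["id"]]) if "id" in codebook.columns else f"row{i + 1}"
        kw["id"] = rid
        for canon, src in codebook.columns.items():
            if canon == "id" or canon not in valid:
                continue
            raw = row[src]
            if pd.isna(raw):
                continue
            if canon in codebook.values:
                raw = codebook.values[canon].get(raw, raw)
            try:
                if canon in CONTINUOUS_FIELDS:
                    val = float(raw)
                    if codebook.units.get(canon) == "mmol/L":
                        val *= MMOL_TO_MGDL[canon]
                    kw[canon] = val
                elif canon == "sex":
                    kw[canon] = str(raw).strip().lower()
                else:
                    b = _coerce_bool(raw)
                    if b is not None:
                        kw[canon] = b
            except (TypeError, ValueError) as exc:
                issues.append({"id": rid, "field": canon, "problem": str(exc)})
        try:
            records.append(ParticipantRecord(**kw))
        except ValueError as exc:
            # invariant violation: keep the row with offending fields blanked
            issues.append({"id": rid, "field": "<record>", "problem": str(exc)})
            records.append(ParticipantRecord(id=rid))
    if not records:
        raise ValueError(f"{path.name}: no data rows")
    report = pd.DataFrame(issues, columns=["id", "field", "problem"])
    return Cohort(records, provenance=str(path)), report


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort as a canonical-column CSV (identity partner of
    :func:`read_cohort` under the identity codebook)."""
    df = cohort.to_dataframe().drop(columns=["age_over_40"])
    df.to_csv(path, index=False)


def identity_codebook() -> Codebook:
    """Codebook mapping canonical names to themselves (for canonical CSVs)."""
    names = ["id", "sex", *CONTINUOUS_FIELDS, *REQUIRED_FLAGS, *OPTIONAL_FLAGS]
    return Codebook(columns={n: n for n in names})


def filter_classifiable(cohort: Cohort) -> tuple[Cohort, pd.DataFrame]:
    """Split a cohort into classifiable records and an exclusion report.

    Mirrors the study's handling of incomplete database entries: records
    missing any input of the five components (or sex) are excluded, not
    imputed.  The report has one row per excluded record with the
    comma-joined missing field names; ``len(kept) + len(report) == len(cohort)``.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    kept, excl = [], []
    for r in cohort:
        miss = r.missing_fields()
        if miss:
            excl.append({"id": r.id, "missing_fields": ",".join(miss)})
        else:
            kept.append(r)
    report = pd.DataFrame(excl, columns=["id", "missing_fields"])
    return Cohort(kept, provenance=cohort.provenance), report
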