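"""Reading, cleaning and merging of JADER-layout spontaneous-report tables.

A case report arrives split over three tables keyed by an opaque case
identifier: DRUG (one row per reported drug, with an involvement category),
REAC (one row per adverse-event preferred term) and DEMO (one row per case
with sex, age, height and weight). This module reads those tables, keeps
only drugs the reporter judged causally involved ("suspected"), removes
duplicate rows, merges everything into one case-level analysis table, and
removes cases with physiologically impossible BMI values.

All tables are plain pandas DataFrames with canonical column names; a
column map translates arbitrary source headers (e.g. the Japanese PMDA
layout) to the canonical ones.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataIntegrityError, SchemaError

#: involvement categories used in the DRUG table
INVOLVEMENT_CATEGORIES = ("suspected", "concomitant", "interaction")

#: canonical column names per table kind
CANONICAL_COLUMNS = {
    "DRUG": ["case_id", "drug_name", "involvement"],
    "REAC": ["case_id", "pt_name"],
    "DEMO": ["case_id", "sex", "age", "height", "weight"],
}

#: identity column map (synthetic fixtures use canonical headers already)
DEFAULT_COLUMN_MAP = {
    kind: {c: c for c in cols} for kind, cols in CANONICAL_COLUMNS.items()
}


def load_column_map(path) -> dict:
    """Load a {kind: {source_column: canonical_column}} map from JSON."""
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)


def read_jader_table(path, kind: str, encoding: str = "utf-8",
                     column_map: dict | None = None,
                     delimiter: str = ",") -> pd.DataFrame:
    """Read one JADER-layout table into a canonical DataFrame.

    Parameters
    ----------
    path : str or Path
        Delimited text file with a header row.
    kind : {"DRUG", "REAC", "DEMO"}
        Which table layout to expect.
    encoding : str
        File encoding; real PMDA distributions are Shift-JIS ("cp932"),
        synthetic fixtures are UTF-8.
    column_map : dict, optional
        Either a full {kind: {src: canonical}} map or the per-kind
        {src: canonical} map. Defaults to the identity map.

    Returns
    -------
    DataFrame with the canonical columns for `kind`, in file order.
    Numeric fields that fail to parse become missing, never errors.
    """
    if kind not in CANONICAL_COLUMNS:
        raise ConfigurationError(f"unknown table kind {kind!r}")
    cmap = column_map or DEFAULT_COLUMN_MAP
    if kind in cmap:
        cmap = cmap[kind]
    df = pd.read_csv(path, encoding=encoding, sep=delimiter, dtype=str,
                     keep_default_na=False)
    df = df.rename(columns=cmap)
    missing = [c for c in CANONICAL_COLUMNS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{kind} table at {path} is missing column(s) {missing}; "
            f"got header {list(df.columns)}")
    df = df[CANONICAL_COLUMNS[kind]].copy()
    if kind == "DRUG":
        bad = ~df["involvement"].isin(INVOLVEMENT_CATEGORIES)
        if bad.any():
            raise SchemaError(
                "DRUG involvement values outside "
                f"{INVOLVEMENT_CATEGORIES}: {sorted(df.loc[bad, 'involvement'].unique())}")
    if kind == "DEMO":
        df["sex"] = df["sex"].str.strip().str.lower().replace("", "missing")
        unknown = ~df["sex"].isin(["male", "female", "missing"])
        df.loc[unknown, "sex"] = "missing"
    return df


def write_jader_table(df: pd.DataFrame, path, kind: str,
                      encoding: str = "utf-8", delimiter: str = ",") -> None:
    """Write a canonical table back to disk (inverse of :func:`read_jader_table`)."""
    df[CANONICAL_COLUMNS[kind]].to_csv(path, index=False, encoding=encoding,
                                       sep=delimiter)


def filter_suspected(drug: pd.DataFrame) -> pd.DataFrame:
    """Keep only rows whose involvement category is "suspected", in stable order."""
    return drug.loc[drug["involvement"] == "suspected"].reset_index(drop=True)


def deduplicate(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Collapse duplicate report rows.

    Exact duplicate tuples collapse to one row, and within a case a repeated
    drug name (DRUG) or preferred term (REAC) collapses to one row, keeping
    the first occurrence. Idempotent and order-stable.
    """
    if kind == "DRUG":
        subset = ["case_id", "drug_name"]
    elif kind == "REAC":
        subset = ["case_id", "pt_name"]
    else:
        raise ConfigurationError(f"deduplicate expects DRUG or REAC, got {kind!r}")
    out = df.drop_duplicates().drop_duplicates(subset=subset, keep="first")
    return out.reset_index(drop=True)


_BAND_RE = re.compile(r"^(\d+)\s*s$")  # decade bands like "70s"
_NUM_RE = re.compile(r"^[+-]?\d+(\.\d+)?$")


def parse_age(raw) -> float:
    """Convert an age string to years.

    Decade bands ("70s") map to their midpoint (75); exact-year strings pass
    through; anything else is missing.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan
    s = str(raw).strip().lower()
    m = _BAND_RE.match(s)
    if m:
        return float(m.group(1)) + 5.0
    if _NUM_RE.match(s):
        return float(s)
    return np.nan


def recode_weight(raw) -> float:
    """Recode a raw weight field to kilograms.

    Open-ended bands are assigned fixed values: over 60 kg becomes 65 kg and
    under 10 kg becomes 5 kg. In-range numbers pass through; unparseable
    values are missing.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan
    if isinstance(raw, (int, float)):
        return float(raw)
    s = str(raw).strip().lower().replace("kg", "").strip()
    if s.startswith(">"):
        return 65.0 if _NUM_RE.match(s[1:].strip()) else np.nan
    if s.startswith("<"):
        return 5.0 if _NUM_RE.match(s[1:].strip()) else np.nan
    if _NUM_RE.match(s):
        return float(s)
    return np.nan


@dataclass
class CleaningReport:
    """Bookkeeping for the BMI outlier-removal step."""

    n_input: int
    n_removed_low_bmi: int
    n_removed_high_bmi: int
    n_output: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def merge_cases(drug: pd.DataFrame, reac: pd.DataFrame,
                demo: pd.DataFrame) -> pd.DataFrame:
    """Merge the three tables into one case-level analysis table.

    One row per case id present in DEMO. Suspected drugs and event terms are
    aggregated into frozensets; cases absent from DRUG or REAC get empty
    sets. Weight recoding, age parsing and BMI computation are applied.

    The DRUG input must already be suspected-only and both DRUG and REAC
    deduplicated.
    """
    if demo["case_id"].duplicated().any():
        dupes = demo.loc[demo["case_id"].duplicated(), "case_id"].unique()[:5]
        raise DataIntegrityError(f"duplicate case_id in DEMO after dedup: {list(dupes)}")
    empty = frozenset()
    drug_sets = drug.groupby("case_id")["drug_name"].agg(frozenset)
    reac_sets = reac.groupby("case_id")["pt_name"].agg(frozenset)

    cases = demo[["case_id", "sex"]].copy()
    cases["age_years"] = demo["age"].map(parse_age)
    height = pd.to_numeric(demo["height"], errors="coerce")
    height = height.where(height >= 0)
    cases["height_cm"] = height
    cases["weight_kg"] = demo["weight"].map(recode_weight)
    cases["bmi"] = cases["weight_kg"] / (cases["height_cm"] / 100.0) ** 2
    drugs_col = cases["case_id"].map(drug_sets)
    events_col = cases["case_id"].map(reac_sets)
    cases["suspected_drugs"] = [s if isinstance(s, frozenset) else empty
                                for s in drugs_col]
    cases["events"] = [s if isinstance(s, frozenset) else empty
                       for s in events_col]
    return cases.reset_index(drop=True)


def clean_bmi(cases: pd.DataFrame, low: float = 5.0,
              high: float = 100.0) -> tuple[pd.DataFrame, CleaningReport]:
    """Remove cases with computable BMI below `low` or at/above `high`.

    Cases with missing BMI are kept: the cleaning targets demonstrably
    impossible values, and per-analysis missing handling happens downstream.
    """
    if low >= high:
        raise ConfigurationError(f"BMI bounds invalid: low={low} >= high={high}")
    bmi = cases["bmi"]
    low_mask = bmi.notna() & (bmi < low)
    high_mask = bmi.notna() & (bmi >= high)
    kept = cases.loc[~(low_mask | high_mask)].reset_index(drop=True)
    report = CleaningReport(
        n_input=len(cases),
        n_removed_low_bmi=int(low_mask.sum()),
        n_removed_high_bmi=int(high_mask.sum()),
        n_output=len(kept),
    )
    return kept, report


def write_cases_csv(cases: pd.DataFrame, path) -> None:
    """Write the merged case table; drug/event sets become sorted ';'-joined lists."""
    out = cases.copy()
    for col in ("suspected_drugs", "events"):
        out[col] = out[col].map(lambda s: ";".join(sorted(s)))
    out.to_csv(path, index=False)


def read_cases_csv(path) -> pd.DataFrame:
    """Inverse of :func:`write_cases_csv`."""
    df = pd.read_csv(path, dtype={"case_id": str}, keep_default_na=True)
    for col in ("suspected_drugs", "events"):
        df[col] = df[col].map(
            lambda s: frozenset(s.split(";")) if isinstance(s, str) and s else frozenset())
    return df
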