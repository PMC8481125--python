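"""CSV readers and writers for the pipeline's tabular interchange formats.

All files are UTF-8 CSV with explicit headers; months are decimal
numbers, concentrations are nM, missing values are empty fields.  The
selectivity matrix is stored long (one row per mutation x drug cell)
so values, censor flags and annotations round-trip losslessly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .classify import GroupAssignment
from .screen import SelectivityMatrix

__all__ = [
    "read_mutation_list",
    "write_assignments",
    "read_assignments",
    "write_selectivity_matrix",
    "read_selectivity_matrix",
    "read_screen_wells",
    "read_cohort",
    "read_responses",
    "SchemaError",
]

SCREEN_COLUMNS = ["cell_line", "drug", "drug_class", "concentration_nM",
                  "replicate", "signal", "is_dmso"]
COHORT_COLUMNS = ["patient_id", "group", "tki_generation", "time_months", "event"]
RESPONSE_COLUMNS = ["patient_id", "group", "best_response"]


class SchemaError(ValueError):
    """A tabular input violated its schema; the message names row numbers."""


def read_mutation_list(path: str | Path, column: str = "allele") -> list[str]:
    """One allele per line (plain text), or a CSV with an ``allele`` column."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mutation file not found: {path}")
    text = path.read_text().strip()
    if not text:
        raise SchemaError(f"{path}: empty mutation file")
    first = text.splitlines()[0]
    if "," in first or first.strip().lower() == column:
        df = pd.read_csv(path)
        if column not in df.columns:
            raise SchemaError(f"{path}: missing column {column!r}")
        return df[column].astype(str).tolist()
    return [line.strip() for line in text.splitlines() if line.strip()]


def write_assignments(assignments: Iterable[GroupAssignment], path: str | Path) -> None:
    rows = []
    for ga in assignments:
        rows.append(
            {
                "allele": str(ga.allele),
                "raw": ga.allele.raw,
                "group": ga.allele_group,
                "subgroup": ga.subgroup or "",
                "label": ga.label,
                "exon": ga.exon_group if ga.exon_group is not None else "",
                "bucket": ga.bucket,
                "variant_groups": "|".join(ga.variant_groups),
                "rule_trace": "|".join(ga.rule_trace),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_assignments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    needed = {"allele", "group", "label", "bucket", "rule_trace"}
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_selectivity_matrix(matrix: SelectivityMatrix, path: str | Path) -> None:
    matrix.to_long().to_csv(path, index=False)


def read_selectivity_matrix(path: str | Path) -> SelectivityMatrix:
    long = pd.read_csv(path, keep_default_na=False, na_values=[""])
    needed = {"mutation", "drug", "log_ratio", "censored"}
    missing = needed - set(long.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    if long["censored"].dtype == object:
        long["censored"] = long["censored"].astype(str).str.lower().isin(["true", "1"])
    values = long.pivot(index="mutation", columns="drug", values="log_ratio")
    censored = long.pivot(index="mutation", columns="drug", values="censored").astype(bool)
    # preserve original appearance order rather than pivot's sort
    row_order = pd.unique(long["mutation"])
    col_order = pd.unique(long["drug"])
    values = values.loc[row_order, col_order]
    censored = censored.loc[row_order, col_order]
    row_groups = row_exons = col_classes = None
    if "group" in long.columns:
        row_groups = long.drop_duplicates("mutation").set_index("mutation")["group"]
    if "exon" in long.columns:
        row_exons = long.drop_duplicates("mutation").set_index("mutation")["exon"]
    if "drug_class" in long.columns:
        col_classes = long.drop_duplicates("drug").set_index("drug")["drug_class"]
    return SelectivityMatrix(values, censored, row_groups, row_exons, col_classes)


def _check_schema(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = set(columns) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")


def read_screen_wells(path: str | Path) -> pd.DataFrame:
    """Long-format raw screen; validates dtypes, naming offending rows."""
    df = pd.read_csv(path)
    _check_schema(df, SCREEN_COLUMNS, path)
    bad = df.index[pd.to_numeric(df["signal"], errors="coerce").isna()]
    if len(bad):
        raise SchemaError(f"{path}: non-numeric signal at rows {list(bad[:5])}")
    bad = df.index[pd.to_numeric(df["concentration_nM"], errors="coerce").isna()]
    if len(bad):
        raise SchemaError(f"{path}: non-numeric concentration at rows {list(bad[:5])}")
    return df


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_schema(df, COHORT_COLUMNS, path)
    times = pd.to_numeric(df["time_months"], errors="coerce")
    bad = df.index[times.isna() | (times <= 0)]
    if len(bad):
        raise SchemaError(f"{path}: non-positive or non-numeric time_months at rows {list(bad[:5])}")
    if not df["event"].isin([0, 1]).all():
        bad = df.index[~df["event"].isin([0, 1])]
        raise SchemaError(f"{path}: event must be 0/1; offending rows {list(bad[:5])}")
    return df


def read_responses(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_schema(df, RESPONSE_COLUMNS, path)
    return df
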