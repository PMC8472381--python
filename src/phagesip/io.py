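"""Reading and validation of the pipeline's TSV dialects.

One dialect everywhere: tab-separated, UTF-8, header row, "." decimal.
Validation reports offending line numbers; unknown columns warn but are
kept. Readers return plain pandas DataFrames.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "TableError",
    "read_qpcr",
    "read_counts",
    "read_fractions",
    "read_fraction_counts",
    "read_copy_numbers",
    "read_taxonomy",
    "read_labeling",
    "read_pfu",
    "read_config",
]

logger = logging.getLogger(__name__)


class TableError(ValueError):
    """A table failed schema validation; the message cites the file and line."""


def _read(
    path: str | Path,
    required: dict[str, str],
    table: str,
    optional: frozenset[str] = frozenset(),
) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TableError(f"{table} table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    missing = set(required) - set(df.columns)
    if missing:
        raise TableError(f"{path}: missing column(s) {sorted(missing)}")
    extra = set(df.columns) - set(required) - optional
    if extra:
        logger.warning("%s: unknown column(s) %s kept as-is", path, sorted(extra))
    for col, kind in required.items():
        if kind == "num":
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
                raise TableError(f"{path}: non-numeric {col!r} at line {line}")
            df[col] = pd.to_numeric(df[col])
    return df


def _check_nonneg(df: pd.DataFrame, col: str, path: str | Path, table: str) -> None:
    bad = df[col] < 0
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise TableError(f"{path}: negative {col!r} in {table} table at line {line}")


def read_qpcr(path: str | Path) -> pd.DataFrame:
    df = _read(path, {"sample_id": "str", "assay": "str",
                      "efficiency_percent": "num", "ct": "num"}, "qpcr")
    bad = ~df["assay"].isin(["internal_standard", "target_16s"])
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise TableError(f"{path}: unknown assay at line {line} "
                         "(expected internal_standard or target_16s)")
    return df


def read_counts(path: str | Path) -> pd.DataFrame:
    df = _read(path, {"sample_id": "str", "asv_id": "str", "reads": "num"}, "counts")
    _check_nonneg(df, "reads", path, "counts")
    df["reads"] = df["reads"].astype(int)
    return df


def read_fractions(path: str | Path) -> pd.DataFrame:
    df = _read(path, {"bottle": "str", "fraction_id": "str",
                      "density_g_per_ml": "num", "dna_ng": "num"}, "fractions")
    _check_nonneg(df, "dna_ng", path, "fractions")
    return df


def read_fraction_counts(path: str | Path) -> pd.DataFrame:
    df = _read(path, {"bottle": "str", "fraction_id": "str",
                      "asv_id": "str", "reads": "num"}, "fraction_counts")
    _check_nonneg(df, "reads", path, "fraction_counts")
    df["reads"] = df["reads"].astype(int)
    return df


def read_copy_numbers(path: str | Path) -> pd.DataFrame:
    df = _read(path, {"genus": "str", "copies_per_genome": "num"}, "copy_numbers")
    if (df["copies_per_genome"] < 1).any():
        raise TableError(f"{path}: copies_per_genome must be >= 1")
    return df


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """ASV → genus lookup with an optional ``gc_fraction`` column."""
    df = _read(path, {"asv_id": "str", "genus": "str"}, "taxonomy",
               optional=frozenset({"gc_fraction"}))
    if "gc_fraction" in df.columns:
        df["gc_fraction"] = pd.to_numeric(df["gc_fraction"], errors="coerce")
    return df


def read_labeling(path: str | Path) -> pd.DataFrame:
    df = _read(path, {"asv_id": "str", "labeling": "num"}, "labeling")
    if ((df["labeling"] < 0) | (df["labeling"] > 1)).any():
        raise TableError(f"{path}: labeling must be an atom fraction in [0, 1]")
    return df


def read_pfu(path: str | Path) -> pd.DataFrame:
    df = _read(path, {"bottle": "str", "time_min": "num", "pfu": "num"}, "pfu")
    _check_nonneg(df, "pfu", path, "pfu")
    return df


def read_config(path: str | Path) -> dict:
    """Key-value run configuration (YAML)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise TableError(f"{path}: config must be a key-value mapping")
    return cfg
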