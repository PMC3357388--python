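"""Readers and writers for the package's tabular formats.

All tabular files are UTF-8 TSV with a header row, decimal points and no
thousands separators. Expression matrices are genes x samples with gene
ids in the first column; sample tables carry ``sample_id``, ``condition``,
``zt`` and ``replicate`` columns; gene sets use the standard GMT layout
(name, description, members, tab-separated).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

SAMPLE_COLUMNS = ("sample_id", "condition", "zt", "replicate")


# ---------------------------------------------------------------------------
# expression matrix


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a log2 expression matrix (genes x samples) from TSV.

    Returns a DataFrame indexed by gene id with float values. Duplicate
    gene ids and non-numeric cells are rejected with errors naming the
    offending row/column.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene ids in {path}: {dupes}")
    try:
        # astype parses with full round-trip precision (to_numeric does not)
        values = raw.astype(float)
    except ValueError:
        coerced = raw.apply(pd.to_numeric, errors="coerce")
        i, j = np.argwhere(coerced.isna().to_numpy())[0]
        raise ParseError(
            f"non-numeric cell in {path}: gene {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r}, value {raw.iloc[i, j]!r}"
        ) from None
    if not np.isfinite(values.to_numpy()).all():
        i, j = np.argwhere(~np.isfinite(values.to_numpy()))[0]
        raise ParseError(
            f"non-finite cell in {path}: gene {values.index[i]!r}, "
            f"sample {values.columns[j]!r}"
        )
    values.index.name = "gene_id"
    return values


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    out.index.name = "gene_id"
    # %.17g guarantees binary round-trip of float64 values
    out.to_csv(path, sep="\t", lineterminator="\n", float_format="%.17g")


# ---------------------------------------------------------------------------
# sample table


def read_sample_table(path: str | Path, period: float = 24.0) -> pd.DataFrame:
    """Read and validate a sample table; ``zt`` is reduced modulo ``period``."""
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    return validate_sample_table(table, period=period)


def validate_sample_table(table: pd.DataFrame, period: float = 24.0) -> pd.DataFrame:
    missing = [c for c in SAMPLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"sample table missing columns: {missing}")
    table = table.loc[:, list(SAMPLE_COLUMNS)].copy()
    try:
        table["zt"] = pd.to_numeric(table["zt"], errors="raise").astype(float)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"non-numeric zt value in sample table: {exc}") from exc
    table["zt"] = np.mod(table["zt"], period)
    table["replicate"] = pd.to_numeric(table["replicate"], errors="raise").astype(int)
    if (table["replicate"] < 1).any():
        raise ValidationError("replicate numbers must be positive integers")
    if table["sample_id"].duplicated().any():
        dupes = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids: {dupes}")
    for condition, sub in table.groupby("condition"):
        if sub["zt"].nunique() < 2:
            raise ValidationError(
                f"condition {condition!r} has fewer than 2 distinct ZT values; "
                "rhythm fitting is impossible"
            )
    return table


def write_sample_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into ``{set_name: member_list}``.

    Each line must have >= 3 tab-separated fields (name, description,
    members...). Duplicate members within a set are dropped, keeping first
    occurrence order.
    """
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name = fields[0]
            members = list(dict.fromkeys(m for m in fields[2:] if m))
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, ""] + list(members)) + "\n")


# ---------------------------------------------------------------------------
# generic result tables


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")
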