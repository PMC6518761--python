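"""Readers and writers for every external format the pipeline touches.

All files are plain delimited text (tab by default, comma via ``delimiter``).
Expression matrices carry a header row of sample ids and feature ids in the
first column.  Interaction databases declare their prediction sources in a
``#sources=a,b,c`` manifest comment on the first line.  Gene sets use the
standard GMT layout (name, description, then genes, tab-separated).  Output
tables are written with a fixed float format and a stable sort so identical
inputs always produce byte-identical files.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    AliasTable,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    InteractionDB,
    SampleGroups,
)
from .errors import (
    DuplicateIdentifierError,
    FlagValueError,
    GMTFormatError,
    GroupingError,
    NonNumericValueError,
    UnknownColumnError,
)

FLOAT_FORMAT = "%.12g"


def _check_exists(path) -> Path:
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(f"no such file: {p}")
    return p


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a features x samples matrix (header = sample ids, col 0 = feature ids).

    Duplicate identifiers and non-numeric cells raise distinct named errors;
    duplicate feature rows are never silently collapsed.
    """
    p = _check_exists(path)
    raw = pd.read_csv(p, sep=delimiter, index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str).str.strip()
    raw.columns = raw.columns.astype(str).str.strip()
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise DuplicateIdentifierError(f"{p}: duplicate feature ids {dupes}")
    if raw.columns.has_duplicates:
        dupes = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise DuplicateIdentifierError(f"{p}: duplicate sample ids {dupes}")
    body = raw.replace({"": np.nan, "NA": np.nan, "nan": np.nan})
    try:
        body = body.astype(float)
    except ValueError as exc:
        raise NonNumericValueError(f"{p}: {exc}") from exc
    return ExpressionMatrix(body)


def write_expression(expr: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    df = expr.data
    df.to_csv(path, sep=delimiter, index_label="feature_id", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# sample groups
# ---------------------------------------------------------------------------

def read_sample_groups(path, control: str, delimiter: str = "\t") -> SampleGroups:
    """Read a two-column (sample_id, group) table; ``control`` names the reference group."""
    p = _check_exists(path)
    df = pd.read_csv(p, sep=delimiter, dtype=str)
    needed = {"sample_id", "group"}
    if not needed.issubset(df.columns):
        raise UnknownColumnError(f"{p}: expected columns {sorted(needed)}, got {df.columns.tolist()}")
    ids = df["sample_id"].astype(str).str.strip()
    if ids.duplicated().any():
        raise DuplicateIdentifierError(f"{p}: duplicate sample ids {ids[ids.duplicated()].tolist()}")
    assignment = dict(zip(ids, df["group"].astype(str).str.strip()))
    if not assignment:
        raise GroupingError(f"{p}: empty group table")
    return SampleGroups(assignment=assignment, control=control)


def write_sample_groups(groups: SampleGroups, path, delimiter: str = "\t") -> None:
    df = pd.DataFrame(
        {"sample_id": list(groups.assignment), "group": list(groups.assignment.values())}
    )
    df.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# interaction database
# ---------------------------------------------------------------------------

def read_interaction_db(path, source_names=None, delimiter: str = "\t") -> InteractionDB:
    """Read an interaction table (mirna, gene, one 0/1 column per source, validated).

    The source list is taken from an explicit ``source_names`` argument or,
    failing that, from a ``#sources=a,b,c`` manifest comment on the first
    line.  Duplicate (mirna, gene) rows are merged by logical OR of every
    flag and the support count recomputed.
    """
    p = _check_exists(path)
    with open(p) as fh:
        first = fh.readline().rstrip("\n")
    manifest_sources = None
    skip = 0
    if first.startswith("#sources="):
        manifest_sources = [s for s in first[len("#sources="):].split(",") if s]
        skip = 1
    if source_names is None:
        source_names = manifest_sources
    if source_names is None:
        raise UnknownColumnError(
            f"{p}: no source_names given and no '#sources=' manifest line"
        )
    source_names = list(source_names)
    df = pd.read_csv(p, sep=delimiter, skiprows=skip, dtype=str)
    expected = ["mirna", "gene", *source_names, "validated"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise UnknownColumnError(f"{p}: missing columns {missing}")
    extra = [c for c in df.columns if c not in expected]
    if extra:
        raise UnknownColumnError(f"{p}: undeclared columns {extra}")
    if df.empty:
        empty = pd.DataFrame(columns=expected)
        for c in [*source_names, "validated"]:
            empty[c] = empty[c].astype(bool)
        return InteractionDB(empty, source_names)
    flags = df[[*source_names, "validated"]]
    bad = ~flags.isin(["0", "1"]).to_numpy()
    if bad.any():
        r, c = np.argwhere(bad)[0]
        col = flags.columns[c]
        raise FlagValueError(
            f"{p}: flag column {col!r} row {r} has value {flags.iloc[r, c]!r}, expected 0/1"
        )
    df[[*source_names, "validated"]] = flags.astype(int).astype(bool)
    return InteractionDB(df, source_names)


def write_interaction_db(db: InteractionDB, path, delimiter: str = "\t") -> None:
    df = db.records.drop(columns=["support_count"]).copy()
    flag_cols = [*db.source_names, "validated"]
    df[flag_cols] = df[flag_cols].astype(int)
    with open(path, "w") as fh:
        fh.write("#sources=" + ",".join(db.source_names) + "\n")
        df.to_csv(fh, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name TAB category TAB gene [TAB gene ...] per line.

    Genes repeated within one line are deduplicated; duplicate set names are
    an error.  Blank lines are ignored.
    """
    p = _check_exists(path)
    sets: list[GeneSet] = []
    seen: set = set()
    with open(p) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTFormatError(
                    f"{p}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name, category, *genes = [f.strip() for f in fields]
            if name in seen:
                raise DuplicateIdentifierError(f"{p}:{lineno}: duplicate set name {name!r}")
            seen.add(name)
            sets.append(GeneSet(name=name, category=category, genes=frozenset(g for g in genes if g)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.set_names):
            s = collection[name]
            fh.write("\t".join([s.name, s.category, *sorted(s.genes)]) + "\n")


# ---------------------------------------------------------------------------
# alias table
# ---------------------------------------------------------------------------

def read_alias_table(path, delimiter: str = "\t") -> AliasTable:
    p = _check_exists(path)
    df = pd.read_csv(p, sep=delimiter, dtype=str)
    if "accession" not in df.columns:
        raise UnknownColumnError(f"{p}: alias table needs an 'accession' column")
    return AliasTable(df)


def write_alias_table(table: AliasTable, path, delimiter: str = "\t") -> None:
    table.table.to_csv(path, sep=delimiter, index_label="accession")


# ---------------------------------------------------------------------------
# generic result tables
# ---------------------------------------------------------------------------

def write_table(records: pd.DataFrame, path, delimiter: str = "\t", sort_by=None) -> None:
    """Write a result table deterministically.

    Rows are stably sorted by ``sort_by`` (a column name or list); floats use
    a fixed 12-significant-digit format, so the same records always yield a
    byte-identical file regardless of input order.
    """
    df = records.copy()
    if sort_by is not None:
        keys = [sort_by] if isinstance(sort_by, str) else list(sort_by)
        missing = [k for k in keys if k not in df.columns]
        if missing:
            raise UnknownColumnError(f"sort keys not in table: {missing}")
        df = df.sort_values(keys, kind="mergesort", ignore_index=True)
    parent = os.path.dirname(str(path))
    if parent and not os.path.isdir(parent):
        raise FileNotFoundError(f"output directory does not exist: {parent}")
    df.to_csv(path, sep=delimiter, index=False, float_format=FLOAT_FORMAT)


def read_table(path, delimiter: str = "\t") -> pd.DataFrame:
    p = _check_exists(path)
    return pd.read_csv(p, sep=delimiter)
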