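"""Optional preprocessing: quantile normalization and miRNA name conversion.

Both steps precede differential testing.  Normalization forces every
sample (column) to share one empirical distribution — the across-sample
mean of order statistics — which removes array-level intensity shifts.
Name conversion maps miRNA identifiers between name-space versions via an
accession-keyed alias table; unmapped names are kept, never dropped.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import AliasTable, ExpressionMatrix
from .errors import AmbiguousAliasError, DegenerateInputError, NonNumericValueError

logger = logging.getLogger(__name__)

NORMALIZATION_METHODS = ("none", "quantile")


def normalize(expr: ExpressionMatrix, method: str = "none") -> ExpressionMatrix:
    """Return a normalized copy of ``expr``.

    ``none`` returns the input unchanged.  ``quantile`` replaces each
    column's sorted values by the across-column mean of sorted values; tied
    values within a column receive the average of the reference values their
    ranks span, so the transform is well defined and idempotent.
    """
    if method not in NORMALIZATION_METHODS:
        raise ValueError(f"unknown normalization method {method!r}; choose from {NORMALIZATION_METHODS}")
    if method == "none":
        return expr
    if expr.shape[1] < 2:
        raise DegenerateInputError("quantile normalization needs >= 2 samples")
    values = expr.values
    if not np.isfinite(values).all():
        raise NonNumericValueError("quantile normalization requires fully finite values")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        # average reference values over ties so equal inputs map to equal outputs
        s = pd.Series(assigned)
        out[:, j] = s.groupby(pd.Series(col)).transform("mean").to_numpy()
    return ExpressionMatrix(pd.DataFrame(out, index=expr.data.index, columns=expr.data.columns))


def log2_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Apply log2(x + 1) for raw (non-log) intensities; values must be >= 0."""
    values = expr.values
    if np.nanmin(values) < 0:
        raise ValueError("log2(x+1) transform requires non-negative values")
    return ExpressionMatrix(
        pd.DataFrame(np.log2(values + 1.0), index=expr.data.index, columns=expr.data.columns)
    )


def convert_mirna_names(names, table: AliasTable, target_version: str) -> dict:
    """Map each miRNA name to its ``target_version`` name via accessions.

    Each input name is looked up in every version column of the alias
    table.  A name resolving to two different accessions raises
    :class:`AmbiguousAliasError`.  A name whose accession lacks a
    ``target_version`` entry, or which is absent from the table altogether,
    maps to ``None`` (unmapped) and is counted in the log — callers keep
    such features under their original names.
    """
    if target_version not in table.versions:
        raise KeyError(
            f"target version {target_version!r} not in alias table versions {table.versions}"
        )
    name_to_accessions: dict[str, set] = {}
    for version in table.versions:
        col = table.table[version]
        for accession, name in col.dropna().items():
            name_to_accessions.setdefault(str(name).strip(), set()).add(accession)

    mapping: dict[str, str | None] = {}
    for raw in names:
        name = str(raw).strip()
        accessions = name_to_accessions.get(name, set())
        if len(accessions) > 1:
            raise AmbiguousAliasError(
                f"name {name!r} matches multiple accessions: {sorted(accessions)}"
            )
        if not accessions:
            mapping[raw] = None
            continue
        (accession,) = accessions
        mapping[raw] = table.name_of(accession, target_version)
    n_unmapped = sum(1 for v in mapping.values() if v is None)
    if n_unmapped:
        logger.warning(
            "%d of %d miRNA names could not be mapped to version %r and are kept as-is",
            n_unmapped, len(mapping), target_version,
        )
    return mapping


def rename_features(expr: ExpressionMatrix, mapping: dict) -> ExpressionMatrix:
    """Apply a name mapping to a matrix, keeping unmapped features unchanged."""
    new_index = [mapping.get(f) or f for f in expr.feature_ids]
    return ExpressionMatrix(
        pd.DataFrame(expr.values, index=pd.Index(new_index), columns=expr.data.columns)
    )
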