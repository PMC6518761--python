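"""Core in-memory containers.

The pipeline moves five kinds of objects around: log2-scale expression
matrices (features x samples), a two-group sample assignment, a table of
candidate miRNA-gene interactions with per-source support flags, named gene
sets, and a miRNA name/accession alias table.  Each container validates its
own invariants at construction so downstream stages can assume them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    DuplicateIdentifierError,
    GroupingError,
    NonNumericValueError,
)


class ExpressionMatrix:
    """A features x samples matrix of log2-scale expression values.

    Wraps a :class:`pandas.DataFrame` whose index holds feature identifiers
    (miRNA names or gene symbols) and whose columns hold sample identifiers.
    Identifiers must be unique; every row must contain at least one finite
    value.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise DuplicateIdentifierError(f"duplicate feature ids: {dupes}")
        if data.columns.has_duplicates:
            dupes = data.columns[data.columns.duplicated()].unique().tolist()
            raise DuplicateIdentifierError(f"duplicate sample ids: {dupes}")
        try:
            values = data.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise NonNumericValueError(f"non-numeric expression value: {exc}") from exc
        if values.shape[0] and values.shape[1]:
            all_nan = ~np.isfinite(values).any(axis=1)
            if all_nan.any():
                bad = data.index[all_nan].tolist()
                raise DegenerateInputError(f"rows with no finite value: {bad}")
        self._data = pd.DataFrame(
            values,
            index=data.index.astype(str).rename(None),
            columns=data.columns.astype(str).rename(None),
        )

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def feature_ids(self) -> list[str]:
        return self._data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self._data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        missing = [f for f in feature_ids if f not in self._data.index]
        if missing:
            raise KeyError(f"features not in matrix: {missing}")
        return ExpressionMatrix(self._data.loc[list(feature_ids)])

    def reorder_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self._data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self._data[list(sample_ids)])

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self._data.equals(other._data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, m = self.shape
        return f"ExpressionMatrix({n} features x {m} samples)"


@dataclass(frozen=True)
class SampleGroups:
    """Assignment of samples to exactly two phenotype groups.

    ``control`` names the reference group; the other label is the case/test
    group.  Log ratios downstream are always case minus control.
    """

    assignment: dict
    control: str

    def __post_init__(self):
        labels = sorted(set(self.assignment.values()))
        if len(labels) != 2:
            raise GroupingError(f"exactly two group labels required, got {labels}")
        if self.control not in labels:
            raise GroupingError(
                f"control label {self.control!r} not among group labels {labels}"
            )

    @property
    def labels(self) -> tuple[str, str]:
        """(control, case) label pair."""
        other = next(g for g in sorted(set(self.assignment.values())) if g != self.control)
        return (self.control, other)

    @property
    def case(self) -> str:
        return self.labels[1]

    def samples_of(self, label: str) -> list[str]:
        return [s for s, g in self.assignment.items() if g == label]

    def indices_for(self, sample_ids, minimum_per_group: int = 2):
        """Map ``sample_ids`` to (control_idx, case_idx) integer arrays.

        Raises if any sample is unassigned or either group is smaller than
        ``minimum_per_group`` (variance-based tests need >= 2 per group).
        """
        missing = [s for s in sample_ids if s not in self.assignment]
        if missing:
            raise GroupingError(f"samples without group assignment: {missing}")
        ctrl, case = self.labels
        ctrl_idx = np.array(
            [i for i, s in enumerate(sample_ids) if self.assignment[s] == ctrl], dtype=int
        )
        case_idx = np.array(
            [i for i, s in enumerate(sample_ids) if self.assignment[s] == case], dtype=int
        )
        if len(ctrl_idx) < minimum_per_group or len(case_idx) < minimum_per_group:
            raise GroupingError(
                f"each group needs >= {minimum_per_group} samples; "
                f"got {len(ctrl_idx)} {ctrl!r} and {len(case_idx)} {case!r}"
            )
        return ctrl_idx, case_idx


class InteractionDB:
    """Candidate miRNA-gene pairs with per-source prediction flags.

    Each record is a (mirna, gene) pair, one boolean flag per declared
    prediction source, a boolean ``validated`` flag (experimentally curated
    evidence), and the derived ``support_count`` = number of true prediction
    flags.  Duplicate pairs are merged by logical OR of all flags.
    """

    def __init__(self, records: pd.DataFrame, source_names: list[str]):
        self.source_names = list(source_names)
        required = ["mirna", "gene", *self.source_names, "validated"]
        missing = [c for c in required if c not in records.columns]
        if missing:
            raise KeyError(f"interaction records missing columns: {missing}")
        df = records[required].copy()
        df["mirna"] = df["mirna"].astype(str).str.strip()
        df["gene"] = df["gene"].astype(str).str.strip()
        flag_cols = [*self.source_names, "validated"]
        df[flag_cols] = df[flag_cols].astype(bool)
        # OR-merge duplicates; sort for a canonical, order-independent layout
        df = df.groupby(["mirna", "gene"], as_index=False)[flag_cols].any()
        df = df.sort_values(["mirna", "gene"], kind="mergesort", ignore_index=True)
        df["support_count"] = df[self.source_names].sum(axis=1).astype(int)
        self._records = df

    @property
    def records(self) -> pd.DataFrame:
        return self._records

    def __len__(self) -> int:
        return len(self._records)

    def lookup(self, pairs: pd.DataFrame) -> pd.DataFrame:
        """Annotate a frame with 'mirna'/'gene' columns with support/validated.

        Pairs absent from the database get support_count 0, validated False.
        """
        key = self._records[["mirna", "gene", "support_count", "validated"]]
        bare = pairs.drop(columns=["support_count", "validated"], errors="ignore")
        out = bare.merge(key, on=["mirna", "gene"], how="left")
        out["support_count"] = out["support_count"].fillna(0).astype(int)
        out["validated"] = out["validated"].eq(True)  # NaN (absent pair) -> False
        return out

    def equals(self, other: "InteractionDB") -> bool:
        return (
            self.source_names == other.source_names
            and self._records.equals(other._records)
        )


@dataclass(frozen=True)
class GeneSet:
    name: str
    category: str
    genes: frozenset

    def __post_init__(self):
        if not self.genes:
            raise DegenerateInputError(f"gene set {self.name!r} is empty")


class GeneSetCollection:
    """Named, categorised gene sets (flat gene lists, no ontology topology)."""

    def __init__(self, sets: list[GeneSet]):
        names = [s.name for s in sets]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise DuplicateIdentifierError(f"duplicate gene-set names: {dupes}")
        self._sets = {s.name: s for s in sets}

    @property
    def set_names(self) -> list[str]:
        return list(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def all_genes(self) -> frozenset:
        out: set = set()
        for s in self._sets.values():
            out |= s.genes
        return frozenset(out)

    def equals(self, other: "GeneSetCollection") -> bool:
        return self._sets == other._sets


class AliasTable:
    """miRNA accession to per-version name mapping.

    One row per stable accession; one column per name-space version label
    (e.g. miRBase releases).  Missing names are NA.
    """

    def __init__(self, table: pd.DataFrame):
        if "accession" not in table.columns:
            raise KeyError("alias table needs an 'accession' column")
        df = table.copy()
        df["accession"] = df["accession"].astype(str).str.strip()
        if df["accession"].duplicated().any():
            dupes = df.loc[df["accession"].duplicated(), "accession"].tolist()
            raise DuplicateIdentifierError(f"duplicate accessions: {dupes}")
        for col in df.columns:
            if col == "accession":
                continue
            names = df[col].dropna().astype(str).str.strip()
            if names.duplicated().any():
                dupes = names[names.duplicated()].tolist()
                raise DuplicateIdentifierError(
                    f"duplicate names within version {col!r}: {dupes}"
                )
        self._table = df.set_index("accession")

    @property
    def versions(self) -> list[str]:
        return self._table.columns.tolist()

    @property
    def table(self) -> pd.DataFrame:
        return self._table

    def name_of(self, accession: str, version: str):
        val = self._table.at[accession, version]
        return None if pd.isna(val) else str(val)

    def equals(self, other: "AliasTable") -> bool:
        return self._table.equals(other._table)
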