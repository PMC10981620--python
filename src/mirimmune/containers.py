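"""Core in-memory containers shared by every pipeline stage.

All containers are thin, validated wrappers around pandas/numpy objects;
validation happens at construction so downstream stages can assume clean
inputs (no duplicate IDs, no missing values, consistent shapes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """An input object violates a structural invariant."""


def _check_unique(ids, what: str) -> None:
    seen: set = set()
    dupes: list = []
    for x in ids:
        if x in seen and x not in dupes:
            dupes.append(x)
        seen.add(x)
    if dupes:
        raise ValidationError(f"duplicate {what}: {', '.join(map(str, dupes))}")


@dataclass
class ExpressionMatrix:
    """A features x samples numeric expression matrix.

    Parameters
    ----------
    data:
        DataFrame with feature IDs as index and sample IDs as columns.
        Must be fully numeric with no missing values.
    feature_kind:
        ``"gene"`` or ``"mirna"`` -- what the rows are.
    unit:
        Free-text declaration of the expression unit (e.g.
        ``"log2-normalized"``); recorded, never transformed.
    """

    data: pd.DataFrame
    feature_kind: str
    unit: str = "arbitrary"

    def __post_init__(self) -> None:
        if self.feature_kind not in ("gene", "mirna"):
            raise ValidationError(
                f"feature_kind must be 'gene' or 'mirna', got {self.feature_kind!r}"
            )
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValidationError("empty expression matrix")
        _check_unique(self.data.index, f"{self.feature_kind} IDs")
        _check_unique(self.data.columns, "sample IDs")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression matrix is not numeric")
        if np.isnan(values.astype(float)).any():
            raise ValidationError("expression matrix contains missing values")

    @property
    def feature_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def vector(self, feature_id: str) -> np.ndarray:
        """Expression of one feature across samples."""
        if feature_id not in self.data.index:
            raise KeyError(f"unknown {self.feature_kind} ID: {feature_id}")
        return self.data.loc[feature_id].to_numpy(dtype=float)


@dataclass
class GeneSet:
    set_id: str
    description: str
    members: frozenset

    def __post_init__(self) -> None:
        if not isinstance(self.members, frozenset):
            object.__setattr__(self, "members", frozenset(self.members))
        if len(self.members) == 0:
            raise ValidationError(f"gene set {self.set_id!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """An ordered collection of gene sets with unique IDs."""

    sets: list

    def __post_init__(self) -> None:
        _check_unique([s.set_id for s in self.sets], "set IDs")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)

    @property
    def set_ids(self) -> list:
        return [s.set_id for s in self.sets]


@dataclass
class GoTermTable:
    """GO term annotations: (term_id, name, description) records."""

    records: pd.DataFrame  # columns: term_id, name, description

    def __post_init__(self) -> None:
        required = ["term_id", "name", "description"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise ValidationError(f"GO table missing columns: {missing}")
        _check_unique(self.records["term_id"], "GO term IDs")
        if (self.records["name"].astype(str).str.len() == 0).any():
            raise ValidationError("GO table has empty term names")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def term_ids(self) -> list:
        return list(self.records["term_id"])

    def subset(self, term_ids) -> "GoTermTable":
        keep = self.records[self.records["term_id"].isin(set(term_ids))]
        return GoTermTable(keep.reset_index(drop=True))


@dataclass
class RankedGeneList:
    """Genes ordered by signed correlation with one miRNA.

    Invariants: scores sorted descending, ties broken by gene_id
    lexicographically; all scores in [-1, 1]; gene IDs unique.
    """

    mirna_id: str
    gene_ids: list
    scores: np.ndarray
    n_dropped_constant: int = 0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.gene_ids) != len(self.scores):
            raise ValidationError("gene_ids and scores length mismatch")
        _check_unique(self.gene_ids, "gene IDs")
        if len(self.scores) and (
            np.any(self.scores > 1 + 1e-12) or np.any(self.scores < -1 - 1e-12)
        ):
            raise ValidationError("correlation scores outside [-1, 1]")
        diffs = np.diff(self.scores)
        if np.any(diffs > 1e-12):
            raise ValidationError("scores not sorted descending")

    def __len__(self) -> int:
        return len(self.gene_ids)

    @property
    def entries(self) -> list:
        return list(zip(self.gene_ids, self.scores))

    def positions_of(self, members) -> np.ndarray:
        """0-based positions of the given genes in the ranked list, sorted."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        pos = sorted(index[g] for g in members if g in index)
        return np.asarray(pos, dtype=np.int64)
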