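"""Pedigree handling and the numerator relationship matrix.

The additive (numerator) relationship matrix ``A`` gives, for every pair of
animals, twice their kinship coefficient: the expected fraction of alleles
shared identical by descent, scaled so that a non-inbred animal has
``A_ii = 1`` and a parent-offspring pair has ``A_ij = 0.5``.  ``A`` is the
covariance structure of the polygenic random effect in the animal model
(``a ~ N(0, A * sigma_a^2)``).

It is built here with the classical tabular method: process animals in an
order where parents precede offspring and fill

    A_ii = 1 + 0.5 * A_{s(i), d(i)}
    A_ij = 0.5 * (A_{j, s(i)} + A_{j, d(i)})   for previously processed j

with unknown-parent terms contributing zero.  Unknown parents are treated as
unrelated, non-inbred founders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

UNKNOWN = ""
_UNKNOWN_TOKENS = {"", "0", ".", "NA", "na", "None"}


class PedigreeError(ValueError):
    """Raised for structural pedigree problems (cycles, duplicates)."""


@dataclass(frozen=True)
class PedigreeRecord:
    animal: str
    sire: str = UNKNOWN
    dam: str = UNKNOWN


@dataclass
class Pedigree:
    """A validated, topologically orderable set of parentage records.

    Parents referenced but never listed as animals are auto-promoted to
    founder records, so ``animals`` is closed under parentage.
    """

    records: list[PedigreeRecord] = field(default_factory=list)
    generation_depth: int = 3

    def __post_init__(self) -> None:
        self.records = _normalise(self.records)
        self._by_id = {r.animal: r for r in self.records}
        self._order = _topological_order(self.records)

    @property
    def animals(self) -> list[str]:
        return [r.animal for r in self.records]

    def topological_order(self) -> list[str]:
        """Animal ids with every parent preceding its offspring."""
        return list(self._order)

    def parents(self, animal: str) -> tuple[str, str]:
        r = self._by_id[animal]
        return r.sire, r.dam

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, animal: str) -> bool:
        return animal in self._by_id

    def trim_to_generations(self, focal: Iterable[str], k: int | None = None) -> "Pedigree":
        """Keep the focal animals plus at most ``k`` ancestral generations.

        Mirrors tracing a pedigree back a fixed number of generations above
        the phenotyped animals; ancestors beyond the cut become founders.
        """
        if k is None:
            k = self.generation_depth
        keep: dict[str, int] = {}
        frontier = [(a, 0) for a in focal if a in self._by_id]
        while frontier:
            animal, depth = frontier.pop()
            if keep.get(animal, k + 1) <= depth:
                continue
            keep[animal] = depth
            if depth < k:
                for p in self.parents(animal):
                    if p != UNKNOWN:
                        frontier.append((p, depth + 1))
        records = []
        for r in self.records:
            if r.animal not in keep:
                continue
            sire = r.sire if r.sire in keep else UNKNOWN
            dam = r.dam if r.dam in keep else UNKNOWN
            records.append(PedigreeRecord(r.animal, sire, dam))
        return Pedigree(records, generation_depth=k)


def _normalise(records: Sequence[PedigreeRecord]) -> list[PedigreeRecord]:
    seen: set[str] = set()
    for r in records:
        if r.animal in seen:
            raise PedigreeError(f"duplicate animal id {r.animal!r}")
        seen.add(r.animal)
    sires = {r.sire for r in records if r.sire != UNKNOWN}
    dams = {r.dam for r in records if r.dam != UNKNOWN}
    both = sires & dams
    if both:
        warnings.warn(
            f"ids appearing as both sire and dam: {sorted(both)[:5]}", stacklevel=3
        )
    out = list(records)
    for p in sorted((sires | dams) - seen):
        out.append(PedigreeRecord(p))  # promote to founder
    return out


def _topological_order(records: Sequence[PedigreeRecord]) -> list[str]:
    ts: TopologicalSorter[str] = TopologicalSorter()
    for r in records:
        preds = [p for p in (r.sire, r.dam) if p != UNKNOWN]
        ts.add(r.animal, *preds)
    try:
        return list(ts.static_order())
    except CycleError as exc:
        cycle = exc.args[1]
        raise PedigreeError(
            f"pedigree contains a cycle through animal {cycle[0]!r}"
        ) from exc


def read_pedigree(
    path,
    dialect: Mapping[str, str] | None = None,
    generation_depth: int = 3,
) -> Pedigree:
    """Read a pedigree CSV with columns ``animal,sire,dam``.

    Empty cells and ``"0"`` denote unknown parents.  ``dialect`` maps the
    canonical column names to the file's actual column names.
    """
    cols = {"animal": "animal", "sire": "sire", "dam": "dam"}
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise PedigreeError(f"pedigree file lacks columns {missing}")

    def clean(v: str) -> str:
        v = v.strip()
        return UNKNOWN if v in _UNKNOWN_TOKENS else v

    records = [
        PedigreeRecord(row[cols["animal"]].strip(), clean(row[cols["sire"]]), clean(row[cols["dam"]]))
        for _, row in df.iterrows()
    ]
    for r in records:
        if r.animal in (r.sire, r.dam):
            raise PedigreeError(f"animal {r.animal!r} listed as its own parent")
    return Pedigree(records, generation_depth=generation_depth)


def write_pedigree(ped: Pedigree, path) -> None:
    df = pd.DataFrame(
        [(r.animal, r.sire, r.dam) for r in ped.records],
        columns=["animal", "sire", "dam"],
    )
    df.to_csv(path, index=False)


@dataclass
class RelationshipMatrix:
    """Dense numerator relationship matrix with its id ordering."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("A matrix shape does not match ids")
        self._index = {a: i for i, a in enumerate(self.ids)}

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        """Rows/columns of A for the given animals, in the given order."""
        idx = [self._index[a] for a in ids]
        return self.values[np.ix_(idx, idx)]

    def loc(self, i: str, j: str) -> float:
        return float(self.values[self._index[i], self._index[j]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="animal")


def build_a_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Ids are returned in topological order (parents before offspring).
    """
    order = ped.topological_order()
    index = {a: i for i, a in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    zero = np.zeros(n)
    for i, animal in enumerate(order):
        sire, dam = ped.parents(animal)
        s = index.get(sire) if sire != UNKNOWN else None
        d = index.get(dam) if dam != UNKNOWN else None
        col_s = A[:i, s] if s is not None else zero[:i]
        col_d = A[:i, d] if d is not None else zero[:i]
        row = 0.5 * (col_s + col_d)
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s is not None and d is not None) else 0.0)
    return RelationshipMatrix(order, A)


def inbreeding_coefficients(A: RelationshipMatrix) -> pd.Series:
    """Per-animal inbreeding coefficient F_i = A_ii - 1."""
    return pd.Series(np.diag(A.values) - 1.0, index=A.ids, name="F")
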