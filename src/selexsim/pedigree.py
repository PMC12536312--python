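"""Pedigree containers, CSV I/O, and the additive (numerator) relationship matrix.

The additive relationship ``A_ij`` is twice the coefficient of coancestry
(kinship).  The diagonal carries ``1 + F_i``, where ``F_i`` is the inbreeding
coefficient of individual *i*.  Founders — individuals with both parents
unknown — are assumed unrelated and non-inbred, the standard base-population
convention when no deeper pedigree exists.

The matrix is built with the tabular (recursive) method, processing
individuals in an order where every parent precedes its offspring:

    A_ij = 1/2 (A_j,sire(i) + A_j,dam(i))     for j already processed
    A_ii = 1 + 1/2 A_sire(i),dam(i)

with unknown parents contributing zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: tokens accepted as "parent unknown" on read (case-insensitive)
MISSING_PARENT_TOKENS = frozenset({"0", "", "na", "nan", "none"})


class PedigreeError(ValueError):
    """Malformed or internally inconsistent pedigree."""


class Line(str, Enum):
    """Selection line of an individual.

    ``BASE`` marks members of the generation-0 founder pool, which exists
    before the top/bottom/control lines are formed.
    """

    TOP = "top"
    BOTTOM = "bottom"
    CONTROL = "control"
    BASE = "base"


@dataclass(frozen=True)
class PedigreeRecord:
    """One individual: identity, parentage, and experimental position."""

    individual_id: str
    sire_id: str | None
    dam_id: str | None
    generation: int
    line: Line = Line.BASE
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.generation < 0:
            raise PedigreeError(
                f"{self.individual_id}: generation must be non-negative"
            )
        if self.replicate < 1:
            raise PedigreeError(f"{self.individual_id}: replicate must be positive")
        for p in (self.sire_id, self.dam_id):
            if p is not None and p == self.individual_id:
                raise PedigreeError(
                    f"{self.individual_id} is listed as its own parent"
                )

    @property
    def is_founder(self) -> bool:
        return self.sire_id is None and self.dam_id is None


class Pedigree:
    """An ordered set of :class:`PedigreeRecord` with parents before offspring.

    Construction validates uniqueness of ids, existence of parent references,
    and acyclicity (enforced through the strictly-increasing generation of
    offspring relative to their parents).  Input order is irrelevant; records
    are topologically sorted by ``(generation, id)``.
    """

    def __init__(self, records: Iterable[PedigreeRecord], *, auto_founders: bool = False):
        records = list(records)
        ids = [r.individual_id for r in records]
        seen: set[str] = set()
        dup = [i for i in ids if i in seen or seen.add(i)]  # type: ignore[func-returns-value]
        if dup:
            raise PedigreeError(f"duplicate individual ids: {sorted(set(dup))[:10]}")
        known = set(ids)

        referenced = {
            p for r in records for p in (r.sire_id, r.dam_id) if p is not None
        }
        missing = sorted(referenced - known)
        if missing:
            if not auto_founders:
                raise PedigreeError(
                    f"unknown parent ids referenced: {missing[:10]}"
                )
            # insert each absent parent as a founder one generation before its
            # earliest child, inheriting that child's line/replicate
            for pid in missing:
                children = [
                    r for r in records if pid in (r.sire_id, r.dam_id)
                ]
                g = min(c.generation for c in children)
                if g == 0:
                    raise PedigreeError(
                        f"parent {pid} of a generation-0 individual cannot be inserted"
                    )
                log.warning("parent %s not listed; inserted as founder at generation %d", pid, g - 1)
                records.append(
                    PedigreeRecord(pid, None, None, g - 1, children[0].line, children[0].replicate)
                )
            known = {r.individual_id for r in records}

        records.sort(key=lambda r: (r.generation, r.individual_id))
        index = {r.individual_id: k for k, r in enumerate(records)}
        for k, r in enumerate(records):
            for p in (r.sire_id, r.dam_id):
                if p is None:
                    continue
                parent = records[index[p]]
                if parent.generation >= r.generation:
                    raise PedigreeError(
                        f"{r.individual_id} (generation {r.generation}) has parent "
                        f"{p} of generation {parent.generation}; parents must be "
                        "of a strictly earlier generation"
                    )
        self.records: tuple[PedigreeRecord, ...] = tuple(records)
        self.index: dict[str, int] = index

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.individual_id for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.individual_id for r in self.records],
                "sire": [r.sire_id or "0" for r in self.records],
                "dam": [r.dam_id or "0" for r in self.records],
                "generation": [r.generation for r in self.records],
                "line": [r.line.value for r in self.records],
                "replicate": [r.replicate for r in self.records],
            }
        )


def _clean_parent(token: object) -> str | None:
    s = "" if token is None else str(token).strip()
    return None if s.lower() in MISSING_PARENT_TOKENS else s


def read_pedigree(path: str | Path, *, auto_founders: bool = True) -> Pedigree:
    """Read a pedigree CSV with columns id, sire, dam, generation, line, replicate.

    Missing parents may be encoded as ``0``, empty, or ``NA``.  Individuals
    referenced as parents but absent as rows are auto-inserted as founders
    with a logged warning (disable with ``auto_founders=False``).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"id", "sire", "dam", "generation"}
    if not required.issubset(df.columns):
        raise PedigreeError(
            f"pedigree file must have columns {sorted(required)}; got {list(df.columns)}"
        )
    records = []
    for row in df.itertuples(index=False):
        records.append(
            PedigreeRecord(
                individual_id=str(row.id).strip(),
                sire_id=_clean_parent(row.sire),
                dam_id=_clean_parent(row.dam),
                generation=int(row.generation),
                line=Line(str(getattr(row, "line", "base")).strip().lower()),
                replicate=int(getattr(row, "replicate", 1)),
            )
        )
    return Pedigree(records, auto_founders=auto_founders)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    ped.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class RelationshipMatrix:
    """Additive relationships ``A_ij`` over an ordered set of individuals."""

    ids: tuple[str, ...]
    values: np.ndarray  # square, symmetric

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("values must be square and match ids")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "_index", {i: k for k, i in enumerate(self.ids)})

    @property
    def inbreeding(self) -> np.ndarray:
        """Per-individual inbreeding coefficient ``F_i = A_ii - 1``."""
        return np.diag(self.values) - 1.0

    @property
    def kinship(self) -> np.ndarray:
        """Coefficients of coancestry, ``A / 2``."""
        return self.values / 2.0

    def loc(self, i: str, j: str) -> float:
        idx = self._index  # type: ignore[attr-defined]
        try:
            return float(self.values[idx[i], idx[j]])
        except KeyError as e:
            raise KeyError(f"id {e.args[0]!r} not in relationship matrix") from None

    def submatrix(self, ids: Sequence[str]) -> "RelationshipMatrix":
        idx = self._index  # type: ignore[attr-defined]
        try:
            rows = [idx[i] for i in ids]
        except KeyError as e:
            raise KeyError(f"id {e.args[0]!r} not in relationship matrix") from None
        return RelationshipMatrix(tuple(ids), self.values[np.ix_(rows, rows)])

    def to_dense_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def to_long_frame(self) -> pd.DataFrame:
        iu = np.triu_indices(len(self.ids))
        return pd.DataFrame(
            {
                "i": [self.ids[a] for a in iu[0]],
                "j": [self.ids[b] for b in iu[1]],
                "value": self.values[iu],
            }
        )

    def write_csv(self, path: str | Path, *, fmt: str = "dense") -> None:
        if fmt == "dense":
            self.to_dense_frame().to_csv(path, index_label="id")
        elif fmt == "long":
            self.to_long_frame().to_csv(path, index=False)
        else:
            raise ValueError(f"unknown format {fmt!r}; use 'dense' or 'long'")

    @classmethod
    def read_dense_csv(cls, path: str | Path) -> "RelationshipMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(tuple(str(i) for i in df.index), df.to_numpy(dtype=float))


def additive_relationship_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix of a pedigree by the tabular method."""
    n = len(ped)
    A = np.zeros((n, n))
    idx = ped.index
    for i, rec in enumerate(ped.records):
        s = idx[rec.sire_id] if rec.sire_id is not None else None
        d = idx[rec.dam_id] if rec.dam_id is not None else None
        if s is not None and d is not None:
            A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
            A[i, i] = 1.0 + 0.5 * A[s, d]
        elif s is not None or d is not None:
            p = s if s is not None else d
            A[i, :i] = 0.5 * A[p, :i]
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    return RelationshipMatrix(ped.ids, A)


def mean_pairwise_relatedness(
    A: RelationshipMatrix, pairs: Sequence[tuple[str, str]]
) -> float:
    """Arithmetic mean of ``A_ij`` over the supplied id pairs."""
    if len(pairs) == 0:
        raise ValueError("pair list is empty")
    return float(np.mean([A.loc(i, j) for i, j in pairs]))
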