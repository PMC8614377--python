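"""Honeybee pedigrees with drone-group pseudo-sires.

A honeybee queen mates once, on a single series of nuptial flights, with a
set of drones.  Because individual drones are never observed, the paternal
side of a pedigree is a *sire group*: the set of D drones the queen mated
with, whose mothers (drone-producing queens, DPQs) are known colony heads at
the mating station.  Drones are haploid and genetically equivalent to single
maternal gametes, which is what makes the kinship algebra of
:mod:`apisqg.relationship` different from the diploid tabular method.

This module holds the pedigree containers, CSV I/O and validation;
relationship computations live in :mod:`apisqg.relationship`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "QueenRecord",
    "SireGroup",
    "Pedigree",
    "PedigreeError",
    "DuplicateIdError",
    "DanglingReferenceError",
    "PartialParentageError",
    "PedigreeCycleError",
    "load_pedigree",
]


class PedigreeError(ValueError):
    """Base class for pedigree validation failures."""


class DuplicateIdError(PedigreeError):
    """The same identifier is used more than once."""


class DanglingReferenceError(PedigreeError):
    """A dam or DPQ id does not resolve to a queen, or a sire-group id to a group."""


class PartialParentageError(PedigreeError):
    """Exactly one of dam / sire group is known; founders must have both unknown."""


class PedigreeCycleError(PedigreeError):
    """An individual is its own ancestor through dam or DPQ links."""


@dataclass(frozen=True)
class QueenRecord:
    """One queen: either a founder (both parents unknown) or a dam x sire-group cross."""

    id: str
    dam_id: str | None = None
    sire_group_id: str | None = None
    year: int | None = None

    def __post_init__(self) -> None:
        if (self.dam_id is None) != (self.sire_group_id is None):
            raise PartialParentageError(
                f"queen {self.id!r}: dam and sire group must be both known or both "
                f"unknown (dam={self.dam_id!r}, sire_group={self.sire_group_id!r})"
            )
        if self.dam_id == self.id:
            raise PedigreeCycleError(f"queen {self.id!r} is her own dam")

    @property
    def is_founder(self) -> bool:
        return self.dam_id is None


@dataclass(frozen=True)
class SireGroup:
    """The D drones one queen mated with, identified by their DPQ mothers.

    Drones are sampled uniformly and independently across the group's DPQ
    mothers, so two distinct drones share a mother with probability 1/m.
    Groups from the same station-year pool may share DPQ mothers but never
    share a drone (a drone mates once and dies).
    """

    id: str
    dpq_ids: tuple[str, ...]
    n_drones: int = 12
    pool_id: str | None = None

    def __post_init__(self) -> None:
        if not self.dpq_ids:
            raise PedigreeError(f"sire group {self.id!r} has no DPQ mothers")
        if len(set(self.dpq_ids)) != len(self.dpq_ids):
            raise DuplicateIdError(f"sire group {self.id!r} lists a DPQ twice")
        if self.n_drones < 1:
            raise PedigreeError(f"sire group {self.id!r}: n_drones must be >= 1")


class Pedigree:
    """Validated, topologically sorted collection of queens and sire groups.

    Parameters
    ----------
    queens, sire_groups
        In any order; the constructor validates referential integrity,
        checks for cycles and stores queens in topological order
        (every dam and DPQ precedes the queens that reference her).
    """

    def __init__(self, queens: Iterable[QueenRecord], sire_groups: Iterable[SireGroup] = ()) -> None:
        queens = list(queens)
        sire_groups = list(sire_groups)

        self.queens: dict[str, QueenRecord] = {}
        for q in queens:
            if q.id in self.queens:
                raise DuplicateIdError(f"duplicate queen id {q.id!r}")
            self.queens[q.id] = q
        self.sire_groups: dict[str, SireGroup] = {}
        for g in sire_groups:
            if g.id in self.sire_groups or g.id in self.queens:
                raise DuplicateIdError(f"duplicate id {g.id!r}")
            self.sire_groups[g.id] = g

        for g in self.sire_groups.values():
            for m in g.dpq_ids:
                if m not in self.queens:
                    raise DanglingReferenceError(
                        f"sire group {g.id!r}: DPQ {m!r} is not a known queen"
                    )
        for q in self.queens.values():
            if q.is_founder:
                continue
            if q.dam_id not in self.queens:
                raise DanglingReferenceError(f"queen {q.id!r}: unknown dam {q.dam_id!r}")
            if q.sire_group_id not in self.sire_groups:
                raise DanglingReferenceError(
                    f"queen {q.id!r}: unknown sire group {q.sire_group_id!r}"
                )

        self.queen_order: list[str] = self._topological_order()

    def _parents(self, qid: str) -> list[str]:
        q = self.queens[qid]
        if q.is_founder:
            return []
        return [q.dam_id] + list(self.sire_groups[q.sire_group_id].dpq_ids)

    def _topological_order(self) -> list[str]:
        # Kahn's algorithm over queen -> (dam, DPQs) dependency edges.
        indeg = {qid: 0 for qid in self.queens}
        children: dict[str, list[str]] = {qid: [] for qid in self.queens}
        for qid in self.queens:
            parents = set(self._parents(qid))
            indeg[qid] = len(parents)
            for p in parents:
                children[p].append(qid)
        ready = sorted(qid for qid, d in indeg.items() if d == 0)
        order: list[str] = []
        while ready:
            qid = ready.pop(0)
            order.append(qid)
            newly = []
            for c in children[qid]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    newly.append(c)
            ready = sorted(newly) + ready
        if len(order) != len(self.queens):
            stuck = sorted(qid for qid, d in indeg.items() if d > 0)
            raise PedigreeCycleError(f"cycle through dam/DPQ links involving {stuck}")
        return order

    def __len__(self) -> int:
        return len(self.queens)

    def founders(self) -> list[str]:
        return [qid for qid in self.queen_order if self.queens[qid].is_founder]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pedigree):
            return NotImplemented
        return self.queens == other.queens and self.sire_groups == other.sire_groups

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Return (queen table, sire-group table) in the CSV column layout."""
        qrows = [
            {
                "id": q.id,
                "dam_id": q.dam_id or "",
                "sire_group_id": q.sire_group_id or "",
                "year": "" if q.year is None else q.year,
            }
            for q in (self.queens[i] for i in self.queen_order)
        ]
        grows = [
            {
                "group_id": g.id,
                "dpq_ids": ";".join(g.dpq_ids),
                "n_drones": g.n_drones,
                "pool_id": g.pool_id or "",
            }
            for g in self.sire_groups.values()
        ]
        return pd.DataFrame(qrows), pd.DataFrame(grows)

    def write_csv(self, pedigree_file: str | Path, sire_group_file: str | Path) -> None:
        qdf, gdf = self.to_frames()
        qdf.to_csv(pedigree_file, index=False)
        gdf.to_csv(sire_group_file, index=False)


def _clean(value: object) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return s or None


def load_pedigree(pedigree_file: str | Path, sire_group_file: str | Path) -> Pedigree:
    """Read pedigree and sire-group CSVs and return a validated :class:`Pedigree`.

    The pedigree CSV has columns ``id,dam_id,sire_group_id`` (optionally
    ``year``); empty dam/sire fields mark founders.  The sire-group CSV has
    columns ``group_id,dpq_ids,n_drones,pool_id`` with DPQ ids separated by
    semicolons.  Row order is irrelevant: queens are topologically sorted.
    """
    qdf = pd.read_csv(pedigree_file, dtype=str)
    gdf = pd.read_csv(sire_group_file, dtype=str)
    for col in ("id", "dam_id", "sire_group_id"):
        if col not in qdf.columns:
            raise PedigreeError(f"pedigree file lacks required column {col!r}")
    for col in ("group_id", "dpq_ids"):
        if col not in gdf.columns:
            raise PedigreeError(f"sire-group file lacks required column {col!r}")

    queens = []
    for row in qdf.itertuples(index=False):
        year = _clean(getattr(row, "year", None))
        queens.append(
            QueenRecord(
                id=_clean(row.id),
                dam_id=_clean(row.dam_id),
                sire_group_id=_clean(row.sire_group_id),
                year=int(year) if year is not None else None,
            )
        )
    groups = []
    for row in gdf.itertuples(index=False):
        dpqs = tuple(p.strip() for p in str(row.dpq_ids).split(";") if p.strip())
        n_drones = _clean(getattr(row, "n_drones", None))
        groups.append(
            SireGroup(
                id=_clean(row.group_id),
                dpq_ids=dpqs,
                n_drones=int(n_drones) if n_drones is not None else 12,
                pool_id=_clean(getattr(row, "pool_id", None)),
            )
        )
    return Pedigree(queens, groups)
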