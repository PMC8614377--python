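"""Numerator relationship matrices under haplodiploid inheritance.

The additive relationship between two honeybee queens is ``a_ij = 2 phi_ij``
where ``phi`` is the kinship (coancestry): the probability that two alleles,
one sampled from each individual, are identical by descent.  The diagonal is
``1 + F`` with ``F`` the inbreeding coefficient.

Haplodiploidy and group mating change the classical tabular method in two
ways:

* A drone is haploid and genetically identical to a single gamete of his
  mother, so a "sire" contributes no paternal grandsire path.
* The paternal parent of a queen is a *sire group* of D drones drawn from m
  drone-producing queens (DPQs).  Two super-sisters may share the very same
  father drone (probability 1/D), which inflates their paternal co-kinship;
  two queens mated to different groups of the same pool can share drone
  mothers but never a drone.

Both effects enter through the kinship of a sire group with itself::

    phi(S, S) = 1/D + (1 - 1/D) * mean_{k,l} phi*(M_k, M_l)

where ``phi*`` is the tabular kinship with self-kinship ``(1 + F)/2`` on the
diagonal, and through the generic rule ``phi(S, x) = mean_k phi(M_k, x)`` for
any other entity ``x``.  A queen's inbreeding is the kinship of her dam with
her sire group, ``F_i = phi(dam_i, S_i)``.

Everything is computed by a dense O(n^2) single pass over the pedigree in
topological order — adequate for populations of a few thousand — and can be
cross-checked against :func:`gene_dropping`, a Monte-Carlo IBD oracle that
simulates allele transmission directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree, PedigreeError

__all__ = [
    "RelationshipMatrix",
    "compute_kinship",
    "gene_dropping",
    "phenotyped_submatrix",
]


@dataclass
class RelationshipMatrix:
    """Symmetric additive relationship matrix over an ordered set of queens."""

    ids: list[str]
    values: np.ndarray  # (n, n), a_ij = 2*kinship, diagonal 1 + F
    inbreeding: np.ndarray  # (n,), F per queen

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.inbreeding = np.asarray(self.inbreeding, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape does not match ids")
        if self.inbreeding.shape != (n,):
            raise ValueError("inbreeding vector length does not match ids")

    @property
    def index(self) -> dict[str, int]:
        return {qid: i for i, qid in enumerate(self.ids)}

    def submatrix(self, ids: Sequence[str]) -> "RelationshipMatrix":
        return phenotyped_submatrix(self, ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_long_frame(self) -> pd.DataFrame:
        """Long format (i, j, a_ij) over the upper triangle including diagonal."""
        rows = []
        for i, qi in enumerate(self.ids):
            for j in range(i, len(self.ids)):
                rows.append({"i": qi, "j": self.ids[j], "a_ij": self.values[i, j]})
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path, long_format: bool = False) -> None:
        if long_format:
            self.to_long_frame().to_csv(path, index=False)
        else:
            self.to_frame().to_csv(path, index_label="id")

    @classmethod
    def read_csv(cls, path: str | Path) -> "RelationshipMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        values = df.to_numpy(dtype=float)
        return cls(list(df.index), values, np.diag(values) - 1.0)


def compute_kinship(ped: Pedigree) -> RelationshipMatrix:
    """Exact numerator relationship matrix by the tabular pass described above.

    Deterministic; queens appear in the pedigree's topological order, so the
    result is independent of input row order.  Sire groups take part in the
    recursion but are excluded from the output (only queens carry phenotypes).
    """
    n_q = len(ped.queens)
    n_g = len(ped.sire_groups)
    n = n_q + n_g
    phi = np.zeros((n, n))
    pos: dict[str, int] = {}
    cursor = 0

    def add_group(gid: str) -> int:
        nonlocal cursor
        g = ped.sire_groups[gid]
        idx = cursor
        cursor += 1
        mrows = [pos[m] for m in g.dpq_ids]
        row = phi[mrows, :idx].mean(axis=0)
        phi[idx, :idx] = row
        phi[:idx, idx] = row
        # mean co-kinship of two *distinct* drones, then add the 1/D
        # same-drone mass
        psi = phi[idx, mrows].mean()
        phi[idx, idx] = 1.0 / g.n_drones + (1.0 - 1.0 / g.n_drones) * psi
        pos[gid] = idx
        return idx

    for qid in ped.queen_order:
        q = ped.queens[qid]
        if not q.is_founder and q.sire_group_id not in pos:
            add_group(q.sire_group_id)
        idx = cursor
        cursor += 1
        if q.is_founder:
            phi[idx, idx] = 0.5
        else:
            d = pos[q.dam_id]
            s = pos[q.sire_group_id]
            row = 0.5 * (phi[d, :idx] + phi[s, :idx])
            phi[idx, :idx] = row
            phi[:idx, idx] = row
            f = phi[d, s]
            phi[idx, idx] = 0.5 * (1.0 + f)
        pos[qid] = idx

    qrows = np.array([pos[qid] for qid in ped.queen_order])
    a = 2.0 * phi[np.ix_(qrows, qrows)]
    inbreeding = np.diag(a) - 1.0
    return RelationshipMatrix(list(ped.queen_order), a, inbreeding)


def gene_dropping(ped: Pedigree, n_reps: int, seed: int) -> RelationshipMatrix:
    """Monte-Carlo estimate of the relationship matrix by allele transmission.

    Founder queens carry two unique alleles.  Each sire group is realised as D
    actual drones, each carrying one random allele of a DPQ mother drawn
    uniformly from the group; every daughter of the mating receives one random
    allele from her dam and the whole (haploid) genome of one drone drawn
    uniformly from the group — so super-sisters can share a father drone.
    Kinship is estimated as the probability that two alleles, one drawn from
    each individual, are IBD; the per-replicate probability is averaged
    exactly over the four allele pairings to reduce Monte-Carlo noise.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    R = n_reps
    alleles: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    group_drones: dict[str, np.ndarray] = {}
    next_label = 0

    for qid in ped.queen_order:
        q = ped.queens[qid]
        if q.is_founder:
            a1 = np.full(R, next_label, dtype=np.int32)
            a2 = np.full(R, next_label + 1, dtype=np.int32)
            next_label += 2
        else:
            gid = q.sire_group_id
            if gid not in group_drones:
                g = ped.sire_groups[gid]
                stacked = np.stack(
                    [np.stack(alleles[m]) for m in g.dpq_ids]
                )  # (m, 2, R)
                m_idx = rng.integers(len(g.dpq_ids), size=(g.n_drones, R))
                coin = rng.integers(2, size=(g.n_drones, R))
                group_drones[gid] = stacked[m_idx, coin, np.arange(R)[None, :]]
            dam1, dam2 = alleles[q.dam_id]
            a1 = np.where(rng.integers(2, size=R) == 0, dam1, dam2)
            drones = group_drones[gid]
            a2 = drones[rng.integers(drones.shape[0], size=R), np.arange(R)]
        alleles[qid] = (a1, a2)

    ids = list(ped.queen_order)
    n = len(ids)
    a = np.empty((n, n))
    for i, qi in enumerate(ids):
        x1, x2 = alleles[qi]
        a[i, i] = 1.0 + np.mean(x1 == x2)
        for j in range(i + 1, n):
            y1, y2 = alleles[ids[j]]
            ibd = (
                (x1 == y1).sum(dtype=np.int64)
                + (x1 == y2).sum(dtype=np.int64)
                + (x2 == y1).sum(dtype=np.int64)
                + (x2 == y2).sum(dtype=np.int64)
            )
            a[i, j] = a[j, i] = 0.5 * ibd / R
    return RelationshipMatrix(ids, a, np.diag(a) - 1.0)


def phenotyped_submatrix(A: RelationshipMatrix, ids: Sequence[str]) -> RelationshipMatrix:
    """Principal submatrix of ``A`` in the requested id order.

    A principal submatrix of a covariance matrix is a valid covariance
    matrix, so this is the right restriction when only a subset of queens is
    phenotyped.
    """
    index = A.index
    missing = [q for q in ids if q not in index]
    if missing:
        raise KeyError(f"ids not in relationship matrix: {missing}")
    sel = np.array([index[q] for q in ids], dtype=int)
    return RelationshipMatrix(
        list(ids), A.values[np.ix_(sel, sel)], A.inbreeding[sel]
    )
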