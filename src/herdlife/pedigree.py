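"""Numerator relationship matrix utilities for the animal model.

The additive-genetic covariance among animals is proportional to the
numerator relationship matrix A built from the pedigree.  Mixed-model
equations need A^-1, which is assembled directly from pedigree recursion
(Henderson's rules, with inbreeding from the Meuwissen-Luo algorithm) in
sparse triplet form — never by dense inversion.  Unknown parents are
treated as unrelated, non-inbred founders; no unknown-parent groups.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "PedigreeError",
    "PedigreeTable",
    "relationship_matrix",
    "a_inverse",
    "inbreeding",
    "mendelian_variance",
]

UNKNOWN = 0


class PedigreeError(ValueError):
    pass


@dataclass
class PedigreeTable:
    """Topologically sorted pedigree with integer-coded parents.

    ``data`` has columns animal / sire / dam (original IDs, 0 = unknown) in
    an order where every parent precedes its offspring.  ``sire_idx`` and
    ``dam_idx`` are 0-based positions into the sorted order (-1 = unknown).
    """

    data: pd.DataFrame
    sire_idx: np.ndarray
    dam_idx: np.ndarray

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def animals(self) -> pd.Index:
        return pd.Index(self.data["animal"])

    def index_of(self, animals) -> np.ndarray:
        """Positions of the given animal IDs in the sorted pedigree."""
        pos = pd.Index(self.data["animal"]).get_indexer(pd.Index(animals))
        if np.any(pos < 0):
            missing = pd.Index(animals)[pos < 0]
            raise PedigreeError(f"animals not in pedigree: {list(missing[:5])}")
        return pos

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PedigreeTable":
        """Build from a 3-column (animal, sire, dam) table, any row order.

        Parents that appear only as parents are added as founders.  Raises
        :class:`PedigreeError` on cycles or duplicate animals.
        """
        frame = frame.rename(columns=dict(zip(frame.columns[:3], ["animal", "sire", "dam"])))
        frame = frame[["animal", "sire", "dam"]].copy()
        if frame["animal"].duplicated().any():
            dup = frame.loc[frame["animal"].duplicated(), "animal"].iloc[0]
            raise PedigreeError(f"duplicate animal id: {dup!r}")
        known = set(frame["animal"])
        extra = []
        for col in ("sire", "dam"):
            for p in frame[col]:
                if p != UNKNOWN and p not in known:
                    known.add(p)
                    extra.append(p)
        if extra:
            frame = pd.concat(
                [pd.DataFrame({"animal": extra, "sire": UNKNOWN, "dam": UNKNOWN}), frame],
                ignore_index=True,
            )

        # Kahn topological sort: parents before offspring, stable in input order
        parents = {row.animal: (row.sire, row.dam) for row in frame.itertuples()}
        children: dict = {a: [] for a in parents}
        indeg = {a: 0 for a in parents}
        for a, (s, d) in parents.items():
            for p in (s, d):
                if p != UNKNOWN:
                    children[p].append(a)
                    indeg[a] += 1
        from collections import deque

        queue = deque(a for a in frame["animal"] if indeg[a] == 0)
        order = []
        while queue:
            a = queue.popleft()
            order.append(a)
            for c in children[a]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != len(parents):
            raise PedigreeError("cycle detected: an animal is its own ancestor")

        pos = {a: i for i, a in enumerate(order)}
        sire_idx = np.array(
            [pos[parents[a][0]] if parents[a][0] != UNKNOWN else -1 for a in order], dtype=np.int64
        )
        dam_idx = np.array(
            [pos[parents[a][1]] if parents[a][1] != UNKNOWN else -1 for a in order], dtype=np.int64
        )
        data = pd.DataFrame(
            {
                "animal": order,
                "sire": [parents[a][0] for a in order],
                "dam": [parents[a][1] for a in order],
            }
        )
        return cls(data=data, sire_idx=sire_idx, dam_idx=dam_idx)


def inbreeding(ped: PedigreeTable) -> np.ndarray:
    """Inbreeding coefficients F by the Meuwissen-Luo algorithm.

    For each animal the diagonal A_ii = sum_j L_j^2 d_j is accumulated over
    its ancestors j, where L_j is the expected genome fraction contributed
    and d_j the within-family (Mendelian sampling) variance scale; F = A_ii - 1.
    Founders have F = 0.
    """
    s, d = ped.sire_idx, ped.dam_idx
    n = ped.n
    F = np.zeros(n)
    dvec = np.zeros(n)  # Mendelian sampling variance scale of each animal
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            dvec[i] = 0.5 - 0.25 * (F[si] + F[di])
        elif si >= 0 or di >= 0:
            known = si if si >= 0 else di
            dvec[i] = 0.75 - 0.25 * F[known]
        else:
            dvec[i] = 1.0
        if si < 0 or di < 0:
            F[i] = 0.0  # no common ancestors possible
            continue
        # accumulate A_ii via ancestors of i (process youngest first);
        # sire may equal dam (selfing), so build coefficients incrementally
        L: dict[int, float] = {}
        for p in (si, di):
            L[p] = L.get(p, 0.0) + 0.5
        heap = [-j for j in L]
        heapq.heapify(heap)
        # A_ii = sum over ancestors (incl. i itself) of L^2 d; L_i = 1
        aii = dvec[i]
        while heap:
            j = -heapq.heappop(heap)
            if j not in L:
                continue
            lj = L.pop(j)
            aii += lj * lj * dvec[j]
            for p in (s[j], d[j]):
                if p >= 0:
                    if p in L:
                        L[p] += 0.5 * lj
                    else:
                        L[p] = 0.5 * lj
                        heapq.heappush(heap, -p)
        F[i] = aii - 1.0
    return F


def relationship_matrix(ped: PedigreeTable) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method.

    A_ii = 1 + F_i; A_ij = mean of A with the parents of the younger animal.
    Quadratic in pedigree size — intended for desk-scale pedigrees and as the
    oracle for the sparse inverse.
    """
    n = ped.n
    s, d = ped.sire_idx, ped.dam_idx
    A = np.zeros((n, n))
    for i in range(n):
        si, di = s[i], d[i]
        if i > 0:
            row = np.zeros(i)
            if si >= 0:
                row += 0.5 * A[si, :i]
            if di >= 0:
                row += 0.5 * A[di, :i]
            A[i, :i] = row
            A[:i, i] = row
        aii = 1.0
        if si >= 0 and di >= 0:
            aii += 0.5 * A[si, di]
        A[i, i] = aii
    return A


def mendelian_variance(ped: PedigreeTable) -> np.ndarray:
    """Within-family variance scale d_i (relative to the additive variance)."""
    F = inbreeding(ped)
    s, d = ped.sire_idx, ped.dam_idx
    dvec = np.where(
        (s >= 0) & (d >= 0),
        0.5 - 0.25 * (F[np.maximum(s, 0)] + F[np.maximum(d, 0)]),
        np.where(
            (s >= 0) | (d >= 0),
            0.75 - 0.25 * F[np.maximum(np.maximum(s, d), 0)],
            1.0,
        ),
    )
    return dvec


def a_inverse(ped: PedigreeTable) -> sparse.csc_matrix:
    """Sparse A^-1 assembled by the inbreeding-aware recursive rules.

    For each animal i with parents s, d and Mendelian variance d_i, add
    alpha = 1/d_i to (i,i), -alpha/2 to (i,parent), alpha/4 to each
    (parent,parent) pair.  Also returns log|A| = sum log d_i via the
    ``.logdet_A`` attribute on the returned matrix.
    """
    n = ped.n
    s, d = ped.sire_idx, ped.dam_idx
    dvec = mendelian_variance(ped)
    alpha = 1.0 / dvec
    rows, cols, vals = [], [], []

    rows.append(np.arange(n)); cols.append(np.arange(n)); vals.append(alpha)
    for par in (s, d):
        m = par >= 0
        rows.append(np.arange(n)[m]); cols.append(par[m]); vals.append(-0.5 * alpha[m])
        rows.append(par[m]); cols.append(np.arange(n)[m]); vals.append(-0.5 * alpha[m])
    for pa, pb in ((s, s), (s, d), (d, s), (d, d)):
        m = (pa >= 0) & (pb >= 0)
        rows.append(pa[m]); cols.append(pb[m]); vals.append(0.25 * alpha[m])

    Ainv = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsc()
    Ainv.logdet_A = float(np.sum(np.log(dvec)))  # type: ignore[attr-defined]
    return Ainv
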