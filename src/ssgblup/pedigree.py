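"""Pedigree container and pedigree-based relationship matrices.

Implements the numerator relationship matrix A (tabular method), inbreeding
coefficients (Meuwissen & Luo algorithm), the sparse inverse A^-1 (Henderson's
rules accounting for parental inbreeding), and extraction of the genotyped
submatrix A22.  Unknown parents are treated as unrelated, non-inbred base
animals; there are no genetic groups.

All matrices carry an explicit id order.  Cross-matrix operations align by id,
never by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "Pedigree",
    "RelationshipMatrix",
    "PedigreeError",
    "build_A",
    "inbreeding",
    "A_inverse",
    "subset_A22",
    "mendelian_variances",
]


class PedigreeError(ValueError):
    """Structural problem in a pedigree (duplicate ids, cycles, ...)."""


@dataclass
class Pedigree:
    """Topologically sorted pedigree.

    Parameters
    ----------
    ids:
        Animal identifiers in sorted order (parents precede offspring).
    sire, dam:
        Integer positions of each animal's parents in ``ids``; ``-1`` marks an
        unknown parent.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if not self._index:
            self._index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def positions(self, ids) -> np.ndarray:
        """Positions of ``ids`` in the pedigree order."""
        try:
            return np.array([self._index[a] for a in ids], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"id {exc.args[0]!r} not in pedigree") from None

    @classmethod
    def from_records(cls, records) -> "Pedigree":
        """Build from an iterable of (id, sire, dam) triples.

        Unknown parents are denoted by ``0``, ``"0"``, ``None`` or ``NaN``.
        Input order is irrelevant: the pedigree is topologically re-sorted.
        Parents that appear only as parents are added as founders.
        """
        rows = list(records)
        ids = [r[0] for r in rows]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids)
            dup = dup[dup.duplicated()].iloc[0]
            raise PedigreeError(f"duplicate animal id {dup!r}")

        def norm(p):
            if p is None or (isinstance(p, float) and np.isnan(p)):
                return None
            if p == 0 or p == "0":
                return None
            return p

        parent_of = {r[0]: (norm(r[1]), norm(r[2])) for r in rows}
        known = set(parent_of)
        # implicit founders: parents never listed as animals
        for s, d in list(parent_of.values()):
            for p in (s, d):
                if p is not None and p not in known:
                    parent_of[p] = (None, None)
                    known.add(p)

        # Kahn topological sort
        children: dict = {a: [] for a in parent_of}
        indeg = {a: 0 for a in parent_of}
        for a, (s, d) in parent_of.items():
            for p in {s, d} - {None}:
                children[p].append(a)
                indeg[a] += 1
        queue = [a for a, k in indeg.items() if k == 0]
        order = []
        while queue:
            nxt = []
            for a in queue:
                order.append(a)
                for c in children[a]:
                    indeg[c] -= 1
                    if indeg[c] == 0:
                        nxt.append(c)
            queue = nxt
        if len(order) != len(parent_of):
            cycle = sorted(
                str(a) for a, k in indeg.items() if k > 0
            )
            raise PedigreeError(
                "pedigree contains a cycle involving ids: " + ", ".join(cycle)
            )

        index = {a: i for i, a in enumerate(order)}
        sire = np.array(
            [index[parent_of[a][0]] if parent_of[a][0] is not None else -1 for a in order],
            dtype=np.int64,
        )
        dam = np.array(
            [index[parent_of[a][1]] if parent_of[a][1] is not None else -1 for a in order],
            dtype=np.int64,
        )
        return cls(np.asarray(order, dtype=object), sire, dam, index)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        """Build from a DataFrame with columns id, sire, dam."""
        return cls.from_records(frame[["id", "sire", "dam"]].itertuples(index=False))

    @classmethod
    def read_csv(cls, path) -> "Pedigree":
        return cls.from_frame(pd.read_csv(path, dtype={"id": str, "sire": str, "dam": str}))

    def to_frame(self) -> pd.DataFrame:
        sire = np.where(self.sire >= 0, self.ids[np.maximum(self.sire, 0)], "0")
        dam = np.where(self.dam >= 0, self.ids[np.maximum(self.dam, 0)], "0")
        return pd.DataFrame({"id": self.ids, "sire": sire, "dam": dam})


@dataclass
class RelationshipMatrix:
    """Square symmetric relationship matrix keyed by animal ids.

    ``kind`` tags the matrix family: "A", "A22", "G" or "H".  ``values`` may
    be a dense ndarray or a scipy sparse matrix (used for inverses).
    """

    values: object
    ids: np.ndarray
    kind: str = "A"
    meta: dict = field(default_factory=dict)
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        if not self._index:
            self._index = {a: i for i, a in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return self.values.toarray()
        return np.asarray(self.values)

    def loc(self, i, j) -> float:
        a, b = self._index[i], self._index[j]
        if sp.issparse(self.values):
            return self.values[a, b]
        return self.values[a, b]

    def reorder(self, ids) -> "RelationshipMatrix":
        """Return the matrix restricted/permuted to ``ids`` (id-aligned)."""
        pos = np.array([self._index[a] for a in ids], dtype=np.int64)
        vals = self.dense()[np.ix_(pos, pos)]
        return RelationshipMatrix(vals, np.asarray(ids), kind=self.kind)

    def to_triplets(self) -> pd.DataFrame:
        """Coordinate triplet export (i_id, j_id, value), lower triangle."""
        m = sp.coo_matrix(sp.tril(self.values) if sp.issparse(self.values)
                          else np.tril(self.dense()))
        return pd.DataFrame(
            {"i_id": self.ids[m.row], "j_id": self.ids[m.col], "value": m.data}
        )


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    a(i,j) = 0.5*(a(j,sire_i) + a(j,dam_i)) for j < i, and
    a(i,i) = 1 + 0.5*a(sire_i, dam_i); unknown parents contribute 0.
    """
    n = ped.n
    A = np.zeros((n, n))
    s, d = ped.sire, ped.dam
    for i in range(n):
        row = np.zeros(i)
        if s[i] >= 0:
            row += 0.5 * A[s[i], :i]
        if d[i] >= 0:
            row += 0.5 * A[d[i], :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s[i], d[i]] if s[i] >= 0 and d[i] >= 0 else 0.0)
    return RelationshipMatrix(A, ped.ids, kind="A")


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen & Luo (1992) algorithm.

    F_i = 0.5 * a(sire_i, dam_i); animals with an unknown parent have F = 0.
    Runs in O(n * depth^2) without forming A.
    """
    import heapq

    n = ped.n
    s, d = ped.sire, ped.dam
    F = np.zeros(n)
    # Mendelian sampling variances, filled as we go
    dvec = np.zeros(n)
    for i in range(n):
        if s[i] < 0 and d[i] < 0:
            dvec[i] = 1.0
            continue
        if s[i] < 0 or d[i] < 0:
            p = max(s[i], d[i])
            dvec[i] = 0.75 - 0.25 * F[p]
            continue
        dvec[i] = 0.5 - 0.25 * (F[s[i]] + F[d[i]])
        # diag(A)_i = sum_k L_ik^2 d_k over ancestors k (L_ii = 1), so walk
        # the ancestor graph youngest-first, accumulating the L-row entries.
        coef = {i: 1.0}
        heap = [-i]
        diag = 0.0
        while heap:
            j = -heapq.heappop(heap)
            cj = coef.pop(j, 0.0)
            if cj == 0.0:
                continue  # already merged and processed
            diag += cj * cj * dvec[j]
            for p in (s[j], d[j]):
                if p >= 0:
                    if p not in coef:
                        heapq.heappush(heap, -p)
                        coef[p] = 0.0
                    coef[p] += 0.5 * cj
        F[i] = diag - 1.0
    return F


def mendelian_variances(ped: Pedigree, F: np.ndarray | None = None) -> np.ndarray:
    """Within-family (Mendelian sampling) variance coefficients d_i.

    d_i = 0.5 - 0.25 (F_s + F_d) when both parents are known, 0.75 - 0.25 F_p
    with a single known parent, and 1 for founders.  These are the diagonal of
    D in A = T D T' and drive both A^-1 and log|A| = sum(log d_i).
    """
    if F is None:
        F = inbreeding(ped)
    s, d = ped.sire, ped.dam
    Fs = np.where(s >= 0, F[np.maximum(s, 0)], 0.0)
    Fd = np.where(d >= 0, F[np.maximum(d, 0)], 0.0)
    both = (s >= 0) & (d >= 0)
    one = (s >= 0) ^ (d >= 0)
    out = np.ones(ped.n)
    out[both] = 0.5 - 0.25 * (Fs[both] + Fd[both])
    out[one] = 0.75 - 0.25 * (Fs[one] + Fd[one])
    return out


def A_inverse(ped: Pedigree, F: np.ndarray | None = None) -> RelationshipMatrix:
    """Sparse A^-1 by Henderson's rules with inbreeding.

    Nonzeros appear only among {animal, sire, dam} triples.
    """
    dvec = mendelian_variances(ped, F)
    s, d = ped.sire, ped.dam
    rows, cols, vals = [], [], []
    for i in range(ped.n):
        b = 1.0 / dvec[i]
        parents = [p for p in (s[i], d[i]) if p >= 0]
        rows.append(i); cols.append(i); vals.append(b)
        for p in parents:
            rows += [i, p]; cols += [p, i]; vals += [-0.5 * b, -0.5 * b]
        for p in parents:
            for q in parents:
                rows.append(p); cols.append(q); vals.append(0.25 * b)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(ped.n, ped.n)).tocsc()
    return RelationshipMatrix(Ainv, ped.ids, kind="A")


def subset_A22(A: RelationshipMatrix, genotyped_ids) -> RelationshipMatrix:
    """Principal submatrix of A on the genotyped animals, in the given order."""
    out = A.reorder(genotyped_ids)
    out.kind = "A22"
    return out
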