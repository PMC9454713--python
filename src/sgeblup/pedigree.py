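"""Pedigree handling and numerator relationship matrices.

A :class:`Pedigree` is an ordered table of (animal, sire, dam) triples with
optional breed labels and metadata.  Unknown parents are coded 0.  All matrix
routines require a topologically sorted pedigree (parents before offspring),
which :func:`validate_and_sort` guarantees.

The numerator relationship matrix ``A`` is built by the tabular method;
``A⁻¹`` is assembled directly from Henderson's rules, with Mendelian-sampling
variances adjusted for parental inbreeding computed by the Meuwissen–Luo
algorithm.  ``A22`` (the genotyped-animal block of ``A``) can be extracted
either from the full matrix or by a recursive kinship walk that never forms
``A``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

UNKNOWN = 0

__all__ = [
    "Pedigree",
    "PedigreeError",
    "validate_and_sort",
    "a_matrix",
    "inbreeding",
    "a_inverse",
    "a22",
    "breed_composition",
]


class PedigreeError(ValueError):
    """Raised for structural pedigree defects (cycles, duplicates, orphans)."""


@dataclass
class Pedigree:
    """Topologically ordered pedigree.

    Attributes
    ----------
    df : pandas.DataFrame
        One row per animal, columns ``id``, ``sire``, ``dam`` (0 = unknown)
        plus any metadata (``breed``, ``sex``, ``birth_batch``, ``litter``).
        Parents always precede offspring.
    sire_idx, dam_idx : ndarray of int
        0-based positional parent indices, -1 for unknown.
    """

    df: pd.DataFrame
    sire_idx: np.ndarray = field(repr=False, default=None)
    dam_idx: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.sire_idx is None:
            pos = {a: i for i, a in enumerate(self.df["id"].to_numpy())}
            self.sire_idx = np.array(
                [pos.get(s, -1) for s in self.df["sire"]], dtype=np.int64
            )
            self.dam_idx = np.array(
                [pos.get(d, -1) for d in self.df["dam"]], dtype=np.int64
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> np.ndarray:
        return self.df["id"].to_numpy()

    def index_of(self, animal_ids) -> np.ndarray:
        """Positional indices of ``animal_ids`` in pedigree order."""
        pos = {a: i for i, a in enumerate(self.ids)}
        try:
            return np.array([pos[a] for a in animal_ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message path
            raise PedigreeError(f"unknown animal id {exc.args[0]!r}") from exc

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        df = pd.read_csv(path)
        return validate_and_sort(df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def validate_and_sort(records) -> Pedigree:
    """Validate raw pedigree records and return a topologically sorted Pedigree.

    Unknown parents (NaN or 0) are normalised to 0.  Raises
    :class:`PedigreeError` on duplicate ids, parents missing from the id
    column, or ancestry cycles (the error names the offending animals).
    """
    df = records.df.copy() if isinstance(records, Pedigree) else pd.DataFrame(records).copy()
    for col in ("id", "sire", "dam"):
        if col not in df.columns:
            raise PedigreeError(f"pedigree is missing required column {col!r}")
    df["sire"] = df["sire"].fillna(UNKNOWN)
    df["dam"] = df["dam"].fillna(UNKNOWN)

    ids = df["id"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        dup = pd.Series(ids).value_counts()
        dup = dup[dup > 1].index.tolist()
        raise PedigreeError(f"duplicate animal ids: {dup}")
    known = set(ids)
    for col in ("sire", "dam"):
        bad = [p for p in df[col] if p != UNKNOWN and p not in known]
        if bad:
            raise PedigreeError(f"{col} ids absent from pedigree: {sorted(set(bad))[:10]}")

    # Kahn topological sort over parent -> offspring edges.
    pos = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    indeg = np.zeros(n, dtype=np.int64)
    children: list[list[int]] = [[] for _ in range(n)]
    for i, (s, d) in enumerate(zip(df["sire"], df["dam"])):
        for p in (s, d):
            if p != UNKNOWN:
                children[pos[p]].append(i)
                indeg[i] += 1
    order: list[int] = []
    stack = [i for i in range(n) if indeg[i] == 0]
    while stack:
        i = stack.pop()
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                stack.append(c)
    if len(order) != n:
        cyc = sorted(ids[i] for i in range(n) if indeg[i] > 0)
        raise PedigreeError(
            "ancestry cycle involving animals {" + ", ".join(map(str, cyc)) + "}"
        )
    # Generation depth (computed in topological order) is the primary sort key;
    # the original row order breaks ties, so an already-sorted pedigree is stable.
    depth = np.zeros(n, dtype=np.int64)
    sire_p = [pos.get(p, -1) if p != UNKNOWN else -1 for p in df["sire"]]
    dam_p = [pos.get(p, -1) if p != UNKNOWN else -1 for p in df["dam"]]
    for i in order:
        for p in (sire_p[i], dam_p[i]):
            if p >= 0:
                depth[i] = max(depth[i], depth[p] + 1)
    order_arr = np.array(sorted(range(n), key=lambda i: (depth[i], i)), dtype=np.int64)
    out = df.iloc[order_arr].reset_index(drop=True)
    return Pedigree(out)


def a_matrix(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method.

    ``a_ii = 1 + F_i`` where ``F_i`` is the inbreeding coefficient; off-diagonals
    follow the recursion ``a_ij = 0.5 (a_{j,s(i)} + a_{j,d(i)})`` for j < i.
    """
    n = len(ped)
    A = np.zeros((n, n))
    s, d = ped.sire_idx, ped.dam_idx
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            A[i, i] = 1.0 + 0.5 * A[si, di]
        else:
            A[i, i] = 1.0
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * A[si, :i]
        if di >= 0:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
    return A


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen & Luo (1992) algorithm.

    Runs in O(n * pedigree depth) without forming A.
    """
    n = len(ped)
    s, d = ped.sire_idx, ped.dam_idx
    F = np.zeros(n)
    # L holds the path coefficients of the animal currently processed.
    point = np.zeros(n, dtype=np.int64)
    L = np.zeros(n)
    D = np.zeros(n)
    for i in range(n):
        si, di = s[i], d[i]
        # Mendelian sampling variance of i given parental inbreeding.
        fs = F[si] if si >= 0 else -1.0
        fd = F[di] if di >= 0 else -1.0
        D[i] = 0.5 - 0.25 * (fs + fd)
        if si < 0 or di < 0:
            F[i] = 0.0
            continue
        fi = -1.0
        L[i] = 1.0
        j = i
        # Walk ancestors in descending index order, accumulating L_j^2 D_j.
        anc = [i]
        visited = {i}
        while anc:
            anc.sort()
            j = anc.pop()  # largest index
            lj = L[j]
            sj, dj = s[j], d[j]
            if sj >= 0:
                L[sj] += 0.5 * lj
                if sj not in visited:
                    anc.append(sj)
                    visited.add(sj)
            if dj >= 0:
                L[dj] += 0.5 * lj
                if dj not in visited:
                    anc.append(dj)
                    visited.add(dj)
            fi += lj * lj * D[j]
            L[j] = 0.0
        F[i] = fi
    return F


def a_inverse(ped: Pedigree, use_inbreeding: bool = True) -> sparse.csr_matrix:
    """Sparse inverse of the numerator relationship matrix (Henderson's rules).

    With ``use_inbreeding`` the Mendelian-sampling variances use parental
    inbreeding from :func:`inbreeding`; otherwise parents are treated as
    non-inbred (classic simple rules).
    """
    n = len(ped)
    s, d = ped.sire_idx, ped.dam_idx
    F = inbreeding(ped) if use_inbreeding else np.zeros(n)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        si, di = s[i], d[i]
        fs = F[si] if si >= 0 else 0.0
        fd = F[di] if di >= 0 else 0.0
        if si >= 0 and di >= 0:
            dm = 0.5 - 0.25 * (fs + fd)
        elif si >= 0 or di >= 0:
            fp = fs if si >= 0 else fd
            dm = 0.75 - 0.25 * fp
        else:
            dm = 1.0
        b = 1.0 / dm
        add(i, i, b)
        for p in (si, di):
            if p >= 0:
                add(i, p, -0.5 * b)
                add(p, i, -0.5 * b)
        if si >= 0 and di >= 0:
            add(si, si, 0.25 * b)
            add(di, di, 0.25 * b)
            add(si, di, 0.25 * b)
            add(di, si, 0.25 * b)
        elif si >= 0:
            add(si, si, 0.25 * b)
        elif di >= 0:
            add(di, di, 0.25 * b)
    out = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    out.sum_duplicates()
    return out


def a22(ped: Pedigree, genotyped_ids, method: str = "auto") -> np.ndarray:
    """Relationship matrix among the genotyped subset.

    ``method='dense'`` extracts from the full tabular A; ``'recursive'``
    computes pairwise relationships by the kinship recursion with memoisation
    and never forms A.  ``'auto'`` picks dense for small pedigrees.
    """
    idx = ped.index_of(genotyped_ids)
    if method == "auto":
        method = "dense" if len(ped) <= 2000 else "recursive"
    if method == "dense":
        return a_matrix(ped)[np.ix_(idx, idx)]

    s, dd = ped.sire_idx, ped.dam_idx
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def rel(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        if i == j:
            si, di = s[i], dd[i]
            return 1.0 + 0.5 * rel(si, di) if (si >= 0 and di >= 0) else 1.0
        if i < j:
            i, j = j, i  # recurse on the younger animal's parents
        return 0.5 * (rel(s[i], j) + rel(dd[i], j))

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * len(ped) + 1000))
    try:
        m = len(idx)
        out = np.empty((m, m))
        for a in range(m):
            for b in range(a, m):
                out[a, b] = out[b, a] = rel(int(idx[a]), int(idx[b]))
    finally:
        sys.setrecursionlimit(old)
    return out


def breed_composition(ped: Pedigree, founder_breed_map: dict | None = None) -> pd.DataFrame:
    """Expected breed fractions per animal by pedigree recursion.

    Founders carry an indicator for their own breed; every other animal is
    half its sire plus half its dam.  Fractions sum to one for every animal.
    When ``founder_breed_map`` is None the pedigree's ``breed`` column labels
    the founders.
    """
    n = len(ped)
    s, d = ped.sire_idx, ped.dam_idx
    if founder_breed_map is None:
        if "breed" not in ped.df.columns:
            raise PedigreeError("no founder_breed_map given and no 'breed' column")
        founder_breed_map = {
            a: b
            for a, b, si, di in zip(ped.ids, ped.df["breed"], s, d)
            if si < 0 and di < 0
        }
    breeds = sorted({str(b) for b in founder_breed_map.values()})
    bpos = {b: k for k, b in enumerate(breeds)}
    frac = np.zeros((n, len(breeds)))
    for i in range(n):
        if s[i] < 0 and d[i] < 0:
            a = ped.ids[i]
            if a not in founder_breed_map:
                raise PedigreeError(f"founder {a!r} has no breed label")
            frac[i, bpos[str(founder_breed_map[a])]] = 1.0
        else:
            if s[i] < 0 or d[i] < 0:
                # unknown parent treated as an unlabeled base animal is not
                # allowed here: composition would not sum to 1
                raise PedigreeError(
                    f"animal {ped.ids[i]!r} has one unknown parent; breed "
                    "composition requires both parents or none"
                )
            frac[i] = 0.5 * frac[s[i]] + 0.5 * frac[d[i]]
    out = pd.DataFrame(frac, columns=breeds)
    out.insert(0, "id", ped.ids)
    return out
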