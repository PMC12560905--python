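"""Pedigree handling and the numerator relationship matrix.

A pedigree is an ordered list of (animal, sire, dam) triples; the additive
(numerator) relationship matrix A it induces has ``A_ii = 1 + F_i`` (F the
inbreeding coefficient) and off-diagonals equal to twice the kinship.  The
animal model places ``a ~ N(0, A sigma_a^2)`` on breeding values, so the
sparse inverse of A (Henderson's rules with inbreeding) is the quantity the
mixed-model equations actually consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

UNKNOWN = ""

#: strings interpreted as "parent unknown" in pedigree files
_MISSING_TOKENS = {"", "0", "na", "nan", "none", ".", "-"}

# guard: dense A is quadratic in pedigree size
_DENSE_A_LIMIT = 2000


class PedigreeError(ValueError):
    """Raised for structural pedigree problems (cycles, duplicates, ...)."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One animal with its (possibly unknown) parents."""

    animal: str
    sire: str = UNKNOWN
    dam: str = UNKNOWN
    sex: str = "unknown"          # "F", "M" or "unknown"
    birth_year: int | None = None

    def __post_init__(self) -> None:
        if not self.animal:
            raise PedigreeError("animal identifier must be non-empty")
        if self.animal == self.sire or self.animal == self.dam:
            raise PedigreeError(f"animal {self.animal!r} is its own parent")


class Pedigree:
    """Topologically ordered pedigree (parents precede offspring).

    Use :func:`read_pedigree` or :meth:`from_records` to construct; both
    perform a Kahn topological sort with ties broken by input order, append
    parents that are referenced but have no row of their own as founders,
    and reject cycles and duplicate rows.
    """

    def __init__(self, records: Sequence[PedigreeRecord]):
        self.records: list[PedigreeRecord] = list(records)
        self.index: dict[str, int] = {r.animal: i for i, r in enumerate(self.records)}
        if len(self.index) != len(self.records):
            raise PedigreeError("duplicate animal identifiers")
        for i, r in enumerate(self.records):
            for parent in (r.sire, r.dam):
                if parent and self.index.get(parent, len(self.records)) >= i:
                    raise PedigreeError(
                        f"pedigree not topologically sorted at {r.animal!r}"
                    )

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(cls, records: Sequence[PedigreeRecord]) -> "Pedigree":
        return cls(_toposort(records))

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, animal: str) -> bool:
        return animal in self.index

    @property
    def ids(self) -> list[str]:
        return [r.animal for r in self.records]

    def parent_indices(self) -> np.ndarray:
        """(n, 2) array of sire/dam positions; -1 where unknown."""
        out = np.full((len(self.records), 2), -1, dtype=np.int64)
        for i, r in enumerate(self.records):
            if r.sire:
                out[i, 0] = self.index[r.sire]
            if r.dam:
                out[i, 1] = self.index[r.dam]
        return out

    def founders(self) -> list[str]:
        return [r.animal for r in self.records if not r.sire and not r.dam]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal": [r.animal for r in self.records],
                "sire": [r.sire for r in self.records],
                "dam": [r.dam for r in self.records],
                "sex": [r.sex for r in self.records],
                "birth_year": [r.birth_year for r in self.records],
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _clean_id(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return UNKNOWN
    s = str(value).strip()
    if s.lower() in _MISSING_TOKENS:
        return UNKNOWN
    return s


def _toposort(records: Sequence[PedigreeRecord]) -> list[PedigreeRecord]:
    """Kahn topological sort, deterministic tie-break by input order.

    Parents referenced without a row of their own are appended as founders
    (in first-reference order, ahead of their offspring).
    """
    seen: dict[str, PedigreeRecord] = {}
    for r in records:
        if r.animal in seen:
            raise PedigreeError(f"duplicate rows for animal(s): {r.animal!r}")
        seen[r.animal] = r
    # implicit founders for referenced-only parents
    for r in list(seen.values()):
        for parent, sex in ((r.sire, "M"), (r.dam, "F")):
            if parent and parent not in seen:
                seen[parent] = PedigreeRecord(parent, sex=sex)

    order_in = {a: i for i, a in enumerate(seen)}
    children: dict[str, list[str]] = {a: [] for a in seen}
    n_parents: dict[str, int] = {a: 0 for a in seen}
    for r in seen.values():
        for parent in (r.sire, r.dam):
            if parent:
                children[parent].append(r.animal)
                n_parents[r.animal] += 1

    ready = sorted((a for a, k in n_parents.items() if k == 0), key=order_in.get)
    out: list[PedigreeRecord] = []
    import heapq

    heap = [(order_in[a], a) for a in ready]
    heapq.heapify(heap)
    while heap:
        _, a = heapq.heappop(heap)
        out.append(seen[a])
        for c in children[a]:
            n_parents[c] -= 1
            if n_parents[c] == 0:
                heapq.heappush(heap, (order_in[c], c))
    if len(out) != len(seen):
        cycle = sorted(a for a, k in n_parents.items() if k > 0)
        raise PedigreeError(f"pedigree contains a cycle involving: {', '.join(cycle)}")
    return out


def read_pedigree(path, dialect: Mapping[str, str] | None = None) -> Pedigree:
    """Read a pedigree CSV with columns ``animal,sire,dam[,sex,birth_year]``.

    Empty strings, ``0``, ``NA`` and similar tokens mark unknown parents.
    ``dialect`` maps the canonical column names to the file's actual headers,
    e.g. ``{"animal": "id", "sire": "father"}``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = {k: k for k in ("animal", "sire", "dam", "sex", "birth_year")}
    if dialect:
        cols.update(dialect)
    if cols["animal"] not in df.columns:
        raise PedigreeError(f"missing animal column {cols['animal']!r}")
    records = []
    for _, row in df.iterrows():
        by = row.get(cols["birth_year"], "")
        records.append(
            PedigreeRecord(
                animal=_clean_id(row[cols["animal"]]),
                sire=_clean_id(row.get(cols["sire"], "")),
                dam=_clean_id(row.get(cols["dam"], "")),
                sex=str(row.get(cols["sex"], "unknown")).strip() or "unknown",
                birth_year=int(by) if str(by).strip().isdigit() else None,
            )
        )
    return Pedigree.from_records(records)


# -- relationship matrix ---------------------------------------------------


@dataclass
class RelationshipMatrix:
    """Dense numerator relationship matrix with its row/column identifiers."""

    values: np.ndarray
    ids: list[str] = field(default_factory=list)

    def loc(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    ``A_ii = 1 + 0.5 A_sd``; ``A_ij = 0.5 (A_js + A_jd)`` for j earlier in
    the pedigree; unknown parents contribute 0.  Dense, so guarded to
    pedigrees of at most 2000 animals — use :func:`build_A_inverse` for the
    sparse inverse at any size.
    """
    n = len(ped)
    if n > _DENSE_A_LIMIT:
        raise PedigreeError(
            f"dense A limited to {_DENSE_A_LIMIT} animals (got {n}); "
            "use build_A_inverse for large pedigrees"
        )
    par = ped.parent_indices()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = par[i]
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
        if i == 0:
            continue
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[:i, s]
        if d >= 0:
            row += 0.5 * A[:i, d]
        A[:i, i] = row
        A[i, :i] = row
    return RelationshipMatrix(A, ped.ids)


def inbreeding(ped: Pedigree) -> dict[str, float]:
    """Inbreeding coefficients ``F_i = A_ii - 1`` (Meuwissen & Luo algorithm).

    Linear memory: never forms A, so it scales to large pedigrees.
    """
    n = len(ped)
    par = ped.parent_indices()
    F = np.zeros(n)
    for i in range(n):
        s, d = par[i]
        if s < 0 and d < 0:
            continue  # founder, F = 0
        # A_ii = sum_j L_j^2 D_j over ancestors j, with L the vector of
        # expected gene contributions of j to i and D_j the within-family
        # (Mendelian-sampling) variance of j.
        L = np.zeros(i + 1)
        L[i] = 1.0
        a_ii = 0.0
        for j in range(i, -1, -1):
            Lj = L[j]
            if Lj == 0.0:
                continue
            sj, dj = par[j]
            Dj = 0.5 - 0.25 * (
                (F[sj] if sj >= 0 else -1.0) + (F[dj] if dj >= 0 else -1.0)
            )
            a_ii += Lj * Lj * Dj
            if sj >= 0:
                L[sj] += 0.5 * Lj
            if dj >= 0:
                L[dj] += 0.5 * Lj
        F[i] = a_ii - 1.0
    return {ped.records[i].animal: float(F[i]) for i in range(n)}


def build_A_inverse(ped: Pedigree, f: Mapping[str, float] | None = None) -> sp.csr_matrix:
    """Sparse inverse of A by Henderson's rules, accounting for inbreeding.

    For each animal the Mendelian-sampling variance is
    ``d_i = 0.5 - 0.25 (F_s + F_d)`` with an unknown parent contributing
    ``F = -1`` (i.e. d = 0.75 with one parent known, 1.0 with none).
    """
    n = len(ped)
    if f is None:
        f = inbreeding(ped)
    Fvec = np.array([f[r.animal] for r in ped.records])
    par = ped.parent_indices()
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = par[i]
        Fs = Fvec[s] if s >= 0 else -1.0
        Fd = Fvec[d] if d >= 0 else -1.0
        alpha = 1.0 / (0.5 - 0.25 * (Fs + Fd))
        add(i, i, alpha)
        for p in (s, d):
            if p >= 0:
                add(i, p, -alpha / 2.0)
                add(p, i, -alpha / 2.0)
        for p in (s, d):
            if p >= 0:
                add(p, p, alpha / 4.0)
        if s >= 0 and d >= 0:
            add(s, d, alpha / 4.0)
            add(d, s, alpha / 4.0)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def export_coo(matrix: sp.spmatrix, ids: Sequence[str], path) -> None:
    """Write a sparse symmetric matrix as row-id, col-id, value text."""
    coo = sp.coo_matrix(matrix)
    with open(path, "w") as fh:
        fh.write("row,col,value\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{ids[i]},{ids[j]},{v!r}\n")
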