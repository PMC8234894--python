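"""Pedigree ingestion and numerator-relationship algebra.

The pedigree is the backbone of every animal-model evaluation: it defines
the additive (numerator) relationship matrix A, whose inverse enters the
mixed-model equations, and the inbreeding coefficients F_i = A_ii - 1 that
correct the Mendelian-sampling variances used to build that inverse.

All matrix routines assume a topologically sorted pedigree (every parent
precedes its offspring); :class:`Pedigree` enforces this at construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse

UNKNOWN = -1  # internal index for an unknown parent

__all__ = [
    "Pedigree",
    "RelationshipFactor",
    "RelationshipKind",
    "load_pedigree",
    "inbreeding",
    "numerator_relationship",
    "a_inverse",
    "subset_A22",
    "PedigreeError",
]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (duplicates, cycles...)."""


class RelationshipKind(str, Enum):
    A = "A"
    A_INV = "A_INV"
    A22 = "A22"
    A22_INV = "A22_INV"
    G_RAW = "G_RAW"
    G_TUNED = "G_TUNED"
    G_BLEND = "G_BLEND"
    H_INV = "H_INV"


@dataclass
class RelationshipFactor:
    """A symmetric relationship matrix together with its row/column labels.

    ``matrix`` is dense ``ndarray`` for the genomic kinds and A/A22, and a
    CSR sparse matrix for A_INV / H_INV.  ``ids`` gives the animal id of
    each row/column.
    """

    kind: RelationshipKind
    matrix: object  # np.ndarray or scipy.sparse.csr_matrix
    ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("relationship matrix must be square")
        if len(self.ids) != n:
            raise ValueError("ids length must equal matrix order")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def to_dense(self) -> np.ndarray:
        m = self.matrix
        return m.toarray() if sparse.issparse(m) else np.asarray(m)

    def check_symmetric(self, tol: float = 1e-10) -> None:
        m = self.matrix
        if sparse.issparse(m):
            d = abs(m - m.T)
            err = d.max() if d.nnz else 0.0
        else:
            err = float(np.max(np.abs(m - m.T))) if m.size else 0.0
        if err > tol:
            raise ValueError(f"matrix of kind {self.kind} not symmetric (max dev {err:.2e})")


# ---------------------------------------------------------------------------
# Pedigree container
# ---------------------------------------------------------------------------


class Pedigree:
    """Topologically sorted pedigree with integer parent indices.

    Parameters
    ----------
    frame : DataFrame with columns ``animal, sire, dam, birth_year, sex``
        (string ids; unknown parents as the token given by ``unknown``).
    unknown : token used for an unknown parent (default ``"0"``; empty
        strings and NaN are always treated as unknown too).
    """

    def __init__(self, frame: pd.DataFrame, unknown: str = "0") -> None:
        df = frame.copy()
        for col in ("animal", "sire", "dam"):
            if col not in df.columns:
                raise PedigreeError(f"pedigree is missing required column '{col}'")
            df[col] = df[col].astype(object)
        if "birth_year" not in df.columns:
            df["birth_year"] = 0
        if "sex" not in df.columns:
            df["sex"] = "NA"

        def norm(x):
            if pd.isna(x) or str(x) in ("", unknown):
                return None
            return str(x)

        animals = [str(a) for a in df["animal"]]
        dup = pd.Series(animals)[pd.Series(animals).duplicated()]
        if len(dup):
            raise PedigreeError(f"duplicate animal id(s): {sorted(set(dup))}")
        sires = [norm(s) for s in df["sire"]]
        dams = [norm(d) for d in df["dam"]]

        known = set(animals)
        extra: list[str] = []
        for p in sires + dams:
            if p is not None and p not in known and p not in extra:
                extra.append(p)
        if extra:
            warnings.warn(
                f"{len(extra)} parent(s) absent from pedigree file added as founders: "
                f"{extra[:5]}{'...' if len(extra) > 5 else ''}",
                stacklevel=2,
            )
            animals = extra + animals
            sires = [None] * len(extra) + sires
            dams = [None] * len(extra) + dams
            years = [int(df["birth_year"].min()) - 1] * len(extra) + [
                int(y) for y in df["birth_year"]
            ]
            sexes = ["NA"] * len(extra) + [str(s) for s in df["sex"]]
        else:
            years = [int(y) for y in df["birth_year"]]
            sexes = [str(s) for s in df["sex"]]

        order = self._toposort(animals, sires, dams)
        self.ids: list[str] = [animals[i] for i in order]
        self.id_index: dict[str, int] = {a: i for i, a in enumerate(self.ids)}
        self.sire = np.array(
            [self.id_index[sires[i]] if sires[i] is not None else UNKNOWN for i in order],
            dtype=np.int64,
        )
        self.dam = np.array(
            [self.id_index[dams[i]] if dams[i] is not None else UNKNOWN for i in order],
            dtype=np.int64,
        )
        self.birth_year = np.array([years[i] for i in order], dtype=np.int64)
        self.sex = np.array([sexes[i] for i in order], dtype=object)
        self._inbreeding: np.ndarray | None = None

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _toposort(animals: list[str], sires: list, dams: list) -> list[int]:
        """Stable topological order: (generation depth, input order).

        Kahn-style depth computation; any animal left with unresolved depth
        sits on a cycle, which is reported.
        """
        n = len(animals)
        index = {a: i for i, a in enumerate(animals)}
        par = [
            [index[p] for p in (sires[i], dams[i]) if p is not None] for i in range(n)
        ]
        for i in range(n):
            if i in par[i]:
                raise PedigreeError(f"animal '{animals[i]}' is its own parent")
        children: list[list[int]] = [[] for _ in range(n)]
        npar = np.zeros(n, dtype=np.int64)
        for i in range(n):
            npar[i] = len(par[i])
            for p in par[i]:
                children[p].append(i)
        depth = np.full(n, -1, dtype=np.int64)
        queue = [i for i in range(n) if npar[i] == 0]
        for i in queue:
            depth[i] = 0
        remaining = npar.copy()
        head = 0
        while head < len(queue):
            i = queue[head]
            head += 1
            for c in children[i]:
                remaining[c] -= 1
                if remaining[c] == 0:
                    depth[c] = max(depth[p] for p in par[c]) + 1
                    queue.append(c)
        if len(queue) < n:
            cyc = [animals[i] for i in range(n) if depth[i] < 0]
            raise PedigreeError(f"pedigree contains a cycle involving: {cyc}")
        return sorted(range(n), key=lambda i: (depth[i], i))

    @classmethod
    def from_file(cls, path, unknown: str = "0", columns: dict | None = None) -> "Pedigree":
        """Read a pedigree CSV (columns animal,sire,dam,birth_year,sex).

        ``columns`` maps the canonical names to the file's column names.
        """
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        if columns:
            df = df.rename(columns={v: k for k, v in columns.items()})
        missing = {"animal", "sire", "dam"} - set(df.columns)
        if missing:
            raise PedigreeError(f"pedigree file lacks column(s): {sorted(missing)}")
        if "birth_year" in df.columns:
            df["birth_year"] = pd.to_numeric(df["birth_year"], errors="coerce").fillna(0)
        return cls(df, unknown=unknown)

    # -- basic properties ----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.ids)

    def __len__(self) -> int:
        return self.n

    def is_founder(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    def to_frame(self) -> pd.DataFrame:
        unk = lambda j: "0" if j == UNKNOWN else self.ids[j]  # noqa: E731
        return pd.DataFrame(
            {
                "animal": self.ids,
                "sire": [unk(j) for j in self.sire],
                "dam": [unk(j) for j in self.dam],
                "birth_year": self.birth_year,
                "sex": self.sex,
            }
        )

    # -- relationship algebra ------------------------------------------------

    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients F (Meuwissen–Luo recursion, O(n·depth))."""
        if self._inbreeding is None:
            self._inbreeding = _ml_inbreeding(self.sire, self.dam)
        return self._inbreeding

    def mendelian_sampling_variance(self) -> np.ndarray:
        """Within-family (Mendelian sampling) variances d_i used by A⁻¹."""
        F = self.inbreeding()
        return _msv(self.sire, self.dam, F)

    def relationship_matrix(self, ids: list[str] | None = None) -> RelationshipFactor:
        """Dense numerator relationship matrix A (or the A22 submatrix).

        For a subset, only the ancestor closure of the subset is expanded,
        so a small genotyped group in a large pedigree stays cheap.
        """
        if ids is None:
            sub = np.arange(self.n)
            closure = np.arange(self.n)
        else:
            if len(ids) == 0:
                raise PedigreeError("empty id set for relationship matrix")
            if len(set(ids)) < len(ids):
                raise PedigreeError("duplicate ids in relationship subset")
            try:
                sub = np.array([self.id_index[a] for a in ids], dtype=np.int64)
            except KeyError as e:
                raise PedigreeError(f"id not in pedigree: {e.args[0]}") from None
            closure = self._ancestor_closure(sub)
        A = _tabular_A(self.sire, self.dam, closure)
        pos = {j: k for k, j in enumerate(closure)}
        idx = np.array([pos[j] for j in sub], dtype=np.int64)
        out = A[np.ix_(idx, idx)]
        kind = RelationshipKind.A if ids is None else RelationshipKind.A22
        labels = self.ids if ids is None else list(ids)
        return RelationshipFactor(kind, out, list(labels))

    def _ancestor_closure(self, sub: np.ndarray) -> np.ndarray:
        keep = np.zeros(self.n, dtype=bool)
        stack = list(sub)
        while stack:
            i = stack.pop()
            if keep[i]:
                continue
            keep[i] = True
            for p in (self.sire[i], self.dam[i]):
                if p != UNKNOWN and not keep[p]:
                    stack.append(p)
        return np.flatnonzero(keep)

    def a_inverse(self) -> RelationshipFactor:
        """Sparse A⁻¹ by Henderson's rules with inbreeding correction.

        Each animal contributes at most 9 nonzeros (itself and its two
        parents); the full dense A is never formed.
        """
        d = self.mendelian_sampling_variance()
        rows, cols, vals = _ainv_triplets(self.sire, self.dam, d)
        Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(self.n, self.n)).tocsr()
        return RelationshipFactor(RelationshipKind.A_INV, Ainv, list(self.ids))

    def a22(self, genotyped_ids: list[str]) -> tuple[RelationshipFactor, RelationshipFactor]:
        """A22 for the genotyped subset and its dense inverse."""
        fac = self.relationship_matrix(genotyped_ids)
        A22 = fac.to_dense()
        try:
            c = np.linalg.cholesky(A22)
        except np.linalg.LinAlgError:
            raise PedigreeError(
                "A22 is singular — check for duplicate genotyped animals"
            ) from None
        inv = np.linalg.inv(c.T) @ np.linalg.inv(c)
        inv = 0.5 * (inv + inv.T)
        return fac, RelationshipFactor(RelationshipKind.A22_INV, inv, list(genotyped_ids))


# ---------------------------------------------------------------------------
# numerical kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _ml_inbreeding(sire: np.ndarray, dam: np.ndarray, unknown: int = UNKNOWN) -> np.ndarray:
    """Meuwissen & Luo style recursion: A_ii = Σ_j L_ij² d_j without full A."""
    n = sire.size
    F = np.zeros(n)
    d = np.zeros(n)
    L = np.zeros(n)
    for i in range(n):
        s, m = sire[i], dam[i]
        if s == unknown and m == unknown:
            d[i] = 1.0
        elif s == unknown:
            d[i] = 0.75 - 0.25 * F[m]
        elif m == unknown:
            d[i] = 0.75 - 0.25 * F[s]
        else:
            d[i] = 0.5 - 0.25 * (F[s] + F[m])
        if s == unknown and m == unknown:
            F[i] = 0.0
            continue
        L[: i + 1] = 0.0
        L[i] = 1.0
        aii = 0.0
        for j in range(i, -1, -1):
            lj = L[j]
            if lj == 0.0:
                continue
            sj, mj = sire[j], dam[j]
            if sj != unknown:
                L[sj] += 0.5 * lj
            if mj != unknown:
                L[mj] += 0.5 * lj
            aii += lj * lj * d[j]
        F[i] = aii - 1.0
    return F


@njit(cache=True)
def _msv(sire: np.ndarray, dam: np.ndarray, F: np.ndarray, unknown: int = UNKNOWN) -> np.ndarray:
    n = sire.size
    d = np.empty(n)
    for i in range(n):
        s, m = sire[i], dam[i]
        if s == unknown and m == unknown:
            d[i] = 1.0
        elif s == unknown:
            d[i] = 0.75 - 0.25 * F[m]
        elif m == unknown:
            d[i] = 0.75 - 0.25 * F[s]
        else:
            d[i] = 0.5 - 0.25 * (F[s] + F[m])
    return d


def _tabular_A(sire: np.ndarray, dam: np.ndarray, closure: np.ndarray) -> np.ndarray:
    """Tabular-method A restricted to a closed (ancestor-complete) index set."""
    pos = {int(j): k for k, j in enumerate(closure)}
    m = closure.size
    A = np.zeros((m, m))
    for k, j in enumerate(closure):
        s = pos[int(sire[j])] if sire[j] != UNKNOWN else -1
        d = pos[int(dam[j])] if dam[j] != UNKNOWN else -1
        if k:
            row = np.zeros(k)
            if s >= 0:
                row += 0.5 * A[s, :k]
            if d >= 0:
                row += 0.5 * A[d, :k]
            A[k, :k] = row
            A[:k, k] = row
        A[k, k] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


def _ainv_triplets(sire: np.ndarray, dam: np.ndarray, d: np.ndarray):
    n = sire.size
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        a = 1.0 / d[i]
        add(i, i, a)
        for p in (sire[i], dam[i]):
            if p != UNKNOWN:
                add(i, p, -0.5 * a)
                add(p, i, -0.5 * a)
        for p in (sire[i], dam[i]):
            if p != UNKNOWN:
                for q in (sire[i], dam[i]):
                    if q != UNKNOWN:
                        add(p, q, 0.25 * a)
    return np.array(rows), np.array(cols), np.array(vals)


# ---------------------------------------------------------------------------
# module-level convenience functions
# ---------------------------------------------------------------------------


def load_pedigree(path, unknown: str = "0", columns: dict | None = None) -> Pedigree:
    """Load, validate and topologically sort a pedigree CSV."""
    return Pedigree.from_file(path, unknown=unknown, columns=columns)


def inbreeding(ped: Pedigree) -> np.ndarray:
    return ped.inbreeding()


def numerator_relationship(ped: Pedigree, ids: list[str] | None = None) -> RelationshipFactor:
    return ped.relationship_matrix(ids)


def a_inverse(ped: Pedigree) -> RelationshipFactor:
    return ped.a_inverse()


def subset_A22(ped: Pedigree, genotyped_ids: list[str]):
    return ped.a22(genotyped_ids)
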