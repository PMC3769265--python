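"""Pedigree handling and the numerator relationship matrix.

The additive (numerator) relationship matrix ``A`` encodes expected additive
genetic relationships among animals implied by the pedigree.  The animal model
never needs ``A`` itself, only its sparse inverse, which Henderson's rules
build directly in a single pass over the (topologically sorted) pedigree;
inbreeding enters through the Mendelian-sampling variances computed with the
Meuwissen & Luo recursion.

Identifiers are opaque strings.  The unknown-parent sentinel is the single
token ``"0"`` (an empty field on read is accepted as the same thing).
Internally animals are mapped to dense 0-based indices in topological order;
the mapping is carried on the :class:`Pedigree` object so file identifiers
can always be recovered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

UNKNOWN = "0"

__all__ = [
    "UNKNOWN",
    "Pedigree",
    "PedigreeError",
    "read_pedigree",
    "write_pedigree",
    "validate_pedigree",
    "relationship_matrix",
    "inbreeding_coefficients",
    "a_inverse",
]


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, conflicting parents, ...)."""


@dataclass
class Pedigree:
    """A validated, topologically sorted pedigree.

    Attributes
    ----------
    ids : list of str
        Animal identifiers in topological order (parents before offspring).
    sire, dam : ndarray of int
        Parent indices into ``ids``; ``-1`` marks an unknown parent.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        """Return the pedigree as an ``animal,sire,dam`` data frame."""

        def name(j: int) -> str:
            return self.ids[j] if j >= 0 else UNKNOWN

        return pd.DataFrame(
            {
                "animal": self.ids,
                "sire": [name(j) for j in self.sire],
                "dam": [name(j) for j in self.dam],
            }
        )


def _as_triples(entries) -> list[tuple[str, str, str]]:
    out = []
    for row in entries:
        a, s, d = row
        a = "" if a is None else str(a).strip()
        s = "" if s is None or (isinstance(s, float) and np.isnan(s)) else str(s).strip()
        d = "" if d is None or (isinstance(d, float) and np.isnan(d)) else str(d).strip()
        if not a:
            raise PedigreeError("blank animal identifier in pedigree")
        out.append((a, s or UNKNOWN, d or UNKNOWN))
    return out


def validate_pedigree(entries) -> Pedigree:
    """Validate raw ``(animal, sire, dam)`` triples and sort topologically.

    Parents that only ever appear in the sire/dam columns are materialised as
    founder rows.  Duplicate animal rows with conflicting parent pairs raise;
    exact duplicate rows are rejected too (a pedigree lists each animal once).

    Raises
    ------
    PedigreeError
        On an empty pedigree, duplicate animal rows, or a cycle (an animal
        that is its own ancestor); the message names an animal on the cycle.
    """
    triples = _as_triples(entries)
    if not triples:
        raise PedigreeError("empty pedigree")

    parents: dict[str, tuple[str, str]] = {}
    order_seen: list[str] = []
    for a, s, d in triples:
        if a in parents:
            if parents[a] != (s, d):
                raise PedigreeError(
                    f"animal {a!r} listed with conflicting parent pairs "
                    f"{parents[a]} and {(s, d)}"
                )
            raise PedigreeError(f"duplicate row for animal {a!r}")
        parents[a] = (s, d)
        order_seen.append(a)

    # materialise parents that never appear as animals, as founders
    for a in list(parents):
        for p in parents[a]:
            if p != UNKNOWN and p not in parents:
                parents[p] = (UNKNOWN, UNKNOWN)
                order_seen.append(p)

    # Kahn's algorithm, stable in first-seen order, parent -> child edges
    children: dict[str, list[str]] = {a: [] for a in parents}
    indeg = {a: 0 for a in parents}
    for a, (s, d) in parents.items():
        for p in (s, d):
            if p != UNKNOWN:
                children[p].append(a)
                indeg[a] += 1

    ready = [a for a in order_seen if indeg[a] == 0]
    topo: list[str] = []
    pos = 0
    while pos < len(ready):
        a = ready[pos]
        pos += 1
        topo.append(a)
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                ready.append(c)
    if len(topo) < len(parents):
        stuck = next(a for a in order_seen if indeg[a] > 0)
        raise PedigreeError(f"pedigree contains a cycle involving animal {stuck!r}")

    idx = {a: i for i, a in enumerate(topo)}
    sire = np.array([idx.get(parents[a][0], -1) for a in topo], dtype=np.int64)
    dam = np.array([idx.get(parents[a][1], -1) for a in topo], dtype=np.int64)
    return Pedigree(ids=topo, sire=sire, dam=dam)


def read_pedigree(path) -> Pedigree:
    """Read a delimited ``animal,sire,dam`` file (comma or tab autodetected)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    missing = {"animal", "sire", "dam"} - set(cols)
    if missing:
        raise PedigreeError(f"pedigree file lacks columns: {sorted(missing)}")
    return validate_pedigree(df[["animal", "sire", "dam"]].itertuples(index=False))


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


def relationship_matrix(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method.

    The recursion (animals in topological order, unknown parents contribute
    zero relationship):

    .. math:: a_{ii} = 1 + \\tfrac12 a_{sd}, \\qquad
              a_{ij} = \\tfrac12 (a_{js} + a_{jd}) \\ (j < i)

    Quadratic in the number of animals — this is the small-pedigree oracle
    against which the sparse-inverse path is verified, not the production
    route.
    """
    n = ped.n
    A = np.zeros((n, n))
    s, d = ped.sire, ped.dam
    for i in range(n):
        si, di = s[i], d[i]
        asd = A[si, di] if si >= 0 and di >= 0 else 0.0
        A[i, i] = 1.0 + 0.5 * asd
        for j in range(i):
            aij = 0.0
            if si >= 0:
                aij += 0.5 * A[j, si]
            if di >= 0:
                aij += 0.5 * A[j, di]
            A[i, j] = A[j, i] = aij
    return A


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients by the Meuwissen–Luo algorithm.

    F_i is half the relationship between the parents.  The algorithm builds,
    for one animal at a time, the nonzero row of the Cholesky factor L of A
    over that animal's ancestors, giving ``A_ii = sum_j L_ij^2 * d_j`` in time
    proportional to pedigree depth rather than n^2.
    """
    n = ped.n
    s, d = ped.sire, ped.dam
    F = np.zeros(n)
    # Mendelian sampling variances, filled as we go (topological order)
    D = np.zeros(n)
    for i in range(n):
        si, di = s[i], d[i]
        fs = F[si] if si >= 0 else 0.0
        fd = F[di] if di >= 0 else 0.0
        if si >= 0 and di >= 0:
            D[i] = 0.5 - 0.25 * (fs + fd)
        elif si >= 0 or di >= 0:
            D[i] = 0.75 - 0.25 * (fs + fd)
        else:
            D[i] = 1.0
        if si < 0 or di < 0:
            F[i] = 0.0
            continue
        # accumulate the L-row over ancestors of i, youngest to oldest
        aii = 0.0
        stack = {i: 1.0}
        for j in range(i, -1, -1):
            lij = stack.pop(j, 0.0)
            if lij == 0.0:
                continue
            aii += lij * lij * D[j]
            for p in (s[j], d[j]):
                if p >= 0:
                    stack[p] = stack.get(p, 0.0) + 0.5 * lij
        F[i] = aii - 1.0
    return F


@dataclass
class RelationshipInverse:
    """Sparse symmetric inverse of the numerator relationship matrix."""

    order: int
    matrix: sparse.csr_matrix
    inbreeding: np.ndarray
    ids: list[str]

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()


def a_inverse(ped: Pedigree, with_inbreeding: bool = True) -> RelationshipInverse:
    """Sparse inverse of A by Henderson's rules.

    For each animal ``i`` with parents ``s``, ``d`` add
    ``b*{(i,i):1, (i,s):-1/2, (i,d):-1/2, (s,s):1/4, (s,d):1/4, (d,d):1/4}``
    where ``b`` is the inverse Mendelian-sampling variance: with
    ``with_inbreeding`` false, b = 2, 4/3 or 1 for two, one or no known
    parents; with it true, b = 1/d_i with d_i adjusted by the parents'
    inbreeding coefficients (Meuwissen–Luo).
    """
    n = ped.n
    s, d = ped.sire, ped.dam
    F = inbreeding_coefficients(ped) if with_inbreeding else np.zeros(n)

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)
        if r != c:
            rows.append(c)
            cols.append(r)
            vals.append(v)

    for i in range(n):
        si, di = s[i], d[i]
        fs = F[si] if si >= 0 else 0.0
        fd = F[di] if di >= 0 else 0.0
        if si >= 0 and di >= 0:
            dm = 0.5 - 0.25 * (fs + fd)
        elif si >= 0 or di >= 0:
            dm = 0.75 - 0.25 * (fs + fd)
        else:
            dm = 1.0
        b = 1.0 / dm
        add(i, i, b)
        for p in (si, di):
            if p >= 0:
                add(i, p, -0.5 * b)
                add(p, p, 0.25 * b)
        if si >= 0 and di >= 0:
            # the (s,d)+(d,s) cross terms collapse onto the diagonal on selfing
            add(si, di, 0.5 * b if si == di else 0.25 * b)
    M = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return RelationshipInverse(order=n, matrix=M, inbreeding=F, ids=list(ped.ids))
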