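"""Pedigree handling: reading, sorting, inbreeding, and relationship matrices.

The additive (numerator) relationship matrix ``A`` encodes expected additive
genetic relationships between animals implied by the pedigree; its diagonal is
``1 + F`` where ``F`` is the inbreeding coefficient.  Mixed-model samplers
never need ``A`` itself, only its sparse inverse, which Henderson's rules
assemble directly from per-animal Mendelian-sampling variances.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

UNKNOWN = -1  # internal index for an unknown parent

__all__ = [
    "Pedigree",
    "PedigreeError",
    "read_pedigree",
    "validate_and_sort",
    "inbreeding_coefficients",
    "additive_relationship_matrix",
    "a_inverse",
]


class PedigreeError(ValueError):
    """Raised for malformed or cyclic pedigrees."""


@dataclass
class Pedigree:
    """An ordered pedigree.

    Attributes
    ----------
    ids : list of str
        Animal identifiers in topological order (parents before offspring).
    sire, dam : ndarray of int
        Index of each animal's sire/dam in ``ids``; ``-1`` marks an unknown
        parent.
    f : ndarray of float or None
        Inbreeding coefficients (filled by :func:`inbreeding_coefficients`).
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    f: np.ndarray | None = None
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, animal_id: str) -> int:
        return self._index[animal_id]

    @property
    def n_founders(self) -> int:
        return int(np.sum((self.sire == UNKNOWN) & (self.dam == UNKNOWN)))


def read_pedigree(path, *, missing: str = "0") -> Pedigree:
    """Read a 3-column (animal, sire, dam) delimited text file.

    Comma or whitespace delimited, header optional.  ``missing`` is the
    sentinel token for an unknown parent.  The result is validated and
    topologically sorted; inbreeding coefficients are computed.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    sep = "," if "," in text.splitlines()[0] else r"\s+"
    df = pd.read_csv(io.StringIO(text), sep=sep, header=None, dtype=str,
                     comment="#", skip_blank_lines=True)
    if df.shape[1] < 3:
        raise PedigreeError("pedigree file must have 3 columns: animal, sire, dam")
    df = df.iloc[:, :3]
    # tolerate an optional header line
    first = [str(v).strip().lower() for v in df.iloc[0]]
    if first[0] in ("animal", "id", "kit") or first[1] in ("sire", "father"):
        df = df.iloc[1:]
    animals = df.iloc[:, 0].str.strip().tolist()
    sires = df.iloc[:, 1].str.strip().tolist()
    dams = df.iloc[:, 2].str.strip().tolist()

    seen: set[str] = set()
    for a in animals:
        if a in seen:
            raise PedigreeError(f"duplicate animal id {a!r}")
        seen.add(a)
    for p in sires + dams:
        if p != missing and p not in seen:
            raise PedigreeError(f"parent {p!r} referenced but never defined")

    idx = {a: i for i, a in enumerate(animals)}
    sire = np.array([UNKNOWN if s == missing else idx[s] for s in sires], dtype=np.int64)
    dam = np.array([UNKNOWN if d == missing else idx[d] for d in dams], dtype=np.int64)
    ped = validate_and_sort(Pedigree(animals, sire, dam))
    ped.f = inbreeding_coefficients(ped)
    return ped


def validate_and_sort(ped: Pedigree) -> Pedigree:
    """Topologically sort a pedigree so every parent precedes its offspring.

    Raises :class:`PedigreeError` naming one animal on any ancestry cycle.
    Self-parenting counts as a cycle.
    """
    n = len(ped)
    n_children = np.zeros(n, dtype=np.int64)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for p in (ped.sire[i], ped.dam[i]):
            if p != UNKNOWN:
                children[p].append(i)
                indeg[i] += 1
    order: list[int] = []
    stack = [i for i in range(n) if indeg[i] == 0]
    while stack:
        i = stack.pop()
        order.append(i)
        for ch in children[i]:
            indeg[ch] -= 1
            if indeg[ch] == 0:
                stack.append(ch)
    if len(order) < n:
        bad = next(i for i in range(n) if indeg[i] > 0)
        raise PedigreeError(f"ancestry cycle involving animal {ped.ids[bad]!r}")
    old2new = np.empty(n, dtype=np.int64)
    old2new[np.array(order, dtype=np.int64)] = np.arange(n)

    def remap(parent: np.ndarray) -> np.ndarray:
        out = np.full(n, UNKNOWN, dtype=np.int64)
        for new_i, old_i in enumerate(order):
            p = parent[old_i]
            out[new_i] = UNKNOWN if p == UNKNOWN else old2new[p]
        return out

    new = Pedigree([ped.ids[i] for i in order], remap(ped.sire), remap(ped.dam))
    if ped.f is not None:
        new.f = ped.f[np.array(order)]
    return new


def _mendelian_variances(sire, dam, f):
    """Within-family (Mendelian sampling) variance d_i for each animal.

    Unknown parents are treated as base-population draws, i.e. their F term
    enters as -1 in the classical bookkeeping: both unknown -> d=1, one known
    -> d = 0.75 - 0.25*F_known, both known -> d = 0.5 - 0.25*(F_s + F_d).
    """
    fs = np.where(sire == UNKNOWN, -1.0, f[np.maximum(sire, 0)])
    fd = np.where(dam == UNKNOWN, -1.0, f[np.maximum(dam, 0)])
    return 0.5 - 0.25 * (fs + fd)


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen–Luo recursion.

    Computes diag(A) = 1 + F animal by animal via the generalized Cholesky
    decomposition A = L D L', tracing each animal's ancestor coefficients.
    Founders get F = 0 exactly.
    """
    n = len(ped)
    sire, dam = ped.sire, ped.dam
    f = np.zeros(n)
    d = np.zeros(n)
    coeff = np.zeros(n)
    for i in range(n):
        d[i] = _mendelian_variances(sire[i:i + 1], dam[i:i + 1], f)[0]
        if sire[i] == UNKNOWN or dam[i] == UNKNOWN:
            f[i] = 0.0
            continue
        # a_ii = sum_j L_ij^2 d_j over ancestors j of i (incl. i, L_ii = 1)
        coeff[:i + 1] = 0.0
        coeff[i] = 1.0
        aii = 0.0
        for j in range(i, -1, -1):
            cj = coeff[j]
            if cj == 0.0:
                continue
            aii += cj * cj * d[j]
            if sire[j] != UNKNOWN:
                coeff[sire[j]] += 0.5 * cj
            if dam[j] != UNKNOWN:
                coeff[dam[j]] += 0.5 * cj
        f[i] = aii - 1.0
    return f


def additive_relationship_matrix(ped: Pedigree, *, max_animals: int = 5000) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular recursion.

    Intended for small pedigrees (tests, synthetic truth); raises for more
    than ``max_animals`` animals to guard against accidental O(n^2) blowups.
    """
    n = len(ped)
    if n > max_animals:
        raise PedigreeError(
            f"dense A requested for {n} animals (cap {max_animals}); "
            "use a_inverse for sampling")
    a = np.zeros((n, n))
    s, d = ped.sire, ped.dam
    for i in range(n):
        asd = a[s[i], d[i]] if (s[i] != UNKNOWN and d[i] != UNKNOWN) else 0.0
        a[i, i] = 1.0 + 0.5 * asd
        for j in range(i):
            v = 0.0
            if s[i] != UNKNOWN:
                v += 0.5 * a[j, s[i]]
            if d[i] != UNKNOWN:
                v += 0.5 * a[j, d[i]]
            a[i, j] = a[j, i] = v
    return a


def a_inverse(ped: Pedigree) -> sparse.csr_matrix:
    """Sparse inverse of A by Henderson's rules with inbreeding.

    Each animal contributes 1/d_i to its own diagonal, -1/(2 d_i) to each
    known parent-offspring pair and 1/(4 d_i) to each known parent-parent
    pair, where d_i is the Mendelian-sampling variance.
    """
    f = ped.f if ped.f is not None else inbreeding_coefficients(ped)
    n = len(ped)
    d = _mendelian_variances(ped.sire, ped.dam, f)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(n):
        alpha = 1.0 / d[i]
        parents = [p for p in (ped.sire[i], ped.dam[i]) if p != UNKNOWN]
        rows.append(i); cols.append(i); vals.append(alpha)
        for p in parents:
            rows += [i, p]; cols += [p, i]; vals += [-alpha / 2, -alpha / 2]
        for p in parents:
            for q in parents:
                rows.append(p); cols.append(q); vals.append(alpha / 4)
    m = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n))
    return m.tocsr()
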