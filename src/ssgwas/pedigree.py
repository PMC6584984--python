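"""Pedigree parsing and pedigree-based relationship machinery.

A pedigree is an ordered list of (animal, sire, dam) triples. From it this
module builds the numerator relationship matrix ``A`` (tabular method), the
inbreeding coefficients ``F`` (Meuwissen–Luo ancestor traversal), the sparse
inverse ``A⁻¹`` (Henderson's rules, accounting for inbreeding) and the
genotyped-animal block ``A22``. Everything is sized for desk-scale pedigrees
(up to a few thousand animals): ``A`` is formed densely, ``A⁻¹`` sparsely.

Unknown parents are treated as unrelated, non-inbred founders; no
unknown-parent groups or metafounders are modelled.
"""
from __future__ import annotations

import heapq
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .containers import RelationshipMatrix
from .exceptions import InputError, NumericalError

UNKNOWN = -1


@dataclass(frozen=True)
class Pedigree:
    """Ordered pedigree records; parents are labels or ``None`` for unknown.

    ``order_index`` is implicit: animal ``ids[k]`` has integer index ``k``.
    A pedigree is *sorted* when every known parent's index is strictly
    smaller than its offspring's; matrix construction requires that.
    """

    ids: tuple[str, ...]
    sires: tuple[str | None, ...]
    dams: tuple[str | None, ...]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            seen: set[str] = set()
            for a in self.ids:
                if a in seen:
                    raise InputError(f"duplicate animal ID {a!r} in pedigree")
                seen.add(a)
        for a, s, d in zip(self.ids, self.sires, self.dams):
            if a == s or a == d:
                raise InputError(f"animal {a!r} is listed as its own parent")

    @property
    def n(self) -> int:
        return len(self.ids)

    @cached_property
    def order_index(self) -> dict[str, int]:
        return {a: k for k, a in enumerate(self.ids)}

    def _parent_indices(self, parents: tuple[str | None, ...]) -> np.ndarray:
        idx = np.empty(self.n, dtype=np.intp)
        lookup = self.order_index
        for k, p in enumerate(parents):
            if p is None:
                idx[k] = UNKNOWN
            else:
                try:
                    idx[k] = lookup[p]
                except KeyError:
                    raise InputError(
                        f"parent {p!r} of animal {self.ids[k]!r} has no pedigree record"
                    ) from None
        return idx

    @cached_property
    def sire_index(self) -> np.ndarray:
        """Integer index of each animal's sire (−1 when unknown)."""
        return self._parent_indices(self.sires)

    @cached_property
    def dam_index(self) -> np.ndarray:
        return self._parent_indices(self.dams)

    @cached_property
    def is_sorted(self) -> bool:
        k = np.arange(self.n)
        return bool(
            np.all(self.sire_index < k) and np.all(self.dam_index < k)
        )


def read_pedigree(path: str | Path, unknown_code: str = "0") -> Pedigree:
    """Read a delimited pedigree file (animal, sire, dam in the first 3 columns).

    Comma or whitespace delimited; a header row is skipped when none of its
    first three fields look numeric. ``unknown_code`` marks phantom parents.
    Records are returned in file order; run :func:`sort_pedigree` before
    building matrices if parents may follow their offspring.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise InputError(f"pedigree file {path} is empty")

    def split(line: str) -> list[str]:
        return [t.strip() for t in (line.split(",") if "," in line else line.split())]

    def looks_numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    first = split(lines[0])
    if len(first) < 3:
        raise InputError(f"pedigree line 1 has fewer than 3 columns: {lines[0]!r}")
    start = 0 if any(looks_numeric(t) for t in first[:3]) else 1

    ids: list[str] = []
    sires: list[str | None] = []
    dams: list[str | None] = []
    for ln_no, line in enumerate(lines[start:], start=start + 1):
        toks = split(line)
        if len(toks) < 3:
            raise InputError(f"pedigree line {ln_no} has fewer than 3 columns: {line!r}")
        a, s, d = toks[0], toks[1], toks[2]
        ids.append(a)
        sires.append(None if s == unknown_code else s)
        dams.append(None if d == unknown_code else d)
    return Pedigree(tuple(ids), tuple(sires), tuple(dams))


def sort_pedigree(p: Pedigree) -> Pedigree:
    """Topologically sort so parents precede offspring (stable in input order).

    Raises :class:`InputError` listing one cycle if the pedigree is cyclic.
    """
    n = p.n
    sire, dam = p.sire_index, p.dam_index
    remaining = np.zeros(n, dtype=int)
    children: list[list[int]] = [[] for _ in range(n)]
    for k in range(n):
        for par in (sire[k], dam[k]):
            if par != UNKNOWN:
                remaining[k] += 1
                children[par].append(k)
    # min-heap on original position keeps the sort stable for ties
    ready = [k for k in range(n) if remaining[k] == 0]
    heapq.heapify(ready)
    order: list[int] = []
    while ready:
        k = heapq.heappop(ready)
        order.append(k)
        for c in children[k]:
            remaining[c] -= 1
            if remaining[c] == 0:
                heapq.heappush(ready, c)
    if len(order) < n:
        cycle = _find_cycle(p, remaining)
        raise InputError(
            "pedigree contains a cycle: " + " -> ".join(p.ids[k] for k in cycle)
        )
    return Pedigree(
        tuple(p.ids[k] for k in order),
        tuple(p.sires[k] for k in order),
        tuple(p.dams[k] for k in order),
    )


def _find_cycle(p: Pedigree, remaining: np.ndarray) -> list[int]:
    stuck = [k for k in range(p.n) if remaining[k] > 0]
    # walk parent links among stuck nodes until a node repeats
    seen: dict[int, int] = {}
    path: list[int] = []
    k = stuck[0]
    while k not in seen:
        seen[k] = len(path)
        path.append(k)
        s, d = p.sire_index[k], p.dam_index[k]
        k = s if s in stuck else d
    return path[seen[k]:] + [k]


def _mendelian_variances(p: Pedigree, F: np.ndarray) -> np.ndarray:
    """Within-family (Mendelian sampling) variance d_i for each animal.

    d = ½ − ¼(F_s + F_d) with both parents known; ¾ − ¼F of the known parent
    with one known; 1 with none. Shared by A⁻¹ construction and the
    polygenic simulator.
    """
    sire, dam = p.sire_index, p.dam_index
    d = np.ones(p.n)
    both = (sire != UNKNOWN) & (dam != UNKNOWN)
    d[both] = 0.5 - 0.25 * (F[sire[both]] + F[dam[both]])
    one_s = (sire != UNKNOWN) & (dam == UNKNOWN)
    d[one_s] = 0.75 - 0.25 * F[sire[one_s]]
    one_d = (sire == UNKNOWN) & (dam != UNKNOWN)
    d[one_d] = 0.75 - 0.25 * F[dam[one_d]]
    return d


def inbreeding_coefficients(p: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F by the Meuwissen–Luo ancestor traversal.

    For animal i with both parents known, 1 + F_i = a_ii = Σ_j L_ij² d_j over
    ancestors j, accumulated by walking the generalized Cholesky rows without
    ever forming A. Founders (and animals with an unknown parent) have F = 0.
    Equivalent to diag(build_A) − 1; O(pedigree depth) memory.
    """
    if not p.is_sorted:
        raise InputError("pedigree must be sorted (parents first); run sort_pedigree")
    n = p.n
    sire, dam = p.sire_index, p.dam_index
    F = np.zeros(n)
    d = np.ones(n)
    for i in range(n):
        s, dd = sire[i], dam[i]
        if s == UNKNOWN and dd == UNKNOWN:
            d[i] = 1.0
            continue
        if s == UNKNOWN or dd == UNKNOWN:
            known = dd if s == UNKNOWN else s
            d[i] = 0.75 - 0.25 * F[known]
            continue  # one unknown parent: parents unrelated, F_i = 0
        d[i] = 0.5 - 0.25 * (F[s] + F[dd])
        # a_ii via traversal from i down through ancestors, largest index first
        L: dict[int, float] = {i: 1.0}
        heap = [-i]
        a_ii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            lj = L.pop(j)
            a_ii += lj * lj * d[j]
            for par in (sire[j], dam[j]):
                if par != UNKNOWN:
                    if par not in L:
                        L[par] = 0.0
                        heapq.heappush(heap, -par)
                    L[par] += 0.5 * lj
        F[i] = a_ii - 1.0
    return F


def build_A(p: Pedigree) -> RelationshipMatrix:
    """Dense numerator relationship matrix A by the tabular method.

    a(i,j) = ½(a(j,s_i) + a(j,d_i)) for j < i and a(i,i) = 1 + ½a(s_i,d_i);
    an unknown parent contributes 0.
    """
    if not p.is_sorted:
        raise InputError("pedigree must be sorted (parents first); run sort_pedigree")
    n = p.n
    sire, dam = p.sire_index, p.dam_index
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s != UNKNOWN:
            row += 0.5 * A[s, :i]
        if d != UNKNOWN:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0)
    return RelationshipMatrix(A, p.ids, kind="A")


def build_A_inverse(p: Pedigree, F: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse A⁻¹ by Henderson's rules with inbreeding.

    Per animal i with Mendelian variance d_i and α_i = 1/d_i: add α_i at
    (i,i), −α_i/2 between i and each known parent, and α_i/4 among known
    parents.
    """
    if not p.is_sorted:
        raise InputError("pedigree must be sorted (parents first); run sort_pedigree")
    if F is None:
        F = inbreeding_coefficients(p)
    d = _mendelian_variances(p, np.asarray(F, dtype=float))
    if np.any(d <= 0):
        bad = p.ids[int(np.argmax(d <= 0))]
        raise NumericalError(f"non-positive Mendelian variance for animal {bad!r}")
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    sire, dam = p.sire_index, p.dam_index
    for i in range(p.n):
        alpha = 1.0 / d[i]
        parents = [q for q in (sire[i], dam[i]) if q != UNKNOWN]
        rows.append(i)
        cols.append(i)
        vals.append(alpha)
        for q in parents:
            rows += [i, q]
            cols += [q, i]
            vals += [-alpha / 2.0, -alpha / 2.0]
        for q in parents:
            for r in parents:
                rows.append(q)
                cols.append(r)
                vals.append(alpha / 4.0)
    M = sp.coo_matrix((vals, (rows, cols)), shape=(p.n, p.n))
    return M.tocsr()


def extract_A22(
    p: Pedigree,
    genotyped_ids,
    A: RelationshipMatrix | None = None,
) -> RelationshipMatrix:
    """A restricted to the genotyped animals, in the given order.

    ``A`` may be passed to avoid recomputing it; it must come from the same
    sorted pedigree.
    """
    if A is None:
        A = build_A(p)
    lookup = p.order_index
    idx = []
    for a in genotyped_ids:
        a = str(a)
        if a not in lookup:
            raise InputError(f"genotyped animal {a!r} has no pedigree record")
        idx.append(lookup[a])
    idx = np.asarray(idx, dtype=np.intp)
    vals = A.values[np.ix_(idx, idx)].copy()
    return RelationshipMatrix(vals, tuple(str(a) for a in genotyped_ids), kind="A22")
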