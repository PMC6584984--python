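"""Single-step GBLUP: the combined relationship inverse H⁻¹, Henderson's
mixed model equations, their direct solution, and the prediction-error
(co)variance block of the genotyped animals.

The model is a single-trait animal model

    y = Xβ + Wu + Sp + e,

with u the breeding values of *all* pedigree animals, Var(u) = Hσ_u² where

    H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A22⁻¹]

combines pedigree and genomic information, and an optional extra non-genetic
random effect p (e.g. the permanent environmental effect of the dam),
Var(p) = Iσ_pe². Variance components are supplied by the user and treated as
known.

At desk scale the coefficient matrix is factorized densely and the genotyped
block of its inverse is extracted exactly; this satisfies the same contract
as the supernodal sparse selected-inverse used by production software on
million-animal systems.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

from .containers import RelationshipMatrix
from .exceptions import InputError, NumericalError


@dataclass
class VarianceComponents:
    sigma_u2: float
    sigma_e2: float
    sigma_pe2: float | None = None

    def __post_init__(self) -> None:
        for name in ("sigma_u2", "sigma_e2"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be > 0")
        if self.sigma_pe2 is not None and self.sigma_pe2 <= 0:
            raise InputError("sigma_pe2 must be > 0 when given")

    @property
    def lambda_u(self) -> float:
        return self.sigma_e2 / self.sigma_u2

    @property
    def lambda_pe(self) -> float:
        if self.sigma_pe2 is None:
            raise InputError("no permanent-environment variance was supplied")
        return self.sigma_e2 / self.sigma_pe2


@dataclass
class ModelSpec:
    """Design of one analysis: phenotypes plus incidence matrices.

    ``X`` is the (full-rank) fixed-effect design, ``W`` links records to
    animals in pedigree order, ``extra_random`` (optional) links records to
    the levels of one additional i.i.d. random effect.
    """

    y: np.ndarray
    X: np.ndarray
    W: sp.spmatrix
    animal_ids: tuple[str, ...]
    extra_random: sp.spmatrix | None = None
    record_ids: tuple[str, ...] | None = None
    fixed_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = self.y.size
        if self.X.shape[0] != n:
            raise InputError(f"X has {self.X.shape[0]} rows for {n} records")
        if self.W.shape[0] != n:
            raise InputError(f"W has {self.W.shape[0]} rows for {n} records")
        if self.W.shape[1] != len(self.animal_ids):
            raise InputError("W columns must match animal_ids")
        rows_per_record = np.asarray((self.W != 0).sum(axis=1)).ravel()
        if not np.all(rows_per_record == 1):
            raise InputError("every record must map to exactly one animal")
        if self.extra_random is not None and self.extra_random.shape[0] != n:
            raise InputError("extra_random incidence has wrong row count")


@dataclass
class MMESystem:
    """Assembled mixed model equations (coefficient matrix includes σ_e⁻²,
    so the inverse of ``lhs`` is directly the prediction-error covariance C)."""

    lhs: np.ndarray
    rhs: np.ndarray
    block_index: dict[str, slice]
    geno_index: np.ndarray  # global row/col positions of genotyped animals
    _chol: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def n(self) -> int:
        return self.rhs.size

    def factor(self):
        """Cached Cholesky factorization of the coefficient matrix."""
        if self._chol is None:
            try:
                self._chol = sla.cho_factor(self.lhs, lower=True)
            except np.linalg.LinAlgError:
                raise NumericalError(
                    "mixed model equations are not positive definite; check "
                    "fixed-effect constraints and variance components"
                ) from None
        return self._chol


@dataclass
class Solutions:
    beta_hat: np.ndarray
    u_hat: np.ndarray
    u2_hat: np.ndarray
    extra_hat: np.ndarray | None = None


@dataclass
class PevBlock:
    """C^{u2u2}: prediction error (co)variances Var(u₂ − û₂) of the genotyped
    animals, in trait units squared."""

    values: np.ndarray


def build_H_inverse(
    A_inv: sp.spmatrix,
    A22: RelationshipMatrix,
    G: RelationshipMatrix,
    geno_index: np.ndarray,
) -> sp.csr_matrix:
    """H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A22⁻¹] scattered into pedigree order.

    ``geno_index`` maps the row order of G/A22 onto pedigree positions.
    G and A22 are inverted by dense Cholesky (desk scale).
    """
    geno_index = np.asarray(geno_index, dtype=np.intp)
    if G.ids != A22.ids:
        raise InputError("G and A22 must carry the same animals in the same order")
    if geno_index.size != G.n:
        raise InputError("geno_index length does not match G")
    if geno_index.size == 0:
        return sp.csr_matrix(A_inv)
    try:
        G_inv = _chol_inverse(G.values)
    except np.linalg.LinAlgError:
        raise NumericalError("G is singular; blend with A22 first") from None
    try:
        A22_inv = _chol_inverse(A22.values)
    except np.linalg.LinAlgError:
        raise NumericalError("A22 is singular (invalid pedigree?)") from None
    corr = G_inv - A22_inv
    rows = np.repeat(geno_index, geno_index.size)
    cols = np.tile(geno_index, geno_index.size)
    n = A_inv.shape[0]
    correction = sp.coo_matrix((corr.ravel(), (rows, cols)), shape=(n, n))
    return (sp.csr_matrix(A_inv) + correction.tocsr()).tocsr()


def _chol_inverse(M: np.ndarray) -> np.ndarray:
    c = sla.cho_factor(M, lower=True)
    inv = sla.cho_solve(c, np.eye(M.shape[0]))
    return (inv + inv.T) / 2.0


def assemble_mme(
    model: ModelSpec,
    H_inv: sp.spmatrix,
    vc: VarianceComponents,
    geno_index: np.ndarray | None = None,
) -> MMESystem:
    """Henderson's mixed model equations for the single-step animal model.

    LHS (×σ_e⁻²)::

        [ X′X    X′W          X′S        ]
        [ W′X    W′W + λ_u H⁻¹  W′S      ]
        [ S′X    S′W          S′S + λ_pe I ]

    with λ_u = σ_e²/σ_u², λ_pe = σ_e²/σ_pe². The S block is present only
    when the model carries an extra random effect. ``geno_index`` gives the
    genotyped animals' positions within the animal block.
    """
    X = model.X
    if np.linalg.matrix_rank(X) < X.shape[1]:
        names = model.fixed_names or tuple(f"col{i}" for i in range(X.shape[1]))
        raise InputError(
            "fixed-effect design is rank deficient; confounded columns among: "
            + ", ".join(names)
        )
    W = sp.csr_matrix(model.W)
    n_anim = W.shape[1]
    if H_inv.shape != (n_anim, n_anim):
        raise InputError("H_inv dimension does not match the animal block")
    blocks = [X, W]
    names = ["fixed", "animal"]
    if model.extra_random is not None:
        if vc.sigma_pe2 is None:
            raise InputError("extra random effect given without sigma_pe2")
        blocks.append(sp.csr_matrix(model.extra_random))
        names.append("pe")

    sizes = [b.shape[1] for b in blocks]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    block_index = {nm: slice(int(offsets[k]), int(offsets[k + 1]))
                   for k, nm in enumerate(names)}
    ntot = int(offsets[-1])
    lhs = np.zeros((ntot, ntot))
    rhs = np.zeros(ntot)
    inv_se = 1.0 / vc.sigma_e2
    for i, bi in enumerate(blocks):
        rhs[block_index[names[i]]] = _to_dense(bi.T @ model.y) * inv_se
        for j, bj in enumerate(blocks):
            if j < i:
                continue
            prod = _to_dense(bi.T @ bj) * inv_se
            lhs[block_index[names[i]], block_index[names[j]]] = prod
            if j > i:
                lhs[block_index[names[j]], block_index[names[i]]] = prod.T
    a_sl = block_index["animal"]
    lhs[a_sl, a_sl] += H_inv.toarray() / vc.sigma_u2
    if "pe" in block_index:
        p_sl = block_index["pe"]
        lhs[p_sl, p_sl] += np.eye(sizes[-1]) / vc.sigma_pe2
    geno = np.asarray([] if geno_index is None else geno_index, dtype=np.intp)
    return MMESystem(lhs, rhs, block_index, geno + a_sl.start)


def _to_dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x)


def solve_mme(sys: MMESystem) -> Solutions:
    """Exact direct solution of the mixed model equations (dense Cholesky)."""
    sol = sla.cho_solve(sys.factor(), sys.rhs)
    b_sl, a_sl = sys.block_index["fixed"], sys.block_index["animal"]
    extra = sol[sys.block_index["pe"]] if "pe" in sys.block_index else None
    return Solutions(
        beta_hat=sol[b_sl],
        u_hat=sol[a_sl],
        u2_hat=sol[sys.geno_index],
        extra_hat=extra,
    )


def pev_genotyped(sys: MMESystem) -> PevBlock:
    """Genotyped-animal block C^{u2u2} of the inverse coefficient matrix.

    Obtained by solving for the genotyped columns of the identity against the
    cached factorization; equivalent to slicing the full dense inverse.
    """
    if sys.geno_index.size == 0:
        raise InputError("model has no genotyped animals")
    E = np.zeros((sys.n, sys.geno_index.size))
    E[sys.geno_index, np.arange(sys.geno_index.size)] = 1.0
    cols = sla.cho_solve(sys.factor(), E)
    C = cols[sys.geno_index, :]
    return PevBlock((C + C.T) / 2.0)


def build_fixed_design(
    table: pd.DataFrame,
    categorical: tuple[str, ...] = (),
    covariates: tuple[str, ...] = (),
    coding: str = "treatment",
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Full-rank fixed-effect design: intercept, coded categoricals, covariates.

    ``coding`` chooses the identifiability constraint for categorical
    effects: ``treatment`` drops the first level, ``sum`` uses sum-to-zero
    contrasts. Estimable functions (breeding values, marker effects,
    p-values) are invariant to this choice.
    """
    n = len(table)
    cols = [np.ones((n, 1))]
    names = ["intercept"]
    for c in categorical:
        if c not in table.columns:
            raise InputError(f"fixed-effect column {c!r} not in phenotype table")
        levels = pd.Categorical(table[c].astype(str))
        dummies = pd.get_dummies(levels, dtype=float).to_numpy()
        if dummies.shape[1] > 1:
            if coding == "treatment":
                coded = dummies[:, 1:]
            elif coding == "sum":
                coded = dummies[:, 1:] - dummies[:, [0]]
            else:
                raise InputError(f"unknown coding {coding!r}")
            cols.append(coded)
            names += [f"{c}={lv}" for lv in levels.categories[1:]]
    for c in covariates:
        if c not in table.columns:
            raise InputError(f"covariate column {c!r} not in phenotype table")
        cols.append(table[c].to_numpy(dtype=float).reshape(-1, 1))
        names.append(c)
    return np.hstack(cols), tuple(names)


def incidence_matrix(labels, level_order=None) -> tuple[sp.csr_matrix, tuple[str, ...]]:
    """0/1 incidence of records onto levels (animals, dams, ...)."""
    labels = [str(x) for x in labels]
    if level_order is None:
        level_order = tuple(dict.fromkeys(labels))
    else:
        level_order = tuple(str(x) for x in level_order)
    lookup = {lv: k for k, lv in enumerate(level_order)}
    try:
        cols = np.array([lookup[x] for x in labels], dtype=np.intp)
    except KeyError as e:
        raise InputError(f"record refers to unknown level {e.args[0]!r}") from None
    n = len(labels)
    M = sp.csr_matrix(
        (np.ones(n), (np.arange(n), cols)), shape=(n, len(level_order))
    )
    return M, level_order
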