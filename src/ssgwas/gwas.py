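"""Marker-level association statistics back-solved from single-step GBLUP.

Given breeding-value solutions û₂ of the genotyped animals and the
prediction-error covariance block C^{u2u2} of the mixed model equations,
allele-substitution effects and their sampling variances are recovered as

    â       = k · Z′ G⁻¹ û₂,
    Var(â_i) = k² · z_i′ G⁻¹ (G σ_u² − C^{u2u2}) G⁻¹ z_i,

with k = (1 − α)·b / 2Σp_j q_j carrying the blending of G. The test statistic
â_i / sd(â_i) is standard normal under the null and is mathematically
equivalent to the single-marker mixed-model (EMMAX) fixed-regression
statistic when every phenotyped animal is genotyped; :func:`emmax_scan`
provides that scan as an independent cross-check.

p-values use the two-sided normal tail 2(1 − Φ(|z|)); the −log10 p column is
computed from the log survival function so it does not underflow to 0 until
|z| ≈ 38.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy import stats

from .containers import RelationshipMatrix
from .exceptions import InputError, NumericalError
from .ssgblup_core import ModelSpec, PevBlock, VarianceComponents

LOG10 = np.log(10.0)
#: markers whose Var(â) is more negative than −1e−10·σ_u² indicate an
#: inconsistent G / C^{u2u2} pair and raise; tinier negatives are rounding
NEG_VAR_TOL = 1e-10

FLAG_OK = "ok"
FLAG_NO_INFO = "no_information"


@dataclass
class BacksolveScale:
    """The factor k = (1−α)·b / 2Σpq applied in the back-solving formulas."""

    alpha: float
    b: float
    sum2pq: float

    def __post_init__(self) -> None:
        if self.sum2pq <= 0:
            raise InputError("sum2pq must be positive")
        if not (0.0 <= self.alpha < 1.0) or self.b <= 0:
            raise InputError("require 0 <= alpha < 1 and b > 0")

    @property
    def scale(self) -> float:
        return (1.0 - self.alpha) * self.b / self.sum2pq


@dataclass
class GwasResult:
    """Per-marker association results plus run-level diagnostics."""

    table: pd.DataFrame
    lambda_gc: float | None = None
    bonferroni_neglog10: float | None = None
    qq: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)
    blend: dict | None = None


def _solve_G(G: RelationshipMatrix, B: np.ndarray) -> np.ndarray:
    try:
        c = sla.cho_factor(G.values, lower=True)
    except np.linalg.LinAlgError:
        raise NumericalError("G is singular; cannot back-solve marker effects") from None
    return sla.cho_solve(c, B)


def backsolve_snp_effects(
    Z: np.ndarray,
    G: RelationshipMatrix,
    u2_hat: np.ndarray,
    s: BacksolveScale,
) -> np.ndarray:
    """Allele-substitution effect estimates â = k · Z′ (G⁻¹ û₂)."""
    u2_hat = np.asarray(u2_hat, dtype=float).ravel()
    if Z.shape[0] != G.n or u2_hat.size != G.n:
        raise InputError(
            f"dimension mismatch: Z {Z.shape}, G {G.n} animals, "
            f"u2_hat {u2_hat.size}"
        )
    return s.scale * (Z.T @ _solve_G(G, u2_hat))


def snp_prediction_error_variance(
    Z: np.ndarray,
    G: RelationshipMatrix,
    C_u2u2: PevBlock,
    vc: VarianceComponents,
    s: BacksolveScale,
) -> tuple[np.ndarray, int]:
    """Sampling variances Var(â_i) = k² z_i′ G⁻¹ (Gσ_u² − C^{u2u2}) G⁻¹ z_i.

    One factorization of G is shared across markers. Returns the variance
    vector and the count of tiny negative values clamped to zero (markers
    the caller should flag as uninformative).
    """
    C = np.asarray(C_u2u2.values, dtype=float)
    if Z.shape[0] != G.n or C.shape != (G.n, G.n):
        raise InputError("Z, G and C_u2u2 must share the genotyped-animal order")
    T = _solve_G(G, Z)  # G⁻¹ Z, genotyped animals × markers
    M = G.values * vc.sigma_u2 - C
    var_a = s.scale**2 * np.einsum("ij,ij->j", T, M @ T)
    floor = -NEG_VAR_TOL * vc.sigma_u2
    if np.any(var_a < floor):
        worst = float(var_a.min())
        raise NumericalError(
            f"Var(a_hat) = {worst:.3e} is negative beyond rounding tolerance; "
            "G and C_u2u2 are inconsistent (different Z, blending, or run?)"
        )
    clamped = int(np.sum(var_a < 0))
    var_a = np.maximum(var_a, 0.0)
    return var_a, clamped


def snp_pvalues(a_hat: np.ndarray, var_a: np.ndarray) -> pd.DataFrame:
    """Two-sided normal p-values for â_i / sd(â_i).

    Markers with zero variance carry no information: their z, p and −log10 p
    are NaN and they are flagged. −log10 p is computed via the log survival
    function, avoiding the 1 − Φ cancellation for large |z|.
    """
    a_hat = np.asarray(a_hat, dtype=float)
    var_a = np.asarray(var_a, dtype=float)
    if np.any(var_a < 0):
        raise InputError("negative Var(a_hat) passed to snp_pvalues")
    ok = var_a > 0
    z = np.full(a_hat.shape, np.nan)
    z[ok] = a_hat[ok] / np.sqrt(var_a[ok])
    pval = np.full(a_hat.shape, np.nan)
    pval[ok] = 2.0 * stats.norm.sf(np.abs(z[ok]))
    neglog10p = np.full(a_hat.shape, np.nan)
    neglog10p[ok] = -(np.log(2.0) + stats.norm.logsf(np.abs(z[ok]))) / LOG10
    flag = np.where(ok, FLAG_OK, FLAG_NO_INFO)
    return pd.DataFrame(
        {"z": z, "pvalue": pval, "neglog10p": neglog10p, "flag": flag}
    )


def variance_explained(
    p_freq: np.ndarray, a_hat: np.ndarray, sigma_u2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Additive variance attributed to each marker: raw 2p_i q_i â_i²,
    and as a percentage of the additive genetic variance σ_u².

    A point estimate only — it carries no uncertainty statement.
    """
    p_freq = np.asarray(p_freq, dtype=float)
    a_hat = np.asarray(a_hat, dtype=float)
    raw = 2.0 * p_freq * (1.0 - p_freq) * a_hat**2
    return raw, raw / sigma_u2 * 100.0


def to_fixed_regression(
    a_hat: np.ndarray, var_a: np.ndarray, sigma_a2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Convert random-effect estimates â to fixed-regression estimates.

    ``sigma_a2`` is the prior variance of one marker effect under the model,
    (1−α)·b·σ_u²/2Σpq (σ_u²/2Σpq when G is unblended). Then
    b̂_i = (σ_a²/Var(â_i)) â_i and Var(b̂_i) = (σ_a²)²/Var(â_i) reproduce the
    GLS single-marker estimates, and b̂/sd(b̂) ≡ â/sd(â) identically.
    Markers with Var(â) = 0 yield NaN (flagged upstream).
    """
    a_hat = np.asarray(a_hat, dtype=float)
    var_a = np.asarray(var_a, dtype=float)
    b_hat = np.full(a_hat.shape, np.nan)
    var_b = np.full(a_hat.shape, np.nan)
    ok = var_a > 0
    b_hat[ok] = sigma_a2 / var_a[ok] * a_hat[ok]
    var_b[ok] = sigma_a2**2 / var_a[ok]
    # internal consistency: the z statistic must be preserved
    za = a_hat[ok] / np.sqrt(var_a[ok])
    zb = b_hat[ok] / np.sqrt(var_b[ok])
    if za.size and not np.allclose(za, zb, rtol=1e-10, atol=1e-12):
        raise NumericalError("fixed-regression conversion broke the z statistic")
    return b_hat, var_b


def bonferroni_threshold(alpha_nominal: float, m_markers: int) -> float:
    """Genome-wide rejection threshold −log10(α/m)."""
    if m_markers < 1:
        raise InputError("m_markers must be >= 1")
    if not (0 < alpha_nominal <= 1):
        raise InputError("alpha_nominal must be in (0, 1]")
    return float(-np.log10(alpha_nominal / m_markers))


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (an extra column beyond the
    Bonferroni threshold the method itself uses); NaN passes through."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = stats.false_discovery_control(p[ok], method="bh")
    return out


CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549...


def inflation_factor(pvalues: np.ndarray) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Genomic-control λ: median association χ²₁ over its null median.

    λ ≈ 1 indicates that relatedness/structure is correctly absorbed by the
    model. Also returns QQ-plot coordinates (expected, observed −log10 p).
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 20:
        raise InputError("need at least 20 p-values to estimate inflation")
    chi2 = stats.chi2.isf(p, 1)
    lam = float(np.median(chi2) / CHI2_1_MEDIAN)
    obs = np.sort(-np.log10(np.clip(p, np.finfo(float).tiny, None)))[::-1]
    m = p.size
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    return lam, (expected, obs)


def emmax_scan(
    model: ModelSpec,
    Z: np.ndarray,
    K: RelationshipMatrix,
    vc: VarianceComponents,
) -> pd.DataFrame:
    """Single-marker mixed-model (EMMAX-style) scan, used as an oracle.

    For each marker the fixed regression y = Xβ + (W z_i) b_i + ε is fitted
    by GLS with Var(y) = W K W′ σ_u² + S S′ σ_pe² + I σ_e², K being the
    genomic (or H-projected) relationship among the animals carrying
    records. Brute force: one variance factorization, one solve per marker.
    Markers whose record-level genotype is constant are confounded with the
    intercept and returned as NaN.
    """
    n = model.y.size
    W = sp.csr_matrix(model.W)
    if W.shape[1] != K.n:
        raise InputError("W columns must match the relationship matrix K")
    if Z.shape[0] != K.n:
        raise InputError("Z rows must match the relationship matrix K")
    Wd = W.toarray()
    V = (Wd @ K.values @ Wd.T) * vc.sigma_u2 + np.eye(n) * vc.sigma_e2
    if model.extra_random is not None:
        if vc.sigma_pe2 is None:
            raise InputError("extra random effect given without sigma_pe2")
        S = sp.csr_matrix(model.extra_random).toarray()
        V += (S @ S.T) * vc.sigma_pe2
    try:
        cv = sla.cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        raise NumericalError("phenotypic variance matrix is singular") from None
    X = model.X
    ViX = sla.cho_solve(cv, X)
    Viy = sla.cho_solve(cv, model.y)
    try:
        cxx = sla.cho_factor(X.T @ ViX, lower=True)
    except np.linalg.LinAlgError:
        raise NumericalError("fixed-effect GLS system is singular") from None
    beta0 = sla.cho_solve(cxx, X.T @ Viy)
    Zrec = Wd @ Z  # record-level gene contents, n × m
    ViZ = sla.cho_solve(cv, Zrec)
    m = Z.shape[1]
    b = np.full(m, np.nan)
    var_b = np.full(m, np.nan)
    for i in range(m):
        x = Zrec[:, i]
        if np.ptp(x) == 0.0:
            continue  # constant covariate: confounded with the intercept
        vix = ViZ[:, i]
        xtvx = X.T @ vix
        # Schur complement of the marker column in the bordered GLS system
        den = float(x @ vix - xtvx @ sla.cho_solve(cxx, xtvx))
        if den <= 0.0:
            continue  # marker lies in the fixed-effect column space
        b[i] = float(x @ Viy - xtvx @ beta0) / den
        var_b[i] = 1.0 / den
    with np.errstate(invalid="ignore"):
        zstat = b / np.sqrt(var_b)
    pval = 2.0 * stats.norm.sf(np.abs(zstat))
    return pd.DataFrame({"b_hat": b, "var_b": var_b, "z": zstat, "pvalue": pval})
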