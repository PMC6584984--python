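"""Independent oracles used across the test suite.

These deliberately use the *variance-form* of BLUP (build the full
phenotypic covariance and apply GLS formulas) or the marker-level MME, so
they share no code path with the package's Henderson-system implementation.
"""
import numpy as np
import scipy.sparse as sp


def dense(M):
    return M.toarray() if sp.issparse(M) else np.asarray(M)


def gls_blup(y, X, W, K, sigma_u2, sigma_e2, S=None, sigma_pe2=None):
    """BLUE/BLUP via the phenotypic covariance: V = WKW'σu² (+ SS'σpe²) + Iσe².

    Returns (beta_hat, u_hat for all K animals, extra_hat or None).
    """
    W = dense(W)
    n = y.size
    V = W @ K @ W.T * sigma_u2 + np.eye(n) * sigma_e2
    Sd = None
    if S is not None:
        Sd = dense(S)
        V += Sd @ Sd.T * sigma_pe2
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    resid = y - X @ beta
    u = sigma_u2 * K @ W.T @ Vi @ resid
    extra = None if Sd is None else sigma_pe2 * Sd.T @ Vi @ resid
    return beta, u, extra


def snp_blup(y, X, W_geno, Z, sigma_u2, sigma_e2, sum2pq, S=None, sigma_pe2=None):
    """Marker-level ridge MME: y = Xβ + (W Z) a + (S p) + e, Var(a_i) = σu²/2Σpq.

    Returns (a_hat, var_a) where var_a_i = σ_a² − PEV_ii from the inverse of
    the coefficient matrix.
    """
    sigma_a2 = sigma_u2 / sum2pq
    T = dense(W_geno) @ Z  # records × markers
    blocks = [X, T]
    if S is not None:
        blocks.append(dense(S))
    F = np.hstack(blocks)
    p, m = X.shape[1], Z.shape[1]
    lhs = F.T @ F
    lhs[p:p + m, p:p + m] += np.eye(m) * (sigma_e2 / sigma_a2)
    if S is not None:
        q = blocks[2].shape[1]
        lhs[p + m:, p + m:] += np.eye(q) * (sigma_e2 / sigma_pe2)
    rhs = F.T @ y
    C = np.linalg.inv(lhs) * sigma_e2  # prediction-error covariance
    sol = np.linalg.solve(lhs, rhs)
    a_hat = sol[p:p + m]
    var_a = sigma_a2 - np.diag(C)[p:p + m]
    return a_hat, var_a


def kinship_recursive(ped):
    """Memoized recursive kinship-based A (independent of the tabular code)."""
    import sys

    sys.setrecursionlimit(100000)
    sire, dam = ped.sire_index, ped.dam_index
    cache = {}

    def a(i, j):
        if i > j:
            i, j = j, i
        if (i, j) in cache:
            return cache[(i, j)]
        if i == j:
            s, d = sire[i], dam[i]
            val = 1.0 + (0.5 * a(s, d) if (s >= 0 and d >= 0) else 0.0)
        else:  # i < j, so i cannot be a descendant of j
            s, d = sire[j], dam[j]
            val = 0.0
            if s >= 0:
                val += 0.5 * a(i, s)
            if d >= 0:
                val += 0.5 * a(i, d)
        cache[(i, j)] = val
        return val

    n = ped.n
    return np.array([[a(i, j) for j in range(n)] for i in range(n)])
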