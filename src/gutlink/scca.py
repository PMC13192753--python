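"""Sparse canonical correlation analysis via penalized matrix decomposition.

Finds paired sparse loading vectors (u over genes, v over taxa) maximizing
u' X'Z v subject to ||u||_2 <= 1, ||u||_1 <= c1, and likewise for v: the
rank-one penalized matrix decomposition, solved by alternating
soft-thresholded power iterations with the threshold found by bisection.
Successive components come from deflating the cross-product by d * u v'.

Penalties are parameterized as fractions of sqrt(dimension), so a fraction
of 1 imposes no sparsity (the L1 ball then contains the L2 ball) and the
model coincides with the truncated SVD of the standardized cross-product.

Penalty tuning and component significance both use leave-one-out
cross-validation on held-out canonical variate pairs (x_i . u^(-i),
z_i . v^(-i)), sign-aligned to the full-data loadings; significance is a
Pearson correlation t-test per component with Benjamini-Hochberg adjustment
across components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .covariates import bh_adjust

__all__ = [
    "soft_threshold",
    "pmd_rank_one",
    "SparseCCAModel",
    "fit_sparse_cca",
    "tune_penalties_loocv",
    "ComponentSignificance",
    "component_significance_loocv",
]

logger = logging.getLogger(__name__)


def soft_threshold(x, delta: float):
    """Elementwise shrinkage sign(x) * max(|x| - delta, 0)."""
    if delta < 0:
        raise ValueError("delta must be non-negative")
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.maximum(np.abs(x) - delta, 0.0)


def _l1_constrained_unit(a: np.ndarray, c: float) -> np.ndarray:
    """Unit-L2 vector u = S(a, delta)/||S(a, delta)||_2 with the smallest
    delta >= 0 satisfying ||u||_1 <= c.

    The L1/L2 ratio of the soft-thresholded vector is non-increasing in
    delta (by Cauchy-Schwarz), so the critical delta solves a per-support
    quadratic exactly: with the top-k absolute values summing to A (squares
    to B), ||S||_1 = c ||S||_2 gives delta = (A - c sqrt((kB - A^2) /
    (k - c^2))) / k on the interval where the support has size k.
    """
    norm = np.linalg.norm(a)
    if norm == 0:
        return np.zeros_like(a)
    u = a / norm
    if np.abs(u).sum() <= c:
        return u
    b = np.sort(np.abs(a[a != 0]))[::-1]
    p = b.size
    A = np.cumsum(b)
    B = np.cumsum(b ** 2)
    ks = np.arange(1, p + 1, dtype=float)
    # ratio at the lower end of each support interval, delta = b[k] (next
    # order statistic); the last entry is the ratio at delta = 0
    nxt = np.concatenate([b[1:], [0.0]])
    s1 = A - ks * nxt
    s2 = B - 2 * A * nxt + ks * nxt ** 2
    # boundaries inside a cluster of (near-)tied values lose all precision to
    # cancellation; their true ratio is at most sqrt(k) and never the first
    # crossing, so mask them out instead of dividing rounding noise
    valid = (s2 > B * 1e-13) & (s1 > 0)
    ratios = np.where(valid, s1 / np.sqrt(np.where(valid, s2, 1.0)), 0.0)
    idx = np.flatnonzero(ratios >= c)
    if idx.size == 0:
        # c below 1: infeasible; closest point is a single spike
        u = np.zeros_like(a)
        i = int(np.argmax(np.abs(a)))
        u[i] = np.sign(a[i])
        return u
    k = int(idx[0]) + 1  # support size at the critical delta
    Ak, Bk = A[k - 1], B[k - 1]
    denom = k - c ** 2
    if denom <= 1e-12:
        delta = nxt[k - 1]
    else:
        delta = (Ak - c * np.sqrt(max(k * Bk - Ak ** 2, 0.0) / denom)) / k
        delta = min(max(delta, nxt[k - 1]), b[k - 1])
    su = soft_threshold(a, delta)
    nrm = np.linalg.norm(su)
    if nrm == 0:  # numerical tie collapse; fall back to a spike
        u = np.zeros_like(a)
        i = int(np.argmax(np.abs(a)))
        u[i] = np.sign(a[i])
        return u
    return su / nrm


def pmd_rank_one(
    K_cross: np.ndarray,
    c1_frac: float,
    c2_frac: float,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """One penalized rank-one factor (u, v, d) of a cross-product matrix.

    Returns ``(u, v, d, converged)``; if ``max_iter`` is exhausted the last
    iterate is returned with ``converged=False`` and a logged warning.
    """
    for name, frac in (("c1_frac", c1_frac), ("c2_frac", c2_frac)):
        if not 0 < frac <= 1:
            raise ValueError(f"{name} must lie in (0, 1], got {frac}")
    K = np.asarray(K_cross, dtype=float)
    p, q = K.shape
    # the L1 budget of a unit-L2 vector lies in [1, sqrt(dim)]; clamp so
    # small fractions on low-dimensional data mean "maximally sparse"
    c1 = max(1.0, c1_frac * np.sqrt(p))
    c2 = max(1.0, c2_frac * np.sqrt(q))
    # initialize v at the leading right singular vector
    v = np.linalg.svd(K, compute_uv=True)[2][0]
    u = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        u_new = _l1_constrained_unit(K @ v, c1)
        v_new = _l1_constrained_unit(K.T @ u_new, c2)
        delta = max(np.abs(u_new - u).max(initial=0.0),
                    np.abs(v_new - v).max(initial=0.0))
        u, v = u_new, v_new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("pmd_rank_one did not converge in %d iterations", max_iter)
    d = float(u @ K @ v)
    if d < 0:  # orient the factor so the singular value is non-negative
        v, d = -v, -d
    return u, v, d, converged


def _standardize(M: np.ndarray):
    """Column-standardize (mean 0, sd 1, ddof 1); zero-variance columns are
    dropped. Returns (standardized, mean, sd, kept boolean mask).

    The variance test is relative: a numerically constant column has
    sd ~ eps * |mean| from rounding of the mean, and standardizing it would
    amplify that rounding noise into a spurious O(1) column.
    """
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    keep = sd > 1e-10 * (1.0 + np.abs(mean))
    return (M[:, keep] - mean[keep]) / sd[keep], mean, sd, keep


@dataclass
class SparseCCAModel:
    """Fitted sparse CCA: per-component loadings, singular values, penalties."""

    u: pd.DataFrame  # genes x components, unit L2 per component (or zero)
    v: pd.DataFrame  # taxa x components
    d: np.ndarray
    c1_frac: float
    c2_frac: float
    gene_means: pd.Series | None = None
    gene_scales: pd.Series | None = None
    taxon_means: pd.Series | None = None
    taxon_scales: pd.Series | None = None
    converged: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.u.shape[1]

    def gene_support(self, k: int, rel_tol: float = 1e-8) -> list[str]:
        """Feature ids with nonzero gene loading in component k (1-based).

        Loadings below ``rel_tol`` times the component's largest magnitude
        are treated as numerical zeros.
        """
        return self._support(self.u, k, rel_tol)

    def taxon_support(self, k: int, rel_tol: float = 1e-8) -> list[str]:
        return self._support(self.v, k, rel_tol)

    @staticmethod
    def _support(frame: pd.DataFrame, k: int, rel_tol: float) -> list[str]:
        col = frame.iloc[:, k - 1]
        cutoff = rel_tol * col.abs().max()
        return col.index[col.abs() > cutoff].tolist()

    def loadings_table(self) -> pd.DataFrame:
        rows = []
        for k in range(self.n_components):
            for mod, frame in (("gene", self.u), ("taxon", self.v)):
                col = frame.iloc[:, k]
                nz = col[col.abs() > 1e-8 * col.abs().max()]
                rows += [(k + 1, fid, val, mod) for fid, val in nz.items()]
        return pd.DataFrame(rows, columns=["component", "feature_id", "loading",
                                           "modality"])

    def to_tsv(self, path) -> None:
        self.loadings_table().to_csv(path, sep="\t", index=False)


def _fit_components(Xs: np.ndarray, Zs: np.ndarray, c1_frac: float, c2_frac: float,
                    K: int, tol: float, max_iter: int):
    """Successive deflated rank-one fits on standardized matrices."""
    Kc = Xs.T @ Zs
    us, vs, ds, conv = [], [], [], []
    for _ in range(K):
        u, v, d, ok = pmd_rank_one(Kc, c1_frac, c2_frac, tol=tol, max_iter=max_iter)
        us.append(u); vs.append(v); ds.append(d); conv.append(ok)
        Kc = Kc - d * np.outer(u, v)
    return np.column_stack(us), np.column_stack(vs), np.array(ds), conv


def fit_sparse_cca(
    X,
    Z,
    c1_frac: float,
    c2_frac: float,
    K: int = 10,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> SparseCCAModel:
    """Fit K sparse CCA components to samples-x-genes X and samples-x-taxa Z.

    Columns are standardized internally (zero-variance columns dropped with a
    warning); components are extracted by successive rank-one fits of the
    deflated cross-product.
    """
    X_df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
    Z_df = Z if isinstance(Z, pd.DataFrame) else pd.DataFrame(np.asarray(Z, float))
    if X_df.shape[0] != Z_df.shape[0]:
        raise ValueError("X and Z must have the same samples (rows)")
    if X_df.shape[0] < 3:
        raise ValueError("sparse CCA needs at least 3 samples")
    if K > min(X_df.shape[1], Z_df.shape[1]):
        raise ValueError("K exceeds the smaller feature dimension")
    Xs, x_mean, x_sd, x_keep = _standardize(X_df.to_numpy(float))
    Zs, z_mean, z_sd, z_keep = _standardize(Z_df.to_numpy(float))
    for keep, cols, name in ((x_keep, X_df.columns, "X"), (z_keep, Z_df.columns, "Z")):
        if not keep.all():
            logger.warning("dropping %d zero-variance %s columns: %s",
                           (~keep).sum(), name, list(cols[~keep][:5]))
    U, V, d, conv = _fit_components(Xs, Zs, c1_frac, c2_frac, K, tol, max_iter)
    u_full = np.zeros((X_df.shape[1], K)); u_full[x_keep] = U
    v_full = np.zeros((Z_df.shape[1], K)); v_full[z_keep] = V
    comp_names = [f"component{k + 1}" for k in range(K)]
    return SparseCCAModel(
        u=pd.DataFrame(u_full, index=X_df.columns, columns=comp_names),
        v=pd.DataFrame(v_full, index=Z_df.columns, columns=comp_names),
        d=d, c1_frac=c1_frac, c2_frac=c2_frac,
        gene_means=pd.Series(x_mean, index=X_df.columns),
        gene_scales=pd.Series(x_sd, index=X_df.columns),
        taxon_means=pd.Series(z_mean, index=Z_df.columns),
        taxon_scales=pd.Series(z_sd, index=Z_df.columns),
        converged=conv,
    )


def _align(u_fold, v_fold, u_ref, v_ref):
    """Resolve the joint sign indeterminacy of a canonical pair by the sign
    of the gene-loading inner product with the reference."""
    s = float(np.sign(u_fold @ u_ref))
    if s == 0:
        s = float(np.sign(v_fold @ v_ref)) or 1.0
    return u_fold * s, v_fold * s


def _loocv_pairs(X: np.ndarray, Z: np.ndarray, c1_frac: float, c2_frac: float,
                 K: int, u_ref: np.ndarray, v_ref: np.ndarray,
                 tol: float, max_iter: int) -> np.ndarray:
    """Held-out canonical variate pairs, shape (n, K, 2).

    For each left-out sample, the model is refitted on the remaining rows
    (standardized within the fold), components matched by extraction order
    and sign-aligned to the reference loadings, and the held-out sample
    projected with the fold's standardization.
    """
    n = X.shape[0]
    pairs = np.empty((n, K, 2))
    for i in range(n):
        mask = np.ones(n, bool); mask[i] = False
        Xs, xm, xs, xk = _standardize(X[mask])
        Zs, zm, zs, zk = _standardize(Z[mask])
        U, V, _, _ = _fit_components(Xs, Zs, c1_frac, c2_frac, K, tol, max_iter)
        xi = (X[i, xk] - xm[xk]) / xs[xk]
        zi = (Z[i, zk] - zm[zk]) / zs[zk]
        for k in range(K):
            u, v = _align(U[:, k], V[:, k], u_ref[xk, k], v_ref[zk, k])
            pairs[i, k] = (xi @ u, zi @ v)
    return pairs


def tune_penalties_loocv(
    X,
    Z,
    grid=None,
    tol: float = 1e-6,
    max_iter: int = 200,
):
    """Grid-search the penalty pair by LOOCV correlation of component 1.

    Each grid point is scored by the Pearson correlation across samples of
    the held-out variate pairs; the argmax wins, with ties broken toward the
    sparsest pair (smallest c1_frac + c2_frac).  Returns ``(best_pair,
    scores)`` where scores is a DataFrame over the grid.
    """
    X = np.asarray(X, float) if not isinstance(X, pd.DataFrame) else X.to_numpy(float)
    Z = np.asarray(Z, float) if not isinstance(Z, pd.DataFrame) else Z.to_numpy(float)
    if grid is None:
        fr = np.round(np.arange(0.1, 1.01, 0.1), 2)
        grid = [(a, b) for a in fr for b in fr]
    grid = list(grid)
    if not grid:
        raise ValueError("penalty grid is empty")
    rows = []
    for c1, c2 in grid:
        model_u, model_v, _, _ = _fit_components(*_std_pair(X, Z), c1, c2, 1,
                                                 tol, max_iter)
        u_ref = np.zeros((X.shape[1], 1)); v_ref = np.zeros((Z.shape[1], 1))
        u_ref[_standardize(X)[3], 0] = model_u[:, 0]
        v_ref[_standardize(Z)[3], 0] = model_v[:, 0]
        pairs = _loocv_pairs(X, Z, c1, c2, 1, u_ref, v_ref, tol, max_iter)
        a, b = pairs[:, 0, 0], pairs[:, 0, 1]
        if np.std(a) == 0 or np.std(b) == 0:
            score = np.nan
        else:
            score = float(np.corrcoef(a, b)[0, 1])
        rows.append((c1, c2, score))
    scores = pd.DataFrame(rows, columns=["c1_frac", "c2_frac", "score"])
    if scores["score"].isna().all():
        raise ValueError("all LOOCV scores undefined (constant variates)")
    best_score = scores["score"].max()
    tied = scores[np.isclose(scores["score"], best_score, equal_nan=False)]
    tied = tied.assign(total=tied["c1_frac"] + tied["c2_frac"])
    row = tied.sort_values(["total", "c1_frac", "c2_frac"]).iloc[0]
    return (float(row["c1_frac"]), float(row["c2_frac"])), scores


def _std_pair(X, Z):
    return _standardize(X)[0], _standardize(Z)[0]


@dataclass
class ComponentSignificance:
    """LOOCV Pearson correlation per component with BH adjustment."""

    table: pd.DataFrame  # component, rho, pval, qval, flagged
    pairs: np.ndarray  # (n, K, 2) held-out variate pairs
    alpha: float = 0.1

    @property
    def flagged_components(self) -> list[int]:
        return self.table.loc[self.table["flagged"], "component"].tolist()


def component_significance_loocv(
    X,
    Z,
    c1_frac: float,
    c2_frac: float,
    K: int = 10,
    alpha: float = 0.1,
    tol: float = 1e-6,
    max_iter: int = 200,
    variance_inflation: float = 2.0,
) -> ComponentSignificance:
    """Test each of K components by LOOCV held-out correlation.

    Every fold refits all K components on n-1 samples; per component the n
    held-out variate pairs give a Pearson rho tested against zero with a t
    statistic (df = n - 2), BH-adjusted across the K components; flagged at
    adjusted p < ``alpha``.

    Held-out pairs from leave-one-out folds are not independent — every two
    folds share n - 2 training samples — which inflates the null standard
    deviation of the correlation to roughly twice the independent-pairs
    value across a wide range of n, dimensions and penalties.  The t
    statistic is therefore divided by ``variance_inflation`` (default 2.0;
    set 1.0 for the naive independent-pairs test).
    """
    X = np.asarray(X, float) if not isinstance(X, pd.DataFrame) else X.to_numpy(float)
    Z = np.asarray(Z, float) if not isinstance(Z, pd.DataFrame) else Z.to_numpy(float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("LOOCV significance needs at least 4 samples")
    if K > min(X.shape[1], Z.shape[1]):
        raise ValueError("K exceeds the smaller feature dimension")
    full = fit_sparse_cca(X, Z, c1_frac, c2_frac, K=K, tol=tol, max_iter=max_iter)
    pairs = _loocv_pairs(X, Z, c1_frac, c2_frac, K,
                         full.u.to_numpy(), full.v.to_numpy(), tol, max_iter)
    rows = []
    for k in range(K):
        a, b = pairs[:, k, 0], pairs[:, k, 1]
        if np.std(a) == 0 or np.std(b) == 0:
            rho, p = np.nan, 1.0
        else:
            rho = float(np.corrcoef(a, b)[0, 1])
            tstat = (rho * np.sqrt((n - 2) / max(1e-12, 1 - rho ** 2))
                     / variance_inflation)
            # one-sided: canonical variate pairs are positively oriented, so
            # only positive held-out correlation is evidence of association
            p = float(scipy.stats.t.sf(tstat, df=n - 2))
        rows.append((k + 1, rho, p))
    table = pd.DataFrame(rows, columns=["component", "rho", "pval"])
    table["qval"] = bh_adjust(table["pval"].to_numpy())
    table["flagged"] = table["qval"] < alpha
    return ComponentSignificance(table=table, pairs=pairs, alpha=alpha)
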