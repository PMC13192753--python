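"""Per-microbe elastic-net gene selection and post-hoc pair correlations.

Each microbe's covariate-adjusted CLR abundance is regressed on the full
covariate-adjusted gene expression matrix,

    microbe ~ intercept + gene_1 + ... + gene_p,

with the elastic-net penalty lambda * (alpha * ||b||_1 + (1-alpha)/2 *
||b||_2^2).  The mixing parameter alpha and strength lambda are tuned
jointly by repeated k-fold cross-validation minimizing mean RMSE; the final
coefficients come from a full-data refit at the selected pair.  Genes with
nonzero coefficients define the gene-microbe pair table.  Covariates are
assumed to have been regressed out upstream, so none enter the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import RepeatedKFold

__all__ = ["ElasticNetFit", "fit_elastic_net", "extract_pairs", "pair_correlation"]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))


@dataclass
class ElasticNetFit:
    """One microbe's tuned elastic-net model over genes."""

    microbe_id: str
    intercept: float
    coefficients: pd.Series  # per gene, original predictor scale
    mixing: float  # alpha in [0.1, 1]: 1 = lasso
    strength: float  # lambda
    cv_rmse: pd.DataFrame  # (mixing, strength) -> mean CV RMSE

    @property
    def n_nonzero(self) -> int:
        return int((self.coefficients != 0).sum())

    def nonzero(self) -> pd.Series:
        return self.coefficients[self.coefficients != 0]


def fit_elastic_net(
    y,
    X,
    alpha_grid=DEFAULT_ALPHA_GRID,
    n_lambda: int = 100,
    folds: int = 5,
    repeats: int = 5,
    seed=None,
    microbe_id: str = "microbe",
    max_iter: int = 5000,
    fixed: tuple[float, float] | None = None,
) -> ElasticNetFit:
    """Tune and fit one microbe's elastic net.

    The lambda path is log-spaced per mixing value from lambda_max =
    max|X'y| / (n * alpha) down four decades (``n_lambda`` values);
    predictors are standardized internally and coefficients reported on the
    original scale.  Deterministic for a fixed seed.  Passing ``fixed =
    (mixing, strength)`` skips cross-validation and fits at that pair.
    """
    X_df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    if X_df.shape[0] != n:
        raise ValueError("X and y must have the same number of samples")
    if np.std(y) == 0:
        raise ValueError("response has zero variance")
    if folds > n:
        raise ValueError(f"folds ({folds}) exceeds sample count ({n})")
    alpha_grid = [float(a) for a in alpha_grid]
    if not alpha_grid or not all(0 < a <= 1 for a in alpha_grid):
        raise ValueError("mixing grid must be non-empty with values in (0, 1]")

    sd = X_df.std(axis=0, ddof=1).to_numpy()
    # relative test: a numerically constant column has sd ~ eps * |mean|
    keep = sd > 1e-10 * (1.0 + np.abs(X_df.mean(axis=0).to_numpy()))
    Xs = (X_df.to_numpy(float)[:, keep] - X_df.to_numpy(float)[:, keep].mean(0)) / sd[keep]
    yc = y - y.mean()

    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if fixed is not None:
            mixing, lam = float(fixed[0]), float(fixed[1])
            surface_rmse = np.full((1, 1), np.nan)
            surface_index = [mixing]
        else:
            cv = RepeatedKFold(n_splits=folds, n_repeats=repeats,
                               random_state=None if seed is None else int(seed))
            enet_cv = ElasticNetCV(
                l1_ratio=alpha_grid, alphas=n_lambda, eps=1e-4, cv=cv,
                fit_intercept=True, max_iter=max_iter,
            )
            enet_cv.fit(Xs, yc)
            # (mixing, lambda) chosen to minimize the mean CV RMSE over folds
            mse = enet_cv.mse_path_
            alphas = np.atleast_2d(enet_cv.alphas_)
            if len(alpha_grid) == 1:
                mse = mse.reshape((1,) + mse.shape[-2:])
            rmse = np.sqrt(mse).mean(axis=-1)  # (n_l1, n_lambda)
            i, j = np.unravel_index(np.argmin(rmse), rmse.shape)
            mixing, lam = float(alpha_grid[i]), float(alphas[i, j])
            surface_rmse, surface_index = rmse, alpha_grid
        final = ElasticNet(alpha=lam, l1_ratio=mixing, fit_intercept=True,
                           max_iter=max_iter)
        final.fit(Xs, yc)

    coefs = np.zeros(X_df.shape[1])
    coefs[keep] = final.coef_ / sd[keep]  # back to the original predictor scale
    # original-scale intercept: y_hat = b0 + X b, with centered fits b0 ~ 0
    intercept = float(y.mean() + final.intercept_
                      - X_df.to_numpy(float).mean(axis=0) @ coefs)
    surface = pd.DataFrame(surface_rmse, index=pd.Index(surface_index, name="mixing"))
    return ElasticNetFit(
        microbe_id=microbe_id,
        intercept=intercept,
        coefficients=pd.Series(coefs, index=X_df.columns, name=microbe_id),
        mixing=mixing,
        strength=lam,
        cv_rmse=surface,
    )


def extract_pairs(fits, X=None, Y=None, region: str | None = None) -> pd.DataFrame:
    """Flatten per-microbe fits into a gene-microbe pair table.

    One row per nonzero coefficient, sorted by microbe then |coefficient|
    descending.  If the sample-level matrices ``X`` (samples x genes) and
    ``Y`` (samples x microbes) are provided, each pair also gets its
    post-hoc Pearson rho and p-value.
    """
    if not fits:
        raise ValueError("no fits provided")
    rows = []
    for fit in fits:
        nz = fit.nonzero()
        order = nz.abs().sort_values(ascending=False).index
        for gene in order:
            rho = p = np.nan
            if X is not None and Y is not None:
                rho, p = pair_correlation(X[gene], Y[fit.microbe_id])
            rows.append((gene, fit.microbe_id, float(nz[gene]), rho, p, region))
    return pd.DataFrame(rows, columns=["gene", "microbe", "coefficient",
                                       "rho", "pval", "region"])


def pair_correlation(x, y) -> tuple[float, float]:
    """Pearson rho with its two-sided t-test p-value (df = n - 2)."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape[0] != y.shape[0]:
        raise ValueError("paired vectors must have equal length")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)
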