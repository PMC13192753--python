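"""Mixed-model covariate adjustment and CLR differential abundance.

Residualization fits, per feature, a linear mixed model with the declared
fixed covariates and a random intercept per patient (REML), then subtracts
the fixed-effect fit (marginal residuals).  Patients contribute up to one
sample per intestinal location, so the random-intercept variance is often
weakly identified; any failed or singular fit falls back to ordinary least
squares with a logged warning.

Differential abundance runs the same model on CLR-transformed taxa with the
intestinal location as the fixed effect of interest (treatment coding
against a reference region), Wald tests per non-reference level, and
Benjamini-Hochberg adjustment across taxa within each contrast.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .containers import FeatureTable, SampleFrame

__all__ = [
    "CovariateDesign",
    "DifferentialResult",
    "design_from_metadata",
    "lmm_residualize",
    "lmm_differential_abundance",
    "bh_adjust",
]

logger = logging.getLogger(__name__)


@dataclass
class CovariateDesign:
    """Fixed covariates plus a random-intercept grouping (patient id)."""

    fixed: pd.DataFrame  # samples x covariates, no intercept column
    groups: pd.Series  # patient id per sample
    intercept: bool = True

    def __post_init__(self):
        self.fixed = self.fixed.copy()
        self.groups = self.groups.copy()
        if not self.fixed.index.equals(self.groups.index):
            raise ValueError("fixed-effect rows and grouping must share sample ids")
        if self.fixed.isna().any().any():
            bad = self.fixed.columns[self.fixed.isna().any()].tolist()
            raise ValueError(f"missing values in covariates: {bad}")
        if self.groups.isna().any():
            raise ValueError("grouping must cover all samples")

    @property
    def sample_ids(self) -> list[str]:
        return self.fixed.index.tolist()

    def exog(self) -> pd.DataFrame:
        X = self.fixed.astype(float)
        if self.intercept:
            X = pd.concat([pd.Series(1.0, index=X.index, name="Intercept"), X], axis=1)
        return X

    def check_rank(self) -> None:
        X = self.exog().to_numpy()
        if X.shape[0] <= self.fixed.shape[1]:
            raise ValueError("more fixed covariates than samples")
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # name columns with negligible pivots in a pivoted QR
            import scipy.linalg
            _, r, piv = scipy.linalg.qr(X, pivoting=True)
            diag = np.abs(np.diag(r))
            tol = diag.max() * max(X.shape) * np.finfo(float).eps
            names = self.exog().columns.to_numpy()[piv[rank:]]
            raise ValueError(f"rank-deficient fixed design; collinear columns: "
                             f"{list(names)} (tol {tol:.2e})")


def design_from_metadata(samples: SampleFrame, covariates, group_col: str = "patient",
                         sample_ids=None) -> CovariateDesign:
    """Build a design from metadata columns; categorical covariates are
    dummy-coded (first level dropped)."""
    df = samples.data if sample_ids is None else samples.align(sample_ids).data
    fixed = pd.get_dummies(df[list(covariates)], drop_first=True, dtype=float)
    return CovariateDesign(fixed=fixed, groups=df[group_col].astype(str))


def _mixedlm_residual(y: np.ndarray, X: pd.DataFrame, groups: pd.Series,
                      conditional: bool) -> tuple[np.ndarray, bool]:
    """Residualize one feature; returns (residuals, used_mixed_model)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM(y, X, groups=groups)
            fit = model.fit(reml=True)
            if not np.isfinite(fit.params).all():
                raise ValueError("non-finite mixed-model estimates")
            re_var = float(np.asarray(fit.cov_re).ravel()[0])
            if re_var <= 1e-10:
                raise ValueError("singular random-effect variance")
            resid = y - X.to_numpy() @ fit.fe_params.to_numpy()
            if conditional:
                re = fit.random_effects
                offsets = groups.map({g: float(np.asarray(v).ravel()[0])
                                      for g, v in re.items()}).to_numpy()
                resid = resid - offsets
            return resid, True
        except Exception:
            beta, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
            return y - X.to_numpy() @ beta, False


def lmm_residualize(y: FeatureTable, design: CovariateDesign,
                    conditional: bool = False) -> FeatureTable:
    """Regress fixed covariates (plus patient random intercept) out of every
    feature; returns marginal residuals (set ``conditional=True`` to also
    subtract predicted random effects)."""
    if y.sample_ids != design.sample_ids:
        raise ValueError("feature table and design must share sample order")
    design.check_rank()
    X = design.exog()
    groups = design.groups
    singleton = groups.value_counts().max() == 1
    vals = y.values()
    out = np.empty_like(vals)
    n_fallback = 0
    for i in range(vals.shape[0]):
        if singleton:
            # one sample per patient: the random intercept is unidentifiable
            beta, *_ = np.linalg.lstsq(X.to_numpy(), vals[i], rcond=None)
            out[i] = vals[i] - X.to_numpy() @ beta
            continue
        out[i], used_mm = _mixedlm_residual(vals[i], X, groups, conditional)
        n_fallback += not used_mm
    if singleton:
        logger.warning("all patients are singletons; used OLS residualization")
    elif n_fallback:
        logger.warning("OLS fallback for %d/%d features (singular or failed "
                       "mixed-model fits)", n_fallback, vals.shape[0])
    return FeatureTable(pd.DataFrame(out, index=y.data.index, columns=y.data.columns),
                        "residual", validate=False)


@dataclass
class DifferentialResult:
    """Per-taxon location contrasts from the CLR mixed model."""

    table: pd.DataFrame  # feature, contrast, coef, stderr, N, N.not.0, pval, qval
    reference_level: str
    covariates: list = field(default_factory=list)

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["qval"] < alpha]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def lmm_differential_abundance(
    clr_taxa: FeatureTable,
    location: pd.Series,
    design: CovariateDesign,
    reference_level: str,
    counts: FeatureTable | None = None,
) -> DifferentialResult:
    """Mixed-model differential abundance of CLR taxa across locations.

    Model per taxon: CLR ~ location + covariates + (1 | patient), with the
    reference region as baseline.  Wald p-values per non-reference level;
    q-values are BH-adjusted across taxa within each contrast.
    """
    if clr_taxa.kind != "clr":
        raise ValueError("differential abundance expects a CLR table")
    location = location.reindex(clr_taxa.sample_ids)
    levels = sorted(location.dropna().unique().tolist())
    if len(levels) < 2:
        raise ValueError("location must have at least 2 levels")
    if reference_level not in levels:
        raise ValueError(f"reference level {reference_level!r} not among {levels}")
    other = [l for l in levels if l != reference_level]
    loc_dummies = pd.DataFrame(
        {f"location[{l}]": (location == l).astype(float) for l in other},
        index=location.index,
    )
    fixed = pd.concat([loc_dummies, design.fixed.astype(float)], axis=1)
    full = CovariateDesign(fixed=fixed, groups=design.groups,
                           intercept=design.intercept)
    full.check_rank()
    X = full.exog()
    vals = clr_taxa.values()
    count_vals = counts.values() if counts is not None else None
    rows = []
    for i, fid in enumerate(clr_taxa.feature_ids):
        y = vals[i]
        n_nonzero = int((count_vals[i] > 0).sum()) if count_vals is not None else np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.MixedLM(y, X, groups=full.groups).fit(reml=True)
                params, bse, pvals = fit.fe_params, fit.bse_fe, fit.pvalues
            except Exception:
                ols = sm.OLS(y, X).fit()
                params, bse, pvals = ols.params, ols.bse, ols.pvalues
        for l in other:
            col = f"location[{l}]"
            rows.append((fid, f"{l}_vs_{reference_level}", float(params[col]),
                         float(bse[col]), len(y), n_nonzero, float(pvals[col])))
    table = pd.DataFrame(rows, columns=["feature", "contrast", "coef", "stderr",
                                        "N", "N.not.0", "pval"])
    table["qval"] = np.nan
    for contrast, idx in table.groupby("contrast").groups.items():
        table.loc[idx, "qval"] = bh_adjust(table.loc[idx, "pval"].to_numpy())
    return DifferentialResult(table=table, reference_level=reference_level,
                              covariates=design.fixed.columns.tolist())


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
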