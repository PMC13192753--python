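"""Feature filtering, normalization, compositional transforms, contaminant scoring.

All filters are order-stable (retained features keep their input order) and
never touch the sample set.  Prevalence thresholds of the form "at least X%
of samples" are applied as ``count >= ceil(frac * n_samples)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .containers import FeatureTable

__all__ = [
    "filter_taxa_prevalence",
    "filter_genes",
    "variance_filter",
    "tss",
    "clr",
    "log_cpm",
    "ContaminantReport",
    "frequency_contaminant_score",
]


def _require_kind(t: FeatureTable, *kinds: str) -> None:
    if t.kind not in kinds:
        raise ValueError(f"expected a {'/'.join(kinds)} table, got {t.kind!r}")


def filter_taxa_prevalence(
    t: FeatureTable,
    min_rel_abund: float = 1e-4,
    min_sample_frac: float = 0.10,
) -> FeatureTable:
    """Keep taxa reaching ``min_rel_abund`` relative abundance in at least
    ``ceil(min_sample_frac * n_samples)`` samples."""
    _require_kind(t, "counts")
    vals = t.values()
    depths = vals.sum(axis=0)
    if (depths == 0).any():
        bad = [t.sample_ids[i] for i in np.flatnonzero(depths == 0)]
        raise ValueError(f"zero-depth samples: {bad}")
    rel = vals / depths[None, :]
    n = vals.shape[1]
    need = math.ceil(min_sample_frac * n)
    keep = (rel >= min_rel_abund).sum(axis=1) >= need
    if not keep.any():
        raise ValueError("no features pass the prevalence filter")
    return FeatureTable(t.data.loc[keep], t.kind, validate=False)


def filter_genes(
    t: FeatureTable,
    min_count: int = 10,
    min_sample_frac: float = 0.33,
) -> FeatureTable:
    """Keep genes with at least ``min_count`` reads in at least
    ``ceil(min_sample_frac * n_samples)`` samples."""
    _require_kind(t, "counts")
    vals = t.values()
    need = math.ceil(min_sample_frac * vals.shape[1])
    keep = (vals >= min_count).sum(axis=1) >= need
    if not keep.any():
        raise ValueError("no genes pass the expression filter")
    return FeatureTable(t.data.loc[keep], t.kind, validate=False)


def variance_filter(t: FeatureTable, quantile: float = 0.25) -> FeatureTable:
    """Drop features whose variance falls strictly below the given empirical
    variance quantile; ties at the quantile are retained."""
    if not 0 <= quantile < 1:
        raise ValueError("quantile must lie in [0, 1)")
    if t.shape[1] < 2:
        raise ValueError("variance filter needs at least 2 samples")
    variances = t.values().var(axis=1, ddof=1)
    cutoff = np.quantile(variances, quantile)
    keep = variances >= cutoff
    return FeatureTable(t.data.loc[keep], t.kind, validate=False)


def tss(t: FeatureTable) -> FeatureTable:
    """Total-sum scaling: divide each sample column by its total."""
    _require_kind(t, "counts", "relative_abundance")
    vals = t.values()
    sums = vals.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(f"zero-sum sample(s): {[t.sample_ids[i] for i in zero]}")
    rel = pd.DataFrame(vals / sums[None, :], index=t.data.index, columns=t.data.columns)
    return FeatureTable(rel, "relative_abundance", validate=False)


def clr(t: FeatureTable, pseudocount: float = 1e-6) -> FeatureTable:
    """Centered log-ratio transform on the relative-abundance scale.

    Counts are total-sum scaled first, then the pseudocount is added and each
    log column is centered, so ``clr(tss(t)) == clr(t)`` for count input.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    _require_kind(t, "counts", "relative_abundance")
    rel = tss(t) if t.kind == "counts" else t
    logx = np.log(rel.values() + pseudocount)
    centered = logx - logx.mean(axis=0, keepdims=True)
    out = pd.DataFrame(centered, index=t.data.index, columns=t.data.columns)
    return FeatureTable(out, "clr", validate=False)


def log_cpm(t: FeatureTable, prior: float = 0.5) -> FeatureTable:
    """log2 counts-per-million with a prior count.

    ``log2((count + prior) / (library size + 2 * prior) * 1e6)`` — an
    approximately variance-stabilized continuous expression matrix.
    """
    if prior <= 0:
        raise ValueError("prior must be positive")
    _require_kind(t, "counts")
    vals = t.values()
    sums = vals.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(f"zero-sum sample(s): {[t.sample_ids[i] for i in zero]}")
    out = np.log2((vals + prior) / (sums + 2 * prior)[None, :] * 1e6)
    return FeatureTable(pd.DataFrame(out, index=t.data.index, columns=t.data.columns),
                        "log_cpm", validate=False)


@dataclass
class ContaminantReport:
    """Per-feature frequency-method contaminant scores.

    ``table`` has one row per feature: ``score`` (p-value; small means the
    inverse-frequency contaminant model fits better), ``slope`` of the free
    log-log regression, ``n_samples_used``, ``evaluable`` and ``flagged``.
    """

    table: pd.DataFrame
    threshold: float

    @property
    def flagged_ids(self) -> list[str]:
        return self.table.index[self.table["flagged"]].tolist()


def frequency_contaminant_score(
    t: FeatureTable,
    dna_conc,
    threshold: float = 0.1,
    min_samples: int = 5,
) -> ContaminantReport:
    """Score each feature for contamination via the frequency method.

    For samples where the feature is present, its log10 relative frequency is
    modelled against log10 DNA concentration under two intercept-only fits:
    the contaminant model with slope fixed at -1 and the non-contaminant
    model with slope 0.  The residual-sum-of-squares ratio SS_contam /
    SS_noncontam is referred to an F(m-1, m-1) distribution (lower tail), so
    small scores favour the contaminant model.  Features present in fewer
    than ``min_samples`` usable samples are marked not evaluable and never
    flagged.
    """
    _require_kind(t, "counts")
    conc = np.asarray(
        pd.Series(dna_conc).reindex(t.sample_ids).to_numpy()
        if isinstance(dna_conc, (pd.Series, dict)) else dna_conc,
        dtype=float,
    )
    if conc.shape[0] != t.shape[1]:
        raise ValueError("dna_conc length does not match sample count")
    vals = t.values()
    depths = vals.sum(axis=0)
    usable = (conc > 0) & ~np.isnan(conc) & (depths > 0)
    rows = []
    for f in range(vals.shape[0]):
        present = usable & (vals[f] > 0)
        m = int(present.sum())
        if m < min_samples:
            rows.append((np.nan, np.nan, m, False, False))
            continue
        y = np.log10(vals[f, present] / depths[present])
        x = np.log10(conc[present])
        ss_contam = np.sum((y + x - np.mean(y + x)) ** 2)
        ss_non = np.sum((y - np.mean(y)) ** 2)
        if ss_non == 0 and ss_contam == 0:
            score, slope = 1.0, 0.0
        else:
            ratio = ss_contam / ss_non if ss_non > 0 else np.inf
            score = float(scipy.stats.f.cdf(ratio, m - 1, m - 1))
            slope = float(np.polyfit(x, y, 1)[0]) if np.ptp(x) > 0 else np.nan
        rows.append((score, slope, m, True, score < threshold))
    table = pd.DataFrame(
        rows,
        index=pd.Index(t.feature_ids, name="feature_id"),
        columns=["score", "slope", "n_samples_used", "evaluable", "flagged"],
    )
    return ContaminantReport(table=table, threshold=threshold)
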