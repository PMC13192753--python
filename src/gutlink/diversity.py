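"""Rarefaction-averaged alpha diversity and beta-diversity distance matrices.

Alpha metrics: species richness, Shannon (natural log), Simpson (1 - sum p^2),
Fisher's alpha, and Faith's phylogenetic diversity (path to the root
included).  Beta metrics: Bray-Curtis, Aitchison (Euclidean distance of CLR
vectors with a pseudocount), and unweighted / weighted-normalized UniFrac.
Metric computations are delegated to scikit-bio; rarefaction is an exact
without-replacement subsample drawn via the multivariate hypergeometric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.spatial.distance as ssd
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import faith_pd, fisher_alpha, shannon, simpson, sobs

from .containers import FeatureTable
from .prep import clr, tss

__all__ = [
    "ALPHA_METRICS",
    "BETA_METRICS",
    "AlphaResult",
    "read_tree",
    "rarefy",
    "alpha_diversity",
    "rarefied_alpha",
    "beta_distance",
]

ALPHA_METRICS = ("richness", "shannon", "simpson", "fisher_alpha", "faith_pd")
BETA_METRICS = ("bray_curtis", "aitchison", "unweighted_unifrac", "weighted_unifrac")


def read_tree(source) -> TreeNode:
    """Parse a rooted newick tree from a string, path, or TreeNode."""
    if isinstance(source, TreeNode):
        return source
    if isinstance(source, str) and source.lstrip().startswith("("):
        return TreeNode.read([source])
    return TreeNode.read(str(source))


def _check_tree(tree: TreeNode, feature_ids) -> None:
    tips = {t.name for t in tree.tips()}
    missing = [f for f in feature_ids if f not in tips]
    if missing:
        raise ValueError(f"tree is missing tips for features: {missing[:10]}")


def rarefy(t: FeatureTable, depth: int, seed=None) -> FeatureTable:
    """Subsample each sample column to exactly ``depth`` reads without
    replacement."""
    if t.kind != "counts":
        raise ValueError("rarefaction requires a counts table")
    if depth < 1:
        raise ValueError("depth must be a positive integer")
    vals = t.values().astype(np.int64)
    sums = vals.sum(axis=0)
    short = np.flatnonzero(sums < depth)
    if short.size:
        names = [t.sample_ids[i] for i in short]
        raise ValueError(f"samples below rarefaction depth {depth}: {names}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(vals[:, j], depth)
    return FeatureTable(pd.DataFrame(out, index=t.data.index, columns=t.data.columns),
                        "counts", validate=False)


def alpha_diversity(t: FeatureTable, metric: str, tree: TreeNode | str | None = None) -> pd.Series:
    """Single-draw per-sample alpha diversity (no rarefaction)."""
    if metric not in ALPHA_METRICS:
        raise ValueError(f"unknown alpha metric {metric!r}; choose from {ALPHA_METRICS}")
    if t.kind != "counts":
        raise ValueError("alpha diversity requires a counts table")
    if metric == "faith_pd":
        if tree is None:
            raise ValueError("faith_pd requires a rooted tree")
        tree = read_tree(tree)
        _check_tree(tree, t.feature_ids)
    vals = t.values().astype(np.int64)
    out = np.empty(vals.shape[1])
    for j in range(vals.shape[1]):
        counts = vals[:, j]
        if metric == "richness":
            out[j] = sobs(counts)
        elif metric == "shannon":
            out[j] = shannon(counts, base=np.e)
        elif metric == "simpson":
            out[j] = simpson(counts)
        elif metric == "fisher_alpha":
            out[j] = fisher_alpha(counts)
        else:  # faith_pd
            out[j] = faith_pd(counts, taxa=t.feature_ids, tree=tree,
                              validate=(j == 0))
    return pd.Series(out, index=t.sample_ids, name=metric)


@dataclass
class AlphaResult:
    """Mean alpha diversity over repeated rarefactions."""

    values: pd.Series  # per sample mean
    metric: str
    depth: int
    n_iterations: int


def rarefied_alpha(
    t: FeatureTable,
    depth: int,
    metric: str,
    n_iter: int = 1000,
    seed=None,
    tree: TreeNode | str | None = None,
) -> AlphaResult:
    """Mean alpha diversity over ``n_iter`` independent rarefactions.

    Deterministic for a fixed seed; with depth equal to every sample's total
    the rarefied table is the input, so the mean equals the single draw.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be positive")
    rng = np.random.default_rng(seed)
    acc = None
    for _ in range(n_iter):
        sub = rarefy(t, depth, seed=rng)
        vals = alpha_diversity(sub, metric, tree=tree)
        acc = vals if acc is None else acc + vals
    return AlphaResult(values=acc / n_iter, metric=metric, depth=depth,
                       n_iterations=n_iter)


def beta_distance(
    t: FeatureTable,
    metric: str,
    tree: TreeNode | str | None = None,
    pseudocount: float = 1e-6,
) -> DistanceMatrix:
    """Pairwise sample dissimilarity under the chosen metric.

    Counts are total-sum scaled internally; UniFrac metrics need the rooted
    tree, and weighted UniFrac is the normalized (bounded) variant.
    """
    if metric not in BETA_METRICS:
        raise ValueError(f"unknown beta metric {metric!r}; choose from {BETA_METRICS}")
    if metric == "aitchison":
        mat = clr(t, pseudocount=pseudocount).values().T  # samples x features
        dm = DistanceMatrix(ssd.squareform(ssd.pdist(mat, "euclidean")), ids=t.sample_ids)
        return dm
    rel = tss(t) if t.kind == "counts" else t
    if metric == "bray_curtis":
        return beta_diversity("braycurtis", rel.values().T, ids=t.sample_ids)
    tree = read_tree(tree) if tree is not None else None
    if tree is None:
        raise ValueError(f"{metric} requires a rooted tree")
    _check_tree(tree, t.feature_ids)
    # UniFrac is invariant to per-sample scaling but requires integer counts;
    # scale relative abundances up before rounding to preserve rare features
    if t.kind == "counts":
        counts = t.values().T.astype(np.int64)
    else:
        counts = np.round(rel.values().T * 1e9).astype(np.int64)
    if metric == "unweighted_unifrac":
        return beta_diversity("unweighted_unifrac", counts, ids=t.sample_ids,
                              taxa=t.feature_ids, tree=tree)
    return beta_diversity("weighted_unifrac", counts, ids=t.sample_ids,
                          taxa=t.feature_ids, tree=tree, normalized=True)


def write_distance_tsv(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).rename_axis("sample_id").to_csv(
        path, sep="\t")
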