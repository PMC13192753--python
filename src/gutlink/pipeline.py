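"""End-to-end orchestration of the three-level integration analysis.

``run_intestine_wide`` executes, on the samples shared by both modalities:
contaminant removal and prevalence filtering of taxa, CLR transform, gene
filtering and log-CPM, mixed-model covariate residualization (location as a
fixed effect intestine-wide), gene variance filtering, then the three
levels — Procrustes concordance on covariate-corrected PCoA of Aitchison
distances, sparse CCA with LOOCV penalty tuning and component significance,
per-microbe elastic nets — plus optional ORA of significant-component genes.
``run_per_region`` splits samples by intestinal location before any
transformation and runs the same battery per region.

Every run writes its intermediate tables and a machine-readable manifest
(parameters, derived seeds, package version, completed stages) sufficient to
reproduce the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import FeatureTable, SampleFrame
from .covariates import CovariateDesign, lmm_residualize
from .concordance import pcoa, procrustes_permutation_test
from .diversity import beta_distance, read_tree
from .enrichment import ora, read_gmt
from .genemicrobe import extract_pairs, fit_elastic_net
from .prep import (clr, filter_genes, filter_taxa_prevalence,
                   frequency_contaminant_score, log_cpm, variance_filter)
from .scca import component_significance_loocv, fit_sparse_cca, tune_penalties_loocv
from .synthetic import read_fixture

__all__ = ["PipelineConfig", "run_intestine_wide", "run_per_region"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs, thresholds and seeds of one pipeline run."""

    # inputs (paths, or leave None and pass in-memory objects to the runners)
    taxa_table: str | None = None
    expression_table: str | None = None
    metadata: str | None = None
    tree: str | None = None
    gene_sets: str | None = None
    output_dir: str = "gutlink_out"
    # metadata columns
    covariates: tuple = ("sex", "age")
    region_column: str = "region"
    patient_column: str = "patient"
    # filters and transforms
    min_rel_abund: float = 1e-4
    min_taxa_sample_frac: float = 0.10
    min_gene_count: int = 10
    min_gene_sample_frac: float = 0.33
    variance_quantile: float = 0.25
    clr_pseudocount: float = 1e-6
    contaminant_threshold: float = 0.1
    remove_contaminants: bool = True
    # concordance
    n_perm: int = 99_999
    # sparse CCA
    scca_grid: tuple = ((0.2, 0.2), (0.2, 0.6), (0.6, 0.2), (0.6, 0.6), (1.0, 1.0))
    scca_k: int = 10
    scca_alpha: float = 0.1
    # elastic net
    enet_alpha_grid: tuple = (0.1, 0.55, 1.0)
    enet_n_lambda: int = 50
    enet_folds: int = 5
    enet_repeats: int = 2
    # enrichment
    ora_min_size: int = 10
    ora_alpha: float = 0.1
    # optional diversity stage
    alpha_metrics: tuple = ()
    beta_metrics: tuple = ()
    rarefaction_depth: int | None = None
    rarefaction_iters: int = 1000
    seed: int = 0

    def validate(self, have_tree: bool) -> None:
        phylo = [m for m in tuple(self.alpha_metrics) + tuple(self.beta_metrics)
                 if "unifrac" in m or m == "faith_pd"]
        if phylo and not have_tree:
            raise ValueError(f"metrics {phylo} require a rooted tree, "
                             "but no tree was provided")
        needs_depth = [m for m in self.alpha_metrics]
        if needs_depth and self.rarefaction_depth is None:
            raise ValueError("alpha_metrics requested without rarefaction_depth")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("scca_grid",):
            if key in raw:
                raw[key] = tuple(tuple(x) for x in raw[key])
        for key in ("covariates", "enet_alpha_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def derived_seeds(self) -> dict[str, int]:
        """Stage seeds derived deterministically from the master seed."""
        ss = np.random.SeedSequence(self.seed)
        names = ("procrustes", "enet", "rarefaction")
        children = ss.spawn(len(names))
        return {name: int(child.generate_state(1)[0] % (2 ** 31))
                for name, child in zip(names, children)}


def _load_inputs(config: PipelineConfig, microbiome=None, expression=None,
                 samples=None, tree=None):
    if microbiome is None:
        if config.taxa_table is None:
            raise ValueError("no taxon table provided (path or in-memory)")
        microbiome = FeatureTable.from_tsv(config.taxa_table)
    if expression is None:
        if config.expression_table is None:
            raise ValueError("no expression table provided (path or in-memory)")
        expression = FeatureTable.from_tsv(config.expression_table)
    if samples is None:
        if config.metadata is None:
            raise ValueError("no metadata provided (path or in-memory)")
        samples = SampleFrame.from_tsv(config.metadata)
    if tree is None and config.tree is not None:
        tree = read_tree(config.tree)
    return microbiome, expression, samples, tree


def _design(samples: SampleFrame, sample_ids, config: PipelineConfig,
            include_location: bool) -> CovariateDesign:
    meta = samples.align(sample_ids).data
    fixed = pd.get_dummies(meta[list(config.covariates)], drop_first=True,
                           dtype=float)
    if include_location:
        loc = pd.get_dummies(meta[config.region_column], prefix="region",
                             drop_first=True, dtype=float)
        fixed = pd.concat([fixed, loc], axis=1)
    return CovariateDesign(fixed=fixed, groups=meta[config.patient_column].astype(str))


def _residualize_ordination(ordination, design: CovariateDesign):
    """Regress covariates out of each PCoA axis (axes as features)."""
    coords = FeatureTable(
        pd.DataFrame(ordination.coordinates.T,
                     index=[f"PCo{i + 1}" for i in range(ordination.n_axes)],
                     columns=ordination.sample_ids),
        "residual", validate=False)
    resid = lmm_residualize(coords, design)
    from .containers import Ordination
    return Ordination(sample_ids=ordination.sample_ids,
                      coordinates=resid.values().T)


def _analyze(microbiome: FeatureTable, expression: FeatureTable,
             samples: SampleFrame, config: PipelineConfig, seeds: dict,
             include_location: bool, outdir: str, label: str,
             tree=None) -> dict:
    """The shared three-level battery on one sample set."""
    os.makedirs(outdir, exist_ok=True)
    stages = []
    results: dict = {"label": label, "stages": stages}
    ids = microbiome.sample_ids

    # -- optional diversity summaries -------------------------------------
    if config.alpha_metrics or config.beta_metrics:
        from .diversity import rarefied_alpha, write_distance_tsv
        for metric in config.alpha_metrics:
            res = rarefied_alpha(microbiome, config.rarefaction_depth, metric,
                                 n_iter=config.rarefaction_iters,
                                 seed=seeds["rarefaction"], tree=tree)
            res.values.to_csv(os.path.join(outdir, f"alpha_{metric}.tsv"), sep="\t")
        for metric in config.beta_metrics:
            dm = beta_distance(microbiome, metric, tree=tree,
                               pseudocount=config.clr_pseudocount)
            write_distance_tsv(dm, os.path.join(outdir, f"beta_{metric}.tsv"))
        stages.append("diversity")

    # -- taxa: contaminants -> prevalence -> CLR -> residualize ----------
    meta = samples.align(ids).data
    if config.remove_contaminants and "dna_conc" in meta.columns:
        report = frequency_contaminant_score(
            microbiome, meta["dna_conc"], threshold=config.contaminant_threshold)
        report.table.to_csv(os.path.join(outdir, "contaminant_scores.tsv"), sep="\t")
        keep = [f for f in microbiome.feature_ids if f not in set(report.flagged_ids)]
        microbiome = microbiome.select_features(keep)
        results["n_contaminants_removed"] = len(report.flagged_ids)
        stages.append("decontaminate")
    taxa = filter_taxa_prevalence(microbiome, config.min_rel_abund,
                                  config.min_taxa_sample_frac)
    taxa_clr = clr(taxa, pseudocount=config.clr_pseudocount)
    design = _design(samples, ids, config, include_location)
    taxa_resid = lmm_residualize(taxa_clr, design)
    taxa_resid.to_tsv(os.path.join(outdir, "taxa_clr_residual.tsv"))
    results["n_taxa"] = taxa.shape[0]
    stages += ["taxa_filter", "taxa_clr", "taxa_residualize"]

    # -- genes: filter -> log-CPM -> residualize -> variance filter ------
    genes = filter_genes(expression, config.min_gene_count,
                         config.min_gene_sample_frac)
    genes_lcpm = log_cpm(genes)
    genes_resid = lmm_residualize(genes_lcpm, design)
    genes_resid = variance_filter(genes_resid, config.variance_quantile)
    genes_resid.to_tsv(os.path.join(outdir, "genes_residual.tsv"))
    results["n_genes"] = genes_resid.shape[0]
    stages += ["gene_filter", "gene_log_cpm", "gene_residualize",
               "gene_variance_filter"]

    # -- global: Aitchison -> PCoA -> covariate-correct -> Procrustes ----
    d_taxa = beta_distance(microbiome.select_samples(ids), "aitchison",
                           pseudocount=config.clr_pseudocount)
    ex_vals = genes_resid.values().T
    from skbio import DistanceMatrix
    import scipy.spatial.distance as ssd
    d_genes = DistanceMatrix(ssd.squareform(ssd.pdist(ex_vals, "euclidean")),
                             ids=ids)
    ord_taxa = _residualize_ordination(pcoa(d_taxa), design)
    ord_genes = pcoa(d_genes)
    proc = procrustes_permutation_test(ord_genes, ord_taxa,
                                       n_perm=config.n_perm,
                                       seed=seeds["procrustes"])
    results["procrustes"] = {"rho": proc.rho, "p_value": proc.p_value,
                             "n_permutations": proc.n_permutations}
    stages.append("procrustes")

    # -- group-group: sparse CCA -----------------------------------------
    X = genes_resid.data.T  # samples x genes
    Z = taxa_resid.data.T
    (c1, c2), grid_scores = tune_penalties_loocv(X, Z, grid=config.scca_grid)
    grid_scores.to_csv(os.path.join(outdir, "scca_grid.tsv"), sep="\t", index=False)
    K = min(config.scca_k, X.shape[1], Z.shape[1])
    model = fit_sparse_cca(X, Z, c1, c2, K=K)
    model.to_tsv(os.path.join(outdir, "scca_loadings.tsv"))
    sig = component_significance_loocv(X, Z, c1, c2, K=K, alpha=config.scca_alpha)
    sig.table.to_csv(os.path.join(outdir, "scca_significance.tsv"), sep="\t",
                     index=False)
    results["scca"] = {"c1_frac": c1, "c2_frac": c2,
                       "significant_components": sig.flagged_components}
    stages.append("sparse_cca")

    # -- individual: per-microbe elastic nets -----------------------------
    rng = np.random.default_rng(seeds["enet"])
    fits = []
    for microbe in Z.columns:
        try:
            fit = fit_elastic_net(
                Z[microbe].to_numpy(), X,
                alpha_grid=config.enet_alpha_grid,
                n_lambda=config.enet_n_lambda,
                folds=config.enet_folds, repeats=config.enet_repeats,
                seed=int(rng.integers(2 ** 31)), microbe_id=microbe)
        except ValueError as err:
            logger.warning("skipping microbe %s: %s", microbe, err)
            continue
        fits.append(fit)
    pairs = extract_pairs(fits, X=X, Y=Z, region=label)
    pairs.to_csv(os.path.join(outdir, "gene_microbe_pairs.tsv"), sep="\t",
                 index=False)
    results["n_pairs"] = len(pairs)
    results["n_pair_genes"] = pairs["gene"].nunique() if len(pairs) else 0
    results["n_pair_microbes"] = pairs["microbe"].nunique() if len(pairs) else 0
    stages.append("elastic_net")

    # -- enrichment of significant-component genes ------------------------
    if config.gene_sets:
        collection = read_gmt(config.gene_sets)
        universe = list(X.columns)
        tables = []
        for k in sig.flagged_components:
            query = model.gene_support(k)
            if not query:
                continue
            res = ora([g for g in query if g in set(universe)], universe,
                      collection, min_size=config.ora_min_size,
                      alpha=config.ora_alpha)
            tbl = res.table.assign(component=k)
            tables.append(tbl)
        if tables:
            enrich = pd.concat(tables, ignore_index=True)
            enrich["members"] = enrich["members"].map(lambda m: ",".join(m))
            enrich.to_csv(os.path.join(outdir, "enrichment.tsv"), sep="\t",
                          index=False)
            results["n_enriched"] = int(enrich["flagged"].sum())
        stages.append("enrichment")
    return results


def run_intestine_wide(config: PipelineConfig, microbiome=None, expression=None,
                       samples=None, tree=None) -> dict:
    """Cross-location analysis: location enters the model as a fixed effect."""
    microbiome, expression, samples, tree = _load_inputs(
        config, microbiome, expression, samples, tree)
    shared = [s for s in samples.real_samples()
              if s in set(microbiome.sample_ids) and s in set(expression.sample_ids)]
    if not shared:
        raise ValueError("no overlapping samples between modalities")
    config.validate(have_tree=tree is not None)
    seeds = config.derived_seeds()
    outdir = os.path.join(config.output_dir, "intestine_wide")
    results = _analyze(microbiome.select_samples(shared),
                       expression.select_samples(shared),
                       samples, config, seeds, include_location=True,
                       outdir=outdir, label="intestine_wide", tree=tree)
    manifest = {
        "analysis": "intestine_wide",
        "gutlink_version": __version__,
        "config": _config_dict(config),
        "seeds": seeds,
        "n_samples": len(shared),
        "results": results,
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def run_per_region(config: PipelineConfig, microbiome=None, expression=None,
                   samples=None, tree=None) -> dict:
    """Within-region analyses: samples split before any transformation."""
    microbiome, expression, samples, tree = _load_inputs(
        config, microbiome, expression, samples, tree)
    shared = [s for s in samples.real_samples()
              if s in set(microbiome.sample_ids) and s in set(expression.sample_ids)]
    if not shared:
        raise ValueError("no overlapping samples between modalities")
    config.validate(have_tree=tree is not None)
    meta = samples.align(shared).data
    seeds = config.derived_seeds()
    bundles = {}
    for region, sub in meta.groupby(config.region_column, sort=True):
        ids = sub.index.tolist()
        if len(ids) < 3:
            logger.warning("skipping region %s: only %d samples", region, len(ids))
            continue
        outdir = os.path.join(config.output_dir, f"region_{region}")
        bundles[str(region)] = _analyze(
            microbiome.select_samples(ids), expression.select_samples(ids),
            samples, config, seeds, include_location=False,
            outdir=outdir, label=str(region), tree=tree)
    manifest = {
        "analysis": "per_region",
        "gutlink_version": __version__,
        "config": _config_dict(config),
        "seeds": seeds,
        "regions": bundles,
    }
    with open(os.path.join(config.output_dir, "per_region_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(list(x) if isinstance(x, tuple) else x for x in v)
    return d


def load_cohort_dir(directory):
    """Read a fixture directory written by :func:`gutlink.synthetic.write_fixture`."""
    return read_fixture(directory)
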