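"""Seeded synthetic paired microbiome/transcriptome cohorts with known truth.

The generator emulates the structure of a multi-region surgical cohort:
genus-level compositional counts and negative-binomial gene counts linked by
shared sparse latent factors, sparse direct gene-to-microbe effects, fixed
covariates with patient-level random intercepts, inverse-DNA-concentration
contaminant taxa, and negative-control samples that carry only contaminant
signal.  Every downstream stage of the pipeline therefore has a planted
recovery target.

The model, per sample i:

* gene g:   count ~ NB(depth_i * softmax_g(eta),  dispersion)
            eta_gi = b_g + sum_l U_gl f_li + covariates + patient offset
* taxon t:  counts ~ Multinomial(depth_i, softmax_t(theta))
            theta_ti = b_t + sum_l V_tl f_li + covariates + patient offset
                       + sum_pairs beta * w (direct effects)
* contaminant taxon: theta_ti = c_t - log(DNA concentration_i)

Factor scores f and direct-pair latents w are standard normal; loadings
outside the sparse supports are exactly zero.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .containers import FeatureTable, SampleFrame

__all__ = [
    "SynthConfig",
    "SyntheticTruth",
    "Cohort",
    "generate_cohort",
    "write_fixture",
    "read_fixture",
]


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of a synthetic paired cohort.

    Defaults give a desk-scale cohort: three intestinal regions of 30
    samples each from 45 patients (so most patients contribute two
    regions), 500 genes, 80 genera, two shared latent factors and ten
    direct gene-to-microbe effects.
    """

    n_samples_per_region: int = 30
    n_regions: int = 3
    n_patients: int = 45
    n_genes: int = 500
    n_taxa: int = 80
    n_latent_factors: int = 2
    factor_gene_sparsity: float = 0.04
    factor_taxon_sparsity: float = 0.10
    n_direct_pairs: int = 10
    effect_size_direct: float = 2.0
    nb_dispersion: float = 0.3
    sequencing_depth_mean: int = 20_000
    expression_depth_mean: int = 100_000
    n_contaminants: int = 10
    n_negative_controls: int = 3
    covariate_spec: tuple = (("sex", "binary", 0.5), ("age", "continuous", 0.3))
    patient_sd: float = 0.5
    region_effect_sd: float = 0.5
    factor_loading_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        pos = {
            "n_samples_per_region": self.n_samples_per_region,
            "n_regions": self.n_regions,
            "n_patients": self.n_patients,
            "n_genes": self.n_genes,
            "n_taxa": self.n_taxa,
            "nb_dispersion": self.nb_dispersion,
            "sequencing_depth_mean": self.sequencing_depth_mean,
            "expression_depth_mean": self.expression_depth_mean,
        }
        for name, val in pos.items():
            if val <= 0:
                raise ValueError(f"{name} must be positive, got {val}")
        nonneg = {
            "n_latent_factors": self.n_latent_factors,
            "n_direct_pairs": self.n_direct_pairs,
            "n_contaminants": self.n_contaminants,
            "n_negative_controls": self.n_negative_controls,
            "patient_sd": self.patient_sd,
        }
        for name, val in nonneg.items():
            if val < 0:
                raise ValueError(f"{name} must be non-negative, got {val}")
        for name in ("factor_gene_sparsity", "factor_taxon_sparsity"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.n_patients > self.n_total_samples:
            raise ValueError(
                f"n_patients ({self.n_patients}) exceeds total samples "
                f"({self.n_total_samples})"
            )
        if self.n_direct_pairs > self.n_genes * self.n_taxa:
            raise ValueError("n_direct_pairs exceeds n_genes * n_taxa")
        if self.n_contaminants >= self.n_taxa:
            raise ValueError("n_contaminants must be smaller than n_taxa")

    @property
    def n_total_samples(self) -> int:
        return self.n_samples_per_region * self.n_regions


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort."""

    factor_gene_support: list = field(default_factory=list)  # list of id lists
    factor_taxon_support: list = field(default_factory=list)
    direct_pairs: list = field(default_factory=list)  # (gene_id, taxon_id, coef)
    contaminant_ids: list = field(default_factory=list)
    covariate_effects: dict = field(default_factory=dict)  # modality -> DataFrame
    patient_offsets: dict = field(default_factory=dict)  # modality -> Series
    factor_gene_loadings: pd.DataFrame | None = None  # genes x factors
    factor_taxon_loadings: pd.DataFrame | None = None  # taxa x factors
    factor_scores: pd.DataFrame | None = None  # samples x factors
    gene_signal: pd.DataFrame | None = None  # latent log-mean, genes x samples
    taxon_logits: pd.DataFrame | None = None  # latent logits, taxa x samples


class Cohort(NamedTuple):
    microbiome: FeatureTable
    expression: FeatureTable
    samples: SampleFrame
    tree: str  # rooted newick with branch lengths
    truth: SyntheticTruth


def _random_rooted_tree(taxa: list[str], rng: np.random.Generator) -> str:
    """Random bifurcating rooted tree over ``taxa`` via coalescent-style joins,
    exponential branch lengths."""
    nodes = list(taxa)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b1, b2 = rng.exponential(1.0, size=2) + 1e-3
        merged = f"({nodes[i]}:{b1:.6f},{nodes[j]}:{b2:.6f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0] + ";"


def generate_cohort(config: SynthConfig) -> Cohort:
    """Draw one cohort. Identical config (including seed) gives identical output."""
    rng = np.random.default_rng(config.seed)
    n = config.n_total_samples
    gene_ids = [f"gene{g:05d}" for g in range(config.n_genes)]
    taxon_ids = [f"taxon{t:03d}" for t in range(config.n_taxa)]
    sample_ids = [f"S{i:03d}" for i in range(n)]
    regions = np.repeat([f"region{r + 1}" for r in range(config.n_regions)],
                        config.n_samples_per_region)
    patients = np.array([f"P{i % config.n_patients:03d}" for i in range(n)])

    # --- metadata -------------------------------------------------------
    pat_ids = sorted(set(patients))
    cov_cols: dict[str, np.ndarray] = {}
    for name, ctype, _scale in config.covariate_spec:
        if ctype == "binary":
            per_pat = rng.integers(0, 2, size=len(pat_ids)).astype(float)
        elif ctype == "continuous":
            per_pat = rng.standard_normal(len(pat_ids))
        else:
            raise ValueError(f"unknown covariate type {ctype!r}")
        lookup = dict(zip(pat_ids, per_pat))
        cov_cols[name] = np.array([lookup[p] for p in patients])
    dna_conc = rng.lognormal(mean=np.log(10.0), sigma=1.0, size=n)

    # --- latent structure ----------------------------------------------
    L = config.n_latent_factors
    F = rng.standard_normal((n, L)) if L else np.zeros((n, 0))
    k_g = max(1, round(config.factor_gene_sparsity * config.n_genes)) if L else 0
    k_t = max(1, round(config.factor_taxon_sparsity * config.n_taxa)) if L else 0
    gene_perm = rng.permutation(config.n_genes)
    taxon_perm = rng.permutation(config.n_taxa)
    U = np.zeros((config.n_genes, L))
    V = np.zeros((config.n_taxa, L))
    gene_support, taxon_support = [], []
    for l in range(L):
        gs = gene_perm[l * k_g:(l + 1) * k_g]
        ts = taxon_perm[l * k_t:(l + 1) * k_t]
        if len(gs) < k_g or len(ts) < k_t:
            raise ValueError("factor supports exceed available features; "
                             "reduce n_latent_factors or sparsity")
        scale = config.factor_loading_scale
        U[gs, l] = rng.choice([-1.0, 1.0], size=len(gs)) * rng.uniform(0.75, 1.25, len(gs)) * scale
        V[ts, l] = rng.choice([-1.0, 1.0], size=len(ts)) * rng.uniform(0.75, 1.25, len(ts)) * scale
        gene_support.append([gene_ids[g] for g in gs])
        taxon_support.append([taxon_ids[t] for t in ts])

    # contaminants and direct pairs drawn from features outside factor supports
    free_genes = gene_perm[L * k_g:]
    free_taxa = taxon_perm[L * k_t:]
    if config.n_contaminants + config.n_direct_pairs > len(free_taxa):
        raise ValueError("not enough taxa outside factor supports for "
                         "contaminants plus direct pairs")
    contam_idx = free_taxa[:config.n_contaminants]
    pair_taxa = free_taxa[config.n_contaminants:
                          config.n_contaminants + config.n_direct_pairs]
    pair_genes = free_genes[:config.n_direct_pairs]
    if len(pair_genes) < config.n_direct_pairs:
        raise ValueError("not enough genes outside factor supports for direct pairs")

    # --- fixed and random effects ---------------------------------------
    cov_names = [c[0] for c in config.covariate_spec]
    cov_mat = np.column_stack([cov_cols[c] for c in cov_names]) if cov_names else np.zeros((n, 0))
    B_gene = np.zeros((config.n_genes, len(cov_names)))
    B_taxon = np.zeros((config.n_taxa, len(cov_names)))
    for j, (_, _, scale) in enumerate(config.covariate_spec):
        hit_g = rng.random(config.n_genes) < 0.10
        hit_t = rng.random(config.n_taxa) < 0.10
        B_gene[hit_g, j] = rng.normal(0, scale, hit_g.sum())
        B_taxon[hit_t, j] = rng.normal(0, scale, hit_t.sum())
    pat_off_gene = rng.normal(0, config.patient_sd, len(pat_ids))
    pat_off_taxon = rng.normal(0, config.patient_sd, len(pat_ids))
    off_g = np.array([pat_off_gene[pat_ids.index(p)] for p in patients])
    off_t = np.array([pat_off_taxon[pat_ids.index(p)] for p in patients])
    region_codes = pd.Categorical(regions).codes
    reg_shift_gene = rng.normal(0, config.region_effect_sd,
                                (config.n_genes, config.n_regions))
    reg_shift_taxon = rng.normal(0, config.region_effect_sd,
                                 (config.n_taxa, config.n_regions))

    # --- gene latent log-means ------------------------------------------
    b_g = rng.normal(0.0, 1.0, config.n_genes)
    eta_gene = (b_g[:, None]
                + U @ F.T
                + B_gene @ cov_mat.T
                + reg_shift_gene[:, region_codes]
                + off_g[None, :])

    # direct pairs: a shared standard-normal latent drives the gene with
    # unit loading and the taxon logit with loading beta
    direct_pairs = []
    theta_direct = np.zeros((config.n_taxa, n))
    for g_idx, t_idx in zip(pair_genes, pair_taxa):
        w = rng.standard_normal(n)
        beta = config.effect_size_direct * rng.choice([-1.0, 1.0])
        eta_gene[g_idx] += w
        theta_direct[t_idx] += beta * w
        direct_pairs.append((gene_ids[g_idx], taxon_ids[t_idx], float(beta)))

    # --- taxon logits ----------------------------------------------------
    b_t = rng.normal(0.0, 1.5, config.n_taxa)
    theta = (b_t[:, None]
             + V @ F.T
             + B_taxon @ cov_mat.T
             + reg_shift_taxon[:, region_codes]
             + off_t[None, :]
             + theta_direct)
    # contaminant expected abundance proportional to 1 / DNA concentration
    c_t = rng.normal(0.0, 0.5, config.n_contaminants)
    theta[contam_idx, :] = c_t[:, None] - np.log(dna_conc)[None, :]

    # --- draw counts -----------------------------------------------------
    gene_depths = rng.lognormal(np.log(config.expression_depth_mean), 0.3, n)
    p_gene = np.exp(eta_gene - eta_gene.max(axis=0, keepdims=True))
    p_gene /= p_gene.sum(axis=0, keepdims=True)
    mu = p_gene * gene_depths[None, :]
    # gamma-Poisson mixture: var = mu + dispersion * mu^2
    shape = 1.0 / config.nb_dispersion
    lam = rng.gamma(shape, mu / shape)
    gene_counts = rng.poisson(lam)

    taxa_depths = np.round(
        rng.lognormal(np.log(config.sequencing_depth_mean), 0.5, n)
    ).astype(np.int64)
    p_taxa = np.exp(theta - theta.max(axis=0, keepdims=True))
    p_taxa /= p_taxa.sum(axis=0, keepdims=True)
    taxa_counts = np.column_stack(
        [rng.multinomial(taxa_depths[i], p_taxa[:, i]) for i in range(n)]
    )

    # --- negative controls ----------------------------------------------
    nc = config.n_negative_controls
    all_sample_ids = list(sample_ids)
    if nc:
        nc_ids = [f"NC{i + 1:02d}" for i in range(nc)]
        nc_conc = rng.lognormal(np.log(0.1), 0.5, nc)
        nc_counts = np.zeros((config.n_taxa, nc), dtype=np.int64)
        if config.n_contaminants:
            p_nc = np.exp(c_t - c_t.max())
            p_nc /= p_nc.sum()
            nc_depths = np.round(
                rng.lognormal(np.log(config.sequencing_depth_mean * 0.02), 0.5, nc)
            ).astype(np.int64)
            for i in range(nc):
                nc_counts[contam_idx, i] = rng.multinomial(nc_depths[i], p_nc)
        taxa_counts = np.column_stack([taxa_counts, nc_counts])
        all_sample_ids += nc_ids
        dna_conc = np.concatenate([dna_conc, nc_conc])

    meta = pd.DataFrame(
        {
            "patient": list(patients) + [f"CTRL{i + 1}" for i in range(nc)],
            "region": list(regions) + ["control"] * nc,
            "dna_conc": dna_conc,
            "is_control": [False] * n + [True] * nc,
            **{c: list(cov_cols[c]) + [np.nan] * nc for c in cov_names},
        },
        index=pd.Index(all_sample_ids, name="sample_id"),
    )

    truth = SyntheticTruth(
        factor_gene_support=gene_support,
        factor_taxon_support=taxon_support,
        direct_pairs=direct_pairs,
        contaminant_ids=[taxon_ids[t] for t in contam_idx],
        covariate_effects={
            "expression": pd.DataFrame(B_gene, index=gene_ids, columns=cov_names),
            "microbiome": pd.DataFrame(B_taxon, index=taxon_ids, columns=cov_names),
        },
        patient_offsets={
            "expression": pd.Series(pat_off_gene, index=pat_ids),
            "microbiome": pd.Series(pat_off_taxon, index=pat_ids),
        },
        factor_gene_loadings=pd.DataFrame(
            U, index=gene_ids, columns=[f"factor{l + 1}" for l in range(L)]
        ),
        factor_taxon_loadings=pd.DataFrame(
            V, index=taxon_ids, columns=[f"factor{l + 1}" for l in range(L)]
        ),
        factor_scores=pd.DataFrame(
            F, index=sample_ids, columns=[f"factor{l + 1}" for l in range(L)]
        ),
        gene_signal=pd.DataFrame(eta_gene, index=gene_ids, columns=sample_ids),
        taxon_logits=pd.DataFrame(theta, index=taxon_ids, columns=sample_ids),
    )

    microbiome = FeatureTable(
        pd.DataFrame(taxa_counts, index=taxon_ids, columns=all_sample_ids), "counts"
    )
    expression = FeatureTable(
        pd.DataFrame(gene_counts, index=gene_ids, columns=sample_ids), "counts"
    )
    tree = _random_rooted_tree(taxon_ids, np.random.default_rng(config.seed + 1))
    return Cohort(microbiome, expression, SampleFrame(meta), tree, truth)


def write_fixture(cohort: Cohort, directory: str | os.PathLike) -> dict[str, str]:
    """Write a cohort to plain-text files; returns the paths written.

    Emits TSV count tables (features as rows), a metadata TSV keyed on
    sample id, the newick tree, and the ground truth (direct pairs and
    contaminant ids as TSV triples, factor supports one line per factor).
    """
    directory = os.fspath(directory)
    if not directory:
        raise IOError("empty fixture directory")
    os.makedirs(directory, exist_ok=True)
    paths = {
        "microbiome": os.path.join(directory, "taxa_counts.tsv"),
        "expression": os.path.join(directory, "gene_counts.tsv"),
        "metadata": os.path.join(directory, "metadata.tsv"),
        "tree": os.path.join(directory, "tree.nwk"),
        "truth_pairs": os.path.join(directory, "truth_direct_pairs.tsv"),
        "truth_contaminants": os.path.join(directory, "truth_contaminants.tsv"),
        "truth_supports": os.path.join(directory, "truth_factor_supports.tsv"),
    }
    cohort.microbiome.to_tsv(paths["microbiome"])
    cohort.expression.to_tsv(paths["expression"])
    cohort.samples.to_tsv(paths["metadata"])
    with open(paths["tree"], "w") as fh:
        fh.write(cohort.tree + "\n")
    pd.DataFrame(cohort.truth.direct_pairs,
                 columns=["gene_id", "taxon_id", "coefficient"]).to_csv(
        paths["truth_pairs"], sep="\t", index=False)
    pd.DataFrame({"taxon_id": cohort.truth.contaminant_ids}).to_csv(
        paths["truth_contaminants"], sep="\t", index=False)
    rows = []
    for l, (gs, ts) in enumerate(zip(cohort.truth.factor_gene_support,
                                     cohort.truth.factor_taxon_support)):
        rows += [(l + 1, "gene", g) for g in gs] + [(l + 1, "taxon", t) for t in ts]
    pd.DataFrame(rows, columns=["factor", "modality", "feature_id"]).to_csv(
        paths["truth_supports"], sep="\t", index=False)
    return paths


def read_fixture(directory: str | os.PathLike) -> tuple[FeatureTable, FeatureTable, SampleFrame, str]:
    """Read back the observable part of a written fixture (no truth)."""
    directory = os.fspath(directory)
    microbiome = FeatureTable.from_tsv(os.path.join(directory, "taxa_counts.tsv"))
    expression = FeatureTable.from_tsv(os.path.join(directory, "gene_counts.tsv"))
    samples = SampleFrame.from_tsv(os.path.join(directory, "metadata.tsv"))
    with open(os.path.join(directory, "tree.nwk")) as fh:
        tree = fh.read().strip()
    return microbiome, expression, samples, tree
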