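"""Synthetic cohorts with the statistical structure the pipeline assumes.

The expression model is log-normal: per-gene log2 abundances are a gene
baseline plus a cluster-specific offset plus Gaussian noise, exponentiated to
an RPM-like scale. A per-sample miRNA value is induced by cluster membership
(one cluster enriched for high miRNA, one for low, the rest mixed), and a
designated target-gene subset is repressed in miRNA-high samples, so the
downstream stratification, differential expression, subtyping, enrichment and
clinical association stages all have plantable, recoverable signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import PathwayGraph


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator; defaults give a clearly structured cohort.

    Shifts and separations are in log2 units on the pre-exponentiation scale.
    """

    n_samples: int = 120
    n_genes: int = 2000
    k_clusters: int = 3
    n_targets: int = 200
    target_shift: float = 2.0
    cluster_separation: float = 2.0
    frac_informative: float = 0.15  # fraction of genes carrying cluster offsets
    noise_sd: float = 1.0
    mirna_cluster_effect: float = 2.0
    clinical_log_odds: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_clusters < 2:
            raise ValueError("k_clusters must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for name in ("n_samples", "n_genes", "n_targets"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.n_targets > self.n_genes:
            raise ValueError("n_targets cannot exceed n_genes")


@dataclass
class SyntheticCohort:
    expression: pd.DataFrame  # genes x samples, RPM-like non-negative
    mirna: pd.Series  # per-sample, log2 RPM scale
    true_cluster: pd.Series  # per-sample label in 1..k
    target_genes: set[str]
    de_genes_true: set[str]
    clinical: pd.DataFrame
    seed: int
    config: SimulationConfig = field(repr=False, default=None)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one synthetic cohort.

    Cluster 1 plays the miRNA-low ("less") role and cluster 2 the miRNA-high
    ("enriched") role; remaining clusters are miRNA-neutral ("unrelated").
    Target genes receive a -target_shift log2 repression in samples whose
    realized miRNA value lies above the cohort median (miRNA-high samples),
    which is exactly the signal the quantile stratification probes.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    samples = [f"S{i:04d}" for i in range(config.n_samples)]

    # balanced cluster assignment, randomly permuted
    base = np.resize(np.arange(1, config.k_clusters + 1), config.n_samples)
    cluster = rng.permutation(base)

    baseline = rng.normal(5.0, 2.0, size=config.n_genes)
    # cluster structure lives in a signature subset of genes, as real molecular
    # subtypes do; the rest of the transcriptome is cluster-neutral
    offsets = np.zeros((config.n_genes, config.k_clusters))
    n_informative = int(round(config.frac_informative * config.n_genes))
    informative_idx = rng.choice(config.n_genes, size=n_informative, replace=False)
    offsets[informative_idx] = rng.normal(
        0.0, 1.0, size=(n_informative, config.k_clusters)
    ) * config.cluster_separation

    log2_expr = (
        baseline[:, None]
        + offsets[:, cluster - 1]
        + rng.normal(0.0, config.noise_sd, size=(config.n_genes, config.n_samples))
    )

    # miRNA induced by cluster membership: cluster 2 enriched, cluster 1 less
    mirna_signal = np.where(cluster == 2, config.mirna_cluster_effect,
                            np.where(cluster == 1, -config.mirna_cluster_effect, 0.0))
    mirna = 5.0 + mirna_signal + rng.normal(0.0, config.noise_sd, size=config.n_samples)
    mirna_high = mirna > np.median(mirna)

    target_idx = rng.choice(config.n_genes, size=config.n_targets, replace=False)
    if config.target_shift != 0.0:
        log2_expr[np.ix_(target_idx, np.flatnonzero(mirna_high))] -= config.target_shift
        de_genes_true = {genes[i] for i in target_idx}
    else:
        de_genes_true = set()

    expression = pd.DataFrame(2.0**log2_expr, index=genes, columns=samples)
    true_cluster = pd.Series(cluster, index=samples, name="true_cluster")
    clinical = _generate_clinical(rng, true_cluster, config.clinical_log_odds)

    return SyntheticCohort(
        expression=expression,
        mirna=pd.Series(mirna, index=samples, name="mirna"),
        true_cluster=true_cluster,
        target_genes={genes[i] for i in target_idx},
        de_genes_true=de_genes_true,
        clinical=clinical,
        seed=config.seed,
        config=replace(config),
    )


def _generate_clinical(rng: np.random.Generator, cluster: pd.Series, log_odds: float) -> pd.DataFrame:
    """Clinical covariates with a logistic link on cluster membership.

    Cluster 1 (the miRNA-less, aggressive-phenotype analogue) carries elevated
    odds of invasive features; gender, age and location are independent noise.
    """
    n = len(cluster)
    aggressive = (cluster == 1).to_numpy()

    def binary(base_logit: float, name: str) -> pd.Series:
        logit = base_logit + log_odds * aggressive
        p = 1.0 / (1.0 + np.exp(-logit))
        return pd.Series(np.where(rng.random(n) < p, "yes", "no"), index=cluster.index, name=name)

    depth_p = 1.0 / (1.0 + np.exp(-(0.5 + log_odds * aggressive)))
    clinical = pd.DataFrame(
        {
            "gender": rng.choice(["female", "male"], size=n),
            "age": np.round(rng.normal(65, 10, size=n)).clip(30, 95).astype(int),
            "location": rng.choice(["colon", "rectum"], size=n, p=[0.7, 0.3]),
            "depth_of_invasion": np.where(rng.random(n) < depth_p, "T3+T4", "T1+T2"),
            "lymph_node_metastasis": binary(-0.5, "lymph_node_metastasis"),
            "distant_metastasis": binary(-1.5, "distant_metastasis"),
            "stage": np.where(rng.random(n) < 1 / (1 + np.exp(-(-0.2 + log_odds * aggressive))),
                              "III+IV", "I+II"),
            "vascular_invasion": binary(-1.0, "vascular_invasion"),
            "lymphatic_invasion": binary(-0.7, "lymphatic_invasion"),
            "perineural_invasion": binary(-1.2, "perineural_invasion"),
        },
        index=cluster.index,
    )
    return clinical


def generate_pathways(
    n_pathways: int = 20,
    genes_per_pathway: int = 20,
    edge_density: float = 0.15,
    frac_perturbed: float = 0.0,
    seed: int = 0,
    perturb_strength: float = 3.0,
    noise_sd: float = 0.25,
    gene_pool: list[str] | None = None,
) -> tuple[list[PathwayGraph], dict[str, float]]:
    """Random signed DAG pathways plus a planted per-gene log fold-change map.

    Edges run from lower to higher node index (acyclic, so the perturbation
    system is always solvable) with random +/-1 signs. The first
    round(frac_perturbed * n_pathways) pathways receive coherent planted
    fold-changes: signs propagate from a root along the edge signs, so the
    accumulated perturbation adds up instead of cancelling. Every pathway gene
    also gets small Gaussian background fold-change noise. When ``gene_pool``
    is given (e.g. a cohort's gene ids), pathway nodes are sampled from it
    without replacement per pathway, so the graphs overlap an expression
    universe.
    """
    if genes_per_pathway < 2:
        raise ValueError("genes_per_pathway must be >= 2")
    if gene_pool is not None and len(gene_pool) < genes_per_pathway:
        raise ValueError("gene_pool smaller than genes_per_pathway")
    rng = np.random.default_rng(seed)
    n_perturbed = int(round(frac_perturbed * n_pathways))
    pathways: list[PathwayGraph] = []
    delta_e: dict[str, float] = {}

    for p in range(n_pathways):
        if gene_pool is not None:
            genes = [gene_pool[i] for i in rng.choice(len(gene_pool),
                                                      size=genes_per_pathway,
                                                      replace=False)]
        else:
            genes = [f"PW{p:02d}_G{j:03d}" for j in range(genes_per_pathway)]
        edges: list[tuple[str, str, int]] = []
        for i in range(genes_per_pathway):
            for j in range(i + 1, genes_per_pathway):
                if rng.random() < edge_density:
                    sign = 1 if rng.random() < 0.7 else -1
                    edges.append((genes[i], genes[j], sign))
        # guarantee connectivity of consecutive nodes so propagation has a spine
        existing = {(s, t) for s, t, _ in edges}
        for i in range(genes_per_pathway - 1):
            if (genes[i], genes[i + 1]) not in existing:
                edges.append((genes[i], genes[i + 1], 1))
        pathway = PathwayGraph(name=f"pathway_{p:02d}", genes=genes, edges=edges)
        pathways.append(pathway)

        for g in genes:
            delta_e[g] = float(rng.normal(0.0, noise_sd))
        if p < n_perturbed:
            sign_of = _coherent_signs(pathway)
            for g in genes:
                delta_e[g] += perturb_strength * sign_of[g]
    return pathways, delta_e


def _coherent_signs(p: PathwayGraph) -> dict[str, int]:
    """Node signs consistent with edge signs: sign(target) = sign(source) * beta.

    Breadth-first from the first node; on conflicting assignments the first
    one wins (possible in non-tree graphs, rare at low density).
    """
    sign_of: dict[str, int] = {p.genes[0]: 1}
    adjacency: dict[str, list[tuple[str, int]]] = {g: [] for g in p.genes}
    for s, t, beta in p.edges:
        adjacency[s].append((t, beta))
    frontier = [p.genes[0]]
    while frontier:
        node = frontier.pop(0)
        for child, beta in adjacency[node]:
            if child not in sign_of:
                sign_of[child] = sign_of[node] * beta
                frontier.append(child)
    for g in p.genes:  # isolated nodes default to the root sign
        sign_of.setdefault(g, 1)
    return sign_of


def generate_qpcr_cohort(
    n_patients: int = 20,
    tumor_shift: float = 3.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired tumor/normal Ct values for a target and a reference miRNA.

    ``tumor_shift`` raises the target Ct in tumor tissue (lower expression,
    the pattern of a repressed tumor-suppressor miRNA); the reference miRNA is
    shift-free. Patient baselines vary so the pairing carries information.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    patient_base = rng.normal(25.0, 1.0, size=n_patients)
    ref_base = rng.normal(24.0, 0.5, size=n_patients)
    df = pd.DataFrame(
        {
            "target_tumor": patient_base + tumor_shift + rng.normal(0, noise_sd, n_patients),
            "ref_tumor": ref_base + rng.normal(0, noise_sd, n_patients),
            "target_normal": patient_base + rng.normal(0, noise_sd, n_patients),
            "ref_normal": ref_base + rng.normal(0, noise_sd, n_patients),
        },
        index=[f"P{i:02d}" for i in range(n_patients)],
    )
    return df.clip(lower=1.0)
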