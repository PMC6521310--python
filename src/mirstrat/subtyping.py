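"""Sample subtyping: UPGMA views, Brunet KL-NMF, consensus clustering with
cophenetic rank selection, and entropy-based metagene feature extraction.

Consensus NMF repeats the factorization from many random starts; the fraction
of runs in which two samples share a dominant metagene forms a consensus
matrix whose clustering stability (cophenetic correlation) selects the rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

EPS = 1e-12  # pseudo-count guarding KL updates against division by zero


# ---------------------------------------------------------------------------
# hierarchical clustering


@dataclass
class HierResult:
    linkage: np.ndarray  # scipy linkage matrix
    leaf_order: list[int]
    labels: list[str]

    def cut(self, k: int) -> pd.Series:
        assign = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(assign, index=self.labels, name="cluster")


def hier_cluster(m: pd.DataFrame, axis: str = "samples") -> HierResult:
    """Agglomerative clustering with Euclidean distance and average (UPGMA) linkage.

    ``axis`` selects whether the samples (columns) or genes (rows) are
    clustered. Ties in merge order follow scipy's deterministic convention
    (lowest index pair first).
    """
    if axis not in {"samples", "genes"}:
        raise ValueError("axis must be 'samples' or 'genes'")
    data = m.T.to_numpy(dtype=float) if axis == "samples" else m.to_numpy(dtype=float)
    labels = list(m.columns if axis == "samples" else m.index)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    if np.isnan(data).any():
        raise ValueError("NaN values are not allowed")
    z = hierarchy.linkage(data, method="average", metric="euclidean")
    order = hierarchy.leaves_list(z).tolist()
    return HierResult(linkage=z, leaf_order=order, labels=labels)


# ---------------------------------------------------------------------------
# Brunet multiplicative-update NMF (KL divergence)


@dataclass
class NMFFactorization:
    W: np.ndarray  # genes x k
    H: np.ndarray  # k x samples
    k: int
    objective_trace: list[float]
    seed: int


def kl_divergence(v: np.ndarray, wh: np.ndarray) -> float:
    """Generalized Kullback-Leibler divergence D(V || WH), with 0 log 0 = 0."""
    wh = np.maximum(wh, EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(v > 0, v * np.log(np.maximum(v, EPS) / wh), 0.0)
    return float(np.sum(term - v + wh))


def nmf_brunet(
    v: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    trace_every: int = 10,
) -> NMFFactorization:
    """KL-divergence NMF by the Brunet multiplicative updates.

    H <- H * (W^T (V / WH)) / (W^T 1);  W <- W * ((V / WH) H^T) / (1 H^T),
    from seeded uniform random initialization. Stops at ``max_iter`` or when
    the KL decrease over ``trace_every`` iterations falls below ``tol``
    (relative to the starting objective). Zero rows/columns are lifted by a
    pseudo-count so the updates stay defined.
    """
    v = np.asarray(v, dtype=float)
    if (v < 0).any():
        raise ValueError("input matrix must be non-negative")
    if k < 1 or k >= min(v.shape):
        raise ValueError(f"rank k={k} must satisfy 1 <= k < min{v.shape}")
    if (v.sum(axis=0) == 0).any() or (v.sum(axis=1) == 0).any():
        v = v + EPS

    rng = np.random.default_rng(seed)
    n, m = v.shape
    W = rng.uniform(EPS, 1.0, size=(n, k))
    H = rng.uniform(EPS, 1.0, size=(k, m))

    trace = [kl_divergence(v, W @ H)]
    scale = max(trace[0], 1.0)
    for it in range(1, max_iter + 1):
        wh = np.maximum(W @ H, EPS)
        H *= (W.T @ (v / wh)) / np.maximum(W.sum(axis=0)[:, None], EPS)
        wh = np.maximum(W @ H, EPS)
        W *= ((v / wh) @ H.T) / np.maximum(H.sum(axis=1)[None, :], EPS)
        if it % trace_every == 0 or it == max_iter:
            obj = kl_divergence(v, W @ H)
            trace.append(obj)
            if trace[-2] - obj < tol * scale:
                break
    return NMFFactorization(W=W, H=H, k=k, objective_trace=trace, seed=seed)


# ---------------------------------------------------------------------------
# consensus clustering over repeated factorizations


@dataclass
class ConsensusResult:
    consensus: dict[int, np.ndarray]  # rank -> sample x sample mean connectivity
    cophenetic: dict[int, float]  # rank -> cophenetic correlation
    selected_rank: int
    assignments: pd.Series  # per-sample cluster label at the selected rank
    sample_ids: list[str] = field(default_factory=list)


def connectivity_matrix(h: np.ndarray) -> np.ndarray:
    """Binary sample x sample matrix: 1 iff two samples share the argmax metagene."""
    dominant = np.argmax(h, axis=0)
    return (dominant[:, None] == dominant[None, :]).astype(float)


def cophenetic_correlation(cbar: np.ndarray) -> float:
    """Cophenetic correlation of the consensus matrix.

    Pearson correlation between the off-diagonal consensus dissimilarities
    (1 - C) and the cophenetic distances induced by their average-linkage
    dendrogram; values near 1 indicate stable, well-separated clusters.
    """
    d = 1.0 - cbar
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    if np.allclose(condensed, condensed[0]):
        return float("nan")
    z = hierarchy.linkage(condensed, method="average")
    coph = hierarchy.cophenet(z)
    if np.allclose(coph, coph[0]):
        return float("nan")
    return float(np.corrcoef(condensed, coph)[0, 1])


def run_seed(base_seed: int, k: int, run: int) -> int:
    """Deterministic per-run seed: a counter scheme over (base, rank, run)."""
    ss = np.random.SeedSequence([int(base_seed), int(k), int(run)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def consensus_nmf(
    v: pd.DataFrame,
    k_min: int = 2,
    k_max: int = 6,
    n_runs: int = 200,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> ConsensusResult:
    """Consensus NMF over ranks [k_min, k_max] with cophenetic rank selection.

    For each rank, ``n_runs`` seeded Brunet factorizations are averaged into a
    consensus matrix; the rank maximizing the cophenetic correlation is
    selected (ties resolved toward the smaller rank), and samples are assigned
    by cutting the average-linkage tree of the consensus dissimilarity.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    values = v.to_numpy(dtype=float)
    samples = list(v.columns)
    n = len(samples)

    consensus: dict[int, np.ndarray] = {}
    cophenetic: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        acc = np.zeros((n, n))
        for run in range(n_runs):
            fac = nmf_brunet(values, k, seed=run_seed(seed, k, run), max_iter=max_iter, tol=tol)
            acc += connectivity_matrix(fac.H)
        cbar = acc / n_runs
        np.fill_diagonal(cbar, 1.0)
        consensus[k] = cbar
        rho = cophenetic_correlation(cbar)
        if np.isnan(rho):
            warnings.warn(f"rank {k}: degenerate consensus matrix, skipped", stacklevel=2)
            continue
        cophenetic[k] = rho

    if not cophenetic:
        raise ValueError("no rank produced a non-degenerate consensus matrix")
    best = max(sorted(cophenetic), key=lambda k: (cophenetic[k], -k))
    d = 1.0 - consensus[best]
    np.fill_diagonal(d, 0.0)
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    assign = hierarchy.fcluster(z, t=best, criterion="maxclust")
    return ConsensusResult(
        consensus=consensus,
        cophenetic=cophenetic,
        selected_rank=best,
        assignments=pd.Series(assign, index=samples, name="cluster"),
        sample_ids=samples,
    )


# ---------------------------------------------------------------------------
# metagene feature extraction


@dataclass
class MetageneFeatures:
    table: pd.DataFrame  # per gene: score, dominant_metagene, selected
    score_threshold: float
    n_sigma: float


def feature_scores(w: np.ndarray) -> np.ndarray:
    """Per-gene concentration score: 1 minus the normalized entropy of the
    gene's relative loading profile across the k metagenes.

    1 means the gene loads on a single metagene; 0 means uniform loadings
    (or an all-zero row).
    """
    w = np.asarray(w, dtype=float)
    k = w.shape[1]
    rowsum = w.sum(axis=1)
    scores = np.zeros(w.shape[0])
    ok = rowsum > 0
    p = w[ok] / rowsum[ok, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    scores[ok] = 1.0 + plogp.sum(axis=1) / np.log2(k)
    return np.clip(scores, 0.0, 1.0)


def extract_features(
    fac: NMFFactorization,
    gene_ids: list[str] | pd.Index | None = None,
    n_sigma: float = 3.0,
) -> MetageneFeatures:
    """Select cluster-defining genes from the basis matrix W.

    A gene is selected when its concentration score exceeds a robust upper
    threshold (median + n_sigma * scaled MAD over all scores) AND its maximal
    basis loading exceeds the median of that metagene's column — the default
    selection rule of consensus-NMF feature extraction.
    """
    if fac.k < 2:
        raise ValueError("feature extraction requires rank >= 2")
    w = fac.W
    genes = list(gene_ids) if gene_ids is not None else [f"g{i}" for i in range(w.shape[0])]
    scores = feature_scores(w)
    med = float(np.median(scores))
    mad = float(np.median(np.abs(scores - med))) * 1.4826  # Gaussian-consistent MAD
    threshold = med + n_sigma * mad

    dominant = np.argmax(w, axis=1)
    col_medians = np.median(w, axis=0)
    max_loading = w[np.arange(w.shape[0]), dominant]
    selected = (scores > threshold) & (max_loading > col_medians[dominant]) & (w.sum(axis=1) > 0)

    table = pd.DataFrame(
        {"score": scores, "dominant_metagene": dominant, "selected": selected},
        index=pd.Index(genes, name="gene"),
    )
    return MetageneFeatures(table=table, score_threshold=threshold, n_sigma=n_sigma)


def cluster_specific_features(feat: MetageneFeatures, clusters: set[int] | list[int]) -> list[str]:
    """Selected features dominated by the given metagene indices, best first."""
    clusters = set(clusters)
    if not clusters:
        raise ValueError("clusters must be non-empty")
    t = feat.table
    sub = t[t["selected"] & t["dominant_metagene"].isin(clusters)]
    sub = sub.sort_values("score", ascending=False, kind="stable")
    return list(sub.index)


def plot_consensus_heatmap(result: ConsensusResult, rank: int | None = None, path=None):
    """Optional consensus-matrix heatmap (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = rank or result.selected_rank
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(result.consensus[k], vmin=0, vmax=1, cmap="viridis")
    ax.set_title(f"Consensus matrix (rank {k})")
    fig.colorbar(im, ax=ax, shrink=0.8)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
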