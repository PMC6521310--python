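"""Signaling pathway impact analysis on signed directed gene graphs.

Each pathway combines two independent pieces of evidence: pNDE, the
hypergeometric over-representation of differentially expressed genes on the
pathway, and pPERT, a bootstrap p-value for the total net perturbation
accumulation tA obtained by propagating per-gene log fold-changes along the
signed topology. The two are merged into a global pG by the Fisher product
formula pG = c - c*ln(c), c = pNDE * pPERT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import PathwayGraph

log = logging.getLogger(__name__)

#: reciprocal condition number below which (I - M) is treated as singular
RCOND_MIN = 1e-10


def _propagation_matrix(p: PathwayGraph) -> tuple[np.ndarray, dict[str, int]]:
    """M[g, u] = beta_ug / N_ds(u): influence of u on its downstream gene g,
    normalized by u's number of outgoing edges."""
    idx = {g: i for i, g in enumerate(p.genes)}
    n = len(p.genes)
    n_ds = np.zeros(n)
    for src, _tgt, _sign in p.edges:
        n_ds[idx[src]] += 1
    m = np.zeros((n, n))
    for src, tgt, sign in p.edges:
        m[idx[tgt], idx[src]] += sign / n_ds[idx[src]]
    return m, idx


def perturbation_factors(
    p: PathwayGraph, delta_e: dict[str, float] | pd.Series
) -> tuple[dict[str, float], dict[str, float], float]:
    """Solve the perturbation propagation system on one pathway.

    PF(g) = dE(g) + sum over upstream u of beta_ug * PF(u) / N_ds(u), solved
    as PF = (I - M)^-1 dE. Returns (PF map, Acc map, tA) where
    Acc(g) = PF(g) - dE(g) and tA = sum of Acc. Raises ValueError when
    (I - M) is singular (e.g. certain cyclic topologies), in which case the
    pathway is not computable.
    """
    m, idx = _propagation_matrix(p)
    de = np.array([float(delta_e.get(g, 0.0)) for g in p.genes])
    a = np.eye(len(p.genes)) - m
    if 1.0 / np.linalg.cond(a) < RCOND_MIN:
        raise ValueError(f"pathway {p.name!r}: I - M is singular, perturbation not computable")
    pf = np.linalg.solve(a, de)
    acc = pf - de
    return (
        {g: float(pf[idx[g]]) for g in p.genes},
        {g: float(acc[idx[g]]) for g in p.genes},
        float(acc.sum()),
    )


def _accumulation_weights(p: PathwayGraph) -> np.ndarray:
    """Row vector c with tA = c . dE, from tA = 1^T ((I - M)^-1 - I) dE.

    Exploits linearity of the propagation so bootstrap iterations reduce to a
    dot product.
    """
    m, _ = _propagation_matrix(p)
    a = np.eye(len(p.genes)) - m
    if 1.0 / np.linalg.cond(a) < RCOND_MIN:
        raise ValueError(f"pathway {p.name!r}: I - M is singular, perturbation not computable")
    inv = np.linalg.inv(a)
    return (inv - np.eye(len(p.genes))).sum(axis=0)


def bootstrap_ppert(
    p: PathwayGraph,
    delta_e: dict[str, float] | pd.Series,
    n_boot: int = 20_000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Bootstrap p-value for the net accumulation tA.

    Each iteration reassigns the observed multiset of nonzero fold-changes to
    uniformly drawn pathway genes (without replacement) and recomputes tA.
    The null is centred at its median m and
    pPERT = (#{|tA_b - m| >= |tA_obs - m|} + 1) / (n_boot + 1) (two-sided).
    Returns (pPERT, null median, tA_obs).
    """
    de_values = np.array([float(delta_e.get(g, 0.0)) for g in p.genes])
    observed = de_values[de_values != 0.0]
    if observed.size == 0:
        raise ValueError("bootstrap requires at least one DE gene on the pathway")
    weights = _accumulation_weights(p)
    ta_obs = float(np.dot(weights, de_values))

    rng = np.random.default_rng(seed)
    # uniformly permuting the full dE vector assigns the observed nonzero
    # multiset to a uniform random gene subset; chunked for memory
    n = len(p.genes)
    ta_null = np.empty(n_boot)
    chunk = max(1, min(n_boot, 4_000_000 // max(n, 1)))
    done = 0
    while done < n_boot:
        m_rows = min(chunk, n_boot - done)
        mat = np.tile(de_values, (m_rows, 1))
        rng.permuted(mat, axis=1, out=mat)
        ta_null[done : done + m_rows] = mat @ weights
        done += m_rows
    med = float(np.median(ta_null))
    if np.allclose(ta_null, ta_null[0]):
        # degenerate null: no resolution to call the observed tA extreme
        return 1.0, med, ta_obs
    exceed = np.count_nonzero(np.abs(ta_null - med) >= abs(ta_obs - med))
    return (exceed + 1) / (n_boot + 1), med, ta_obs


def combine_pg(p_nde: float, p_pert: float) -> float:
    """Fisher product combination: pG = c - c*ln(c) with c = pNDE * pPERT."""
    if not (0 < p_nde <= 1 and 0 < p_pert <= 1):
        raise ValueError("both p-values must lie in (0, 1]")
    c = p_nde * p_pert
    return float(c - c * np.log(c)) if c < 1 else 1.0


@dataclass
class SPIAResult:
    pathway: str
    n_de: int
    t_a: float
    p_nde: float
    p_pert: float
    p_g: float
    status: str  # activated / inhibited / none
    significant: bool
    computable: bool = True


def run_spia(
    pathways: list[PathwayGraph],
    degs: pd.DataFrame,
    universe: set[str] | None = None,
    alpha_de: float = 0.05,
    threshold: float = 2e-6,
    n_boot: int = 20_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pathway impact analysis over a pathway collection.

    DE genes are rows of ``degs`` with p_adj < alpha_de; their logFC values
    form the perturbation input dE (non-DE genes contribute 0). Pathways with
    no overlap with the universe are skipped; singular topologies are reported
    as non-computable. Results are sorted by pG.
    """
    if universe is None:
        universe = set(degs.index)
    de_table = degs[degs["p_adj"] < alpha_de]
    de_genes = set(de_table.index)
    delta_e = de_table["logFC"].to_dict()
    n_u, n_de_total = len(universe), len(de_genes)

    rows = []
    for i, p in enumerate(pathways):
        on_pathway = set(p.genes) & universe
        if not on_pathway:
            log.info("pathway %r has no overlap with the universe; skipped", p.name)
            continue
        de_on_pathway = de_genes & on_pathway
        n_de = len(de_on_pathway)
        p_nde = float(stats.hypergeom.sf(n_de - 1, n_u, len(on_pathway), n_de_total))
        p_nde = min(max(p_nde, np.finfo(float).tiny), 1.0)
        if n_de == 0:
            rows.append(SPIAResult(p.name, 0, 0.0, p_nde, 1.0, combine_pg(p_nde, 1.0),
                                   "none", False))
            continue
        try:
            p_pert, med, ta_obs = bootstrap_ppert(
                p, delta_e, n_boot=n_boot, seed=seed + i
            )
        except ValueError as exc:
            log.warning("%s", exc)
            rows.append(SPIAResult(p.name, n_de, float("nan"), p_nde, float("nan"),
                                   float("nan"), "none", False, computable=False))
            continue
        p_g = combine_pg(p_nde, p_pert)
        status = "activated" if ta_obs > med else ("inhibited" if ta_obs < med else "none")
        rows.append(SPIAResult(p.name, n_de, ta_obs, p_nde, p_pert, p_g,
                               status, p_g < threshold))

    if not rows:
        raise ValueError("no computable pathway overlaps the universe")
    table = pd.DataFrame(
        [
            {
                "pathway": r.pathway,
                "n_de": r.n_de,
                "tA": r.t_a,
                "pNDE": r.p_nde,
                "pPERT": r.p_pert,
                "pG": r.p_g,
                "status": r.status,
                "significant": r.significant,
                "computable": r.computable,
            }
            for r in rows
        ]
    ).set_index("pathway")
    return table.sort_values("pG", kind="stable", na_position="last")
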