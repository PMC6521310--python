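"""Target-set enrichment by a label-permutation Kolmogorov-Smirnov test, and
hypergeometric over-representation analysis.

Two per-gene statistics are tested for enrichment in a miRNA target set:
an association score a_g = -log10(p_g) and a magnitude score derived from the
absolute fold change. The enrichment score is the one-sided two-sample KS
statistic D+ between target and non-target score distributions, and its null
is built by randomly permuting the target labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection

log = logging.getLogger(__name__)

P_FLOOR = 1e-300  # floor before -log10 so scores stay finite
FC_FLOOR = 1.0 + 1e-12  # floor on |fold change| so the magnitude score is >= 0


def gene_statistics(degs: pd.DataFrame) -> pd.DataFrame:
    """Per-gene association and magnitude scores from a DEG table.

    association = -log10(p) (larger = stronger association);
    magnitude = log10(|fold change|) with the fold-change magnitude
    2**|logFC| >= 1, so larger values mean larger expression changes in either
    direction.
    """
    p = np.clip(degs["p"].to_numpy(dtype=float), P_FLOOR, 1.0)
    fc_mag = np.maximum(2.0 ** np.abs(degs["logFC"].to_numpy(dtype=float)), FC_FLOOR)
    return pd.DataFrame(
        {"association": -np.log10(p), "magnitude": np.log10(fc_mag)},
        index=degs.index,
    )


def _rank_targets(scores: pd.Series, targets: set[str]) -> np.ndarray:
    """Boolean target indicator in descending-score order (ties by gene id)."""
    genes = scores.index.to_numpy()
    vals = scores.to_numpy(dtype=float)
    order = np.lexsort((genes, -vals))
    return np.isin(genes[order], list(targets))


def _es_from_indicator(is_target: np.ndarray) -> float:
    n_t = int(is_target.sum())
    n_n = int(len(is_target) - n_t)
    steps = np.where(is_target, 1.0 / n_t, -1.0 / n_n)
    return float(np.max(np.cumsum(steps)))


def ks_enrichment_score(scores: pd.Series, targets: set[str]) -> float:
    """One-sided KS enrichment score of a target set among ranked genes.

    Genes are sorted by score descending; a running sum climbs 1/|T| at
    targets and falls 1/|N| elsewhere, and the ES is its maximum — equal to
    the one-sided KS statistic D+ = sup(F_T - F_N) over score thresholds.
    Always in (0, 1]; 1 iff all targets outrank all non-targets.
    """
    targets = set(targets)
    n_t = len(targets & set(scores.index))
    if n_t == 0:
        raise ValueError("target set has no overlap with scored genes")
    if n_t == len(scores):
        raise ValueError("target set must be a proper subset of scored genes")
    return _es_from_indicator(_rank_targets(scores, targets))


@dataclass
class EnrichmentResult:
    es_observed: float
    es_null: np.ndarray
    nes: float  # NaN when the null is degenerate
    p_empirical: float
    B: int
    target_set_size: int
    statistic_kind: str


def permutation_test(
    scores: pd.Series,
    targets: set[str],
    B: int = 10_000,
    seed: int = 0,
    statistic_kind: str = "association",
) -> EnrichmentResult:
    """Label-permutation null for the KS enrichment score.

    Each of the B permutations draws |T| genes uniformly without replacement
    and recomputes the ES. The empirical p uses +1 smoothing,
    p = (#{ES_b >= ES_obs} + 1) / (B + 1), so its floor is exactly 1/(B+1);
    NES is the z-score of the observed ES against the permuted ones.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    targets = set(targets) & set(scores.index)
    is_target = _rank_targets(scores, targets)
    es_obs = _es_from_indicator(is_target)
    n = len(is_target)
    n_t = int(is_target.sum())

    rng = np.random.default_rng(seed)
    steps = np.where(is_target, 1.0 / n_t, -1.0 / (n - n_t))
    es_null = np.empty(B)
    # permuting the step vector uniformly == drawing |T| labels without
    # replacement; chunked to bound memory
    chunk = max(1, min(B, 4_000_000 // max(n, 1)))
    done = 0
    while done < B:
        m_rows = min(chunk, B - done)
        mat = np.tile(steps, (m_rows, 1))
        rng.permuted(mat, axis=1, out=mat)
        es_null[done : done + m_rows] = np.cumsum(mat, axis=1).max(axis=1)
        done += m_rows

    p_emp = (np.count_nonzero(es_null >= es_obs) + 1) / (B + 1)
    sd = es_null.std(ddof=1) if B > 1 else 0.0
    nes = (es_obs - es_null.mean()) / sd if sd > 0 else float("nan")
    return EnrichmentResult(
        es_observed=es_obs,
        es_null=es_null,
        nes=float(nes),
        p_empirical=float(p_emp),
        B=B,
        target_set_size=n_t,
        statistic_kind=statistic_kind,
    )


def run_target_enrichment(
    degs: pd.DataFrame,
    targets: list[str] | set[str],
    B: int = 10_000,
    seed: int = 0,
) -> tuple[EnrichmentResult, EnrichmentResult]:
    """Enrichment of a miRNA target set for association and magnitude signals.

    Returns (association result, magnitude result); the two statistics are
    permuted independently. Targets outside the DEG universe are dropped with
    a log entry.
    """
    target_set = set(targets)
    n_dup = len(list(targets)) - len(target_set)
    if n_dup:
        log.info("deduplicated %d target gene(s)", n_dup)
    universe = set(degs.index)
    dropped = target_set - universe
    if dropped:
        log.info("%d target gene(s) outside the expression universe dropped", len(dropped))
    target_set &= universe
    if not target_set:
        raise ValueError("no target genes overlap the DEG universe")

    scores = gene_statistics(degs)
    assoc = permutation_test(scores["association"], target_set, B=B, seed=seed,
                             statistic_kind="association")
    mag = permutation_test(scores["magnitude"], target_set, B=B, seed=seed + 1,
                           statistic_kind="magnitude")
    return assoc, mag


def ora_hypergeometric(
    hits: set[str],
    sets: GeneSetCollection,
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a hit list in each gene set.

    Per set S, p = P(X >= |hits & S|) with X hypergeometric(|U|, |S & U|,
    |hits|). Returns a DataFrame (set name -> overlap, set_size, expected,
    p, significant) sorted by p.
    """
    hits = set(hits) & universe
    n_u = len(universe)
    n_hits = len(hits)
    rows = []
    for name, members in sets.sets.items():
        in_universe = members & universe
        overlap = len(hits & in_universe)
        if not in_universe:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(overlap - 1, n_u, len(in_universe), n_hits))
        rows.append(
            {
                "set": name,
                "overlap": overlap,
                "set_size": len(in_universe),
                "expected": n_hits * len(in_universe) / n_u if n_u else 0.0,
                "p": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows).set_index("set").sort_values("p", kind="stable")
    table["significant"] = table["p"] < alpha
    return table
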