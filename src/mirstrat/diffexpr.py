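"""Moderated two-sample t-tests between the miRNA-high and miRNA-low groups.

The per-gene pooled variance is shrunk toward a common prior estimated by
moment matching on the log sample variances (the empirical-Bayes scheme of
the standard moderated t-statistic), which stabilises inference when group
sizes are small relative to the number of genes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats

from .preprocess import Stratification

#: degrees-of-freedom cap used when the prior df estimate is infinite
D0_CAP = 1e6


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching estimate of the prior (d0, s0^2) from sample variances.

    Matches the first two moments of z = log(s2), whose distribution under a
    scaled chi-square model involves digamma/trigamma terms; when the observed
    spread of z is no larger than expected from chi-square sampling alone the
    prior df is infinite (all genes share one variance).
    """
    s2 = np.asarray(s2, float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = len(e)
    evar = np.sum((e - emean) ** 2) / (n - 1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        # no excess dispersion: all genes share one variance, taken as the
        # mean sample variance so the infinite-shrinkage limit reproduces the
        # ordinary pooled t exactly
        return np.inf, float(np.mean(s2[ok]))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_2 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_2)


def moderated_t_test(
    m: pd.DataFrame,
    s: Stratification,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Per-gene moderated t between high and low groups of a log-scale matrix.

    Returns a DataFrame indexed by gene with columns mean_high, mean_low,
    logFC, s2, df, t_mod, p, p_adj, direction; the estimated prior (d0, s0_2)
    is stored in ``result.attrs``. ``d0_override`` forces the prior df
    (0 recovers the ordinary pooled t).
    """
    high = [c for c in m.columns if s.labels.get(c) == "high"]
    low = [c for c in m.columns if s.labels.get(c) == "low"]
    n1, n2 = len(high), len(low)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >= 2 samples per group, got high={n1}, low={n2}")

    xh = m[high].to_numpy(dtype=float)
    xl = m[low].to_numpy(dtype=float)
    mean_high = xh.mean(axis=1)
    mean_low = xl.mean(axis=1)
    logfc = mean_high - mean_low
    df_resid = n1 + n2 - 2
    ss = ((xh - mean_high[:, None]) ** 2).sum(axis=1) + ((xl - mean_low[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid

    if d0_override is not None:
        d0 = float(d0_override)
        s0_2 = float(np.mean(s2[s2 > 0])) if (s2 > 0).any() else 1.0
    else:
        d0, s0_2 = estimate_prior(s2, df_resid)
    d0_eff = min(d0, D0_CAP)

    s2_post = (d0_eff * s0_2 + df_resid * s2) / (d0_eff + df_resid)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    df_total = d0_eff + df_resid

    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, logfc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    # a gene with no within-group variance carries no sampling information of
    # its own; report p = 1 rather than borrowing a prior-only variance
    degenerate = (se == 0) | (s2 == 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with zero posterior variance; p set to 1",
            stacklevel=2,
        )
        p[degenerate] = 1.0
        t_mod = np.where(degenerate, 0.0, t_mod)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    table = pd.DataFrame(
        {
            "mean_high": mean_high,
            "mean_low": mean_low,
            "logFC": logfc,
            "s2": s2,
            "df": float(df_resid),
            "t_mod": t_mod,
            "p": p,
            "p_adj": bh_adjust(p),
            "direction": np.where(logfc > 0, "up", "down"),
        },
        index=m.index,
    )
    table.attrs["d0"] = d0
    table.attrs["s0_2"] = s0_2
    table.attrs["n_high"] = n1
    table.attrs["n_low"] = n2
    return table


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def select_degs(
    table: pd.DataFrame,
    alpha: float = 0.05,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Rows with p_adj < alpha, optionally truncated to the top_k smallest p.

    Ordering is by raw p then gene id (a deterministic tie-break).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    sig = table[table["p_adj"] < alpha] if alpha < 1 else table
    ordered = sig.iloc[np.lexsort((sig.index.to_numpy(), sig["p"].to_numpy()))]
    if top_k is not None:
        ordered = ordered.head(top_k)
    return ordered
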