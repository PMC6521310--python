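"""Expression filtering, connectivity-based outlier removal, log2 normalization,
and quantile dichotomization of samples by a miRNA expression vector.

The outlier step mirrors the network-QC convention of weighted co-expression
analysis: a sample's connectivity is the sum of soft-thresholded signed
biweight midcorrelations to all other samples, and samples whose standardized
connectivity is extreme are dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def filter_expressed(m: pd.DataFrame, min_nonzero_frac: float = 0.8) -> pd.DataFrame:
    """Keep genes detected (value > 0) in at least ``min_nonzero_frac`` of samples.

    The boundary is inclusive: a gene present in exactly the required fraction
    of samples is kept. Gene order and the sample set are preserved.
    """
    if not 0 < min_nonzero_frac <= 1:
        raise ValueError("min_nonzero_frac must be in (0, 1]")
    frac = (m > 0).mean(axis=1)
    kept = m.loc[frac >= min_nonzero_frac]
    if kept.empty:
        warnings.warn("no genes pass the expression filter", stacklevel=2)
    return kept


def _biweight_transform(v: np.ndarray, c: float = 9.0) -> np.ndarray:
    """Normalized biweight-centred vector; bicor(x, y) = transform(x) . transform(y).

    Observations are weighted by Tukey's biweight around the median with
    tuning constant ``c`` (9 by convention); an observation further than
    c * MAD from the median gets weight zero. When a vector has zero MAD the
    weights are undefined and the vector falls back to its Pearson terms
    (mean-centred, unit weights), the usual pearsonFallback behaviour.
    """
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        centred = v - v.mean()
    else:
        u = (v - med) / (c * mad)
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        centred = (v - med) * w
    norm = np.sqrt(np.sum(centred**2))
    if norm == 0:
        return np.zeros_like(centred)
    return centred / norm


def bicor(x: np.ndarray, y: np.ndarray, c: float = 9.0) -> float:
    """Biweight midcorrelation of two vectors."""
    return float(
        np.dot(
            _biweight_transform(np.asarray(x, float), c),
            _biweight_transform(np.asarray(y, float), c),
        )
    )


def sample_connectivity(m: pd.DataFrame, beta: float = 2.0) -> pd.Series:
    """Signed weighted connectivity k_i = sum_j ((1 + bicor(i, j)) / 2) ** beta, j != i."""
    values = m.to_numpy(dtype=float)
    n = values.shape[1]
    if n < 3:
        raise ValueError("connectivity requires at least 3 samples")
    transformed = np.column_stack([_biweight_transform(values[:, i]) for i in range(n)])
    corr = np.clip(transformed.T @ transformed, -1.0, 1.0)
    adjacency = ((1 + corr) / 2) ** beta
    np.fill_diagonal(adjacency, 0.0)
    return pd.Series(adjacency.sum(axis=0), index=m.columns, name="connectivity")


def remove_outliers(
    m: pd.DataFrame,
    z_cut: float = 5.0,
    beta: float = 2.0,
    tail: str = "both",
) -> tuple[pd.DataFrame, list[str]]:
    """Drop samples with extreme standardized connectivity (single pass).

    ``tail`` selects which side counts as outlying: ``above`` (literally more
    than z_cut SDs above mean connectivity), ``below`` (low-connectivity
    samples, i.e. samples that do not correlate with the rest), or ``both``
    (default, |Z| > z_cut).
    """
    if tail not in {"above", "below", "both"}:
        raise ValueError("tail must be one of above/below/both")
    k = sample_connectivity(m, beta=beta)
    sd = k.std(ddof=1)
    if sd < 1e-12 * max(1.0, abs(k.mean())):
        # perfectly homogeneous cohort: all Z = 0, nothing to remove
        return m, []
    z = (k - k.mean()) / sd
    if tail == "above":
        bad = z > z_cut
    elif tail == "below":
        bad = z < -z_cut
    else:
        bad = z.abs() > z_cut
    removed = list(m.columns[bad.to_numpy()])
    if removed:
        log.info("removed %d connectivity outlier sample(s): %s", len(removed), removed)
    return m.loc[:, ~bad.to_numpy()], removed


def normalize_log2(m: pd.DataFrame, rounding_cutoff: float = 1.0) -> pd.DataFrame:
    """log2-transform with a floor: value -> log2(max(value, rounding_cutoff)).

    With the default cutoff of 1 the floor maps all sub-unit abundances to 0,
    the usual behaviour for RPM-scale data.
    """
    if rounding_cutoff <= 0:
        raise ValueError("rounding_cutoff must be positive")
    return np.log2(m.clip(lower=rounding_cutoff))


@dataclass
class Stratification:
    """Per-sample high/low/excluded labels from quantile dichotomization."""

    labels: pd.Series  # values in {"high", "low", "excluded"}
    q: float
    low_cut: float
    high_cut: float

    @property
    def high_samples(self) -> pd.Index:
        return self.labels.index[self.labels == "high"]

    @property
    def low_samples(self) -> pd.Index:
        return self.labels.index[self.labels == "low"]


def stratify(v: pd.Series, q: float = 0.25) -> Stratification:
    """Dichotomize samples by a miRNA vector at the lower/upper q-quantiles.

    Quantiles use linear interpolation between order statistics. A sample is
    labelled ``high`` iff its value is strictly greater than the upper cut,
    ``low`` iff strictly less than the lower cut, else ``excluded``. Group
    sizes are therefore convention-dependent and never hard-coded.
    """
    if not 0 < q < 0.5:
        raise ValueError("q must be in (0, 0.5)")
    values = v.to_numpy(dtype=float)
    low_cut = float(np.quantile(values, q))
    high_cut = float(np.quantile(values, 1 - q))
    labels = pd.Series("excluded", index=v.index, name="label")
    labels[v > high_cut] = "high"
    labels[v < low_cut] = "low"
    if (labels == "excluded").all():
        warnings.warn("all samples excluded by stratification (constant miRNA vector?)", stacklevel=2)
    return Stratification(labels=labels, q=q, low_cut=low_cut, high_cut=high_cut)
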