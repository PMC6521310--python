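"""Clinical association tests, qPCR cohort statistics, and small utilities.

Cluster or stratification labels are tested against clinical binaries with a
binomial-family logistic regression and a likelihood-ratio test, optionally
adjusted for gender, age and tumor location; qPCR relative expression follows
the ratio-of-Ct convention with a delta-delta-Ct alternative behind a switch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .diffexpr import bh_adjust

log = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    feature: str
    lr_statistic: float | None
    df: int
    p: float | None
    p_adjusted_covariates: float | None
    counts: pd.DataFrame  # outcome level x predictor level contingency table
    converged: bool = True
    params: dict[str, float] | None = None  # full-model coefficients


def _design(frame: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Intercept + dummy-coded design matrix for the named columns."""
    parts = [pd.Series(1.0, index=frame.index, name="const")]
    for col in columns:
        s = frame[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float))
        else:
            parts.append(pd.get_dummies(s.astype(str), prefix=col, drop_first=True, dtype=float))
    return pd.concat(parts, axis=1)


def _lr_test(outcome: pd.Series, frame: pd.DataFrame, predictor: str,
             covariates: list[str]) -> tuple[float, int, float, bool, dict[str, float]]:
    y = outcome.astype(float)
    x_full = _design(frame, covariates + [predictor])
    x_red = _design(frame, covariates)
    df = x_full.shape[1] - x_red.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.GLM(y, x_full, family=sm.families.Binomial()).fit(maxiter=100)
        red = sm.GLM(y, x_red, family=sm.families.Binomial()).fit(maxiter=100)
    converged = bool(full.converged and red.converged) and np.all(np.abs(full.params) < 30)
    lr = 2.0 * (full.llf - red.llf)
    lr = max(lr, 0.0)
    p = float(stats.chi2.sf(lr, df)) if df > 0 else 1.0
    return lr, df, p, converged, dict(full.params)


def logistic_association(
    outcome: pd.Series,
    predictor: pd.Series,
    covariates: pd.DataFrame | None = None,
    min_complete: int = 10,
) -> AssociationResult:
    """Likelihood-ratio test of a categorical predictor on a binary outcome.

    The predictor (e.g. a 3-level subtype label) enters a binomial GLM as
    dummy variables and is tested against the covariate-only model with an
    LR chi-square on (levels - 1) df. Complete cases only; perfect separation
    is reported as non-converged with the p omitted.
    """
    frame = pd.DataFrame({"outcome": outcome, "predictor": predictor.astype(str)})
    cov_cols: list[str] = []
    if covariates is not None:
        for c in covariates.columns:
            frame[c] = covariates[c]
            cov_cols.append(c)
    frame = frame.dropna()
    if frame.shape[0] < min_complete:
        raise ValueError(f"need >= {min_complete} complete cases, got {frame.shape[0]}")
    levels = frame["outcome"].unique()
    if len(levels) < 2:
        raise ValueError("outcome must have two levels among complete cases")
    y = (frame["outcome"] == sorted(map(str, levels.astype(str)))[-1]) \
        if frame["outcome"].dtype == object else frame["outcome"].astype(int)
    y = pd.Series(np.asarray(y, dtype=float), index=frame.index)

    counts = pd.crosstab(frame["outcome"], frame["predictor"])
    try:
        lr, df, p, converged, params = _lr_test(y, frame, "predictor", cov_cols)
    except Exception as exc:  # separation or IRLS failure
        log.warning("logistic fit failed: %s", exc)
        return AssociationResult(outcome.name or "outcome", None, 0, None, None, counts, False)
    if not converged:
        log.warning("logistic fit did not converge (possible separation)")
        return AssociationResult(outcome.name or "outcome", None, df, None, None, counts, False)
    return AssociationResult(
        feature=outcome.name or "outcome",
        lr_statistic=lr,
        df=df,
        p=p,
        p_adjusted_covariates=p if cov_cols else None,
        counts=counts,
        params=params,
    )


def association_table(
    clinical: pd.DataFrame,
    predictor: pd.Series,
    features: list[str],
    covariate_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Test each clinical binary feature against the predictor; BH across features.

    Returns per-feature unadjusted p, covariate-adjusted p, and FDR-adjusted
    (BH over the covariate-adjusted) p, mirroring the usual three-column
    clinical association layout. Features that fail to fit get NaN p-values.
    """
    covariate_cols = covariate_cols or []
    rows = []
    for feat in features:
        out = clinical[feat]
        try:
            unadj = logistic_association(out.rename(feat), predictor)
            adj = (
                logistic_association(out.rename(feat), predictor, clinical[covariate_cols])
                if covariate_cols
                else unadj
            )
            rows.append({"feature": feat, "p": unadj.p,
                         "p_covariate_adjusted": adj.p})
        except ValueError as exc:
            log.warning("feature %r skipped: %s", feat, exc)
            rows.append({"feature": feat, "p": np.nan, "p_covariate_adjusted": np.nan})
    table = pd.DataFrame(rows).set_index("feature")
    ok = table["p_covariate_adjusted"].notna()
    fdr = pd.Series(np.nan, index=table.index)
    if ok.any():
        fdr[ok] = bh_adjust(table.loc[ok, "p_covariate_adjusted"].to_numpy())
    table["p_fdr"] = fdr
    return table


def wilcoxon_test(x, y=None, paired: bool = False) -> float:
    """Two-sided Wilcoxon p-value.

    Unpaired (default): rank-sum / Mann-Whitney, exact for small untied
    samples and normal approximation with tie correction otherwise. Paired:
    signed-rank on the differences. Degenerate all-equal data returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    if paired:
        if y is None:
            raise ValueError("paired test needs both samples")
        y = np.asarray(y, dtype=float)
        d = x - y
        if np.all(d == 0):
            return 1.0
        return float(stats.wilcoxon(x, y, alternative="two-sided").pvalue)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("each group needs at least one observation")
    if np.all(np.concatenate([x, y]) == np.concatenate([x, y])[0]):
        return 1.0
    both = np.concatenate([x, y])
    has_ties = len(np.unique(both)) < both.size
    method = "exact" if (max(x.size, y.size) <= 12 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def qpcr_relative_expression(cohort: pd.DataFrame, method: str = "ct_ratio") -> tuple[pd.DataFrame, dict]:
    """Relative target-miRNA expression per patient and cohort summary.

    Default ``ct_ratio``: rel = Ct(target)/Ct(reference) per tissue and
    ratio = rel_tumor / rel_normal (the convention used by the study this
    pipeline models). ``ddct`` provides the conventional 2^-ddCt alternative
    (non-default). Note that under ct_ratio a ratio > 1 means HIGHER target Ct
    in tumor, i.e. LOWER tumor expression; the summary's ``frac_ratio_below_1``
    therefore counts patients with reduced tumor Ct ratio.
    """
    for col in ["target_tumor", "ref_tumor", "target_normal", "ref_normal"]:
        if (cohort[col] <= 0).any():
            raise ValueError(f"non-positive Ct in column {col}")
        if cohort[col].isna().any():
            raise ValueError(f"missing Ct in column {col}")
    if method == "ct_ratio":
        rel_tumor = cohort["target_tumor"] / cohort["ref_tumor"]
        rel_normal = cohort["target_normal"] / cohort["ref_normal"]
        ratio = rel_tumor / rel_normal
    elif method == "ddct":
        dct_t = cohort["target_tumor"] - cohort["ref_tumor"]
        dct_n = cohort["target_normal"] - cohort["ref_normal"]
        rel_tumor = 2.0 ** (-dct_t)
        rel_normal = 2.0 ** (-dct_n)
        ratio = rel_tumor / rel_normal
    else:
        raise ValueError("method must be 'ct_ratio' or 'ddct'")
    per_patient = pd.DataFrame(
        {"rel_tumor": rel_tumor, "rel_normal": rel_normal, "ratio": ratio},
        index=cohort.index,
    )
    # under ct_ratio, higher tumor Ct (less expression) pushes the ratio above 1,
    # so reduced tumor expression shows as ratio > 1; under ddct as ratio < 1
    below = per_patient["ratio"] < 1
    reduced = (per_patient["ratio"] > 1) if method == "ct_ratio" else below
    summary = {
        "n": int(len(per_patient)),
        "n_ratio_below_1": int(below.sum()),
        "frac_ratio_below_1": float(below.mean()),
        "n_reduced_expression": int(reduced.sum()),
        "frac_reduced_expression": float(reduced.mean()),
        "wilcoxon_p": wilcoxon_test(rel_tumor.to_numpy(), rel_normal.to_numpy()),
    }
    return per_patient, summary


def tumor_volume(length: float, width: float, lenient: bool = False) -> float:
    """Ellipsoid-style tumor volume (L * W^2) / 2 from caliper dimensions in mm.

    L is the larger and W the smaller dimension; with ``lenient`` swapped
    inputs are corrected with a warning instead of rejected.
    """
    if width <= 0 or length <= 0:
        raise ValueError("dimensions must be positive")
    if width > length:
        if not lenient:
            raise ValueError("W must not exceed L (pass lenient=True to auto-swap)")
        warnings.warn("W > L; swapping dimensions", stacklevel=2)
        length, width = width, length
    return length * width**2 / 2.0
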