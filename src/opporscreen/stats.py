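"""Fracture-association statistics.

Implements the analysis battery used to relate bone measures to
prevalent vertebral fracture status:

* standardisation to per-SD risk scores (bone measures are *negated*
  first so that OR > 1 / AUC > 0.5 mean higher fracture risk per SD
  *decrease* of the measure);
* logistic regression odds ratios with Wald 95% CIs, crude and
  age/sex-adjusted (maximum likelihood via statsmodels);
* empirical ROC curves whose AUC equals the Mann-Whitney concordance
  probability (ties counted 1/2), with DeLong structural-components
  variance and the paired DeLong test for two correlated ROC curves;
* sensitivity/specificity at fixed cutoffs;
* group descriptive comparisons (two-sample t test, chi-squared for
  sex) shaped like a study-characteristics table;
* Bland-Altman bias/limits of agreement and R-squared for method
  agreement.

Significance is read against a two-sided 0.05 level throughout; no
multiplicity correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import (
    DegeneratePredictorError,
    SeparationError,
    UndefinedStatisticError,
)

Z_95 = sps.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# Standardisation


def standardize(values, risk_direction: str = "lower", ddof: int = 1) -> np.ndarray:
    """Z-score values as a fracture-risk score.

    ``risk_direction="lower"`` (bone measures: lower is worse) negates
    the z-score so that one unit corresponds to a one-SD *decrease*;
    ``"higher"`` (e.g. age) keeps the sign. The SD is the whole-sample
    SD of the passed values.
    """
    x = np.asarray(values, dtype=np.float64)
    sd = x.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise DegeneratePredictorError("predictor has zero variance")
    z = (x - x.mean()) / sd
    if risk_direction == "lower":
        return -z
    if risk_direction == "higher":
        return z
    raise ValueError(f"risk_direction must be 'lower' or 'higher', got {risk_direction!r}")


def binormal_auc(mean_pos: float, sd_pos: float, mean_neg: float, sd_neg: float) -> float:
    """Closed-form AUC of two Gaussian classes, risk-oriented.

    For a bone measure (positives = fractured have the *lower* mean)
    pass the group parameters directly; the orientation is handled by
    taking the probability that a random positive scores higher risk:
    Phi(|mu_neg - mu_pos| / sqrt(sd_pos^2 + sd_neg^2)).
    """
    delta = abs(mean_neg - mean_pos)
    return float(sps.norm.cdf(delta / np.hypot(sd_pos, sd_neg)))


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong


@dataclass
class RocCurve:
    """Empirical ROC curve with DeLong variance.

    ``thresholds`` are midpoints between adjacent distinct scores
    (plus sentinels beyond the extremes); a subject is called positive
    when its risk score is >= the threshold. ``auc`` is the
    Mann-Whitney concordance probability with ties counted 1/2.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_var: float
    ci: tuple[float, float]
    n_pos: int
    n_neg: int


def _split_classes(outcome, scores) -> tuple[np.ndarray, np.ndarray]:
    outcome = np.asarray(outcome, dtype=bool)
    scores = np.asarray(scores, dtype=np.float64)
    if outcome.shape != scores.shape:
        raise UndefinedStatisticError("outcome and scores must align")
    pos, neg = scores[outcome], scores[~outcome]
    if pos.size == 0 or neg.size == 0:
        raise UndefinedStatisticError("both outcome classes must be present")
    return pos, neg


def _structural_components(pos: np.ndarray, neg: np.ndarray):
    """DeLong placement values.

    Returns (auc, v10, v01): v10[i] is the probability that positive i
    outranks a random negative (ties 1/2), v01[j] likewise per
    negative. Their means both equal the AUC.
    """
    cmp = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return float(cmp.mean()), v10, v01


def roc_auc(outcome, scores) -> RocCurve:
    """Empirical ROC analysis of a risk-oriented score.

    ``scores`` must already be oriented so that higher values indicate
    higher fracture risk (see :func:`standardize`).
    """
    pos, neg = _split_classes(outcome, scores)
    auc, v10, v01 = _structural_components(pos, neg)
    m, n = pos.size, neg.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n

    uniq = np.unique(np.concatenate([pos, neg]))
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.empty(0)
    span = max(uniq[-1] - uniq[0], 1.0)
    thresholds = np.concatenate([[uniq[0] - span], mids, [uniq[-1] + span]])
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])

    half = Z_95 * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return RocCurve(thresholds, sens, spec, auc, float(var), ci, m, n)


def delong_test(outcome, scores_a, scores_b) -> dict:
    """DeLong's test for two correlated ROC curves on the same subjects.

    Returns a dict with the two AUCs, their difference (a - b), the
    variance of the difference and the two-sided normal p value.
    Identical score vectors give difference 0 and p = 1.
    """
    pos_a, neg_a = _split_classes(outcome, scores_a)
    pos_b, neg_b = _split_classes(outcome, scores_b)
    auc_a, v10_a, v01_a = _structural_components(pos_a, neg_a)
    auc_b, v10_b, v01_b = _structural_components(pos_b, neg_b)
    m, n = pos_a.size, neg_a.size
    # 2x2 covariance of the placement values, paired over subjects.
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    diff = auc_a - auc_b
    if var <= 0:
        p = 1.0 if diff == 0 else 0.0
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        z = diff / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return {
        "auc_a": auc_a,
        "auc_b": auc_b,
        "difference": diff,
        "variance": float(var),
        "z": float(z) if np.isfinite(z) else z,
        "p": p,
    }


def sens_spec_at(outcome, values, cutoff: float, direction: str = "below") -> tuple[float, float]:
    """Sensitivity and specificity (percent) of a fixed cutoff.

    ``direction="below"``: a measurement below the cutoff calls the
    subject abnormal (the convention for bone density thresholds), so
    sensitivity is the fraction of fractured subjects below the cutoff
    and specificity the fraction of non-fractured at or above it.
    """
    if not np.isfinite(cutoff):
        raise UndefinedStatisticError("cutoff must be finite")
    pos, neg = _split_classes(outcome, values)
    if direction == "below":
        sens = (pos < cutoff).mean()
        spec = (neg >= cutoff).mean()
    elif direction == "above":
        sens = (pos >= cutoff).mean()
        spec = (neg < cutoff).mean()
    else:
        raise ValueError(f"direction must be 'below' or 'above', got {direction!r}")
    return float(100.0 * sens), float(100.0 * spec)


# ---------------------------------------------------------------------------
# Logistic odds ratios


@dataclass
class OrResult:
    """Odds ratio per one-SD change with Wald 95% CI."""

    odds_ratio: float
    ci: tuple[float, float]
    p: float
    adjusted: bool
    covariates: tuple[str, ...] = ()
    coef: float = field(default=np.nan)
    se: float = field(default=np.nan)


def logistic_or(outcome, predictor_z, covariates: pd.DataFrame | None = None) -> OrResult:
    """Odds ratio for a standardised predictor from a logistic fit.

    ``predictor_z`` should come from :func:`standardize`, so the OR
    reads "per one SD change in the risk direction". ``covariates``
    may carry an ``age`` column and/or a ``sex`` column (coded
    ``"F"``/``"M"`` or numeric). Perfect separation raises
    :class:`SeparationError` instead of returning a spurious estimate.
    """
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise UndefinedStatisticError("both outcome classes must be present")
    z = np.asarray(predictor_z, dtype=np.float64)
    X = pd.DataFrame({"predictor": z})
    cov_names: tuple[str, ...] = ()
    if covariates is not None and len(covariates.columns) > 0:
        cov = covariates.copy()
        if "sex" in cov.columns and cov["sex"].dtype == object:
            cov["sex"] = (cov["sex"] == "F").astype(float)
        for c in cov.columns:
            X[c] = np.asarray(cov[c], dtype=np.float64)
        cov_names = tuple(covariates.columns)
    X = sm.add_constant(X, has_constant="add")
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation is detected post-fit from the estimates
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError et al.
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    coef = float(fit.params["predictor"])
    se = float(fit.bse["predictor"])
    if not np.isfinite(coef) or not np.isfinite(se) or abs(coef) > 30 or se > 100:
        raise SeparationError("perfect separation: no finite odds ratio")
    lo, hi = np.exp(coef - Z_95 * se), np.exp(coef + Z_95 * se)
    return OrResult(
        odds_ratio=float(np.exp(coef)),
        ci=(float(lo), float(hi)),
        p=float(fit.pvalues["predictor"]),
        adjusted=bool(cov_names),
        covariates=cov_names,
        coef=coef,
        se=se,
    )


# ---------------------------------------------------------------------------
# Group comparison and agreement


def group_compare(table: pd.DataFrame, measures: tuple[str, ...]) -> pd.DataFrame:
    """Study-characteristics comparison stratified by fracture status.

    For each continuous measure, group means (SD) and a pooled-variance
    two-sample t test; for sex, a chi-squared test of independence.
    ``table`` needs boolean ``fracture``, ``sex`` and the measure
    columns.
    """
    frac = table[table["fracture"]]
    nofrac = table[~table["fracture"]]
    if len(frac) == 0 or len(nofrac) == 0:
        raise UndefinedStatisticError("both fracture groups must be non-empty")
    rows = []
    if "sex" in table.columns:
        contingency = pd.crosstab(table["fracture"], table["sex"])
        if contingency.shape == (2, 2):
            chi2, p, _, _ = sps.chi2_contingency(contingency, correction=False)
        else:  # single-sex cohort: independence is vacuous
            chi2, p = 0.0, 1.0
        rows.append(
            {
                "variable": "women_n",
                "nonfractured_mean": float((nofrac["sex"] == "F").sum()),
                "nonfractured_sd": np.nan,
                "fractured_mean": float((frac["sex"] == "F").sum()),
                "fractured_sd": np.nan,
                "statistic": float(chi2),
                "p": float(p),
                "test": "chi2",
            }
        )
    for measure in measures:
        a, b = nofrac[measure].to_numpy(float), frac[measure].to_numpy(float)
        t, p = sps.ttest_ind(a, b, equal_var=True)
        rows.append(
            {
                "variable": measure,
                "nonfractured_mean": a.mean(),
                "nonfractured_sd": a.std(ddof=1),
                "fractured_mean": b.mean(),
                "fractured_sd": b.std(ddof=1),
                "statistic": float(t),
                "p": float(p),
                "test": "t",
            }
        )
    return pd.DataFrame(rows)


def pooled_mean(means, ns) -> float:
    """Size-weighted mean, e.g. a 'Total' column from group summaries."""
    means = np.asarray(means, dtype=np.float64)
    ns = np.asarray(ns, dtype=np.float64)
    return float(np.sum(means * ns) / np.sum(ns))


def bland_altman(series_a, series_b) -> dict:
    """Bias and 95% limits of agreement of two paired measurement series."""
    a = np.asarray(series_a, dtype=np.float64)
    b = np.asarray(series_b, dtype=np.float64)
    if a.shape != b.shape:
        raise UndefinedStatisticError("paired series must have equal length")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return {"bias": bias, "loa_low": bias - 1.96 * sd, "loa_high": bias + 1.96 * sd}


def r_squared(series_a, series_b) -> float:
    """Coefficient of determination of the least-squares fit of b on a."""
    a = np.asarray(series_a, dtype=np.float64)
    b = np.asarray(series_b, dtype=np.float64)
    if a.shape != b.shape:
        raise UndefinedStatisticError("paired series must have equal length")
    return float(sps.linregress(a, b).rvalue ** 2)
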