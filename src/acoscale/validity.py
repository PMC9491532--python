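"""Clinical validity and clinical utility of a sum score.

Covers the statistics used to judge how well a questionnaire total score
separates patients from healthy controls: Cohen's d, adjusted R^2 of the
group indicator regressed on the score, ROC area under the curve with a
Hanley-McNeil confidence interval, the Youden-optimal cutoff with its
sensitivity and specificity, and T-scores normed on the control group.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import norm, rankdata

from .simulate import ItemResponseTable

__all__ = [
    "total_score",
    "cohens_d",
    "adjusted_r2",
    "roc_auc",
    "roc_curve_points",
    "youden_cutoff",
    "t_score",
    "ValidityReport",
    "evaluate_validity",
]


def total_score(
    table: ItemResponseTable,
    items=None,
    *,
    prorate: bool = False,
    max_missing_fraction: float = 0.2,
) -> np.ndarray:
    """Per-respondent sum over the selected items.

    With complete data this is the plain integer sum in [0, 4k].  If
    ``prorate`` is set, respondents missing at most ``max_missing_fraction``
    of the selected items get mean-imputed sums (k * mean of observed);
    beyond that limit the score is NaN.  Without ``prorate`` any missing
    entry raises.
    """
    ids = list(table.item_ids if items is None else items)
    col = {i: j for j, i in enumerate(table.item_ids)}
    X = table.responses[:, [col[i] for i in ids]]
    k = len(ids)
    miss = np.isnan(X)
    if not prorate:
        if miss.any():
            raise ValueError("missing responses among selected items; enable prorate")
        return X.sum(axis=1)
    n_miss = miss.sum(axis=1)
    with np.errstate(invalid="ignore"):
        score = np.nanmean(X, axis=1) * k
    score[n_miss > max_missing_fraction * k] = np.nan
    score[n_miss == k] = np.nan
    return score


def _split(scores, groups):
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    pat = scores[groups == "patient"]
    con = scores[groups == "control"]
    if pat.size == 0 or con.size == 0:
        raise ValueError("both groups must be non-empty")
    return con, pat


def cohens_d(scores, groups) -> float:
    """Standardized mean difference (patient - control) / pooled SD."""
    con, pat = _split(scores, groups)
    if con.size < 2 or pat.size < 2:
        raise ValueError("need at least 2 respondents per group")
    n1, n2 = con.size, pat.size
    v1, v2 = con.var(ddof=1), pat.var(ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((pat.mean() - con.mean()) / np.sqrt(pooled))


def adjusted_r2(scores, groups) -> float:
    """Adjusted R^2 of the binary group indicator regressed on the score."""
    scores = np.asarray(scores, dtype=float)
    y = (np.asarray(groups) == "patient").astype(float)
    n = scores.size
    if n <= 2:
        raise ValueError("need n > 2")
    if scores.std() == 0:
        raise ValueError("constant scores")
    r = np.corrcoef(scores, y)[0, 1]
    r2 = r * r
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - 2))


def roc_auc(scores, groups, *, alpha: float = 0.05) -> tuple[float, float, float]:
    """AUC via the Mann-Whitney rank identity, with a Hanley-McNeil CI.

    AUC is the probability that a randomly drawn patient outscores a
    randomly drawn control, ties counted one half.
    """
    con, pat = _split(scores, groups)
    n_c, n_p = con.size, pat.size
    ranks = rankdata(np.concatenate([con, pat]))
    auc = (ranks[n_c:].sum() - n_p * (n_p + 1) / 2.0) / (n_c * n_p)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_p - 1) * (q1 - auc * auc)
        + (n_c - 1) * (q2 - auc * auc)
    ) / (n_c * n_p)
    z = norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return float(auc), float(max(auc - half, 0.0)), float(min(auc + half, 1.0))


def roc_curve_points(scores, groups) -> np.ndarray:
    """(threshold, sensitivity, specificity) rows for all attainable cutoffs,
    under the decision rule "score >= threshold -> flagged"."""
    con, pat = _split(scores, groups)
    thresholds = np.unique(np.concatenate([con, pat]))
    thresholds = np.concatenate([thresholds, [thresholds[-1] + 1]])
    out = np.empty((thresholds.size, 3))
    for i, c in enumerate(thresholds):
        sens = np.mean(pat >= c)
        spec = np.mean(con < c)
        out[i] = (c, sens, spec)
    return out


def youden_cutoff(scores, groups) -> tuple[float, float, float]:
    """Cutoff maximizing sensitivity + specificity - 1 (smallest on ties).

    Returns (cutoff, sensitivity, specificity) for the rule
    "score >= cutoff -> flagged as patient".
    """
    con, pat = _split(scores, groups)
    thresholds = np.unique(np.concatenate([con, pat]))
    thresholds = np.concatenate([thresholds, [thresholds[-1] + 1]])
    # integer-count criterion: maximizing tp/n_p + tn/n_c is equivalent to
    # maximizing tp*n_c + tn*n_p, and exact ties stay exact ties
    tp = (pat[None, :] >= thresholds[:, None]).sum(axis=1)
    tn = (con[None, :] < thresholds[:, None]).sum(axis=1)
    j_scaled = tp * con.size + tn * pat.size
    best = int(np.argmax(j_scaled))  # first maximum -> smallest cutoff
    c = thresholds[best]
    return float(c), float(tp[best] / pat.size), float(tn[best] / con.size)


def t_score(raw, reference_mean: float, reference_sd: float):
    """Norm-referenced T-score: 50 + 10 * (raw - mean) / sd."""
    if reference_sd <= 0:
        raise ValueError("reference SD must be positive")
    return 50.0 + 10.0 * (np.asarray(raw, dtype=float) - reference_mean) / reference_sd


@dataclass
class ValidityReport:
    cohens_d: float
    adjusted_r2: float
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    cutoff_raw: float
    cutoff_t: float
    sensitivity: float
    specificity: float
    reference_mean: float
    reference_sd: float

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_validity(table: ItemResponseTable, items=None) -> ValidityReport:
    """Full clinical-validity panel for the sum score over ``items``.

    The T-score reference is the healthy control sample, so the cutoff's
    T-value states how extreme a flagged score is relative to controls.
    """
    scores = total_score(table, items)
    groups = table.group
    con, _ = _split(scores, groups)
    auc, lo, hi = roc_auc(scores, groups)
    cutoff, sens, spec = youden_cutoff(scores, groups)
    ref_mean, ref_sd = float(con.mean()), float(con.std(ddof=1))
    return ValidityReport(
        cohens_d=cohens_d(scores, groups),
        adjusted_r2=adjusted_r2(scores, groups),
        auc=auc,
        auc_ci_low=lo,
        auc_ci_high=hi,
        cutoff_raw=float(cutoff),
        cutoff_t=float(t_score(cutoff, ref_mean, ref_sd)),
        sensitivity=sens,
        specificity=spec,
        reference_mean=ref_mean,
        reference_sd=ref_sd,
    )
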