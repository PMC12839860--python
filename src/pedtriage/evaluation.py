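"""Discrimination analysis: ROC/AUC, DeLong comparisons, threshold tables.

The AUC is computed as the Mann-Whitney pair statistic (ties credited 1/2),
with its variance and the covariance between two correlated score vectors
estimated from DeLong placement values.  Confidence intervals are built on
the logit scale and back-transformed so they stay inside [0, 1]; the paired
AUC comparison refers ``(AUC_a - AUC_b)^2 / var(diff)`` to a chi-square
distribution with one degree of freedom (equivalently a two-sided z-test).

Threshold operating characteristics use the ``strict_greater`` convention by
default (a patient is predicted positive when the score strictly exceeds the
threshold, matching "score > t" reporting); ``geq`` is available as well.
Descriptive group comparisons use Pearson chi-square (no continuity
correction) for categoricals and Kruskal-Wallis (tie-corrected) for
continuous variables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .exceptions import DegenerateGroupError, DegenerateLabelsError
from .nfptcr import NfptcrResult
from .records import PatientRecord
from .scores import compute_iss

THRESHOLD_MODES = ("strict_greater", "geq")
DEFAULT_THRESHOLDS = (5.0, 10.0, 15.0, 20.0)


@dataclass
class RocResult:
    """ROC curve with AUC, DeLong variance and 95% CI.

    ``points`` holds one row per cut point, ordered by increasing threshold
    with -inf/+inf sentinels; ``sensitivity`` and ``specificity`` are
    proportions in [0, 1].
    """

    metric_name: str
    points: pd.DataFrame
    auc: float
    auc_se: float
    auc_ci: tuple[float, float]
    n_pos: int
    n_neg: int


@dataclass
class AucComparison:
    """Paired DeLong comparison of two correlated AUCs."""

    metric_a: str
    metric_b: str
    auc_a: float
    auc_b: float
    auc_diff: float
    var_diff: float
    statistic: float
    p_value: float


@dataclass
class ThresholdRow:
    """Operating characteristics at one threshold (percent units)."""

    metric_name: str
    threshold: float
    sensitivity: float
    specificity: float
    tp: int
    fn: int
    tn: int
    fp: int


def _check_inputs(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    if labels.all() or not labels.any():
        raise DegenerateLabelsError(
            "ROC analysis needs at least one positive and one negative label")
    return scores, labels


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values.

    ``v10[i]`` is the fraction of negatives a given positive outranks (ties
    half-credited); ``v01[j]`` the fraction of positives a given negative is
    outranked by.  The AUC is the mean of either vector.
    """
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    ranks_all = stats.rankdata(np.concatenate([pos, neg]))
    v10 = (ranks_all[:m] - stats.rankdata(pos)) / n
    v01 = 1.0 - (ranks_all[m:] - stats.rankdata(neg)) / m
    auc = float(v10.mean())
    return auc, v10, v01


def _logit_ci(auc: float, se: float, alpha: float = 0.05) -> tuple[float, float]:
    if se == 0.0:
        return (auc, auc)
    if auc <= 0.0 or auc >= 1.0:
        z = stats.norm.ppf(1 - alpha / 2)
        return (max(0.0, auc - z * se), min(1.0, auc + z * se))
    z = stats.norm.ppf(1 - alpha / 2)
    logit = np.log(auc / (1 - auc))
    se_logit = se / (auc * (1 - auc))
    lo, hi = logit - z * se_logit, logit + z * se_logit
    return (float(1 / (1 + np.exp(-lo))), float(1 / (1 + np.exp(-hi))))


def roc_auc(scores: Sequence[float], labels: Sequence[bool],
            metric_name: str = "score") -> RocResult:
    """ROC curve and AUC with a DeLong 95% confidence interval.

    Cut points enumerate every distinct score value plus -inf/+inf
    sentinels.  Raises
    :class:`~pedtriage.exceptions.DegenerateLabelsError` when only one class
    is present.
    """
    scores, labels = _check_inputs(scores, labels)
    auc, v10, v01 = _placements(scores, labels)
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    se = float(np.sqrt(var))

    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    pts = pd.DataFrame({
        "threshold": thresholds[::-1],
        "sensitivity": tpr[::-1],
        "specificity": 1.0 - fpr[::-1],
    })
    # sklearn's top sentinel is +inf (nothing predicted positive); add the
    # matching -inf sentinel (everything predicted positive).
    pts = pd.concat([
        pd.DataFrame({"threshold": [-np.inf], "sensitivity": [1.0],
                      "specificity": [0.0]}),
        pts,
    ], ignore_index=True)
    return RocResult(metric_name=metric_name, points=pts, auc=auc, auc_se=se,
                     auc_ci=_logit_ci(auc, se), n_pos=m, n_neg=n)


def compare_auc(scores_a: Sequence[float], scores_b: Sequence[float],
                labels: Sequence[bool], metric_a: str = "a",
                metric_b: str = "b") -> AucComparison:
    """DeLong test for two correlated ROC curves sharing the same labels.

    The statistic ``(AUC_a - AUC_b)^2 / var(diff)`` is referred to
    chi-square with 1 df.  If the variance of the difference is zero the
    statistic is undefined: p = 1 when the AUCs are equal, p = 0 otherwise.
    """
    sa, labels_a = _check_inputs(scores_a, labels)
    sb, labels_b = _check_inputs(scores_b, labels)
    auc_a, v10_a, v01_a = _placements(sa, labels_a)
    auc_b, v10_b, v01_b = _placements(sb, labels_b)
    m, n = len(v10_a), len(v01_a)
    d10 = v10_a - v10_b
    d01 = v01_a - v01_b
    var_diff = (np.var(d10, ddof=1) / m if m > 1 else 0.0) + \
               (np.var(d01, ddof=1) / n if n > 1 else 0.0)
    diff = auc_a - auc_b
    if var_diff <= 0.0:
        statistic = float("nan")
        p_value = 1.0 if diff == 0.0 else 0.0
    else:
        statistic = diff * diff / var_diff
        p_value = float(stats.chi2.sf(statistic, df=1))
    return AucComparison(metric_a=metric_a, metric_b=metric_b, auc_a=auc_a,
                         auc_b=auc_b, auc_diff=diff, var_diff=float(var_diff),
                         statistic=statistic, p_value=p_value)


def sens_spec_at(scores: Sequence[float], labels: Sequence[bool],
                 threshold: float, mode: str = "strict_greater",
                 metric_name: str = "score") -> ThresholdRow:
    """Sensitivity/specificity (percent) at one threshold.

    ``strict_greater`` predicts positive when score > threshold (the
    default, matching "score > t" table rows); ``geq`` when
    score >= threshold.
    """
    if mode not in THRESHOLD_MODES:
        raise ValueError(f"unknown threshold mode {mode!r}")
    scores, labels = _check_inputs(scores, labels)
    pred = scores > threshold if mode == "strict_greater" else scores >= threshold
    tp = int(np.sum(pred & labels))
    fn = int(np.sum(~pred & labels))
    tn = int(np.sum(~pred & ~labels))
    fp = int(np.sum(pred & ~labels))
    return ThresholdRow(metric_name=metric_name, threshold=float(threshold),
                        sensitivity=100.0 * tp / (tp + fn),
                        specificity=100.0 * tn / (tn + fp),
                        tp=tp, fn=fn, tn=tn, fp=fp)


def threshold_table(score_sets: Mapping[str, Sequence[float]],
                    labels: Sequence[bool],
                    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                    mode: str = "strict_greater") -> pd.DataFrame:
    """Operating-characteristics table for several metrics.

    One row per (metric, threshold) with percent sensitivity/specificity and
    the metric's AUC repeated down its rows; empty ``thresholds`` yields an
    empty table.
    """
    rows = []
    for name, scores in score_sets.items():
        auc = roc_auc(scores, labels, metric_name=name).auc
        for t in thresholds:
            row = sens_spec_at(scores, labels, t, mode=mode, metric_name=name)
            rows.append((name, row.threshold, row.sensitivity,
                         row.specificity, auc))
    return pd.DataFrame(rows, columns=["metric", "threshold", "sensitivity",
                                       "specificity", "auc"])


# ---------------------------------------------------------------------------
# Descriptive group comparison
# ---------------------------------------------------------------------------

def _fmt_count(k: int, n: int) -> str:
    return f"{k} ({round(100.0 * k / n)})"


def _fmt_median(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:g} ({q1:g}-{q3:g})"


def describe_cohort(cohort: Sequence[PatientRecord],
                    nfptcr_results: Sequence[NfptcrResult],
                    scores: pd.DataFrame) -> pd.DataFrame:
    """Descriptive comparison of NFPTCR+ vs NFPTCR- groups.

    Categorical variables are shown as ``n (%)`` with Pearson chi-square
    p-values (no continuity correction); continuous variables as
    ``median (IQR)`` with Kruskal-Wallis p-values (for two groups this is
    the Wilcoxon rank-sum test on the chi-square scale, 1 df).  Raises
    :class:`~pedtriage.exceptions.DegenerateGroupError` if either group is
    empty.
    """
    pos_mask = np.array([r.positive for r in nfptcr_results], dtype=bool)
    if len(cohort) != len(nfptcr_results) or len(cohort) != len(scores):
        raise ValueError("cohort, NFPTCR results and scores must align")
    if pos_mask.all() or not pos_mask.any():
        raise DegenerateGroupError("both NFPTCR groups must be non-empty")

    df = pd.DataFrame({
        "age_years": [r.age_years for r in cohort],
        "female": [r.sex == "F" for r in cohort],
        "mechanism": [r.mechanism for r in cohort],
        "died": [r.died for r in cohort],
        "icu_days": [r.icu_days for r in cohort],
        "hospital_hours": [r.hospital_hours for r in cohort],
        "iss": scores["iss"].to_numpy(),
        "iciss_scaled": scores["iciss_scaled"].to_numpy(),
        "icass": scores["icass"].to_numpy(),
    })
    n_pos = int(pos_mask.sum())
    n_neg = int((~pos_mask).sum())

    rows = []

    def continuous(label: str, col: str) -> None:
        a = df.loc[pos_mask, col].to_numpy(dtype=float)
        b = df.loc[~pos_mask, col].to_numpy(dtype=float)
        if np.all(np.concatenate([a, b]) == np.concatenate([a, b])[0]):
            p = 1.0  # constant variable; no rank information
        else:
            p = float(stats.kruskal(a, b).pvalue)
        rows.append((label, _fmt_median(a), _fmt_median(b), p))

    def binary(label: str, col: str) -> None:
        ct = pd.crosstab(df[col], pos_mask)
        if ct.shape[0] < 2:
            p = 1.0
        else:
            p = float(stats.chi2_contingency(ct.to_numpy(), correction=False)[1])
        ka = int(df.loc[pos_mask, col].sum())
        kb = int(df.loc[~pos_mask, col].sum())
        rows.append((label, _fmt_count(ka, n_pos), _fmt_count(kb, n_neg), p))

    continuous("Age, years", "age_years")
    binary("Sex, female", "female")

    ct = pd.crosstab(df["mechanism"], pos_mask)
    p_mech = (float(stats.chi2_contingency(ct.to_numpy(), correction=False)[1])
              if ct.shape[0] > 1 else 1.0)
    rows.append(("Injury mechanism", "", "", p_mech))
    for mech in sorted(df["mechanism"].unique()):
        ka = int(((df["mechanism"] == mech) & pos_mask).sum())
        kb = int(((df["mechanism"] == mech) & ~pos_mask).sum())
        rows.append((f"  {mech}", _fmt_count(ka, n_pos), _fmt_count(kb, n_neg),
                     np.nan))

    binary("Death", "died")
    continuous("Intensive care unit days", "icu_days")
    continuous("Hospital length of stay, hours", "hospital_hours")
    continuous("Injury Severity Score (ISS)", "iss")
    continuous("ICD Injury Severity Score (ICISS)", "iciss_scaled")
    continuous("ICD Critical Care Severity Score (ICASS)", "icass")

    out = pd.DataFrame(rows, columns=["variable",
                                      f"nfptcr_pos (n={n_pos})",
                                      f"nfptcr_neg (n={n_neg})",
                                      "p_value"])
    return out


def plot_roc(roc_results: Sequence[RocResult], path) -> None:
    """Plot ROC curves for several metrics to ``path`` (SVG/PNG by suffix)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for res in roc_results:
        pts = res.points.sort_values("threshold")
        ax.plot(1.0 - pts["specificity"], pts["sensitivity"],
                label=f"{res.metric_name} (AUC {res.auc:.3f})")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
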