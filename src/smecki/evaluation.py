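"""Discrimination and calibration machinery.

Discrimination is measured by the Mann-Whitney concordance AUC and two
correlated ROC curves on the same patients are compared with the DeLong
test (placement-value / structural-components covariance).  Calibration
is assessed by splitting the cohort into deciles of predicted risk and
comparing observed with expected events per decile (Hosmer-Lemeshow
chi-square), plus a plot-ready calibration table.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

logger = logging.getLogger(__name__)


class DegenerateLabelsError(ValueError):
    """Labels contain only one class; ROC quantities are undefined."""


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    y = y.astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise DegenerateLabelsError("need at least one positive and one negative label")
    return y


def auc(scores, labels) -> float:
    """Mann-Whitney concordance: P(score_pos > score_neg) with ties at 1/2.

    Midrank formulation; identical to brute-force pair counting.
    """
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    if len(s) != len(y):
        raise ValueError("scores and labels disagree in length")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _placement_values(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components.

    Returns (v10, v01, auc): v10[i] is positive i's placement among the
    negatives, v01[j] is one minus negative j's placement among the
    positives, and their common mean is the AUC.
    """
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01, float(v10.mean())


@dataclass(frozen=True)
class RocComparison:
    """Paired-AUC comparison of two scores on the same patients."""

    auc_a: float
    auc_b: float
    variance_diff: float
    z: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "auc_a": self.auc_a,
            "auc_b": self.auc_b,
            "variance_diff": self.variance_diff,
            "z": self.z,
            "p_value": self.p_value,
        }


def delong_compare(scores_a, scores_b, labels) -> RocComparison:
    """DeLong test for two correlated ROC curves.

    The covariance of the paired AUCs comes from the empirical
    covariance of the placement values; z = (auc_a - auc_b) / sqrt(var);
    two-sided normal p value.
    """
    y = _check_labels(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) != len(y) or len(b) != len(y):
        raise ValueError("score vectors must align with the labels")
    if y.sum() < 2 or (len(y) - y.sum()) < 2:
        raise ValueError("need at least 2 positives and 2 negatives")

    v10_a, v01_a, auc_a = _placement_values(a, y)
    v10_b, v01_b, auc_b = _placement_values(b, y)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    var = float(max(var, 0.0))
    diff = auc_a - auc_b
    if var == 0.0:
        if abs(diff) > 1e-12:
            raise FloatingPointError(
                "zero DeLong variance with unequal AUCs; comparison degenerate"
            )
        z, p = 0.0, 1.0
    else:
        z = diff / np.sqrt(var)
        p = float(2 * norm.sf(abs(z)))
    return RocComparison(auc_a=auc_a, auc_b=auc_b, variance_diff=var, z=float(z), p_value=p)


@dataclass(frozen=True)
class CalibrationTable:
    """Per-decile predicted vs observed events plus the HL statistic."""

    groups: pd.DataFrame  # columns: n, mean_predicted, observed_events, expected_events
    hl_statistic: float
    df: int
    p_value: float

    def to_csv(self, path) -> None:
        self.groups.to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "hl_statistic": self.hl_statistic,
            "df": self.df,
            "p_value": self.p_value,
        }


def _risk_groups(predicted: np.ndarray, n_groups: int) -> list[np.ndarray]:
    """Quantile bins of predicted risk, deterministic under ties.

    Stable sort on (predicted, index) then near-equal splits, so group
    sizes differ by at most one when predictions are distinct.
    """
    if len(np.unique(predicted)) < n_groups:
        raise ValueError(
            f"only {len(np.unique(predicted))} distinct predicted values for "
            f"{n_groups} risk groups; reduce n_groups"
        )
    order = np.argsort(predicted, kind="stable")
    return np.array_split(order, n_groups)


def _validate_calibration_inputs(predicted, observed, n_groups):
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(observed)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("observed outcomes must be binary 0/1")
    y = y.astype(int)
    if len(p) != len(y):
        raise ValueError("predicted and observed disagree in length")
    if not ((p > 0) & (p < 1)).all():
        raise ValueError("predicted risks must lie strictly in (0, 1)")
    if len(p) < n_groups:
        raise ValueError(f"need at least {n_groups} patients for {n_groups} groups")
    return p, y


def hosmer_lemeshow(
    predicted, observed, n_groups: int = 10, *, external: bool = False
) -> CalibrationTable:
    """Hosmer-Lemeshow chi-square over deciles of predicted risk.

    statistic = sum_g (O_g - E_g)^2 / (E_g (1 - pbar_g)) with pbar_g the
    group mean predicted risk; upper-tail chi-square p value.  The
    default df = n_groups - 2 is the classical choice for a model fitted
    on the same data; ``external=True`` uses n_groups - 1 for
    externally specified probabilities (validation setting), where no
    parameters were estimated from the sample.  A group whose expected
    events reach 0 or its full size gets a continuity floor of 0.5
    expected events (logged warning) instead of failing, so small
    cohorts stay computable.
    """
    p, y = _validate_calibration_inputs(predicted, observed, n_groups)
    rows = []
    statistic = 0.0
    for idx in _risk_groups(p, n_groups):
        n_g = len(idx)
        e_g = float(p[idx].sum())
        o_g = int(y[idx].sum())
        pbar = float(p[idx].mean())
        rows.append((n_g, pbar, o_g, e_g))
        if e_g < 0.5 or e_g > n_g - 0.5:
            warnings.warn(
                f"risk group with expected events {e_g:.3g} of {n_g}; "
                "applying 0.5-event continuity floor",
                stacklevel=2,
            )
            e_eff = min(max(e_g, 0.5), n_g - 0.5)
            pbar_eff = e_eff / n_g
            statistic += (o_g - e_g) ** 2 / (e_eff * (1 - pbar_eff))
        else:
            statistic += (o_g - e_g) ** 2 / (e_g * (1 - pbar))
    df = n_groups - 1 if external else n_groups - 2
    groups = pd.DataFrame(
        rows, columns=["n", "mean_predicted", "observed_events", "expected_events"]
    )
    return CalibrationTable(
        groups=groups,
        hl_statistic=float(statistic),
        df=df,
        p_value=float(chi2.sf(statistic, df)),
    )


def calibration_curve(predicted, observed, n_groups: int = 10) -> pd.DataFrame:
    """Plot-ready (mean_predicted, observed_rate) per decile of risk."""
    p, y = _validate_calibration_inputs(predicted, observed, n_groups)
    rows = []
    for idx in _risk_groups(p, n_groups):
        rows.append((len(idx), float(p[idx].mean()), float(y[idx].mean())))
    return pd.DataFrame(rows, columns=["n", "mean_predicted", "observed_rate"])


def roc_points(scores, labels) -> pd.DataFrame:
    """(FPR, TPR) pairs at every distinct threshold, for ROC plotting."""
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    distinct = np.r_[np.where(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tpr = tps[distinct] / y.sum()
    fpr = fps[distinct] / (len(y) - y.sum())
    return pd.DataFrame({"fpr": np.r_[0.0, fpr], "tpr": np.r_[0.0, tpr]})


def export_comparison(comparison: RocComparison, path) -> None:
    with open(path, "w") as fh:
        json.dump(comparison.to_dict(), fh, indent=2)
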