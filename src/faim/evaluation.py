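"""Test-split evaluation: AUC, bootstrap CIs, Youden-thresholded operating points,
fairness metrics and per-variable subgroup gaps.

The comparison layout mirrors a two-dimensional audit: discrimination
(AUC, sensitivity, specificity, each with a 95% percentile-bootstrap CI)
against fairness (equal opportunity, equalized odds, BER equality) for the
fairness-unaware baseline, the under-blindness model (all sensitive
variables excluded) and the selected fairness-aware model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import Dataset, encode_design
from .fairness import (
    FairnessProfile,
    fairness_profile,
    joint_group_labels,
    subgroup_rates,
    youden_threshold,
)
from .glm import predict_probability

logger = logging.getLogger(__name__)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with half credit for ties, via rank sums (O(n log n))."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both outcome classes required")
    ranks = rankdata(scores)
    pos_rank_sum = float(np.sum(ranks[labels == 1]))
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def auc_rows(score_matrix: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Row-wise AUC for a (models x observations) score matrix."""
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both outcome classes required")
    ranks = rankdata(score_matrix, axis=1)
    pos_rank_sum = ranks[:, labels == 1].sum(axis=1)
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def bootstrap_ci(
    statistic,
    arrays: tuple[np.ndarray, ...],
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Seeded nonparametric percentile bootstrap over rows.

    ``statistic`` receives the resampled arrays and returns a scalar; a
    resample on which it raises ``ValueError`` (e.g. a single-class draw) is
    redrawn, with a warning if redraws exceed 10% of B.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    arrays = tuple(np.asarray(a) for a in arrays)
    n = len(arrays[0])
    rng = np.random.default_rng(seed)
    values = np.empty(B)
    redraws = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, n)
            try:
                values[b] = statistic(*(a[idx] for a in arrays))
                break
            except ValueError:
                redraws += 1
                if redraws > 50 * B:  # pragma: no cover - pathological input
                    raise RuntimeError("bootstrap cannot find a valid resample")
    if redraws > 0.1 * B:
        logger.warning("bootstrap redrew %d resamples (>10%% of B=%d)", redraws, B)
    lo, hi = np.percentile(values, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return float(lo), float(hi)


@dataclass
class MetricsReport:
    """One comparison row: discrimination with CIs plus fairness metrics."""

    label: str
    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    equal_opportunity: float
    equalized_odds: float
    ber_equality: float
    threshold: float

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "auc": self.auc,
            "auc_ci_low": self.auc_ci[0],
            "auc_ci_high": self.auc_ci[1],
            "sensitivity": self.sensitivity,
            "sensitivity_ci_low": self.sensitivity_ci[0],
            "sensitivity_ci_high": self.sensitivity_ci[1],
            "specificity": self.specificity,
            "specificity_ci_low": self.specificity_ci[0],
            "specificity_ci_high": self.specificity_ci[1],
            "equal_opportunity": self.equal_opportunity,
            "equalized_odds": self.equalized_odds,
            "ber_equality": self.ber_equality,
            "threshold": self.threshold,
        }


def reports_frame(reports: list[MetricsReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in reports])


def _sensitivity(preds: np.ndarray, labels: np.ndarray) -> float:
    pos = labels == 1
    if not pos.any():
        raise ValueError("no positives")
    return float(np.mean(preds[pos]))


def _specificity(preds: np.ndarray, labels: np.ndarray) -> float:
    neg = labels == 0
    if not neg.any():
        raise ValueError("no negatives")
    return float(1.0 - np.mean(preds[neg]))


def evaluate_on_test(
    beta: np.ndarray,
    case,
    data: Dataset,
    label: str = "custom",
    audited: tuple[str, ...] | None = None,
    B: int = 1000,
    seed: int = 0,
    min_count: int = 20,
) -> MetricsReport:
    """Evaluate a coefficient vector on the test split.

    The classification threshold is fit on the *validation* split by
    Youden's J and applied unchanged to the test split (the threshold is
    model policy, not a test-set quantity); sensitivity/specificity CIs
    bootstrap the thresholded predictions with the threshold held fixed.
    """
    validation = data.subset("validation")
    test = data.subset("test")
    probs_val = predict_probability(beta, encode_design(validation, data.schema, case))
    threshold = youden_threshold(probs_val, validation.outcome)

    probs = predict_probability(beta, encode_design(test, data.schema, case))
    y = test.outcome
    preds = (probs >= threshold).astype(int)

    point_auc = auc(probs, y)
    auc_ci = bootstrap_ci(auc, (probs, y), B=B, seed=seed)
    sens = _sensitivity(preds, y)
    sens_ci = bootstrap_ci(_sensitivity, (preds, y), B=B, seed=seed + 1)
    spec = _specificity(preds, y)
    spec_ci = bootstrap_ci(_specificity, (preds, y), B=B, seed=seed + 2)

    groups = joint_group_labels(test, audited)
    profile: FairnessProfile = fairness_profile(
        subgroup_rates(preds, y, groups, min_count=min_count), threshold=threshold
    )
    return MetricsReport(
        label=label,
        auc=point_auc,
        auc_ci=auc_ci,
        sensitivity=sens,
        sensitivity_ci=sens_ci,
        specificity=spec,
        specificity_ci=spec_ci,
        equal_opportunity=profile.equal_opportunity,
        equalized_odds=profile.equalized_odds,
        ber_equality=profile.ber_equality,
        threshold=threshold,
    )


def marginal_subgroup_gaps(
    beta: np.ndarray,
    case,
    data: Dataset,
    variable: str,
    min_count: int = 20,
    threshold: float | None = None,
) -> dict[str, float]:
    """Max-min TPR and TNR gaps across one sensitive variable's marginal levels.

    Other sensitive variables are marginalized over; levels with undefined
    rates are excluded with a warning (handled inside the rate ranges).
    """
    if variable not in data.schema.sensitive and variable not in data.schema.predictors:
        raise ValueError(f"unknown variable {variable!r}")
    validation = data.subset("validation")
    test = data.subset("test")
    if test.frame[variable].nunique() < 2:
        raise ValueError(f"variable {variable!r} has fewer than 2 levels in the test split")
    if threshold is None:
        probs_val = predict_probability(beta, encode_design(validation, data.schema, case))
        threshold = youden_threshold(probs_val, validation.outcome)
    probs = predict_probability(beta, encode_design(test, data.schema, case))
    preds = (probs >= threshold).astype(int)
    rates = subgroup_rates(preds, test.outcome, test.frame[variable].astype(str).to_numpy(), min_count=min_count)
    tpr = rates.table["tpr"].to_numpy(dtype=float)
    tnr = rates.table["tnr"].to_numpy(dtype=float)

    def rng(v: np.ndarray) -> float:
        v = v[np.isfinite(v)]
        return 0.0 if len(v) < 2 else float(v.max() - v.min())

    if np.isnan(tpr).any() or np.isnan(tnr).any():
        logger.warning("variable %r: some levels have undefined rates; excluded from gaps", variable)
    return {"variable": variable, "delta_tpr": rng(tpr), "delta_tnr": rng(tnr)}
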