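"""Separation-based fairness metrics, the fairness ranking index, and model selection.

All metrics are ranges (max minus min) of conditional error rates across
subgroups defined by the joint levels of the audited sensitive variables:

* equal opportunity   = range of true-positive rates,
* equalized odds      = max of the TPR range and the FPR range,
* BER equality        = range of (FPR + FNR).

Smaller is fairer.  The fairness ranking index (FRI) aggregates the metric
vector (m_1, ..., m_J) through the circular sum of adjacent products,

    FRI = 1 / sum_j m_j * m_{j+1},   with m_{J+1} := m_1,

so that a model has to be good on *pairs* of adjacent metrics to rank high
(the analogue of a small radar-chart area).  A model perfect on all metrics
gets FRI = +inf and ranks first.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Dataset, encode_design
from .glm import predict_probability

logger = logging.getLogger(__name__)

OTHER_GROUP = "(other)"


class SelectionError(ValueError):
    """No ranked model satisfies the requested constraint."""


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidate cutoffs are the observed scores; prediction rule is
    ``yhat = 1 iff score >= t``.  Ties in J are broken toward the largest
    cutoff (favors specificity), which makes the choice deterministic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes required to compute a Youden threshold")
    thresholds = np.unique(scores)  # ascending
    # at cutoff t: TP = #pos with score >= t, FP = #neg with score >= t
    pos_scores = np.sort(scores[labels == 1])
    neg_scores = np.sort(scores[labels == 0])
    tp = n_pos - np.searchsorted(pos_scores, thresholds, side="left")
    fp = n_neg - np.searchsorted(neg_scores, thresholds, side="left")
    # integer-exact J comparison: J ∝ tp*n_neg - fp*n_pos, so ties are exact
    j_scaled = tp * n_neg - fp * n_pos
    best = np.flatnonzero(j_scaled == j_scaled.max())[-1]
    return float(thresholds[best])


@dataclass
class SubgroupRates:
    """Confusion-matrix rates per subgroup (joint sensitive-variable levels).

    Subgroups smaller than ``min_count`` are pooled into ``(other)`` before
    rates are computed; a subgroup lacking positives (or negatives) has its
    TPR/FNR (or FPR/TNR) undefined (NaN) and is skipped by range metrics.
    """

    table: pd.DataFrame  # index: subgroup; columns: count, positives, negatives, tpr, fpr, tnr, fnr
    merged: list[str] = field(default_factory=list)

    @property
    def subgroups(self) -> list[str]:
        return list(self.table.index)


def subgroup_rates(
    predicted: np.ndarray,
    labels: np.ndarray,
    groups: np.ndarray | pd.Series,
    min_count: int = 20,
) -> SubgroupRates:
    predicted = np.asarray(predicted, dtype=int)
    labels = np.asarray(labels, dtype=int)
    groups = np.asarray(groups, dtype=object).astype(str)
    if len(predicted) == 0:
        raise ValueError("empty input")
    if not (len(predicted) == len(labels) == len(groups)):
        raise ValueError("predicted, labels and groups must have equal length")

    names, counts = np.unique(groups, return_counts=True)
    small = set(names[counts < min_count])
    if small:
        logger.info("pooling %d subgroups below min_count=%d into %r", len(small), min_count, OTHER_GROUP)
        groups = np.where(np.isin(groups, list(small)), OTHER_GROUP, groups)

    rows = {}
    for g in np.unique(groups):
        m = groups == g
        y, yhat = labels[m], predicted[m]
        pos = int(np.sum(y == 1))
        neg = int(np.sum(y == 0))
        tp = int(np.sum((y == 1) & (yhat == 1)))
        fp = int(np.sum((y == 0) & (yhat == 1)))
        tpr = tp / pos if pos else np.nan
        fpr = fp / neg if neg else np.nan
        rows[g] = {
            "count": int(m.sum()),
            "positives": pos,
            "negatives": neg,
            "tpr": tpr,
            "fpr": fpr,
            "tnr": 1.0 - fpr if neg else np.nan,
            "fnr": 1.0 - tpr if pos else np.nan,
        }
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return SubgroupRates(table=table, merged=sorted(small))


@dataclass
class FairnessProfile:
    """The three separation-metric values of one model at one threshold."""

    equal_opportunity: float
    equalized_odds: float
    ber_equality: float
    threshold: float = math.nan

    def metrics(self) -> tuple[float, ...]:
        """Metric vector in FRI order."""
        return (self.equal_opportunity, self.equalized_odds, self.ber_equality)

    @property
    def fri(self) -> float:
        return fri(self.metrics())


def _range(values: np.ndarray) -> float:
    vals = values[np.isfinite(values)]
    if len(vals) == 0:
        return math.nan
    return float(vals.max() - vals.min())


def fairness_profile(rates: SubgroupRates, threshold: float = math.nan) -> FairnessProfile:
    """Range-based metrics over subgroups with defined rates."""
    tpr = rates.table["tpr"].to_numpy(dtype=float)
    fpr = rates.table["fpr"].to_numpy(dtype=float)
    eo = _range(tpr)
    fpr_range = _range(fpr)
    ber = _range(fpr + (1.0 - tpr))  # FPR + FNR per subgroup
    if math.isnan(eo) and math.isnan(fpr_range):
        raise ValueError("all subgroups have undefined rates")
    if math.isnan(eo) or math.isnan(fpr_range):
        logger.warning("one rate family undefined in every subgroup; metrics fall back to the defined family")
    eo = 0.0 if math.isnan(eo) else eo
    fpr_range = 0.0 if math.isnan(fpr_range) else fpr_range
    ber = 0.0 if math.isnan(ber) else ber
    return FairnessProfile(
        equal_opportunity=eo,
        equalized_odds=max(eo, fpr_range),
        ber_equality=ber,
        threshold=threshold,
    )


def fri(metrics) -> float:
    """Fairness ranking index: inverse circular sum of adjacent metric products."""
    m = np.asarray(list(metrics), dtype=float)
    if np.any(m < 0):
        raise ValueError("fairness metrics must be nonnegative")
    denom = float(np.sum(m * np.roll(m, -1)))
    return math.inf if denom == 0.0 else 1.0 / denom


@dataclass
class RankedModel:
    """An IRS member with its fairness profile, FRI and rank."""

    candidate: "object"  # rashomon.CandidateModel (kept loose to avoid an import cycle)
    profile: FairnessProfile
    fri: float
    threshold: float
    rank: int = 0

    @property
    def candidate_id(self) -> int:
        return self.candidate.candidate_id

    @property
    def case_id(self) -> str:
        return self.candidate.case.case_id


def joint_group_labels(data: Dataset, audited: tuple[str, ...] | None = None) -> np.ndarray:
    """Intersectional subgroup label per row, e.g. ``race=B|sex=F``."""
    audited = tuple(audited) if audited else tuple(data.schema.sensitive)
    parts = [data.frame[v].astype(str).map(lambda x, v=v: f"{v}={x}") for v in audited]
    out = parts[0]
    for p in parts[1:]:
        out = out + "|" + p
    return out.to_numpy(dtype=object)


def rank_irs(
    irs,
    validation: Dataset,
    audited: tuple[str, ...] | None = None,
    min_count: int = 20,
) -> list[RankedModel]:
    """Rank every IRS member by FRI computed on the validation split.

    For each member: predicted probabilities -> per-model Youden threshold ->
    binary predictions -> joint-subgroup rates -> metric profile -> FRI.
    Sort order: FRI descending, ties by equalized odds ascending, then by
    candidate id (deterministic and input-order invariant).
    """
    y = validation.outcome
    groups = joint_group_labels(validation, audited)
    designs: dict[str, np.ndarray] = {}
    ranked: list[RankedModel] = []
    for member in irs.members:
        cid = member.case.case_id
        if cid not in designs:
            designs[cid] = encode_design(validation, validation.schema, member.case).X
        probs = predict_probability(member.beta, designs[cid])
        t = youden_threshold(probs, y)
        preds = (probs >= t).astype(int)
        rates = subgroup_rates(preds, y, groups, min_count=min_count)
        profile = fairness_profile(rates, threshold=t)
        ranked.append(RankedModel(candidate=member, profile=profile, fri=profile.fri, threshold=t))
    ranked.sort(key=lambda r: (-r.fri, r.profile.equalized_odds, r.candidate_id))
    for i, r in enumerate(ranked, start=1):
        r.rank = i
    return ranked


def ranking_frame(ranked: list[RankedModel]) -> pd.DataFrame:
    """Flat export of a ranking (one row per model)."""
    return pd.DataFrame(
        {
            "rank": [r.rank for r in ranked],
            "candidate_id": [r.candidate_id for r in ranked],
            "case_id": [r.case_id for r in ranked],
            "fri": [r.fri for r in ranked],
            "equal_opportunity": [r.profile.equal_opportunity for r in ranked],
            "equalized_odds": [r.profile.equalized_odds for r in ranked],
            "ber_equality": [r.profile.ber_equality for r in ranked],
            "threshold": [r.threshold for r in ranked],
            "validation_auc": [r.candidate.validation_metric for r in ranked],
        }
    )


def tabulate_by_case(ranked: list[RankedModel], n_bins: int = 4) -> pd.DataFrame:
    """Counts of each exclusion case's models per fairness-rank bin + best rank.

    Ranks 1..N are cut into ``n_bins`` contiguous near-equal bins ordered
    from most fair to least fair.
    """
    if not ranked:
        raise ValueError("empty ranking")
    n = len(ranked)
    if n_bins > n:
        raise ValueError(f"n_bins={n_bins} exceeds the number of ranked models ({n})")
    chunks = np.array_split(np.arange(1, n + 1), n_bins)
    bin_labels = [f"ranks {c[0]}-{c[-1]}" for c in chunks]
    edges = np.array([c[-1] for c in chunks])
    cases = sorted({r.case_id for r in ranked})
    table = pd.DataFrame(0, index=cases, columns=bin_labels + ["best_rank"])
    table["best_rank"] = n + 1
    for r in ranked:
        b = int(np.searchsorted(edges, r.rank, side="left"))
        table.loc[r.case_id, bin_labels[b]] += 1
        table.loc[r.case_id, "best_rank"] = min(table.loc[r.case_id, "best_rank"], r.rank)
    table.index.name = "case_id"
    return table


@dataclass
class SelectedModel:
    """The fairness-aware model: coefficients, case, threshold, profile, rank."""

    beta: np.ndarray
    case: "object"
    columns: tuple[str, ...]
    register: dict[str, str]
    candidate_id: int
    threshold: float
    profile: FairnessProfile
    fri: float
    rank: int


def select_model(
    ranked: list[RankedModel],
    must_exclude: tuple[str, ...] | None = None,
    choice: int | None = None,
) -> SelectedModel:
    """Pick the fairness-aware model from a ranking.

    Default is the rank-1 model.  ``must_exclude`` restricts to models whose
    exclusion case drops every listed sensitive variable (the contextual
    override); ``choice`` selects an explicit candidate id and overrides both.
    """
    if not ranked:
        raise ValueError("empty ranking")
    pool = ranked
    if choice is not None:
        pool = [r for r in ranked if r.candidate_id == choice]
        if not pool:
            raise SelectionError(f"no ranked model has candidate_id={choice}")
    elif must_exclude:
        pool = [r for r in ranked if all(r.candidate.case.excludes(v) for v in must_exclude)]
        if not pool:
            nearest = ", ".join(f"{r.case_id} (rank {r.rank})" for r in ranked[:3])
            raise SelectionError(
                f"no model excludes all of {tuple(must_exclude)}; best-ranked alternatives: {nearest}"
            )
    best = min(pool, key=lambda r: r.rank)
    logger.info(
        "selected candidate %d (case %s, rank %d, FRI %.4g)",
        best.candidate_id, best.case_id, best.rank, best.fri,
    )
    member = best.candidate
    return SelectedModel(
        beta=np.asarray(member.beta, dtype=float),
        case=member.case,
        columns=member.columns,
        register=dict(member.register),
        candidate_id=best.candidate_id,
        threshold=best.threshold,
        profile=best.profile,
        fri=best.fri,
        rank=best.rank,
    )
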