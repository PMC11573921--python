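"""Near-optimal model generation by rejection sampling.

For each sensitive-variable exclusion case S', candidate coefficient vectors
are drawn from N(beta*, k_i Sigma*) around that case's optimum, with the
scope-width k_i ~ U(u1, u2), and kept when their validation performance M
(AUC by default) satisfies M >= (1 - eps0) * M(case optimum).  The integral
Rashomon set (IRS) is the union of the surviving candidates across every
case whose own optimum is near-optimal relative to the full model:
M(case optimum) >= (1 - eps0) * M(full-model optimum).

With the default calibration eps0 = 1 - sqrt(1 - eps), the two slacks
compound multiplicatively so every IRS member is guaranteed to satisfy
M >= (1 - eps) * M(full-model optimum).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Dataset, encode_design
from .evaluation import auc_rows
from .glm import ExclusionCase, FittedModel, predict_probability

logger = logging.getLogger(__name__)


def default_epsilon0(epsilon: float) -> float:
    """Case-level slack such that (1-eps0)^2 = 1-eps."""
    return 1.0 - math.sqrt(1.0 - epsilon)


@dataclass
class RashomonConfig:
    """Sampling and rejection parameters.

    epsilon : overall near-optimality slack for the IRS (default 0.05).
    epsilon0 : case-level slack; derived as 1-sqrt(1-epsilon) when None.
    u1, u2 : bounds of the uniform law for the covariance scale k.
    n_draws_per_case : fixed pre-filter draw budget per admitted case.
    metric : "auc" (validation AUC, the practical anchor) or "loss"
        (mean validation log-loss; rejection then uses <= (1+eps0) * optimum).
    seed : master seed; each case gets an independent derived stream.
    """

    epsilon: float = 0.05
    epsilon0: float | None = None
    u1: float = 0.5
    u2: float = 2.0
    n_draws_per_case: int = 2000
    metric: str = "auc"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.epsilon < 1.0):
            raise ValueError("epsilon must be in (0,1)")
        if self.epsilon0 is None:
            self.epsilon0 = default_epsilon0(self.epsilon)
        if not (0.0 < self.epsilon0 <= self.epsilon):
            raise ValueError("need 0 < epsilon0 <= epsilon")
        if not (0.0 <= self.u1 <= self.u2):
            raise ValueError("need 0 <= u1 <= u2")
        if self.n_draws_per_case < 1:
            raise ValueError("n_draws_per_case must be >= 1")
        if self.metric not in ("auc", "loss"):
            raise ValueError(f"unknown metric {self.metric!r}")


@dataclass
class CandidateModel:
    """One sampled coefficient vector with its provenance and accept status."""

    case: ExclusionCase
    beta: np.ndarray
    k: float
    columns: tuple[str, ...]
    register: dict[str, str]
    candidate_id: int = -1
    validation_metric: float = math.nan
    accepted: bool = False


@dataclass
class CaseAdmission:
    """Per-case bookkeeping for the IRS assembly."""

    case_id: str
    case_metric: float
    admitted: bool
    n_drawn: int = 0
    n_accepted: int = 0


@dataclass
class IRS:
    """The integral Rashomon set: accepted candidates across admitted cases."""

    members: list[CandidateModel]
    admission: dict[str, CaseAdmission]
    global_anchor: float
    config: RashomonConfig

    @property
    def size(self) -> int:
        return len(self.members)

    def to_frame(self) -> pd.DataFrame:
        """Wide export: one row per member, coefficients as named columns."""
        rows = []
        for m in self.members:
            row = {
                "candidate_id": m.candidate_id,
                "case_id": m.case.case_id,
                "k": m.k,
                "validation_metric": m.validation_metric,
            }
            row.update({f"beta:{c}": v for c, v in zip(m.columns, m.beta)})
            rows.append(row)
        return pd.DataFrame(rows)

    def admission_record(self) -> dict:
        return {
            "global_anchor": self.global_anchor,
            "epsilon": self.config.epsilon,
            "epsilon0": self.config.epsilon0,
            "metric": self.config.metric,
            "cases": {
                cid: {
                    "case_metric": a.case_metric,
                    "admitted": a.admitted,
                    "n_drawn": a.n_drawn,
                    "n_accepted": a.n_accepted,
                }
                for cid, a in self.admission.items()
            },
        }


def _cholesky_with_jitter(sigma: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * np.trace(sigma) / sigma.shape[0]
        logger.warning("covariance not PD; retrying Cholesky with diagonal jitter %.3g", jitter)
        try:
            return np.linalg.cholesky(sigma + jitter * np.eye(sigma.shape[0]))
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariance matrix not decomposable even with jitter") from exc


def draw_candidates(
    model: FittedModel,
    cfg: RashomonConfig,
    rng: np.random.Generator | None = None,
) -> list[CandidateModel]:
    """Draw the pre-filter candidate list for one case.

    Per draw i: k_i ~ U(u1, u2), then beta_i ~ N(beta*, k_i Sigma*) via the
    Cholesky factor (scaled by sqrt(k_i)).  The draw sequence is a prefix of
    any longer sequence from the same stream, so enlarging the budget only
    appends candidates.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    L = _cholesky_with_jitter(model.sigma)
    p = model.beta.shape[0]
    out = []
    for _ in range(cfg.n_draws_per_case):
        k = float(rng.uniform(cfg.u1, cfg.u2))
        z = rng.standard_normal(p)
        beta = model.beta + math.sqrt(k) * (L @ z)
        out.append(
            CandidateModel(
                case=model.case, beta=beta, k=k,
                columns=model.columns, register=dict(model.register),
            )
        )
    return out


def _score_candidates(
    candidates: list[CandidateModel],
    X_val: np.ndarray,
    y_val: np.ndarray,
    metric: str,
) -> np.ndarray:
    betas = np.stack([c.beta for c in candidates])
    if metric == "auc":
        probs = predict_probability_matrix(betas, X_val)
        return auc_rows(probs, y_val)
    # mean log-loss (reported as positive loss; smaller is better)
    eta = betas @ X_val.T
    y = np.asarray(y_val, dtype=float)
    ll = (y * eta - np.logaddexp(0.0, eta)).mean(axis=1)
    return -ll


def predict_probability_matrix(betas: np.ndarray, X: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(betas @ X.T)


def score_model(model_beta: np.ndarray, X_val: np.ndarray, y_val: np.ndarray, metric: str) -> float:
    if metric == "auc":
        from .evaluation import auc

        return auc(predict_probability(model_beta, X_val), y_val)
    eta = X_val @ model_beta
    y = np.asarray(y_val, dtype=float)
    return float(-(y * eta - np.logaddexp(0.0, eta)).mean())


def _passes(metric_value: np.ndarray | float, anchor: float, cfg: RashomonConfig):
    if cfg.metric == "auc":
        return metric_value >= (1.0 - cfg.epsilon0) * anchor
    return metric_value <= (1.0 + cfg.epsilon0) * anchor


def filter_near_optimal(
    candidates: list[CandidateModel],
    X_val: np.ndarray,
    y_val: np.ndarray,
    case_optimal_metric: float,
    cfg: RashomonConfig,
) -> list[CandidateModel]:
    """Score candidates on the validation split and keep the near-optimal ones."""
    y_val = np.asarray(y_val)
    if y_val.min() == y_val.max():
        raise ValueError("validation split needs both outcome classes")
    if not candidates:
        return []
    scores = _score_candidates(candidates, X_val, y_val, cfg.metric)
    ok = _passes(scores, case_optimal_metric, cfg)
    for c, s, flag in zip(candidates, scores, ok):
        c.validation_metric = float(s)
        c.accepted = bool(flag)
    accepted = [c for c in candidates if c.accepted]
    logger.info("accepted %d / %d candidates", len(accepted), len(candidates))
    return accepted


def assemble_irs(
    case_models: dict[ExclusionCase, FittedModel],
    data: Dataset,
    cfg: RashomonConfig,
) -> IRS:
    """Build the integral Rashomon set from the per-case optima.

    Steps: (1) global anchor = full-model optimum's validation metric;
    (2) admit a case iff its own optimum meets the case-admission bound
    against the global anchor; (3) draw and filter candidates per admitted
    case; (4) take the union with per-case provenance.
    """
    schema = data.schema
    full = ExclusionCase(retained=tuple(schema.sensitive))
    if full not in case_models:
        raise ValueError("the full (no-exclusion) case must be among the fitted models")
    validation = data.subset("validation")
    y_val = validation.outcome

    # canonical case order for deterministic per-case seed streams
    ordered = sorted(case_models, key=lambda c: (-len(c.retained), c.case_id))
    designs = {c: encode_design(validation, schema, c).X for c in ordered}
    case_metrics = {
        c: score_model(case_models[c].beta, designs[c], y_val, cfg.metric) for c in ordered
    }
    global_anchor = case_metrics[full]

    members: list[CandidateModel] = []
    admission: dict[str, CaseAdmission] = {}
    next_id = 0
    base_seed = cfg.seed & 0x7FFFFFFF
    for idx, case in enumerate(ordered):
        metric = case_metrics[case]
        admitted = bool(_passes(metric, global_anchor, cfg))
        record = CaseAdmission(case_id=case.case_id, case_metric=metric, admitted=admitted)
        if admitted:
            rng = np.random.default_rng([base_seed, idx])
            cands = draw_candidates(case_models[case], cfg, rng=rng)
            for c in cands:
                c.candidate_id = next_id
                next_id += 1
            record.n_drawn = len(cands)
            accepted = filter_near_optimal(cands, designs[case], y_val, metric, cfg)
            record.n_accepted = len(accepted)
            members.extend(accepted)
        admission[case.case_id] = record
    assert any(a.admitted for a in admission.values()), "full case must always be admitted"
    logger.info(
        "IRS assembled: %d members over %d admitted cases (anchor %.4f)",
        len(members), sum(a.admitted for a in admission.values()), global_anchor,
    )
    return IRS(members=members, admission=admission, global_anchor=global_anchor, config=cfg)
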