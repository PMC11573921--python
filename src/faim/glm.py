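"""Logistic regression core: exclusion cases, Newton/IRLS fitting, Wald inference.

The case-specific optimum beta* and its inverse-Fisher-information covariance
Sigma* are the anchor of the near-optimal model sampler, so the fit exposes
both, plus the log-likelihood and convergence diagnostics.  The optimizer is
deterministic (Newton with step-halving, started at the zero vector), so a
refit on identical data is bit-stable.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .data import DesignMatrix, INTERCEPT

logger = logging.getLogger(__name__)

#: 95% two-sided normal quantile used for all Wald intervals.
Z95 = 1.959964

MAX_SENSITIVE = 10


class SeparationError(RuntimeError):
    """Perfect or quasi-complete separation: the MLE diverges."""


class SingularInformationError(RuntimeError):
    """The observed information matrix is singular at the current iterate."""


@dataclass(frozen=True)
class ExclusionCase:
    """A subset S' of the sensitive variables retained in the model."""

    retained: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "retained", tuple(self.retained))

    @property
    def case_id(self) -> str:
        return "keep:" + ("+".join(self.retained) if self.retained else "none")

    def retains(self, name: str) -> bool:
        return name in self.retained

    def excludes(self, name: str) -> bool:
        return name not in self.retained

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.case_id


def enumerate_cases(sensitive_names: tuple[str, ...] | list[str]) -> list[ExclusionCase]:
    """All 2^k retained-subsets of the sensitive variables, in canonical order.

    Order: subset size descending (full model first, complete exclusion
    last), ties broken lexicographically by case id.  Deterministic across
    calls.
    """
    names = tuple(sensitive_names)
    k = len(names)
    if k == 0:
        raise ValueError("no sensitive variables declared: nothing to audit")
    if k > MAX_SENSITIVE:
        raise ValueError(
            f"{k} sensitive variables would require {2**k} exclusion cases; "
            f"audit at most {MAX_SENSITIVE} at a time"
        )
    cases = []
    for r in range(k, -1, -1):
        level = [ExclusionCase(retained=combo) for combo in itertools.combinations(names, r)]
        level.sort(key=lambda c: c.case_id)
        cases.extend(level)
    return cases


@dataclass
class FittedModel:
    """Maximum-likelihood logistic fit for one exclusion case.

    ``sigma`` is the inverse observed Fisher information at ``beta``; its
    scaled versions parameterize the multivariate-normal coefficient sampler.
    """

    case: ExclusionCase | None
    beta: np.ndarray
    sigma: np.ndarray
    log_likelihood: float
    columns: tuple[str, ...]
    register: dict[str, str]
    n_iter: int
    max_score: float
    converged: bool

    def predict(self, design: DesignMatrix) -> np.ndarray:
        return predict_probability(self.beta, design)


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # sum y*eta - log(1+exp(eta)), numerically stable at large |eta|
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def log_likelihood(beta: np.ndarray, design: DesignMatrix, y: np.ndarray) -> float:
    """Bernoulli log-likelihood of *beta* on (design, y)."""
    return _log_likelihood(design.X @ beta, np.asarray(y, dtype=float))


def observed_information(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Observed Fisher information X' W X with W = p(1-p) at *beta*."""
    p = expit(X @ beta)
    w = p * (1.0 - p)
    return (X * w[:, None]).T @ X


def covariance_at(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Inverse observed information at an arbitrary coefficient vector.

    Used to attach Fisher-information standard errors to the selected
    fairness-aware coefficients exactly as is done for the optimum.
    """
    info = observed_information(X, beta)
    try:
        return np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate input
        raise SingularInformationError("information matrix singular at given beta") from exc


def fit_logistic(
    design: DesignMatrix,
    outcome: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    max_abs_beta: float = 30.0,
) -> FittedModel:
    """Fit logistic regression by Newton iterations with step-halving.

    Starts at the zero vector; convergence is declared when the score
    (gradient) max-norm falls below *tol*.  A coefficient exceeding
    *max_abs_beta* in magnitude, or failure to converge, is treated as the
    signature of (quasi-)complete separation.
    """
    X = design.X
    y = np.asarray(outcome, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more rows ({n}) than design columns ({p})")
    if y.min() == y.max():
        raise ValueError("outcome has a single class; logistic fit undefined")

    beta = np.zeros(p)
    ll = _log_likelihood(X @ beta, y)
    score = X.T @ (y - expit(X @ beta))
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        info = observed_information(X, beta)
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SingularInformationError(
                "singular information matrix; check for collinear or constant columns"
            ) from exc
        # step-halving keeps the iteration monotone in the log-likelihood
        step = 1.0
        for _ in range(40):
            cand = beta + step * delta
            cand_ll = _log_likelihood(X @ cand, y)
            if cand_ll >= ll - 1e-12:
                break
            step *= 0.5
        beta, ll = cand, cand_ll
        if np.max(np.abs(beta)) > max_abs_beta:
            j = int(np.argmax(np.abs(beta)))
            raise SeparationError(
                f"coefficient for column {design.columns[j]!r} diverged "
                f"(|beta|>{max_abs_beta}); data are likely separated by this column"
            )
        score = X.T @ (y - expit(X @ beta))
        if np.max(np.abs(score)) < tol:
            break
    max_score = float(np.max(np.abs(score)))
    if max_score >= tol:
        raise SeparationError(
            f"no convergence in {max_iter} Newton iterations (score max-norm {max_score:.3g}); "
            "data may be quasi-separated"
        )
    info = observed_information(X, beta)
    try:
        sigma = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise SingularInformationError("information matrix singular at the optimum") from exc
    sigma = (sigma + sigma.T) / 2.0
    # quasi-separation can saturate the score below tol while |beta| is still
    # moderate; an exploding Wald standard error is its other signature
    se = np.sqrt(np.clip(np.diag(sigma), 0.0, None))
    if np.any(se > 100.0):
        j = int(np.argmax(se))
        raise SeparationError(
            f"standard error for column {design.columns[j]!r} exploded (se={se[j]:.3g}); "
            "data are likely separated by this column"
        )
    return FittedModel(
        case=design.case,
        beta=beta,
        sigma=sigma,
        log_likelihood=ll,
        columns=design.columns,
        register=dict(design.register),
        n_iter=n_iter,
        max_score=max_score,
        converged=True,
    )


def predict_probability(beta: np.ndarray, design: DesignMatrix | np.ndarray) -> np.ndarray:
    """Elementwise logistic response 1/(1+exp(-X beta)), overflow-safe."""
    X = design.X if isinstance(design, DesignMatrix) else np.asarray(design, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if X.shape[1] != beta.shape[0]:
        raise ValueError(f"design has {X.shape[1]} columns but beta has {beta.shape[0]}")
    return expit(X @ beta)


def _split_term(column: str, register: dict[str, str]) -> tuple[str, str]:
    term = register.get(column, column)
    if column.endswith("]") and "[" in column:
        return term, column[column.index("[") + 1 : -1]
    return term, ""


def wald_odds_ratios(model: FittedModel, beta: np.ndarray | None = None, sigma: np.ndarray | None = None) -> pd.DataFrame:
    """Per-coefficient odds ratios with 95% Wald intervals (intercept omitted).

    Rows with a non-finite or zero standard error are kept but flagged.
    Passing *beta*/*sigma* overrides the fitted values, which lets the same
    machinery report inference for a sampled near-optimal coefficient vector.
    """
    b = model.beta if beta is None else np.asarray(beta, dtype=float)
    s = model.sigma if sigma is None else np.asarray(sigma, dtype=float)
    se = np.sqrt(np.clip(np.diag(s), 0.0, None))
    rows = []
    for j, col in enumerate(model.columns):
        if col == INTERCEPT:
            continue
        term, level = _split_term(col, model.register)
        bad = not np.isfinite(se[j]) or se[j] == 0.0
        z = np.nan if bad else b[j] / se[j]
        rows.append(
            {
                "term": term,
                "level": level,
                "odds_ratio": float(np.exp(b[j])),
                "ci_low": np.nan if bad else float(np.exp(b[j] - Z95 * se[j])),
                "ci_high": np.nan if bad else float(np.exp(b[j] + Z95 * se[j])),
                "z": z,
                "p_value": np.nan if bad else float(2.0 * norm.sf(abs(z))),
                "flagged": bad,
            }
        )
    table = pd.DataFrame(rows)
    if table["flagged"].any():
        logger.warning("%d coefficients have degenerate standard errors", int(table["flagged"].sum()))
    return table
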