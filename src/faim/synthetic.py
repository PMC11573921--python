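"""Seeded synthetic emergency-department admission cohorts with known ground truth.

The generator emulates a triage-to-admission cohort: two sensitive
attributes (a four-level ``race`` and a binary ``sex``), five standardized
continuous vitals-like predictors, and a three-level ``triage`` acuity
score.  Subgroup bias can be injected through three mechanisms that
separation-based fairness metrics respond to:

* ``delta``   — per-race-level intercept shifts in the outcome model,
* ``rho``     — per-race-level label-flip (noise) rates after generation,
* ``proxy_r`` — correlation linking the ``pain_score`` predictor to race,
                so bias persists even when race is excluded from a model.

With all knobs at zero the outcome follows one logistic law identical
across subgroups, so the generating process is separation-fair by
construction and the fitted full model's measured gaps shrink to zero as
the sample grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data import Dataset, Schema, from_dataframe

RACE_LEVELS = ("A", "B", "C", "D")
SEX_LEVELS = ("F", "M")
TRIAGE_LEVELS = ("P1", "P2", "P3")
CONTINUOUS = ("age", "heart_rate", "resp_rate", "sbp", "pain_score")
PROXY = "pain_score"


def cohort_schema() -> Schema:
    return Schema(
        outcome="admitted",
        sensitive=("race", "sex"),
        predictors=(*CONTINUOUS, "triage"),
        categorical_levels={
            "race": RACE_LEVELS,
            "sex": SEX_LEVELS,
            "triage": TRIAGE_LEVELS,
        },
    )


@dataclass
class CohortSpec:
    """Generating parameters for one synthetic cohort.

    Subgroup probabilities are equal by default so every audit group has the
    same statistical support; real cohorts are more skewed (a deliberately
    non-emulated feature).  Effect sizes are moderate and the marginal
    admission prevalence is ~0.45.
    """

    n: int = 10_000
    race_probs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    sex_prob_f: float = 0.5
    triage_probs: tuple[float, ...] = (0.4, 0.35, 0.25)
    intercept: float = -0.2
    beta_continuous: tuple[float, ...] = (0.4, 0.3, 0.3, 0.2, 0.1)
    beta_triage: tuple[float, ...] = (0.0, -0.3, -0.6)  # per level, reference first
    delta: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)     # per race level
    rho: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)       # per race level
    proxy_r: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, k in (("race_probs", len(RACE_LEVELS)), ("triage_probs", len(TRIAGE_LEVELS))):
            probs = tuple(float(p) for p in getattr(self, name))
            setattr(self, name, probs)
            if len(probs) != k or abs(sum(probs) - 1.0) > 1e-9 or any(p <= 0 for p in probs):
                raise ValueError(f"{name} must be {k} positive values summing to 1")
        self.beta_continuous = tuple(float(b) for b in self.beta_continuous)
        self.beta_triage = tuple(float(b) for b in self.beta_triage)
        self.delta = tuple(float(d) for d in self.delta)
        self.rho = tuple(float(r) for r in self.rho)
        if len(self.delta) != len(RACE_LEVELS) or len(self.rho) != len(RACE_LEVELS):
            raise ValueError("delta and rho need one value per race level")
        if any(not (0.0 <= r <= 0.5) for r in self.rho):
            raise ValueError("label-flip rates must lie in [0, 0.5]")
        if not (-1.0 <= self.proxy_r <= 1.0):
            raise ValueError("proxy correlation must lie in [-1, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        for key in ("race_probs", "triage_probs", "beta_continuous", "beta_triage", "delta", "rho"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """The generating record returned with each cohort."""

    spec: CohortSpec
    design_beta: dict[str, float]  # truth on the full-design coefficient scale
    prevalence: float = field(default=np.nan)


def _true_design_beta(spec: CohortSpec) -> dict[str, float]:
    """Truth expressed in full-design (reference-coded) coordinates.

    Race intercept shifts fold into the intercept (reference level) and the
    race dummies; sex carries no true effect; label flips are noise on top
    of this law, so these are the pre-noise coefficients.
    """
    out = {"(Intercept)": spec.intercept + spec.delta[0]}
    for j, level in enumerate(RACE_LEVELS[1:], start=1):
        out[f"race[{level}]"] = spec.delta[j] - spec.delta[0]
    out[f"sex[{SEX_LEVELS[1]}]"] = 0.0
    for name, b in zip(CONTINUOUS, spec.beta_continuous):
        out[name] = float(b)
    for j, level in enumerate(TRIAGE_LEVELS[1:], start=1):
        out[f"triage[{level}]"] = spec.beta_triage[j] - spec.beta_triage[0]
    return out


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> tuple[Dataset, GroundTruth]:
    """Draw one cohort from the spec; identical seeds give identical data."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n

    race_idx = rng.choice(len(RACE_LEVELS), size=n, p=spec.race_probs)
    sex = np.where(rng.random(n) < spec.sex_prob_f, SEX_LEVELS[0], SEX_LEVELS[1])
    triage_idx = rng.choice(len(TRIAGE_LEVELS), size=n, p=spec.triage_probs)

    X = rng.standard_normal((n, len(CONTINUOUS)))
    if spec.proxy_r != 0.0:
        # standardized race code drives the proxy predictor
        codes = np.arange(len(RACE_LEVELS), dtype=float)
        mean = float(np.dot(spec.race_probs, codes))
        var = float(np.dot(spec.race_probs, (codes - mean) ** 2))
        z = (race_idx - mean) / np.sqrt(var)
        j = CONTINUOUS.index(PROXY)
        X[:, j] = spec.proxy_r * z + np.sqrt(1.0 - spec.proxy_r**2) * X[:, j]

    eta = (
        spec.intercept
        + X @ np.asarray(spec.beta_continuous)
        + np.asarray(spec.beta_triage)[triage_idx]
        + np.asarray(spec.delta)[race_idx]
    )
    p = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.random(n) < p).astype(int)
    flip = rng.random(n) < np.asarray(spec.rho)[race_idx]
    y = np.where(flip, 1 - y, y)

    frame = pd.DataFrame({"admitted": y})
    frame["race"] = np.asarray(RACE_LEVELS, dtype=object)[race_idx]
    frame["sex"] = sex
    for j, name in enumerate(CONTINUOUS):
        frame[name] = X[:, j]
    frame["triage"] = np.asarray(TRIAGE_LEVELS, dtype=object)[triage_idx]

    data = from_dataframe(frame, cohort_schema())
    truth = GroundTruth(spec=spec, design_beta=_true_design_beta(spec), prevalence=float(y.mean()))
    return data, truth


def true_subgroup_prevalence(spec: CohortSpec, n_mc: int = 1_000_000, seed: int = 12345) -> pd.Series:
    """Large-sample Monte-Carlo outcome prevalence per race level (noise included)."""
    big = CohortSpec.from_dict({**spec.to_dict(), "n": n_mc, "seed": seed})
    data, _ = generate_cohort(big)
    return data.frame.groupby("race")["admitted"].mean()


def biased_preset(level: str = "none", seed: int = 0, n: int = 10_000) -> CohortSpec:
    """Canned bias scenarios used throughout the end-to-end checks.

    ``strong`` shifts race-level log-odds by (+0.8, 0, 0, -0.8), flips 10%
    of labels in the last race level, and ties the proxy predictor to race
    with correlation 0.6; ``mild`` halves the shifts; ``none`` zeroes all
    knobs.
    """
    base = dict(n=n, seed=seed)
    if level == "none":
        return CohortSpec(**base)
    if level == "mild":
        return CohortSpec(delta=(0.4, 0.0, 0.0, -0.4), rho=(0.0, 0.0, 0.0, 0.05), proxy_r=0.3, **base)
    if level == "strong":
        return CohortSpec(delta=(0.8, 0.0, 0.0, -0.8), rho=(0.0, 0.0, 0.0, 0.1), proxy_r=0.6, **base)
    raise ValueError(f"unknown bias preset {level!r}")
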