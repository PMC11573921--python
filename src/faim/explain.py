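"""Exact Shapley attribution for linear (logistic) models.

For a linear predictor with an independence baseline, the interventional
Shapley value of design column j on the log-odds scale has the closed form

    phi_j(x) = beta_j * (x_j - mean background x_j),

which is the exact limit of sampling-based SHAP estimators.  Dummy-column
contributions are summed to the schema-column level so categorical variables
get a single attribution, and variable importance is the mean absolute
contribution over the explained instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DesignMatrix, INTERCEPT
from .glm import FittedModel


@dataclass
class Attribution:
    """Per-instance, per-column log-odds contributions.

    ``base + phi.sum(axis=1)`` reproduces each instance's linear predictor
    to machine precision.
    """

    phi: pd.DataFrame        # instances x design columns (intercept excluded)
    base: float              # linear predictor at the background mean
    importance: pd.Series    # mean |phi| aggregated to schema columns

    def linear_predictor(self) -> np.ndarray:
        return self.base + self.phi.to_numpy().sum(axis=1)


def _check_alignment(model: FittedModel, design: DesignMatrix) -> None:
    if design.columns != model.columns:
        raise ValueError(
            f"design columns {design.columns} do not match model columns {model.columns}"
        )


def linear_shap(model: FittedModel, background: DesignMatrix, instances: DesignMatrix) -> Attribution:
    """Exact Shapley attributions against the background mean."""
    _check_alignment(model, background)
    _check_alignment(model, instances)
    if background.n_rows == 0:
        raise ValueError("background must be non-empty")
    mu = background.X.mean(axis=0)
    contrib = (instances.X - mu) * model.beta  # includes intercept column: x=1, mu=1 -> 0
    base = float(model.beta @ mu)
    keep = [j for j, c in enumerate(model.columns) if c != INTERCEPT]
    cols = [model.columns[j] for j in keep]
    phi = pd.DataFrame(contrib[:, keep], columns=cols)

    by_schema: dict[str, np.ndarray] = {}
    for col in cols:
        var = model.register.get(col, col)
        by_schema[var] = by_schema.get(var, 0.0) + phi[col].to_numpy()
    importance = pd.Series({var: float(np.mean(np.abs(v))) for var, v in by_schema.items()})
    return Attribution(phi=phi, base=base, importance=importance)


def importance_comparison(
    baseline: FittedModel,
    faim: FittedModel | "object",
    background_full: DesignMatrix,
    instances_full: DesignMatrix,
    background_faim: DesignMatrix,
    instances_faim: DesignMatrix,
) -> pd.DataFrame:
    """Side-by-side mean |SHAP| importance of the baseline vs the FAIM model.

    Sensitive variables excluded by the FAIM model appear with importance 0
    on its side.  Rows are sorted by baseline importance, descending.
    """
    imp_base = linear_shap(baseline, background_full, instances_full).importance
    faim_model = faim if isinstance(faim, FittedModel) else FittedModel(
        case=faim.case, beta=faim.beta, sigma=np.eye(len(faim.beta)),
        log_likelihood=float("nan"), columns=faim.columns, register=faim.register,
        n_iter=0, max_score=float("nan"), converged=True,
    )
    imp_faim = linear_shap(faim_model, background_faim, instances_faim).importance
    rows = []
    for var in imp_base.index:
        b = float(imp_base[var])
        f = float(imp_faim.get(var, 0.0))
        rows.append({"variable": var, "baseline_importance": b, "faim_importance": f, "difference": f - b})
    for var in imp_faim.index:
        if var not in imp_base.index:  # pragma: no cover - FAIM design is a subset
            rows.append({
                "variable": var, "baseline_importance": 0.0,
                "faim_importance": float(imp_faim[var]), "difference": float(imp_faim[var]),
            })
    table = pd.DataFrame(rows).sort_values("baseline_importance", ascending=False, kind="mergesort")
    return table.reset_index(drop=True)
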