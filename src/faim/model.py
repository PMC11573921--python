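"""Statsmodels-style front end: the :class:`FAIM` model and its fitted results.

Typical use::

    spec = synthetic.biased_preset("strong", seed=7, n=20_000)
    data, _ = synthetic.generate_cohort(spec)
    res = FAIM(data, FAIMConfig(seed=7)).fit()
    print(res.summary())
    reports = res.evaluate()         # baseline / under-blindness / FAIM rows
    gaps = res.subgroup_gaps()       # per-variable TPR/TNR gaps
    imp = res.importance_comparison()

``fit()`` runs the whole pipeline: seeded 70/10/20 split, per-exclusion-case
logistic optima on the training split, rejection-sampled integral Rashomon
set anchored on the validation AUC, FRI ranking, and selection of the
fairness-aware model (honoring any configured exclusion constraint).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import evaluation, explain, fairness, glm, rashomon
from .data import Dataset, Schema, encode_design, from_dataframe, load_dataset, split_dataset

logger = logging.getLogger(__name__)


@dataclass
class FAIMConfig:
    """All tunables of a run; one integer seed drives every random stage."""

    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    stratify: bool = False
    epsilon: float = 0.05
    epsilon0: float | None = None
    u1: float = 0.5
    u2: float = 2.0
    n_draws_per_case: int = 2000
    metric: str = "auc"
    min_count: int = 20
    n_bins: int = 4
    must_exclude: tuple[str, ...] | None = None
    choice: int | None = None
    bootstrap_B: int = 1000
    background_size: int = 500
    explain_size: int = 500
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fractions"] = list(self.fractions)
        if self.must_exclude is not None:
            d["must_exclude"] = list(self.must_exclude)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FAIMConfig":
        d = dict(d)
        if "fractions" in d:
            d["fractions"] = tuple(d["fractions"])
        if d.get("must_exclude") is not None:
            d["must_exclude"] = tuple(d["must_exclude"])
        return cls(**d)


class FAIM:
    """Fairness-aware interpretable modeling over a tabular dataset.

    Parameters
    ----------
    data : Dataset
        Validated dataset (with or without split labels; unsplit data is
        split inside :meth:`fit` with the configured seed).
    config : FAIMConfig, optional
    """

    def __init__(self, data: Dataset, config: FAIMConfig | None = None):
        self.data = data
        self.config = config or FAIMConfig()

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, schema: Schema, config: FAIMConfig | None = None) -> "FAIM":
        return cls(from_dataframe(frame, schema), config)

    @classmethod
    def from_csv(cls, path, schema: Schema, config: FAIMConfig | None = None) -> "FAIM":
        return cls(load_dataset(path, schema), config)

    def fit(self) -> "FAIMResults":
        cfg = self.config
        data = self.data
        if data.split_labels is None:
            data = split_dataset(data, cfg.fractions, seed=cfg.seed, stratify=cfg.stratify)
        schema = data.schema
        train = data.subset("train")

        cases = glm.enumerate_cases(schema.sensitive)
        case_fits: dict[glm.ExclusionCase, glm.FittedModel] = {}
        for case in cases:
            design = encode_design(train, schema, case)
            case_fits[case] = glm.fit_logistic(design, train.outcome)

        rcfg = rashomon.RashomonConfig(
            epsilon=cfg.epsilon, epsilon0=cfg.epsilon0, u1=cfg.u1, u2=cfg.u2,
            n_draws_per_case=cfg.n_draws_per_case, metric=cfg.metric, seed=cfg.seed,
        )
        irs = rashomon.assemble_irs(case_fits, data, rcfg)
        ranked = fairness.rank_irs(irs, data.subset("validation"), min_count=cfg.min_count)
        selected = fairness.select_model(ranked, must_exclude=cfg.must_exclude, choice=cfg.choice)
        return FAIMResults(model=self, data=data, cases=cases, case_fits=case_fits,
                           irs=irs, ranking=ranked, selected=selected)


@dataclass
class FAIMResults:
    """Fitted FAIM pipeline: optima, the IRS, the ranking, and the selection."""

    model: FAIM
    data: Dataset
    cases: list[glm.ExclusionCase]
    case_fits: dict[glm.ExclusionCase, glm.FittedModel]
    irs: rashomon.IRS
    ranking: list[fairness.RankedModel]
    selected: fairness.SelectedModel
    _selected_sigma: np.ndarray | None = field(default=None, repr=False)

    # -- statsmodels-flavoured accessors -------------------------------------

    @property
    def config(self) -> FAIMConfig:
        return self.model.config

    @property
    def baseline(self) -> glm.FittedModel:
        """The fairness-unaware optimum (full case)."""
        full = glm.ExclusionCase(retained=tuple(self.data.schema.sensitive))
        return self.case_fits[full]

    @property
    def under_blindness(self) -> glm.FittedModel:
        """The complete-exclusion optimum."""
        return self.case_fits[glm.ExclusionCase(retained=())]

    @property
    def params(self) -> pd.Series:
        """Selected fairness-aware coefficients, indexed by design column."""
        return pd.Series(self.selected.beta, index=list(self.selected.columns))

    @property
    def bse(self) -> pd.Series:
        """Fisher-information standard errors at the selected coefficients."""
        return pd.Series(np.sqrt(np.diag(self.selected_sigma)), index=list(self.selected.columns))

    @property
    def selected_sigma(self) -> np.ndarray:
        """Inverse observed information at beta-tilde on the training design."""
        if self._selected_sigma is None:
            train = self.data.subset("train")
            X = encode_design(train, self.data.schema, self.selected.case).X
            self._selected_sigma = glm.covariance_at(X, self.selected.beta)
        return self._selected_sigma

    # -- reporting -----------------------------------------------------------

    def odds_ratios(self, which: str = "faim") -> pd.DataFrame:
        """Wald odds-ratio table for 'faim', 'baseline' or 'under_blindness'."""
        if which == "baseline":
            return glm.wald_odds_ratios(self.baseline)
        if which == "under_blindness":
            return glm.wald_odds_ratios(self.under_blindness)
        if which == "faim":
            shell = glm.FittedModel(
                case=self.selected.case, beta=self.selected.beta, sigma=self.selected_sigma,
                log_likelihood=float("nan"), columns=self.selected.columns,
                register=self.selected.register, n_iter=0, max_score=float("nan"), converged=True,
            )
            return glm.wald_odds_ratios(shell)
        raise ValueError(f"unknown model label {which!r}")

    def ranking_frame(self) -> pd.DataFrame:
        return fairness.ranking_frame(self.ranking)

    def case_table(self, n_bins: int | None = None) -> pd.DataFrame:
        return fairness.tabulate_by_case(self.ranking, n_bins or self.config.n_bins)

    def evaluate(self, B: int | None = None, seed: int | None = None) -> pd.DataFrame:
        """Test-split comparison rows for baseline, under blindness and FAIM."""
        B = self.config.bootstrap_B if B is None else B
        seed = self.config.seed if seed is None else seed
        rows = []
        for label, beta, case in (
            ("baseline", self.baseline.beta, self.baseline.case),
            ("under_blindness", self.under_blindness.beta, self.under_blindness.case),
            ("faim", self.selected.beta, self.selected.case),
        ):
            rows.append(evaluation.evaluate_on_test(
                beta, case, self.data, label=label, B=B, seed=seed,
                min_count=self.config.min_count,
            ))
        return evaluation.reports_frame(rows)

    def subgroup_gaps(self) -> pd.DataFrame:
        """Per-sensitive-variable TPR/TNR gaps for the three comparison models."""
        rows = []
        for label, beta, case in (
            ("baseline", self.baseline.beta, self.baseline.case),
            ("under_blindness", self.under_blindness.beta, self.under_blindness.case),
            ("faim", self.selected.beta, self.selected.case),
        ):
            for var in self.data.schema.sensitive:
                entry = evaluation.marginal_subgroup_gaps(
                    beta, case, self.data, var, min_count=self.config.min_count
                )
                rows.append({"label": label, **entry})
        return pd.DataFrame(rows)

    def importance_comparison(self, seed: int | None = None) -> pd.DataFrame:
        """Mean |SHAP| importance, baseline vs FAIM, on shared subsamples.

        Background rows come from the training split and explained rows from
        the validation split, subsampled to the configured sizes.
        """
        cfg = self.config
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        schema = self.data.schema
        train = self.data.subset("train")
        validation = self.data.subset("validation")
        bg_idx = rng.choice(train.n_rows, size=min(cfg.background_size, train.n_rows), replace=False)
        ex_idx = rng.choice(validation.n_rows, size=min(cfg.explain_size, validation.n_rows), replace=False)
        bg = Dataset(train.frame.iloc[bg_idx].reset_index(drop=True), schema)
        ex = Dataset(validation.frame.iloc[ex_idx].reset_index(drop=True), schema)
        return explain.importance_comparison(
            self.baseline, self.selected,
            encode_design(bg, schema, self.baseline.case),
            encode_design(ex, schema, self.baseline.case),
            encode_design(bg, schema, self.selected.case),
            encode_design(ex, schema, self.selected.case),
        )

    def summary(self) -> str:
        """Human-readable run summary."""
        sel = self.selected
        lines = [
            "Fairness-aware interpretable modeling results",
            "=" * 61,
            f"Sensitive variables:    {', '.join(self.data.schema.sensitive)}",
            f"Exclusion cases fitted: {len(self.cases)}",
            f"IRS size:               {self.irs.size} members "
            f"({sum(a.admitted for a in self.irs.admission.values())} admitted cases)",
            f"Validation anchor:      {self.irs.config.metric.upper()} = {self.irs.global_anchor:.4f} "
            f"(epsilon = {self.irs.config.epsilon:.3f}, epsilon0 = {self.irs.config.epsilon0:.4f})",
            "-" * 61,
            f"Selected model:         candidate {sel.candidate_id} (rank {sel.rank})",
            f"  exclusion case:       {sel.case.case_id}",
            f"  FRI:                  {sel.fri:.4g}",
            f"  equal opportunity:    {sel.profile.equal_opportunity:.4f}",
            f"  equalized odds:       {sel.profile.equalized_odds:.4f}",
            f"  BER equality:         {sel.profile.ber_equality:.4f}",
            f"  Youden threshold:     {sel.threshold:.4f}",
            f"  validation {self.irs.config.metric.upper()}:       "
            f"{[r for r in self.ranking if r.rank == sel.rank][0].candidate.validation_metric:.4f}",
            "-" * 61,
            "Coefficients (beta-tilde) with Fisher-information SEs:",
        ]
        params, bse = self.params, self.bse
        for name in params.index:
            lines.append(f"  {name:<24s} {params[name]: .4f}  (se {bse[name]:.4f})")
        return "\n".join(lines)


def config_from_yaml(path) -> tuple[str | None, Schema, FAIMConfig]:
    """Read a declarative run config: data path, schema block, faim block."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    schema = Schema.from_dict(doc)
    cfg = FAIMConfig.from_dict(doc.get("faim", {}))
    return doc.get("data"), schema, cfg


def config_to_yaml(path, data_path: str, schema: Schema, cfg: FAIMConfig) -> None:
    doc = {"data": str(data_path), **schema.to_dict(), "faim": cfg.to_dict()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
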