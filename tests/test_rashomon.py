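import numpy as np
import pytest

from oracles import auc_pair_count

from faim.data import encode_design, split_dataset
from faim.glm import ExclusionCase, enumerate_cases, fit_logistic
from faim.rashomon import (
    IRS,
    RashomonConfig,
    assemble_irs,
    default_epsilon0,
    draw_candidates,
    filter_near_optimal,
)
from faim.synthetic import biased_preset, generate_cohort


@pytest.fixture(scope="module")
def small_pipeline():
    """Cohort, split, and per-case optima shared by the module's tests."""
    data, _ = generate_cohort(biased_preset("strong", seed=11, n=2500))
    data = split_dataset(data, seed=11)
    train = data.subset("train")
    fits = {}
    for case in enumerate_cases(data.schema.sensitive):
        fits[case] = fit_logistic(encode_design(train, data.schema, case), train.outcome)
    return data, fits


class TestDrawCandidates:
    def test_degenerate_scale_reproduces_optimum(self, small_pipeline):
        _, fits = small_pipeline
        model = next(iter(fits.values()))
        cfg = RashomonConfig(u1=0.0, u2=0.0, n_draws_per_case=20, seed=1)
        for cand in draw_candidates(model, cfg):
            np.testing.assert_array_equal(cand.beta, model.beta)
            assert cand.k == 0.0

    def test_same_seed_identical_draws(self, small_pipeline):
        _, fits = small_pipeline
        model = next(iter(fits.values()))
        cfg = RashomonConfig(n_draws_per_case=50, seed=42)
        a = draw_candidates(model, cfg)
        b = draw_candidates(model, cfg)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.beta, cb.beta)
            assert ca.k == cb.k

    def test_empirical_covariance_matches_sigma(self, small_pipeline):
        # u1=u2=1: the draw law is exactly N(beta*, Sigma*)
        _, fits = small_pipeline
        model = fits[ExclusionCase(retained=())]
        cfg = RashomonConfig(u1=1.0, u2=1.0, n_draws_per_case=60_000, seed=3)
        draws = np.stack([c.beta for c in draw_candidates(model, cfg)])
        emp = np.cov(draws, rowvar=False)
        scale = np.sqrt(np.outer(np.diag(model.sigma), np.diag(model.sigma)))
        np.testing.assert_allclose(emp / scale, model.sigma / scale, atol=0.05)


class TestFilter:
    def test_vacuous_filter_accepts_all(self, small_pipeline):
        data, fits = small_pipeline
        case = ExclusionCase(retained=())
        model = fits[case]
        val = data.subset("validation")
        X = encode_design(val, data.schema, case).X
        cfg = RashomonConfig(epsilon=0.999, epsilon0=0.99, n_draws_per_case=50, seed=5)
        cands = draw_candidates(model, cfg)
        accepted = filter_near_optimal(cands, X, val.outcome, case_optimal_metric=0.6, cfg=cfg)
        assert len(accepted) == len(cands)

    def test_zero_slack_keeps_only_at_or_above_optimum(self, small_pipeline):
        data, fits = small_pipeline
        case = ExclusionCase(retained=())
        model = fits[case]
        val = data.subset("validation")
        X = encode_design(val, data.schema, case).X
        from faim.evaluation import auc
        from faim.glm import predict_probability

        opt = auc(predict_probability(model.beta, X), val.outcome)
        cfg = RashomonConfig(epsilon=1e-12, epsilon0=1e-12, n_draws_per_case=100, seed=6)
        accepted = filter_near_optimal(draw_candidates(model, cfg), X, val.outcome, opt, cfg)
        for c in accepted:
            assert c.validation_metric >= opt * (1 - 1e-12)

    def test_single_class_validation_rejected(self, small_pipeline):
        data, fits = small_pipeline
        case = ExclusionCase(retained=())
        cfg = RashomonConfig(n_draws_per_case=5, seed=0)
        cands = draw_candidates(fits[case], cfg)
        X = np.ones((4, len(fits[case].beta)))
        with pytest.raises(ValueError):
            filter_near_optimal(cands, X, np.ones(4, dtype=int), 0.7, cfg)


class TestAssembleIRS:
    def test_admitted_cases_bounded_by_power_set(self, small_pipeline):
        data, fits = small_pipeline
        irs = assemble_irs(fits, data, RashomonConfig(n_draws_per_case=100, seed=11))
        assert len(irs.admission) == 4
        assert sum(a.admitted for a in irs.admission.values()) <= 4

    def test_bad_case_contributes_nothing(self, small_pipeline):
        data, fits = small_pipeline
        # corrupt one partial case so its optimum scores far below the anchor
        fits = dict(fits)
        bad_case = ExclusionCase(retained=("sex",))
        bad = fits[bad_case]
        import dataclasses

        fits[bad_case] = dataclasses.replace(bad, beta=-5 * np.ones_like(bad.beta))
        irs = assemble_irs(fits, data, RashomonConfig(n_draws_per_case=50, seed=2))
        rec = irs.admission[bad_case.case_id]
        assert not rec.admitted
        assert rec.n_drawn == 0 and rec.n_accepted == 0
        assert all(m.case != bad_case for m in irs.members)

    def test_membership_and_anchor_guarantee(self, small_pipeline):
        data, fits = small_pipeline
        cfg = RashomonConfig(n_draws_per_case=200, seed=11)
        irs = assemble_irs(fits, data, cfg)
        assert irs.size == sum(a.n_accepted for a in irs.admission.values())
        # independent pair-counting AUC recomputation for every member
        val = data.subset("validation")
        y = val.outcome
        from faim.glm import predict_probability

        designs = {}
        for m in irs.members:
            cid = m.case.case_id
            if cid not in designs:
                designs[cid] = encode_design(val, data.schema, m.case).X
            auc_o = auc_pair_count(predict_probability(m.beta, designs[cid]), y)
            assert auc_o == pytest.approx(m.validation_metric, abs=1e-12)
            assert auc_o >= (1 - cfg.epsilon) * irs.global_anchor - 1e-12
            assert auc_o >= (1 - cfg.epsilon0) * irs.admission[cid].case_metric - 1e-12

    def test_deterministic_given_config(self, small_pipeline):
        data, fits = small_pipeline
        cfg = RashomonConfig(n_draws_per_case=80, seed=7)
        a = assemble_irs(fits, data, cfg)
        b = assemble_irs(fits, data, cfg)
        assert a.size == b.size
        for ma, mb in zip(a.members, b.members):
            assert ma.candidate_id == mb.candidate_id
            np.testing.assert_array_equal(ma.beta, mb.beta)

    def test_monotone_in_budget_and_slack(self, small_pipeline):
        data, fits = small_pipeline
        small = assemble_irs(fits, data, RashomonConfig(n_draws_per_case=50, seed=7)).size
        big = assemble_irs(fits, data, RashomonConfig(n_draws_per_case=150, seed=7)).size
        assert big >= small
        tight = assemble_irs(
            fits, data, RashomonConfig(epsilon=0.02, n_draws_per_case=100, seed=7)
        ).size
        loose = assemble_irs(
            fits, data, RashomonConfig(epsilon=0.10, n_draws_per_case=100, seed=7)
        ).size
        assert loose >= tight

    def test_full_case_required(self, small_pipeline):
        data, fits = small_pipeline
        partial = {c: f for c, f in fits.items() if c.retained != tuple(data.schema.sensitive)}
        with pytest.raises(ValueError, match="full"):
            assemble_irs(partial, data, RashomonConfig(seed=0))


def test_epsilon0_default_compounds_to_epsilon():
    eps = 0.05
    eps0 = default_epsilon0(eps)
    assert (1 - eps0) ** 2 == pytest.approx(1 - eps, abs=1e-15)
    with pytest.raises(ValueError):
        RashomonConfig(epsilon=0.05, epsilon0=0.2)


def test_export_frame_shape(small_pipeline):
    data, fits = small_pipeline
    irs = assemble_irs(fits, data, RashomonConfig(n_draws_per_case=40, seed=1))
    frame = irs.to_frame()
    assert len(frame) == irs.size
    assert {"candidate_id", "case_id", "k", "validation_metric"} <= set(frame.columns)
    record = irs.admission_record()
    assert set(record["cases"]) == set(irs.admission)
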