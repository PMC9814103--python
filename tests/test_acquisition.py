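"""Acquisition values, batch proposals vs an exhaustive oracle, campaign loop."""

import math

import numpy as np
import pytest

from flowbo import (
    AcquisitionConfig,
    CampaignState,
    Condition,
    ExhaustionError,
    ValidationError,
    acq_ei,
    acq_lcb,
    advance_round,
    initial_design,
    propose_batch,
    run_closed_loop,
)
from flowbo import acquisition, gp


class TestLCB:
    @pytest.mark.parametrize(
        "mean, sd, beta, expected",
        [(50, 10, 2, 70), (50, 10, 0, 50), (42, 0, 5, 42), (0, 3, 1, 3)],
    )
    def test_optimistic_bound(self, mean, sd, beta, expected):
        assert acq_lcb(mean, sd, beta) == pytest.approx(expected)

    def test_monotone_in_beta(self, rng):
        mean, sd = rng.uniform(0, 100, 50), rng.uniform(0, 20, 50)
        betas = np.linspace(0, 5, 11)
        vals = np.array([acq_lcb(mean, sd, b) for b in betas])
        assert np.all(np.diff(vals, axis=0) >= 0)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValidationError):
            acq_lcb(50, -1, 2)


class TestEI:
    def test_no_improvement_when_deterministic_and_below_best(self):
        assert acq_ei(40, 0.0, best_observed=50) == 0.0

    def test_deterministic_improvement(self):
        assert acq_ei(60, 0.0, best_observed=50, xi=5) == pytest.approx(5.0)

    def test_zero_mean_gap_closed_form(self):
        # EI at mean == incumbent equals sigma/sqrt(2*pi)
        sigma = 7.3
        assert acq_ei(50, sigma, best_observed=50, xi=0) == pytest.approx(
            sigma / math.sqrt(2 * math.pi)
        )

    def test_matches_monte_carlo(self, rng):
        mean, sd, best = 55.0, 8.0, 60.0
        draws = rng.normal(mean, sd, size=1_000_000)
        mc = np.mean(np.maximum(draws - best, 0.0))
        assert acq_ei(mean, sd, best) == pytest.approx(mc, rel=5e-3)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValidationError):
            acq_ei(50, -0.1, 40)


def line_state(line_space, xs, ys, config):
    return CampaignState(
        space=line_space,
        conditions=[Condition({"x": float(v)}) for v in xs],
        yields=[float(y) for y in ys],
        config=config,
    )


def oracle_sequential_batch(space, state, model):
    """Independent exhaustive re-implementation of the batch rule: enumerate
    every lab-grid point, hallucinate sequentially, argmax each step."""
    config = state.config
    grid = space.grid_conditions()
    X = np.array(sorted(
        (space.encode(c).values for c in grid), key=lambda r: tuple(r)
    ))
    taken = {tuple(np.round(space.encode(c).values, 10)) for c in state.conditions}
    best = max(state.yields)
    chosen = []
    current = model
    for _ in range(config.batch_size):
        mask = [tuple(np.round(row, 10)) not in taken for row in X]
        cand = X[np.array(mask)]
        mean, sd = current.predict_arrays(cand)
        if config.base_kind == "lcb":
            vals = mean + config.beta * sd
        else:
            vals = acq_ei(mean, sd, best, config.xi)
        pick = cand[int(np.argmax(vals))]
        chosen.append(space.decode(pick))
        taken.add(tuple(np.round(pick, 10)))
        if config.hallucinate:
            lie = float(current.predict_arrays(pick.reshape(1, -1))[0][0])
            current = current.condition_on(pick, lie)
    return chosen


class TestProposeBatch:
    def test_exploitation_limit_picks_posterior_mean_maximizer(self, line_space):
        # peak of the fitted mean lies between the two best observations,
        # at an unobserved grid point
        cfg = AcquisitionConfig(kind="lcb", beta=0.0, batch_size=1,
                                n_candidates=512, seed=3)
        state = line_state(line_space, [0, 2, 4, 6, 8, 11], [5, 20, 70, 70, 20, 5], cfg)
        model = state.fit_model()
        proposal = propose_batch(state, model)
        grid = line_space.grid_conditions()
        unobserved = [c for c in grid if c not in state.conditions]
        means = [model.predict_arrays(line_space.encode(c).values.reshape(1, -1))[0][0]
                 for c in unobserved]
        assert proposal.conditions[0] == unobserved[int(np.argmax(means))]

    @pytest.mark.parametrize("kind", ["parallel_lcb", "parallel_ei", "lcb"])
    def test_equals_exhaustive_oracle_on_discrete_space(self, line_space, kind):
        cfg = AcquisitionConfig(kind=kind, batch_size=3, n_candidates=1024, seed=11)
        state = line_state(line_space, [0, 3, 5, 9, 11], [10, 40, 62, 35, 8], cfg)
        model = state.fit_model()
        expected = oracle_sequential_batch(line_space, state, model)
        proposal = propose_batch(state, model)
        assert list(proposal.conditions) == expected

    def test_batch_distinct_and_valid(self, line_space):
        cfg = AcquisitionConfig(batch_size=3, n_candidates=512, seed=0)
        state = line_state(line_space, [0, 5, 11], [10, 50, 20], cfg)
        proposal = propose_batch(state)
        assert len(set(proposal.conditions)) == 3
        for c in proposal.conditions:
            line_space.validate(c)
            assert float(c["x"]) == round(float(c["x"]))  # on the lab grid

    def test_deterministic_given_seed(self, line_space):
        cfg = AcquisitionConfig(batch_size=2, n_candidates=256, seed=42)
        state = line_state(line_space, [0, 4, 8], [10, 60, 30], cfg)
        p1 = propose_batch(state)
        p2 = propose_batch(state)
        assert p1.conditions == p2.conditions
        assert p1.acquisition_values == p2.acquisition_values

    def test_exhaustion_when_grid_smaller_than_batch(self):
        from flowbo import ContinuousParam, ParameterSpace

        tiny = ParameterSpace([ContinuousParam("x", 0.0, 2.0, precision=1.0)])
        cfg = AcquisitionConfig(batch_size=3, n_candidates=128, seed=0)
        state = CampaignState(
            space=tiny,
            conditions=[Condition({"x": 0.0}), Condition({"x": 1.0})],
            yields=[10.0, 20.0],
            config=cfg,
        )
        with pytest.raises(ExhaustionError):
            propose_batch(state)

    def test_hallucination_never_increases_variance(self, line_space, rng):
        cfg = AcquisitionConfig(seed=0)
        state = line_state(line_space, [0, 3, 7, 11], [10, 50, 45, 15], cfg)
        model = state.fit_model()
        x = line_space.encode(Condition({"x": 5.0})).values
        lie = float(model.predict_arrays(x.reshape(1, -1))[0][0])
        conditioned = model.condition_on(x, lie)
        probe = rng.uniform(0, 1, size=(40, 1))
        _, sd_before = model.predict_arrays(probe)
        _, sd_after = conditioned.predict_arrays(probe)
        assert np.all(sd_after <= sd_before + 1e-8)

    def test_kriging_believer_keeps_posterior_mean(self, line_space):
        cfg = AcquisitionConfig(seed=0)
        state = line_state(line_space, [0, 3, 7, 11], [10, 50, 45, 15], cfg)
        model = state.fit_model()
        x = line_space.encode(Condition({"x": 5.0})).values
        mean_before = model.predict_arrays(x.reshape(1, -1))[0][0]
        conditioned = model.condition_on(x, float(mean_before))
        mean_after = conditioned.predict_arrays(x.reshape(1, -1))[0][0]
        assert mean_after == pytest.approx(mean_before, abs=1e-6)


class TestAdvanceRound:
    def test_bookkeeping(self, line_space):
        cfg = AcquisitionConfig(batch_size=3, n_candidates=256, seed=1)
        state = line_state(line_space, [0, 2, 4, 6, 8, 10], [68, 73, 42, 28, 55, 75], cfg)
        proposal = propose_batch(state)
        new = advance_round(state, proposal, [81.0, 77.0, 40.0])
        assert len(new.conditions) == 9
        assert new.round == 1

    def test_count_mismatch_and_range_guard(self, line_space):
        cfg = AcquisitionConfig(batch_size=2, n_candidates=256, seed=1)
        state = line_state(line_space, [0, 5, 11], [10, 50, 20], cfg)
        proposal = propose_batch(state)
        with pytest.raises(ValidationError):
            advance_round(state, proposal, [50.0])
        with pytest.raises(ValidationError):
            advance_round(state, proposal, [50.0, 105.0])

    def test_save_load_resume_determinism(self, line_space, tmp_path):
        cfg = AcquisitionConfig(batch_size=2, n_candidates=256, seed=9)
        state = line_state(line_space, [0, 4, 8, 11], [10, 60, 30, 5], cfg)
        path = tmp_path / "campaign.json"
        acquisition.save_state(state, path)
        restored = acquisition.load_state(line_space, path)
        p1 = propose_batch(state)
        p2 = propose_batch(restored)
        assert p1.conditions == p2.conditions


class TestClosedLoop:
    def _quadratic_objective(self, space):
        class Obj:
            def true_value(self, cond):
                x = float(cond["x"])
                return max(0.0, 90 - 2.0 * (x - 7) ** 2)

            def __call__(self, cond):
                return self.true_value(cond)

        return Obj()

    def test_zero_rounds_is_initial_design_only(self, line_space):
        obj = self._quadratic_objective(line_space)
        init = [Condition({"x": 0.0}), Condition({"x": 5.0}), Condition({"x": 11.0})]
        hist = run_closed_loop(line_space, obj, init, rounds=0,
                               config=AcquisitionConfig(n_candidates=128, seed=0))
        assert len(hist.conditions) == 3
        assert hist.n_init == 3

    def test_trace_monotone_and_history_grows(self, line_space):
        obj = self._quadratic_objective(line_space)
        init = [Condition({"x": 0.0}), Condition({"x": 4.0}), Condition({"x": 11.0})]
        cfg = AcquisitionConfig(batch_size=2, n_candidates=256, seed=2)
        hist = run_closed_loop(line_space, obj, init, rounds=2, config=cfg)
        assert len(hist.conditions) == 3 + 2 * 2
        assert np.all(np.diff(hist.best_so_far) >= 0)

    def test_empty_init_rejected(self, line_space):
        obj = self._quadratic_objective(line_space)
        with pytest.raises(ValidationError):
            run_closed_loop(line_space, obj, [], 1, AcquisitionConfig(seed=0))


class TestInitialDesign:
    def test_balanced_categorical_coverage(self, small_space):
        design = initial_design(small_space, 6, seed=4)
        mixers = [c["mixer"] for c in design]
        assert mixers.count("comet_x") == mixers.count("beta_type") == 2
        for c in design:
            small_space.validate(c)

    def test_deterministic(self, small_space):
        assert initial_design(small_space, 6, seed=4) == initial_design(
            small_space, 6, seed=4
        )
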