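import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from surgevol.io_tables import PollSeries
from surgevol.synthetic_data import SyntheticConfig, simulate_polls
from surgevol.transition_estimation import (DEFAULT_RIDGE, FREE_ENTRIES,
                                            ROW_SUM_A, ZERO_ENTRIES,
                                            TransitionChain, TransitionMatrix,
                                            build_pooled_window,
                                            build_qp_window,
                                            estimate_constant_transition,
                                            estimate_transition_chain,
                                            solve_transition_qp)

from conftest import MIXING_P


def slsqp_oracle(window, ridge=DEFAULT_RIDGE):
    """Independent constrained minimizer of the same ridged objective."""
    X, y = window.design, window.target
    Q = X.T @ X
    lam = max(ridge * np.trace(Q), 1e-13)
    Q = Q + lam * np.eye(window.n_params)
    prior = TransitionMatrix.identity().to_free()
    c = X.T @ y + lam * prior
    res = minimize(lambda v: 0.5 * v @ Q @ v - c @ v, x0=prior,
                   jac=lambda v: Q @ v - c, method="SLSQP",
                   constraints=[{"type": "eq",
                                 "fun": lambda v: ROW_SUM_A @ v - 1,
                                 "jac": lambda v: ROW_SUM_A}],
                   bounds=[(0.0, 1.0)] * window.n_params,
                   options={"maxiter": 1000, "ftol": 1e-16})
    assert res.success
    return res.x


def random_feasible(rng, m):
    """Random banded row-stochastic matrices as free-parameter vectors."""
    feas = np.empty((m, 10))
    feas[:, 0:2] = rng.dirichlet([1, 1], m)
    feas[:, 2:5] = rng.dirichlet([1, 1, 1], m)
    feas[:, 5:8] = rng.dirichlet([1, 1, 1], m)
    feas[:, 8:10] = rng.dirichlet([1, 1], m)
    return feas


def dirichlet_vectors(rng, k=3):
    return [rng.dirichlet(np.full(4, 2.0)) for _ in range(k)]


class TestTransitionMatrixType:
    def test_zero_pattern_enforced(self):
        bad = np.full((4, 4), 0.25)
        with pytest.raises(ValueError, match="exactly 0"):
            TransitionMatrix(bad)

    def test_row_sums_enforced(self):
        m = MIXING_P.copy()
        m[0, 0] = 0.5
        with pytest.raises(ValueError, match="sum"):
            TransitionMatrix(m)

    def test_free_round_trip(self):
        m = TransitionMatrix(MIXING_P.copy())
        again = TransitionMatrix.from_free(m.to_free())
        np.testing.assert_allclose(again.values, m.values)

    def test_rows_renormalized_exactly(self):
        m = MIXING_P.copy()
        m[0, 0] += 3e-9
        tm = TransitionMatrix(m)
        np.testing.assert_allclose(tm.values.sum(axis=1), np.ones(4),
                                   atol=1e-15)


class TestBuildQPWindow:
    def test_shape_and_constraints(self, rng):
        w = build_qp_window(*dirichlet_vectors(rng))
        assert w.design.shape == (8, 10)
        assert w.target.shape == (8,)
        assert w.equality.shape == (4, 10)
        # 4 equality rows, each parameter bounded both sides -> 20 bounds
        assert w.equality.sum() == 10

    def test_unoccupied_sources_give_zero_rows(self):
        e1 = np.array([1.0, 0, 0, 0])
        w = build_qp_window(e1, e1, e1)
        # destinations 3 and 4 can only be entered from states 2-4, all empty
        for j in (2, 3):
            np.testing.assert_array_equal(w.design[2 * j], 0)
            np.testing.assert_array_equal(w.design[2 * j + 1], 0)

    def test_noiseless_design_consistency(self, rng):
        # oracle: direct matrix multiplication
        P = MIXING_P
        for _ in range(10):
            y0 = rng.dirichlet(np.full(4, 1.0))
            y1, y2 = y0 @ P, y0 @ P @ P
            w = build_qp_window(y0, y1, y2)
            p_free = TransitionMatrix(P.copy()).to_free()
            np.testing.assert_allclose(w.design @ p_free, w.target,
                                       atol=1e-12)

    def test_invalid_vector_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            build_qp_window([0.5, 0.1, 0.1, 0.1], [1, 0, 0, 0], [1, 0, 0, 0])


class TestSolveTransitionQP:
    def test_exact_recovery_all_states_occupied(self):
        y0 = np.array([0.4, 0.3, 0.2, 0.1])
        w = build_qp_window(y0, y0 @ MIXING_P, y0 @ MIXING_P @ MIXING_P)
        sol = solve_transition_qp(w)
        assert np.abs(sol.values - MIXING_P).max() <= 1e-6
        assert sol.sse <= 1e-12

    def test_matches_slsqp_oracle_on_noisy_windows(self, rng):
        for _ in range(20):
            w = build_qp_window(*dirichlet_vectors(rng))
            sol = solve_transition_qp(w)
            alt = slsqp_oracle(w)
            ident = w.identifiable()
            assert np.abs(sol.raw - alt)[ident].max() <= 1e-5

    def test_beats_random_feasible_points(self, rng):
        for _ in range(5):
            w = build_qp_window(*dirichlet_vectors(rng))
            sol = solve_transition_qp(w)
            objs = ((w.target[None, :] - random_feasible(rng, 2000)
                     @ w.design.T) ** 2).sum(axis=1)
            assert w.objective(sol.raw) <= objs.min() + 1e-9

    def test_negative_ridge_rejected(self, rng):
        w = build_qp_window(*dirichlet_vectors(rng))
        with pytest.raises(ValueError):
            solve_transition_qp(w, ridge=-1.0)

    def test_ridge_is_vanishing_perturbation(self, rng):
        for _ in range(5):
            w = build_qp_window(*dirichlet_vectors(rng))
            base = w.objective(solve_transition_qp(w, ridge=0.0).raw)
            for ridge in (1e-8, 1e-6):
                obj = w.objective(solve_transition_qp(w, ridge=ridge).raw)
                assert obj - base <= ridge * 10

    def test_unidentified_row_pinned_to_prior(self):
        e1 = np.array([1.0, 0, 0, 0])
        sol = solve_transition_qp(build_qp_window(e1, e1, e1))
        # rows 3 and 4 carry no data; the persistence prior keeps them put
        np.testing.assert_allclose(sol.values[2], [0, 0, 1, 0], atol=1e-9)
        np.testing.assert_allclose(sol.values[3], [0, 0, 0, 1], atol=1e-9)

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_solution_always_valid(self, seed):
        rng = np.random.default_rng(seed)
        sol = solve_transition_qp(build_qp_window(*dirichlet_vectors(rng)))
        for i, j in ZERO_ENTRIES:
            assert sol.values[i, j] == 0.0
        assert np.all(sol.values >= 0) and np.all(sol.values <= 1)
        np.testing.assert_allclose(sol.values.sum(axis=1), 1.0, atol=1e-12)


class TestEstimateTransitionChain:
    def make_polls(self, proportions):
        dates = [f"2020-03-{13 + 7 * k:02d}" if 13 + 7 * k <= 31
                 else f"2020-04-{13 + 7 * k - 31:02d}"
                 for k in range(len(proportions))]
        return PollSeries(dates=dates, proportions=np.asarray(proportions))

    def test_requires_three_polls(self):
        polls = self.make_polls([[1, 0, 0, 0], [1, 0, 0, 0]])
        with pytest.raises(ValueError):
            estimate_transition_chain(polls)

    def test_first_window_uses_baseline(self):
        # all polls at (1,0,0,0): the baseline start makes identity a
        # perfect fit, so fitted == observed exactly
        polls = self.make_polls([[1, 0, 0, 0]] * 4)
        chain = estimate_transition_chain(polls)
        assert len(chain) == 3
        np.testing.assert_allclose(chain.fitted, polls.proportions, atol=1e-6)
        np.testing.assert_allclose(chain.matrices[0].values, np.eye(4),
                                   atol=1e-6)

    def test_zero_residual_constant_reproducible_series(self):
        # proportions follow y_{t+1} = y_t P exactly from the baseline
        y = [np.array([1.0, 0, 0, 0])]
        for _ in range(5):
            y.append(y[-1] @ MIXING_P)
        polls = self.make_polls(np.vstack(y[1:]))
        chain = estimate_transition_chain(polls)
        np.testing.assert_allclose(chain.fitted, polls.proportions, atol=1e-6)
        for m in chain.matrices:
            assert m.sse <= 1e-10

    def test_chain_length_and_alignment(self, small_fixture):
        chain = estimate_transition_chain(small_fixture.polls)
        assert len(chain) == len(small_fixture.polls) - 1
        assert chain.dates == small_fixture.polls.dates
        assert chain.fitted.shape == small_fixture.polls.proportions.shape

    def test_fitted_are_probability_vectors(self, small_fixture):
        chain = estimate_transition_chain(small_fixture.polls)
        assert np.all(chain.fitted >= 0)
        np.testing.assert_allclose(chain.fitted.sum(axis=1), 1.0, atol=1e-12)

    def test_json_round_trip(self, small_fixture, tmp_path):
        chain = estimate_transition_chain(small_fixture.polls)
        chain.to_json(tmp_path / "chain.json")
        again = TransitionChain.from_json(tmp_path / "chain.json")
        assert len(again) == len(chain)
        assert again.dates == chain.dates
        for a, b in zip(again.matrices, chain.matrices):
            np.testing.assert_allclose(a.values, b.values, atol=1e-15)
        np.testing.assert_allclose(again.fitted, chain.fitted, atol=1e-15)

    def test_propagate_shape(self, small_fixture):
        chain = estimate_transition_chain(small_fixture.polls)
        traj = chain.propagate(small_fixture.polls.baseline)
        assert traj.shape == (len(chain) + 1, 4)
        np.testing.assert_allclose(traj.sum(axis=1), 1.0, atol=1e-9)


class TestConstantRecovery:
    def simulate(self, n, seed):
        cfg = SyntheticConfig(n_weeks=17, sample_size_range=(n, n), seed=seed)
        chain = TransitionChain([TransitionMatrix(MIXING_P.copy())] * 16)
        return simulate_polls(chain, cfg)

    def test_pooled_recovery_large_samples(self):
        polls = self.simulate(100_000, seed=3)
        est = estimate_constant_transition(polls)
        ident = build_pooled_window(polls).identifiable()
        truth = TransitionMatrix(MIXING_P.copy()).to_free()
        assert np.abs(est.to_free() - truth)[ident].max() <= 0.05

    def test_error_shrinks_with_sample_size(self):
        truth = TransitionMatrix(MIXING_P.copy()).to_free()
        med = {}
        for n in (100, 10_000):
            errs = []
            for seed in range(8):
                polls = self.simulate(n, seed)
                est = estimate_constant_transition(polls)
                ident = build_pooled_window(polls).identifiable()
                errs.append(np.abs(est.to_free() - truth)[ident].max())
            med[n] = np.median(errs)
        assert med[10_000] < med[100]

    def test_pooled_window_shape(self, small_fixture):
        w = build_pooled_window(small_fixture.polls)
        T = len(small_fixture.polls)
        assert w.design.shape == (4 * T, 10)
        p_free = TransitionMatrix(MIXING_P.copy()).to_free()
        assert np.isfinite(w.objective(p_free))
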