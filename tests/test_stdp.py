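"""Tests of the pair/triplet STDP kernels and their rate-based limit."""

from dataclasses import replace

import numpy as np
import pytest

from cortexbcm import stdp
from cortexbcm.stdp import (
    SpikeTriplet,
    TripletParams,
    expected_drift,
    fit_triplet_params,
    pair_stdp_dw,
    quadrant_map,
    triplet_apply,
    triplet_sequence,
)
from cortexbcm.stimuli import poisson_train, spawn_seeds

GRID = np.array([5.0, 10.0, 15.0, 20.0, 30.0, 40.0, 50.0])


class TestParams:
    def test_threshold_positivity_constraint_enforced(self):
        with pytest.raises(ValueError, match="A2_minus"):
            TripletParams(A2_plus=1.0e-2, A2_minus=1.0e-3)

    def test_defaults_satisfy_constraint(self, triplet_params):
        p = triplet_params
        assert p.A2_minus * p.tau_minus > p.A2_plus * p.tau_plus


class TestSpikeTriplet:
    def test_sign_consistency_enforced(self):
        SpikeTriplet("post-pre-post", -10.0, 10.0)
        with pytest.raises(ValueError, match="inconsistent"):
            SpikeTriplet("post-pre-post", 10.0, 10.0)

    def test_unknown_ordering_rejected(self):
        with pytest.raises(ValueError):
            SpikeTriplet("pre-pre-pre", 1.0, 2.0)


class TestPairSTDP:
    def test_small_positive_lag_low_state_potentiates(self, triplet_params):
        assert pair_stdp_dw(5.0, 100.0, triplet_params) > 0

    def test_negative_lag_depresses(self, triplet_params):
        assert pair_stdp_dw(-5.0, 100.0, triplet_params) < 0
        assert pair_stdp_dw(-40.0, 300.0, triplet_params) < 0

    def test_long_lag_high_state_flips_to_depression(self, triplet_params):
        # the decay of a high history state overcomes the residual LTP kernel
        assert pair_stdp_dw(45.0, 300.0, triplet_params) < 0

    def test_zero_lag_rejected(self, triplet_params):
        with pytest.raises(ValueError):
            pair_stdp_dw(0.0, 100.0, triplet_params)


class TestTripletApply:
    def test_no_post_spikes_no_change(self, triplet_params):
        pre = poisson_train(20, 2000, seed=1)
        trace = triplet_apply(pre, np.empty(0), triplet_params)
        assert trace.total == 0.0

    def test_isolated_pair_matches_pair_kernel(self, triplet_params):
        # suppression is inert for first spikes; a single pre->post pair
        # reduces to the exponential pair kernel
        for lag in (5.0, 12.0, 30.0):
            total = triplet_apply(np.array([0.0]), np.array([lag]), triplet_params).total
            expected = triplet_params.A2_plus * np.exp(-lag / triplet_params.tau_plus)
            assert total == pytest.approx(expected, rel=1e-12)

    def test_single_post_pre_pair_matches_depression_kernel(self, triplet_params):
        for lag in (5.0, 20.0):
            total = triplet_apply(np.array([lag]), np.array([0.0]), triplet_params).total
            expected = -triplet_params.A2_minus * np.exp(-lag / triplet_params.tau_minus)
            assert total == pytest.approx(expected, rel=1e-12)

    def test_simultaneous_pre_post_rejected(self, triplet_params):
        with pytest.raises(ValueError, match="simultaneous"):
            triplet_apply(np.array([1.0]), np.array([1.0]), triplet_params)

    def test_pair_reduction_with_triplet_terms_off(self):
        # A3 = 0, tau_supp = 0: the model is exactly pair STDP on single pairs
        p = stdp._unchecked_params(A3_plus=0.0, A3_minus=0.0, tau_supp=0.0)
        total = triplet_apply(np.array([0.0, 100.0]), np.array([8.0, 110.0]), p).total
        # all-to-all pairs: pre->post lags 8, 110, 10; post->pre lag 92
        expected = (
            p.A2_plus * np.exp(-8.0 / p.tau_plus)
            + p.A2_plus * np.exp(-110.0 / p.tau_plus)
            + p.A2_plus * np.exp(-10.0 / p.tau_plus)
            - p.A2_minus * np.exp(-92.0 / p.tau_minus)
        )
        assert total == pytest.approx(expected, rel=1e-9)

    def test_monte_carlo_matches_closed_form_drift(self, triplet_params):
        """All-to-All triplet drift on independent Poisson trains equals the
        rate-based quadratic within 3 Monte-Carlo standard errors."""
        p = replace(triplet_params, tau_supp=0.0)  # suppression-free limit
        seeds = spawn_seeds(20240101, 200)
        k = 0
        for rho_x, rho_y in [(10.0, 10.0), (20.0, 40.0), (40.0, 20.0)]:
            T, reps = 400_000.0, 8
            vals = []
            for _ in range(reps):
                pre = poisson_train(rho_x, T, int(seeds[k])); k += 1
                post = poisson_train(rho_y, T, int(seeds[k])); k += 1
                vals.append(triplet_apply(pre, post, p).total / (T / 1000.0))
            vals = np.asarray(vals)
            mc, se = vals.mean(), vals.std(ddof=1) / np.sqrt(reps)
            cf = expected_drift(rho_x, rho_y, p)
            assert abs(mc - cf) < 3 * se, (rho_x, rho_y, mc, cf, se)


class TestQuadrantMap:
    def test_quadrant_one_is_pure_potentiation(self, triplet_params):
        dG, _ = quadrant_map(GRID, GRID + 2.0, triplet_params)
        assert np.nanmin(dG) >= 0

    def test_quadrant_three_is_pure_depression(self, triplet_params):
        dG, _ = quadrant_map(-GRID, -(GRID + 2.0), triplet_params)
        assert np.nanmax(dG) <= 0

    def test_quadrant_two_sign_flip_across_lag_asymmetry(self, triplet_params):
        dG, orderings = quadrant_map(-GRID, GRID, triplet_params)
        assert orderings[0, 0] == "post-pre-post"
        # |dt1| << |dt2|: the early depression pair dominates
        assert dG[0, -1] < 0
        # |dt1| >> |dt2|: the late potentiation pair dominates
        assert dG[-1, 0] > 0

    def test_quadrant_four_no_crossover_near_diagonal(self, triplet_params):
        dG, orderings = quadrant_map(GRID, -GRID, triplet_params)
        assert orderings[0, 0] == "pre-post-pre"
        diag = np.diag(dG)  # |dt1| = |dt2|
        assert np.all(diag < 0)

    def test_zero_lag_grid_rejected(self, triplet_params):
        with pytest.raises(ValueError):
            quadrant_map([0.0, 5.0], [5.0], triplet_params)


def _make_observations(params, lags):
    obs = []
    for d1 in lags:
        for d2 in lags:
            for ordering, s1, s2 in [("post-pre-post", -1, 1), ("pre-post-pre", 1, -1)]:
                dd1, dd2 = s1 * d1, s2 * d2
                pre, post = triplet_sequence(ordering, dd1, dd2)
                obs.append(((ordering, dd1, dd2), triplet_apply(pre, post, params).total))
    return obs


class TestFitTripletParams:
    TRUE = stdp._unchecked_params(
        A2_plus=3.6e-3, A2_minus=1.2e-2, A3_plus=7.0e-3, A3_minus=2.5e-3,
        tau_plus=19.0, tau_minus=30.0, tau_x=90.0, tau_y=140.0,
    )
    LAGS = [5.0, 10.0, 15.0, 20.0, 25.0, 35.0, 50.0]

    def test_noiseless_round_trip(self):
        obs = _make_observations(self.TRUE, self.LAGS)
        fit = fit_triplet_params(obs)
        for f in stdp._FIT_FIELDS:
            assert getattr(fit, f) == pytest.approx(getattr(self.TRUE, f), rel=1e-3)

    def test_noisy_amplitude_recovery_within_15_percent(self):
        rng = np.random.default_rng(0)
        obs = [
            (key, dg * (1 + 0.05 * rng.standard_normal()))
            for key, dg in _make_observations(self.TRUE, self.LAGS)
        ]
        fit = fit_triplet_params(obs)
        for f in ("A2_plus", "A2_minus", "A3_plus", "A3_minus"):
            rel = abs(getattr(fit, f) - getattr(self.TRUE, f)) / getattr(self.TRUE, f)
            assert rel < 0.15, f

    def test_underdetermined_input_rejected(self):
        obs = _make_observations(self.TRUE, [10.0])[:4]  # too few points
        with pytest.raises(ValueError, match="underdetermined"):
            fit_triplet_params(obs)
        # enough points but one typical quadrant missing
        only_q2 = [
            (k, v) for k, v in _make_observations(self.TRUE, self.LAGS)
            if k[0] == "post-pre-post"
        ]
        with pytest.raises(ValueError, match="pre-post-pre"):
            fit_triplet_params(only_q2)

    def test_constraint_violating_data_warns(self):
        bad = stdp._unchecked_params(A2_plus=8.0e-3, A2_minus=1.0e-4)
        obs = _make_observations(bad, [5.0, 10.0, 20.0, 35.0])
        with pytest.warns(UserWarning, match="threshold"):
            fit_triplet_params(obs)
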