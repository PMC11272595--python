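"""Ideal-observer geometry: posterior updates, EE, and placement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circlequest.geometry import (
    InconsistentObservationError,
    PosteriorBelief,
    SampleObservation,
    SearchSpace,
    best_placement,
    ee,
    expected_error,
    init_posterior,
    localization_error,
    posterior_from_observations,
    simulate_observation,
    update_posterior,
)


def belief_from(points, weights, space) -> PosteriorBelief:
    pts = np.asarray(points, dtype=float)
    w = np.asarray(weights, dtype=float)
    return PosteriorBelief(space=space, candidates=pts, weights=w / w.sum())


class TestSearchSpace:
    def test_uniform_prior_over_admissible_grid(self):
        space = SearchSpace(width=100, height=100, circle_radius=10, grid_step=10)
        belief = init_posterior(space)
        assert np.allclose(belief.weights, belief.weights[0])
        # centers inset by the radius so the circle fits on screen
        assert belief.candidates[:, 0].min() >= 10
        assert belief.candidates[:, 0].max() <= 90

    def test_tight_space_leaves_center_candidate(self):
        space = SearchSpace(width=40, height=40, circle_radius=19, grid_step=1)
        belief = init_posterior(space)
        assert belief.support_size >= 1

    def test_circle_must_fit(self):
        with pytest.raises(ValueError):
            SearchSpace(width=200, height=200, circle_radius=130)

    def test_grid_step_below_one_rejected(self):
        with pytest.raises(ValueError):
            SearchSpace(width=100, height=100, circle_radius=10, grid_step=0.5)


class TestUpdatePosterior:
    def test_inside_sample_keeps_near_candidates(self, small_space):
        belief = belief_from([(20, 20), (50, 20)], [0.5, 0.5], small_space)
        out = update_posterior(
            belief, SampleObservation(20, 20, "inside")
        )
        assert out.candidates.tolist() == [[20, 20]]
        assert out.weights.tolist() == [1.0]

    def test_outside_sample_keeps_far_candidates(self, small_space):
        belief = belief_from([(20, 20), (50, 20)], [0.5, 0.5], small_space)
        out = update_posterior(belief, SampleObservation(20, 20, "outside"))
        assert out.candidates.tolist() == [[50, 20]]

    def test_retained_fraction_matches_brute_force(self, small_space):
        belief = init_posterior(small_space)
        obs = SampleObservation(50, 50, "inside")
        out = update_posterior(belief, obs)
        r = small_space.circle_radius
        brute = sum(
            1
            for (x, y) in belief.candidates
            if math.hypot(x - 50, y - 50) <= r
        )
        assert out.support_size == brute

    def test_contradiction_raises(self, small_space):
        belief = init_posterior(small_space)
        belief = update_posterior(belief, SampleObservation(50, 50, "inside"))
        with pytest.raises(InconsistentObservationError):
            update_posterior(belief, SampleObservation(50, 50, "outside"))


class TestExpectedErrorAndPlacement:
    def test_zero_for_singleton(self, default_space):
        b = belief_from([(100, 100)], [1.0], default_space)
        assert expected_error(b, (100, 100)) == 0.0
        assert ee(b).ee == 0.0
        assert best_placement(b) == (100, 100)

    def test_symmetric_pair(self, default_space):
        b = belief_from([(0, 0), (0, 10)], [0.5, 0.5], default_space)
        assert expected_error(b, (0, 5)) == pytest.approx(5.0)
        est = ee(b)
        assert est.centroid == pytest.approx((0.0, 5.0))
        assert est.ee == pytest.approx(5.0)

    def test_weighted_centroid(self, default_space):
        b = belief_from([(0, 0), (8, 0)], [0.75, 0.25], default_space)
        assert best_placement(b) == pytest.approx((2.0, 0.0))

    def test_matches_loop_oracle(self, default_space, rng):
        pts = rng.uniform(0, 200, size=(20, 2))
        w = rng.uniform(0.1, 1, size=20)
        b = belief_from(pts, w, default_space)
        placement = (77.0, 133.0)
        oracle = sum(
            wi * math.hypot(x - placement[0], y - placement[1])
            for (x, y), wi in zip(b.candidates, b.weights)
        )
        assert expected_error(b, placement) == pytest.approx(oracle, abs=1e-9)
        # ee() equals the oracle evaluated at the centroid
        cx = sum(wi * x for (x, _), wi in zip(b.candidates, b.weights))
        cy = sum(wi * y for (_, y), wi in zip(b.candidates, b.weights))
        oracle_ee = sum(
            wi * math.hypot(x - cx, y - cy)
            for (x, y), wi in zip(b.candidates, b.weights)
        )
        assert ee(b).ee == pytest.approx(oracle_ee, abs=1e-9)


class TestSimulateObservation:
    def test_boundary_is_inside(self, small_space):
        obs = simulate_observation((50, 50), (60, 50), small_space)
        assert obs.label == "inside"  # dist == r exactly
        obs = simulate_observation((50, 50), (60.001, 50), small_space)
        assert obs.label == "outside"

    def test_localization_error_345(self):
        assert localization_error((0, 0), (3, 4)) == pytest.approx(5.0)
        assert localization_error((7, 7), (7, 7)) == 0.0


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    n_obs=st.integers(1, 12),
)
def test_nested_support_and_consistency(seed, n_obs):
    """Support only shrinks, and the true center is never eliminated."""
    space = SearchSpace(width=100, height=100, circle_radius=10, grid_step=2)
    rng = np.random.default_rng(seed)
    grid = space.candidate_grid()
    true_center = tuple(grid[rng.integers(grid.shape[0])])
    belief = init_posterior(space)
    for _ in range(n_obs):
        pt = (rng.uniform(0, 100), rng.uniform(0, 100))
        obs = simulate_observation(true_center, pt, space)
        new = update_posterior(belief, obs)
        old_set = set(map(tuple, belief.candidates))
        new_set = set(map(tuple, new.candidates))
        assert new_set <= old_set
        assert tuple(true_center) in new_set
        belief = new


@settings(max_examples=10, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_ee_matches_dense_double_loop(seed):
    """EE and centroid agree with a dense brute-force summation to 1e-9."""
    space = SearchSpace(width=60, height=60, circle_radius=8, grid_step=1)
    rng = np.random.default_rng(seed)
    grid = space.candidate_grid()
    true_center = tuple(grid[rng.integers(grid.shape[0])])
    obs = [
        simulate_observation(
            true_center, (rng.uniform(0, 60), rng.uniform(0, 60)), space
        )
        for _ in range(4)
    ]
    belief = posterior_from_observations(space, obs)
    # independent enumeration over the full initial grid
    r = space.circle_radius
    kept = []
    for x, y in grid:
        ok = True
        for o in obs:
            d = math.hypot(x - o.x, y - o.y)
            if (o.label == "inside") != (d <= r):
                ok = False
                break
        if ok:
            kept.append((x, y))
    cx = sum(x for x, _ in kept) / len(kept)
    cy = sum(y for _, y in kept) / len(kept)
    oracle = sum(math.hypot(x - cx, y - cy) for x, y in kept) / len(kept)
    est = ee(belief)
    assert est.ee == pytest.approx(oracle, abs=1e-9)
    assert est.centroid == pytest.approx((cx, cy), abs=1e-9)


def test_grid_refinement_bound(rng):
    """EE at grid_step 4 stays within 2*step of the step-1 reference."""
    coarse = SearchSpace(width=100, height=100, circle_radius=10, grid_step=4)
    fine = SearchSpace(width=100, height=100, circle_radius=10, grid_step=1)
    for _ in range(5):
        center = (rng.uniform(15, 85), rng.uniform(15, 85))
        pts = [(rng.uniform(0, 100), rng.uniform(0, 100)) for _ in range(3)]
        obs_c = [simulate_observation(center, p, coarse) for p in pts]
        ee_c = ee(posterior_from_observations(coarse, obs_c)).ee
        ee_f = ee(posterior_from_observations(fine, obs_c)).ee
        assert abs(ee_c - ee_f) < 2 * coarse.grid_step
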