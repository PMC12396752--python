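"""Continuous ocotillo search: factor closed forms and the run contracts."""

import math

import numpy as np
import pytest

from ocotillo.core import (
    OcoaParams,
    amplitude,
    convergence_factor,
    distance_factor,
    exploit_candidates,
    exploit_step,
    explore_step,
    learning_factor,
    optimize,
    oscillation_sum,
)
from ocotillo.errors import InvalidParameterError, InvalidSpecError
from ocotillo.objectives import benchmark_objective, sphere
from ocotillo.space import SearchSpace, apply_bounds


# ---------------------------------------------------------------------------
# Closed-form factors
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "theta, train, expected",
    [([0.0], 1.0, [2.0]), ([np.pi], 1.0, [-2.0]), ([0.0], 2.0, [0.5])],
)
def test_distance_factor_values(theta, train, expected):
    np.testing.assert_allclose(distance_factor(np.array(theta), train), expected, atol=1e-12)


@pytest.mark.parametrize(
    "theta, ab, expected",
    [([0.0], 1.0, [0.0]), ([np.pi / 2], 1.0, [1.0]), ([np.pi / 4], 2.0, [1.0])],
)
def test_amplitude_values(theta, ab, expected):
    np.testing.assert_allclose(amplitude(np.array(theta), ab), expected, atol=1e-12)


@pytest.mark.parametrize(
    "theta, expected",
    [([0.0], [1.0]), ([np.pi / 2], [-1.0]), ([np.pi], [1.0])],
)
def test_learning_factor_values(theta, expected):
    np.testing.assert_allclose(learning_factor(np.array(theta)), expected, atol=1e-12)


@pytest.mark.parametrize(
    "theta, train, expected",
    [([0.0], 1.0, [0.0]), ([np.pi], 1.0, [0.0]), ([np.pi / 2], 1.0, [1.0])],
)
def test_oscillation_sum_values(theta, train, expected):
    # at pi/2 the 11 terms are 0,1,0,-1,0,1,0,-1,0,1,0 summing to 1
    np.testing.assert_allclose(oscillation_sum(np.array(theta), train), expected, atol=1e-12)


@pytest.mark.parametrize("factor", [distance_factor, oscillation_sum])
def test_train_must_be_positive(factor):
    with pytest.raises(InvalidParameterError):
        factor(np.array([0.5]), 0.0)


def test_factor_closed_forms_match_bruteforce(rng):
    """Vectorized factors agree with scalar-loop evaluation at random points."""
    thetas = rng.uniform(-10, 10, size=1000)
    trains = rng.uniform(0.1, 500, size=1000)
    for th, tr in zip(thetas[:50], trains[:50]):  # scalar spot checks, full math
        assert distance_factor(np.array([th]), tr)[0] == pytest.approx(2 * math.cos(th) / tr**2, abs=1e-12)
        assert learning_factor(np.array([th]))[0] == pytest.approx(
            1 - 2 * math.sin(th) * (1 + 8 * math.cos(th)) ** 2, rel=1e-12, abs=1e-12
        )
        brute = sum(math.sin(n * th) for n in range(11)) / tr**2
        assert oscillation_sum(np.array([th]), tr)[0] == pytest.approx(brute, rel=1e-11, abs=1e-12)
    # vectorized consistency over the full 1000 points
    np.testing.assert_allclose(
        distance_factor(thetas, 3.0), np.array([2 * math.cos(t) / 9 for t in thetas]), atol=1e-12
    )


@pytest.mark.parametrize(
    "g, a, d, expected",
    [([0.0], [0.5], [0.5], [1.0]), ([1.0], [0.5], [0.5], [0.0]), ([2.0], [0.5], [0.5], [-3.0])],
)
def test_convergence_factor_values(g, a, d, expected):
    np.testing.assert_allclose(
        convergence_factor(np.array(g), np.array(a), np.array(d)), expected, atol=1e-12
    )


def test_convergence_factor_guards_zero_denominator():
    out = convergence_factor(np.array([1.0]), np.array([0.5]), np.array([-0.5]))
    assert np.isfinite(out).all() and out[0] <= 1.0


# ---------------------------------------------------------------------------
# Update steps and bounds
# ---------------------------------------------------------------------------

def test_explore_step_examples():
    np.testing.assert_allclose(explore_step(np.zeros(2), 0.0, 1.0), np.zeros(2), atol=1e-12)
    # A*D = 0, L = 1 at the origin, so the move is r1 alone
    np.testing.assert_allclose(explore_step(np.zeros(2), 0.5, 1.0), [0.5, 0.5], atol=1e-12)
    # at pi/2: A=1, D=0, L=-1
    np.testing.assert_allclose(explore_step(np.array([np.pi / 2]), 1.0, 1.0), [np.pi / 2 - 1.0], atol=1e-12)


def test_explore_step_rejects_bad_r1():
    with pytest.raises(InvalidParameterError):
        explore_step(np.zeros(2), 1.5, 1.0)


def test_apply_bounds_modes():
    space = SearchSpace.cube(1, 0.0, 1.0)
    assert apply_bounds(np.array([2.0]), space, "clip")[0] == 1.0
    assert apply_bounds(np.array([-0.25]), space, "reflect")[0] == 0.25
    for mode in ("clip", "reflect"):
        assert apply_bounds(np.array([0.5]), space, mode)[0] == 0.5
    with pytest.raises(InvalidParameterError):
        apply_bounds(np.array([0.5]), space, "wrap")


def test_search_space_validation():
    with pytest.raises(InvalidSpecError):
        SearchSpace(dim=2, lower=np.array([0.0, 1.0]), upper=np.array([1.0, 1.0]))


def test_exploit_candidates_vanish_at_origin():
    params = OcoaParams()
    a, b = exploit_candidates(np.zeros(1), np.zeros(1), 1, 1.0, params, r1=0.0, r2=0.0, gauss=np.zeros(1))
    np.testing.assert_allclose(a, [0.0], atol=1e-12)
    np.testing.assert_allclose(b, [0.0], atol=1e-12)


def test_exploit_gaussian_candidate_terms():
    # theta = pi/2: L1=-1, Ai=1, F=1; best=0 so Ao=0 -> candidate a = g - r1
    params = OcoaParams()
    a, _ = exploit_candidates(
        np.array([np.pi / 2]), np.zeros(1), 1, 1.0, params, r1=1.0, r2=0.0, gauss=np.zeros(1)
    )
    np.testing.assert_allclose(a, [-1.0], atol=1e-12)


def test_exploit_alternative_candidate_formula():
    # (r2*i^2)*(K*A/(i*train)^2)^2 with K*A forced to 1 via theta=pi/2, g=0:
    # K = 1 - (0/(A+D))^2 = 1, A = sin(pi/2) = 1; i=2, train=1 -> 4*(1/4)^2 = 0.25
    params = OcoaParams()
    _, b = exploit_candidates(
        np.array([np.pi / 2]), np.zeros(1), 2, 1.0, params, r1=0.0, r2=1.0, gauss=np.zeros(1)
    )
    np.testing.assert_allclose(b, [4.0 * (1.0 / 4.0) ** 2], atol=1e-12)


def test_exploit_step_returns_fitter_candidate(rng):
    space = SearchSpace.cube(1, -5.0, 5.0)
    params = OcoaParams()
    pos, fit = exploit_step(
        np.array([np.pi / 2]), np.zeros(1), np.zeros(1), 1, 1.0, params, rng, sphere, space,
        r1=1.0, r2=0.0, gauss=np.zeros(1),
    )
    # candidate a = -1 (fitness 1), candidate b = 0 (fitness 0) -> b wins
    np.testing.assert_allclose(pos, [0.0], atol=1e-12)
    assert fit == 0.0


# ---------------------------------------------------------------------------
# Full runs
# ---------------------------------------------------------------------------

def test_params_validation():
    with pytest.raises(InvalidParameterError):
        OcoaParams(population_size=0)
    with pytest.raises(InvalidParameterError):
        OcoaParams(ab=0.0)
    with pytest.raises(InvalidParameterError):
        OcoaParams(train_convention="bogus")


def test_constant_objective_returns_constant():
    res = optimize(lambda th: 5.0, SearchSpace.cube(3, -1, 1), OcoaParams(max_iter=5, population_size=5, seed=0))
    assert res.best.fitness == 5.0


def test_determinism_bit_identical():
    space = SearchSpace.cube(4, -5, 5)
    params = OcoaParams(population_size=6, max_iter=20, seed=99)
    r1 = optimize(sphere, space, params)
    r2 = optimize(sphere, space, params)
    assert r1.history == r2.history
    np.testing.assert_array_equal(r1.best.position, r2.best.position)


def test_elitism_and_budget_accounting():
    params = OcoaParams(population_size=7, max_iter=30, seed=3)
    res = optimize(sphere, SearchSpace.cube(3, -5, 5), params)
    fitnesses = [f for _, f in res.history]
    assert all(b <= a + 1e-15 for a, b in zip(fitnesses, fitnesses[1:]))
    assert res.evaluations_used == 7 * (1 + 3 * 30)


def test_positions_respect_bounds_with_clip():
    space = SearchSpace.cube(2, -1.0, 2.0)
    tracked = []
    def spy(theta):
        tracked.append(theta.copy())
        return sphere(theta)
    optimize(spy, space, OcoaParams(population_size=5, max_iter=10, seed=1))
    pts = np.array(tracked)
    assert np.all(pts >= space.lower - 1e-12) and np.all(pts <= space.upper + 1e-12)


def test_non_finite_objective_becomes_inf():
    res = optimize(lambda th: float("nan"), SearchSpace.cube(2, -1, 1),
                   OcoaParams(population_size=3, max_iter=2, seed=0))
    assert math.isinf(res.best.fitness)


def test_sphere_converges_far_below_random_search():
    """Median best over seeds must undercut the initial population by orders of magnitude."""
    space = SearchSpace.cube(5, -5, 5)
    finals, initials = [], []
    for seed in range(1, 6):
        res = optimize(benchmark_objective("sphere"), space, OcoaParams(max_iter=100, seed=seed))
        finals.append(res.best.fitness)
        initials.append(res.history[0][1])
    assert np.median(finals) < np.median(initials) * 1e-3
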