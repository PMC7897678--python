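"""Minimal-distance CFDs, Monte Carlo shuffle envelopes, signed-rank test."""

import numpy as np
import pytest
from oracles import brute_force_nearest

from synaptoquant import (
    ColocPlanEntry,
    SceneSpec,
    SpotSet,
    compare_observed_vs_null,
    min_distance_cfd,
    plant_ground_truth,
    shuffle_centroids,
    shuffle_envelope,
)
from conftest import uniform_spots

FIELD = np.array([12800.0, 12800.0, 3000.0])


def test_single_pair_cfd():
    A = SpotSet.from_coords([[1000.0, 1000.0, 1000.0]], FIELD)
    B = SpotSet.from_coords([[1300.0, 1000.0, 1000.0]], FIELD)
    cfd = min_distance_cfd(A, B)
    assert np.allclose(cfd.distances_nm, [300.0])
    assert np.allclose(cfd.cum_freq, [1.0])
    assert cfd.evaluate(np.array([299.0, 300.0, 301.0])).tolist() == [0.0, 1.0, 1.0]


def test_identical_channels_all_zero(rng):
    A = uniform_spots(rng, 30, FIELD)
    cfd = min_distance_cfd(A, A)
    assert np.all(cfd.distances_nm == 0.0)
    assert cfd.median_nm == 0.0


def test_cfd_matches_brute_force_double_loop(rng):
    A = uniform_spots(rng, 50, FIELD)
    B = uniform_spots(rng, 50, FIELD)
    cfd = min_distance_cfd(A, B)
    assert np.allclose(cfd.distances_nm, np.sort(brute_force_nearest(A.coords_nm, B.coords_nm)))


def test_empty_target_rejected(rng):
    A = uniform_spots(rng, 5, FIELD)
    with pytest.raises(ValueError):
        min_distance_cfd(A, uniform_spots(rng, 0, FIELD))


def test_shuffle_preserves_count_and_field(rng):
    S = uniform_spots(rng, 77, FIELD)
    sh = shuffle_centroids(S, seed=5)
    assert len(sh) == 77
    assert np.array_equal(sh.field_size_nm, S.field_size_nm)
    sh2 = shuffle_centroids(S, seed=6)
    assert not np.array_equal(sh.coords_nm, sh2.coords_nm)


def test_shuffled_nearest_neighbor_matches_poisson_limit(rng):
    # mean NN distance of a uniform process: Gamma(4/3) * (3V / 4 pi n)^(1/3)
    # = 0.554 * (V/n)^(1/3)
    field = np.array([10000.0, 10000.0, 10000.0])
    n = 1000
    expected = 0.5540 * (np.prod(field) / n) ** (1.0 / 3.0)
    B = uniform_spots(rng, n, field)
    A = uniform_spots(rng, 400, field)
    means = [
        min_distance_cfd(A, shuffle_centroids(B, seed=s)).distances_nm.mean()
        for s in range(20)
    ]
    assert abs(np.mean(means) - expected) / expected < 0.05


def test_envelope_contains_uniform_observation(rng):
    # pointwise coverage is nominally 95%; average the inside fraction over
    # independent fields since excursions are correlated along the grid
    coverages = []
    for _ in range(25):
        A = uniform_spots(rng, 100, FIELD)
        B = uniform_spots(rng, 100, FIELD)
        env = shuffle_envelope(A, B, n_iterations=100, seed=int(rng.integers(2**31)))
        obs = env.observed.evaluate(env.grid_nm)
        inside = (obs >= env.ci_low) & (obs <= env.ci_high)
        coverages.append(inside.mean())
        assert np.all(env.ci_low <= env.mean_null_cfd + 1e-12)
        assert np.all(env.mean_null_cfd <= env.ci_high + 1e-12)
    assert np.mean(coverages) >= 0.90


def test_envelope_detects_planted_attraction():
    spec = SceneSpec(
        channels=("a", "b"),
        n_spots_per_channel={"a": 100, "b": 100},
        coloc_plan=(ColocPlanEntry("a", "b", 0.5, 50.0),),
        seed=11,
    )
    truth = plant_ground_truth(spec)
    env = shuffle_envelope(truth.spot_set("a"), truth.spot_set("b"),
                           n_iterations=100, seed=3)
    short = (env.grid_nm > 0) & (env.grid_nm < 200.0)
    obs = env.observed.evaluate(env.grid_nm)
    assert np.all(obs[short] > env.ci_high[short])
    assert env.observed_median_nm < env.null_median_nm


def test_envelope_deterministic_under_seed(rng):
    A = uniform_spots(rng, 40, FIELD)
    B = uniform_spots(rng, 40, FIELD)
    e1 = shuffle_envelope(A, B, n_iterations=100, seed=12)
    e2 = shuffle_envelope(A, B, n_iterations=100, seed=12)
    assert np.array_equal(e1.mean_null_cfd, e2.mean_null_cfd)
    assert np.array_equal(e1.ci_low, e2.ci_low)
    assert np.array_equal(e1.per_iteration_medians, e2.per_iteration_medians)


def test_envelope_needs_two_iterations(rng):
    A = uniform_spots(rng, 10, FIELD)
    with pytest.raises(ValueError):
        shuffle_envelope(A, A, n_iterations=1, seed=0)


# --- signed-rank comparison -------------------------------------------------


def test_degenerate_identical_pairs():
    pairs = [(500.0, 500.0)] * 10
    res = compare_observed_vs_null(pairs)
    assert res.degenerate_pairs
    assert res.p_value == 1.0


def test_too_few_pairs_rejected():
    with pytest.raises(ValueError):
        compare_observed_vs_null([(1.0, 2.0)] * 5)


def test_planted_attraction_detected_at_eighteen_images():
    rng = np.random.default_rng(13)
    detections = 0
    reps = 10
    for _ in range(reps):
        med = []
        for _ in range(18):
            spec = SceneSpec(
                channels=("a", "b"),
                n_spots_per_channel={"a": 100, "b": 100},
                coloc_plan=(ColocPlanEntry("a", "b", 0.5, 50.0),),
                seed=int(rng.integers(2**31)),
            )
            truth = plant_ground_truth(spec)
            env = shuffle_envelope(
                truth.spot_set("a"), truth.spot_set("b"),
                n_iterations=100, seed=int(rng.integers(2**31)),
            )
            med.append((env.observed_median_nm, env.null_median_nm))
        res = compare_observed_vs_null(med)
        if res.p_value < 0.05 and res.median_paired_difference < 0:
            detections += 1
    assert detections == reps
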