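"""Ellipsoid-overlap predicate, pairwise and synaptic-triple colocalization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import brute_force_pairs

from synaptoquant import (
    ColocPlanEntry,
    EllipsoidSpec,
    SceneSpec,
    SpotSet,
    ellipsoids_overlap,
    pairwise_coloc,
    plant_ground_truth,
    synaptic_filter,
    triple_coloc,
)
from conftest import uniform_spots

SPEC = EllipsoidSpec()  # 200 nm lateral, 500 nm axial, full-axis convention


@pytest.mark.parametrize(
    "delta,expected",
    [
        ((0.0, 0.0, 0.0), True),  # identity
        ((200.0, 0.0, 0.0), True),  # lateral tangency, scaled distance exactly 2
        ((0.0, 200.0, 0.0), True),
        ((0.0, 0.0, 500.0), True),  # axial tangency
        ((0.0, 0.0, 600.0), False),  # 600/250 = 2.4 > 2
        ((201.0, 0.0, 0.0), False),
    ],
)
def test_overlap_predicate_tangency(delta, expected):
    c = np.array([5000.0, 5000.0, 1000.0])
    assert ellipsoids_overlap(c, c + np.array(delta), SPEC) is expected


def test_semi_axis_convention_doubles_reach():
    spec = EllipsoidSpec(size_convention="semi-axis")
    c = np.zeros(3)
    assert ellipsoids_overlap(c, [400.0, 0.0, 0.0], spec)
    assert not ellipsoids_overlap(c, [400.0001, 0.0, 0.0], spec)


@settings(deadline=None, max_examples=200)
@given(
    dx=st.floats(-1000, 1000),
    dy=st.floats(-1000, 1000),
    dz=st.floats(-1500, 1500),
    lat=st.floats(50, 600),
    ax=st.floats(50, 1200),
)
def test_overlap_symmetry_and_size_monotonicity(dx, dy, dz, lat, ax):
    c1 = np.array([2000.0, 2000.0, 2000.0])
    c2 = c1 + np.array([dx, dy, dz])
    spec = EllipsoidSpec(lateral_size_nm=lat, axial_size_nm=ax)
    bigger = EllipsoidSpec(lateral_size_nm=lat * 1.5, axial_size_nm=ax * 1.5)
    assert ellipsoids_overlap(c1, c2, spec) == ellipsoids_overlap(c2, c1, spec)
    if ellipsoids_overlap(c1, c2, spec):
        assert ellipsoids_overlap(c1, c2, bigger)


def test_self_coloc_fraction_is_one(rng):
    A = uniform_spots(rng, 40, (10000.0, 10000.0, 3000.0))
    res = pairwise_coloc(A, A, SPEC)
    assert res.fraction_A_coloc == 1.0
    assert res.n_A_coloc == 40


def test_empty_reference_fraction_undefined(rng):
    field = (10000.0, 10000.0, 3000.0)
    A = uniform_spots(rng, 0, field)
    B = uniform_spots(rng, 10, field)
    res = pairwise_coloc(A, B, SPEC)
    assert res.n_A_coloc == 0
    assert math.isnan(res.fraction_A_coloc)


def test_planted_fraction_recovered():
    spec = SceneSpec(
        field_size_nm=(50000.0, 50000.0, 3000.0),
        channels=("a", "b"),
        n_spots_per_channel={"a": 200, "b": 200},
        coloc_plan=(ColocPlanEntry("a", "b", 0.5, 0.0),),
        seed=31,
    )
    truth = plant_ground_truth(spec)
    res = pairwise_coloc(truth.spot_set("a"), truth.spot_set("b"), SPEC)
    assert abs(res.fraction_A_coloc - 0.5) <= 1.0 / 200 + 0.02


def test_chance_rate_matches_poisson_closed_form():
    # fraction ~ 1 - (1 - v_e/V)^n_B for independent uniform channels, where
    # v_e is the volume of the scaled-distance-2 ellipsoid (semi-axes 2a, 2c)
    field = np.array([12800.0, 12800.0, 3000.0])
    v_e = 4.0 / 3.0 * np.pi * 200.0 * 200.0 * 500.0
    n_b = 200
    expected = 1.0 - (1.0 - v_e / np.prod(field)) ** n_b
    rng = np.random.default_rng(37)
    fracs = [
        pairwise_coloc(
            uniform_spots(rng, 200, field), uniform_spots(rng, n_b, field), SPEC
        ).fraction_A_coloc
        for _ in range(40)
    ]
    # SE of the mean over 40 fields of 200 reference spots is ~0.002
    assert abs(np.mean(fracs) - expected) < 0.01


def test_kdtree_matches_brute_force_all_pairs(rng):
    field = np.array([8000.0, 8000.0, 3000.0])
    for _ in range(10):
        A = uniform_spots(rng, 120, field)
        B = uniform_spots(rng, 150, field)
        res = pairwise_coloc(A, B, SPEC)
        expected = brute_force_pairs(A.coords_nm, B.coords_nm, SPEC.semi_axes_nm)
        got = {(a - 1, b - 1) for a, b in res.pair_list}  # labels are 1-based
        assert got == expected
        assert res.n_A_coloc == len({i for i, _ in expected})


def test_mismatched_fields_rejected(rng):
    A = uniform_spots(rng, 5, (8000.0, 8000.0, 3000.0))
    B = uniform_spots(rng, 5, (9000.0, 9000.0, 3000.0))
    with pytest.raises(ValueError):
        pairwise_coloc(A, B, SPEC)


# --- synaptic filter and triple analysis -----------------------------------


def test_synaptic_filter_empty_marker(rng):
    field = (10000.0, 10000.0, 3000.0)
    A = uniform_spots(rng, 20, field)
    empty = uniform_spots(rng, 0, field)
    assert len(synaptic_filter(A, empty, SPEC)) == 0


def test_synaptic_filter_superset_marker(rng):
    field = (10000.0, 10000.0, 3000.0)
    A = uniform_spots(rng, 20, field)
    filtered = synaptic_filter(A, A, SPEC)
    assert np.array_equal(filtered.labels, A.labels)


def test_synaptic_filter_counts_planted_links():
    spec = SceneSpec(
        field_size_nm=(50000.0, 50000.0, 3000.0),
        channels=("a", "syp"),
        n_spots_per_channel={"a": 200, "syp": 200},
        coloc_plan=(ColocPlanEntry("a", "syp", 0.4, 0.0),),
        seed=41,
    )
    truth = plant_ground_truth(spec)
    filtered = synaptic_filter(truth.spot_set("a"), truth.spot_set("syp"), SPEC)
    # 80 planted links; at this density chance adds at most a couple spots
    assert 80 <= len(filtered) <= 83


def test_triple_all_identical_channels(rng):
    A = uniform_spots(rng, 25, (10000.0, 10000.0, 3000.0))
    res = triple_coloc(A, A, A, SPEC)
    assert res.fraction_A_coloc == 1.0


def test_triple_disjoint_synaptic_pools():
    field = (20000.0, 20000.0, 3000.0)
    # A and its synapses on the left, B and its synapses far right
    a = np.array([[2000.0, 2000.0, 1000.0]])
    b = np.array([[18000.0, 18000.0, 2000.0]])
    syp = np.vstack([a, b])
    A = SpotSet.from_coords(a, field)
    B = SpotSet.from_coords(b, field)
    S = SpotSet.from_coords(syp, field)
    res = triple_coloc(A, B, S, SPEC)
    assert res.n_A == 1 and res.n_A_coloc == 0
    assert res.fraction_A_coloc == 0.0
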