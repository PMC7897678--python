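"""Generator ground truth: planted counts, links, rendering fidelity."""

import numpy as np
import pytest
from oracles import points_in_spheres

from synaptoquant import (
    ColocPlanEntry,
    MaskPlan,
    SceneSpec,
    make_flow_events,
    make_fraction_tables,
    make_mask_scene,
    make_spot_scene,
    plant_ground_truth,
)
from synaptoquant.synthetic import DensityError


def test_single_blob_argmax_is_planted_centroid():
    spec = SceneSpec(
        channels=("a",),
        n_spots_per_channel={"a": 1},
        background_level=0.0,
        noise_sd=0.0,
        seed=3,
    )
    grids, truth = make_spot_scene(spec)
    g = grids["a"]
    zyx = np.unravel_index(np.argmax(g.data), g.data.shape)
    c = truth.centroids["a"][0]
    assert np.all(np.floor(c / g.voxel_size_nm).astype(int) == np.array(zyx)[::-1])


def test_full_coloc_zero_jitter_coincides():
    spec = SceneSpec(
        channels=("a", "b"),
        n_spots_per_channel={"a": 50, "b": 50},
        coloc_plan=(ColocPlanEntry("a", "b", 1.0, 0.0),),
        seed=5,
    )
    truth = plant_ground_truth(spec)
    b = truth.centroids["b"]
    for _, i, _, j in truth.links:
        assert np.allclose(truth.centroids["a"][i], b[j])
    assert len(truth.links) == 50


def test_link_count_matches_rounded_fraction(paired_spec):
    truth = plant_ground_truth(paired_spec)
    # oracle: direct count of planted pairs
    assert sum(1 for l in truth.links if l[0] == "a" and l[2] == "b") == 100
    assert truth.planted_fraction("a", "b") == 0.5


@pytest.mark.parametrize("fraction", [0.1, 0.33, 0.501, 0.87])
def test_planted_fraction_recomputes_within_1_over_n(fraction):
    n = 73
    spec = SceneSpec(
        channels=("a", "b"),
        n_spots_per_channel={"a": n, "b": n},
        coloc_plan=(ColocPlanEntry("a", "b", fraction, 30.0),),
        seed=11,
    )
    truth = plant_ground_truth(spec)
    assert abs(truth.planted_fraction("a", "b") - fraction) <= 1.0 / n


def test_jitter_bounds_linked_pair_distance():
    jitter = 80.0
    spec = SceneSpec(
        channels=("a", "b"),
        n_spots_per_channel={"a": 100, "b": 100},
        coloc_plan=(ColocPlanEntry("a", "b", 1.0, jitter),),
        seed=13,
    )
    truth = plant_ground_truth(spec)
    for _, i, _, j in truth.links:
        d = np.linalg.norm(truth.centroids["a"][i] - truth.centroids["b"][j])
        assert d <= 3.0 * jitter + 1e-9


def test_scene_determinism_byte_identical(paired_spec):
    g1, t1 = make_spot_scene(paired_spec)
    g2, t2 = make_spot_scene(paired_spec)
    for ch in g1:
        assert np.array_equal(g1[ch].data, g2[ch].data)
    assert t1.links == t2.links
    for ch in t1.centroids:
        assert np.array_equal(t1.centroids[ch], t2.centroids[ch])


def test_rendered_blob_center_of_mass_within_half_voxel(small_noiseless_spec):
    grids, truth = make_spot_scene(small_noiseless_spec)
    g = grids["a"]
    half_diag = float(np.linalg.norm(g.voxel_size_nm)) / 2.0
    sigma = np.asarray(small_noiseless_spec.spot_sigma_nm)
    checked = 0
    for c in truth.centroids["a"]:
        if np.any(c < 3 * sigma) or np.any(c > g.field_size_nm - 3 * sigma):
            continue  # blob truncated by the field boundary
        iv = np.floor(c / g.voxel_size_nm).astype(int)
        lo = np.maximum(iv - 6, 0)
        hi = np.minimum(iv + 7, np.array(g.data.shape)[::-1])
        sub = g.data[lo[2] : hi[2], lo[1] : hi[1], lo[0] : hi[0]]
        vox = np.argwhere(sub > 0) + lo[::-1]
        w = sub[sub > 0]
        com = (g.voxel_centers_nm(vox) * w[:, None]).sum(axis=0) / w.sum()
        assert np.linalg.norm(com - c) <= half_diag
        checked += 1
    assert checked >= 10  # most blobs are interior at this density


def test_overdense_scene_refused():
    with pytest.raises(DensityError):
        plant_ground_truth(
            SceneSpec(
                field_size_nm=(2000.0, 2000.0, 1600.0),
                voxel_size_nm=(50.0, 50.0, 150.0),
                channels=("a",),
                n_spots_per_channel={"a": 2000},
            )
        )


# --- mask scenes -----------------------------------------------------------


@pytest.mark.parametrize("frac,expected", [(0.0, 0), (1.0, 50), (0.6489, 32)])
def test_mask_membership_counts(frac, expected):
    spec = SceneSpec(
        channels=("tagged",),
        n_spots_per_channel={"tagged": 50},
        mask_plan=MaskPlan(engulfed_fraction=frac, channel="tagged"),
        noise_sd=0.0,
        seed=21,
    )
    _, truth = make_mask_scene(spec)
    member = truth.mask_membership["tagged"]
    assert member.sum() == expected
    # oracle: point-in-blob test over the ground-truth blob centers
    oracle = points_in_spheres(
        truth.centroids["tagged"],
        truth.mask_blob_centers_nm,
        truth.mask_blob_radius_nm,
    )
    assert np.array_equal(member, oracle)


def test_mask_plan_validation():
    with pytest.raises(ValueError):
        SceneSpec(mask_plan=MaskPlan(engulfed_fraction=1.2))


# --- flow events -----------------------------------------------------------


def test_flow_all_background():
    df = make_flow_events(500, 0.0, 0.0, 0.0, seed=1)
    assert (df["true_label"] == "neg").all()


def test_flow_planted_counts():
    df = make_flow_events(10_000, frac_Apos=0.1085, frac_Bpos=0.4238,
                          frac_double=0.1049, seed=2)
    labels = df["true_label"].value_counts()
    assert labels.get("double", 0) == 1049
    assert labels.get("double", 0) + labels.get("A_only", 0) == 1085
    assert labels.get("double", 0) + labels.get("B_only", 0) == 4238


def test_flow_determinism_and_validation():
    a = make_flow_events(1000, 0.2, 0.3, 0.1, seed=9)
    b = make_flow_events(1000, 0.2, 0.3, 0.1, seed=9)
    assert a.equals(b)
    with pytest.raises(ValueError):
        make_flow_events(100, 0.1, 0.2, 0.15, seed=0)


# --- fractionation tables --------------------------------------------------

MIX = np.array([[0.8, 0.15, 0.05], [0.1, 0.8, 0.1], [0.1, 0.05, 0.85]])


def test_fraction_table_identity_no_noise():
    df = make_fraction_tables({"np1": (3.0, 2.0, 1.0)}, np.eye(3), seed=0)
    sig = df[df.marker_or_protein == "np1"].set_index("fraction")["signal"]
    assert np.allclose(
        [sig["SPM"], sig["Cytoplasm"], sig["Mitochondria"]], [3.0, 2.0, 1.0]
    )


def test_fraction_table_matrix_vector_product():
    # matrix-vector oracle: MIX @ (10, 2, 1) = (8.35, 2.7, 1.95)
    df = make_fraction_tables({"np1": (10.0, 2.0, 1.0)}, MIX, seed=0)
    sig = df[df.marker_or_protein == "np1"].set_index("fraction")["signal"]
    assert np.allclose(
        [sig["SPM"], sig["Cytoplasm"], sig["Mitochondria"]], [8.35, 2.7, 1.95]
    )


def test_fraction_table_zero_levels_zero_signal():
    df = make_fraction_tables({"p": (0.0, 0.0, 0.0)}, MIX, noise_cv=0.1, seed=4)
    assert (df[df.marker_or_protein == "p"]["signal"] == 0).all()


def test_fraction_table_rejects_negative_levels():
    with pytest.raises(ValueError):
        make_fraction_tables({"p": (-1.0, 0.0, 0.0)}, MIX)
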