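import math

import numpy as np
import pytest

from platefit import (
    ControlPairSet,
    GeometryError,
    ParameterError,
    PointCloud,
    SelectionError,
    TriangleMesh,
    apply_tps,
    bending_energy,
    curvature_scores,
    fit_tps,
    projection_prefit,
    select_control_points,
    tps_kernel,
)
from platefit.tps import TPSModel


def random_pairs(n=40, seed=0, scale=10.0):
    rng = np.random.default_rng(seed)
    src = rng.uniform(-scale, scale, size=(n, 3))
    tgt = src + rng.normal(0, 1.0, size=(n, 3))
    return ControlPairSet(src, tgt)


def test_kernel_values_and_errors():
    assert tps_kernel(0.0) == 0.0
    assert tps_kernel(1.0) == 0.0
    assert tps_kernel(math.e) == pytest.approx(math.e**2, rel=1e-12)
    assert tps_kernel(2.5, kernel="r") == 2.5
    with pytest.raises(ParameterError):
        tps_kernel(1.0, kernel="gauss")
    with pytest.raises(ParameterError):
        tps_kernel(-0.1)


def test_identity_fit_gives_identity_map():
    pairs = ControlPairSet(random_pairs(20, seed=1).source_points,
                           random_pairs(20, seed=1).source_points)
    model = fit_tps(pairs)
    assert np.abs(model.weights).max() <= 1e-10
    probe = np.random.default_rng(2).uniform(-5, 5, size=(50, 3))
    np.testing.assert_allclose(model(probe), probe, atol=1e-8)
    assert bending_energy(model) == pytest.approx(0.0, abs=1e-12)


def test_pure_translation_is_reproduced_by_affine_part():
    src = random_pairs(30, seed=3).source_points
    shift = np.array([1.0, 0.0, 0.0])
    model = fit_tps(ControlPairSet(src, src + shift))
    assert np.abs(model.weights).max() <= 1e-8
    probe = np.random.default_rng(4).uniform(-8, 8, size=(20, 3))
    np.testing.assert_allclose(model(probe), probe + shift, atol=1e-8)
    assert bending_energy(model) == pytest.approx(0.0, abs=1e-9)


def test_general_affine_map_yields_zero_weights():
    rng = np.random.default_rng(5)
    src = rng.uniform(-10, 10, size=(35, 3))
    amat = np.eye(3) + 0.1 * rng.normal(size=(3, 3))
    shift = rng.normal(size=3)
    model = fit_tps(ControlPairSet(src, src @ amat.T + shift))
    assert np.abs(model.weights).max() <= 1e-8
    probe = rng.uniform(-10, 10, size=(20, 3))
    np.testing.assert_allclose(model(probe), probe @ amat.T + shift, atol=1e-7)


def test_interpolation_exact_at_lambda_zero():
    pairs = random_pairs(40, seed=6)
    model = fit_tps(pairs, regularization=0.0)
    residual = np.linalg.norm(model(pairs.source_points) - pairs.target_points, axis=1)
    assert residual.max() < 1e-8


def test_side_conditions_hold():
    pairs = random_pairs(40, seed=7)
    model = fit_tps(pairs)
    assert np.abs(model.weights.sum(axis=0)).max() < 1e-8
    moments = model.control_points.T @ model.weights
    assert np.abs(moments).max() < 1e-8


def test_regularization_trades_accuracy_for_smoothness():
    pairs = random_pairs(40, seed=8)
    lambdas = [0.0, 0.1, 1.0]
    residuals, energies = [], []
    for lam in lambdas:
        model = fit_tps(pairs, regularization=lam)
        residuals.append(
            np.linalg.norm(model(pairs.source_points) - pairs.target_points, axis=1).max()
        )
        energies.append(bending_energy(model))
    assert residuals[0] <= residuals[1] + 1e-9 <= residuals[2] + 2e-9
    assert energies[0] + 1e-9 >= energies[1] >= energies[2] - 1e-9


def test_coincident_control_points_raise():
    src = np.random.default_rng(9).uniform(-5, 5, size=(10, 3))
    src[1] = src[0]  # coincident sources with different targets
    tgt = src + np.random.default_rng(10).normal(0, 1, size=src.shape)
    tgt[1] = tgt[0] + 5.0
    with pytest.raises(GeometryError):
        fit_tps(ControlPairSet(src, tgt))
    with pytest.raises(GeometryError):
        fit_tps(random_pairs(3, seed=11))  # too few pairs
    with pytest.raises(ParameterError):
        fit_tps(random_pairs(10, seed=12), regularization=-1.0)


def test_coplanar_sources_still_interpolate():
    # flat plates give exactly coplanar control sources; the minimum-norm
    # solve must still satisfy the interpolation conditions
    rng = np.random.default_rng(13)
    src = rng.uniform(-10, 10, size=(30, 3))
    src[:, 2] = 0.0
    tgt = src + rng.normal(0, 0.5, size=src.shape)
    model = fit_tps(ControlPairSet(src, tgt))
    residual = np.linalg.norm(model(src) - tgt, axis=1)
    assert residual.max() < 1e-8


def test_apply_tps_keeps_mesh_topology():
    verts = np.random.default_rng(14).uniform(-5, 5, size=(20, 3))
    faces = np.array([[0, 1, 2], [3, 4, 5], [6, 7, 8]])
    mesh = TriangleMesh(verts, faces)
    src = np.random.default_rng(15).uniform(-5, 5, size=(20, 3))
    model = fit_tps(ControlPairSet(src, src + [1.0, 0, 0]))
    warped = apply_tps(model, mesh)
    np.testing.assert_array_equal(warped.faces, mesh.faces)
    np.testing.assert_allclose(warped.vertices, mesh.vertices + [1.0, 0, 0], atol=1e-8)
    with pytest.raises(ParameterError):
        apply_tps(model, "not geometry")


def bump_scene(seed=0):
    """Bone = plane with one Gaussian bump; plate = plane hovering above."""
    rng = np.random.default_rng(seed)
    n = 3000
    bone = np.zeros((n, 3))
    bone[:, :2] = rng.uniform(-20, 20, size=(n, 2))
    sigma = 2.0
    r2 = bone[:, 0] ** 2 + bone[:, 1] ** 2
    bone[:, 2] = 4.0 * np.exp(-r2 / (2 * sigma**2))
    plate = np.zeros((800, 3))
    plate[:, :2] = rng.uniform(-20, 20, size=(800, 2))
    plate[:, 2] = 6.0
    return PointCloud(plate), curvature_scores(PointCloud(bone), k=20), sigma


def test_control_points_prefer_the_bump():
    plate, bone, sigma = bump_scene()
    pairs = select_control_points(
        plate, bone, n_points=30, min_spacing=0.0, max_pair_distance=np.inf
    )
    r = np.linalg.norm(pairs.target_points[:, :2], axis=1)
    assert np.mean(r <= 2 * sigma) >= 0.8


def test_control_point_selection_errors():
    plate, bone, _ = bump_scene(seed=1)
    with pytest.raises(ParameterError):
        select_control_points(plate, bone, n_points=10)  # outside [30, 50]
    with pytest.raises(SelectionError) as excinfo:
        select_control_points(
            plate, bone, n_points=30, min_spacing=1e4, max_pair_distance=np.inf
        )
    assert excinfo.value.achievable == 1


def test_pairs_and_model_serialization_round_trip(tmp_path):
    pairs = random_pairs(35, seed=16)
    csv = tmp_path / "pairs.csv"
    pairs.save_csv(csv)
    again = ControlPairSet.load_csv(csv)
    np.testing.assert_allclose(again.source_points, pairs.source_points, atol=1e-15)
    np.testing.assert_allclose(again.target_points, pairs.target_points, atol=1e-15)

    model = fit_tps(pairs)
    doc = tmp_path / "model.json"
    model.to_json(doc)
    loaded = TPSModel.from_json(doc)
    probe = np.random.default_rng(17).uniform(-5, 5, size=(10, 3))
    np.testing.assert_allclose(loaded(probe), model(probe), atol=1e-12)


def test_projection_prefit_blends_toward_bone():
    rng = np.random.default_rng(18)
    bone = PointCloud(rng.uniform(-5, 5, size=(500, 3)))
    plate = PointCloud(rng.uniform(-5, 5, size=(100, 3)) + [0, 0, 10.0])
    full = projection_prefit(plate, bone, alpha=1.0)
    from platefit import gap_cost

    assert gap_cost(full, bone) == pytest.approx(0.0, abs=1e-12)
    half = projection_prefit(plate, bone, alpha=0.5)
    assert gap_cost(half, bone) < gap_cost(plate, bone)
    with pytest.raises(ParameterError):
        projection_prefit(plate, bone, alpha=1.5)
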