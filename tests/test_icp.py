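import math

import numpy as np
import pytest

from platefit import (
    GeometryError,
    ParameterError,
    PointCloud,
    RigidTransform,
    best_rigid_transform,
    nearest_correspondences,
    run_icp,
)
from tests.conftest import random_rigid, rotation_matrix


def brute_force_pairing(src, tgt):
    d = np.linalg.norm(src[:, None, :] - tgt[None, :, :], axis=2)
    idx = d.argmin(axis=1)
    return idx, d[np.arange(len(src)), idx]


def test_correspondences_trivial_cases():
    pts = np.random.default_rng(0).normal(size=(50, 3))
    idx, dist = nearest_correspondences(pts, pts)
    np.testing.assert_array_equal(idx, np.arange(50))
    np.testing.assert_allclose(dist, 0.0)

    idx, dist = nearest_correspondences(
        np.array([[0.0, 0, 0]]), np.array([[1.0, 0, 0], [0, 2.0, 0]])
    )
    assert idx[0] == 0 and dist[0] == pytest.approx(1.0)

    with pytest.raises(ParameterError):
        nearest_correspondences(np.zeros((0, 3)), pts)


def test_correspondences_match_brute_force():
    rng = np.random.default_rng(1)
    src = rng.uniform(-10, 10, size=(500, 3))
    tgt = rng.uniform(-10, 10, size=(500, 3))
    idx, dist = nearest_correspondences(src, tgt)
    bf_idx, bf_dist = brute_force_pairing(src, tgt)
    np.testing.assert_array_equal(idx, bf_idx)
    np.testing.assert_array_equal(dist, bf_dist)


def test_best_rigid_transform_identity_and_known_motion():
    pts = np.eye(3)
    ident = best_rigid_transform(pts, pts)
    np.testing.assert_allclose(ident.rotation, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(ident.translation, 0.0, atol=1e-12)

    rot = rotation_matrix([0, 0, 1.0], math.pi / 2)
    shift = np.array([1.0, 2.0, 3.0])
    moved = pts @ rot.T + shift
    recovered = best_rigid_transform(pts, moved)
    np.testing.assert_allclose(recovered.rotation, rot, atol=1e-12)
    np.testing.assert_allclose(recovered.translation, shift, atol=1e-12)
    np.testing.assert_allclose(recovered.apply(pts), moved, atol=1e-12)


def test_best_rigid_transform_recovers_random_motions():
    rng = np.random.default_rng(2)
    for _ in range(100):
        pts = rng.normal(size=(100, 3))
        truth = random_rigid(rng)
        moved = truth.apply(pts)
        est = best_rigid_transform(pts, moved)
        assert np.abs(est.rotation - truth.rotation).max() < 1e-10
        assert np.abs(est.translation - truth.translation).max() < 1e-10


def test_best_rigid_transform_degenerate_inputs():
    line = np.outer(np.arange(5.0), [1.0, 0, 0])
    with pytest.raises(GeometryError):
        best_rigid_transform(line, line + 1.0)
    with pytest.raises(GeometryError):
        best_rigid_transform(np.zeros((2, 3)), np.zeros((2, 3)))
    with pytest.raises(ParameterError):
        best_rigid_transform(np.zeros((4, 3)), np.zeros((5, 3)))


def test_icp_recovers_small_displacement_exactly():
    rng = np.random.default_rng(3)
    target = rng.uniform(-50, 50, size=(2000, 3))
    truth = RigidTransform(
        rotation_matrix([0.2, 1.0, 0.1], math.radians(5.0)), [2.0, 0.5, -1.0]
    )
    source = truth.apply(target)  # displaced copy; recovery target = inverse
    result = run_icp(PointCloud(source), PointCloud(target))
    assert result.converged
    assert result.final_mse < 1e-10
    err = result.transform.compose(truth)
    assert err.rotation_angle() < 1e-6
    assert np.linalg.norm(err.translation) < 1e-6


def test_icp_identical_clouds_stop_at_min_iterations():
    pts = np.random.default_rng(4).normal(size=(300, 3))
    result = run_icp(PointCloud(pts), PointCloud(pts), min_iterations=20)
    assert result.converged
    assert result.iterations == 20
    assert all(m == 0.0 for m in result.mse_trace)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_icp_trace_is_monotone_on_noisy_clouds(seed):
    rng = np.random.default_rng(seed)
    target = rng.uniform(-20, 20, size=(800, 3))
    source = random_rigid(rng, max_angle_rad=0.5, max_shift=5.0).apply(target)
    source = source + rng.normal(0, 0.5, size=source.shape)
    result = run_icp(PointCloud(source), PointCloud(target))
    trace = result.mse_trace
    assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))
    assert result.iterations == len(trace)


def test_icp_rejects_invalid_init_and_parameters():
    pts = np.random.default_rng(5).normal(size=(50, 3))
    bad = RigidTransform(np.eye(3) * 2.0, np.zeros(3))
    with pytest.raises(ParameterError):
        run_icp(PointCloud(pts), PointCloud(pts), init=bad)
    with pytest.raises(ParameterError):
        run_icp(PointCloud(pts), PointCloud(pts), min_iterations=0)


def test_rigid_transform_io_round_trip(tmp_path):
    truth = random_rigid(np.random.default_rng(6))
    path = tmp_path / "t.txt"
    truth.save(path)
    again = RigidTransform.load(path)
    np.testing.assert_allclose(again.rotation, truth.rotation, atol=1e-15)
    np.testing.assert_allclose(again.translation, truth.translation, atol=1e-15)
    inv = truth.compose(truth.inverse())
    assert inv.rotation_angle() < 1e-12


def test_icp_trace_csv_export(tmp_path):
    pts = np.random.default_rng(7).normal(size=(100, 3))
    result = run_icp(PointCloud(pts + 0.1), PointCloud(pts))
    out = tmp_path / "trace.csv"
    result.save_trace(out)
    lines = out.read_text().strip().splitlines()
    assert lines[0] == "iteration,mse_mm2"
    assert len(lines) == result.iterations + 1
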