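import math

import numpy as np
import pytest
from scipy import stats

from platefit import (
    GeometryError,
    ParameterError,
    PointCloud,
    TriangleMesh,
    curvature_scores,
    estimate_normals,
    sample_surface,
)
from tests.conftest import rotation_matrix


def two_triangle_mesh():
    """Two coplanar triangles with areas 1 and 3."""
    verts = np.array(
        [
            [0, 0, 0], [2, 0, 0], [0, 1, 0],      # area 1
            [10, 0, 0], [16, 0, 0], [10, 1, 0],   # area 3
        ],
        dtype=float,
    )
    return TriangleMesh(verts, np.array([[0, 1, 2], [3, 4, 5]]))


def plane_cloud(n=200, side=10.0, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.zeros((n, 3))
    pts[:, :2] = rng.uniform(-side, side, size=(n, 2))
    return PointCloud(pts)


def sphere_cloud(radius, n=2000):
    from tests.conftest import fibonacci_sphere

    return PointCloud(fibonacci_sphere(n, radius))


def test_sampling_is_area_uniform_across_faces():
    mesh = two_triangle_mesh()
    cloud = sample_surface(mesh, 40_000, seed=42)
    on_small = np.count_nonzero(cloud.points[:, 0] < 5.0)
    counts = [on_small, 40_000 - on_small]
    result = stats.chisquare(counts, f_exp=[10_000, 30_000])
    assert result.pvalue > 0.01


def test_sampling_is_deterministic_and_validates():
    mesh = two_triangle_mesh()
    a = sample_surface(mesh, 500, seed=7)
    b = sample_surface(mesh, 500, seed=7)
    np.testing.assert_array_equal(a.points, b.points)
    with pytest.raises(ParameterError):
        sample_surface(mesh, 0)
    degenerate = TriangleMesh(np.zeros((3, 3)), np.array([[0, 1, 2]]))
    with pytest.raises(GeometryError):
        sample_surface(degenerate, 10)


def test_plane_normals_are_vertical_and_consistent():
    cloud = estimate_normals(plane_cloud(), k=12)
    assert np.allclose(np.linalg.norm(cloud.normals, axis=1), 1.0, atol=1e-6)
    # all normals agree in sign and are +/-(0,0,1)
    assert np.allclose(np.abs(cloud.normals[:, 2]), 1.0, atol=1e-6)
    assert np.all(cloud.normals[:, 2] > 0) or np.all(cloud.normals[:, 2] < 0)


def test_sphere_normals_are_radial_within_2_degrees():
    cloud = sphere_cloud(radius=10.0)
    oriented = estimate_normals(cloud, k=20, orient_reference=np.zeros(3))
    radial = cloud.points / np.linalg.norm(cloud.points, axis=1, keepdims=True)
    cos = np.einsum("ij,ij->i", oriented.normals, radial)
    angles = np.degrees(np.arccos(np.clip(cos, -1, 1)))
    assert angles.max() < 2.0


def test_normal_estimation_is_rotation_equivariant():
    cloud = sphere_cloud(radius=5.0, n=600)
    rot = rotation_matrix([1.0, 2.0, 0.5], 1.1)
    base = estimate_normals(cloud, k=15, orient_reference=np.zeros(3))
    rotated = estimate_normals(
        PointCloud(cloud.points @ rot.T), k=15, orient_reference=np.zeros(3)
    )
    # up to sign, rotating the cloud rotates the normals
    dots = np.abs(np.einsum("ij,ij->i", rotated.normals, base.normals @ rot.T))
    assert np.all(dots > 1 - 1e-6)


def test_normals_parameter_validation():
    tiny = PointCloud(np.zeros((2, 3)))
    with pytest.raises(ParameterError):
        estimate_normals(tiny, k=3)
    with pytest.raises(ParameterError):
        estimate_normals(plane_cloud(), k=2)


def test_curvature_flat_plane_is_zero():
    scored = curvature_scores(plane_cloud(n=400), k=12)
    assert scored.curvature.max() < 1e-6
    assert scored.curvature.min() >= 0.0


def test_curvature_concentrates_on_a_bump():
    rng = np.random.default_rng(11)
    n = 4000
    pts = np.zeros((n, 3))
    pts[:, :2] = rng.uniform(-10, 10, size=(n, 2))
    sigma = 2.5
    r2 = pts[:, 0] ** 2 + pts[:, 1] ** 2
    pts[:, 2] = 4.0 * np.exp(-r2 / (2 * sigma**2))
    scored = curvature_scores(PointCloud(pts), k=20)
    top = np.argsort(scored.curvature)[-n // 10 :]
    dist_to_centre = np.sqrt(r2[top])
    assert np.mean(dist_to_centre <= 2 * sigma) >= 0.8


def test_curvature_scales_inversely_with_sphere_radius():
    # same k and same point density (points per unit area): the tighter
    # sphere is more curved, so its surface-variation scores are larger
    density = 4.0  # points per mm^2
    small = curvature_scores(
        sphere_cloud(2.0, n=int(density * 4 * math.pi * 2.0**2)), k=20
    )
    large = curvature_scores(
        sphere_cloud(20.0, n=int(density * 4 * math.pi * 20.0**2)), k=20
    )
    assert small.curvature.mean() > large.curvature.mean()


def test_curvature_is_rigid_invariant():
    cloud = sphere_cloud(4.0, n=800)
    rot = rotation_matrix([0.3, 1.0, 0.2], 0.7)
    moved = PointCloud(cloud.points @ rot.T + np.array([5.0, -2.0, 1.0]))
    a = curvature_scores(cloud, k=15).curvature
    b = curvature_scores(moved, k=15).curvature
    np.testing.assert_allclose(a, b, atol=1e-9)
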