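import math

import numpy as np
import pytest
import trimesh

from platefit import (
    BoneSpec,
    PlateSpec,
    RigidTransform,
    TriangleMesh,
    make_displaced_pair,
)


def rotation_matrix(axis, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation about ``axis`` (need not be unit length)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle_rad) * k + (1 - math.cos(angle_rad)) * k @ k


def random_rigid(rng, max_angle_rad=math.pi, max_shift=10.0) -> RigidTransform:
    axis = rng.normal(size=3)
    angle = rng.uniform(-max_angle_rad, max_angle_rad)
    shift = rng.uniform(-max_shift, max_shift, size=3)
    return RigidTransform(rotation_matrix(axis, angle), shift)


def fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """Near-uniform sphere lattice (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return radius * np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def point_triangle_distances(points: np.ndarray, mesh: TriangleMesh) -> np.ndarray:
    """Exact distance of each point to the mesh surface, brute force.

    Closed-form point-triangle distance evaluated against every face;
    the independent oracle for decimation fidelity checks.
    """
    tri = mesh.vertices[mesh.faces]
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac = b - a, c - a
    out = np.empty(len(points))
    for i, p in enumerate(points):
        ap = p - a
        d1 = np.einsum("ij,ij->i", ab, ap)
        d2 = np.einsum("ij,ij->i", ac, ap)
        bp = p - b
        d3 = np.einsum("ij,ij->i", ab, bp)
        d4 = np.einsum("ij,ij->i", ac, bp)
        cp = p - c
        d5 = np.einsum("ij,ij->i", ab, cp)
        d6 = np.einsum("ij,ij->i", ac, cp)
        va = d3 * d6 - d5 * d4
        vb = d5 * d2 - d1 * d6
        vc = d1 * d4 - d3 * d2
        denom = va + vb + vc
        v = np.where(denom != 0, vb / np.where(denom != 0, denom, 1.0), 0.0)
        w = np.where(denom != 0, vc / np.where(denom != 0, denom, 1.0), 0.0)
        closest = a + v[:, None] * ab + w[:, None] * ac
        # clamp to the triangle: handle vertex/edge regions explicitly
        region_a = (d1 <= 0) & (d2 <= 0)
        region_b = (d3 >= 0) & (d4 <= d3)
        region_c = (d6 >= 0) & (d5 <= d6)
        edge_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
        edge_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
        edge_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
        t_ab = np.clip(d1 / np.where(d1 - d3 != 0, d1 - d3, 1.0), 0, 1)
        t_ac = np.clip(d2 / np.where(d2 - d6 != 0, d2 - d6, 1.0), 0, 1)
        num_bc = d4 - d3
        den_bc = (d4 - d3) + (d5 - d6)
        t_bc = np.clip(num_bc / np.where(den_bc != 0, den_bc, 1.0), 0, 1)
        closest = np.where(edge_bc[:, None], b + t_bc[:, None] * (c - b), closest)
        closest = np.where(edge_ac[:, None], a + t_ac[:, None] * ac, closest)
        closest = np.where(edge_ab[:, None], a + t_ab[:, None] * ab, closest)
        closest = np.where(region_c[:, None], c, closest)
        closest = np.where(region_b[:, None], b, closest)
        closest = np.where(region_a[:, None], a, closest)
        out[i] = np.sqrt(((p - closest) ** 2).sum(axis=1).min())
    return out


@pytest.fixture
def cube_mesh() -> TriangleMesh:
    """Unit cube as raw triangle soup: 36 vertex records, 12 faces."""
    box = trimesh.creation.box((1.0, 1.0, 1.0))
    soup = box.vertices[box.faces].reshape(-1, 3)
    faces = np.arange(36).reshape(-1, 3)
    return TriangleMesh(soup, faces, name="cube")


@pytest.fixture
def icosphere_mesh() -> TriangleMesh:
    sphere = trimesh.creation.icosphere(subdivisions=3, radius=10.0)  # 1280 faces
    return TriangleMesh(np.asarray(sphere.vertices), np.asarray(sphere.faces))


SMALL_BONE = dict(resolution=1500)
SMALL_PLATE = dict(resolution=600)


@pytest.fixture(scope="session")
def displaced_pair():
    """Bowed bone + flat plate displaced by a small known rigid motion."""
    truth = RigidTransform(
        rotation_matrix([0.0, 1.0, 0.0], math.radians(5.0)), [2.0, 1.0, 0.0]
    )
    bone, plate, truth = make_displaced_pair(
        BoneSpec(**SMALL_BONE), PlateSpec(**SMALL_PLATE), truth
    )
    return bone, plate, truth
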