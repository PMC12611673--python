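"""Parametric bone-like and plate-like test geometry with known ground truth.

Real CT-derived femur models cannot ship with the package, so every
pipeline stage is exercised on synthetic stand-ins: a long bone is
modeled as a watertight tube swept along a bowed (circular-arc) axis
with optional condylar bumps near one end and Gaussian radial surface
noise; a plate is a rectangular strip, optionally cylindrically pre-bent,
with annular vertex rings marking screw-hole stations. The bone model is
deliberately a controllable idealization — its curvature, bow and noise
are exactly the features rigid and non-rigid registration must cope
with — not an anatomical atlas.

Default dimensions loosely follow a large-animal femur shaft
(length 300 mm, shaft radius 15 mm); they are conventions of this
package, chosen to keep millimetre-scale tolerances meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

from .errors import GeometryError, ParameterError
from .icp import RigidTransform
from .mesh_io import TriangleMesh

__all__ = [
    "BoneSpec",
    "PlateSpec",
    "make_bone",
    "make_plate",
    "make_displaced_pair",
    "canonical_plate_pose",
]


@dataclass
class BoneSpec:
    """Parameters of the synthetic long bone (all lengths in mm)."""

    length: float = 300.0
    shaft_radius: float = 15.0
    bow_sagitta: float = 8.0  # max lateral deviation of the curved shaft axis
    condyle_radius: float = 25.0
    condyle_count: int = 2
    noise_sd: float = 0.0
    resolution: int = 4000  # approximate face count
    seed: int = 0

    def validate(self) -> None:
        if self.length <= 0 or self.shaft_radius <= 0:
            raise ParameterError("length and shaft_radius must be positive")
        if self.bow_sagitta < 0 or self.noise_sd < 0:
            raise ParameterError("bow_sagitta and noise_sd must be >= 0")
        if self.condyle_count < 0:
            raise ParameterError("condyle_count must be >= 0")
        if self.condyle_count and self.condyle_radius <= 0:
            raise ParameterError("condyle_radius must be positive")
        if self.condyle_count and self.condyle_radius > self.length / 2:
            raise ParameterError(
                f"condyle_radius {self.condyle_radius} exceeds half the bone "
                f"length {self.length / 2}"
            )
        if self.resolution < 100:
            raise ParameterError("resolution must be >= 100 faces")


@dataclass
class PlateSpec:
    """Parameters of the synthetic osteosynthesis plate (mm)."""

    length: float = 100.0
    width: float = 20.0
    arc_radius: float = math.inf  # pre-bend radius; inf = flat strip
    hole_positions: list = field(default_factory=lambda: [15.0, 50.0, 85.0])
    hole_radius: float | None = None  # default width / 5
    resolution: int = 1500

    def validate(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ParameterError("plate length and width must be positive")
        if self.arc_radius <= 0:
            raise ParameterError("arc_radius must be positive (inf for flat)")
        if math.isfinite(self.arc_radius) and self.width > 2 * self.arc_radius:
            raise ParameterError(
                f"width {self.width} exceeds twice the bend radius {self.arc_radius}"
            )
        for h in self.hole_positions:
            if not 0 <= h <= self.length:
                raise ParameterError(f"hole position {h} outside [0, {self.length}]")
        if self.resolution < 50:
            raise ParameterError("resolution must be >= 50 faces")


def _axis_curve(spec: BoneSpec, t: np.ndarray):
    """Bowed axis: points, unit tangents, and in-plane outward normals.

    The axis is a circular arc in the x-z plane through (0,0,0) and
    (0,0,L) bulging to x = bow_sagitta at mid-length; a straight segment
    when the sagitta is zero.
    """
    length, sag = spec.length, spec.bow_sagitta
    t = np.asarray(t, dtype=float)
    if sag == 0:
        pts = np.column_stack([np.zeros_like(t), np.zeros_like(t), t * length])
        tan = np.tile([0.0, 0.0, 1.0], (len(t), 1))
        nrm = np.tile([1.0, 0.0, 0.0], (len(t), 1))
        return pts, tan, nrm
    radius = (sag**2 + (length / 2) ** 2) / (2 * sag)
    center = np.array([sag - radius, 0.0, length / 2])
    half_angle = math.asin((length / 2) / radius)
    ang = (2 * t - 1) * half_angle  # angle from the mid-arc direction (+x)
    pts = center + radius * np.column_stack(
        [np.cos(ang), np.zeros_like(ang), np.sin(ang)]
    )
    tan = np.column_stack([-np.sin(ang), np.zeros_like(ang), np.cos(ang)])
    nrm = np.column_stack([np.cos(ang), np.zeros_like(ang), np.sin(ang)])
    return pts, tan, nrm


def make_bone(spec: BoneSpec) -> TriangleMesh:
    """Build a watertight bowed tube with condylar bumps and end caps."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    circumference = 2 * math.pi * spec.shaft_radius
    # roughly isotropic triangles: rows/cols follow the surface aspect ratio
    n_circ = max(12, int(round(math.sqrt(spec.resolution / 2 * circumference / spec.length))))
    n_axial = max(8, int(round(spec.resolution / (2 * n_circ))) + 1)

    t = np.linspace(0.0, 1.0, n_axial)
    axis_pts, tangents, normals = _axis_curve(spec, t)
    binormal = np.array([0.0, 1.0, 0.0])
    theta = np.linspace(0.0, 2 * math.pi, n_circ, endpoint=False)

    # radial offsets: condylar bumps + Gaussian noise, on the unrolled surface
    arclen = t * _arc_length(spec)
    radius = np.full((n_axial, n_circ), spec.shaft_radius)
    if spec.condyle_count:
        sigma = spec.condyle_radius / 2.0
        z_c = arclen[-1] - spec.condyle_radius
        for j in range(spec.condyle_count):
            theta_c = 2 * math.pi * j / spec.condyle_count + math.pi / spec.condyle_count
            d_theta = np.angle(np.exp(1j * (theta[None, :] - theta_c)))
            d2 = (arclen[:, None] - z_c) ** 2 + (spec.shaft_radius * d_theta) ** 2
            radius += 0.6 * spec.condyle_radius * np.exp(-d2 / (2 * sigma**2))
    if spec.noise_sd > 0:
        radius += rng.normal(0.0, spec.noise_sd, size=radius.shape)

    cos_t, sin_t = np.cos(theta), np.sin(theta)
    ring_dirs = (
        normals[:, None, :] * cos_t[None, :, None]
        + binormal[None, None, :] * sin_t[None, :, None]
    )
    vertices = axis_pts[:, None, :] + radius[:, :, None] * ring_dirs
    vertices = vertices.reshape(-1, 3)

    faces = []
    for i in range(n_axial - 1):
        for j in range(n_circ):
            a = i * n_circ + j
            b = i * n_circ + (j + 1) % n_circ
            c = (i + 1) * n_circ + j
            d = (i + 1) * n_circ + (j + 1) % n_circ
            faces.append((a, b, d))
            faces.append((a, d, c))
    # end caps: triangle fans to on-axis pole vertices
    pole0 = len(vertices)
    pole1 = pole0 + 1
    vertices = np.vstack([vertices, axis_pts[0], axis_pts[-1]])
    for j in range(n_circ):
        faces.append((pole0, (j + 1) % n_circ, j))
        base = (n_axial - 1) * n_circ
        faces.append((pole1, base + j, base + (j + 1) % n_circ))
    return TriangleMesh(vertices, np.asarray(faces), name="synthetic_bone")


def _arc_length(spec: BoneSpec) -> float:
    if spec.bow_sagitta == 0:
        return spec.length
    radius = (spec.bow_sagitta**2 + (spec.length / 2) ** 2) / (2 * spec.bow_sagitta)
    return 2 * radius * math.asin((spec.length / 2) / radius)


def make_plate(spec: PlateSpec) -> TriangleMesh:
    """Build a (possibly pre-bent) plate strip with hole markings.

    The strip is triangulated from a 2D parameter grid plus annular
    vertex rings at each screw-hole station (markings, not cut-outs),
    then bent so the across-width coordinate becomes arc length on a
    cylinder of radius ``arc_radius``. In the local frame the plate runs
    along z (centred), spans y across its width, and bends toward -x, so
    its concave face looks at the local -x half-space where the bone is
    posed.
    """
    spec.validate()
    hole_radius = spec.hole_radius if spec.hole_radius is not None else spec.width / 5
    aspect = spec.length / spec.width
    n_len = max(8, int(round(math.sqrt(spec.resolution / 2 * aspect))) + 1)
    n_wid = max(4, int(round(n_len / aspect)) + 1)

    uu = np.linspace(0.0, spec.length, n_len)
    vv = np.linspace(-spec.width / 2, spec.width / 2, n_wid)
    grid = np.array([(u, v) for u in uu for v in vv])
    ring_pts = []
    ring_angles = np.linspace(0.0, 2 * math.pi, 16, endpoint=False)
    for h in spec.hole_positions:
        ring = np.column_stack(
            [h + hole_radius * np.cos(ring_angles), hole_radius * np.sin(ring_angles)]
        )
        ring[:, 1] = np.clip(ring[:, 1], -spec.width / 2, spec.width / 2)
        ring_pts.append(ring)
    params = np.vstack([grid] + ring_pts) if ring_pts else grid
    # drop near-duplicate parameter points so Delaunay stays well posed
    _, keep = np.unique(np.round(params / 1e-9).astype(np.int64), axis=0, return_index=True)
    params = params[np.sort(keep)]
    tri = Delaunay(params)

    u = params[:, 0] - spec.length / 2  # centre along the length axis
    v = params[:, 1]
    if math.isfinite(spec.arc_radius):
        ang = v / spec.arc_radius
        x = spec.arc_radius * (np.cos(ang) - 1.0)
        y = spec.arc_radius * np.sin(ang)
    else:
        x = np.zeros_like(v)
        y = v
    vertices = np.column_stack([x, y, u])
    return TriangleMesh(vertices, tri.simplices, name="synthetic_plate")


def canonical_plate_pose(bone_spec: BoneSpec, clearance: float | None = None) -> RigidTransform:
    """Rigid pose placing a plate tangent to the bone shaft mid-section.

    The plate's local -x face is turned toward the bone axis and its
    mid-line rests ``clearance`` mm above the shaft surface on the
    convex (bowed) side. The default clearance (0.5 mm plus three noise
    standard deviations) keeps the canonical pose penetration-free.
    """
    if clearance is None:
        clearance = 0.5 + 3.0 * bone_spec.noise_sd
    pts, tans, nrms = _axis_curve(bone_spec, np.array([0.5]))
    mid, tangent, outward = pts[0], tans[0], nrms[0]
    binormal = np.cross(tangent, outward)
    stand_off = bone_spec.shaft_radius + clearance
    rotation = np.column_stack([outward, binormal, tangent])
    translation = mid + stand_off * outward
    return RigidTransform(rotation, translation)


def make_displaced_pair(
    bone_spec: BoneSpec,
    plate_spec: PlateSpec,
    true_transform: RigidTransform | None = None,
    seed: int | None = None,
) -> tuple[TriangleMesh, TriangleMesh, RigidTransform]:
    """Bone mesh plus a plate first posed canonically, then displaced.

    The plate is placed tangent to the bone shaft mid-section (the
    canonical pose) and then moved by ``true_transform``; the inverse of
    that motion is the ground truth a rigid registration should recover.
    """
    if seed is not None:
        bone_spec = BoneSpec(**{**bone_spec.__dict__, "seed": seed})
    if true_transform is None:
        true_transform = RigidTransform.identity()
    true_transform.validate()
    bone = make_bone(bone_spec)
    plate = make_plate(plate_spec)
    pose = canonical_plate_pose(bone_spec)
    placed = TriangleMesh(pose.apply(plate.vertices), plate.faces, plate.name)
    displaced = TriangleMesh(
        true_transform.apply(placed.vertices), placed.faces, plate.name
    )
    return bone, displaced, true_transform
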