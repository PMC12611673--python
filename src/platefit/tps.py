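"""Thin-plate-spline (TPS) warping of the plate onto the bone surface.

The deformation field is, per output coordinate,

    f(x) = a1 + a2*x + a3*y + a4*z + sum_i w_i * U(||x - x_i||)

with radial basis U(r) = r^2 ln r (the value 0 is taken at r = 0, its
continuous limit) and control points x_i on the plate mapped to matched
targets on the bone. The three output coordinates share the kernel
matrix and control points; fitting is a single stacked linear solve

    [[K + lambda*I, P], [P^T, 0]] [w; a] = [targets; 0]

whose side conditions (sum of weights zero, first moments zero) remove
the affine component from the radial part. With lambda = 0 the map
interpolates the control pairs exactly; lambda > 0 trades control-point
accuracy for smoothness, damping the over-deformation that an exactly
interpolating spline can exhibit between sparse landmarks.

Control points are picked automatically on the bone at locations of high
local curvature (ridges and depressions, ranked by the surface-variation
score) subject to a minimum spacing, then paired with their nearest
plate points; a manual pair list can be supplied instead.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import GeometryError, ParameterError, SelectionError
from .mesh_io import TriangleMesh
from .pointcloud import PointCloud, curvature_scores

__all__ = [
    "TPSModel",
    "ControlPairSet",
    "tps_kernel",
    "select_control_points",
    "fit_tps",
    "apply_tps",
    "bending_energy",
    "projection_prefit",
]

KERNELS = ("r2logr", "r")
DEFAULT_N_CONTROL = 40  # middle of the 30-50 policy band
CONTROL_BOUNDS = (30, 50)


def tps_kernel(r, kernel: str = "r2logr"):
    """Radial basis U(r); vectorized over ``r >= 0``.

    ``"r2logr"`` is r^2 ln r with U(0) = 0; ``"r"`` is the classical 3D
    biharmonic spline, offered for comparison.
    """
    if kernel not in KERNELS:
        raise ParameterError(f"unknown kernel {kernel!r}; choose from {KERNELS}")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ParameterError("r must be >= 0")
    if kernel == "r":
        return r if r.ndim else float(r)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(r > 0, r * r * np.log(np.where(r > 0, r, 1.0)), 0.0)
    return out if out.ndim else float(out)


@dataclass
class ControlPairSet:
    """Matched control points: ``source_points`` on the plate,
    ``target_points`` on the bone."""

    source_points: np.ndarray
    target_points: np.ndarray

    def __post_init__(self) -> None:
        self.source_points = np.ascontiguousarray(self.source_points, dtype=float).reshape(-1, 3)
        self.target_points = np.ascontiguousarray(self.target_points, dtype=float).reshape(-1, 3)
        if len(self.source_points) != len(self.target_points):
            raise ParameterError("source and target control lists differ in length")

    def __len__(self) -> int:
        return len(self.source_points)

    def save_csv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as handle:
            handle.write("sx,sy,sz,tx,ty,tz\n")
            for s, t in zip(self.source_points, self.target_points):
                handle.write(",".join(repr(float(v)) for v in (*s, *t)) + "\n")

    @classmethod
    def load_csv(cls, path: str | os.PathLike) -> "ControlPairSet":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        if data.shape[1] != 6:
            raise ParameterError(f"{path}: expected 6 columns (sx..tz)")
        return cls(data[:, :3], data[:, 3:])


@dataclass
class TPSModel:
    """Fitted TPS deformation field.

    ``affine`` is (4, 3): row 0 the constant a1, rows 1..3 the linear
    coefficients a2..a4, one column per output coordinate. ``weights``
    is (N, 3): RBF weights per control point per output coordinate.
    """

    control_points: np.ndarray
    affine: np.ndarray
    weights: np.ndarray
    kernel: str = "r2logr"
    regularization: float = 0.0

    def __post_init__(self) -> None:
        self.control_points = np.ascontiguousarray(self.control_points, dtype=float).reshape(-1, 3)
        self.affine = np.ascontiguousarray(self.affine, dtype=float).reshape(4, 3)
        self.weights = np.ascontiguousarray(self.weights, dtype=float).reshape(len(self.control_points), 3)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        dist = np.linalg.norm(pts[:, None, :] - self.control_points[None, :, :], axis=2)
        basis = tps_kernel(dist, self.kernel)
        return self.affine[0] + pts @ self.affine[1:] + basis @ self.weights

    def to_json(self, path: str | os.PathLike) -> None:
        doc = {
            "kernel": self.kernel,
            "regularization": self.regularization,
            "control_points": self.control_points.tolist(),
            "affine": self.affine.tolist(),
            "weights": self.weights.tolist(),
        }
        with open(path, "w") as handle:
            json.dump(doc, handle, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "TPSModel":
        with open(path) as handle:
            doc = json.load(handle)
        return cls(
            np.asarray(doc["control_points"]),
            np.asarray(doc["affine"]),
            np.asarray(doc["weights"]),
            kernel=doc["kernel"],
            regularization=float(doc["regularization"]),
        )


def select_control_points(
    plate: PointCloud,
    bone: PointCloud,
    n_points: int = DEFAULT_N_CONTROL,
    curvature_k: int = 30,
    min_spacing: float | None = None,
    max_pair_distance: float | None = None,
    bounds: tuple[int, int] = CONTROL_BOUNDS,
    seed: int = 0,
) -> ControlPairSet:
    """Pick high-curvature bone landmarks and pair them with plate points.

    Bone points are ranked by curvature score (computed with
    ``curvature_k`` neighbors when absent) and accepted greedily subject
    to a pairwise spacing of at least ``min_spacing`` (default 2% of the
    bone bounding-box diagonal), which keeps the TPS kernel matrix well
    conditioned. Only bone points within ``max_pair_distance`` of the
    plate are eligible (default: twice the 95th percentile of the
    plate-to-bone nearest distances), so the landmarks lie in the
    plate's contact strip rather than on remote anatomy. Each selected
    bone point is then paired with its nearest plate point — source on
    the plate, target on the bone — and a candidate whose plate point
    falls within a quarter of ``min_spacing`` of an already-used source
    is skipped, so the source set stays distinct and well separated.

    Deterministic: ties in the curvature ranking are broken by point
    index; ``seed`` is accepted for interface symmetry with the sampling
    stage.
    """
    lo, hi = bounds
    if not (lo <= n_points <= hi):
        raise ParameterError(f"n_points must lie in [{lo}, {hi}], got {n_points}")
    if len(plate) == 0 or len(bone) == 0:
        raise ParameterError("plate and bone clouds must be non-empty")
    if bone.curvature is None:
        bone = curvature_scores(bone, k=curvature_k)
    if min_spacing is None:
        diag = np.linalg.norm(bone.points.max(axis=0) - bone.points.min(axis=0))
        min_spacing = 0.02 * diag
    plate_tree = cKDTree(plate.points)
    if max_pair_distance is None:
        gaps_to_bone, _ = cKDTree(bone.points).query(plate.points, k=1)
        max_pair_distance = 2.0 * float(np.percentile(gaps_to_bone, 95))

    gap, nearest_plate = plate_tree.query(bone.points, k=1)
    eligible = np.flatnonzero(gap <= max_pair_distance)
    if len(eligible) == 0:
        raise SelectionError(
            "no bone points within max_pair_distance of the plate", achievable=0
        )

    order = eligible[np.lexsort((eligible, -bone.curvature[eligible]))]
    source_spacing = 0.25 * min_spacing
    chosen: list[int] = []
    for idx in order:
        pt = bone.points[idx]
        src = plate.points[nearest_plate[idx]]
        if all(
            np.linalg.norm(pt - bone.points[c]) >= min_spacing
            and np.linalg.norm(src - plate.points[nearest_plate[c]]) >= source_spacing
            for c in chosen
        ):
            chosen.append(int(idx))
            if len(chosen) == n_points:
                break
    if len(chosen) < n_points:
        raise SelectionError(
            f"only {len(chosen)} control points admissible under "
            f"min_spacing={min_spacing:.3g} mm (requested {n_points})",
            achievable=len(chosen),
        )
    chosen_arr = np.asarray(chosen)
    return ControlPairSet(
        source_points=plate.points[nearest_plate[chosen_arr]],
        target_points=bone.points[chosen_arr],
    )


def fit_tps(
    pairs: ControlPairSet,
    regularization: float = 0.0,
    kernel: str = "r2logr",
) -> TPSModel:
    """Solve the TPS linear system for a 3D deformation field.

    With ``regularization`` (lambda) zero the fitted field maps every
    source control point exactly onto its target; increasing lambda
    relaxes interpolation toward a smoother, lower-bending map.
    """
    if regularization < 0:
        raise ParameterError("regularization must be >= 0")
    if kernel not in KERNELS:
        raise ParameterError(f"unknown kernel {kernel!r}")
    src, tgt = pairs.source_points, pairs.target_points
    n = len(src)
    if n < 4:
        raise GeometryError("TPS needs at least 4 control pairs")
    dist = np.linalg.norm(src[:, None, :] - src[None, :, :], axis=2)
    kmat = tps_kernel(dist, kernel)
    pmat = np.hstack([np.ones((n, 1)), src])
    system = np.zeros((n + 4, n + 4))
    system[:n, :n] = kmat + regularization * np.eye(n)
    system[:n, n:] = pmat
    system[n:, :n] = pmat.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = tgt
    # Minimum-norm solve: coplanar control points (a flat plate is the
    # common case) leave the affine block rank-deficient while the
    # interpolation problem itself stays consistent; the pseudoinverse
    # picks the solution with no component along the affine null space.
    solution, _, _, _ = np.linalg.lstsq(system, rhs, rcond=None)
    model = TPSModel(
        control_points=src.copy(),
        affine=solution[n:],
        weights=solution[:n],
        kernel=kernel,
        regularization=regularization,
    )
    if regularization == 0.0:
        residual = np.max(np.linalg.norm(model(src) - tgt, axis=1))
        scale = max(1.0, float(np.abs(tgt).max()))
        if residual > 1e-6 * scale:
            raise GeometryError(
                "singular TPS system (coincident or collinear control "
                f"points): interpolation residual {residual:.3g} mm"
            )
    return model


def apply_tps(model: TPSModel, geometry):
    """Evaluate the deformation field on a cloud or mesh.

    Mesh topology is unchanged; cloud normals and curvature are dropped
    because a non-rigid warp invalidates both.
    """
    if isinstance(geometry, TriangleMesh):
        return TriangleMesh(model(geometry.vertices), geometry.faces.copy(), geometry.name)
    if isinstance(geometry, PointCloud):
        return PointCloud(model(geometry.points))
    raise ParameterError(f"cannot warp object of type {type(geometry).__name__}")


def bending_energy(model: TPSModel) -> float:
    """Bending energy w^T K w summed over output coordinates.

    Zero for purely affine deformations; grows with non-affine warp and
    flags over-deformation between sparse control points.
    """
    dist = np.linalg.norm(
        model.control_points[:, None, :] - model.control_points[None, :, :], axis=2
    )
    kmat = tps_kernel(dist, model.kernel)
    energy = float(np.einsum("ic,ij,jc->", model.weights, kmat, model.weights))
    return max(energy, 0.0)


def projection_prefit(
    plate: PointCloud, bone: PointCloud, alpha: float = 0.5
) -> PointCloud:
    """Blend each plate point toward its closest bone point.

    An optional pre-warp stage run between rigid alignment and the TPS
    fit: each plate point p moves to (1 - alpha) * p + alpha * q with q
    its nearest bone point. This is a closest-point projection blend,
    not an angle-preserving (conformal) parameterization; it merely
    shrinks large gaps so the spline works from a closer start.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ParameterError("alpha must lie in [0, 1]")
    if len(plate) == 0 or len(bone) == 0:
        raise ParameterError("clouds must be non-empty")
    _, idx = cKDTree(bone.points).query(plate.points, k=1)
    blended = (1.0 - alpha) * plate.points + alpha * bone.points[idx]
    return PointCloud(blended)
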