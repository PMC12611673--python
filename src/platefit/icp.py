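"""Rigid alignment by point-to-point iterative closest point (ICP).

The plate cloud is the moving source and the bone cloud the fixed
target. Each iteration pairs every source point with its nearest target
point, solves the closed-form least-squares rigid motion (Kabsch/SVD),
and applies it; the mean squared pairing distance is recorded per
iteration. The objective is

    E = sum_i || p_i - (R q_i + t) ||^2

over current correspondences, and the standard alternating scheme makes
the recorded mean squared error non-increasing.

Termination follows a dual criterion: the relative change in MSE between
consecutive iterations must fall below ``rel_tol`` AND at least
``min_iterations`` iterations (default 20) must have run; a hard
``max_iterations`` cap guarantees termination on non-converging inputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import GeometryError, ParameterError
from .pointcloud import PointCloud

__all__ = [
    "RigidTransform",
    "ICPResult",
    "nearest_correspondences",
    "best_rigid_transform",
    "run_icp",
]

_REL_CHANGE_EPS = 1e-30


@dataclass(frozen=True)
class RigidTransform:
    """Rotation ``R`` (proper orthonormal) and translation ``t`` in mm."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "rotation", np.ascontiguousarray(self.rotation, dtype=float).reshape(3, 3)
        )
        object.__setattr__(
            self, "translation", np.ascontiguousarray(self.translation, dtype=float).reshape(3)
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def validate(self, tol: float = 1e-6) -> None:
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=tol):
            raise ParameterError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=tol):
            raise ParameterError("rotation matrix determinant is not +1")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self @ other``: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def as_matrix(self) -> np.ndarray:
        mat = np.eye(4)
        mat[:3, :3] = self.rotation
        mat[:3, 3] = self.translation
        return mat

    @classmethod
    def from_matrix(cls, mat: np.ndarray) -> "RigidTransform":
        mat = np.asarray(mat, dtype=float).reshape(4, 4)
        return cls(mat[:3, :3], mat[:3, 3])

    def save(self, path: str | os.PathLike) -> None:
        """Write as a 4x4 row-major homogeneous matrix, plain text."""
        np.savetxt(path, self.as_matrix(), fmt="%.17g")

    @classmethod
    def load(cls, path: str | os.PathLike) -> "RigidTransform":
        return cls.from_matrix(np.loadtxt(path))

    def rotation_angle(self) -> float:
        """Rotation magnitude in radians."""
        cos = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(cos, -1.0, 1.0)))


@dataclass
class ICPResult:
    """Outcome of an ICP run.

    ``mse_trace`` holds the mean squared correspondence distance (mm^2)
    after each iteration's transform update — the data behind a
    convergence plot.
    """

    transform: RigidTransform
    mse_trace: list[float] = field(default_factory=list)
    converged: bool = False

    @property
    def iterations(self) -> int:
        return len(self.mse_trace)

    @property
    def final_mse(self) -> float:
        return self.mse_trace[-1] if self.mse_trace else float("nan")

    @property
    def final_rms(self) -> float:
        return float(np.sqrt(self.final_mse))

    def save_trace(self, path: str | os.PathLike) -> None:
        """Write the per-iteration MSE as CSV (iteration, mse_mm2)."""
        with open(path, "w") as handle:
            handle.write("iteration,mse_mm2\n")
            for i, mse in enumerate(self.mse_trace, start=1):
                handle.write(f"{i},{mse!r}\n")


def _as_points(cloud) -> np.ndarray:
    pts = cloud.points if isinstance(cloud, PointCloud) else np.asarray(cloud, dtype=float)
    return pts.reshape(-1, 3)


def nearest_correspondences(source, target) -> tuple[np.ndarray, np.ndarray]:
    """Nearest target index and Euclidean distance for every source point.

    KD-tree accelerated; identical to a brute-force scan.

    Returns
    -------
    indices : (N,) int array
    distances : (N,) float array
    """
    src, tgt = _as_points(source), _as_points(target)
    if len(src) == 0 or len(tgt) == 0:
        raise ParameterError("point clouds must be non-empty")
    dist, idx = cKDTree(tgt).query(src, k=1)
    return np.asarray(idx, dtype=np.int64), np.asarray(dist, dtype=float)


def best_rigid_transform(source_pts, target_pts) -> RigidTransform:
    """Closed-form least-squares rigid motion mapping source onto target.

    Centroid-aligns both sets, takes the SVD of the cross-covariance and
    corrects an improper (reflective) solution, minimizing
    ``sum_i || target_i - (R source_i + t) ||^2`` (Kabsch/Umeyama).
    """
    src = np.asarray(source_pts, dtype=float).reshape(-1, 3)
    tgt = np.asarray(target_pts, dtype=float).reshape(-1, 3)
    if len(src) != len(tgt):
        raise ParameterError("matched point lists must have equal length")
    if len(src) < 3:
        raise GeometryError("at least 3 point pairs are required")
    c_src, c_tgt = src.mean(axis=0), tgt.mean(axis=0)
    cross = (tgt - c_tgt).T @ (src - c_src)
    if np.linalg.matrix_rank(cross, tol=1e-12 * max(1.0, np.abs(cross).max())) < 2:
        raise GeometryError("degenerate (collinear or coincident) point configuration")
    u, _, vt = np.linalg.svd(cross)
    sign = np.sign(np.linalg.det(u @ vt))
    diag = np.diag([1.0, 1.0, sign if sign != 0 else 1.0])
    rotation = u @ diag @ vt
    translation = c_tgt - rotation @ c_src
    return RigidTransform(rotation, translation)


def run_icp(
    source,
    target,
    init: RigidTransform | None = None,
    min_iterations: int = 20,
    rel_tol: float = 1e-6,
    max_iterations: int = 200,
    abs_tol: float = 1e-12,
) -> ICPResult:
    """Point-to-point ICP aligning ``source`` (plate) to ``target`` (bone).

    Parameters
    ----------
    init : RigidTransform, optional
        Initial pose of the source, standing in for a manual
        landmark-based placement. Identity by default.
    min_iterations : int
        Floor on the iteration count; the tolerance test only takes
        effect once this many iterations have run.
    rel_tol : float
        Relative MSE change threshold, |MSE_{k-1} - MSE_k| / MSE_{k-1}.
    max_iterations : int
        Hard cap guaranteeing termination.
    abs_tol : float
        Absolute MSE floor (mm^2). Below it the relative test is
        meaningless — the residual is floating-point noise — so the run
        counts as converged once ``min_iterations`` have run. The
        default corresponds to an RMS of 1e-6 mm, far below any
        fabrication tolerance.

    Returns
    -------
    ICPResult
        The composed transform (including ``init``), MSE trace, and a
        convergence flag (True iff the tolerance test was met).
    """
    if min_iterations < 1 or max_iterations < min_iterations:
        raise ParameterError("need 1 <= min_iterations <= max_iterations")
    if rel_tol < 0:
        raise ParameterError("rel_tol must be >= 0")
    src = _as_points(source)
    tgt = _as_points(target)
    if len(src) == 0 or len(tgt) == 0:
        raise ParameterError("point clouds must be non-empty")
    if init is None:
        init = RigidTransform.identity()
    init.validate()

    tree = cKDTree(tgt)
    current = init
    moved = init.apply(src)
    trace: list[float] = []
    converged = False
    prev_mse = None
    for _ in range(max_iterations):
        dist, idx = tree.query(moved, k=1)
        if np.all(dist == 0.0):
            # already an exact match; the update would be identity up to
            # floating-point jitter, so keep the trace at exactly zero
            mse = 0.0
        else:
            step = best_rigid_transform(moved, tgt[idx])
            current = step.compose(current)
            moved = current.apply(src)
            mse = float(np.mean(np.sum((moved - tgt[idx]) ** 2, axis=1)))
        trace.append(mse)
        if len(trace) >= min_iterations:
            if mse <= abs_tol:
                converged = True
                break
            if prev_mse is not None:
                rel_change = abs(prev_mse - mse) / max(prev_mse, _REL_CHANGE_EPS)
                if rel_change < rel_tol:
                    converged = True
                    break
        prev_mse = mse
    return ICPResult(transform=current, mse_trace=trace, converged=converged)
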