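"""Plate-bone fit metrics: gap cost, RMS distance, penetration detection.

All metrics are nearest-neighbor point metrics from the plate cloud to
the bone cloud. The gap cost is the plain sum

    E = sum_j min_i || p_j - q_i ||

over plate points p_j and bone points q_i; because a sum scales with the
number of sampled points, the mean and maximum gap are reported
alongside. Penetration of the plate into the bone is detected by the
sign of the projection of (p - q) onto the outward bone normal at the
nearest bone point q.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .icp import nearest_correspondences
from .pointcloud import PointCloud

__all__ = [
    "FitReport",
    "gap_cost",
    "rms_distance",
    "detect_penetrations",
    "fit_report",
    "resolve_penetrations",
    "write_report_csv",
]

REPORT_COLUMNS = (
    "stage",
    "rms_mm",
    "gap_cost_mm",
    "mean_gap_mm",
    "max_gap_mm",
    "penetration_count",
    "max_penetration_mm",
)


@dataclass
class FitReport:
    """Fit summary for one plate/bone pair at one pipeline stage."""

    stage_label: str
    rms: float
    gap_cost: float
    mean_gap: float
    max_gap: float
    penetration_count: int
    max_penetration_depth: float
    n_plate_points: int

    def row(self) -> dict:
        return {
            "stage": self.stage_label,
            "rms_mm": self.rms,
            "gap_cost_mm": self.gap_cost,
            "mean_gap_mm": self.mean_gap,
            "max_gap_mm": self.max_gap,
            "penetration_count": self.penetration_count,
            "max_penetration_mm": self.max_penetration_depth,
        }


def _distances(plate, bone) -> np.ndarray:
    _, dist = nearest_correspondences(plate, bone)
    return dist


def gap_cost(plate, bone) -> float:
    """Sum over plate points of the distance to the nearest bone point (mm)."""
    return float(_distances(plate, bone).sum())


def rms_distance(plate, bone) -> float:
    """Root mean squared nearest-bone distance over plate points (mm)."""
    return float(np.sqrt(np.mean(_distances(plate, bone) ** 2)))


def detect_penetrations(
    plate: PointCloud, bone: PointCloud, tol: float = 1e-6
) -> tuple[int, np.ndarray]:
    """Count plate points lying inside the bone surface.

    A plate point p with nearest bone point q and outward bone normal
    n_q penetrates when (p - q) . n_q < -tol. Returns the count and the
    per-point signed clearance (negative = depth of penetration).
    """
    if bone.normals is None:
        raise ParameterError(
            "bone cloud needs consistently oriented normals; run estimate_normals"
        )
    idx, _ = nearest_correspondences(plate, bone)
    offset = plate.points - bone.points[idx]
    signed = np.einsum("ij,ij->i", offset, bone.normals[idx])
    count = int(np.count_nonzero(signed < -tol))
    return count, signed


def resolve_penetrations(
    plate: PointCloud, bone: PointCloud, clearance: float = 0.0, tol: float = 1e-6
) -> PointCloud:
    """Push penetrating plate points outward along the local bone normal.

    Each point with signed clearance below ``-tol`` is moved along the
    outward normal of its nearest bone point until it sits at
    ``clearance`` mm above the surface. A corrective step, applied only
    on request after the warp.
    """
    count, signed = detect_penetrations(plate, bone, tol=tol)
    if count == 0:
        return plate.copy()
    idx, _ = nearest_correspondences(plate, bone)
    shift = np.zeros(len(plate))
    mask = signed < -tol
    shift[mask] = clearance - signed[mask]
    points = plate.points + shift[:, None] * bone.normals[idx]
    return PointCloud(points)


def fit_report(plate: PointCloud, bone: PointCloud, stage_label: str = "") -> FitReport:
    """Aggregate all fit metrics for one stage into a :class:`FitReport`."""
    dist = _distances(plate, bone)
    if bone.normals is not None:
        count, signed = detect_penetrations(plate, bone)
        max_depth = float(max(0.0, -signed.min())) if len(signed) else 0.0
    else:
        count, max_depth = 0, 0.0
    return FitReport(
        stage_label=stage_label,
        rms=float(np.sqrt(np.mean(dist**2))),
        gap_cost=float(dist.sum()),
        mean_gap=float(dist.mean()),
        max_gap=float(dist.max()),
        penetration_count=count,
        max_penetration_depth=max_depth,
        n_plate_points=len(plate),
    )


def write_report_csv(reports, path: str | os.PathLike) -> None:
    """Write stage reports as one concatenable CSV table."""
    with open(path, "w") as handle:
        handle.write(",".join(REPORT_COLUMNS) + "\n")
        for report in reports:
            row = report.row()
            handle.write(",".join(str(row[c]) for c in REPORT_COLUMNS) + "\n")
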