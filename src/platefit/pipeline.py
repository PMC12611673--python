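"""End-to-end plate-fitting workflow.

Stage order: clean meshes -> sample point clouds -> optional initial
rigid pose (standing in for manual landmark alignment) -> ICP rigid
refinement -> bone normals and curvature -> optional closest-point
projection pre-fit -> TPS warp on curvature-selected control pairs ->
intersection check -> staged fit report.

Every stage appends a row to the fit report, so the rigid and
non-rigid improvements can be read off one CSV table; with fixed seeds
the whole run is bit-reproducible.
"""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass

import yaml

from . import fit_metrics, pointcloud, tps
from .errors import ParameterError, PlatefitError
from .icp import ICPResult, RigidTransform, run_icp
from .mesh_io import TriangleMesh, clean_mesh, read_stl, write_stl
from .pointcloud import PointCloud, curvature_scores, estimate_normals, sample_surface

log = logging.getLogger("platefit")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Effective configuration of one plate-fitting run."""

    bone_path: str = ""
    plate_path: str = ""
    init_transform_path: str | None = None
    pairs_csv: str | None = None
    out_dir: str = "platefit_out"
    # sampling
    n_points: int = pointcloud.DEFAULT_N_POINTS
    seed: int = 0
    # icp
    icp_min_iterations: int = 20
    icp_rel_tol: float = 1e-6
    icp_max_iterations: int = 200
    # normals / curvature
    neighbor_k: int = 30
    # tps
    n_control: int = tps.DEFAULT_N_CONTROL
    min_spacing: float | None = None
    max_pair_distance: float | None = None
    regularization: float = 0.0
    kernel: str = "r2logr"
    # prefit (closest-point projection blend; NOT a conformal map)
    prefit_enabled: bool = False
    prefit_alpha: float = 0.5
    # cleaning
    weld_tol: float = 1e-6
    target_faces: int | None = None

    def validate(self) -> None:
        if self.n_points < 1:
            raise ParameterError("sampling.n_points must be >= 1")
        if self.kernel not in tps.KERNELS:
            raise ParameterError(f"unknown kernel {self.kernel!r}")
        if not 0.0 <= self.prefit_alpha <= 1.0:
            raise ParameterError("prefit.alpha must lie in [0, 1]")

    # -- YAML round trip ---------------------------------------------------

    _YAML_LAYOUT = {
        "inputs": ("bone_path", "plate_path", "init_transform_path", "pairs_csv"),
        "sampling": ("n_points", "seed"),
        "icp": ("icp_min_iterations", "icp_rel_tol", "icp_max_iterations"),
        "normals": ("neighbor_k",),
        "tps": ("n_control", "min_spacing", "max_pair_distance", "regularization", "kernel"),
        "prefit": ("prefit_enabled", "prefit_alpha"),
        "cleaning": ("weld_tol", "target_faces"),
        "output": ("out_dir",),
    }

    def to_yaml(self, path: str | os.PathLike) -> None:
        doc = {
            section: {k: getattr(self, k) for k in keys}
            for section, keys in self._YAML_LAYOUT.items()
        }
        with open(path, "w") as handle:
            yaml.safe_dump(doc, handle, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as handle:
            doc = yaml.safe_load(handle) or {}
        cfg = cls()
        known = {k for keys in cls._YAML_LAYOUT.values() for k in keys}
        for section, content in doc.items():
            if not isinstance(content, dict):
                raise ParameterError(f"config section {section!r} must be a mapping")
            for key, value in content.items():
                if key not in known:
                    raise ParameterError(f"unknown config key {section}.{key}")
                setattr(cfg, key, value)
        return cfg


@dataclass
class PipelineResult:
    """Artifacts of a finished run."""

    reports: list
    icp_result: ICPResult
    tps_model: tps.TPSModel | None
    warped_plate: TriangleMesh
    transform: RigidTransform
    out_dir: str | None = None

    @property
    def rms_by_stage(self) -> dict:
        return {r.stage_label: r.rms for r in self.reports}


def _stage(label: str, started: float) -> None:
    log.info("stage %-12s done in %.2f s", label, time.perf_counter() - started)


def run_pipeline(
    config: PipelineConfig,
    bone_mesh: TriangleMesh | None = None,
    plate_mesh: TriangleMesh | None = None,
    write_outputs: bool = True,
) -> PipelineResult:
    """Execute the full workflow.

    Meshes may be passed in memory (tests, synthetic studies) or read
    from the configured STL paths. When ``write_outputs`` is true the
    warped plate, transforms, TPS model, reports and the effective
    configuration are written under ``config.out_dir``.
    """
    config.validate()
    stage = "setup"
    try:
        t0 = time.perf_counter()
        if bone_mesh is None:
            bone_mesh = read_stl(config.bone_path)
        if plate_mesh is None:
            plate_mesh = read_stl(config.plate_path)
        bone_mesh = clean_mesh(bone_mesh, config.weld_tol, config.target_faces)
        plate_mesh = clean_mesh(plate_mesh, config.weld_tol, config.target_faces)
        _stage("clean", t0)

        stage = "sample"
        t0 = time.perf_counter()
        bone_cloud = sample_surface(bone_mesh, config.n_points, seed=config.seed)
        plate_cloud = sample_surface(plate_mesh, config.n_points, seed=config.seed + 1)
        _stage(stage, t0)

        stage = "init"
        init = RigidTransform.identity()
        if config.init_transform_path:
            init = RigidTransform.load(config.init_transform_path)
            init.validate()
        plate_cloud_init = plate_cloud.transformed(init.rotation, init.translation)

        stage = "normals"
        t0 = time.perf_counter()
        bone_cloud = estimate_normals(
            bone_cloud, k=config.neighbor_k,
            orient_reference=bone_cloud.points.mean(axis=0),
        )
        bone_cloud = curvature_scores(bone_cloud, k=config.neighbor_k)
        _stage(stage, t0)

        reports = [fit_metrics.fit_report(plate_cloud_init, bone_cloud, "initial")]

        stage = "icp"
        t0 = time.perf_counter()
        icp_result = run_icp(
            plate_cloud,
            bone_cloud,
            init=init,
            min_iterations=config.icp_min_iterations,
            rel_tol=config.icp_rel_tol,
            max_iterations=config.icp_max_iterations,
        )
        aligned_cloud = PointCloud(icp_result.transform.apply(plate_cloud.points))
        aligned_mesh = TriangleMesh(
            icp_result.transform.apply(plate_mesh.vertices),
            plate_mesh.faces,
            plate_mesh.name,
        )
        reports.append(fit_metrics.fit_report(aligned_cloud, bone_cloud, "post_icp"))
        _stage(stage, t0)

        warp_cloud, warp_mesh = aligned_cloud, aligned_mesh
        if config.prefit_enabled:
            stage = "prefit"
            t0 = time.perf_counter()
            warp_cloud = tps.projection_prefit(
                warp_cloud, bone_cloud, alpha=config.prefit_alpha
            )
            warp_mesh = TriangleMesh(
                tps.projection_prefit(
                    PointCloud(warp_mesh.vertices), bone_cloud, alpha=config.prefit_alpha
                ).points,
                warp_mesh.faces,
                warp_mesh.name,
            )
            reports.append(fit_metrics.fit_report(warp_cloud, bone_cloud, "post_prefit"))
            _stage(stage, t0)

        stage = "tps"
        t0 = time.perf_counter()
        if config.pairs_csv:
            pairs = tps.ControlPairSet.load_csv(config.pairs_csv)
        else:
            pairs = tps.select_control_points(
                warp_cloud,
                bone_cloud,
                n_points=config.n_control,
                curvature_k=config.neighbor_k,
                min_spacing=config.min_spacing,
                max_pair_distance=config.max_pair_distance,
                seed=config.seed,
            )
        model = tps.fit_tps(pairs, regularization=config.regularization, kernel=config.kernel)
        warped_cloud = tps.apply_tps(model, warp_cloud)
        warped_mesh = tps.apply_tps(model, warp_mesh)
        reports.append(fit_metrics.fit_report(warped_cloud, bone_cloud, "post_tps"))
        _stage(stage, t0)

        result = PipelineResult(
            reports=reports,
            icp_result=icp_result,
            tps_model=model,
            warped_plate=warped_mesh,
            transform=icp_result.transform,
        )
        if write_outputs:
            stage = "write"
            os.makedirs(config.out_dir, exist_ok=True)
            out = config.out_dir
            write_stl(warped_mesh, os.path.join(out, "warped_plate.stl"))
            icp_result.transform.save(os.path.join(out, "transform.txt"))
            model.to_json(os.path.join(out, "tps_model.json"))
            pairs.save_csv(os.path.join(out, "control_pairs.csv"))
            fit_metrics.write_report_csv(reports, os.path.join(out, "report.csv"))
            icp_result.save_trace(os.path.join(out, "icp_trace.csv"))
            config.to_yaml(os.path.join(out, "config_used.yaml"))
            result.out_dir = out
        return result
    except PlatefitError as exc:
        raise PlatefitError(f"pipeline stage {stage!r} failed: {exc}") from exc
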