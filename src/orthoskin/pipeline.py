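"""End-to-end model building: depth scans in, watertight body mesh out.

Stage order: per-scan crop -> nominal rigid transform to the object frame ->
voxel downsampling -> normal estimation (oriented toward the scanner);
per-stop merging; sequential pairwise ICP around the turn; pose-graph loop
closure; merge; statistical outlier removal; moving-least-squares smoothing;
implicit surface reconstruction.  Each stage logs point counts and residuals
for reproducibility audits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .pointcloud import (
    PointCloud,
    SubjectBounds,
    crop_to_subject,
    estimate_normals,
    mls_smooth,
    remove_outliers,
    voxel_downsample,
)
from .reconstruct import reconstruct_surface
from .registration import (
    accumulate_poses,
    apply_transform,
    close_loop,
    icp_register,
    transform_error,
)
from .synthdata import ScanSession

__all__ = ["BuildParams", "BuildResult", "default_bounds", "register_session", "build_model"]


@dataclass(frozen=True)
class BuildParams:
    """Tunables of the model-building pipeline with their standard defaults:
    45-degree stops are a property of the session; the 5 cm MLS radius and
    reconstruction depth 7 are the smoothness/resolution trade-off chosen for
    whole-body scans; the remaining values are engineering defaults."""

    voxel: float = 0.01
    normals_k: int = 30
    outlier_k: int = 20
    outlier_std_mult: float = 1.0
    icp_max_corr: float = 0.02
    icp_coarse_schedule: tuple[float, ...] = (0.08, 0.04)
    icp_max_iterations: int = 50
    icp_metric: str = "point_to_plane"
    icp_normal_reject_deg: float | None = 25.0
    refine_rounds: int = 4
    refine_corr: float = 0.012
    mls_radius: float = 0.05
    mls_order: int = 2
    depth: int = 7
    skip_mls: bool = False
    skip_loop_closure: bool = False


@dataclass
class BuildResult:
    mesh: trimesh.Trimesh
    merged_cloud: PointCloud
    stop_transforms: list[np.ndarray]  # corrected absolute pose per arm stop
    log: dict = field(default_factory=dict)


def default_bounds() -> SubjectBounds:
    """Generous subject box: the standing area inside the rotating arm."""
    return SubjectBounds((-0.6, 0.0, -0.6), (0.6, 2.2, 0.6))


def _merge(clouds: list[PointCloud]) -> PointCloud:
    pts = np.vstack([c.points for c in clouds])
    normals = None
    if all(c.normals is not None for c in clouds):
        normals = np.vstack([c.normals for c in clouds])
    return PointCloud(points=pts, normals=normals, frame="ocs")


def register_session(
    session: ScanSession,
    params: BuildParams = BuildParams(),
    bounds: SubjectBounds | None = None,
    log: dict | None = None,
) -> tuple[list[PointCloud], list[np.ndarray]]:
    """Per-stop preprocessed clouds and their loop-consistent corrections.

    Every cloud is cropped, downsampled and oriented individually, clouds of
    one arm stop are merged, consecutive stops are registered by ICP around
    the full turn (including the closing pair), and the cycle error is
    distributed by pose-graph loop closure.  Returns the per-stop clouds
    (uncorrected) and the absolute correction transform per stop.
    """
    bounds = bounds or default_bounds()
    log = log if log is not None else {}
    n_stops = len(session.angles_deg)
    per_stop: list[list[PointCloud]] = [[] for _ in range(n_stops)]
    counts = []
    for i, cloud in enumerate(session.clouds):
        ocs = cloud.to_ocs()
        cropped = crop_to_subject(ocs, bounds)
        down = voxel_downsample(cropped, params.voxel)
        oriented = estimate_normals(down, k=params.normals_k)
        counts.append({"raw": len(cloud), "cropped": len(cropped), "downsampled": len(down)})
        per_stop[session.cloud_angle_index(i)].append(oriented)
    log["per_scan_counts"] = counts
    stops = [_merge(group) for group in per_stop]

    edges = []
    icp_log = []
    for i in range(n_stops):
        j = (i + 1) % n_stops
        # coarse-to-fine correspondence distances: mount errors of a few
        # degrees displace points far beyond the final correspondence radius
        T = np.eye(4)
        for corr in (*params.icp_coarse_schedule, params.icp_max_corr):
            res = icp_register(
                stops[j],
                stops[i],
                init=T,
                max_corr_dist=corr,
                max_iterations=params.icp_max_iterations,
                metric=params.icp_metric,
                normal_reject_deg=params.icp_normal_reject_deg,
            )
            T = res.transform
        edges.append(res.transform)
        icp_log.append({"edge": (i, j), "rms": res.rms, "iterations": res.iterations})
    log["icp"] = icp_log
    loop = np.eye(4)
    for T in edges:
        loop = loop @ T
    log["loop_error_before"] = transform_error(loop)
    if params.skip_loop_closure:
        absolute = accumulate_poses(edges)
    else:
        corrected = close_loop(edges)
        absolute = accumulate_poses(corrected)
        loop_c = np.eye(4)
        for T in corrected:
            loop_c = loop_c @ T
        log["loop_error_after"] = transform_error(loop_c)

    # Global refinement: each stop re-registered against the union of the
    # others, averaging out the small per-edge biases the ring of pairwise
    # registrations leaves behind.  Every stop (including the first) is
    # refined symmetrically; the gauge is restored afterwards by expressing
    # all poses relative to the first stop, which cancels any common-mode
    # drift of the consensus frame.
    for _ in range(params.refine_rounds if not params.skip_loop_closure else 0):
        refined = []
        for i in range(0, n_stops):
            others = [
                PointCloud(
                    points=apply_transform(stops[k].points, absolute[k]),
                    normals=stops[k].normals @ absolute[k][:3, :3].T,
                    frame="ocs",
                )
                for k in range(n_stops)
                if k != i
            ]
            merged_others = _merge(others)
            moved = PointCloud(
                points=apply_transform(stops[i].points, absolute[i]),
                normals=stops[i].normals @ absolute[i][:3, :3].T,
                frame="ocs",
            )
            res = icp_register(
                moved,
                merged_others,
                max_corr_dist=params.refine_corr,
                max_iterations=params.icp_max_iterations,
                metric=params.icp_metric,
                normal_reject_deg=params.icp_normal_reject_deg,
            )
            refined.append(res.transform @ absolute[i])
        gauge = np.linalg.inv(refined[0])
        absolute = [gauge @ X for X in refined]
    return stops, absolute


def build_model(
    session: ScanSession,
    params: BuildParams = BuildParams(),
    bounds: SubjectBounds | None = None,
) -> BuildResult:
    """Run the full model-building pipeline on a scan session."""
    log: dict = {}
    stops, absolute = register_session(session, params, bounds, log)
    aligned = []
    for cloud, X in zip(stops, absolute):
        pts = apply_transform(cloud.points, X)
        nrm = cloud.normals @ X[:3, :3].T if cloud.normals is not None else None
        aligned.append(PointCloud(points=pts, normals=nrm, frame="ocs"))
    merged = _merge(aligned)
    log["merged"] = len(merged)
    merged = voxel_downsample(merged, params.voxel)
    log["merged_downsampled"] = len(merged)
    merged = remove_outliers(merged, k=params.outlier_k, std_mult=params.outlier_std_mult)
    log["after_outlier_removal"] = len(merged)
    if not params.skip_mls:
        merged = mls_smooth(merged, radius=params.mls_radius, order=params.mls_order)
    mesh = reconstruct_surface(merged, depth=params.depth)
    log["mesh_faces"] = len(mesh.faces)
    log["mesh_watertight"] = bool(mesh.is_watertight)
    return BuildResult(mesh=mesh, merged_cloud=merged, stop_transforms=absolute, log=log)
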