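"""Disk formats: scan-session directories, camera-rig descriptions, meshes.

A session directory is fully self-describing:

* ``manifest.json`` — per-view camera metadata (angle, height, radius,
  calibration) and per-cloud scanner metadata with file paths;
* ``clouds/*.ply`` — depth scans in DCS;
* ``images/*.png`` — high-resolution photographs;
* ``ground_truth.json`` — the phantom spec, marker geometry and injected
  pose perturbations (synthetic sessions only).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import trimesh
from PIL import Image

from .geometry import CameraCalib, RigidPose
from .pointcloud import PointCloud
from .render import CameraView
from .synthdata import ArmSpec, MarkerSpec, Phantom, PhantomSpec, ScanSession

__all__ = [
    "calib_to_dict",
    "calib_from_dict",
    "save_rig",
    "load_rig",
    "write_session",
    "read_session",
    "save_mesh",
    "load_mesh",
]


def calib_to_dict(calib: CameraCalib) -> dict:
    return {
        "Q": np.asarray(calib.Q).ravel().tolist(),
        "T": np.asarray(calib.T).tolist(),
        "d": calib.d,
        "principal_point": np.asarray(calib.principal_point).tolist(),
        "image_size": list(calib.image_size),
    }


def calib_from_dict(d: dict) -> CameraCalib:
    return CameraCalib(
        Q=np.asarray(d["Q"], dtype=float).reshape(3, 3),
        T=np.asarray(d["T"], dtype=float),
        d=float(d["d"]),
        principal_point=np.asarray(d["principal_point"], dtype=float),
        image_size=tuple(d["image_size"]),
    )


def save_rig(views: list[CameraView], path: str | Path, image_paths: dict[int, str] | None = None) -> None:
    """Write the camera-rig description JSON (one record per view)."""
    records = []
    for v in views:
        rec = {
            "view_id": v.view_id,
            "alpha_deg": v.pose.alpha_deg,
            "h": v.pose.h,
            "r": v.pose.r,
            **calib_to_dict(v.calib),
        }
        if image_paths and v.view_id in image_paths:
            rec["image_path"] = image_paths[v.view_id]
        records.append(rec)
    Path(path).write_text(json.dumps(records, indent=2))


def load_rig(path: str | Path, load_images: bool = True) -> list[CameraView]:
    """Read a camera-rig JSON; image paths are resolved relative to the file."""
    path = Path(path)
    views = []
    for rec in json.loads(path.read_text()):
        pose = RigidPose.from_degrees(rec["alpha_deg"], rec["h"], rec["r"])
        calib = calib_from_dict(rec)
        image = None
        if load_images and rec.get("image_path"):
            image = np.asarray(Image.open(path.parent / rec["image_path"]))
        views.append(CameraView(pose=pose, calib=calib, image=image, view_id=rec["view_id"]))
    return views


def _spec_to_dict(spec: PhantomSpec) -> dict:
    d = dataclasses.asdict(spec)
    return d


def _spec_from_dict(d: dict) -> PhantomSpec:
    markers = tuple(MarkerSpec(**{**m, "tag_mm": tuple(m["tag_mm"])}) for m in d.get("markers", []))
    arms = tuple(ArmSpec(**{**a, "y_range": tuple(a["y_range"])}) for a in d.get("arms", []))
    return PhantomSpec(
        semi_axes=tuple(d["semi_axes"]),
        y_range=tuple(d["y_range"]),
        cap_height=d["cap_height"],
        markers=markers,
        arms=arms,
        segments=d["segments"],
        rings_per_meter=d["rings_per_meter"],
    )


def write_session(session: ScanSession, directory: str | Path) -> Path:
    """Write a scan session as a self-describing directory; returns its path."""
    directory = Path(directory)
    (directory / "clouds").mkdir(parents=True, exist_ok=True)
    (directory / "images").mkdir(exist_ok=True)
    manifest: dict = {"angles_deg": np.asarray(session.angles_deg).tolist(), "views": [], "clouds": []}
    for v in session.views:
        rec = {
            "view_id": v.view_id,
            "alpha_deg": v.pose.alpha_deg,
            "h": v.pose.h,
            "r": v.pose.r,
            **calib_to_dict(v.calib),
        }
        if v.image is not None:
            rel = f"images/view_{v.view_id:03d}.png"
            Image.fromarray(v.image).save(directory / rel)
            rec["image_path"] = rel
        manifest["views"].append(rec)
    for i, c in enumerate(session.clouds):
        rel = f"clouds/scan_{i:03d}.ply"
        trimesh.PointCloud(c.points).export(directory / rel)
        manifest["clouds"].append(
            {
                "cloud_id": i,
                "alpha_deg": c.pose.alpha_deg if c.pose else None,
                "h": c.pose.h if c.pose else None,
                "r": c.pose.r if c.pose else None,
                "frame": c.frame,
                "ply_path": rel,
            }
        )
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    truth = {
        "phantom_spec": _spec_to_dict(session.phantom.spec),
        "perturbations": [np.asarray(T).tolist() for T in session.perturbations],
        "markers_ocs": [
            {
                "center": session.phantom.marker_center(i).tolist(),
                "normal": session.phantom.marker_normal(i).tolist(),
                "tag_corners": session.phantom.tag_corners(i).tolist(),
            }
            for i in range(len(session.phantom.spec.markers))
        ],
    }
    (directory / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return directory


def read_session(directory: str | Path, load_images: bool = True) -> ScanSession:
    """Reload a session directory written by :func:`write_session`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    truth = json.loads((directory / "ground_truth.json").read_text())
    phantom = Phantom(_spec_from_dict(truth["phantom_spec"]))
    views = []
    for rec in manifest["views"]:
        image = None
        if load_images and rec.get("image_path"):
            image = np.asarray(Image.open(directory / rec["image_path"]))
        views.append(
            CameraView(
                pose=RigidPose.from_degrees(rec["alpha_deg"], rec["h"], rec["r"]),
                calib=calib_from_dict(rec),
                image=image,
                view_id=rec["view_id"],
            )
        )
    clouds = []
    for rec in manifest["clouds"]:
        pts = np.asarray(trimesh.load(directory / rec["ply_path"]).vertices, dtype=float)
        pose = None
        if rec["alpha_deg"] is not None:
            pose = RigidPose.from_degrees(rec["alpha_deg"], rec["h"], rec["r"])
        clouds.append(PointCloud(points=pts, pose=pose, frame=rec["frame"]))
    perts = [np.asarray(T, dtype=float) for T in truth.get("perturbations", [])]
    return ScanSession(phantom, views, clouds, np.asarray(manifest["angles_deg"]), perts)


def save_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    """Export a mesh as PLY or OBJ, by file extension."""
    mesh.export(str(path))


def load_mesh(path: str | Path) -> trimesh.Trimesh:
    loaded = trimesh.load(str(path), force="mesh")
    return loaded
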