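"""Marker morphology: the quantitative yardstick for rectification quality.

Round calibration markers of known diameter printed on the skin (or phantom)
should come out of orthorectification as circles of the right area, and the
rectangular tags holding them should have right-angle corners.  Fitted
ellipse axis ratio, physical area and shear angle therefore measure how well
the rectification undoes foreshortening, perspective scaling and shear.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.measure import label

from .ortho import OrthoPatch

__all__ = [
    "MarkerMeasurement",
    "MarkerReport",
    "SegmentationError",
    "segment_marker",
    "fit_ellipse",
    "marker_area",
    "shear_angle",
    "aggregate_report",
    "save_report_csv",
    "save_report_json",
]


class SegmentationError(RuntimeError):
    """No dark marker component found at the patch center."""


def _between_class_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Threshold maximizing between-class variance of the histogram.

    Ties (a plateau of equally good splits across an empty histogram gap)
    resolve to the middle of the plateau, so the returned threshold sits in
    the gap between the two classes rather than on a populated bin edge.
    """
    hist, edges = np.histogram(values, bins=nbins)
    hist = hist.astype(float)
    w0 = np.cumsum(hist)
    w1 = w0[-1] - w0
    centers = 0.5 * (edges[:-1] + edges[1:])
    cum = np.cumsum(hist * centers)
    mu0 = np.where(w0 > 0, cum / np.maximum(w0, 1), 0.0)
    mu1 = np.where(w1 > 0, (cum[-1] - cum) / np.maximum(w1, 1), 0.0)
    var = w0 * w1 * (mu0 - mu1) ** 2
    var = var[:-1]  # a split needs both classes non-empty
    best = np.flatnonzero(var == var.max())
    k = best[len(best) // 2]
    return float(edges[k + 1])


@dataclass(frozen=True)
class MarkerMeasurement:
    """One marker measured in one condition ('original' or 'orthorectified')."""

    marker_id: int
    condition: str
    axis_ratio: float
    area_cm2: float
    shear_angle_dev_deg: float | None = None


@dataclass(frozen=True)
class MarkerReport:
    """Aggregate mean and relative standard deviation (sigma/mu) per attribute
    and condition, mirroring a before/after comparison table."""

    summary: dict  # condition -> attribute -> {"mean": .., "rel_std": ..}
    n_markers: dict  # condition -> count


def segment_marker(patch: OrthoPatch | np.ndarray, center_radius: int = 3) -> np.ndarray:
    """Binary mask of the dark marker disk at the center of a patch.

    The threshold maximizes between-class variance of the patch histogram
    (Otsu — deterministic given the patch); the mask is the largest dark
    connected component within ``center_radius`` pixels of the patch center,
    with holes filled.  Invalid patch pixels never join the mask.
    """
    if isinstance(patch, OrthoPatch):
        img = np.asarray(patch.image, dtype=float)
        valid = patch.valid_mask
    else:
        img = np.asarray(patch, dtype=float)
        valid = np.ones(img.shape[:2], dtype=bool)
    gray = img.mean(axis=-1) if img.ndim == 3 else img
    values = gray[valid]
    if values.size == 0 or values.min() == values.max():
        raise SegmentationError("patch has no contrast to segment")
    thr = _between_class_threshold(values)
    dark = (gray < thr) & valid
    labels = label(dark, connectivity=2)
    h, w = gray.shape
    cy, cx = (h - 1) // 2, (w - 1) // 2
    y0, y1 = max(0, cy - center_radius), min(h, cy + center_radius + 1)
    x0, x1 = max(0, cx - center_radius), min(w, cx + center_radius + 1)
    candidates = np.unique(labels[y0:y1, x0:x1])
    candidates = candidates[candidates > 0]
    if len(candidates) == 0:
        raise SegmentationError("no dark component touches the patch center")
    best = max(candidates, key=lambda c: int((labels == c).sum()))
    return binary_fill_holes(labels == best)


def fit_ellipse(mask: np.ndarray) -> tuple[float, float, np.ndarray, float]:
    """Ellipse (a, b, center, orientation) from second central moments.

    For a solid ellipse the covariance eigenvalues are (a/2)^2 and (b/2)^2,
    so the semi-axes are ``2 * sqrt(eigenvalue)``; a >= b, orientation is the
    angle of the major axis in radians.  Moment-based fitting is closed-form
    and has no iterative failure modes.
    """
    ys, xs = np.nonzero(mask)
    if len(xs) == 0:
        raise SegmentationError("empty mask")
    cx, cy = xs.mean(), ys.mean()
    u, v = xs - cx, ys - cy
    cov = np.array([[np.mean(u * u), np.mean(u * v)], [np.mean(u * v), np.mean(v * v)]])
    vals, vecs = np.linalg.eigh(cov)
    if vals[1] <= 0:
        raise SegmentationError("degenerate (zero-variance) mask")
    b_ax, a_ax = 2.0 * np.sqrt(np.maximum(vals, 0.0))
    orientation = float(np.arctan2(vecs[1, 1], vecs[0, 1]))
    return float(a_ax), float(b_ax), np.array([cx, cy]), orientation


def marker_area(mask: np.ndarray, scale_px_per_mm: float) -> float:
    """Physical mask area in cm^2: pixel count / scale^2, mm^2 -> cm^2."""
    if not scale_px_per_mm > 0:
        raise ValueError("scale must be positive")
    area_mm2 = int(np.count_nonzero(mask)) / scale_px_per_mm**2
    return area_mm2 / 100.0


def shear_angle(corners: np.ndarray) -> float:
    """Deviation of a tag corner from the right angle, degrees.

    ``corners`` are the four tag corners ordered around the rectangle; the
    angle between the two edges meeting at the first corner is measured and
    |angle - 90| returned.  Zero for a true (possibly rotated or scaled)
    rectangle.
    """
    c = np.asarray(corners, dtype=float)
    if c.shape != (4, 2):
        raise ValueError("need four 2D corners")
    e1 = c[1] - c[0]
    e2 = c[3] - c[0]
    cross = e1[0] * e2[1] - e1[1] * e2[0]
    n1, n2 = np.linalg.norm(e1), np.linalg.norm(e2)
    if n1 == 0 or n2 == 0 or abs(cross) < 1e-12 * n1 * n2:
        raise ValueError("collinear corners: shear angle undefined")
    ang = np.degrees(np.arccos(np.clip(e1 @ e2 / (n1 * n2), -1.0, 1.0)))
    return float(abs(ang - 90.0))


def aggregate_report(measurements: list[MarkerMeasurement]) -> MarkerReport:
    """Mean and relative standard deviation per attribute, per condition."""
    if not measurements:
        raise ValueError("at least one measurement is required")
    summary: dict[str, dict[str, dict[str, float]]] = {}
    counts: dict[str, int] = {}
    conditions = sorted({m.condition for m in measurements})
    for cond in conditions:
        rows = [m for m in measurements if m.condition == cond]
        counts[cond] = len(rows)
        attrs: dict[str, dict[str, float]] = {}
        for attr in ("axis_ratio", "area_cm2", "shear_angle_dev_deg"):
            vals = np.array([getattr(m, attr) for m in rows if getattr(m, attr) is not None])
            if len(vals) == 0:
                continue
            mu = float(vals.mean())
            sd = float(vals.std())
            if mu != 0:
                rel = sd / abs(mu)
            else:
                rel = 0.0 if sd == 0 else float("inf")
            attrs[attr] = {"mean": mu, "rel_std": rel}
        summary[cond] = attrs
    return MarkerReport(summary, counts)


def save_report_csv(measurements: list[MarkerMeasurement], path: str | Path) -> None:
    with open(path, "w", newline="") as f:
        writer = csv.DictWriter(
            f, fieldnames=["marker_id", "condition", "axis_ratio", "area_cm2", "shear_angle_dev_deg"]
        )
        writer.writeheader()
        for m in measurements:
            writer.writerow(asdict(m))


def save_report_json(report: MarkerReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"summary": report.summary, "n_markers": report.n_markers}, indent=2))
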