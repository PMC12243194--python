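"""Per-segment blob descriptors f1-f8.

All grey-value statistics (f2, f3, f4, f6) are computed on the normalized
attenuation image by default; a ``raw`` switch is kept because the source
description of the method leaves the choice open for f2/f4.

f1  segment size in pixels
f2  mean grey value over the segment
f3  virtual weight: sum of normalized grey values
f4  population standard deviation of the grey values
f5  sphere radius: radius of the circle of equal area, sqrt(f1/pi)
f6  average weight: f2 * f5
f7  minimum covering circle radius of the pixel centers
f8  sphere ratio f5/f7 in (0, 1]: 1 for a circle, -> 0 for a line
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .preprocessing import AttenuationImage
from .segmentation import GrainSegment

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "compute_feature_vector",
    "min_enclosing_circle",
    "features_table",
    "write_features_csv",
    "read_features_csv",
]

FEATURE_NAMES = ("f1", "f2", "f3", "f4", "f5", "f6", "f7", "f8")


@dataclass(frozen=True)
class FeatureVector:
    f1_size_px: int
    f2_mean: float
    f3_weight: float
    f4_sd: float
    f5_sphere_radius_px: float
    f6_avg_weight: float
    f7_mcc_radius_px: float
    f8_sphere_ratio: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.f1_size_px,
                self.f2_mean,
                self.f3_weight,
                self.f4_sd,
                self.f5_sphere_radius_px,
                self.f6_avg_weight,
                self.f7_mcc_radius_px,
                self.f8_sphere_ratio,
            ],
            dtype=np.float64,
        )


# ---------------------------------------------------------------------------
# minimum enclosing circle (Welzl, move-to-front, on the convex hull)
# ---------------------------------------------------------------------------

def _circle_two(p, q):
    center = (p + q) / 2.0
    return center, float(np.hypot(*(p - center)))

def _circle_three(p, q, r):
    # circumcircle; degenerate (collinear) -> None
    ax, ay = p
    bx, by = q
    cx, cy = r
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-14:
        return None
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
          + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
          + (cx**2 + cy**2) * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, float(np.hypot(*(p - center)))

def _in_circle(circle, p, eps=1e-12):
    center, radius = circle
    return np.hypot(*(p - center)) <= radius + eps

def _mec_trivial(boundary):
    if not boundary:
        return np.zeros(2), 0.0
    if len(boundary) == 1:
        return boundary[0].copy(), 0.0
    if len(boundary) == 2:
        return _circle_two(boundary[0], boundary[1])
    # smallest circle through 2 of the 3, else circumcircle
    for i in range(3):
        for j in range(i + 1, 3):
            c = _circle_two(boundary[i], boundary[j])
            if all(_in_circle(c, boundary[k]) for k in range(3)):
                return c
    c = _circle_three(*boundary)
    if c is None:    # collinear: span of the extremes
        pts = np.array(boundary)
        i, j = np.unravel_index(
            np.argmax(((pts[:, None] - pts[None]) ** 2).sum(-1)), (3, 3)
        )
        return _circle_two(pts[i], pts[j])
    return c


def _welzl(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Iterative move-to-front Welzl; expected linear time."""
    pts = [p for p in points]
    circle = _mec_trivial([])

    def mec_with_boundary(limit, boundary):
        circle = _mec_trivial(boundary)
        if len(boundary) == 3:
            return circle
        for i in range(limit):
            p = pts[i]
            if not _in_circle(circle, p):
                circle = mec_with_boundary(i, boundary + [p])
        return circle

    for i, p in enumerate(pts):
        if not _in_circle(circle, p):
            circle = mec_with_boundary(i, [p])
    return circle


def min_enclosing_circle(points: Iterable[tuple[float, float]]):
    """Smallest circle covering all points; returns ((row, col), radius).

    Points are pixel centers; a single point yields radius 0.  Input is
    reduced to its convex hull first, then solved exactly with Welzl's
    algorithm under a fixed shuffle for determinism.
    """
    pts = np.asarray(sorted(points), dtype=np.float64)
    if pts.size == 0:
        raise ValueError("min_enclosing_circle requires at least one point")
    pts = np.unique(pts.reshape(-1, 2), axis=0)
    if len(pts) == 1:
        return (float(pts[0, 0]), float(pts[0, 1])), 0.0
    if len(pts) > 8:
        try:
            from scipy.spatial import ConvexHull
            pts = pts[ConvexHull(pts).vertices]
        except Exception:   # collinear or tiny sets: fall through to all points
            pass
    rng = np.random.default_rng(1905)
    pts = pts[rng.permutation(len(pts))]
    center, radius = _welzl(pts)
    # tighten: exact radius is the max distance to the computed center
    radius = float(np.max(np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])))
    return (float(center[0]), float(center[1])), radius


# ---------------------------------------------------------------------------
# descriptor computation
# ---------------------------------------------------------------------------

def compute_feature_vector(
    segment: GrainSegment, att: AttenuationImage
) -> FeatureVector:
    """Compute f1..f8 for one segment on the attenuation image."""
    values = np.asarray(att.values)
    rr, cc = segment.pixel_arrays()
    if (rr.min() < 0 or cc.min() < 0
            or rr.max() >= values.shape[0] or cc.max() >= values.shape[1]):
        raise ValueError(f"segment {segment.label} has pixels outside the image")
    grey = values[rr, cc].astype(np.float64)

    f1 = int(len(grey))
    f2 = float(grey.mean())
    f3 = float(grey.sum())
    f4 = float(grey.std())          # population SD: descriptor, not estimator
    f5 = math.sqrt(f1 / math.pi)
    f6 = f2 * f5
    _, f7 = min_enclosing_circle(zip(rr.tolist(), cc.tolist()))
    f8 = f5 / f7 if f7 > 0 else 1.0
    return FeatureVector(f1, f2, f3, f4, f5, f6, f7, f8)


def features_table(
    segments: Sequence[GrainSegment], att: AttenuationImage
) -> tuple[list[int], np.ndarray]:
    """(labels, n x 8 array) in label order."""
    labels = [seg.label for seg in segments]
    if not segments:
        return labels, np.empty((0, len(FEATURE_NAMES)))
    rows = np.vstack([compute_feature_vector(s, att).as_array() for s in segments])
    return labels, rows


def write_features_csv(path, labels: Sequence[int], table: np.ndarray) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(("label",) + FEATURE_NAMES)
        for label, row in zip(labels, table):
            writer.writerow([label] + [repr(float(v)) for v in row])


def read_features_csv(path) -> tuple[list[int], np.ndarray]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if tuple(header) != ("label",) + FEATURE_NAMES:
            raise ValueError(f"{path}: unexpected feature CSV header {header}")
        labels, rows = [], []
        for rec in reader:
            labels.append(int(rec[0]))
            rows.append([float(v) for v in rec[1:]])
    table = np.array(rows, dtype=np.float64) if rows else np.empty((0, 8))
    return labels, table
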