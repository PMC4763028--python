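"""Exact parametric voxel-walk ray tracing (Siddon-style).

Provides water-equivalent (radiological) path lengths through a voxel
phantom and the four special points of a treatment beam: body entrance,
target entrance, target exit and body exit.  From those the effective path
length EP (water-equivalent skin-to-isocenter distance) and tumor size TS
(water-equivalent in-target length) are derived; they drive per-angle
energy selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .beam_model import SAD
from .phantom import GeometryError, VoxelPhantom


class NoTargetError(ValueError):
    """The ray does not intersect the target volume."""


@dataclass(frozen=True)
class Ray:
    """A source-to-isocenter ray; parameter t is distance (cm) from the source."""

    source: Tuple[float, float, float]
    direction: Tuple[float, float, float]
    isocenter: Tuple[float, float, float]

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = float(np.linalg.norm(d))
        if abs(n - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")

    @classmethod
    def from_gantry(
        cls, angle_deg: float, isocenter, sad: float = SAD
    ) -> "Ray":
        """Isocentric ray for a gantry angle.

        Angle 0 enters anteriorly (source on +y); angles increase clockwise
        viewed from the patient's feet, so 90 deg puts the source on the
        patient's left (+x).
        """
        th = math.radians(angle_deg)
        u = np.array([math.sin(th), math.cos(th), 0.0])
        iso = np.asarray(isocenter, dtype=float)
        src = iso + sad * u
        return cls(source=tuple(src), direction=tuple(-u), isocenter=tuple(iso))

    @property
    def t_isocenter(self) -> float:
        s = np.asarray(self.source)
        i = np.asarray(self.isocenter)
        return float(np.dot(i - s, np.asarray(self.direction)))

    def reversed(self) -> "Ray":
        """The same line traced from the opposite side."""
        s = np.asarray(self.source)
        d = np.asarray(self.direction)
        t_iso = self.t_isocenter
        new_src = s + 2.0 * t_iso * d
        return Ray(
            source=tuple(new_src), direction=tuple(-d), isocenter=self.isocenter
        )


@dataclass(frozen=True)
class FourPointTrace:
    """Depths (cm from the body entrance, along the ray) of the four special
    points, with water-equivalent EP and TS."""

    p1_depth: float
    p2_depth: float
    p3_depth: float
    p4_depth: float
    ep: float
    ts: float

    def __post_init__(self) -> None:
        if not (
            self.p1_depth <= self.p2_depth <= self.p3_depth <= self.p4_depth
        ):
            raise ValueError("four-point depths must be ordered p1<=p2<=p3<=p4")


def _segments(
    phantom: VoxelPhantom, ray: Ray, t0: float, t1: float
):
    """Elementary voxel segments of the ray between parameters t0 and t1.

    Returns (t_edges, lengths, flat_voxel_indices) for the portion inside
    the grid; raises GeometryError if the segment misses the grid entirely.
    """
    src = np.asarray(ray.source, dtype=float)
    d = np.asarray(ray.direction, dtype=float)
    origin = np.asarray(phantom.origin)
    spacing = np.asarray(phantom.spacing)
    shape = np.asarray(phantom.shape)
    hi = origin + shape * spacing

    # slab clipping to the grid
    tlo, thi = t0, t1
    for a in range(3):
        if abs(d[a]) < 1e-12:
            if not (origin[a] <= src[a] < hi[a]):
                raise GeometryError("ray segment lies outside the voxel grid")
            continue
        ta = (origin[a] - src[a]) / d[a]
        tb = (hi[a] - src[a]) / d[a]
        tlo = max(tlo, min(ta, tb))
        thi = min(thi, max(ta, tb))
    if thi <= tlo:
        raise GeometryError("ray segment does not intersect the voxel grid")

    ts = [np.array([tlo, thi])]
    for a in range(3):
        if abs(d[a]) < 1e-12:
            continue
        ks = np.arange(shape[a] + 1)
        t_planes = (origin[a] + ks * spacing[a] - src[a]) / d[a]
        ts.append(t_planes[(t_planes > tlo) & (t_planes < thi)])
    edges = np.unique(np.concatenate(ts))
    lengths = np.diff(edges)
    keep = lengths > 1e-12
    mids = src[None, :] + 0.5 * (edges[:-1] + edges[1:])[:, None] * d[None, :]
    idx = np.floor((mids - origin) / spacing).astype(int)
    np.clip(idx, 0, shape - 1, out=idx)
    flat = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), phantom.shape)
    return edges, lengths[keep], flat[keep], edges[:-1][keep], edges[1:][keep]


def radiological_path(
    phantom: VoxelPhantom, ray: Ray, from_depth: float, to_depth: float
) -> float:
    """Water-equivalent length (cm) of the ray between two parameters.

    ``from_depth``/``to_depth`` are distances along the ray from its source.
    Equals the line integral of relative electron density; portions of the
    segment outside the grid contribute nothing, but the segment must
    intersect the grid.
    """
    if from_depth > to_depth:
        raise ValueError("from_depth must not exceed to_depth")
    if to_depth - from_depth < 1e-12:
        return 0.0
    _, lengths, flat, _, _ = _segments(phantom, ray, from_depth, to_depth)
    dens = phantom.density.ravel()[flat]
    return float(np.sum(dens * lengths))


def trace_four_points(phantom: VoxelPhantom, ray: Ray) -> FourPointTrace:
    """Locate body/target entrance and exit along the ray; compute EP and TS.

    Depths are reported from the body entrance (p1 = 0).  EP integrates
    density from the skin to the isocenter; TS integrates density over
    in-target subsegments only (a ray crossing a disconnected target uses
    first entry and last exit).
    """
    t_far = ray.t_isocenter * 4.0
    try:
        _, lengths, flat, seg_lo, seg_hi = _segments(phantom, ray, 0.0, t_far)
    except GeometryError:
        raise GeometryError("ray misses the phantom grid") from None
    body = phantom.structures["BODY"].ravel()[flat]
    ptv = phantom.structures["PTV"].ravel()[flat]
    dens = phantom.density.ravel()[flat]
    if not body.any():
        raise GeometryError("ray does not intersect the BODY contour")
    if not ptv.any():
        raise NoTargetError("ray does not intersect the PTV")

    t1 = float(seg_lo[body.argmax()])
    t4 = float(seg_hi[len(body) - 1 - body[::-1].argmax()])
    t2 = float(seg_lo[ptv.argmax()])
    t3 = float(seg_hi[len(ptv) - 1 - ptv[::-1].argmax()])

    t_iso = ray.t_isocenter
    in_ep = np.clip(seg_hi, t1, t_iso) - np.clip(seg_lo, t1, t_iso)
    ep = float(np.sum(dens * np.maximum(in_ep, 0.0)))
    ts_len = np.where(ptv, lengths, 0.0)
    ts = float(np.sum(dens * ts_len))

    return FourPointTrace(
        p1_depth=0.0,
        p2_depth=t2 - t1,
        p3_depth=t3 - t1,
        p4_depth=t4 - t1,
        ep=ep,
        ts=ts,
    )
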