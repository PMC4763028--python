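"""Divergent pencil-beam dose engine: beamlet deposition matrices (DDCs).

Each beam is decomposed into 1 x 1 cm beamlets at the isocenter plane.  A
beamlet's dose to a voxel is

    PDD(water-equivalent depth along the beamlet axis)
      x off-axis ratio (lateral distance, back-projected to isocenter scale)
      x inverse-square factor (SAD / source-to-voxel distance)^2,

normalized so the open-field composite of all beamlets equals 1.0 at
water-equivalent dmax on the central axis.  Water-equivalent depth is the
radiological path along the beamlet axis from the skin (first-order pencil
beam; no lateral heterogeneity correction).  Dose is additive over beamlets
(d = A x), so plans are evaluated by sparse matrix-vector products.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from .beam_model import SAD, BeamProfile, PDDCurve, pdd_at, off_axis_ratio
from .phantom import VoxelPhantom
from .raytrace import Ray, _segments

#: Entries below this fraction of their column maximum are dropped.
SPARSE_DROP_FRACTION = 1e-4

#: Lateral distance (cm, isocenter scale) beyond which a beamlet deposits nothing.
LATERAL_CUTOFF_CM = 3.0


@dataclass
class BeamletGrid:
    """Regular grid of beamlet center positions at the isocenter plane.

    ``u`` spans the in-transverse-plane lateral direction, ``v`` the
    longitudinal direction; both are unit vectors perpendicular to the beam
    axis.  The extent covers the target's beam's-eye-view projection plus a
    one-beamlet margin ring.
    """

    beam: Ray
    energy_MV: float
    beamlet_size: float = 1.0
    centers_uv: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    u_axis: np.ndarray = field(default_factory=lambda: np.zeros(3))
    v_axis: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def n_beamlets(self) -> int:
        return len(self.centers_uv)


@dataclass
class DoseDepositionMatrix:
    """Sparse a_ij: relative dose to BODY voxel i per unit weight of beamlet j."""

    matrix: sp.csr_matrix  # (n_body_voxels, n_beamlets)
    voxel_indices: np.ndarray  # flat indices into the phantom grid
    grid_shape: Tuple[int, int, int]
    metadata: Dict = field(default_factory=dict)

    @property
    def n_beamlets(self) -> int:
        return self.matrix.shape[1]


def beam_basis(ray: Ray) -> Tuple[np.ndarray, np.ndarray]:
    """Orthonormal (u, v) transverse basis for a beam axis in the x-y plane."""
    d = np.asarray(ray.direction)
    z = np.array([0.0, 0.0, 1.0])
    u = np.cross(d, z)
    nu = np.linalg.norm(u)
    if nu < 1e-9:
        raise ValueError("beam axis parallel to the longitudinal axis")
    u = u / nu
    v = np.cross(u, d)
    return u, v


def make_beamlet_grid(
    phantom: VoxelPhantom,
    ray: Ray,
    energy_MV: float,
    beamlet_size: float = 1.0,
    margin_rings: int = 1,
) -> BeamletGrid:
    """Beamlet grid covering the PTV beam's-eye-view projection plus margin."""
    u, v = beam_basis(ray)
    src = np.asarray(ray.source)
    iso = np.asarray(ray.isocenter)
    sad = float(np.linalg.norm(iso - src))
    idx = np.argwhere(phantom.structures["PTV"])
    pts = np.asarray(phantom.origin) + (idx + 0.5) * np.asarray(phantom.spacing)
    rel = pts - src
    t = rel @ np.asarray(ray.direction)
    a = (rel @ u) * sad / t
    b = (rel @ v) * sad / t
    s = beamlet_size
    ia = np.arange(
        int(np.floor(a.min() / s)) - margin_rings,
        int(np.ceil(a.max() / s)) + margin_rings,
    )
    ib = np.arange(
        int(np.floor(b.min() / s)) - margin_rings,
        int(np.ceil(b.max() / s)) + margin_rings,
    )
    A, B = np.meshgrid((ia + 0.5) * s, (ib + 0.5) * s, indexing="ij")
    centers = np.column_stack([A.ravel(), B.ravel()])
    return BeamletGrid(
        beam=ray,
        energy_MV=energy_MV,
        beamlet_size=beamlet_size,
        centers_uv=centers,
        u_axis=u,
        v_axis=v,
    )


def _axis_wed_table(phantom: VoxelPhantom, axis_ray: Ray):
    """Cumulative water-equivalent depth vs distance-from-source along a ray.

    Returns (t_points, wed_points) for np.interp; WED is measured from the
    first BODY voxel (the skin) along the axis.
    """
    t_far = axis_ray.t_isocenter * 4.0
    _, lengths, flat, seg_lo, seg_hi = _segments(phantom, axis_ray, 0.0, t_far)
    body = phantom.structures["BODY"].ravel()[flat]
    dens = np.where(body, phantom.density.ravel()[flat], 0.0)
    wed = np.concatenate([[0.0], np.cumsum(dens * lengths)])
    tpts = np.concatenate([[seg_lo[0]], seg_hi])
    return tpts, wed


def compute_ddc(
    phantom: VoxelPhantom,
    grid: BeamletGrid,
    curve: PDDCurve,
    profile: BeamProfile,
    drop_fraction: float = SPARSE_DROP_FRACTION,
) -> DoseDepositionMatrix:
    """Score the dose deposition coefficients of every beamlet.

    Deterministic divergent pencil-beam kernel standing behind the beamlet
    superposition model: dose is a separable product of the depth-dose along
    the beamlet axis, the lateral profile, and the inverse-square factor.
    """
    body = phantom.structures["BODY"]
    vox_idx = np.flatnonzero(body.ravel())
    idx3 = np.column_stack(np.unravel_index(vox_idx, phantom.shape))
    pts = np.asarray(phantom.origin) + (idx3 + 0.5) * np.asarray(phantom.spacing)
    src = np.asarray(grid.beam.source)
    iso = np.asarray(grid.beam.isocenter)
    sad = float(np.linalg.norm(iso - src))
    rel = pts - src
    half = grid.beamlet_size / 2.0

    cols = []
    col_idx = []
    warn_empty = 0
    for jcol, (cu, cv) in enumerate(grid.centers_uv):
        target = iso + cu * grid.u_axis + cv * grid.v_axis
        dj = target - src
        dj = dj / np.linalg.norm(dj)
        axis_ray = Ray(source=tuple(src), direction=tuple(dj), isocenter=tuple(iso))
        t = rel @ dj
        lat_vec = rel - np.outer(t, dj)
        r = np.linalg.norm(lat_vec, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r_iso = r * sad / t
        near = (t > 1e-6) & (r_iso < LATERAL_CUTOFF_CM)
        if not near.any():
            warn_empty += 1
            cols.append(sp.csr_matrix((len(vox_idx), 1)))
            col_idx.append(jcol)
            continue
        tpts, wed = _axis_wed_table(phantom, axis_ray)
        depth = np.interp(t[near], tpts, wed)
        vals = (
            np.asarray(pdd_at(curve, depth)) / 100.0
            * off_axis_ratio(profile, r_iso[near], half)
            * (sad / t[near]) ** 2
        )
        cmax = vals.max() if len(vals) else 0.0
        keep = vals > drop_fraction * cmax
        rows = np.flatnonzero(near)[keep]
        col = sp.csr_matrix(
            (vals[keep], (rows, np.zeros(len(rows), dtype=int))),
            shape=(len(vox_idx), 1),
        )
        cols.append(col)
        col_idx.append(jcol)

    A = sp.hstack(cols, format="csr")

    # normalize: open-field composite = 1 at water-equivalent dmax on central axis
    axis0 = Ray(
        source=tuple(src),
        direction=tuple((iso - src) / sad),
        isocenter=tuple(iso),
    )
    tpts, wed = _axis_wed_table(phantom, axis0)
    t_dmax = float(np.interp(curve.dmax_depth, wed, tpts))
    p_star = src + t_dmax * (iso - src) / sad
    norm_val = 0.0
    for cu, cv in grid.centers_uv:
        target = iso + cu * grid.u_axis + cv * grid.v_axis
        dj = target - src
        dj = dj / np.linalg.norm(dj)
        axis_ray = Ray(source=tuple(src), direction=tuple(dj), isocenter=tuple(iso))
        relp = p_star - src
        tp = float(relp @ dj)
        rp = float(np.linalg.norm(relp - tp * dj))
        tpj, wedj = _axis_wed_table(phantom, axis_ray)
        depth = float(np.interp(tp, tpj, wedj))
        norm_val += (
            float(pdd_at(curve, depth)) / 100.0
            * float(off_axis_ratio(profile, rp * sad / tp, half))
            * (sad / tp) ** 2
        )
    if norm_val <= 0:
        raise ValueError("open-field normalization point receives no dose")
    A = A.multiply(1.0 / norm_val).tocsr()

    return DoseDepositionMatrix(
        matrix=A,
        voxel_indices=vox_idx,
        grid_shape=phantom.shape,
        metadata={
            "energy_MV": grid.energy_MV,
            "beamlet_size_cm": grid.beamlet_size,
            "drop_fraction": drop_fraction,
            "lateral_cutoff_cm": LATERAL_CUTOFF_CM,
            "empty_columns": warn_empty,
            "normalization": "open-field composite = 1 at WED dmax on axis",
        },
    )


def concat_ddc(mats: Sequence[DoseDepositionMatrix]) -> DoseDepositionMatrix:
    """Stack per-beam DDC matrices into one multi-beam matrix (shared voxels)."""
    first = mats[0]
    for m in mats[1:]:
        if not np.array_equal(m.voxel_indices, first.voxel_indices):
            raise ValueError("DDC matrices index different voxel sets")
    return DoseDepositionMatrix(
        matrix=sp.hstack([m.matrix for m in mats], format="csr"),
        voxel_indices=first.voxel_indices,
        grid_shape=first.grid_shape,
        metadata={"beams": [m.metadata for m in mats]},
    )


def accumulate_dose(A: DoseDepositionMatrix, x: np.ndarray) -> np.ndarray:
    """Superpose weighted beamlets into a dose grid (zeros outside BODY)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (A.n_beamlets,):
        raise ValueError(
            f"weight vector length {x.shape} does not match {A.n_beamlets} beamlets"
        )
    if np.any(x < 0):
        raise ValueError("beamlet weights must be nonnegative")
    d_body = A.matrix @ x
    grid = np.zeros(int(np.prod(A.grid_shape)))
    grid[A.voxel_indices] = d_body
    return grid.reshape(A.grid_shape)
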