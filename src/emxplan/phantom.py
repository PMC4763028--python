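"""Synthetic voxel phantoms: calibration slab and patient-like archetypes.

A phantom is a 3D grid of relative electron density (water = 1.0) plus named
binary structure masks.  Coordinates are right-handed patient coordinates in
cm: x lateral (+x = patient left), y anterior-posterior (+y = anterior),
z longitudinal (+z = superior).  Voxel (i, j, k) occupies the half-open box
[origin + i*spacing, origin + (i+1)*spacing) per axis.  Gantry angle 0
enters anteriorly (source on the +y side) and angles increase clockwise
viewed from the feet.

Density is assigned by region label (water 1.0, lung 0.25, bone 1.4,
air 0.001); no CT-number calibration is involved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Tuple

import h5py
import numpy as np

DENSITY_WATER = 1.0
DENSITY_LUNG = 0.25
DENSITY_BONE = 1.4
DENSITY_AIR = 0.001

ARCHETYPE_NAMES = ("lung_like", "deep_pelvic", "brain_like")


class GeometryError(ValueError):
    """Requested geometry is inconsistent (e.g. target larger than depth allows)."""


@dataclass
class VoxelPhantom:
    """Voxel grid of relative electron density with named structure masks."""

    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float]
    density: np.ndarray
    structures: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if np.any(self.density < 0):
            raise ValueError("densities must be nonnegative")
        if "BODY" not in self.structures or "PTV" not in self.structures:
            raise ValueError("phantom must define BODY and PTV masks")
        body = self.structures["BODY"]
        for name, mask in self.structures.items():
            if mask.shape != self.density.shape:
                raise ValueError(f"mask {name!r} shape mismatch")
            if not mask.any():
                raise ValueError(f"mask {name!r} is empty")
            if name != "BODY" and np.any(mask & ~body):
                raise ValueError(f"mask {name!r} extends outside BODY")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.density.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in cm^3."""
        return float(np.prod(self.spacing))

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def voxel_centers(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Meshgrid ('ij') of voxel-center coordinates."""
        return np.meshgrid(*(self.axis_centers(a) for a in range(3)), indexing="ij")

    def structure_centroid(self, name: str) -> np.ndarray:
        mask = self.structures[name]
        idx = np.argwhere(mask)
        centers = np.array(self.origin) + (idx + 0.5) * np.array(self.spacing)
        return centers.mean(axis=0)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["spacing"] = self.spacing
            f.attrs["origin"] = self.origin
            f.create_dataset("density", data=self.density, compression="gzip")
            g = f.create_group("structures")
            for name, mask in self.structures.items():
                g.create_dataset(name, data=mask.astype(np.uint8), compression="gzip")

    @classmethod
    def load(cls, path) -> "VoxelPhantom":
        with h5py.File(path, "r") as f:
            return cls(
                spacing=tuple(f.attrs["spacing"]),
                origin=tuple(f.attrs["origin"]),
                density=f["density"][...],
                structures={
                    name: ds[...].astype(bool) for name, ds in f["structures"].items()
                },
            )


def _sphere_mask(ph_centers, center, radius) -> np.ndarray:
    X, Y, Z = ph_centers
    return (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2 <= radius**2


def _cylinder_mask_z(ph_centers, cx, cy, radius) -> np.ndarray:
    X, Y, _ = ph_centers
    return (X - cx) ** 2 + (Y - cy) ** 2 <= radius**2


def make_selector_phantom(
    ep: float,
    ts: float,
    thickness: float,
    spacing: float = 0.25,
    lateral: float | None = None,
) -> VoxelPhantom:
    """Water slab with a spherical target on the central axis.

    The slab entrance face sits at y = 0 with the beam understood to travel
    in -y (posteriorly, gantry 0); the sphere of diameter ``ts`` is centered
    ``ep`` below the entrance.  This is the calibration geometry of the
    energy selector: a spherical tumor merged in water whose center lies the
    effective path length away from the entrance.
    """
    if ep < ts / 2:
        raise GeometryError(
            f"EP ({ep} cm) must be at least the tumor radius ({ts / 2} cm)"
        )
    if thickness < ep + ts / 2:
        raise GeometryError("slab thickness must cover the distal target surface")
    if lateral is None:
        lateral = max(ts + 6.0, 10.0)
    nx = nz = int(round(lateral / spacing))
    ny = int(round(thickness / spacing))
    shape = (nx, ny, nz)
    origin = (-lateral / 2, -thickness, -lateral / 2)  # entrance face at y = 0
    density = np.full(shape, DENSITY_WATER)
    ph = object.__new__(VoxelPhantom)  # centers needed before validation
    ph.spacing = (spacing,) * 3
    ph.origin = origin
    ph.density = density
    ph.structures = {}
    centers = ph.voxel_centers()
    body = np.ones(shape, dtype=bool)
    ptv = _sphere_mask(centers, (0.0, -ep, 0.0), ts / 2)
    return VoxelPhantom(
        spacing=(spacing,) * 3,
        origin=origin,
        density=density,
        structures={"BODY": body, "PTV": ptv},
    )


def make_archetype(name: str, seed: int, spacing: float = 0.25) -> VoxelPhantom:
    """Deterministic patient-like phantom archetype.

    ``lung_like``: thorax-like ellipse with low-density lungs and a small
    target inside one lung; ``deep_pelvic``: large pelvis-like cross section
    with a deep central target flanked by bony lateral structures;
    ``brain_like``: small head-like section with the target abutting serial
    organs at risk.  The seed jitters target position within +-0.5 cm so
    repeated studies are not geometrically identical, but each (name, seed)
    pair is bit-reproducible.
    """
    if name not in ARCHETYPE_NAMES:
        raise KeyError(f"unknown archetype {name!r}; choose from {ARCHETYPE_NAMES}")
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-0.5, 0.5, size=3)

    if name == "lung_like":
        rx, ry, hz = 15.0, 10.0, 6.0
    elif name == "deep_pelvic":
        rx, ry, hz = 17.0, 12.0, 6.0
    else:
        rx, ry, hz = 8.0, 9.5, 6.0

    pad = 1.0
    nx = int(round(2 * (rx + pad) / spacing))
    ny = int(round(2 * (ry + pad) / spacing))
    nz = int(round(2 * hz / spacing))
    origin = (-(rx + pad), -(ry + pad), -hz)
    ph = object.__new__(VoxelPhantom)
    ph.spacing = (spacing,) * 3
    ph.origin = origin
    ph.density = np.zeros((nx, ny, nz))
    ph.structures = {}
    C = ph.voxel_centers()
    X, Y, Z = C

    body = (X / rx) ** 2 + (Y / ry) ** 2 <= 1.0
    density = np.where(body, DENSITY_WATER, DENSITY_AIR)
    structures: Dict[str, np.ndarray] = {"BODY": body}

    if name == "lung_like":
        lung_l = ((X - 7.0) / 5.5) ** 2 + (Y / 6.5) ** 2 <= 1.0
        lung_r = ((X + 7.0) / 5.5) ** 2 + (Y / 6.5) ** 2 <= 1.0
        lung = (lung_l | lung_r) & body
        density[lung] = DENSITY_LUNG
        spine = _cylinder_mask_z(C, 0.0, -7.5, 1.5) & body
        density[spine] = DENSITY_BONE
        cord = _cylinder_mask_z(C, 0.0, -7.5, 0.6) & body
        eso = _cylinder_mask_z(C, 0.0, -4.5, 0.8) & body
        ptv_center = np.array([7.0, 1.0, 0.0]) + jitter
        ptv = _sphere_mask(C, ptv_center, 1.5) & body
        density[ptv] = DENSITY_WATER  # solid tumor inside lung
        structures.update(
            {"PTV": ptv, "LUNGS": lung, "SPINAL_CORD": cord, "ESOPHAGUS": eso}
        )
    elif name == "deep_pelvic":
        femur_l = _cylinder_mask_z(C, 11.0, -1.0, 2.2) & body
        femur_r = _cylinder_mask_z(C, -11.0, -1.0, 2.2) & body
        density[femur_l | femur_r] = DENSITY_BONE
        ptv_center = np.array([0.0, -1.0, 0.0]) + jitter
        ptv = _sphere_mask(C, ptv_center, 2.5) & body
        rectum = _cylinder_mask_z(C, 0.0, -6.5, 1.2) & body & ~ptv
        structures.update(
            {"PTV": ptv, "FEMUR_L": femur_l, "FEMUR_R": femur_r, "RECTUM": rectum}
        )
    else:  # brain_like
        skull = ((X / rx) ** 2 + (Y / ry) ** 2 > 0.88) & body
        density[skull] = DENSITY_BONE
        ptv_center = np.array([2.5, 1.5, 0.0]) + jitter
        ptv = _sphere_mask(C, ptv_center, 2.0) & body
        brainstem = _cylinder_mask_z(C, 0.0, -2.0, 1.0) & body & ~ptv
        chiasm = _sphere_mask(C, (0.0, 1.5, 0.5), 0.7) & body & ~ptv
        structures.update({"PTV": ptv, "BRAINSTEM": brainstem, "CHIASM": chiasm})

    return VoxelPhantom(
        spacing=(spacing,) * 3, origin=origin, density=density, structures=structures
    )
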