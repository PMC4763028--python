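"""Plan evaluation: DVHs, dose-volume metrics, normalization and comparison.

Plans are normalized so the 100% isodose (the prescription) covers 95% of
the target volume, i.e. the dose grid is rescaled so D95% of the PTV equals
the prescription.  All metrics are computed from the exact sorted voxel
doses (no binning): Dq% uses the inverse empirical CDF with linear
interpolation, VxGy counts voxels at or above the threshold, and the
homogeneity index is HI = (D2% - D98%) / D50% (smaller = more homogeneous).
Integral dose over normal tissue (BODY excluding PTV) is reported both as
the mean dose in Gy and as the dose-volume product in Gy.L.

Side-by-side comparison of two plans (e.g. energy-modulated vs fixed-energy)
uses the relative difference 100% x (index_b - index_a) / index_a.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .phantom import VoxelPhantom


class EmptyStructureError(ValueError):
    """Metric requested for an empty structure mask."""


@dataclass
class DVH:
    """Cumulative dose-volume histogram stored as the exact sorted doses."""

    structure: str
    doses_sorted: np.ndarray
    voxel_volume: float

    @property
    def n_voxels(self) -> int:
        return len(self.doses_sorted)

    @property
    def volume_cc(self) -> float:
        return self.n_voxels * self.voxel_volume

    def volume_fraction_at_least(self, dose: float) -> float:
        """Percent of the structure receiving at least ``dose``."""
        n_ge = self.n_voxels - np.searchsorted(self.doses_sorted, dose, side="left")
        return 100.0 * n_ge / self.n_voxels

    def curve(self, edges: Optional[np.ndarray] = None) -> pd.DataFrame:
        """Cumulative curve sampled on dose bin edges (default 0.05 Gy)."""
        if edges is None:
            top = float(self.doses_sorted[-1]) if self.n_voxels else 0.0
            edges = np.arange(0.0, top + 0.1, 0.05)
        vols = [self.volume_fraction_at_least(e) for e in edges]
        return pd.DataFrame({"dose_Gy": edges, "volume_pct": vols})


def compute_dvh(
    dose: np.ndarray, mask: np.ndarray, voxel_volume: float, structure: str = ""
) -> DVH:
    """Empirical cumulative DVH of a structure."""
    if not mask.any():
        raise EmptyStructureError(f"structure {structure!r} has no voxels")
    vals = np.sort(np.asarray(dose)[mask].ravel())
    return DVH(structure=structure, doses_sorted=vals, voxel_volume=voxel_volume)


def dose_at_volume(dvh: DVH, q: float) -> float:
    """Dq%: the largest dose received by at least q% of the volume.

    Inverse empirical CDF with linear interpolation between sorted voxel
    doses (the hottest q% of the volume receives at least this dose).
    """
    if not (0.0 < q < 100.0):
        raise ValueError("volume percentage must lie in (0, 100)")
    return float(np.quantile(dvh.doses_sorted, 1.0 - q / 100.0, method="linear"))


def v_dose(dvh: DVH, threshold: float) -> float:
    """VxGy: percent of the structure receiving at least ``threshold`` Gy."""
    if threshold < 0:
        raise ValueError("dose threshold must be nonnegative")
    return dvh.volume_fraction_at_least(threshold)


def homogeneity_index(d2: float, d98: float, d50: float) -> float:
    """HI = (D2% - D98%) / D50%."""
    if d50 <= 0:
        raise ValueError("D50% must be positive")
    if d2 < d98:
        raise ValueError("D2% must be at least D98%")
    return (d2 - d98) / d50


def normalize_plan(
    dose: np.ndarray, ptv_mask: np.ndarray, prescription: float, voxel_volume: float = 1.0
) -> np.ndarray:
    """Scale the dose grid so the prescription isodose covers 95% of the PTV."""
    dvh = compute_dvh(dose, ptv_mask, voxel_volume, "PTV")
    d95 = dose_at_volume(dvh, 95.0)
    if d95 <= 0:
        raise ValueError("PTV D95% of the raw plan is not positive")
    return dose * (prescription / d95)


def integral_dose(
    dose: np.ndarray,
    body_mask: np.ndarray,
    ptv_mask: np.ndarray,
    voxel_volume: float,
) -> Tuple[float, float]:
    """Normal-tissue integral dose: (mean Gy over BODY minus PTV, Gy.L)."""
    region = body_mask & ~ptv_mask
    n = int(region.sum())
    if n == 0:
        raise EmptyStructureError("BODY minus PTV region is empty")
    total = float(np.asarray(dose)[region].sum())
    mean = total / n
    gy_l = total * voxel_volume / 1000.0
    return mean, gy_l


def relative_difference(index_b: float, index_a: float) -> float:
    """100% x (index_b - index_a) / index_a; ``nan`` when index_a is zero."""
    if index_a == 0:
        return float("nan")
    return 100.0 * (index_b - index_a) / index_a


def plan_metrics(
    dose: np.ndarray,
    phantom: VoxelPhantom,
    prescription: float,
    oar_vdose_levels: Iterable[float] = (),
) -> pd.DataFrame:
    """Standard metric table: one row per (structure, index).

    Target rows: Dmean, D2%, D50%, D95%, D98% (Gy, 1 decimal in reports) and
    HI; OAR rows: Dmean, Dmax and any requested VxGy levels; plus the
    normal-tissue integral dose in both conventions.
    """
    vv = phantom.voxel_volume
    rows = []
    ptv = phantom.structures["PTV"]
    dvh_t = compute_dvh(dose, ptv, vv, "PTV")
    d2 = dose_at_volume(dvh_t, 2.0)
    d50 = dose_at_volume(dvh_t, 50.0)
    d95 = dose_at_volume(dvh_t, 95.0)
    d98 = dose_at_volume(dvh_t, 98.0)
    rows += [
        ("PTV", "D95%", d95),
        ("PTV", "Dmean", float(dvh_t.doses_sorted.mean())),
        ("PTV", "D98%", d98),
        ("PTV", "D2%", d2),
        ("PTV", "D50%", d50),
        ("PTV", "HI", homogeneity_index(d2, d98, d50)),
    ]
    for name, mask in phantom.structures.items():
        if name in ("BODY", "PTV"):
            continue
        dvh = compute_dvh(dose, mask, vv, name)
        rows.append((name, "Dmean", float(dvh.doses_sorted.mean())))
        rows.append((name, "Dmax", float(dvh.doses_sorted[-1])))
        for lvl in oar_vdose_levels:
            rows.append((name, f"V{lvl:g}Gy", v_dose(dvh, lvl)))
    mean_gy, gy_l = integral_dose(dose, phantom.structures["BODY"], ptv, vv)
    rows.append(("NORMAL_TISSUE", "IntegralDose_meanGy", mean_gy))
    rows.append(("NORMAL_TISSUE", "IntegralDose_GyL", gy_l))
    return pd.DataFrame(rows, columns=["structure", "index", "value"])


def compare_plans(metrics_a: pd.DataFrame, metrics_b: pd.DataFrame) -> pd.DataFrame:
    """Side-by-side comparison with the relative-difference column.

    ``a`` is the baseline (e.g. the fixed-energy plan); positive relative
    differences mean plan ``b`` has the larger index.
    """
    merged = metrics_a.merge(
        metrics_b, on=["structure", "index"], suffixes=("_a", "_b")
    )
    merged["relative_difference_pct"] = [
        round(relative_difference(b, a), 1)
        for a, b in zip(merged["value_a"], merged["value_b"])
    ]
    return merged
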