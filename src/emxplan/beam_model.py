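"""Per-energy photon beam models: depth-dose curves and lateral profiles.

Each nominal accelerating potential in the pool (2, 3, 4, 5, 6 and 10 MV)
is represented by a percent-depth-dose (PDD) curve anchored to published
Monte Carlo water-phantom data (10 x 10 cm field, 100 cm SSD) and by a
flat-core / error-function-penumbra off-axis profile.  The PDD curve is a
monotone shape-preserving (PCHIP) interpolant through the anchors on
[0, 30] cm with a single-exponential tail beyond the last anchor, so every
printed anchor is reproduced exactly and no physics parameters are invented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.special import erf

#: Nominal energies (MV) of the default beam pool.
ENERGY_POOL: Tuple[int, ...] = (2, 3, 4, 5, 6, 10)

#: Source-to-axis distance in cm (isocentric machine convention).
SAD: float = 100.0

#: Default penumbra sigma (cm) per nominal energy.
DEFAULT_PENUMBRA_SIGMA: Dict[int, float] = {2: 0.3, 3: 0.3, 4: 0.3, 5: 0.3, 6: 0.3, 10: 0.4}


class InsufficientDataError(ValueError):
    """Fewer depth-dose anchors than the fit requires."""


class InvalidAnchorError(ValueError):
    """Anchor set violates monotonicity or normalization requirements."""


@dataclass(frozen=True)
class PDDAnchorSet:
    """Printed depth-dose anchors for one nominal energy.

    ``depth_at_percent`` holds (percent dose, depth cm) pairs — the depths at
    which the curve crosses given percent levels, including the 100% / dmax
    pair.  ``percent_at_depth`` holds (depth cm, percent dose) pairs,
    including the surface dose at depth 0.  ``measured`` optionally carries
    ion-chamber measurements as metadata; the model is fitted to the
    simulated values only.
    """

    energy_label: float
    depth_at_percent: Tuple[Tuple[float, float], ...]
    percent_at_depth: Tuple[Tuple[float, float], ...]
    measured: Tuple[Tuple[str, float, float], ...] = ()

    def __post_init__(self) -> None:
        percents = [p for p, _ in self.depth_at_percent]
        if any(not (0.0 < p <= 100.0) for p in percents):
            raise InvalidAnchorError("percent values must lie in (0, 100]")
        if sum(1 for p in percents if p == 100.0) != 1:
            raise InvalidAnchorError("exactly one 100% (dmax) anchor is required")
        if any(d < 0 for _, d in self.depth_at_percent) or any(
            d < 0 for d, _ in self.percent_at_depth
        ):
            raise InvalidAnchorError("depths must be nonnegative")

    @property
    def dmax_depth(self) -> float:
        return next(d for p, d in self.depth_at_percent if p == 100.0)

    def as_depth_percent_pairs(self) -> List[Tuple[float, float]]:
        """All anchors merged as (depth, percent), sorted by depth."""
        pts: Dict[float, float] = {}
        for p, d in self.depth_at_percent:
            pts[float(d)] = float(p)
        for d, p in self.percent_at_depth:
            pts[float(d)] = float(p)
        return sorted(pts.items())


@dataclass(frozen=True)
class PDDCurve:
    """Percent depth dose vs depth, normalized to 100 at dmax."""

    energy_label: float
    dmax_depth: float
    _evaluator: Callable[[np.ndarray], np.ndarray]
    max_anchor_depth: float = 30.0

    def __call__(self, depth):
        return pdd_at(self, depth)


@dataclass(frozen=True)
class BeamProfile:
    """Off-axis ratio model: flat core with error-function penumbra.

    The ratio is the convolution of an ideal rectangular field of the given
    half-width with a Gaussian of standard deviation ``sigma`` (cm), which
    gives exactly 0.5 at the geometric field edge.  Horn-shaped unevenness of
    real open fields is deliberately not modeled: beamlet weighting during
    inverse planning absorbs fluence non-flatness.
    """

    energy_label: float
    reference_depth: float = 10.0
    sigma: float = 0.3

    def __call__(self, x, half_width):
        return off_axis_ratio(self, x, half_width)


@dataclass(frozen=True)
class BeamQuality:
    """TPR20,10 beam-quality index (approximated as %D(20)/%D(10))."""

    energy_label: float
    tpr_20_10: float

    def __post_init__(self) -> None:
        if not (0.0 < self.tpr_20_10):
            raise ValueError("TPR20,10 must be positive")


def load_anchor_sets(source=None) -> Dict[int, PDDAnchorSet]:
    """Load the packaged beam-data fixture (or a user CSV of the same layout).

    The CSV has columns ``energy_MV, kind, key, value`` where kind is
    ``depth_at_percent`` (key = percent, value = depth cm) or
    ``percent_at_depth`` (key = depth cm, value = percent); ``measured_*``
    rows are carried along as metadata.
    """
    if source is None:
        with resources.files("emxplan.data").joinpath("beam_anchors.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(source)
    out: Dict[int, PDDAnchorSet] = {}
    for energy, grp in df.groupby("energy_MV"):
        dap = tuple(
            (float(r.key), float(r.value))
            for r in grp[grp.kind == "depth_at_percent"].itertuples()
        )
        pad = tuple(
            (float(r.key), float(r.value))
            for r in grp[grp.kind == "percent_at_depth"].itertuples()
        )
        meas = tuple(
            (str(r.kind), float(r.key), float(r.value))
            for r in grp[grp.kind.str.startswith("measured")].itertuples()
        )
        out[int(energy)] = PDDAnchorSet(
            energy_label=float(energy),
            depth_at_percent=dap,
            percent_at_depth=pad,
            measured=meas,
        )
    return out


def fit_pdd(anchors: PDDAnchorSet) -> PDDCurve:
    """Fit a monotone shape-preserving depth-dose curve through the anchors.

    PCHIP interpolation on the anchor support guarantees the curve passes
    through every anchor and preserves the rise to dmax / monotone fall-off
    beyond it.  Past the deepest anchor the curve decays exponentially with
    the rate fitted to the last two anchors.
    """
    pts = anchors.as_depth_percent_pairs()
    if len(pts) < 4:
        raise InsufficientDataError(
            f"need at least 4 distinct anchor depths, got {len(pts)}"
        )
    depths = np.array([d for d, _ in pts])
    percents = np.array([p for _, p in pts])
    dmax = anchors.dmax_depth
    beyond = percents[depths >= dmax]
    if np.any(np.diff(beyond) > 0):
        raise InvalidAnchorError("anchors beyond dmax must be nonincreasing")
    before = percents[depths <= dmax]
    if np.any(np.diff(before) < 0):
        raise InvalidAnchorError("anchors before dmax must be nondecreasing")

    interp = PchipInterpolator(depths, percents, extrapolate=False)
    d_last, p_last = depths[-1], percents[-1]
    d_prev, p_prev = depths[-2], percents[-2]
    mu = math.log(p_prev / p_last) / (d_last - d_prev)  # tail decay (1/cm)

    def evaluator(depth: np.ndarray) -> np.ndarray:
        depth = np.asarray(depth, dtype=float)
        inside = np.clip(depth, depths[0], d_last)
        vals = np.asarray(interp(inside), dtype=float)
        tail = p_last * np.exp(-mu * (depth - d_last))
        return np.where(depth > d_last, tail, vals)

    return PDDCurve(
        energy_label=anchors.energy_label,
        dmax_depth=float(dmax),
        _evaluator=evaluator,
        max_anchor_depth=float(d_last),
    )


def pdd_at(curve: PDDCurve, depth) -> np.ndarray | float:
    """Percent dose at the given depth(s) in cm (>= 0)."""
    arr = np.asarray(depth, dtype=float)
    if np.any(arr < 0):
        raise ValueError("depth must be nonnegative")
    out = curve._evaluator(arr)
    if np.isscalar(depth) or arr.ndim == 0:
        return float(out)
    return out


def tpr_20_10(curve: PDDCurve) -> BeamQuality:
    """Beam-quality index %D(20)/%D(10) of the curve."""
    if curve.max_anchor_depth < 20.0:
        raise ValueError("curve must be anchored to at least 20 cm depth")
    ratio = pdd_at(curve, 20.0) / pdd_at(curve, 10.0)
    return BeamQuality(energy_label=curve.energy_label, tpr_20_10=float(ratio))


def off_axis_ratio(profile: BeamProfile, x, half_width: float):
    """Off-axis ratio at lateral distance x (cm) for a field of given half-width.

    Rectangular fluence convolved with a Gaussian penumbra:
    ``0.5 * (erf((w - x) / (sigma*sqrt2)) + erf((w + x) / (sigma*sqrt2)))``.
    Symmetric in x; exactly 0.5 at the field edge; -> 0 far off axis.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    x = np.abs(np.asarray(x, dtype=float))
    s = profile.sigma * math.sqrt(2.0)
    out = 0.5 * (erf((half_width - x) / s) + erf((half_width + x) / s))
    if out.ndim == 0:
        return float(out)
    return out


def default_curves(source=None) -> Dict[int, PDDCurve]:
    """Fitted PDD curves for the whole default pool."""
    return {e: fit_pdd(a) for e, a in load_anchor_sets(source).items()}


def default_profiles() -> Dict[int, BeamProfile]:
    """Default lateral profiles for the pool."""
    return {
        e: BeamProfile(energy_label=float(e), sigma=DEFAULT_PENUMBRA_SIGMA[e])
        for e in ENERGY_POOL
    }
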