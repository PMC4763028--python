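"""Beamlet-weight optimization: dose-volume-constrained steepest descent.

The objective is quadratic in the dose: a least-squares term pulling every
target voxel to the prescription, plus penalty terms for violated
dose-volume (DV) constraints on the target and on each critical structure,
all DV penalties scaled by a factor r that escalates as iterations proceed,

    F(x, r) = sum_target (d_i - p0)^2
            + r * sum_k w_k     * sum_target  delta_i (d_i - p_k)^2
            + r * sum_n w_n     * sum_k w_nk * sum_struct delta_i (d_i - p_nk)^2,

where d = A x and delta_i flags voxels that violate the constraint.  The
volume bookkeeping completes the per-point flag definition: for an upper
constraint (at most v% of the structure above dose p) the hottest v% of
voxels are permitted above p and only the remaining voxels above p are
flagged; lower (coverage) constraints mirror this on the coldest fraction.

Weights are optimized by projected steepest descent (nonnegativity is
enforced by projection) with Armijo backtracking line search, starting from
the target's beam's-eye-view aperture (intensity one inside, zero outside)
as the initial guess.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .dose import DoseDepositionMatrix
from .phantom import VoxelPhantom
from .raytrace import Ray, trace_four_points, NoTargetError


class ConfigurationError(ValueError):
    """Objective references a structure the phantom does not define."""


@dataclass(frozen=True)
class DVConstraint:
    """One dose-volume constraint on a named structure.

    ``direction='upper'``: at most ``volume_percent`` of the structure may
    exceed ``dose``; ``'lower'``: at most ``volume_percent`` may fall below
    ``dose`` (target coverage).
    """

    structure: str
    dose: float
    volume_percent: float
    direction: str = "upper"
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("constraint dose must be nonnegative")
        if not (0.0 < self.volume_percent < 100.0):
            raise ValueError("volume fraction must lie in (0, 100)")
        if self.direction not in ("upper", "lower"):
            raise ValueError("direction must be 'upper' or 'lower'")
        if self.weight < 0:
            raise ValueError("constraint weight must be nonnegative")


@dataclass
class PlanObjective:
    """Prescription, DV constraints and penalty bookkeeping for one plan."""

    prescription: float
    target: str = "PTV"
    target_constraints: Tuple[DVConstraint, ...] = ()
    oar_constraints: Dict[str, Tuple[DVConstraint, ...]] = field(default_factory=dict)
    oar_weights: Dict[str, float] = field(default_factory=dict)
    r_initial: float = 1.0

    def __post_init__(self) -> None:
        if self.prescription <= 0:
            raise ValueError("prescription must be positive")
        if len(self.target_constraints) > 2:
            raise ValueError("at most two target DV constraints are supported")
        if self.r_initial <= 0:
            raise ValueError("penalty factor r must be positive")

    @classmethod
    def with_default_target_bounds(
        cls,
        prescription: float,
        oar_constraints: Optional[Dict[str, Tuple[DVConstraint, ...]]] = None,
        oar_weights: Optional[Dict[str, float]] = None,
        lower_factor: float = 0.98,
        upper_factor: float = 1.08,
    ) -> "PlanObjective":
        """Objective with the conventional target DV band around p0.

        Coverage: at most 2% of the target below ``lower_factor * p0``;
        hot spots: at most 2% above ``upper_factor * p0``.
        """
        tcs = (
            DVConstraint("PTV", lower_factor * prescription, 2.0, "lower", 1.0),
            DVConstraint("PTV", upper_factor * prescription, 2.0, "upper", 1.0),
        )
        return cls(
            prescription=prescription,
            target_constraints=tcs,
            oar_constraints=oar_constraints or {},
            oar_weights=oar_weights or {},
        )


@dataclass
class ViolationFlags:
    """delta_i flags per constraint: 1 where the constraint is violated."""

    target: Tuple[np.ndarray, ...] = ()
    oars: Dict[str, Tuple[np.ndarray, ...]] = field(default_factory=dict)


@dataclass
class OptimizerControls:
    max_iterations: int = 500
    rel_tolerance: float = 1e-5
    tolerance_window: int = 5
    r_multiplier: float = 2.0
    r_every: int = 20
    time_limit_s: Optional[float] = None
    armijo_c: float = 1e-4
    initial_step: float = 1.0
    #: every this many iterations, minimize the frozen-flag quadratic over
    #: the free variables (conjugate-gradient subspace polish); 0 disables.
    subspace_every: int = 5


@dataclass
class OptimizerState:
    iterations: int = 0
    objective_history: List[float] = field(default_factory=list)
    r_history: List[float] = field(default_factory=list)
    stop_reason: str = ""
    x: Optional[np.ndarray] = None


def structure_rows(
    A: DoseDepositionMatrix, phantom: VoxelPhantom, name: str
) -> np.ndarray:
    """Row indices (into the BODY-voxel dose vector) of a named structure."""
    if name not in phantom.structures:
        raise ConfigurationError(f"structure {name!r} not defined in the phantom")
    mask_flat = phantom.structures[name].ravel()
    return np.flatnonzero(mask_flat[A.voxel_indices])


def _dv_flags(doses: np.ndarray, c: DVConstraint) -> np.ndarray:
    """Per-voxel violation flags with DVH volume bookkeeping."""
    n = len(doses)
    n_allowed = int(np.floor(c.volume_percent / 100.0 * n))
    ranks = np.empty(n, dtype=int)
    if c.direction == "upper":
        order = np.argsort(doses, kind="stable")[::-1]  # hottest first
        ranks[order] = np.arange(n)
        return (doses > c.dose) & (ranks >= n_allowed)
    order = np.argsort(doses, kind="stable")  # coldest first
    ranks[order] = np.arange(n)
    return (doses < c.dose) & (ranks >= n_allowed)


def evaluate_objective(
    x: np.ndarray,
    A: DoseDepositionMatrix,
    obj: PlanObjective,
    phantom: VoxelPhantom,
    r: Optional[float] = None,
) -> Tuple[float, ViolationFlags]:
    """Objective value and the violation flags at the current weights."""
    r = obj.r_initial if r is None else r
    d = A.matrix @ np.asarray(x, dtype=float)
    t_rows = structure_rows(A, phantom, obj.target)
    dt = d[t_rows]
    value = float(np.sum((dt - obj.prescription) ** 2))

    t_flags = []
    for c in obj.target_constraints:
        f = _dv_flags(dt, c)
        t_flags.append(f)
        value += r * c.weight * float(np.sum(f * (dt - c.dose) ** 2))

    oar_flags: Dict[str, Tuple[np.ndarray, ...]] = {}
    for name, cs in obj.oar_constraints.items():
        rows = structure_rows(A, phantom, name)
        dn = d[rows]
        wn = obj.oar_weights.get(name, 1.0)
        fl = []
        for c in cs:
            f = _dv_flags(dn, c)
            fl.append(f)
            value += r * wn * c.weight * float(np.sum(f * (dn - c.dose) ** 2))
        oar_flags[name] = tuple(fl)

    return value, ViolationFlags(target=tuple(t_flags), oars=oar_flags)


def objective_gradient(
    x: np.ndarray,
    A: DoseDepositionMatrix,
    obj: PlanObjective,
    phantom: VoxelPhantom,
    r: Optional[float] = None,
    flags: Optional[ViolationFlags] = None,
) -> np.ndarray:
    """Gradient of the objective w.r.t. the beamlet weights.

    Violation flags are held fixed (subgradient convention at the DVH
    switching surfaces); if not supplied they are computed at x.
    """
    r = obj.r_initial if r is None else r
    x = np.asarray(x, dtype=float)
    d = A.matrix @ x
    if flags is None:
        _, flags = evaluate_objective(x, A, obj, phantom, r)
    resid = np.zeros_like(d)
    t_rows = structure_rows(A, phantom, obj.target)
    dt = d[t_rows]
    rt = 2.0 * (dt - obj.prescription)
    for c, f in zip(obj.target_constraints, flags.target):
        rt += r * c.weight * 2.0 * f * (dt - c.dose)
    resid[t_rows] = rt
    for name, cs in obj.oar_constraints.items():
        rows = structure_rows(A, phantom, name)
        dn = d[rows]
        wn = obj.oar_weights.get(name, 1.0)
        rn = np.zeros_like(dn)
        for c, f in zip(cs, flags.oars[name]):
            rn += r * wn * c.weight * 2.0 * f * (dn - c.dose)
        resid[rows] += rn
    return A.matrix.T @ resid


def ciao_init(
    grid, phantom: VoxelPhantom, A: Optional[DoseDepositionMatrix] = None
) -> np.ndarray:
    """Aperture initialization: weight 1 for beamlets aimed at the target.

    The aperture is the target's beam's-eye-view projection: a beamlet is
    inside it when its axis ray crosses the PTV mask.  A beam that misses
    the target entirely yields an all-zero start (with a warning flag in
    the returned array's writeable state left untouched).
    """
    import warnings

    src = np.asarray(grid.beam.source)
    iso = np.asarray(grid.beam.isocenter)
    x = np.zeros(grid.n_beamlets)
    for j, (cu, cv) in enumerate(grid.centers_uv):
        target = iso + cu * grid.u_axis + cv * grid.v_axis
        dj = target - src
        dj = dj / np.linalg.norm(dj)
        ray = Ray(source=tuple(src), direction=tuple(dj), isocenter=tuple(iso))
        try:
            trace_four_points(phantom, ray)
        except NoTargetError:
            continue
        except Exception:
            continue
        x[j] = 1.0
    if not x.any():
        warnings.warn("beam does not intersect the target: all-zero aperture init")
    return x


def optimize(
    A: DoseDepositionMatrix,
    obj: PlanObjective,
    phantom: VoxelPhantom,
    init: np.ndarray,
    controls: OptimizerControls = OptimizerControls(),
) -> Tuple[np.ndarray, OptimizerState]:
    """Projected steepest descent with escalating DV penalties.

    At each iteration the violation flags are frozen, a backtracking Armijo
    line search is taken along the projected negative gradient, and the
    penalty factor r doubles every ``r_every`` iterations.  Stops when the
    objective is nearly unchanged for ``tolerance_window`` consecutive
    iterations, at the iteration cap, or at the wall-clock limit.
    """
    x = np.maximum(np.asarray(init, dtype=float), 0.0)
    r = obj.r_initial
    state = OptimizerState()
    t0 = time.monotonic()
    f_cur, flags = evaluate_objective(x, A, obj, phantom, r)
    if not np.isfinite(f_cur):
        raise FloatingPointError(f"non-finite objective at init: {f_cur}")
    state.objective_history.append(f_cur)
    state.r_history.append(r)
    step = controls.initial_step
    stall = 0

    for it in range(controls.max_iterations):
        if it > 0 and it % controls.r_every == 0:
            r *= controls.r_multiplier
            f_cur, flags = evaluate_objective(x, A, obj, phantom, r)
        g = objective_gradient(x, A, obj, phantom, r, flags)
        gnorm2 = float(g @ g)
        if gnorm2 == 0.0:
            state.stop_reason = "converged"
            break

        # With flags frozen the objective is quadratic, so the exact
        # minimizer along -g is gnorm2 / (2 * curvature); backtrack from
        # there to honor the nonnegativity projection.
        curv = _curvature_along(g, A, obj, phantom, r, flags)
        alpha = gnorm2 / (2.0 * curv) if curv > 0 else step
        accepted = False
        for _ in range(40):
            x_new = np.maximum(x - alpha * g, 0.0)
            f_new = _objective_fixed_flags(x_new, A, obj, phantom, r, flags)
            decrease = f_cur - f_new
            needed = controls.armijo_c * float(g @ (x - x_new))
            if decrease >= needed and f_new <= f_cur:
                accepted = True
                break
            alpha *= 0.5
        if not np.isfinite(f_new):
            raise FloatingPointError(
                f"non-finite objective at iteration {it}: {f_new}"
            )
        if accepted:
            x = x_new
            step = alpha

        # periodic subspace polish: with flags frozen the objective is a
        # linear least-squares problem; minimizing it over the currently
        # free variables (x > 0 or pushed inward by the gradient) and
        # backtracking the projected step keeps descent monotone while
        # sidestepping the slow tail of plain gradient iterations.
        if controls.subspace_every and (it + 1) % controls.subspace_every == 0:
            x, f_pol = _subspace_polish(x, A, obj, phantom, r, flags)
        # refresh flags at the new point
        f_next, flags = evaluate_objective(x, A, obj, phantom, r)
        state.iterations = it + 1
        state.objective_history.append(f_next)
        state.r_history.append(r)

        rel = abs(f_cur - f_next) / max(abs(f_cur), 1e-30)
        f_cur = f_next
        if rel < controls.rel_tolerance:
            stall += 1
            if stall >= controls.tolerance_window:
                state.stop_reason = "converged"
                break
        else:
            stall = 0
        if (
            controls.time_limit_s is not None
            and time.monotonic() - t0 > controls.time_limit_s
        ):
            state.stop_reason = "time_limit"
            break
    else:
        state.stop_reason = "max_iter"
    if not state.stop_reason:
        state.stop_reason = "converged"
    state.x = x
    return x, state


def _stacked_system(
    A: DoseDepositionMatrix,
    obj: PlanObjective,
    phantom: VoxelPhantom,
    r: float,
    flags: ViolationFlags,
):
    """The frozen-flag objective as one least-squares system ||M x - b||^2."""
    import scipy.sparse as sp

    t_rows = structure_rows(A, phantom, obj.target)
    blocks = [A.matrix[t_rows]]
    rhs = [np.full(len(t_rows), obj.prescription)]
    for c, f in zip(obj.target_constraints, flags.target):
        idx = t_rows[f]
        if len(idx):
            w = np.sqrt(r * c.weight)
            blocks.append(A.matrix[idx] * w)
            rhs.append(np.full(len(idx), w * c.dose))
    for name, cs in obj.oar_constraints.items():
        rows = structure_rows(A, phantom, name)
        wn = obj.oar_weights.get(name, 1.0)
        for c, f in zip(cs, flags.oars[name]):
            idx = rows[f]
            if len(idx):
                w = np.sqrt(r * wn * c.weight)
                blocks.append(A.matrix[idx] * w)
                rhs.append(np.full(len(idx), w * c.dose))
    return sp.vstack(blocks, format="csr"), np.concatenate(rhs)


def _subspace_polish(
    x: np.ndarray,
    A: DoseDepositionMatrix,
    obj: PlanObjective,
    phantom: VoxelPhantom,
    r: float,
    flags: ViolationFlags,
) -> Tuple[np.ndarray, float]:
    """One Moré-Toraldo-style subspace minimization of the frozen-flag
    quadratic over the free variables, with monotone projected backtracking."""
    from scipy.sparse.linalg import lsmr

    g = objective_gradient(x, A, obj, phantom, r, flags)
    free = (x > 0) | (g < 0)
    if not free.any():
        return x, _objective_fixed_flags(x, A, obj, phantom, r, flags)
    M, b = _stacked_system(A, obj, phantom, r, flags)
    resid = b - M @ x
    dx = lsmr(M[:, free].tocsc(), resid, atol=1e-10, btol=1e-10, maxiter=500)[0]
    d = np.zeros_like(x)
    d[free] = dx
    f_cur = _objective_fixed_flags(x, A, obj, phantom, r, flags)
    step = 1.0
    for _ in range(50):
        x_new = np.maximum(x + step * d, 0.0)
        f_new = _objective_fixed_flags(x_new, A, obj, phantom, r, flags)
        if f_new <= f_cur:
            return x_new, f_new
        step *= 0.5
    return x, f_cur


def _curvature_along(
    p: np.ndarray,
    A: DoseDepositionMatrix,
    obj: PlanObjective,
    phantom: VoxelPhantom,
    r: float,
    flags: ViolationFlags,
) -> float:
    """Quadratic-form curvature sum_s w_s ||M_s p||^2 of the frozen-flag
    objective along direction p (one sparse matvec)."""
    dp = A.matrix @ np.asarray(p, dtype=float)
    t_rows = structure_rows(A, phantom, obj.target)
    dpt = dp[t_rows]
    curv = float(np.sum(dpt**2))
    for c, f in zip(obj.target_constraints, flags.target):
        curv += r * c.weight * float(np.sum(f * dpt**2))
    for name, cs in obj.oar_constraints.items():
        rows = structure_rows(A, phantom, name)
        dpn = dp[rows]
        wn = obj.oar_weights.get(name, 1.0)
        for c, f in zip(cs, flags.oars[name]):
            curv += r * wn * c.weight * float(np.sum(f * dpn**2))
    return curv


def _objective_fixed_flags(
    x: np.ndarray,
    A: DoseDepositionMatrix,
    obj: PlanObjective,
    phantom: VoxelPhantom,
    r: float,
    flags: ViolationFlags,
) -> float:
    """Objective with the delta flags held fixed (line-search surrogate)."""
    d = A.matrix @ np.asarray(x, dtype=float)
    t_rows = structure_rows(A, phantom, obj.target)
    dt = d[t_rows]
    value = float(np.sum((dt - obj.prescription) ** 2))
    for c, f in zip(obj.target_constraints, flags.target):
        value += r * c.weight * float(np.sum(f * (dt - c.dose) ** 2))
    for name, cs in obj.oar_constraints.items():
        rows = structure_rows(A, phantom, name)
        dn = d[rows]
        wn = obj.oar_weights.get(name, 1.0)
        for c, f in zip(cs, flags.oars[name]):
            value += r * wn * c.weight * float(np.sum(f * (dn - c.dose) ** 2))
    return value
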