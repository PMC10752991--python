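"""Via-point routing calibration against reference moment-arm curves.

Model moment-arm curves (tendon excursion method) are fitted to
reference curves by moving the palmar depth of the via points, scored
with the mean absolute error (MAE) and the MAE normalized to the mean
of the measured data (NMAE, reported in percent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .hand import JOINT_NAMES, DigitGeometry, HandModel, RoutingPath, path_length

__all__ = [
    "MomentArmCurve",
    "RoutingFitResult",
    "nmae",
    "curve_moment_arms",
    "optimize_routing",
    "summarize_fit",
]


@dataclass(frozen=True)
class MomentArmCurve:
    """One (digit, muscle, joint) moment-arm curve sampled over joint angle.

    Angles are radians (strictly increasing grid, >= 3 samples), arms in
    meters.  The curve is defined with all other joints of the digit held
    straight (q = 0).
    """

    digit: int
    muscle: str
    joint: str  # "MCP" | "PIP" | "DIP"
    angles: np.ndarray
    arms: np.ndarray
    source: str = "reference"

    def __post_init__(self) -> None:
        object.__setattr__(self, "angles", np.asarray(self.angles, dtype=float))
        object.__setattr__(self, "arms", np.asarray(self.arms, dtype=float))
        if self.joint not in JOINT_NAMES:
            raise ValueError(f"unknown joint {self.joint!r}")
        if self.angles.size < 3:
            raise ValueError("a moment-arm curve needs >= 3 samples")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angle grid must be strictly increasing")
        if self.angles.shape != self.arms.shape:
            raise ValueError("angles and arms must have equal length")

    @property
    def joint_idx(self) -> int:
        return JOINT_NAMES.index(self.joint)


@dataclass
class RoutingFitResult:
    paths: dict[int, RoutingPath]  # optimized path per digit
    per_curve: dict[tuple[int, str, str], tuple[float, float]]  # (mae m, nmae %)
    iterations: int
    converged: bool

    @property
    def nmae_values(self) -> list[float]:
        return [v[1] for v in self.per_curve.values()]


def nmae(pred, meas) -> tuple[float, float]:
    """(MAE, NMAE %) of predictions against measurements.

    MAE = mean |pred - meas|; NMAE = MAE / mean(meas), reported as a
    percentage.  NMAE is invariant under a common positive rescaling of
    both series; it is undefined (error) when the measured mean is zero.
    """
    pred = np.asarray(pred, dtype=float)
    meas = np.asarray(meas, dtype=float)
    if pred.shape != meas.shape or pred.size == 0:
        raise ValueError("pred and meas must be non-empty and of equal length")
    mean_meas = meas.mean()
    if mean_meas == 0:
        raise ValueError("normalization undefined: mean of measured data is zero")
    mae = float(np.abs(pred - meas).mean())
    return mae, 100.0 * mae / mean_meas


def curve_moment_arms(
    digit: DigitGeometry,
    path: RoutingPath,
    joint_idx: int,
    angles: np.ndarray,
    h: float = 1e-6,
) -> np.ndarray:
    """Moment arms over an angle grid of one joint (other joints straight)."""
    angles = np.asarray(angles, dtype=float)
    q = np.zeros((angles.size, 3))
    q[:, joint_idx] = angles
    qp, qm = q.copy(), q.copy()
    qp[:, joint_idx] += h
    qm[:, joint_idx] -= h
    return -(path_length(digit, path, qp) - path_length(digit, path, qm)) / (2 * h)


def _resample(curve: MomentArmCurve, step_deg: float = 2.0):
    """Common evaluation grid: linear interpolation onto a 2-degree grid."""
    step = np.deg2rad(step_deg)
    lo, hi = curve.angles[0], curve.angles[-1]
    n = max(int(round((hi - lo) / step)) + 1, 3)
    grid = np.linspace(lo, hi, n)
    return grid, np.interp(grid, curve.angles, curve.arms)


def _default_bounds(path: RoutingPath) -> tuple[np.ndarray, np.ndarray]:
    """Depth bounds keeping via points on their anatomical side of the bone."""
    ys = path.locals[:, 1]
    palmar = ys < 0
    lo = np.where(palmar, -0.018, 0.001)
    hi = np.where(palmar, -0.001, 0.018)
    return lo, hi


def optimize_routing(
    model: HandModel,
    muscle: str,
    references: list[MomentArmCurve],
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    init: dict[int, RoutingPath] | None = None,
    max_nfev: int = 500,
) -> RoutingFitResult:
    """Fit via-point depths of one muscle so model arms match the references.

    The free parameters are the local y coordinates (palmar depth) of
    every via point of the muscle's path; digits are fitted
    independently since their paths share no points.  Residuals pool all
    reference curves of a digit (joints are coupled through shared via
    points).  Returns the better of the initial and optimized routing
    per digit (the reported NMAE never exceeds the initial one).
    """
    refs = [c for c in references if c.muscle == muscle]
    if not refs:
        raise ValueError(f"no reference curves for muscle {muscle!r}")
    digits = sorted({c.digit for c in refs})
    out_paths: dict[int, RoutingPath] = {}
    per_curve: dict[tuple[int, str, str], tuple[float, float]] = {}
    total_iter = 0
    converged = True

    for d in digits:
        digit = model.digits[d]
        d_refs = [c for c in refs if c.digit == d]
        path0 = (init or {}).get(d, model.paths[(d, muscle)])
        for c in d_refs:
            if c.joint_idx not in path0.crossed_joints():
                raise ValueError(
                    f"{muscle} digit {d}: reference curve for {c.joint} but the "
                    "path does not cross that joint"
                )
        grids = [_resample(c) for c in d_refs]
        xs0 = path0.locals.copy()
        y0 = xs0[:, 1]
        lo, hi = bounds if bounds is not None else _default_bounds(path0)
        lo = np.broadcast_to(np.asarray(lo, dtype=float), y0.shape)
        hi = np.broadcast_to(np.asarray(hi, dtype=float), y0.shape)
        if np.any(lo >= hi):
            raise ValueError("infeasible bounds: lower >= upper")
        y0c = np.clip(y0, lo, hi)

        def build(y):
            pts = xs0.copy()
            pts[:, 1] = y
            return path0.with_locals(pts)

        def resid(y):
            p = build(y)
            res = []
            for c, (grid, arms_ref) in zip(d_refs, grids):
                arms = curve_moment_arms(digit, p, c.joint_idx, grid)
                res.append((arms - arms_ref) * 1e3)  # mm-scale residuals
            return np.concatenate(res)

        r0 = resid(y0c)
        sol = least_squares(
            resid, y0c, bounds=(lo, hi), method="trf",
            ftol=1e-10, xtol=1e-10, gtol=1e-10,
            diff_step=1e-3, max_nfev=max_nfev,
        )
        total_iter += sol.nfev
        if not sol.success:
            converged = False
        y_best = sol.x if 0.5 * np.dot(sol.fun, sol.fun) <= 0.5 * np.dot(r0, r0) else y0c
        best = build(y_best)
        out_paths[d] = best
        for c in d_refs:
            grid, arms_ref = _resample(c)
            arms = curve_moment_arms(digit, best, c.joint_idx, grid)
            per_curve[(d, muscle, c.joint)] = nmae(arms, arms_ref)

    return RoutingFitResult(out_paths, per_curve, total_iter, converged)


def summarize_fit(
    nmae_values: list[float], thresholds: tuple[float, ...] = (5.0, 25.0)
) -> dict:
    """Min/max and count-below-threshold summary of per-curve NMAE values (%)."""
    if len(nmae_values) == 0:
        raise ValueError("empty NMAE list")
    vals = np.asarray(nmae_values, dtype=float)
    out = {"n": int(vals.size), "min": float(vals.min()), "max": float(vals.max())}
    out["count_below"] = {float(t): int((vals < t).sum()) for t in thresholds}
    return out
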