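"""Tendon material calibration against reference stress-strain curves.

The serial-elastic tendon parameters (force fraction at the toe/linear
transition, transition stretch, linear stretch increment) are fitted so
the model stress-strain curve sigma(eps) = F_SEE(eps) / CSA matches a
measured curve; fit quality is scored with windowed NMAE values (0-3 %
and 0-5 % strain) and the linear-branch Young's modulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .mtu import SEEParams, see_force, see_young_modulus
from .routing import nmae

__all__ = [
    "StressStrainCurve",
    "TendonFitResult",
    "model_stress_strain",
    "windowed_nmae",
    "fit_see",
]


@dataclass(frozen=True)
class StressStrainCurve:
    """Tendon stress-strain samples: strain (dimensionless), stress (Pa)."""

    strains: np.ndarray
    stresses: np.ndarray
    label: str = "reference"

    def __post_init__(self) -> None:
        object.__setattr__(self, "strains", np.asarray(self.strains, dtype=float))
        object.__setattr__(self, "stresses", np.asarray(self.stresses, dtype=float))
        if self.strains.shape != self.stresses.shape or self.strains.size < 2:
            raise ValueError("strains and stresses must be equal-length (>= 2)")
        if np.any(self.strains < 0) or np.any(np.diff(self.strains) <= 0):
            raise ValueError("strains must be non-negative and strictly increasing")
        if np.any(self.stresses < 0):
            raise ValueError("stresses must be non-negative")


@dataclass
class TendonFitResult:
    see: SEEParams
    nmae3: float  # %
    nmae5: float  # %
    E: float  # Pa
    converged: bool


def _stress(frac, dU_nll, dU_l, sigma_norm, eps):
    """Piecewise tendon stress with normalization stress Fmax/CSA."""
    nu = dU_nll / dU_l
    toe = frac * sigma_norm * np.power(np.clip(eps, 0.0, None) / dU_nll, nu)
    lin = frac * sigma_norm * (1.0 + (eps - dU_nll) / dU_l)
    return np.where(eps <= 0, 0.0, np.where(eps < dU_nll, toe, lin))


def model_stress_strain(
    see: SEEParams, Fmax: float, csa: float, grid: np.ndarray
) -> StressStrainCurve:
    """Model stress-strain curve sigma(eps) = F_SEE / CSA on a strain grid."""
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0) or np.any(grid > 0.1):
        raise ValueError("strain grid must lie within [0, 0.1]")
    s = see if np.isfinite(see.l_see_0) else see.with_rest_length(1.0)
    stresses = see_force(s, Fmax, s.l_see_0 * (1.0 + grid)) / csa
    return StressStrainCurve(grid, np.atleast_1d(stresses), label="model")


def windowed_nmae(
    model: StressStrainCurve, ref: StressStrainCurve, eps_max: float
) -> float:
    """NMAE (%) restricted to reference samples with strain <= eps_max.

    The model curve is resampled onto the reference grid by linear
    interpolation before comparison.
    """
    sel = ref.strains <= eps_max + 1e-12
    if not np.any(sel):
        raise ValueError(f"empty strain window [0, {eps_max}]")
    pred = np.interp(ref.strains[sel], model.strains, model.stresses)
    _, value = nmae(pred, ref.stresses[sel])
    return value


def fit_see(
    ref: StressStrainCurve,
    Fmax: float,
    csa: float,
    init: SEEParams | None = None,
    bounds: dict | None = None,
    window: float = 0.03,
) -> TendonFitResult:
    """Fit (dF_see_0_frac, dU_see_nll, dU_see_l) to a reference curve.

    Bounded least squares on the 0-3 % strain window (the primary fit
    window; the 0-5 % score is reported alongside).  Internally the
    linear stretch is parameterized as a ratio of the transition stretch
    so the toe exponent stays > 1 throughout the fit.  The result never
    scores worse than the initial parameter set on the fit window.
    """
    if ref.strains[-1] < 0.05 - 1e-12:
        raise ValueError("reference must cover strains up to at least 5%")
    init = init or SEEParams()
    b = {
        "frac": (0.1, 1.2),
        "dU_nll": (0.005, 0.08),
        "ratio": (0.05, 0.95),  # dU_l / dU_nll
        **(bounds or {}),
    }
    sigma_norm = Fmax / csa
    sel = ref.strains <= window + 1e-12
    eps_w, sig_w = ref.strains[sel], ref.stresses[sel]
    scale = max(sig_w.mean(), 1.0)

    def unpack(x):
        frac, dU_nll, ratio = x
        return frac, dU_nll, ratio * dU_nll

    def resid(x):
        frac, dU_nll, dU_l = unpack(x)
        return (_stress(frac, dU_nll, dU_l, sigma_norm, eps_w) - sig_w) / scale

    x0 = np.array(
        [init.dF_see_0_frac, init.dU_see_nll, init.dU_see_l / init.dU_see_nll]
    )
    lo = np.array([b["frac"][0], b["dU_nll"][0], b["ratio"][0]])
    hi = np.array([b["frac"][1], b["dU_nll"][1], b["ratio"][1]])
    x0 = np.clip(x0, lo, hi)
    sol = least_squares(
        resid, x0, bounds=(lo, hi), method="trf",
        ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=2000,
    )
    frac, dU_nll, dU_l = unpack(sol.x)
    fitted = SEEParams(frac, dU_nll, dU_l)

    def scores(p: SEEParams):
        m = model_stress_strain(p, Fmax, csa, ref.strains)
        return windowed_nmae(m, ref, 0.03), windowed_nmae(m, ref, 0.05)

    n3_fit, n5_fit = scores(fitted)
    n3_init, n5_init = scores(init)
    if n3_fit > n3_init:  # safeguard: never worse than the starting point
        fitted, (n3_fit, n5_fit) = init, (n3_init, n5_init)
    return TendonFitResult(
        see=fitted,
        nmae3=n3_fit,
        nmae5=n5_fit,
        E=see_young_modulus(fitted, Fmax, csa),
        converged=bool(sol.success),
    )
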