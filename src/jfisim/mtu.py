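"""Hill-type muscle-tendon-unit (MTU) mechanics.

Each MTU is a contractile element (CE) in series with an elastic tendon
(serial elastic element, SEE) and in parallel with a passive elastic
element (PEE).  The tendon follows the extended-Hill-type convention: a
non-linear "toe" region up to the relative stretch ``dU_see_nll`` where
it carries the force ``dF_see_0_frac * Fmax``, followed by a linear
region whose stiffness is set by ``dU_see_l`` (the additional stretch
that produces one more increment of ``dF_see_0_frac * Fmax``).  The toe
exponent ``nu = dU_see_nll / dU_see_l`` makes the curve once
continuously differentiable at the transition.

All quantities are SI (m, s, N, Pa) unless noted otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SEEParams",
    "CEParams",
    "PEEParams",
    "ActivationParams",
    "MTUParams",
    "StrandSpec",
    "MTUState",
    "see_force",
    "see_young_modulus",
    "ce_isometric_factor",
    "pee_force",
    "ce_force",
    "force_residual",
    "contraction_rate",
    "activation_step",
    "init_equilibrium",
    "scale_fmax",
    "mtu_outputs",
]

STANDARD_GRAVITY = 9.80665  # m/s^2


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SEEParams:
    """Serial elastic element (tendon) parameters.

    dF_see_0_frac : force at the toe/linear transition, as fraction of Fmax
    dU_see_nll    : relative stretch at the toe/linear transition
    dU_see_l      : relative stretch in the linear part that adds another
                    ``dF_see_0_frac * Fmax`` of force
    l_see_0       : tendon rest length (m); may be ``nan`` until the strand
                    is initialized with :func:`init_equilibrium`
    """

    dF_see_0_frac: float = 0.4
    dU_see_nll: float = 0.0425
    dU_see_l: float = 0.017
    l_see_0: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.dF_see_0_frac > 0 and self.dU_see_nll > 0 and self.dU_see_l > 0):
            raise ValueError("SEE parameters must be strictly positive")
        if self.dF_see_0_frac > 1.5:
            raise ValueError("dF_see_0_frac must be <= 1.5")
        if self.dU_see_nll <= self.dU_see_l:
            raise ValueError(
                "dU_see_nll must exceed dU_see_l (toe exponent nu must be > 1)"
            )

    @property
    def nu_see(self) -> float:
        """Toe-region exponent enforcing C1 continuity at the transition."""
        return self.dU_see_nll / self.dU_see_l

    def with_rest_length(self, l_see_0: float) -> "SEEParams":
        return replace(self, l_see_0=l_see_0)


@dataclass(frozen=True)
class CEParams:
    """Contractile element parameters (force-length bell + Hill force-velocity)."""

    l_ce_opt: float = 0.06
    dW_asc: float = 0.57
    dW_desc: float = 0.14
    nu_asc: float = 4.0
    nu_desc: float = 3.0
    a_rel: float = 0.2
    b_rel: float = 2.0  # 1/s
    F_ecc: float = 1.5
    S_ecc: float = 2.0

    def __post_init__(self) -> None:
        if self.l_ce_opt <= 0:
            raise ValueError("l_ce_opt must be positive")
        if not (0 < self.dW_asc <= 1 and 0 < self.dW_desc <= 1):
            raise ValueError("bell widths must lie in (0, 1]")
        if self.F_ecc <= 1:
            raise ValueError("eccentric plateau F_ecc must exceed 1")


@dataclass(frozen=True)
class PEEParams:
    """Parallel elastic element: zero below ``L_pee_0 * l_ce_opt``, then a
    power law reaching ``F_pee * Fmax`` at ``(1 + dW_desc) * l_ce_opt``.

    The default slack length equals the optimal fiber length, so a strand
    assembled at its initial length equilibrium (fiber at optimum, tendon
    at rest) carries no passive preload.
    """

    L_pee_0: float = 1.0
    F_pee: float = 2.0
    nu_pee: float = 2.5

    def __post_init__(self) -> None:
        if self.L_pee_0 <= 0:
            raise ValueError("L_pee_0 must be positive")
        if self.nu_pee < 1:
            raise ValueError("nu_pee must be >= 1")


@dataclass(frozen=True)
class ActivationParams:
    tau_act: float = 0.010
    tau_deact: float = 0.040
    a_min: float = 0.005

    def __post_init__(self) -> None:
        if self.tau_act <= 0 or self.tau_deact <= 0:
            raise ValueError("activation time constants must be positive")
        if not (0 <= self.a_min < 1):
            raise ValueError("a_min must lie in [0, 1)")


@dataclass(frozen=True)
class MTUParams:
    """Full parameter set of one muscle strand (one tendon path)."""

    name: str
    Fmax: float
    csa: float
    see: SEEParams
    ce: CEParams
    pee: PEEParams = field(default_factory=PEEParams)
    act: ActivationParams = field(default_factory=ActivationParams)
    group: str = "flexor"
    d_se: float = 0.0  # serial damping coefficient (N*s/m); set by fixtures

    def __post_init__(self) -> None:
        if self.Fmax <= 0:
            raise ValueError(f"{self.name}: Fmax must be positive")
        if self.csa <= 0:
            raise ValueError(f"{self.name}: csa must be positive")
        if self.group not in ("flexor", "extensor"):
            raise ValueError(f"{self.name}: group must be 'flexor' or 'extensor'")


@dataclass(frozen=True)
class StrandSpec:
    """Whole-muscle maximum isometric force split over parallel strands."""

    Fmax_T: float
    n_s: int

    def __post_init__(self) -> None:
        if self.n_s < 1 or int(self.n_s) != self.n_s:
            raise ValueError("n_s must be a positive integer")
        if self.Fmax_T <= 0:
            raise ValueError("Fmax_T must be positive")


@dataclass
class MTUState:
    """Dynamic state of one strand: activation, fiber length, path length.

    ``l_mtu`` is the *effective* MTU length (geometric path plus the
    initialization offset, see :func:`init_equilibrium`).
    """

    a: float
    l_ce: float
    l_mtu: float

    @property
    def l_see(self) -> float:
        return self.l_mtu - self.l_ce


# ---------------------------------------------------------------------------
# element force laws
# ---------------------------------------------------------------------------


def see_force(see: SEEParams, Fmax: float, l_see) -> float | np.ndarray:
    """Tendon force at serial-element length ``l_see`` (m).

    Zero below the rest length; toe region
    ``dF * (eps/dU_nll)**nu`` for strain ``0 <= eps < dU_nll`` with
    ``nu = dU_nll/dU_l``; linear ``dF * (1 + (eps - dU_nll)/dU_l)`` above,
    where ``dF = dF_see_0_frac * Fmax`` and ``eps = (l_see - l_see_0)/l_see_0``.
    """
    l_see = np.asarray(l_see, dtype=float)
    if not np.all(np.isfinite(l_see)):
        raise ValueError("l_see must be finite")
    if np.any(l_see < 0):
        raise ValueError("l_see must be non-negative")
    if not math.isfinite(see.l_see_0) or see.l_see_0 <= 0:
        raise ValueError("SEEParams.l_see_0 must be set (initialize the strand)")
    eps = (l_see - see.l_see_0) / see.l_see_0
    dF = see.dF_see_0_frac * Fmax
    nu = see.nu_see
    toe = dF * np.power(np.clip(eps, 0.0, None) / see.dU_see_nll, nu)
    lin = dF * (1.0 + (eps - see.dU_see_nll) / see.dU_see_l)
    out = np.where(eps <= 0.0, 0.0, np.where(eps < see.dU_see_nll, toe, lin))
    return float(out) if out.ndim == 0 else out


def see_stiffness(see: SEEParams, Fmax: float, l_see: float) -> float:
    """dF/dl of the tendon at ``l_see`` (N/m)."""
    eps = (l_see - see.l_see_0) / see.l_see_0
    dF = see.dF_see_0_frac * Fmax
    if eps <= 0.0:
        return 0.0
    if eps < see.dU_see_nll:
        nu = see.nu_see
        return dF * nu * (eps / see.dU_see_nll) ** (nu - 1) / (see.dU_see_nll * see.l_see_0)
    return dF / (see.dU_see_l * see.l_see_0)


def see_young_modulus(see: SEEParams, Fmax: float, csa: float) -> float:
    """Young's modulus (Pa) of the tendon's linear branch.

    The linear-branch stress/strain slope is
    ``(dF_see_0_frac * Fmax / dU_see_l) / csa``; it is invariant under a
    common rescaling of Fmax and csa.
    """
    if csa <= 0:
        raise ValueError("csa must be positive")
    if Fmax <= 0:
        raise ValueError("Fmax must be positive")
    return see.dF_see_0_frac * Fmax / see.dU_see_l / csa


def ce_isometric_factor(ce: CEParams, l_ce) -> float | np.ndarray:
    """Bell-shaped isometric force-length factor, 1 at the optimal length."""
    l_ce = np.asarray(l_ce, dtype=float)
    if not np.all(np.isfinite(l_ce)):
        raise ValueError("l_ce must be finite")
    if np.any(l_ce <= 0):
        raise ValueError("l_ce must be positive")
    rel = l_ce / ce.l_ce_opt - 1.0
    asc = np.exp(-np.power(np.abs(rel) / ce.dW_asc, ce.nu_asc))
    desc = np.exp(-np.power(np.abs(rel) / ce.dW_desc, ce.nu_desc))
    out = np.where(rel <= 0, asc, desc)
    return float(out) if out.ndim == 0 else out


def pee_force(pee: PEEParams, ce: CEParams, Fmax: float, l_ce) -> float | np.ndarray:
    """Parallel elastic force; engages above ``L_pee_0 * l_ce_opt``."""
    l_ce = np.asarray(l_ce, dtype=float)
    l0 = pee.L_pee_0 * ce.l_ce_opt
    span = ce.l_ce_opt * (ce.dW_desc + 1.0 - pee.L_pee_0)
    k = pee.F_pee * Fmax / span**pee.nu_pee
    out = np.where(l_ce > l0, k * np.power(np.clip(l_ce - l0, 0.0, None), pee.nu_pee), 0.0)
    return float(out) if out.ndim == 0 else out


def _b_ecc(ce: CEParams, f_isom: float) -> float:
    """Eccentric hyperbola constant giving slope continuity / S_ecc scaling at v=0."""
    conc_slope = (f_isom + ce.a_rel) / ce.b_rel  # normalized dF/dv_norm at v=0-
    return (ce.F_ecc - 1.0) * f_isom / (ce.S_ecc * conc_slope)


def ce_force(params: MTUParams, a: float, l_ce: float, v_ce: float) -> float:
    """Active contractile force at fiber velocity ``v_ce`` (m/s, lengthening > 0)."""
    ce = params.ce
    f_isom = float(ce_isometric_factor(ce, l_ce))
    vn = v_ce / ce.l_ce_opt  # 1/s
    if vn <= 0.0:  # concentric (shortening) Hill hyperbola
        if vn <= -ce.b_rel * f_isom / ce.a_rel:
            return 0.0
        f = (f_isom + ce.a_rel) * ce.b_rel / (ce.b_rel - vn) - ce.a_rel
        return params.Fmax * a * max(f, 0.0)
    be = _b_ecc(ce, f_isom)
    f = ce.F_ecc * f_isom - (ce.F_ecc - 1.0) * f_isom * be / (be + vn)
    return params.Fmax * a * f


def force_residual(params: MTUParams, state: MTUState, v_mtu: float, v_ce: float) -> float:
    """Series force balance residual g(v_ce) = F_CE + F_PEE - F_SEE - F_SED.

    ``g`` is strictly increasing in ``v_ce`` whenever the serial damping
    coefficient is positive, so the balance has a unique root.
    """
    f_see = see_force(params.see, params.Fmax, max(state.l_see, 0.0))
    f_sed = params.d_se * (v_mtu - v_ce)
    f_pee = pee_force(params.pee, params.ce, params.Fmax, state.l_ce)
    return ce_force(params, state.a, state.l_ce, v_ce) + f_pee - f_see - f_sed


def contraction_rate(params: MTUParams, state: MTUState, v_mtu: float = 0.0) -> float:
    """Fiber velocity (m/s) solving the series force balance.

    Bracketed root find on ``v_ce`` starting from ±20 optimal fiber
    lengths per second, expanding the bracket if the root lies outside
    (fast eccentric transients).  Raises if no sign change can be
    bracketed, reporting the force residuals at the bracket ends.
    """
    if state.l_see < 0:
        raise ValueError("state not initialized: l_see < 0")
    span = 20.0 * params.ce.l_ce_opt
    lo, hi = -span, span
    g = lambda v: force_residual(params, state, v_mtu, v)
    glo, ghi = g(lo), g(hi)
    n_expand = 0
    while glo * ghi > 0 and n_expand < 40:
        lo *= 2.0
        hi *= 2.0
        glo, ghi = g(lo), g(hi)
        n_expand += 1
    if glo * ghi > 0:
        raise ArithmeticError(
            f"{params.name}: no sign change in contraction-rate bracket "
            f"[{lo:.3g}, {hi:.3g}] m/s; residuals ({glo:.6g}, {ghi:.6g}) N"
        )
    if glo == 0.0:
        return lo
    if ghi == 0.0:
        return hi
    return float(brentq(g, lo, hi, xtol=1e-10))


def activation_step(act: ActivationParams, a: float, u: float, dt: float) -> float:
    """Exact first-order activation update over one step ``dt``.

    Uses ``a + (u - a) * (1 - exp(-dt/tau))`` with the activation time
    constant when ``u > a`` and the deactivation constant otherwise, so
    the step is integrator-independent; the result is clamped to
    ``[a_min, 1]``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    tau = act.tau_act if u > a else act.tau_deact
    a_new = a + (u - a) * (1.0 - math.exp(-dt / tau))
    return min(1.0, max(act.a_min, a_new))


def init_equilibrium(
    l_mtu_i: float,
    l_ce_opt: float,
    group: str,
    c_e_f: tuple[float, float] = (0.95, 1.05),
    name: str = "strand",
) -> tuple[float, float]:
    """Initial length equilibrium: fiber at its optimum, tendon at rest.

    The scaled initial MTU length ``c * l_mtu_i`` (c = 0.95 for extensors,
    1.05 for flexors, representing the initially compressed or stretched
    state of a straight hand) is split as ``l_ce_i + l_see_0`` with
    ``l_ce_i = l_ce_opt``.  Returns ``(l_ce_i, l_see_0)``.
    """
    c_ext, c_flex = c_e_f
    c = c_flex if group == "flexor" else c_ext
    l_see_0 = c * l_mtu_i - l_ce_opt
    if l_see_0 <= 0:
        raise ValueError(
            f"{name}: infeasible geometry, l_see_0 = {l_see_0:.4g} m <= 0 "
            f"(l_mtu_i = {l_mtu_i:.4g}, l_ce_opt = {l_ce_opt:.4g}, c = {c})"
        )
    return l_ce_opt, l_see_0


def scale_fmax(spec: StrandSpec) -> float:
    """Per-strand maximum isometric force ``Fmax_T / n_s``."""
    return spec.Fmax_T / spec.n_s


def mtu_outputs(params: MTUParams, state: MTUState) -> tuple[float, float]:
    """Current MTU force (N) and engineering tendon strain.

    Strain is defined on the tendon rest length; negative strain means a
    slack tendon carrying zero force.
    """
    eps_see = (state.l_mtu - state.l_ce - params.see.l_see_0) / params.see.l_see_0
    f_mtu = see_force(params.see, params.Fmax, max(state.l_see, 0.0))
    return float(f_mtu), float(eps_see)
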