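"""Two-stage jersey-finger load case and the simulation protocol.

Stage 1 (0 to t_R = 100 ms): the finger flexors receive a step neural
input and close the hand around a rigid cylindrical rod (100 mm x 20 mm
diameter) held in the palm plane; hand-rod interaction is a penalty
contact with regularized Coulomb friction, and a tied (stiff elastic)
coupling engages at 80 ms so the contact reaction cannot loosen the
grip.  Stage 2 (t_R to 200 ms): the rod is retracted kinematically,
ramping to 11.615 m/s, forcing the flexed fingers open and loading the
flexor tendons eccentrically.

The protocol runs eight retraction simulations over the activation grid
0/20/40/60/70/80/90/100 % plus a model-check run at 100 % without
retraction, scores every flexor strand with the injury criteria and
tabulates the results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import hand as _hand
from .hand import HandModel
from .injury import InjuryFinding, InjuryThresholds, assess_avulsion, assess_msic, assess_tsic
from .synthetic import Strand

__all__ = [
    "RodConfig",
    "ContactParams",
    "LoadCaseConfig",
    "SimulationResult",
    "EffectivenessResult",
    "contact_force",
    "run_load_case",
    "activation_effectiveness",
    "run_protocol",
    "ProtocolResult",
]

ACTIVATION_GRID = (0.0, 0.2, 0.4, 0.6, 0.7, 0.8, 0.9, 1.0)


@dataclass(frozen=True)
class RodConfig:
    """Rigid cylindrical rod, kinematically driven."""

    length: float = 0.100  # m (out of plane; informational)
    diameter: float = 0.020  # m
    center: tuple[float, float] = (0.040, -0.034)  # m, palm plane
    retraction_velocity: float = 11.615  # m/s
    velocity_ramp_time: float = 0.001  # s
    retract_direction: tuple[float, float] = (0.6, -0.8)

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("rod diameter must be positive")
        if self.retraction_velocity < 0:
            raise ValueError("retraction velocity must be non-negative")

    @property
    def direction(self) -> np.ndarray:
        d = np.asarray(self.retract_direction, dtype=float)
        return d / np.linalg.norm(d)


@dataclass(frozen=True)
class ContactParams:
    mu_static: float = 0.4
    mu_dynamic: float = 0.3
    penalty_stiffness: float = 2.0e4  # N/m
    penalty_damping: float = 20.0  # N*s/m
    skin_pad: float = 0.005  # m, soft-tissue pad added to the rod radius
    regularization_velocity: float = 0.005  # m/s, static->dynamic transition
    stick_viscosity: float = 100.0  # N*s/m, bounded friction slope near sticking
    tie_activation_time: float = 0.080  # s
    tie_stiffness: float = 5.0e3  # N/m
    tie_damping: float = 10.0  # N*s/m
    tie_breakaway_elongation: float = 0.005  # m

    def __post_init__(self) -> None:
        if not (0 <= self.mu_dynamic <= self.mu_static):
            raise ValueError("require 0 <= mu_dynamic <= mu_static")
        if self.penalty_stiffness <= 0 or self.tie_stiffness <= 0:
            raise ValueError("stiffnesses must be positive")


@dataclass(frozen=True)
class LoadCaseConfig:
    activation: float = 1.0  # flexor neural input in [0, 1]
    retract: bool = True
    t_R: float = 0.100  # s, grip end / retraction start
    t_end: float = 0.200  # s
    dt: float = 2.0e-5  # s
    record_stride: int = 4  # record every n-th step (sampling >= 1 kHz)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.activation <= 1.0):
            raise ValueError("activation must lie in [0, 1]")
        if not (0 < self.t_R < self.t_end):
            raise ValueError("require 0 < t_R < t_end")
        if self.dt <= 0 or self.record_stride < 1:
            raise ValueError("dt and record_stride must be positive")
        if self.record_stride * self.dt > 1e-3:
            raise ValueError("recording must sample at >= 1 kHz")


@dataclass
class SimulationResult:
    """Recorded time series of one load-case run (shared time grid)."""

    time: np.ndarray  # (N,)
    f_mtu: np.ndarray  # (N, S) tendon (SEE) forces, N
    eps_see: np.ndarray  # (N, S) engineering tendon strains
    activation: np.ndarray  # (N, S)
    l_ce: np.ndarray  # (N, S) fiber lengths, m
    q: np.ndarray  # (N, D, 3) joint angles, rad
    qdot: np.ndarray  # (N, D, 3) joint velocities, rad/s
    contact_force: np.ndarray  # (N, D) summed normal contact force, N
    rod_pos: np.ndarray  # (N, 2)
    strand_names: list[str]
    digit_ids: list[int]
    config: LoadCaseConfig
    flags: dict = field(default_factory=dict)

    def strand_index(self, name: str) -> int:
        return self.strand_names.index(name)

    def series(self, kind: str, name: str) -> tuple[np.ndarray, np.ndarray]:
        arr = {"force": self.f_mtu, "strain": self.eps_see, "l_ce": self.l_ce}[kind]
        return self.time, arr[:, self.strand_index(name)]


@dataclass(frozen=True)
class EffectivenessResult:
    """Muscle activation effectiveness eta_a over the grip phase."""

    a: float
    F_bar_mtu: float  # mean over flexor strands of each strand's peak force, N
    F_bar_max: float  # mean flexor Fmax, N
    eta_a: float  # %
    eta_a_sd: float  # % (SD of per-strand peak/Fmax ratios)


# ---------------------------------------------------------------------------
# contact
# ---------------------------------------------------------------------------


def _point_contact(points, vels, center, rod_vel, radius_eff, p: ContactParams):
    """Penalty + regularized-Coulomb contact of points against the rod circle.

    Returns (forces on the points (..., 2), normal force magnitudes (...,)).
    """
    rel = points - center
    dist = np.linalg.norm(rel, axis=-1)
    dist = np.where(dist < 1e-9, 1e-9, dist)
    normal = rel / dist[..., None]
    pen = radius_eff - dist
    in_contact = pen > 0.0
    rel_v = vels - rod_vel
    v_n = np.einsum("...i,...i->...", rel_v, normal)
    f_n = np.where(in_contact, p.penalty_stiffness * pen - p.penalty_damping * v_n, 0.0)
    f_n = np.clip(f_n, 0.0, None)
    tangent = np.stack([-normal[..., 1], normal[..., 0]], axis=-1)
    v_t = np.einsum("...i,...i->...", rel_v, tangent)
    mu = p.mu_dynamic + (p.mu_static - p.mu_dynamic) * np.exp(
        -np.abs(v_t) / p.regularization_velocity
    )
    # Coulomb friction capped by a viscous branch near sticking, so the
    # force-velocity slope stays bounded (no stick-slip chatter under
    # explicit integration)
    f_t = -np.sign(v_t) * np.minimum(mu * f_n, p.stick_viscosity * np.abs(v_t))
    force = f_n[..., None] * normal + f_t[..., None] * tangent
    return force, f_n


def contact_force(
    rod: RodConfig,
    point,
    params: ContactParams,
    rel_velocity=(0.0, 0.0),
    rod_center=None,
) -> np.ndarray:
    """Contact force (2,) on a single segment point against the rod.

    Zero when separated; penalty normal force along the outward circle
    normal plus regularized Coulomb friction (|F_t| <= mu_s * F_n,
    = mu_d * F_n once sliding exceeds the regularization threshold).
    """
    point = np.asarray(point, dtype=float)
    if not np.all(np.isfinite(point)):
        raise ValueError("point must be finite")
    center = np.asarray(rod_center if rod_center is not None else rod.center, float)
    radius_eff = rod.diameter / 2.0 + params.skin_pad
    force, _ = _point_contact(
        point, np.asarray(rel_velocity, float), center, np.zeros(2), radius_eff, params
    )
    return force


def _rod_state(rod: RodConfig, cfg: LoadCaseConfig, t: float):
    """Rod center and velocity at time t (kinematic retraction)."""
    c0 = np.asarray(rod.center, dtype=float)
    if not cfg.retract or t <= cfg.t_R:
        return c0, np.zeros(2)
    s = t - cfg.t_R
    ramp, vmax = rod.velocity_ramp_time, rod.retraction_velocity
    if s < ramp:
        v = vmax * s / ramp
        disp = 0.5 * vmax * s**2 / ramp
    else:
        v = vmax
        disp = vmax * (s - ramp / 2.0)
    d = rod.direction
    return c0 + disp * d, v * d


# ---------------------------------------------------------------------------
# vectorized engine internals
# ---------------------------------------------------------------------------


class _Engine:
    """Array-packed state for all digits and strands of one simulation."""

    H = 1e-6  # rad, central-difference step for moment arms

    def __init__(self, model: HandModel, strands: list[Strand]):
        self.model = model
        self.digit_ids = model.digit_ids
        self.D = len(self.digit_ids)
        digs = [model.digits[d] for d in self.digit_ids]
        self.seg_len = np.array([g.segment_lengths for g in digs])  # (D,3)
        self.mc_len = np.array([g.metacarpal_length for g in digs])  # (D,)
        self.masses = np.array([g.masses for g in digs])
        self.inertias = np.array([g.inertias for g in digs])
        joints = [model.joints[d] for d in self.digit_ids]
        self.k_joint = np.array([[j.stiffness for j in row] for row in joints])
        self.c_joint = np.array([[j.damping for j in row] for row in joints])
        self.k_lim = np.array([[j.limit_stiffness for j in row] for row in joints])
        self.rom_lo = np.array([[j.rom[0] for j in row] for row in joints])
        self.rom_hi = np.array([[j.rom[1] for j in row] for row in joints])
        self.q_rest = np.array([[j.q_rest for j in row] for row in joints])

        # muscle routing, padded to a common point count per muscle
        self.muscles = sorted({s.muscle for s in strands})
        self.mus_segs, self.mus_locals = {}, {}
        for m in self.muscles:
            paths = [model.paths[(d, m)] for d in self.digit_ids]
            P = max(len(p.via_points) for p in paths)
            segs = np.zeros((self.D, P), dtype=int)
            locs = np.zeros((self.D, P, 2))
            for i, p in enumerate(paths):
                s_arr, l_arr = p.segments, p.locals
                n = len(s_arr)
                segs[i, :n], locs[i, :n] = s_arr, l_arr
                segs[i, n:], locs[i, n:] = s_arr[-1], l_arr[-1]  # zero-length pad
            self.mus_segs[m], self.mus_locals[m] = segs, locs

        # strand packing
        self.strands = strands
        self.S = len(strands)
        order = {d: i for i, d in enumerate(self.digit_ids)}
        self.s_digit = np.array([order[s.digit_id] for s in strands])
        self.s_muscle = np.array([self.muscles.index(s.muscle) for s in strands])
        p = [s.params for s in strands]
        self.Fmax = np.array([x.Fmax for x in p])
        self.l_opt = np.array([x.ce.l_ce_opt for x in p])
        self.dW_asc = np.array([x.ce.dW_asc for x in p])
        self.nu_asc = np.array([x.ce.nu_asc for x in p])
        self.dW_desc = np.array([x.ce.dW_desc for x in p])
        self.nu_desc = np.array([x.ce.nu_desc for x in p])
        self.a_rel = np.array([x.ce.a_rel for x in p])
        self.b_rel = np.array([x.ce.b_rel for x in p])
        self.F_ecc = np.array([x.ce.F_ecc for x in p])
        self.S_ecc = np.array([x.ce.S_ecc for x in p])
        self.L_pee0 = np.array([x.pee.L_pee_0 for x in p])
        self.F_pee = np.array([x.pee.F_pee for x in p])
        self.nu_pee = np.array([x.pee.nu_pee for x in p])
        self.see_frac = np.array([x.see.dF_see_0_frac for x in p])
        self.see_nll = np.array([x.see.dU_see_nll for x in p])
        self.see_l = np.array([x.see.dU_see_l for x in p])
        self.l_see0 = np.array([x.see.l_see_0 for x in p])
        if not np.all(np.isfinite(self.l_see0)):
            raise ValueError("all strands must be initialized (l_see_0 set)")
        self.d_se = np.array([x.d_se for x in p])
        if np.any(self.d_se <= 0):
            raise ValueError("the load-case engine requires serial damping d_se > 0")
        self.tau_act = np.array([x.act.tau_act for x in p])
        self.tau_deact = np.array([x.act.tau_deact for x in p])
        self.a_min = np.array([x.act.a_min for x in p])
        self.is_flexor = np.array([x.group == "flexor" for x in p])
        self.offset = np.array([s.path_offset for s in strands])

        # constant angular part of the mass matrix: theta_s depends on q_j, j <= s
        dep = (
            (np.arange(3)[:, None, None] >= np.arange(3)[None, :, None])
            & (np.arange(3)[:, None, None] >= np.arange(3)[None, None, :])
        ).astype(float)
        self.M_ang = np.einsum("ds,sij->dij", self.inertias, dep)

        # contact sample points along the palmar bone line of each digit
        Lp, Lm, Ld = self.seg_len[:, 0], self.seg_len[:, 1], self.seg_len[:, 2]
        self.con_segs = np.array([1, 2, 3, 3])
        z = np.zeros(self.D)
        self.con_locals = np.stack(
            [
                np.stack([0.6 * Lp, z], axis=-1),
                np.stack([0.6 * Lm, z], axis=-1),
                np.stack([0.5 * Ld, z], axis=-1),
                np.stack([Ld, z], axis=-1),
            ],
            axis=1,
        )  # (D, 4, 2)

    # -- geometry ----------------------------------------------------------

    def muscle_geometry(self, q):
        """Path lengths (D, M) and moment arms (D, M, 3) at angles q (D, 3)."""
        h = self.H
        Q = np.repeat(q[:, None, :], 7, axis=1)
        for j in range(3):
            Q[:, 1 + 2 * j, j] += h
            Q[:, 2 + 2 * j, j] -= h
        origins, rots = _hand._frames(self.seg_len[:, None, :], self.mc_len[:, None], Q)
        M = len(self.muscles)
        L = np.zeros((self.D, 7, M))
        for mi, m in enumerate(self.muscles):
            segs, locs = self.mus_segs[m], self.mus_locals[m]
            o = np.take_along_axis(origins, segs[:, None, :, None], axis=2)
            r = np.take_along_axis(rots, segs[:, None, :, None, None], axis=2)
            pts = o + np.einsum("dkpij,dpj->dkpi", r, locs)
            L[:, :, mi] = np.linalg.norm(np.diff(pts, axis=2), axis=-1).sum(axis=2)
        lengths = L[:, 0, :]
        arms = np.stack(
            [-(L[:, 1 + 2 * j, :] - L[:, 2 + 2 * j, :]) / (2 * h) for j in range(3)],
            axis=-1,
        )  # (D, M, 3)
        return lengths, arms

    def contact_points(self, q):
        """World contact points (D, P, 2), velocities jacobian (D, P, 3, 2)."""
        origins, rots = _hand._frames(self.seg_len, self.mc_len, q)
        o = origins[:, self.con_segs, :]
        r = rots[:, self.con_segs, :, :]
        pts = o + np.einsum("dpij,dpj->dpi", r, self.con_locals)
        centers = origins[:, 1:, :]  # joint centers (D, 3, 2)
        rel = pts[:, :, None, :] - centers[:, None, :, :]
        jac = np.stack([rel[..., 1], -rel[..., 0]], axis=-1)  # (D, P, 3, 2)
        mask = self.con_segs[None, :, None] >= (np.arange(3) + 1)[None, None, :]
        return pts, jac * mask[..., None]

    # -- muscle dynamics ---------------------------------------------------

    def isometric_factor(self, l_ce):
        rel = l_ce / self.l_opt - 1.0
        asc = np.exp(-np.power(np.abs(rel) / self.dW_asc, self.nu_asc))
        desc = np.exp(-np.power(np.abs(rel) / self.dW_desc, self.nu_desc))
        return np.where(rel <= 0, asc, desc)

    def pee_force(self, l_ce):
        l0 = self.L_pee0 * self.l_opt
        span = self.l_opt * (self.dW_desc + 1.0 - self.L_pee0)
        k = self.F_pee * self.Fmax / span**self.nu_pee
        return np.where(
            l_ce > l0, k * np.power(np.clip(l_ce - l0, 0.0, None), self.nu_pee), 0.0
        )

    def see_force(self, l_see):
        eps = (l_see - self.l_see0) / self.l_see0
        dF = self.see_frac * self.Fmax
        nu = self.see_nll / self.see_l
        toe = dF * np.power(np.clip(eps, 0.0, None) / self.see_nll, nu)
        lin = dF * (1.0 + (eps - self.see_nll) / self.see_l)
        return np.where(eps <= 0.0, 0.0, np.where(eps < self.see_nll, toe, lin))

    def _ce_and_slope(self, a, f_isom, vn):
        """Active CE force and d(F_CE)/d(v_ce) at normalized velocity vn."""
        A = a * self.Fmax
        denom = self.b_rel - np.minimum(vn, 0.0)
        f_conc = A * ((f_isom + self.a_rel) * self.b_rel / denom - self.a_rel)
        g_conc = A * (f_isom + self.a_rel) * self.b_rel / denom**2 / self.l_opt
        clamped = f_conc <= 0.0
        f_conc = np.where(clamped, 0.0, f_conc)
        g_conc = np.where(clamped, 0.0, g_conc)
        be = (self.F_ecc - 1.0) * f_isom * self.b_rel / (
            self.S_ecc * (f_isom + self.a_rel)
        )
        vnp = np.maximum(vn, 0.0)
        f_ecc = A * (self.F_ecc * f_isom - (self.F_ecc - 1.0) * f_isom * be / (be + vnp))
        g_ecc = A * (self.F_ecc - 1.0) * f_isom * be / (be + vnp) ** 2 / self.l_opt
        conc = vn <= 0.0
        return np.where(conc, f_conc, f_ecc), np.where(conc, g_conc, g_ecc)

    def solve_vce(self, a, l_ce, l_see, v_mtu, v_init):
        """Vectorized fiber velocities from the series force balance.

        Damped-Newton iteration with a maintained sign-change bracket;
        the serial damping term makes the residual strictly increasing
        in v_ce so the root is unique.
        """
        f_isom = self.isometric_factor(l_ce)
        rhs = self.see_force(np.clip(l_see, 0.0, None)) - self.pee_force(l_ce)

        def g_and_slope(v):
            f_ce, slope = self._ce_and_slope(a, f_isom, v / self.l_opt)
            return f_ce - rhs - self.d_se * (v_mtu - v), slope + self.d_se

        lo = -50.0 * self.l_opt + np.minimum(v_mtu, 0.0)
        hi = 50.0 * self.l_opt + np.maximum(v_mtu, 0.0)
        for _ in range(60):
            glo, _ = g_and_slope(lo)
            ghi, _ = g_and_slope(hi)
            bad_lo, bad_hi = glo > 0.0, ghi < 0.0
            if not (bad_lo.any() or bad_hi.any()):
                break
            lo = np.where(bad_lo, lo * 2.0 - 1.0, lo)
            hi = np.where(bad_hi, hi * 2.0 + 1.0, hi)
        v = np.clip(v_init, lo, hi)
        tol = 1e-9 * self.Fmax
        for _ in range(30):
            g, slope = g_and_slope(v)
            if np.all(np.abs(g) < tol):
                break
            lo = np.where(g < 0.0, v, lo)
            hi = np.where(g > 0.0, v, hi)
            step = g / np.maximum(slope, 1e-12)
            v_new = v - step
            outside = (v_new <= lo) | (v_new >= hi)
            v = np.where(outside, 0.5 * (lo + hi), v_new)
        return v

    # -- skeleton dynamics -------------------------------------------------

    def passive(self, q, qdot):
        tau = -self.k_joint * (q - self.q_rest) - self.c_joint * qdot
        tau -= self.k_lim * (
            np.clip(q - self.rom_hi, 0.0, None) + np.clip(q - self.rom_lo, None, 0.0)
        )
        return tau

    def see_stiffness(self, l_see):
        """Tendon stiffness dF/dl (N/m) at the current serial-element length."""
        eps = (l_see - self.l_see0) / self.l_see0
        dF = self.see_frac * self.Fmax
        nu = self.see_nll / self.see_l
        toe = (
            dF * nu * np.power(np.clip(eps, 1e-12, None) / self.see_nll, nu - 1.0)
            / (self.see_nll * self.l_see0)
        )
        lin = dF / (self.see_l * self.l_see0)
        return np.where(eps <= 0.0, 0.0, np.where(eps < self.see_nll, toe, lin))

    def accel(self, q, qdot, tau_ext):
        """Joint accelerations; frames/jacobians computed once per call."""
        origins, rots = _hand._frames(self.seg_len, self.mc_len, q)
        full = np.einsum(
            "dsij,dsj->dsi",
            rots[:, 1:, :, :],
            np.stack([self.seg_len, np.zeros_like(self.seg_len)], axis=-1),
        )  # (D, 3, 2) rotated full segment vectors
        half = 0.5 * full
        coms = origins[:, 1:, :] + half
        centers = origins[:, 1:, :]
        rel = coms[:, :, None, :] - centers[:, None, :, :]
        jac = np.stack([rel[..., 1], -rel[..., 0]], axis=-1)
        jac *= (np.arange(3)[:, None] >= np.arange(3)[None, :])[None, :, :, None]
        m = np.einsum("ds,dsix,dsjx->dij", self.masses, jac, jac) + self.M_ang
        w2 = np.cumsum(qdot, axis=-1) ** 2
        acc = np.zeros_like(coms)
        run = np.zeros((self.D, 2))
        for s in range(3):
            acc[:, s, :] = -(run + w2[:, s, None] * half[:, s, :])
            run = run + w2[:, s, None] * full[:, s, :]
        b = np.einsum("ds,dsjx,dsx->dj", self.masses, jac, acc)
        tau = tau_ext + self.passive(q, qdot)
        return np.linalg.solve(m, (tau - b)[..., None])[..., 0]

    def step_skeleton(self, q, qdot, tau_ext, dt):
        k1v = self.accel(q, qdot, tau_ext)
        k2q = qdot + 0.5 * dt * k1v
        k2v = self.accel(q + 0.5 * dt * qdot, k2q, tau_ext)
        k3q = qdot + 0.5 * dt * k2v
        k3v = self.accel(q + 0.5 * dt * k2q, k3q, tau_ext)
        k4q = qdot + dt * k3v
        k4v = self.accel(q + dt * k3q, k4q, tau_ext)
        q_new = q + dt / 6.0 * (qdot + 2 * k2q + 2 * k3q + k4q)
        qdot_new = qdot + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
        return q_new, qdot_new

    def coupled_accel(self, qs, qds, ts, ctx):
        """Joint accelerations with muscle, contact and tie forces evaluated
        at the substate.

        Muscle forces follow the SEE stiffness linearization
        F = F0 + k_see * dL(path) around the step's start state (moment
        arms and fiber length frozen within the step); contact and tie
        forces are recomputed from the substate geometry, so the stiff
        force elements are integrated by the full RK4 scheme.
        """
        origins, rots = _hand._frames(self.seg_len, self.mc_len, qs)
        # muscle torques
        dq = qs - ctx["q0"]
        dL = -np.einsum("sj,sj->s", ctx["arms_s"], dq[self.s_digit])
        F = np.clip(ctx["f_see0"] + ctx["k_see"] * dL, 0.0, None)
        F_grid = np.zeros((self.D, len(self.muscles)))
        F_grid[self.s_digit, self.s_muscle] = F
        tau = np.einsum("dmj,dm->dj", ctx["arms"], F_grid)
        # contact + tie
        o = origins[:, self.con_segs, :]
        r = rots[:, self.con_segs, :, :]
        pts = o + np.einsum("dpij,dpj->dpi", r, self.con_locals)
        centers = origins[:, 1:, :]
        relc = pts[:, :, None, :] - centers[:, None, :, :]
        jac_c = np.stack([relc[..., 1], -relc[..., 0]], axis=-1)
        jac_c *= (self.con_segs[:, None] >= (np.arange(3) + 1))[None, :, :, None]
        vels = np.einsum("dpjx,dj->dpx", jac_c, qds)
        rod_c, rod_v = ctx["rod_state"](ts)
        f_pts, _ = _point_contact(
            pts, vels, rod_c, rod_v, ctx["radius_eff"], ctx["contact"]
        )
        alive = ctx["ties_alive"]
        if alive.any():
            dvec = rod_c + ctx["tie_offsets"] - pts
            f_tie = ctx["contact"].tie_stiffness * dvec + ctx["contact"].tie_damping * (
                rod_v[None, None, :] - vels
            )
            f_pts = f_pts + np.where(alive[..., None], f_tie, 0.0)
        tau += np.einsum("dpjx,dpx->dj", jac_c, f_pts)
        # chain dynamics
        full = np.einsum(
            "dsij,dsj->dsi",
            rots[:, 1:, :, :],
            np.stack([self.seg_len, np.zeros_like(self.seg_len)], axis=-1),
        )
        half = 0.5 * full
        coms = origins[:, 1:, :] + half
        rel = coms[:, :, None, :] - origins[:, None, 1:, :]
        jac = np.stack([rel[..., 1], -rel[..., 0]], axis=-1)
        jac *= (np.arange(3)[:, None] >= np.arange(3)[None, :])[None, :, :, None]
        m = np.einsum("ds,dsix,dsjx->dij", self.masses, jac, jac) + self.M_ang
        w2 = np.cumsum(qds, axis=-1) ** 2
        acc = np.zeros_like(coms)
        run = np.zeros((self.D, 2))
        for s in range(3):
            acc[:, s, :] = -(run + w2[:, s, None] * half[:, s, :])
            run = run + w2[:, s, None] * full[:, s, :]
        b = np.einsum("ds,dsjx,dsx->dj", self.masses, jac, acc)
        tau += self.passive(qs, qds)
        return np.linalg.solve(m, (tau - b)[..., None])[..., 0]

    def coupled_step(self, q, qdot, dt, t, ctx):
        k1v = self.coupled_accel(q, qdot, t, ctx)
        k2q = qdot + 0.5 * dt * k1v
        k2v = self.coupled_accel(q + 0.5 * dt * qdot, k2q, t + 0.5 * dt, ctx)
        k3q = qdot + 0.5 * dt * k2v
        k3v = self.coupled_accel(q + 0.5 * dt * k2q, k3q, t + 0.5 * dt, ctx)
        k4q = qdot + dt * k3v
        k4v = self.coupled_accel(q + dt * k3q, k4q, t + dt, ctx)
        q_new = q + dt / 6.0 * (qdot + 2 * k2q + 2 * k3q + k4q)
        qdot_new = qdot + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
        return q_new, qdot_new


# ---------------------------------------------------------------------------
# load case
# ---------------------------------------------------------------------------


def run_load_case(
    model: HandModel,
    strands: list[Strand],
    cfg: LoadCaseConfig | None = None,
    rod: RodConfig | None = None,
    contact: ContactParams | None = None,
) -> SimulationResult:
    """Simulate one grip-and-retraction load case.

    Flexor strands receive the neural input ``cfg.activation`` from t = 0
    (filtered by first-order activation dynamics); extensors stay at the
    minimum activation.  Deterministic given the configuration.
    """
    cfg = cfg or LoadCaseConfig()
    rod = rod or RodConfig()
    contact = contact or ContactParams()
    eng = _Engine(model, strands)
    dt = cfg.dt
    n_steps = int(round(cfg.t_end / dt))
    radius_eff = rod.diameter / 2.0 + contact.skin_pad

    q = np.zeros((eng.D, 3))
    qdot = np.zeros((eng.D, 3))
    a = eng.a_min.copy()
    l_ce = eng.l_opt.copy()
    v_ce = np.zeros(eng.S)
    u = np.where(eng.is_flexor, cfg.activation, eng.a_min)
    decay_act = -np.expm1(-dt / eng.tau_act)
    decay_deact = -np.expm1(-dt / eng.tau_deact)

    ties_alive = np.zeros((eng.D, 4), dtype=bool)
    tie_offsets = np.zeros((eng.D, 4, 2))
    ties_engaged = False

    rec_idx = np.arange(0, n_steps + 1, cfg.record_stride)
    n_rec = rec_idx.size
    rec = {
        "time": np.zeros(n_rec),
        "f_mtu": np.zeros((n_rec, eng.S)),
        "eps_see": np.zeros((n_rec, eng.S)),
        "activation": np.zeros((n_rec, eng.S)),
        "l_ce": np.zeros((n_rec, eng.S)),
        "q": np.zeros((n_rec, eng.D, 3)),
        "qdot": np.zeros((n_rec, eng.D, 3)),
        "contact_force": np.zeros((n_rec, eng.D)),
        "rod_pos": np.zeros((n_rec, 2)),
    }
    flags: dict = {"grip_at_tR": None}
    r_i = 0
    contact_at_tR_checked = False

    for k in range(n_steps + 1):
        t = k * dt
        # --- muscle state at time t
        lengths, arms = eng.muscle_geometry(q)
        l_mtu = lengths[eng.s_digit, eng.s_muscle] + eng.offset
        arms_s = arms[eng.s_digit, eng.s_muscle, :]  # (S, 3)
        v_mtu = -np.einsum("sj,sj->s", arms_s, qdot[eng.s_digit])
        l_see = l_mtu - l_ce
        f_see = eng.see_force(np.clip(l_see, 0.0, None))
        eps_see = (l_see - eng.l_see0) / eng.l_see0

        # --- contact at time t
        rod_c, rod_v = _rod_state(rod, cfg, t)
        pts, jac = eng.contact_points(q)
        vels = np.einsum("dpjx,dj->dpx", jac, qdot)
        f_pts, f_n = _point_contact(pts, vels, rod_c, rod_v, radius_eff, contact)

        if not ties_engaged and t >= contact.tie_activation_time:
            ties_engaged = True
            ties_alive = f_n > 0.0
            tie_offsets = pts - rod_c
        if ties_engaged and ties_alive.any():
            target = rod_c + tie_offsets
            dvec = target - pts
            elong = np.linalg.norm(dvec, axis=-1)
            ties_alive = ties_alive & (elong < contact.tie_breakaway_elongation)
            f_tie = contact.tie_stiffness * dvec + contact.tie_damping * (
                rod_v[None, None, :] - vels
            )
            f_pts = f_pts + np.where(ties_alive[..., None], f_tie, 0.0)

        if not contact_at_tR_checked and t >= cfg.t_R:
            contact_at_tR_checked = True
            gripped = bool((f_n > 0.0).any() or ties_alive.any())
            flags["grip_at_tR"] = gripped
            if not gripped:
                warnings.warn("grip failure: no hand-rod contact at t_R", stacklevel=2)

        # --- record
        if r_i < n_rec and k == rec_idx[r_i]:
            rec["time"][r_i] = t
            rec["f_mtu"][r_i] = f_see
            rec["eps_see"][r_i] = eps_see
            rec["activation"][r_i] = a
            rec["l_ce"][r_i] = l_ce
            rec["q"][r_i] = q
            rec["qdot"][r_i] = qdot
            rec["contact_force"][r_i] = f_n.sum(axis=-1)
            rec["rod_pos"][r_i] = rod_c
            r_i += 1
        if k == n_steps:
            flags["ties_alive"] = ties_alive.copy()
            flags["tie_offsets"] = tie_offsets.copy()
            break

        # --- advance muscle state
        decay = np.where(u > a, decay_act, decay_deact)
        a = np.clip(a + (u - a) * decay, eng.a_min, 1.0)
        v_ce = eng.solve_vce(a, l_ce, l_see, v_mtu, v_ce)
        l_ce = np.maximum(l_ce + v_ce * dt, 0.2 * eng.l_opt)

        # --- advance skeleton (coupled RK4; muscle force linearized in path
        # length through the tendon stiffness, fiber state frozen in the step)
        l_see_new = np.clip(l_mtu - l_ce, 0.0, None)
        ctx = {
            "q0": q,
            "arms": arms,
            "arms_s": arms_s,
            "f_see0": eng.see_force(l_see_new),
            "k_see": eng.see_stiffness(l_see_new),
            "rod_state": lambda ts: _rod_state(rod, cfg, ts),
            "radius_eff": radius_eff,
            "contact": contact,
            "ties_alive": ties_alive,
            "tie_offsets": tie_offsets,
        }
        q, qdot = eng.coupled_step(q, qdot, dt, t, ctx)
        if not (np.all(np.isfinite(q)) and np.all(np.isfinite(qdot))):
            raise ArithmeticError(f"simulation diverged at t = {t:.5f} s")

    return SimulationResult(
        time=rec["time"],
        f_mtu=rec["f_mtu"],
        eps_see=rec["eps_see"],
        activation=rec["activation"],
        l_ce=rec["l_ce"],
        q=rec["q"],
        qdot=rec["qdot"],
        contact_force=rec["contact_force"],
        rod_pos=rec["rod_pos"],
        strand_names=[s.params.name for s in strands],
        digit_ids=eng.digit_ids,
        config=cfg,
        flags=flags,
    )


def activation_effectiveness(
    result: SimulationResult, strands: list[Strand]
) -> EffectivenessResult:
    """Activation effectiveness eta_a = mean flexor peak force / mean Fmax.

    Peaks are taken over the grip phase [0, t_R]; only FDP and FDS
    strands enter.
    """
    flex = [i for i, s in enumerate(strands) if s.muscle in ("FDP", "FDS")]
    if not flex:
        raise ValueError("no flexor strands in the model")
    sel = result.time <= result.config.t_R + 1e-12
    peaks = result.f_mtu[sel][:, flex].max(axis=0)
    fmax = np.array([strands[i].params.Fmax for i in flex])
    ratios = 100.0 * peaks / fmax
    return EffectivenessResult(
        a=result.config.activation,
        F_bar_mtu=float(peaks.mean()),
        F_bar_max=float(fmax.mean()),
        eta_a=float(100.0 * peaks.mean() / fmax.mean()),
        eta_a_sd=float(ratios.std()),
    )


@dataclass
class ProtocolResult:
    results: list[SimulationResult | None]
    effectiveness: list[EffectivenessResult | None]
    findings: list[list[InjuryFinding]]
    report: "object"  # pandas DataFrame


def _assess_run(
    result: SimulationResult, strands: list[Strand], thresholds: InjuryThresholds
) -> list[InjuryFinding]:
    findings = []
    for i, s in enumerate(strands):
        if s.muscle not in ("FDP", "FDS"):
            continue
        name = s.params.name
        t = result.time
        findings.append(assess_avulsion((t, result.f_mtu[:, i]), thresholds, name))
        findings.append(assess_tsic((t, result.eps_see[:, i]), thresholds, name))
        ce_strain = result.l_ce[:, i] / s.params.ce.l_ce_opt - 1.0
        findings.append(assess_msic((t, ce_strain), thresholds.msic, name))
    return findings


def run_protocol(
    model: HandModel,
    strands: list[Strand],
    base: LoadCaseConfig | None = None,
    rod: RodConfig | None = None,
    contact: ContactParams | None = None,
    thresholds: InjuryThresholds | None = None,
) -> ProtocolResult:
    """Run the 9-simulation protocol and aggregate the injury table.

    Eight retraction runs over the activation grid plus the 100 %
    model-check run without retraction.  A failed run is flagged and the
    protocol continues.
    """
    from .injury import build_report

    base = base or LoadCaseConfig()
    thresholds = thresholds or InjuryThresholds()
    plan = [(a, True) for a in ACTIVATION_GRID] + [(1.0, False)]
    results, effectiveness, findings_all, table = [], [], [], []
    for i, (a, retract) in enumerate(plan, start=1):
        cfg = replace(base, activation=a, retract=retract)
        meta = {"simulation": i, "a": a, "retract": retract}
        try:
            res = run_load_case(model, strands, cfg, rod, contact)
        except ArithmeticError as err:
            warnings.warn(f"simulation {i} failed: {err}", stacklevel=2)
            results.append(None)
            effectiveness.append(None)
            findings_all.append([])
            meta["failed"] = True
            table.append((meta, []))
            continue
        eff = activation_effectiveness(res, strands)
        meta["eta_a"], meta["eta_a_sd"] = eff.eta_a, eff.eta_a_sd
        findings = _assess_run(res, strands, thresholds)
        results.append(res)
        effectiveness.append(eff)
        findings_all.append(findings)
        table.append((meta, findings))
    return ProtocolResult(results, effectiveness, findings_all, build_report(table))
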