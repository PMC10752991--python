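"""Reduced-order planar digit mechanics.

Each digit (index..little, ids 2..5) is a chain of three rigid phalanges
behind a fixed metacarpal, articulated by revolute MCP, PIP and DIP
joints.  The model lives in the flexion (sagittal) plane of the digit:
x points distally along each segment, the palmar side is negative y,
flexion angles are positive and a straight finger is q = 0.

Muscles are routed as polylines through via points attached to the
segments; moment arms follow from the tendon-excursion relation
r_j = -d(path length)/d(q_j).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SEG_METACARPAL",
    "SEG_PROXIMAL",
    "SEG_MIDDLE",
    "SEG_DISTAL",
    "JOINT_NAMES",
    "ViaPoint",
    "DigitGeometry",
    "RevoluteJoint",
    "RoutingPath",
    "HandState",
    "HandModel",
    "forward_kinematics",
    "path_length",
    "moment_arm",
    "joint_torques",
    "passive_torques",
    "mass_matrix",
    "coriolis_bias",
    "step_dynamics",
    "moment_arm_topology",
]

SEG_METACARPAL, SEG_PROXIMAL, SEG_MIDDLE, SEG_DISTAL = 0, 1, 2, 3
JOINT_NAMES = ("MCP", "PIP", "DIP")  # joint j sits between segments j and j+1

_ROT90 = np.array([[0.0, -1.0], [1.0, 0.0]])  # +90 deg (z-hat cross)


@dataclass(frozen=True)
class ViaPoint:
    segment: int  # 0 metacarpal .. 3 distal phalanx
    local: tuple[float, float]  # coordinates in the segment frame (m)
    palmar: bool = True

    def __post_init__(self) -> None:
        if self.segment not in (0, 1, 2, 3):
            raise ValueError("segment id must be 0..3")
        if self.palmar and self.local[1] >= 0:
            raise ValueError("palmar via points must have negative local y")
        if not self.palmar and self.local[1] <= 0:
            raise ValueError("dorsal via points must have positive local y")


@dataclass(frozen=True)
class DigitGeometry:
    """Planar geometry of one digit (2 = index ... 5 = little)."""

    digit_id: int
    segment_lengths: tuple[float, float, float]  # proximal, middle, distal (m)
    metacarpal_length: float = 0.07
    linear_density: float = 0.35  # kg/m, sets segment masses and inertias

    def __post_init__(self) -> None:
        if self.digit_id not in (2, 3, 4, 5):
            raise ValueError("digit_id must be 2..5")
        if any(l <= 0 for l in self.segment_lengths) or self.metacarpal_length <= 0:
            raise ValueError("segment lengths must be positive")

    @property
    def masses(self) -> np.ndarray:
        return self.linear_density * np.asarray(self.segment_lengths)

    @property
    def inertias(self) -> np.ndarray:
        ls = np.asarray(self.segment_lengths)
        return self.masses * ls**2 / 12.0


@dataclass(frozen=True)
class RevoluteJoint:
    """Revolute joint with passive stiffness, damping and ROM penalty."""

    rom: tuple[float, float] = (0.0, np.pi / 2)  # rad
    stiffness: float = 0.01  # N*m/rad about q_rest
    damping: float = 0.002  # N*m*s/rad
    limit_stiffness: float = 5.0  # N*m/rad beyond the ROM
    q_rest: float = 0.0

    def __post_init__(self) -> None:
        if self.rom[0] >= self.rom[1]:
            raise ValueError("rom_min must be below rom_max")
        if self.stiffness < 0 or self.damping < 0:
            raise ValueError("stiffness and damping must be non-negative")


@dataclass(frozen=True)
class RoutingPath:
    """Ordered via points of one muscle strand along one digit."""

    mtu_name: str
    via_points: tuple[ViaPoint, ...]

    def __post_init__(self) -> None:
        if len(self.via_points) < 2:
            raise ValueError(f"{self.mtu_name}: a routing path needs >= 2 points")
        segs = [p.segment for p in self.via_points]
        if any(abs(b - a) > 1 for a, b in zip(segs, segs[1:])):
            raise ValueError(
                f"{self.mtu_name}: consecutive via points must sit on the same "
                "or adjacent segments"
            )

    @property
    def segments(self) -> np.ndarray:
        return np.array([p.segment for p in self.via_points])

    @property
    def locals(self) -> np.ndarray:
        return np.array([p.local for p in self.via_points])

    def crossed_joints(self) -> tuple[int, ...]:
        """Joint indices spanned by the path (joint j: segments j vs j+1)."""
        segs = self.segments
        return tuple(j for j in range(3) if segs.min() <= j and segs.max() > j)

    def with_locals(self, locals_xy: np.ndarray) -> "RoutingPath":
        pts = tuple(
            ViaPoint(p.segment, (float(x), float(y)), p.palmar)
            for p, (x, y) in zip(self.via_points, locals_xy)
        )
        return RoutingPath(self.mtu_name, pts)


@dataclass
class HandState:
    """Joint angles and velocities, shape (n_digits, 3)."""

    q: np.ndarray
    qdot: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.atleast_2d(np.asarray(self.q, dtype=float))
        self.qdot = np.atleast_2d(np.asarray(self.qdot, dtype=float))
        if self.q.shape != self.qdot.shape or self.q.shape[-1] != 3:
            raise ValueError("q and qdot must both have shape (n_digits, 3)")
        if not (np.all(np.isfinite(self.q)) and np.all(np.isfinite(self.qdot))):
            raise ValueError("state must be finite")


@dataclass
class HandModel:
    """Digits 2..5 with joints and muscle routing paths.

    ``paths`` maps ``(digit_id, muscle)`` to a :class:`RoutingPath`;
    muscle is one of "FDP", "FDS", "EXT".
    """

    digits: dict[int, DigitGeometry]
    joints: dict[int, tuple[RevoluteJoint, RevoluteJoint, RevoluteJoint]]
    paths: dict[tuple[int, str], RoutingPath] = field(default_factory=dict)

    @property
    def digit_ids(self) -> list[int]:
        return sorted(self.digits)

    def digit_paths(self, digit_id: int) -> dict[str, RoutingPath]:
        return {m: p for (d, m), p in self.paths.items() if d == digit_id}


# ---------------------------------------------------------------------------
# forward kinematics (batched over arbitrary leading axes of q)
# ---------------------------------------------------------------------------


def _frames(seg_lengths: np.ndarray, metacarpal_length, q: np.ndarray):
    """Origins (..., 4, 2) and rotations (..., 4, 2, 2) of the segment frames.

    ``seg_lengths`` broadcasts against the leading axes of ``q``
    (shape (..., 3)); flexion positive rotates toward the palmar side
    (negative y).
    """
    q = np.asarray(q, dtype=float)
    theta = -np.cumsum(q, axis=-1)  # (..., 3) CCW frame angles
    c, s = np.cos(theta), np.sin(theta)
    rots = np.zeros(q.shape[:-1] + (4, 2, 2))
    rots[..., 0, 0, 0] = 1.0
    rots[..., 0, 1, 1] = 1.0
    rots[..., 1:, 0, 0] = c
    rots[..., 1:, 0, 1] = -s
    rots[..., 1:, 1, 0] = s
    rots[..., 1:, 1, 1] = c

    seg_lengths = np.broadcast_to(np.asarray(seg_lengths, dtype=float), q.shape)
    origins = np.zeros(q.shape[:-1] + (4, 2))
    origins[..., 0, 0] = -np.asarray(metacarpal_length)
    # MCP joint at the global origin; PIP and DIP follow the chain
    origins[..., 2, :] = origins[..., 1, :] + np.einsum(
        "...ij,...j->...i",
        rots[..., 1, :, :],
        np.stack([seg_lengths[..., 0], np.zeros_like(seg_lengths[..., 0])], axis=-1),
    )
    origins[..., 3, :] = origins[..., 2, :] + np.einsum(
        "...ij,...j->...i",
        rots[..., 2, :, :],
        np.stack([seg_lengths[..., 1], np.zeros_like(seg_lengths[..., 1])], axis=-1),
    )
    return origins, rots


def forward_kinematics(digit: DigitGeometry, q: np.ndarray):
    """Segment frame origins and rotation matrices for one digit."""
    return _frames(np.asarray(digit.segment_lengths), digit.metacarpal_length, q)


def _world_points(origins, rots, segments: np.ndarray, locals_xy: np.ndarray):
    """Via-point world coordinates, shape (..., P, 2)."""
    o = origins[..., segments, :]
    r = rots[..., segments, :, :]
    return o + np.einsum("...ij,...j->...i", r, locals_xy)


def _polyline_length(pts: np.ndarray) -> np.ndarray:
    d = np.diff(pts, axis=-2)
    seg = np.linalg.norm(d, axis=-1)
    return seg.sum(axis=-1)


def path_length(digit: DigitGeometry, path: RoutingPath, q: np.ndarray) -> float:
    """Polyline length (m) of the routing path at joint angles ``q`` (rad)."""
    q = np.asarray(q, dtype=float)
    if np.any(np.abs(q) > 2 * np.pi):
        raise ValueError("q must lie within +/- 2*pi")
    origins, rots = forward_kinematics(digit, q)
    pts = _world_points(origins, rots, path.segments, path.locals)
    d = np.linalg.norm(np.diff(pts, axis=-2), axis=-1)
    if np.any(d < 1e-12):
        raise ValueError(f"{path.mtu_name}: coincident consecutive via points")
    return float(d.sum(axis=-1)) if d.ndim == 1 else d.sum(axis=-1)


def moment_arm(
    digit: DigitGeometry,
    path: RoutingPath,
    q: np.ndarray,
    joint_idx: int,
    h: float = 1e-6,
) -> float:
    """Tendon-excursion moment arm r_j = -dL/dq_j by central difference.

    Palmar (flexor) paths give positive flexion arms; a path that does
    not cross the joint yields 0 with a warning.
    """
    if joint_idx not in path.crossed_joints():
        warnings.warn(
            f"{path.mtu_name}: path does not cross joint {JOINT_NAMES[joint_idx]}",
            stacklevel=2,
        )
        return 0.0
    q = np.asarray(q, dtype=float)
    qp, qm = q.copy(), q.copy()
    qp[joint_idx] += h
    qm[joint_idx] -= h
    return -(path_length(digit, path, qp) - path_length(digit, path, qm)) / (2 * h)


# ---------------------------------------------------------------------------
# torques and chain dynamics
# ---------------------------------------------------------------------------


def passive_torques(
    joints: tuple[RevoluteJoint, ...], q: np.ndarray, qdot: np.ndarray
) -> np.ndarray:
    """Stiffness, damping and ROM-penalty torques of one digit (N*m)."""
    q = np.asarray(q, dtype=float)
    qdot = np.asarray(qdot, dtype=float)
    tau = np.zeros_like(q)
    for j, jnt in enumerate(joints):
        tau[..., j] = -jnt.stiffness * (q[..., j] - jnt.q_rest) - jnt.damping * qdot[..., j]
        lo, hi = jnt.rom
        over = np.clip(q[..., j] - hi, 0.0, None)
        under = np.clip(q[..., j] - lo, None, 0.0)
        tau[..., j] -= jnt.limit_stiffness * (over + under)
    return tau


def joint_torques(
    model: HandModel,
    digit_id: int,
    q: np.ndarray,
    mtu_forces: dict[str, float],
    qdot: np.ndarray | None = None,
) -> np.ndarray:
    """Net joint torques of one digit: muscle + passive contributions.

    ``mtu_forces`` maps muscle name ("FDP", ...) to a non-negative strand
    force; each contributes ``r_j * F`` at every joint its path crosses.
    """
    digit = model.digits[digit_id]
    q = np.asarray(q, dtype=float)
    qdot = np.zeros_like(q) if qdot is None else np.asarray(qdot, dtype=float)
    tau = passive_torques(model.joints[digit_id], q, qdot)
    for muscle, force in mtu_forces.items():
        if force < 0:
            raise ValueError("muscle forces must be non-negative")
        path = model.paths[(digit_id, muscle)]
        for j in path.crossed_joints():
            tau[j] += moment_arm(digit, path, q, j) * force
    return tau


def mass_matrix(digit: DigitGeometry, q: np.ndarray) -> np.ndarray:
    """Joint-space mass matrix (3, 3) of the phalanx chain."""
    return _mass_matrix(
        np.asarray(digit.segment_lengths), digit.masses, digit.inertias,
        digit.metacarpal_length, np.asarray(q, dtype=float),
    )


def _com_jacobians(seg_lengths, metacarpal_length, q):
    """COM positions (..., 3, 2), joint centers (..., 3, 2) and COM
    jacobians (..., 3 segs, 3 joints, 2)."""
    origins, rots = _frames(seg_lengths, metacarpal_length, q)
    seg_lengths = np.broadcast_to(np.asarray(seg_lengths, dtype=float), q.shape)
    half = np.stack(
        [seg_lengths / 2.0, np.zeros_like(seg_lengths)], axis=-1
    )  # (..., 3, 2) local COM offsets
    coms = origins[..., 1:, :] + np.einsum("...sij,...sj->...si", rots[..., 1:, :, :], half)
    centers = origins[..., 1:, :]  # joint j center = origin of segment j+1
    rel = coms[..., :, None, :] - centers[..., None, :, :]  # (..., s, j, 2)
    # d p / d q_j = -(z-hat x (p - C_j)) for j <= s, else 0
    jac = np.stack([rel[..., 1], -rel[..., 0]], axis=-1)
    mask = (np.arange(3)[:, None] >= np.arange(3)[None, :])[
        (None,) * (q.ndim - 1) + (Ellipsis,)
    ]
    return coms, centers, jac * mask[..., None]


def _mass_matrix(seg_lengths, masses, inertias, metacarpal_length, q):
    _, _, jac = _com_jacobians(seg_lengths, metacarpal_length, q)
    masses = np.broadcast_to(np.asarray(masses, dtype=float), q.shape)
    inertias = np.broadcast_to(np.asarray(inertias, dtype=float), q.shape)
    m_trans = np.einsum("...s,...sid,...sjd->...ij", masses, jac, jac)
    # angular part: theta_s depends on q_j for j <= s with unit gain
    dep = (np.arange(3)[:, None, None] >= np.arange(3)[None, :, None]) & (
        np.arange(3)[:, None, None] >= np.arange(3)[None, None, :]
    )  # (s, i, j)
    m_ang = np.einsum("...s,sij->...ij", inertias, dep.astype(float))
    return m_trans + m_ang


def coriolis_bias(digit: DigitGeometry, q: np.ndarray, qdot: np.ndarray) -> np.ndarray:
    """Velocity-product generalized forces b(q, qdot) with M qddot + b = Q."""
    return _coriolis_bias(
        np.asarray(digit.segment_lengths), digit.masses, digit.metacarpal_length,
        np.asarray(q, dtype=float), np.asarray(qdot, dtype=float),
    )


def _coriolis_bias(seg_lengths, masses, metacarpal_length, q, qdot):
    origins, rots = _frames(seg_lengths, metacarpal_length, q)
    seg_lengths_b = np.broadcast_to(np.asarray(seg_lengths, dtype=float), q.shape)
    masses = np.broadcast_to(np.asarray(masses, dtype=float), q.shape)
    omega = np.cumsum(qdot, axis=-1)  # |theta_dot| of segments 1..3
    # chain vectors: v_k = R_k * (L_k, 0) for k < s, R_s * (L_s/2, 0) for k = s
    full = np.einsum(
        "...sij,...sj->...si",
        rots[..., 1:, :, :],
        np.stack([seg_lengths_b, np.zeros_like(seg_lengths_b)], axis=-1),
    )  # (..., 3, 2) rotated full segment vectors
    half = 0.5 * full
    # COM acceleration at qddot = 0: a_s = -sum_k omega_k^2 * v_k
    w2 = omega**2
    acc = np.zeros(q.shape[:-1] + (3, 2))
    run = np.zeros(q.shape[:-1] + (2,))
    for s in range(3):
        acc[..., s, :] = -(run + w2[..., s, None] * half[..., s, :])
        run = run + w2[..., s, None] * full[..., s, :]
    _, _, jac = _com_jacobians(seg_lengths, metacarpal_length, q)
    return np.einsum("...s,...sjd,...sd->...j", masses, jac, acc)


def step_dynamics(
    digit: DigitGeometry,
    joints: tuple[RevoluteJoint, ...],
    q: np.ndarray,
    qdot: np.ndarray,
    tau_ext: np.ndarray,
    dt: float,
    dt_max: float = 2e-5,
) -> tuple[np.ndarray, np.ndarray]:
    """One fixed-step RK4 update of a digit chain.

    ``tau_ext`` (e.g. muscle and contact torques) is held constant over
    the step; passive stiffness/damping/ROM torques are re-evaluated at
    the RK4 substates.
    """
    if dt > dt_max * (1 + 1e-12):
        raise ValueError(f"dt = {dt} exceeds stability-checked dt_max = {dt_max}")
    q = np.asarray(q, dtype=float)
    qdot = np.asarray(qdot, dtype=float)
    tau_ext = np.asarray(tau_ext, dtype=float)

    def deriv(qi, qdi):
        tau = tau_ext + passive_torques(joints, qi, qdi)
        m = mass_matrix(digit, qi)
        b = coriolis_bias(digit, qi, qdi)
        return qdi, np.linalg.solve(m, tau - b)

    k1q, k1v = deriv(q, qdot)
    k2q, k2v = deriv(q + 0.5 * dt * k1q, qdot + 0.5 * dt * k1v)
    k3q, k3v = deriv(q + 0.5 * dt * k2q, qdot + 0.5 * dt * k2v)
    k4q, k4v = deriv(q + dt * k3q, qdot + dt * k3v)
    q_new = q + dt / 6.0 * (k1q + 2 * k2q + 2 * k3q + k4q)
    qdot_new = qdot + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
    if not (np.all(np.isfinite(q_new)) and np.all(np.isfinite(qdot_new))):
        raise ArithmeticError("non-finite digit state after dynamics step")
    return q_new, qdot_new


def moment_arm_topology(model: HandModel) -> list[tuple[str, str, int]]:
    """All (muscle, joint, digit) flexor moment-arm curves the topology yields.

    FDP crosses MCP+PIP+DIP on each digit, FDS crosses MCP+PIP; with
    digits 2..5 this is the full 20-curve set.
    """
    out = []
    for (digit_id, muscle), p in sorted(model.paths.items()):
        if muscle not in ("FDP", "FDS"):
            continue
        for j in p.crossed_joints():
            out.append((muscle, JOINT_NAMES[j], digit_id))
    return out
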