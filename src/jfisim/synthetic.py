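"""Synthetic reference data and the default hand fixture.

The calibration stages need reference inputs that in practice come from
the experimental literature: joint-angle-dependent moment-arm curves of
the deep and superficial finger flexors, tendon stress-strain curves of
unembalmed human tendons, and whole-muscle Hill parameters.  None of
those datasets are redistributable, so this module generates
statistically controlled surrogates: smooth moment-arm curves anchored
at literature-scale means (FDP over MCP around 9.7 mm), piecewise
toe/linear/necking stress-strain curves with a configurable linear
modulus, and a planar four-digit hand with FDP/FDS/extensor strands
whose parameters are plausible but synthetic.

All generators are deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hand import (
    JOINT_NAMES,
    DigitGeometry,
    HandModel,
    RevoluteJoint,
    RoutingPath,
    ViaPoint,
    path_length,
)
from .mtu import (
    ActivationParams,
    CEParams,
    MTUParams,
    PEEParams,
    SEEParams,
    StrandSpec,
    init_equilibrium,
    scale_fmax,
)
from .routing import MomentArmCurve
from .tendon import StressStrainCurve, _stress

__all__ = [
    "Strand",
    "MomentArmReferenceSpec",
    "TendonReferenceSpec",
    "HandFixtureSpec",
    "gen_moment_arm_reference",
    "gen_tendon_reference",
    "gen_hand_fixture",
]


@dataclass(frozen=True)
class Strand:
    """One assembled muscle strand: parameters plus its routing context.

    ``path_offset`` converts the geometric in-hand path length into the
    effective MTU length: l_mtu(t) = path(q(t)) + path_offset.  It
    contains the extra-hand (forearm) tendon/belly length and the
    initialization scaling offset (c_e,f - 1) * l_mtu_i, so that at the
    initial posture the strand sits exactly at its length equilibrium
    (fiber at optimal length, tendon at rest length).
    """

    params: MTUParams
    digit_id: int
    muscle: str  # "FDP" | "FDS" | "EXT"
    path_offset: float
    l_mtu_i: float  # unscaled initial MTU length (path + forearm constant)


# ---------------------------------------------------------------------------
# moment-arm reference curves
# ---------------------------------------------------------------------------

_JOINT_RANGES_DEG = {"MCP": 90.0, "PIP": 100.0, "DIP": 80.0}

# literature-scale mean arms (m); FDP over MCP anchored at 9.7 mm
_DEFAULT_MEANS = {
    ("FDP", "MCP"): 0.0097,
    ("FDP", "PIP"): 0.0062,
    ("FDP", "DIP"): 0.0042,
    ("FDS", "MCP"): 0.0090,
    ("FDS", "PIP"): 0.0058,
}


@dataclass(frozen=True)
class MomentArmReferenceSpec:
    """Statistical description of the surrogate moment-arm curves.

    Arms follow ``mean * digit_scale * (1 + c1*(x-1/2) + c2*(x-1/2)^2)``
    with x the normalized joint angle, plus additive white noise.
    """

    means: dict = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    digit_scale: dict = field(
        default_factory=lambda: {2: 0.97, 3: 1.05, 4: 1.0, 5: 0.85}
    )
    shape_c1: float = 0.25
    shape_c2: float = -0.15
    noise_sd: float = 0.0  # m
    n_samples: int = 46
    digits: tuple[int, ...] = (2, 3, 4, 5)

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.means.values()):
            raise ValueError("mean arms must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


def gen_moment_arm_reference(
    spec: MomentArmReferenceSpec | None = None, seed: int = 0
) -> list[MomentArmCurve]:
    """Generate the full surrogate curve set (20 curves for FDP+FDS)."""
    spec = spec or MomentArmReferenceSpec()
    rng = np.random.default_rng(seed)
    curves = []
    for (muscle, joint), mean in sorted(spec.means.items()):
        for d in spec.digits:
            hi = np.deg2rad(_JOINT_RANGES_DEG[joint])
            angles = np.linspace(0.0, hi, spec.n_samples)
            x = angles / hi - 0.5
            arms = mean * spec.digit_scale[d] * (
                1.0 + spec.shape_c1 * x + spec.shape_c2 * x**2
            )
            if spec.noise_sd > 0:
                arms = arms + rng.normal(0.0, spec.noise_sd, arms.shape)
            curves.append(MomentArmCurve(d, muscle, joint, angles, arms))
    return curves


# ---------------------------------------------------------------------------
# tendon stress-strain reference
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TendonReferenceSpec:
    """Piecewise toe / linear / necking stress-strain surrogate.

    With ``necking = False`` the curve is exactly a member of the
    serial-elastic model family (toe exponent chosen for C1 continuity),
    so a parameter fit recovers it perfectly.
    """

    toe_end_strain: float = 0.015
    linear_end_strain: float = 0.04
    linear_modulus: float = 2.4e9  # Pa
    toe_transition_stress: float = 12e6  # Pa, stress at the toe/linear transition
    necking: bool = True
    necking_modulus_fraction: float = 0.25
    failure_strain: float = 0.10
    eps_max: float = 0.06
    n_samples: int = 200
    noise_sd: float = 0.0  # Pa

    def __post_init__(self) -> None:
        if not (0 < self.toe_end_strain < self.linear_end_strain < self.failure_strain):
            raise ValueError("require 0 < toe_end < linear_end < failure_strain")
        if self.linear_modulus <= 0 or self.toe_transition_stress <= 0:
            raise ValueError("moduli and stresses must be positive")


def gen_tendon_reference(
    spec: TendonReferenceSpec | None = None, seed: int = 0
) -> StressStrainCurve:
    """Generate the surrogate tendon stress-strain curve (C0 everywhere)."""
    spec = spec or TendonReferenceSpec()
    rng = np.random.default_rng(seed)
    eps = np.linspace(0.0, spec.eps_max, spec.n_samples)
    # toe + linear parts exactly in the SEE family: dU_l = sigma0 / E_lin
    dU_l = spec.toe_transition_stress / spec.linear_modulus
    sig = _stress(1.0, spec.toe_end_strain, dU_l, spec.toe_transition_stress, eps)
    if spec.necking:
        e_neck = spec.necking_modulus_fraction * spec.linear_modulus
        sig_lin_end = _stress(
            1.0, spec.toe_end_strain, dU_l, spec.toe_transition_stress,
            np.array([spec.linear_end_strain]),
        )[0]
        past = eps > spec.linear_end_strain
        sig = np.where(past, sig_lin_end + e_neck * (eps - spec.linear_end_strain), sig)
    if spec.noise_sd > 0:
        sig = sig + rng.normal(0.0, spec.noise_sd, sig.shape)
    return StressStrainCurve(eps, np.clip(sig, 0.0, None), label="reference")


# ---------------------------------------------------------------------------
# hand fixture
# ---------------------------------------------------------------------------

_SEGMENT_LENGTHS = {
    2: (0.045, 0.027, 0.020),
    3: (0.050, 0.030, 0.022),
    4: (0.046, 0.029, 0.021),
    5: (0.038, 0.023, 0.018),
}

_ROM_DEG = {"MCP": (0.0, 90.0), "PIP": (0.0, 100.0), "DIP": (0.0, 80.0)}


@dataclass(frozen=True)
class HandFixtureSpec:
    """Parameters of the synthetic planar hand (digits 2-5).

    Whole-muscle maximum isometric forces are synthetic stand-ins of
    plausible magnitude, split over parallel strands (one per digit);
    the normalization stress Fmax/CSA = 30 MPa ties the strand CSA to
    its Fmax so the tuned tendon parameter set yields a 2.4 GPa
    Young's modulus.
    """

    segment_lengths: dict = field(default_factory=lambda: dict(_SEGMENT_LENGTHS))
    metacarpal_length: float = 0.07
    linear_density: float = 0.35  # kg/m
    whole_fmax: dict = field(
        default_factory=lambda: {"FDP": 360.0, "FDS": 320.0, "EXT": 80.0}
    )
    l_ce_opt: dict = field(
        default_factory=lambda: {"FDP": 0.068, "FDS": 0.072, "EXT": 0.058}
    )
    forearm_length: dict = field(
        default_factory=lambda: {"FDP": 0.15, "FDS": 0.14, "EXT": 0.12}
    )
    see: SEEParams = field(default_factory=lambda: SEEParams(0.8, 0.02, 0.01))
    normalization_stress: float = 30e6  # Pa, Fmax / CSA
    c_e_f: tuple[float, float] = (0.95, 1.05)  # (extensors, flexors)
    d_se_frac: float = 0.2  # serial damping, N*s/m per newton of Fmax
    joint_stiffness: float = 0.01
    joint_damping: float = 0.002
    limit_stiffness: float = 5.0


def _flexor_path(name: str, muscle: str, Lmc: float, Lp: float, Lm: float) -> RoutingPath:
    pts = [
        ViaPoint(0, (0.008, -0.0080)),
        ViaPoint(0, (Lmc - 0.010, -0.0085)),
        ViaPoint(1, (0.010, -0.0065)),
        ViaPoint(1, (Lp - 0.008, -0.0050)),
        ViaPoint(2, (0.008, -0.0042)),
    ]
    if muscle == "FDP":
        pts += [ViaPoint(2, (Lm - 0.006, -0.0036)), ViaPoint(3, (0.006, -0.0030))]
    else:  # FDS inserts on the middle phalanx
        pts += [ViaPoint(2, (Lm - 0.006, -0.0038))]
    return RoutingPath(name, tuple(pts))


def _extensor_path(name: str, Lmc: float, Lp: float, Lm: float) -> RoutingPath:
    pts = (
        ViaPoint(0, (0.008, 0.0060), palmar=False),
        ViaPoint(0, (Lmc - 0.008, 0.0055), palmar=False),
        ViaPoint(1, (0.008, 0.0045), palmar=False),
        ViaPoint(1, (Lp - 0.006, 0.0035), palmar=False),
        ViaPoint(2, (0.006, 0.0030), palmar=False),
        ViaPoint(2, (Lm - 0.005, 0.0026), palmar=False),
        ViaPoint(3, (0.005, 0.0022), palmar=False),
    )
    return RoutingPath(name, pts)


def gen_hand_fixture(
    spec: HandFixtureSpec | None = None,
) -> tuple[HandModel, list[Strand]]:
    """Build the synthetic hand: 4 digits x (FDP + FDS + extensor) strands.

    Every strand is initialized to its length equilibrium at the straight
    posture (q = 0): fiber at optimal length, tendon at the rest length
    from the extensor/flexor scaling rule.
    """
    spec = spec or HandFixtureSpec()
    digits, joints, paths = {}, {}, {}
    for d, segs in sorted(spec.segment_lengths.items()):
        digits[d] = DigitGeometry(
            d, tuple(segs), spec.metacarpal_length, spec.linear_density
        )
        joints[d] = tuple(
            RevoluteJoint(
                rom=tuple(np.deg2rad(_ROM_DEG[j])),
                stiffness=spec.joint_stiffness,
                damping=spec.joint_damping,
                limit_stiffness=spec.limit_stiffness,
            )
            for j in JOINT_NAMES
        )
        Lmc, (Lp, Lm, _) = spec.metacarpal_length, segs
        paths[(d, "FDP")] = _flexor_path(f"FDP {d}", "FDP", Lmc, Lp, Lm)
        paths[(d, "FDS")] = _flexor_path(f"FDS {d}", "FDS", Lmc, Lp, Lm)
        paths[(d, "EXT")] = _extensor_path(f"EXT {d}", Lmc, Lp, Lm)
    model = HandModel(digits, joints, paths)

    strands = []
    n_digits = len(digits)
    for muscle in ("FDP", "FDS", "EXT"):
        strand_spec = StrandSpec(spec.whole_fmax[muscle], n_digits)
        fmax = scale_fmax(strand_spec)
        group = "extensor" if muscle == "EXT" else "flexor"
        for d in sorted(digits):
            name = f"{muscle} {d}"
            l_path0 = path_length(digits[d], paths[(d, muscle)], np.zeros(3))
            l_mtu_i = l_path0 + spec.forearm_length[muscle]
            l_ce_opt = spec.l_ce_opt[muscle]
            _, l_see_0 = init_equilibrium(l_mtu_i, l_ce_opt, group, spec.c_e_f, name)
            c = spec.c_e_f[1] if group == "flexor" else spec.c_e_f[0]
            params = MTUParams(
                name=name,
                Fmax=fmax,
                csa=fmax / spec.normalization_stress,
                see=spec.see.with_rest_length(l_see_0),
                ce=CEParams(l_ce_opt=l_ce_opt),
                pee=PEEParams(),
                act=ActivationParams(),
                group=group,
                d_se=spec.d_se_frac * fmax,
            )
            strands.append(
                Strand(
                    params=params,
                    digit_id=d,
                    muscle=muscle,
                    path_offset=l_mtu_i - l_path0 + (c - 1.0) * l_mtu_i,
                    l_mtu_i=l_mtu_i,
                )
            )
    return model, strands
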