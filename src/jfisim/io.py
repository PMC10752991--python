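"""Plain-text I/O: parameter tables, curve CSVs, reports, geometry configs.

Numbers are written with full ``repr`` precision so that read/write
round-trips are bit-exact.  Config files may declare their units
(length: m/mm, stress: Pa/MPa/GPa, time: s/ms); values are converted to
SI on load.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hand import DigitGeometry, HandModel, RevoluteJoint, RoutingPath, ViaPoint
from .injury import InjuryFinding
from .mtu import ActivationParams, CEParams, MTUParams, PEEParams, SEEParams
from .routing import MomentArmCurve
from .synthetic import Strand
from .tendon import StressStrainCurve

__all__ = [
    "write_muscle_table",
    "read_muscle_table",
    "write_moment_arm_curves",
    "read_moment_arm_curves",
    "write_stress_strain",
    "read_stress_strain",
    "write_simulation_result",
    "write_injury_findings",
    "write_hand_geometry",
    "read_hand_geometry",
]

_LENGTH = {"m": 1.0, "mm": 1e-3}
_STRESS = {"Pa": 1.0, "MPa": 1e6, "GPa": 1e9}
_TIME = {"s": 1.0, "ms": 1e-3}


# ---------------------------------------------------------------------------
# muscle parameter table
# ---------------------------------------------------------------------------

_MTU_COLS = [
    "name", "digit", "muscle", "group", "Fmax", "csa", "l_ce_opt",
    "dF_see_0_frac", "dU_see_nll", "dU_see_l", "l_see_0",
    "dW_asc", "dW_desc", "nu_asc", "nu_desc", "a_rel", "b_rel", "F_ecc", "S_ecc",
    "L_pee_0", "F_pee", "nu_pee", "tau_act", "tau_deact", "a_min",
    "d_se", "path_offset", "l_mtu_i",
]


def write_muscle_table(strands: list[Strand], path) -> None:
    """One row per strand; full-precision CSV that round-trips bit-exactly."""
    rows = []
    for s in strands:
        p = s.params
        rows.append({
            "name": p.name, "digit": s.digit_id, "muscle": s.muscle,
            "group": p.group, "Fmax": p.Fmax, "csa": p.csa,
            "l_ce_opt": p.ce.l_ce_opt,
            "dF_see_0_frac": p.see.dF_see_0_frac, "dU_see_nll": p.see.dU_see_nll,
            "dU_see_l": p.see.dU_see_l, "l_see_0": p.see.l_see_0,
            "dW_asc": p.ce.dW_asc, "dW_desc": p.ce.dW_desc,
            "nu_asc": p.ce.nu_asc, "nu_desc": p.ce.nu_desc,
            "a_rel": p.ce.a_rel, "b_rel": p.ce.b_rel,
            "F_ecc": p.ce.F_ecc, "S_ecc": p.ce.S_ecc,
            "L_pee_0": p.pee.L_pee_0, "F_pee": p.pee.F_pee, "nu_pee": p.pee.nu_pee,
            "tau_act": p.act.tau_act, "tau_deact": p.act.tau_deact,
            "a_min": p.act.a_min, "d_se": p.d_se,
            "path_offset": s.path_offset, "l_mtu_i": s.l_mtu_i,
        })
    pd.DataFrame(rows, columns=_MTU_COLS).to_csv(path, index=False)


def read_muscle_table(path) -> list[Strand]:
    df = pd.read_csv(path, float_precision="round_trip")
    strands = []
    for _, r in df.iterrows():
        params = MTUParams(
            name=r["name"], Fmax=r["Fmax"], csa=r["csa"],
            see=SEEParams(r["dF_see_0_frac"], r["dU_see_nll"], r["dU_see_l"],
                          r["l_see_0"]),
            ce=CEParams(r["l_ce_opt"], r["dW_asc"], r["dW_desc"], r["nu_asc"],
                        r["nu_desc"], r["a_rel"], r["b_rel"], r["F_ecc"], r["S_ecc"]),
            pee=PEEParams(r["L_pee_0"], r["F_pee"], r["nu_pee"]),
            act=ActivationParams(r["tau_act"], r["tau_deact"], r["a_min"]),
            group=r["group"], d_se=r["d_se"],
        )
        strands.append(Strand(params, int(r["digit"]), r["muscle"],
                              r["path_offset"], r["l_mtu_i"]))
    return strands


# ---------------------------------------------------------------------------
# curves
# ---------------------------------------------------------------------------


def write_moment_arm_curves(curves: list[MomentArmCurve], path) -> None:
    """Long-format CSV: digit, muscle, joint, angle_deg, arm_mm."""
    rows = []
    for c in curves:
        for ang, arm in zip(c.angles, c.arms):
            rows.append({"digit": c.digit, "muscle": c.muscle, "joint": c.joint,
                         "angle_deg": np.rad2deg(ang), "arm_mm": arm * 1e3,
                         "source": c.source})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_moment_arm_curves(path) -> list[MomentArmCurve]:
    df = pd.read_csv(path, float_precision="round_trip")
    curves = []
    for (d, m, j, src), grp in df.groupby(["digit", "muscle", "joint", "source"],
                                          sort=True):
        grp = grp.sort_values("angle_deg")
        curves.append(MomentArmCurve(
            int(d), m, j, np.deg2rad(grp["angle_deg"].to_numpy()),
            grp["arm_mm"].to_numpy() * 1e-3, src,
        ))
    return curves


def write_stress_strain(curve: StressStrainCurve, path) -> None:
    pd.DataFrame({
        "strain": curve.strains, "stress_MPa": curve.stresses / 1e6,
    }).to_csv(path, index=False)


def read_stress_strain(path, label: str = "reference") -> StressStrainCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    return StressStrainCurve(df["strain"].to_numpy(),
                             df["stress_MPa"].to_numpy() * 1e6, label)


# ---------------------------------------------------------------------------
# simulation results and injury reports
# ---------------------------------------------------------------------------


def write_simulation_result(result, path) -> None:
    """Wide CSV time series: forces, strains, activations, angles, contact."""
    data = {"t_s": result.time}
    for i, name in enumerate(result.strand_names):
        key = name.replace(" ", "")
        data[f"F_mtu_N_{key}"] = result.f_mtu[:, i]
        data[f"eps_see_{key}"] = result.eps_see[:, i]
        data[f"a_{key}"] = result.activation[:, i]
    for di, d in enumerate(result.digit_ids):
        for j, jn in enumerate(("MCP", "PIP", "DIP")):
            data[f"q_rad_d{d}_{jn}"] = result.q[:, di, j]
        data[f"contact_N_d{d}"] = result.contact_force[:, di]
    data["rod_x_m"] = result.rod_pos[:, 0]
    data["rod_y_m"] = result.rod_pos[:, 1]
    pd.DataFrame(data).to_csv(path, index=False)


def write_routing_fit(result, path) -> None:
    """Routing fit report: per-curve MAE/NMAE plus the optimized via points."""
    doc = {
        "converged": bool(result.converged),
        "iterations": int(result.iterations),
        "curves": [
            {"digit": d, "muscle": m, "joint": j,
             "mae_mm": mae * 1e3, "nmae_percent": val}
            for (d, m, j), (mae, val) in sorted(result.per_curve.items())
        ],
        "via_points": {
            str(d): [{"segment": int(pt.segment),
                      "xy_mm": [pt.local[0] * 1e3, pt.local[1] * 1e3],
                      "palmar": pt.palmar}
                     for pt in p.via_points]
            for d, p in sorted(result.paths.items())
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def write_tendon_fit(result, path) -> None:
    """Tendon fit report: fitted parameters, windowed NMAE scores, modulus."""
    doc = {
        "dF_see_0_frac": result.see.dF_see_0_frac,
        "dU_see_nll": result.see.dU_see_nll,
        "dU_see_l": result.see.dU_see_l,
        "nmae3_percent": result.nmae3,
        "nmae5_percent": result.nmae5,
        "E_GPa": result.E / 1e9,
        "converged": bool(result.converged),
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def write_injury_findings(findings: list[InjuryFinding], path) -> None:
    Path(path).write_text(
        json.dumps([dataclasses.asdict(f) for f in findings], indent=2)
    )


# ---------------------------------------------------------------------------
# hand geometry config (YAML, unit-aware)
# ---------------------------------------------------------------------------


def write_hand_geometry(model: HandModel, path, length_unit: str = "mm") -> None:
    scale = _LENGTH[length_unit]
    doc: dict = {"units": {"length": length_unit, "angle": "deg"}, "digits": {}}
    for d in model.digit_ids:
        g = model.digits[d]
        joints = model.joints[d]
        doc["digits"][d] = {
            "segment_lengths": [l / scale for l in g.segment_lengths],
            "metacarpal_length": g.metacarpal_length / scale,
            "linear_density": g.linear_density,
            "joints": [
                {"rom_deg": [float(np.rad2deg(j.rom[0])),
                             float(np.rad2deg(j.rom[1]))],
                 "stiffness": j.stiffness, "damping": j.damping,
                 "limit_stiffness": j.limit_stiffness}
                for j in joints
            ],
            "paths": {
                m: [{"segment": p.segment,
                     "xy": [p.local[0] / scale, p.local[1] / scale],
                     "palmar": p.palmar}
                    for p in model.paths[(d, m)].via_points]
                for m in sorted(mm for (dd, mm) in model.paths if dd == d)
            },
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_hand_geometry(path) -> HandModel:
    doc = yaml.safe_load(Path(path).read_text())
    scale = _LENGTH[doc.get("units", {}).get("length", "m")]
    digits, joints, paths = {}, {}, {}
    for d, spec in doc["digits"].items():
        d = int(d)
        digits[d] = DigitGeometry(
            d, tuple(x * scale for x in spec["segment_lengths"]),
            spec["metacarpal_length"] * scale, spec.get("linear_density", 0.35),
        )
        joints[d] = tuple(
            RevoluteJoint(
                rom=(float(np.deg2rad(j["rom_deg"][0])),
                     float(np.deg2rad(j["rom_deg"][1]))),
                stiffness=j["stiffness"], damping=j["damping"],
                limit_stiffness=j["limit_stiffness"],
            )
            for j in spec["joints"]
        )
        for m, pts in spec["paths"].items():
            paths[(d, m)] = RoutingPath(f"{m} {d}", tuple(
                ViaPoint(p["segment"], (p["xy"][0] * scale, p["xy"][1] * scale),
                         p["palmar"])
                for p in pts
            ))
    return HandModel(digits, joints, paths)
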