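"""Jersey-finger injury criteria.

The combined criterion grades two mechanisms:

* tendon avulsion — the distal tendon insertion tears off the bone when
  the MTU force exceeds the lowest avulsion load reported for the FDP
  insertion (10.8 kg, i.e. 105.91 N);
* tendon strain injury (TSIC) — severity graded by peak engineering
  tendon strain: minor at 4 % (start of strain hardening), major at 8 %
  (start of necking), rupture at 10 % (material failure).

A muscle strain criterion (MSIC) with the same grading semantics can be
applied to the contractile-element strain; its thresholds are not set by
default and must be supplied from the literature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .mtu import STANDARD_GRAVITY

__all__ = [
    "InjuryThresholds",
    "InjuryFinding",
    "load_to_force",
    "assess_tsic",
    "assess_avulsion",
    "assess_msic",
    "build_report",
]

_TSIC_GRADES = ("minor", "major", "rupture")
_TYPE_LABELS = {
    "AVULSION": "Tendon Avulsion",
    "TSIC": "Tendon Strain",
    "MSIC": "Muscle Strain",
}


def load_to_force(mass: float) -> float:
    """Convert a hanging mass (kg) to force (N) with standard gravity.

    10.8 kg -> 105.91 N (to two decimals); rounding happens only at
    reporting, the returned value is exact.
    """
    if mass < 0:
        raise ValueError("mass must be non-negative")
    return mass * STANDARD_GRAVITY


@dataclass(frozen=True)
class InjuryThresholds:
    """TSIC strain grades, avulsion force, optional MSIC strain triple."""

    tsic_minor: float = 0.04
    tsic_major: float = 0.08
    tsic_rupture: float = 0.10
    avulsion_force: float = load_to_force(10.8)  # 105.91 N
    msic: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not (0 < self.tsic_minor < self.tsic_major < self.tsic_rupture):
            raise ValueError("TSIC thresholds must satisfy 0 < minor < major < rupture")
        if self.avulsion_force <= 0:
            raise ValueError("avulsion force must be positive")
        if self.msic is not None and not (
            0 < self.msic[0] < self.msic[1] < self.msic[2]
        ):
            raise ValueError("MSIC thresholds must be strictly increasing")


@dataclass(frozen=True)
class InjuryFinding:
    mtu_name: str
    criterion: str  # "TSIC" | "AVULSION" | "MSIC"
    severity: str  # none | minor | major | rupture | avulsion | not_evaluated
    first_crossing_time: float | None  # s; None when severity is none
    peak_value: float  # strain or N depending on criterion

    @property
    def injured(self) -> bool:
        return self.severity not in ("none", "not_evaluated")


def _check_series(times, values) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size == 0 or times.shape != values.shape:
        raise ValueError("series must be non-empty with matching time grid")
    if not (np.all(np.isfinite(times)) and np.all(np.isfinite(values))):
        raise ValueError("series must be finite")
    return times, values


def _grade(times, values, grades: Sequence[tuple[float, str]], criterion, name):
    """Inclusive (>=) grading by peak value; crossing time of the top grade."""
    peak = float(values.max())
    severity, first_t = "none", None
    for thr, label in grades:
        if peak >= thr:
            severity = label
            first_t = float(times[np.argmax(values >= thr)])
    return InjuryFinding(name, criterion, severity, first_t, peak)


def assess_tsic(
    strain_series, thresholds: InjuryThresholds, name: str = "MTU"
) -> InjuryFinding:
    """Grade a tendon strain time series (times, strains) with the TSIC."""
    times, strains = _check_series(*strain_series)
    grades = list(
        zip((thresholds.tsic_minor, thresholds.tsic_major, thresholds.tsic_rupture),
            _TSIC_GRADES)
    )
    return _grade(times, strains, grades, "TSIC", name)


def assess_avulsion(
    force_series, thresholds: InjuryThresholds, name: str = "MTU"
) -> InjuryFinding:
    """Avulsion if the peak MTU force reaches the avulsion threshold."""
    times, forces = _check_series(*force_series)
    if np.any(forces < 0):
        raise ValueError("forces must be non-negative")
    return _grade(times, forces, [(thresholds.avulsion_force, "avulsion")],
                  "AVULSION", name)


def assess_msic(
    fiber_strain_series,
    msic_thresholds: tuple[float, float, float] | None,
    name: str = "MTU",
) -> InjuryFinding:
    """Grade contractile-element strain (l_ce/l_ce_opt - 1) like the TSIC.

    With no thresholds supplied the finding is marked not evaluated.
    """
    times, strains = _check_series(*fiber_strain_series)
    if msic_thresholds is None:
        return InjuryFinding(name, "MSIC", "not_evaluated", None, float(strains.max()))
    lo, mid, hi = msic_thresholds
    if not (lo < mid < hi):
        raise ValueError("MSIC thresholds must be strictly increasing")
    return _grade(times, strains, list(zip((lo, mid, hi), _TSIC_GRADES)), "MSIC", name)


def build_report(
    findings_per_simulation: list[tuple[dict, list[InjuryFinding]]],
) -> pd.DataFrame:
    """Aggregate findings into a protocol summary table.

    Each entry is (metadata, findings); metadata may carry
    ``simulation``, ``a`` (activation, 0..1), ``eta_a`` / ``eta_a_sd``
    (percent) and ``retract``.  Injured MTUs are named "FDP 3"-style
    (3 = middle finger).
    """
    rows = []
    for meta, findings in findings_per_simulation:
        injured = [f for f in findings if f.injured]
        types = sorted({_TYPE_LABELS[f.criterion] for f in injured})
        eta = meta.get("eta_a")
        eta_sd = meta.get("eta_a_sd")
        if eta is not None and eta_sd is not None:
            eta_str = f"{eta:.1f} ± {eta_sd:.1f}"
        elif eta is not None:
            eta_str = f"{eta:.1f}"
        else:
            eta_str = ""
        rows.append(
            {
                "Simulation No.": meta.get("simulation"),
                "a [%]": 100.0 * meta["a"] if "a" in meta else None,
                "eta_a [%]": eta_str,
                "Rod retraction": "Yes" if meta.get("retract", True) else "No",
                "No. of injuries": len(injured),
                "Type of injury": ", ".join(types) if types else "-",
                "Injured MTU": ", ".join(f.mtu_name for f in injured) or "-",
            }
        )
    return pd.DataFrame(rows)
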