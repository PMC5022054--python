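"""Per-system sensitivity estimation and linear calibration.

A test system's sensitivity z_x is the mean difference between its
observed responses and the pooled model's intrinsic values.  On top of
that, a per-system linear calibration

    observed ~ alpha_x * (intrinsic + z_x) + beta_x

rescales the pooled prediction onto the system's own response scale; the
reference system has (z, alpha, beta) = (0, 1, 0) by convention.  The same
two-stage procedure onboards a brand-new test system from a handful of
measurements against a frozen pooled model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data_model import DescriptorTable, IonDescriptors, ToxicityRecord
from .pooled import PooledModelFit, intrinsic_value, published_table


@dataclass(frozen=True)
class SystemCalibration:
    """Sensitivity and calibration line of one test system."""

    system_id: str
    z: float  # log units
    alpha: float  # dimensionless slope
    beta: float  # log units
    r_squared: float
    se: float  # log units
    n: int

    def to_dict(self) -> dict:
        return {
            "system_id": self.system_id,
            "z": self.z,
            "alpha": self.alpha,
            "beta": self.beta,
            "r_squared": self.r_squared,
            "se": self.se,
            "n": self.n,
        }


def estimate_z(
    observed: Sequence[float], calculated: Sequence[float]
) -> float:
    """Sensitivity offset: mean of (observed - calculated)."""
    obs = np.asarray(observed, dtype=float)
    calc = np.asarray(calculated, dtype=float)
    if obs.size == 0:
        raise ValueError("cannot estimate z from zero observations")
    if obs.shape != calc.shape:
        raise ValueError("observed and calculated must have equal length")
    return float(np.mean(obs - calc))


def calibrate(
    observed: Sequence[float], calculated: Sequence[float]
) -> tuple[float, float, float, float]:
    """OLS line observed ~ alpha*calculated + beta.

    Returns (alpha, beta, r_squared, se) with se = sqrt(RSS/(n-2)).
    Requires at least three points and a non-degenerate predictor.
    """
    obs = np.asarray(observed, dtype=float)
    calc = np.asarray(calculated, dtype=float)
    if obs.shape != calc.shape:
        raise ValueError("observed and calculated must have equal length")
    n = obs.size
    if n < 3:
        raise ValueError(f"need at least 3 points to calibrate, got {n}")
    if np.ptp(calc) == 0.0:
        raise ValueError("calculated values have zero variance; cannot fit a slope")
    fit = stats.linregress(calc, obs)
    alpha, beta = float(fit.slope), float(fit.intercept)
    resid = obs - (alpha * calc + beta)
    se = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    return alpha, beta, float(fit.rvalue**2), se


def predict_eq5(
    cation: IonDescriptors,
    anion: IonDescriptors,
    system_id: str,
    model: PooledModelFit,
    calibrations: Mapping[str, SystemCalibration],
    include_z: bool = True,
) -> float:
    """Calibrated prediction alpha_x*(intrinsic + z_x) + beta_x.

    ``include_z=False`` switches to the alternative convention where the
    calibration line was fitted against the z-free intrinsic value.
    """
    if system_id not in calibrations:
        raise KeyError(
            f"no calibration for system {system_id!r}; "
            "onboard it first with onboard_system()"
        )
    cal = calibrations[system_id]
    base = intrinsic_value(cation, anion, model)
    if include_z:
        base += cal.z
    return cal.alpha * base + cal.beta


def onboard_system(
    new_records: Sequence[ToxicityRecord],
    descriptors: DescriptorTable,
    model: PooledModelFit,
    min_points: int = 5,
    include_z: bool = True,
) -> SystemCalibration:
    """Estimate (z, alpha, beta) for a new test system from a few records.

    All records must come from a single system.  Intrinsic values are
    computed with the frozen pooled model, z is the mean observed-minus-
    intrinsic difference, and (alpha, beta) are fitted by OLS of the
    observed responses on the z-shifted (or, with ``include_z=False``,
    z-free) intrinsic values.
    """
    records = list(new_records)
    if not records:
        raise ValueError("no records to onboard")
    systems = {r.system_id for r in records}
    if len(systems) != 1:
        raise ValueError(f"records span several systems: {', '.join(sorted(systems))}")
    if len(records) < min_points:
        raise ValueError(
            f"need at least {min_points} records to onboard a system, "
            f"got {len(records)}"
        )
    system_id = records[0].system_id
    obs = np.array([r.response for r in records])
    try:
        calc = np.array(
            [
                intrinsic_value(
                    descriptors.get(r.cation_id, "cation"),
                    descriptors.get(r.anion_id, "anion"),
                    model,
                )
                for r in records
            ]
        )
    except KeyError as exc:
        raise ValueError(f"onboarding {system_id!r}: {exc.args[0]}") from exc
    z = estimate_z(obs, calc)
    predictor = calc + z if include_z else calc
    alpha, beta, r2, se = calibrate(obs, predictor)
    return SystemCalibration(
        system_id=system_id, z=z, alpha=alpha, beta=beta,
        r_squared=r2, se=se, n=len(records),
    )


def calibrate_panel(
    records: Sequence[ToxicityRecord],
    descriptors: DescriptorTable,
    model: PooledModelFit,
    min_points: int = 5,
    include_z: bool = True,
) -> dict[str, SystemCalibration]:
    """Onboard every system present in a panel (skipping none silently).

    Systems with fewer than ``min_points`` records raise; group the input
    beforehand if partial calibration is wanted.
    """
    by_system: dict[str, list[ToxicityRecord]] = {}
    for r in records:
        by_system.setdefault(r.system_id, []).append(r)
    return {
        system: onboard_system(recs, descriptors, model, min_points, include_z)
        for system, recs in sorted(by_system.items())
    }


def screen_systems(
    fits: Sequence[SystemCalibration],
    r2_min: float = 0.6,
    r2_soft: float = 0.55,
    se_max: float = 0.35,
) -> dict[str, list[str]]:
    """Partition systems into covered vs exceptional by fit quality.

    A system is covered when R^2 >= r2_min, or when R^2 is only slightly
    below the cut (>= r2_soft) but the standard error is small
    (<= se_max) — the low-scatter exemption.  Everything else is
    exceptional and should be modelled separately.
    """
    covered, exceptional = [], []
    for fit in fits:
        ok = fit.r_squared >= r2_min or (
            fit.r_squared >= r2_soft and fit.se <= se_max
        )
        (covered if ok else exceptional).append(fit.system_id)
    return {"covered": covered, "exceptional": exceptional}


def published_calibrations() -> dict[str, SystemCalibration]:
    """Catalogued per-system (z, alpha, beta, R^2, SE, N) as calibrations."""
    table = published_table()
    return {
        str(row.system): SystemCalibration(
            system_id=str(row.system),
            z=float(row.z),
            alpha=float(row.alpha),
            beta=float(row.beta),
            r_squared=float(row.R2),
            se=float(row.SE),
            n=int(row.N),
        )
        for row in table.itertuples(index=False)
    }


def calibrations_to_json(
    calibrations: Mapping[str, SystemCalibration], path: str | Path
) -> None:
    payload = [calibrations[k].to_dict() for k in sorted(calibrations)]
    Path(path).write_text(json.dumps(payload, indent=2))


def calibrations_from_json(path: str | Path) -> dict[str, SystemCalibration]:
    payload = json.loads(Path(path).read_text())
    return {
        str(item["system_id"]): SystemCalibration(
            system_id=str(item["system_id"]),
            z=float(item["z"]),
            alpha=float(item["alpha"]),
            beta=float(item["beta"]),
            r_squared=float(item["r_squared"]),
            se=float(item["se"]),
            n=int(item["n"]),
        )
        for item in payload
    }
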