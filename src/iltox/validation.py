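"""Fit diagnostics and trimmed-MAE external validation.

Observed-vs-predicted agreement is summarised by an identity-line R^2
(1 - SSE/SStot, penalising bias, not the squared correlation) and a
standard error sqrt(SSE/(n-2)).  External predictions are judged by
mean-absolute-error criteria computed after discarding the 5 % of points
with the largest absolute residuals, classified against thresholds
expressed as fractions of the training-set response range: good when
MAE <= 0.1*range and MAE + 3*sd <= 0.2*range, bad when MAE > 0.15*range
or MAE + 3*sd > 0.25*range, moderate otherwise (sd taken over the kept
absolute residuals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import SystemCalibration, predict_eq5
from .data_model import DescriptorTable, ToxicityRecord
from .pooled import PooledModelFit

#: (mae, mae+3sd) thresholds as fractions of the training response range
GOOD_THRESHOLDS = (0.10, 0.20)
BAD_THRESHOLDS = (0.15, 0.25)


def r2_se(
    observed: Sequence[float],
    predicted: Sequence[float],
    kind: str = "identity",
) -> tuple[float, float]:
    """Observed-vs-predicted R^2 and standard error.

    ``kind="identity"`` (default) uses 1 - SSE/SStot about the identity
    line; ``kind="pearson"`` uses the squared Pearson correlation.  The
    standard error is sqrt(SSE/(n-2)) in both cases.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    n = obs.size
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    sstot = float(np.sum((obs - obs.mean()) ** 2))
    if sstot == 0.0:
        raise ValueError("observed values have zero variance")
    sse = float(np.sum((obs - pred) ** 2))
    if kind == "identity":
        r2 = 1.0 - sse / sstot
    elif kind == "pearson":
        if np.ptp(pred) == 0.0:
            r2 = 0.0
        else:
            r2 = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    else:
        raise ValueError(f"unknown R^2 kind {kind!r}")
    return r2, float(np.sqrt(sse / (n - 2)))


@dataclass(frozen=True)
class ValidationReport:
    """Trimmed-MAE summary of an external prediction set."""

    n: int
    mae_full: float
    mae_95: float
    residual_sd_95: float
    training_range: float
    predictability_class: str  # good | moderate | bad
    removed_indices: tuple[int, ...]
    trim: float
    good_thresholds: tuple[float, float] = GOOD_THRESHOLDS
    bad_thresholds: tuple[float, float] = BAD_THRESHOLDS

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mae_full": self.mae_full,
            "mae_95": self.mae_95,
            "residual_sd_95": self.residual_sd_95,
            "training_range": self.training_range,
            "predictability_class": self.predictability_class,
            "removed_indices": list(self.removed_indices),
            "trim": self.trim,
            "good_thresholds": list(self.good_thresholds),
            "bad_thresholds": list(self.bad_thresholds),
        }


def _classify(
    mae: float, sd: float, training_range: float
) -> str:
    if training_range <= 0:
        return "good" if mae == 0.0 else "bad"
    crit = mae + 3.0 * sd
    if mae <= GOOD_THRESHOLDS[0] * training_range and crit <= GOOD_THRESHOLDS[1] * training_range:
        return "good"
    if mae > BAD_THRESHOLDS[0] * training_range or crit > BAD_THRESHOLDS[1] * training_range:
        return "bad"
    return "moderate"


def trimmed_mae(
    observed: Sequence[float],
    predicted: Sequence[float],
    trim: float = 0.05,
    training_range: float | None = None,
) -> ValidationReport:
    """MAE before and after discarding the largest absolute residuals.

    ``floor(trim * n)`` points with the largest |observed - predicted| are
    removed (ties broken by input order); MAE and the standard deviation of
    the kept absolute residuals feed the predictability classification.
    ``training_range`` defaults to the span of the observed values.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    n = obs.size
    if n < 1:
        raise ValueError("need at least one point")
    if not 0 <= trim < 1:
        raise ValueError(f"trim must be in [0, 1), got {trim}")
    abs_resid = np.abs(obs - pred)
    n_remove = math.floor(trim * n)
    order = np.argsort(-abs_resid, kind="stable")
    removed = tuple(int(i) for i in order[:n_remove])
    keep = np.ones(n, dtype=bool)
    keep[list(removed)] = False
    kept = abs_resid[keep]
    mae_full = float(abs_resid.mean())
    mae_t = float(kept.mean())
    sd_t = float(kept.std(ddof=1)) if kept.size > 1 else 0.0
    rng = float(np.ptp(obs)) if training_range is None else float(training_range)
    return ValidationReport(
        n=n,
        mae_full=mae_full,
        mae_95=mae_t,
        residual_sd_95=sd_t,
        training_range=rng,
        predictability_class=_classify(mae_t, sd_t, rng),
        removed_indices=removed,
        trim=trim,
    )


@dataclass(frozen=True)
class PanelReport:
    """Per-system and pooled observed-vs-predicted diagnostics."""

    per_system: tuple[dict, ...]  # system_id, n, r_squared, se, se_n
    pooled: dict | None
    uncalibrated: tuple[tuple[str, int], ...] = ()

    def to_frame(self) -> pd.DataFrame:
        rows = list(self.per_system)
        if self.pooled is not None:
            rows.append(self.pooled)
        return pd.DataFrame(
            rows, columns=["system_id", "n", "r_squared", "se", "se_n"]
        )


def _diag_row(system_id: str, obs: np.ndarray, pred: np.ndarray) -> dict:
    n = obs.size
    sse = float(np.sum((obs - pred) ** 2))
    if n >= 3 and np.ptp(obs) > 0:
        r2, se = r2_se(obs, pred)
    else:
        r2 = float("nan")
        se = float(np.sqrt(sse / (n - 2))) if n > 2 else float("nan")
    return {
        "system_id": system_id,
        "n": n,
        "r_squared": r2,
        "se": se,
        "se_n": float(np.sqrt(sse / n)),
    }


def panel_report(
    model: PooledModelFit,
    calibrations: Mapping[str, SystemCalibration],
    records: Sequence[ToxicityRecord],
    descriptors: DescriptorTable,
    include_z: bool = True,
) -> PanelReport:
    """Calibrated-prediction diagnostics per system plus a pooled row.

    Records whose system has no calibration are listed under
    ``uncalibrated`` (with counts), never silently dropped.
    """
    by_system: dict[str, list[ToxicityRecord]] = {}
    for r in records:
        by_system.setdefault(r.system_id, []).append(r)
    rows = []
    uncal = []
    all_obs: list[float] = []
    all_pred: list[float] = []
    for system in sorted(by_system):
        recs = by_system[system]
        if system not in calibrations:
            uncal.append((system, len(recs)))
            continue
        obs = np.array([r.response for r in recs])
        pred = np.array(
            [
                predict_eq5(
                    descriptors.get(r.cation_id, "cation"),
                    descriptors.get(r.anion_id, "anion"),
                    system,
                    model,
                    calibrations,
                    include_z=include_z,
                )
                for r in recs
            ]
        )
        rows.append(_diag_row(system, obs, pred))
        all_obs.extend(obs)
        all_pred.extend(pred)
    pooled = (
        _diag_row("(pooled)", np.array(all_obs), np.array(all_pred))
        if all_obs
        else None
    )
    return PanelReport(
        per_system=tuple(rows), pooled=pooled, uncalibrated=tuple(uncal)
    )
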