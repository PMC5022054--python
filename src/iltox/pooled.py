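"""Pooled LFER regression with per-system sensitivity dummies.

The pooled model regresses the common response log10(1/C) on the twelve
split cation/anion descriptors plus one indicator column per non-reference
test system:

    log 1/C = e_c*E_c + s_c*S_c + a_c*A_c + b_c*B_c + v_c*V_c + j+*J+
            + e_a*E_a + s_a*S_a + a_a*A_a + b_a*B_a + v_a*V_a + j-*J-
            + c + sum_x z_x * Z_x

The dummy coefficients z_x measure each system's sensitivity relative to
the reference system (which has z = 0 by construction).  Descriptor terms
whose two-sided t-test p-value exceeds a threshold (default 0.05) are
removed one at a time by backward elimination; the intercept and the
system dummies are never candidates for removal.

The module also packages the published nine-coefficient model together
with the catalogued per-system sensitivities.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_model import (
    DESCRIPTOR_TERMS,
    TERM_TO_FIELD,
    Design,
    DescriptorTable,
    IonDescriptors,
    ToxicityRecord,
    build_design,
)

#: retained coefficients of the published pooled model
PUBLISHED_COEFFICIENTS: dict[str, float] = {
    "E_c": 2.254,
    "S_c": -2.545,
    "A_c": 0.646,
    "B_c": -1.471,
    "V_c": 1.650,
    "J_plus": 2.917,
    "E_a": -0.201,
    "V_a": 0.418,
    "J_minus": 0.131,
}
PUBLISHED_INTERCEPT = -0.709
PUBLISHED_REFERENCE_SYSTEM = "Leukemia rat cell (A)"
#: headline diagnostics of the published pooled fit
PUBLISHED_DIAGNOSTICS = {"n_obs": 1633, "r_squared": 0.880, "se": 0.465}


class CollinearityError(ValueError):
    """Design matrix is rank deficient; names the offending columns."""


def published_table() -> pd.DataFrame:
    """The packaged per-system catalogue (NO, system, R2, SE, z, alpha, beta, N)."""
    with resources.files("iltox.assets").joinpath("table1.csv").open("r") as fh:
        return pd.read_csv(fh)


@dataclass(frozen=True)
class MLRResult:
    """One ordinary-least-squares fit of the pooled design."""

    terms: tuple[str, ...]  # descriptor terms actually fitted
    coefficients: dict[str, float]  # per descriptor term
    intercept: float
    z: dict[str, float]  # per system, reference -> 0.0
    p_values: dict[str, float]  # per descriptor term
    conf_int: dict[str, tuple[float, float]]  # 95 % CI per descriptor term
    r_squared: float
    se: float  # sqrt(RSS / (n - k)), k = all fitted parameters
    se_n: float  # sqrt(RSS / n), alternative convention
    n_obs: int
    n_params: int
    dropped_constant: tuple[str, ...] = ()


def _find_collinear(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns linearly dependent on their predecessors (incl. intercept)."""
    n = X.shape[0]
    kept = np.ones((n, 1))
    bad = []
    for j, name in enumerate(names):
        col = X[:, j : j + 1]
        trial = np.hstack([kept, col])
        if np.linalg.matrix_rank(trial) == kept.shape[1]:
            bad.append(name)
        else:
            kept = trial
    return bad


def fit_mlr(design: Design, terms: Sequence[str] | None = None) -> MLRResult:
    """Ordinary least squares on (a subset of) the descriptor terms + dummies.

    Descriptor columns with zero variance are dropped with a warning before
    fitting.  Raises :class:`CollinearityError` naming the collinear columns
    if the design (with intercept) is rank deficient, and ``ValueError`` if
    there are too few rows.
    """
    if terms is None:
        terms = list(design.descriptor_names)
    else:
        unknown = set(terms) - set(design.descriptor_names)
        if unknown:
            raise ValueError(f"unknown descriptor terms: {', '.join(sorted(unknown))}")
        terms = list(terms)

    name_to_idx = {t: i for i, t in enumerate(design.descriptor_names)}
    dropped = []
    for t in list(terms):
        col = design.X[:, name_to_idx[t]]
        if np.ptp(col) == 0.0:
            dropped.append(t)
            terms.remove(t)
    if dropped:
        warnings.warn(
            f"dropping constant descriptor column(s): {', '.join(dropped)}",
            stacklevel=2,
        )

    dummy_names = [f"z:{s}" for s in design.dummy_systems]
    blocks = [design.X[:, [name_to_idx[t] for t in terms]], design.dummy_block()]
    X = np.hstack([b for b in blocks if b.shape[1]]) if (terms or dummy_names) else np.empty((design.n_obs, 0))
    names = terms + dummy_names

    k = X.shape[1] + 1  # + intercept
    if design.n_obs <= k:
        raise ValueError(
            f"insufficient data: {design.n_obs} rows for {k} parameters "
            f"(need at least {k + 1})"
        )
    with_const = np.hstack([np.ones((design.n_obs, 1)), X])
    if np.linalg.matrix_rank(with_const) < k:
        bad = _find_collinear(X, names)
        raise CollinearityError(
            f"design matrix is rank deficient; collinear column(s): {', '.join(bad)}"
        )

    frame = pd.DataFrame(X, columns=names)
    res = sm.OLS(design.y, sm.add_constant(frame)).fit()

    coeffs = {t: float(res.params[t]) for t in terms}
    # an exactly-zero coefficient in a perfect fit has 0/0 t-statistic;
    # such a term carries no information and is treated as not significant
    pvals = {
        t: (1.0 if np.isnan(res.pvalues[t]) else float(res.pvalues[t]))
        for t in terms
    }
    ci = res.conf_int(alpha=0.05)
    conf = {t: (float(ci.loc[t, 0]), float(ci.loc[t, 1])) for t in terms}
    z = {design.reference_system: 0.0}
    for s in design.dummy_systems:
        z[s] = float(res.params[f"z:{s}"])
    rss = float(np.sum(res.resid**2))
    return MLRResult(
        terms=tuple(terms),
        coefficients=coeffs,
        intercept=float(res.params["const"]),
        z=z,
        p_values=pvals,
        conf_int=conf,
        r_squared=float(res.rsquared),
        se=float(np.sqrt(rss / res.df_resid)),
        se_n=float(np.sqrt(rss / design.n_obs)),
        n_obs=design.n_obs,
        n_params=k,
        dropped_constant=tuple(dropped),
    )


@dataclass(frozen=True)
class PooledModelFit:
    """A fitted (or packaged) pooled model with per-system sensitivities."""

    retained_terms: tuple[str, ...]
    coefficients: dict[str, float]
    intercept: float
    z: dict[str, float]
    reference_system: str
    n_obs: int
    r_squared: float
    se: float
    p_values: dict[str, float] = field(default_factory=dict)
    elimination_history: tuple[tuple[str, float], ...] = ()
    provenance: str = "fitted"

    def to_dict(self) -> dict:
        return {
            "terms": list(self.retained_terms),
            "coefficients": dict(self.coefficients),
            "intercept": self.intercept,
            "z": dict(self.z),
            "reference_system": self.reference_system,
            "diagnostics": {
                "n_obs": self.n_obs,
                "r_squared": self.r_squared,
                "se": self.se,
            },
            "p_values": dict(self.p_values),
            "elimination_history": [list(t) for t in self.elimination_history],
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, payload: Mapping) -> "PooledModelFit":
        diag = payload.get("diagnostics", {})
        return cls(
            retained_terms=tuple(payload["terms"]),
            coefficients={k: float(v) for k, v in payload["coefficients"].items()},
            intercept=float(payload["intercept"]),
            z={k: float(v) for k, v in payload["z"].items()},
            reference_system=str(payload["reference_system"]),
            n_obs=int(diag.get("n_obs", 0)),
            r_squared=float(diag.get("r_squared", float("nan"))),
            se=float(diag.get("se", float("nan"))),
            p_values={k: float(v) for k, v in payload.get("p_values", {}).items()},
            elimination_history=tuple(
                (str(t), float(p)) for t, p in payload.get("elimination_history", [])
            ),
            provenance=str(payload.get("provenance", "fitted")),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PooledModelFit":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _fit_to_pooled(
    result: MLRResult,
    design: Design,
    history: Sequence[tuple[str, float]],
) -> PooledModelFit:
    return PooledModelFit(
        retained_terms=result.terms,
        coefficients=result.coefficients,
        intercept=result.intercept,
        z=result.z,
        reference_system=design.reference_system,
        n_obs=result.n_obs,
        r_squared=result.r_squared,
        se=result.se,
        p_values=result.p_values,
        elimination_history=tuple(history),
        provenance="fitted",
    )


def backward_eliminate(design: Design, p_threshold: float = 0.05) -> PooledModelFit:
    """Backward elimination of descriptor terms by t-test p-value.

    Starting from all twelve descriptor terms, the single descriptor with
    the largest p-value above ``p_threshold`` is removed and the model is
    refitted, until every remaining descriptor term is significant.  The
    intercept and the system dummies are never removed.  If all descriptor
    terms are eliminated a dummies-only model is returned with a warning.
    """
    if not 0 < p_threshold <= 1:
        raise ValueError(f"p_threshold must be in (0, 1], got {p_threshold}")
    terms = list(design.descriptor_names)
    history: list[tuple[str, float]] = []
    result = fit_mlr(design, terms)
    terms = list(result.terms)  # constant columns may have been dropped
    while terms:
        worst = max(terms, key=lambda t: result.p_values[t])
        if result.p_values[worst] <= p_threshold:
            break
        history.append((worst, result.p_values[worst]))
        terms.remove(worst)
        result = fit_mlr(design, terms)
    if not terms:
        warnings.warn(
            "all descriptor terms eliminated; returning dummies-only model",
            stacklevel=2,
        )
    return _fit_to_pooled(result, design, history)


def fit_pooled_model(
    records: Sequence[ToxicityRecord],
    descriptors: DescriptorTable,
    reference_system: str | None = None,
    p_threshold: float = 0.05,
) -> PooledModelFit:
    """Convenience wrapper: build the design and run backward elimination."""
    design = build_design(records, descriptors, reference_system)
    return backward_eliminate(design, p_threshold)


def published_model() -> PooledModelFit:
    """The packaged published pooled model.

    Nine retained descriptor coefficients, the intercept, and the full
    catalogued per-system sensitivity (z) map.  The reference system is the
    rat leukemia cell line (z = 0).
    """
    table = published_table()
    z = {str(row.system): float(row.z) for row in table.itertuples(index=False)}
    return PooledModelFit(
        retained_terms=tuple(PUBLISHED_COEFFICIENTS),
        coefficients=dict(PUBLISHED_COEFFICIENTS),
        intercept=PUBLISHED_INTERCEPT,
        z=z,
        reference_system=PUBLISHED_REFERENCE_SYSTEM,
        n_obs=PUBLISHED_DIAGNOSTICS["n_obs"],
        r_squared=PUBLISHED_DIAGNOSTICS["r_squared"],
        se=PUBLISHED_DIAGNOSTICS["se"],
        provenance="published",
    )


def _check_roles(cation: IonDescriptors, anion: IonDescriptors) -> None:
    if cation.role != "cation":
        raise ValueError(f"expected a cation, got {cation.role} {cation.ion_id!r}")
    if anion.role != "anion":
        raise ValueError(f"expected an anion, got {anion.role} {anion.ion_id!r}")


def intrinsic_value(
    cation: IonDescriptors, anion: IonDescriptors, model: PooledModelFit
) -> float:
    """Descriptor-only model value: sum of coeff*descriptor + intercept.

    No per-system sensitivity (z) is added; this is the toxicity the pooled
    model attributes to the ion pair itself.
    """
    _check_roles(cation, anion)
    total = model.intercept
    for term in model.retained_terms:
        role, fieldname = TERM_TO_FIELD[term]
        ion = cation if role == "cation" else anion
        total += model.coefficients[term] * ion.descriptor(fieldname)
    return float(total)


def predict_eq4(
    cation: IonDescriptors,
    anion: IonDescriptors,
    system_id: str,
    model: PooledModelFit,
) -> float:
    """Pooled-model prediction for one system: intrinsic value + z_x."""
    if system_id not in model.z:
        raise KeyError(
            f"unknown system {system_id!r}; known systems: {len(model.z)} "
            "(use onboard_system to calibrate a new one)"
        )
    return intrinsic_value(cation, anion, model) + model.z[system_id]
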