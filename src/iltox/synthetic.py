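"""Synthetic descriptor tables and multi-system toxicity panels.

The generator emulates the statistical structure the pooled model assumes:
an intrinsic LFER surface over split cation/anion descriptors, additive
per-system sensitivity offsets, optional per-system linear distortion of
the response, and Gaussian noise on the log scale,

    y = alpha_x * (x . coeffs + c + z_x) + beta_x + eps,
    eps ~ Normal(0, noise_sd^2).

With alpha_x = 1 and beta_x = 0 everywhere this is exactly the generative
form of the pooled dummy-variable regression; non-trivial alpha/beta
exercise the per-system calibration stage.

Descriptor ranges are chosen to mimic common IL ions: cations have
positive E, S and V (with V driven by a simulated alkyl-chain length, one
CH2 adding 0.1409 McGowan units) and J+ near 1; anions have E near zero or
negative and a broad volume range.  The default noise level, 0.45 log
units, matches the residual scale of pooled multi-assay IL panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data_model import (
    DESCRIPTOR_TERMS,
    ENDPOINTS,
    DescriptorTable,
    IonDescriptors,
    ToxicityRecord,
)
from .pooled import PUBLISHED_COEFFICIENTS, PUBLISHED_INTERCEPT

#: default intrinsic surface: published coefficients, eliminated terms at 0
DEFAULT_TRUE_COEFFICIENTS: dict[str, float] = {
    term: PUBLISHED_COEFFICIENTS.get(term, 0.0) for term in DESCRIPTOR_TERMS
}
DEFAULT_NOISE_SD = 0.45  # log units

#: McGowan volume increment of one CH2 unit [cm^3 mol^-1 / 100]
MCGOWAN_CH2 = 0.1409


@dataclass(frozen=True)
class SystemSpec:
    """True sensitivity and distortion of one simulated test system."""

    system_id: str
    z: float = 0.0
    alpha: float = 1.0
    beta: float = 0.0


@dataclass(frozen=True)
class TrueModel:
    """Ground-truth generative model of a synthetic panel."""

    coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_COEFFICIENTS)
    )
    intercept: float = PUBLISHED_INTERCEPT
    systems: tuple[SystemSpec, ...] = (SystemSpec("reference"),)
    noise_sd: float = DEFAULT_NOISE_SD

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.systems:
            raise ValueError("at least one system is required")
        ref = self.systems[0]
        if not (ref.z == 0.0 and ref.alpha == 1.0 and ref.beta == 0.0):
            raise ValueError(
                "the first (reference) system must have z=0, alpha=1, beta=0"
            )
        ids = [s.system_id for s in self.systems]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate system ids in systems spec")

    @property
    def reference_system(self) -> str:
        return self.systems[0].system_id

    @property
    def z_true(self) -> dict[str, float]:
        return {s.system_id: s.z for s in self.systems}

    @property
    def alpha_true(self) -> dict[str, float]:
        return {s.system_id: s.alpha for s in self.systems}

    @property
    def beta_true(self) -> dict[str, float]:
        return {s.system_id: s.beta for s in self.systems}

    def coefficient_vector(self) -> np.ndarray:
        return np.array([self.coefficients.get(t, 0.0) for t in DESCRIPTOR_TERMS])

    def intrinsic(self, cation: IonDescriptors, anion: IonDescriptors) -> float:
        x = np.array(
            [cation.E, cation.S, cation.A, cation.B, cation.V, cation.J,
             anion.E, anion.S, anion.A, anion.B, anion.V, anion.J]
        )
        return float(x @ self.coefficient_vector() + self.intercept)


@dataclass(frozen=True)
class IonRanges:
    """Sampling ranges of the descriptor generator (uniform unless noted)."""

    cation_E: tuple[float, float] = (0.0, 1.3)
    cation_S: tuple[float, float] = (0.6, 2.6)
    cation_A: tuple[float, float] = (0.0, 0.6)
    cation_B: tuple[float, float] = (0.0, 0.9)
    cation_V_base: float = 0.6  # head-group volume before the alkyl chain
    cation_chain: tuple[int, int] = (2, 14)  # CH2 units, inclusive
    cation_J_mean_sd: tuple[float, float] = (1.0, 0.25)  # normal
    anion_E: tuple[float, float] = (-0.6, 0.3)
    anion_S: tuple[float, float] = (0.0, 2.0)
    anion_A: tuple[float, float] = (0.0, 0.5)
    anion_B: tuple[float, float] = (0.0, 1.5)
    anion_V: tuple[float, float] = (0.3, 2.2)
    anion_J_mean_sd: tuple[float, float] = (-0.3, 0.4)  # normal


def gen_ions(
    n_cations: int,
    n_anions: int,
    seed: int,
    ranges: IonRanges | None = None,
) -> DescriptorTable:
    """Draw a reproducible synthetic descriptor table.

    Cation volumes grow with a simulated alkyl-chain length so that the
    homologous side-chain effect (toxicity increasing with chain length via
    V_c) is present in every generated table.  Anion E is drawn from a range
    straddling zero with most of its mass at or below zero.
    """
    if n_cations < 1 or n_anions < 1:
        raise ValueError("need at least one cation and one anion")
    r = ranges or IonRanges()
    rng = np.random.default_rng(seed)
    ions = []
    width = max(2, len(str(max(n_cations, n_anions))))
    for i in range(n_cations):
        chain = int(rng.integers(r.cation_chain[0], r.cation_chain[1] + 1))
        ions.append(
            IonDescriptors(
                ion_id=f"C{i + 1:0{width}d}",
                role="cation",
                E=float(rng.uniform(*r.cation_E)),
                S=float(rng.uniform(*r.cation_S)),
                A=float(rng.uniform(*r.cation_A)),
                B=float(rng.uniform(*r.cation_B)),
                V=float(r.cation_V_base + MCGOWAN_CH2 * chain
                        + rng.normal(0.0, 0.05)),
                J=float(rng.normal(*r.cation_J_mean_sd)),
            )
        )
    for i in range(n_anions):
        ions.append(
            IonDescriptors(
                ion_id=f"A{i + 1:0{width}d}",
                role="anion",
                E=float(rng.uniform(*r.anion_E)),
                S=float(rng.uniform(*r.anion_S)),
                A=float(rng.uniform(*r.anion_A)),
                B=float(rng.uniform(*r.anion_B)),
                V=float(rng.uniform(*r.anion_V)),
                J=float(rng.normal(*r.anion_J_mean_sd)),
            )
        )
    return DescriptorTable(ions)


def gen_systems(
    n_systems: int,
    seed: int,
    z_range: tuple[float, float] = (-1.9, 2.8),
    alpha_range: tuple[float, float] = (1.0, 1.0),
    beta_range: tuple[float, float] = (0.0, 0.0),
) -> tuple[SystemSpec, ...]:
    """Draw system specs; the first is the reference (z=0, alpha=1, beta=0).

    The default z range spans the catalogued per-system sensitivities;
    alpha/beta default to the undistorted pooled-model form.
    """
    if n_systems < 1:
        raise ValueError("need at least one system")
    rng = np.random.default_rng(seed)
    width = max(2, len(str(n_systems)))
    specs = [SystemSpec(f"sys{1:0{width}d}")]
    for i in range(1, n_systems):
        specs.append(
            SystemSpec(
                system_id=f"sys{i + 1:0{width}d}",
                z=float(rng.uniform(*z_range)),
                alpha=float(rng.uniform(*alpha_range)),
                beta=float(rng.uniform(*beta_range)),
            )
        )
    return tuple(specs)


def gen_panel(
    true_model: TrueModel,
    ions: DescriptorTable,
    systems: Sequence[SystemSpec] | None = None,
    n_per_system: int | Sequence[int] = 50,
    seed: int = 0,
) -> list[ToxicityRecord]:
    """Simulate a multi-system toxicity panel from the true model.

    For each system, ion pairs are sampled uniformly with replacement and
    the response is ``alpha_x * (intrinsic + z_x) + beta_x + eps`` with
    ``eps ~ Normal(0, noise_sd^2)``.  ``n_per_system`` may be a single count
    or one count per system.  Output is reproducible given the seed.
    """
    cations = ions.cations
    anions = ions.anions
    if not cations or not anions:
        raise ValueError("ion table must contain at least one cation and one anion")
    specs = tuple(systems) if systems is not None else true_model.systems
    if isinstance(n_per_system, int):
        counts = [n_per_system] * len(specs)
    else:
        counts = list(n_per_system)
        if len(counts) != len(specs):
            raise ValueError("n_per_system length must match the number of systems")
    if any(c < 1 for c in counts):
        raise ValueError("n_per_system must be >= 1")

    coef = true_model.coefficient_vector()
    cat_mat = np.array([[c.E, c.S, c.A, c.B, c.V, c.J] for c in cations])
    an_mat = np.array([[a.E, a.S, a.A, a.B, a.V, a.J] for a in anions])

    rng = np.random.default_rng(seed)
    records = []
    for spec, n in zip(specs, counts):
        ci = rng.integers(0, len(cations), n)
        ai = rng.integers(0, len(anions), n)
        x = np.hstack([cat_mat[ci], an_mat[ai]])
        intrinsic = x @ coef + true_model.intercept
        eps = rng.normal(0.0, true_model.noise_sd, n) if true_model.noise_sd else 0.0
        y = spec.alpha * (intrinsic + spec.z) + spec.beta + eps
        endpoints = rng.choice(ENDPOINTS, n)
        for j in range(n):
            records.append(
                ToxicityRecord(
                    cation_id=cations[ci[j]].ion_id,
                    anion_id=anions[ai[j]].ion_id,
                    system_id=spec.system_id,
                    endpoint=str(endpoints[j]),
                    response=float(np.atleast_1d(y)[j]),
                )
            )
    return records
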