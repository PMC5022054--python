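"""Domain types, CSV I/O and design-matrix construction.

An ionic liquid (IL) is treated as a fully dissociated cation/anion pair.
Each ion carries Abraham-type solvation descriptors extended with an
ionic-interaction term:

* ``E`` — excess molar refraction [cm^3 mol^-1 / 10]
* ``S`` — dipolarity/polarizability [-]
* ``A`` / ``B`` — hydrogen-bond acidity / basicity [-]
* ``V`` — McGowan characteristic volume [cm^3 mol^-1 / 100]
* ``J`` — ionic-interaction descriptor (J+ for cations, J- for anions) [-]

Toxicity endpoints (EC50, LC50, IC50, MIC, MBC; concentrations in mM) are
pooled on a single response scale ``log10(1/C)`` so that larger values mean
higher toxicity.  A pooled multi-system panel is encoded as a design matrix
with the twelve split cation/anion descriptor columns followed by one 0/1
indicator (dummy) column per non-reference test system; the dummy
coefficients estimate the per-system sensitivity offsets.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

ROLES = ("cation", "anion")
ENDPOINTS = ("EC50", "LC50", "IC50", "MIC", "MBC")
VALUE_TYPES = ("conc_mM", "log_inv")

CATION_TERMS = ("E_c", "S_c", "A_c", "B_c", "V_c", "J_plus")
ANION_TERMS = ("E_a", "S_a", "A_a", "B_a", "V_a", "J_minus")
#: canonical ordering of the twelve descriptor columns of the pooled design
DESCRIPTOR_TERMS = CATION_TERMS + ANION_TERMS

#: model term -> (ion role, descriptor attribute)
TERM_TO_FIELD = {
    "E_c": ("cation", "E"),
    "S_c": ("cation", "S"),
    "A_c": ("cation", "A"),
    "B_c": ("cation", "B"),
    "V_c": ("cation", "V"),
    "J_plus": ("cation", "J"),
    "E_a": ("anion", "E"),
    "S_a": ("anion", "S"),
    "A_a": ("anion", "A"),
    "B_a": ("anion", "B"),
    "V_a": ("anion", "V"),
    "J_minus": ("anion", "J"),
}

DESCRIPTOR_CSV_COLUMNS = ("ion_id", "role", "E", "S", "A", "B", "V", "J")
TOXICITY_CSV_COLUMNS = (
    "cation_id",
    "anion_id",
    "system_id",
    "endpoint",
    "value",
    "value_type",
)


def to_log_inverse(concentration_mm: float, *, label: str | None = None) -> float:
    """Transform a concentration in mM to the common response log10(1/C).

    Parameters
    ----------
    concentration_mm:
        Effect concentration (EC50/LC50/IC50/MIC/MBC) in mM; must be a
        finite, strictly positive number.
    label:
        Optional identifier of the originating record, used in error
        messages.

    Returns
    -------
    float
        ``log10(1 / concentration_mm)`` in log units of mM.
    """
    where = f" (record {label})" if label else ""
    if not math.isfinite(concentration_mm):
        raise ValueError(f"non-finite concentration {concentration_mm!r}{where}")
    if concentration_mm <= 0:
        raise ValueError(
            f"concentration must be > 0 mM, got {concentration_mm!r}{where}"
        )
    return -math.log10(concentration_mm)


@dataclass(frozen=True)
class IonDescriptors:
    """Solvation descriptor vector of one ion.

    ``J`` is interpreted as J+ when ``role == "cation"`` and as J- when
    ``role == "anion"``.
    """

    ion_id: str
    role: str
    E: float
    S: float
    A: float
    B: float
    V: float
    J: float

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(
                f"unknown role {self.role!r} for ion {self.ion_id!r}; "
                f"allowed roles: {', '.join(ROLES)}"
            )
        for name in ("E", "S", "A", "B", "V", "J"):
            value = getattr(self, name)
            if not math.isfinite(float(value)):
                raise ValueError(
                    f"descriptor {name} of ion {self.ion_id!r} is not finite: {value!r}"
                )

    def descriptor(self, field: str) -> float:
        """Return one of E, S, A, B, V, J by name."""
        return float(getattr(self, field))


class DescriptorTable:
    """Lookup table of ion descriptors keyed by (ion_id, role).

    Duplicate (ion_id, role) pairs are rejected; the same label may appear
    once as a cation and once as an anion.
    """

    def __init__(self, ions: Iterable[IonDescriptors]):
        self._ions: dict[tuple[str, str], IonDescriptors] = {}
        for ion in ions:
            key = (ion.ion_id, ion.role)
            if key in self._ions:
                raise ValueError(
                    f"duplicate descriptor entry for {ion.role} {ion.ion_id!r}"
                )
            self._ions[key] = ion

    def __len__(self) -> int:
        return len(self._ions)

    def __iter__(self) -> Iterator[IonDescriptors]:
        return iter(self._ions.values())

    def get(self, ion_id: str, role: str) -> IonDescriptors:
        try:
            return self._ions[(ion_id, role)]
        except KeyError:
            raise KeyError(f"no descriptors for {role} {ion_id!r}") from None

    @property
    def cations(self) -> list[IonDescriptors]:
        return [i for i in self._ions.values() if i.role == "cation"]

    @property
    def anions(self) -> list[IonDescriptors]:
        return [i for i in self._ions.values() if i.role == "anion"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "ion_id": i.ion_id,
                    "role": i.role,
                    "E": i.E,
                    "S": i.S,
                    "A": i.A,
                    "B": i.B,
                    "V": i.V,
                    "J": i.J,
                }
                for i in self._ions.values()
            ],
            columns=list(DESCRIPTOR_CSV_COLUMNS),
        )


def read_descriptor_table(path: str | Path) -> DescriptorTable:
    """Read an ion-descriptor CSV (columns ion_id, role, E, S, A, B, V, J)."""
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(DESCRIPTOR_CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(
            f"descriptor table {path} is missing columns: {', '.join(sorted(missing))}"
        )
    ions = []
    for row in frame.itertuples(index=False):
        try:
            ions.append(
                IonDescriptors(
                    ion_id=str(row.ion_id),
                    role=str(row.role),
                    E=float(row.E),
                    S=float(row.S),
                    A=float(row.A),
                    B=float(row.B),
                    V=float(row.V),
                    J=float(row.J),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"bad descriptor row for ion {row.ion_id!r}: {exc}") from exc
    return DescriptorTable(ions)


def write_descriptor_table(table: DescriptorTable, path: str | Path) -> None:
    """Write a descriptor table as CSV at full float precision."""
    table.to_frame().to_csv(path, index=False, float_format="%.17g")


@dataclass(frozen=True)
class ToxicityRecord:
    """One toxicity measurement of an ion pair in one test system."""

    cation_id: str
    anion_id: str
    system_id: str
    endpoint: str
    response: float  # log10(1/C), C in mM

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise ValueError(
                f"unknown endpoint {self.endpoint!r}; allowed: {', '.join(ENDPOINTS)}"
            )
        if not math.isfinite(float(self.response)):
            raise ValueError(
                f"non-finite response for {self.cation_id}/{self.anion_id} "
                f"in {self.system_id}"
            )

    @property
    def label(self) -> str:
        return f"{self.cation_id}+{self.anion_id}@{self.system_id}"


def read_toxicity_table(path: str | Path) -> list[ToxicityRecord]:
    """Read a toxicity CSV.

    Expected columns: cation_id, anion_id, system_id, endpoint, value,
    value_type.  ``value_type`` is ``conc_mM`` (value is a concentration in
    mM, transformed to log10(1/C) on read) or ``log_inv`` (value is already
    on the response scale).
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(TOXICITY_CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(
            f"toxicity table {path} is missing columns: {', '.join(sorted(missing))}"
        )
    records = []
    for row in frame.itertuples(index=False):
        label = f"{row.cation_id}+{row.anion_id}@{row.system_id}"
        value_type = str(row.value_type)
        if value_type not in VALUE_TYPES:
            raise ValueError(
                f"unknown value_type {value_type!r} (record {label}); "
                f"allowed: {', '.join(VALUE_TYPES)}"
            )
        value = float(row.value)
        response = to_log_inverse(value, label=label) if value_type == "conc_mM" else value
        records.append(
            ToxicityRecord(
                cation_id=str(row.cation_id),
                anion_id=str(row.anion_id),
                system_id=str(row.system_id),
                endpoint=str(row.endpoint),
                response=response,
            )
        )
    return records


def write_toxicity_table(records: Sequence[ToxicityRecord], path: str | Path) -> None:
    """Write records as CSV with responses on the log10(1/C) scale."""
    pd.DataFrame(
        [
            {
                "cation_id": r.cation_id,
                "anion_id": r.anion_id,
                "system_id": r.system_id,
                "endpoint": r.endpoint,
                "value": r.response,
                "value_type": "log_inv",
            }
            for r in records
        ],
        columns=list(TOXICITY_CSV_COLUMNS),
    ).to_csv(path, index=False, float_format="%.17g")


def choose_reference_system(records: Sequence[ToxicityRecord]) -> str:
    """Pick the reference system: largest record count, ties lexicographic.

    Mirrors the convention that the assay contributing the most data points
    becomes the standard (zero-offset) test method.
    """
    if not records:
        raise ValueError("no records given")
    counts = Counter(r.system_id for r in records)
    return min(counts, key=lambda s: (-counts[s], s))


@dataclass(frozen=True)
class Design:
    """Pooled design matrix: 12 descriptor columns + system dummies."""

    X: np.ndarray  # (n_obs, 12 + n_dummies)
    y: np.ndarray  # (n_obs,)
    descriptor_names: tuple[str, ...]
    dummy_systems: tuple[str, ...]  # non-reference systems, sorted
    reference_system: str
    systems: tuple[str, ...]  # per-row system id

    @property
    def n_obs(self) -> int:
        return int(self.X.shape[0])

    @property
    def columns(self) -> tuple[str, ...]:
        return self.descriptor_names + tuple(f"z:{s}" for s in self.dummy_systems)

    def descriptor_block(self) -> np.ndarray:
        return self.X[:, : len(self.descriptor_names)]

    def dummy_block(self) -> np.ndarray:
        return self.X[:, len(self.descriptor_names):]


def build_design(
    records: Sequence[ToxicityRecord],
    descriptors: DescriptorTable,
    reference_system: str | None = None,
) -> Design:
    """Assemble the pooled design matrix from records and ion descriptors.

    Row order follows the input record order.  Each row holds the twelve
    descriptor values (cation block then anion block, canonical order) and
    a dummy indicator per non-reference system; a row of the reference
    system has an all-zero dummy block, any other row has exactly one 1.
    The intercept is left implicit (added at fit time).
    """
    records = list(records)
    if not records:
        raise ValueError("cannot build a design from zero records")
    present = sorted({r.system_id for r in records})
    if reference_system is None:
        reference_system = choose_reference_system(records)
    elif reference_system not in present:
        raise ValueError(
            f"reference system {reference_system!r} has no records; "
            f"systems present: {', '.join(present)}"
        )
    dummy_systems = tuple(s for s in present if s != reference_system)
    dummy_index = {s: j for j, s in enumerate(dummy_systems)}

    n = len(records)
    X = np.zeros((n, 12 + len(dummy_systems)))
    y = np.empty(n)
    for i, rec in enumerate(records):
        try:
            cat = descriptors.get(rec.cation_id, "cation")
            an = descriptors.get(rec.anion_id, "anion")
        except KeyError as exc:
            raise ValueError(f"record {rec.label}: {exc.args[0]}") from exc
        X[i, :6] = (cat.E, cat.S, cat.A, cat.B, cat.V, cat.J)
        X[i, 6:12] = (an.E, an.S, an.A, an.B, an.V, an.J)
        if rec.system_id != reference_system:
            X[i, 12 + dummy_index[rec.system_id]] = 1.0
        y[i] = rec.response
    return Design(
        X=X,
        y=y,
        descriptor_names=DESCRIPTOR_TERMS,
        dummy_systems=dummy_systems,
        reference_system=reference_system,
        systems=tuple(r.system_id for r in records),
    )
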