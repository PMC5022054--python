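"""Additive cation/anion toxicity contributions and ion ranking.

Because the pooled model is additive in the two ions, the cationic and
anionic parts of the model sum can be evaluated separately (excluding the
intercept, so that the two roles are directly comparable).  Ranking ions
by these contributions orders them from most to least toxic under the
model; structural-applicability warnings flag very large cations, where
the model is known to over-predict toxicity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .data_model import (
    ANION_TERMS,
    CATION_TERMS,
    TERM_TO_FIELD,
    DescriptorTable,
    IonDescriptors,
)
from .pooled import PooledModelFit

#: V_c above which a cation is flagged as outside the reliable domain.
#: Long-chain phosphonium-type cations (e.g. trihexyltetradecylphosphonium)
#: sit well above this volume and are systematically over-predicted.
DEFAULT_LARGE_CATION_V = 3.5


@dataclass(frozen=True)
class IonContribution:
    ion_id: str
    role: str
    contribution: float  # log units, intercept excluded
    rank: int


def _role_contribution(
    ion: IonDescriptors, model: PooledModelFit, role: str
) -> float:
    if ion.role != role:
        raise ValueError(f"expected a {role}, got {ion.role} {ion.ion_id!r}")
    terms = CATION_TERMS if role == "cation" else ANION_TERMS
    total = 0.0
    for term in terms:
        if term in model.retained_terms:
            total += model.coefficients[term] * ion.descriptor(TERM_TO_FIELD[term][1])
    return float(total)


def cation_contribution(cation: IonDescriptors, model: PooledModelFit) -> float:
    """Cationic part of the model sum (no intercept)."""
    return _role_contribution(cation, model, "cation")


def anion_contribution(anion: IonDescriptors, model: PooledModelFit) -> float:
    """Anionic part of the model sum (no intercept)."""
    return _role_contribution(anion, model, "anion")


def rank_ions(
    descriptors: DescriptorTable, role: str, model: PooledModelFit
) -> list[IonContribution]:
    """Rank all ions of a role by descending contribution (most toxic first).

    Ties share the smaller rank and the following rank is skipped
    (competition ranking).  The returned order is deterministic: by
    contribution, ties broken by ion_id.
    """
    if role not in ("cation", "anion"):
        raise ValueError(f"unknown role {role!r}")
    ions = descriptors.cations if role == "cation" else descriptors.anions
    if not ions:
        raise ValueError(f"no {role}s in the descriptor table")
    contrib = {
        ion.ion_id: _role_contribution(ion, model, role) for ion in ions
    }
    ordered = sorted(contrib, key=lambda i: (-contrib[i], i))
    values = [contrib[i] for i in ordered]
    out = []
    for pos, ion_id in enumerate(ordered):
        rank = 1 + sum(1 for v in values if v > contrib[ion_id])
        out.append(
            IonContribution(
                ion_id=ion_id, role=role, contribution=contrib[ion_id], rank=rank
            )
        )
    return out


def applicability_flags(
    cation: IonDescriptors,
    anion: IonDescriptors | None = None,
    large_cation_v: float = DEFAULT_LARGE_CATION_V,
) -> list[str]:
    """Structural-applicability warnings for a query ion pair.

    Currently one rule: very large cations (V_c above the threshold,
    typical of long-alkyl-chain phosphonium heads) fall outside the
    reliable domain and tend to be over-predicted.  Warnings never block
    prediction.  Set the threshold to ``math.inf`` to disable.
    """
    if cation.role != "cation":
        raise ValueError(f"expected a cation, got {cation.role} {cation.ion_id!r}")
    flags = []
    if math.isfinite(large_cation_v) and cation.V > large_cation_v:
        flags.append(
            f"large cation {cation.ion_id!r}: V_c = {cation.V:.3g} exceeds the "
            f"applicability threshold {large_cation_v:.3g}; toxicity is likely "
            "over-estimated for long-chain heads"
        )
    return flags
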