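"""Linkage-quality layer: confidence levels and hierarchical ordering.

Matching on hashed partial identifiers can return records whose link to
the requested patient is certain (the full name + birth date digest
matched), plausible (only a name-component combination matched, as for a
married woman filed under one of her two last names), or merely
phonetic.  Each returned record gets a HIGH / MEDIUM / LOW linkage
level, and results are ordered hierarchically so the practitioner
validates the confident links first.

The level rule is deterministic, driven by the matched basis tier:
FULL → HIGH; TOKEN → MEDIUM, promoted to HIGH when at least two distinct
token bases corroborate the same record; PHONETIC → LOW.  The signature
admits a future probabilistic scorer trained on observed match
frequencies without changing the interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from typing import List, Optional, Sequence

from .hospital import EMRDocument
from .identity import IdentityBasis, Tier

__all__ = ["LinkageLevel", "RankedResult", "assign_level", "rank_results"]


class LinkageLevel(IntEnum):
    """Total order HIGH > MEDIUM > LOW."""

    LOW = 1
    MEDIUM = 2
    HIGH = 3


def assign_level(
    matched_basis_tier: Tier, n_distinct_bases_matched: int = 1
) -> LinkageLevel:
    """Linkage level from the best matched tier and corroboration count.

    Pure function: permuting or repeating inputs never changes a level.
    """
    if n_distinct_bases_matched < 1:
        raise ValueError("a matched record has at least one matched basis")
    if matched_basis_tier is Tier.FULL:
        return LinkageLevel.HIGH
    if matched_basis_tier is Tier.TOKEN:
        return (
            LinkageLevel.HIGH
            if n_distinct_bases_matched >= 2
            else LinkageLevel.MEDIUM
        )
    return LinkageLevel.LOW


@dataclass(frozen=True)
class RankedResult:
    """One returned record, annotated for practitioner validation."""

    emr: EMRDocument
    hs_id: str
    level: LinkageLevel
    matched_basis: IdentityBasis
    matched_digest: str = ""
    #: hook for patient-assisted validation ("I was never in that hospital")
    patient_confirmed: Optional[bool] = None

    def to_dict(self) -> dict:
        return {
            "hs_id": self.hs_id,
            "level": self.level.name,
            "matched_basis": {
                "first_part": self.matched_basis.first_part,
                "last_part": self.matched_basis.last_part,
                "birth_date": self.matched_basis.birth_date,
                "tier": self.matched_basis.tier.value,
            },
            "matched_digest": self.matched_digest,
            "patient_confirmed": self.patient_confirmed,
            "emr": self.emr.to_dict(),
        }


def rank_results(results: Sequence[RankedResult]) -> List[RankedResult]:
    """Hierarchical order: HIGH first, then hospital id, then stay start.

    A stable sort — the output is a permutation of the input, so ranking
    never gains or loses a record.
    """
    return sorted(
        results,
        key=lambda r: (-int(r.level), r.hs_id, r.emr.stay_start),
    )


def results_to_json(results: Sequence[RankedResult]) -> str:
    """Serialize ranked output with explicit level and basis fields."""
    return json.dumps([r.to_dict() for r in results], indent=2, sort_keys=True)
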