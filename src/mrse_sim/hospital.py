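"""Hospital-side EMR repository: pseudonym index, digest search, filtering.

Records stay in their native, unmodified form — the only structure the
protocol assumes is the universal identity header (names + birth date)
plus a thin metadata envelope (stay period, department, pathology) used
by the selection-criteria tool.  The clinical payload is never parsed.

The index maps every partial-pseudonym digest of a record's header to
the record, so an incoming hashed request is answered by dictionary
lookup, not by rescanning content.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .errors import CriteriaError, InvalidDateError, InvalidIdentityError
from .identity import (
    IdentityTraits,
    Tier,
    derive_pseudonym_set,
)

__all__ = [
    "EMRDocument",
    "SelectionCriteria",
    "SearchHit",
    "HospitalStore",
    "filter_by_criteria",
]


@dataclass(frozen=True)
class EMRDocument:
    """One medical record: identity header + opaque clinical payload."""

    header: IdentityTraits
    hs_id: str
    stay_start: str  # ISO-8601
    stay_end: str
    department: str
    pathology: str
    payload: str
    record_id: str = ""

    def to_dict(self) -> dict:
        bd = self.header.birth_date
        if isinstance(bd, (_dt.date, _dt.datetime)):
            bd = bd.isoformat()
        return {
            "first_name": self.header.first_name_raw,
            "last_name": self.header.last_name_raw,
            "birth_date": bd,
            "hs_id": self.hs_id,
            "stay_start": self.stay_start,
            "stay_end": self.stay_end,
            "department": self.department,
            "pathology": self.pathology,
            "payload": self.payload,
            "record_id": self.record_id,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "EMRDocument":
        return cls(
            header=IdentityTraits(
                first_name_raw=obj["first_name"],
                last_name_raw=obj["last_name"],
                birth_date=obj["birth_date"],
            ),
            hs_id=obj["hs_id"],
            stay_start=obj["stay_start"],
            stay_end=obj["stay_end"],
            department=obj.get("department", ""),
            pathology=obj.get("pathology", ""),
            payload=obj.get("payload", ""),
            record_id=obj.get("record_id", ""),
        )


@dataclass(frozen=True)
class SelectionCriteria:
    """Optional request refinements; all-None means match-all.

    ``period`` is a (start, end) ISO-date pair tested by interval
    overlap with the stay; text fields match case-insensitively as
    substrings; ``hospitals`` whitelists responding structures.
    """

    period: Optional[Tuple[str, str]] = None
    hospitals: Optional[Tuple[str, ...]] = None
    department: Optional[str] = None
    event: Optional[str] = None
    pathology: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "period": list(self.period) if self.period else None,
            "hospitals": list(self.hospitals) if self.hospitals else None,
            "department": self.department,
            "event": self.event,
            "pathology": self.pathology,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "SelectionCriteria":
        return cls(
            period=tuple(obj["period"]) if obj.get("period") else None,
            hospitals=tuple(obj["hospitals"]) if obj.get("hospitals") else None,
            department=obj.get("department"),
            event=obj.get("event"),
            pathology=obj.get("pathology"),
        )


@dataclass(frozen=True)
class SearchHit:
    """One matched record with the best-tier digest that reached it."""

    record: EMRDocument
    position: int
    matched_digest: str
    matched_tier: Tier
    all_matched_digests: Tuple[str, ...]


@dataclass
class HospitalStore:
    hs_id: str
    records: List[EMRDocument] = field(default_factory=list)
    index: Dict[str, List[Tuple[int, Tier]]] = field(default_factory=dict)
    skipped: List[Tuple[int, str]] = field(default_factory=list)
    _indexed: bool = False

    def add_record(self, doc: EMRDocument) -> None:
        if not doc.record_id:
            doc = replace(doc, record_id=f"{self.hs_id}:{len(self.records)}")
        self.records.append(doc)
        self._indexed = False

    # -- indexing ----------------------------------------------------------

    def build_index(
        self, include_phonetic: bool = True, hash_key: Optional[bytes] = None
    ) -> "HospitalStore":
        """(Re)build the digest index over all records.

        Idempotent and deterministic; records whose header cannot be
        canonicalized are skipped and noted in ``self.skipped``.
        """
        self.index = {}
        self.skipped = []
        for pos, doc in enumerate(self.records):
            try:
                pset = derive_pseudonym_set(
                    doc.header, include_phonetic=include_phonetic, hash_key=hash_key
                )
            except (InvalidIdentityError, InvalidDateError) as exc:
                self.skipped.append((pos, str(exc)))
                continue
            for pseudonym in pset:
                self.index.setdefault(pseudonym.digest, []).append(
                    (pos, pseudonym.basis.tier)
                )
        self._indexed = True
        return self

    # -- search ------------------------------------------------------------

    def search_by_digest(self, digests: Sequence[str]) -> List[SearchHit]:
        """Look up request digests; one hit per record, best tier wins.

        A record reached by several digests appears once, annotated with
        the highest-tier digest (FULL beats TOKEN beats PHONETIC) and
        with every digest that hit it; output ordered by record position.
        """
        if not self._indexed:
            raise RuntimeError("index not built; call build_index() first")
        per_record: Dict[int, List[Tuple[str, Tier]]] = {}
        for digest in digests:
            for pos, tier in self.index.get(digest, ()):
                per_record.setdefault(pos, []).append((digest, tier))
        hits = []
        for pos in sorted(per_record):
            matches = per_record[pos]
            best_digest, best_tier = max(
                matches, key=lambda dt: (dt[1].rank, dt[0])
            )
            hits.append(
                SearchHit(
                    record=self.records[pos],
                    position=pos,
                    matched_digest=best_digest,
                    matched_tier=best_tier,
                    all_matched_digests=tuple(sorted({d for d, _ in matches})),
                )
            )
        return hits

    # -- persistence -------------------------------------------------------

    def to_jsonl(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for doc in self.records:
                fh.write(json.dumps(doc.to_dict(), sort_keys=True) + "\n")

    @classmethod
    def from_jsonl(cls, path, hs_id: Optional[str] = None) -> "HospitalStore":
        store = cls(hs_id=hs_id or "")
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                doc = EMRDocument.from_dict(json.loads(line))
                if not store.hs_id:
                    store.hs_id = doc.hs_id
                store.add_record(doc)
        return store

    @classmethod
    def from_header_csv(cls, path, hs_id: str) -> "HospitalStore":
        """Header-only fixture loader (first_name,last_name,birth_date)."""
        from .identity import read_traits_csv

        store = cls(hs_id=hs_id)
        for traits in read_traits_csv(path):
            store.add_record(
                EMRDocument(
                    header=traits,
                    hs_id=hs_id,
                    stay_start="1900-01-01",
                    stay_end="1900-01-01",
                    department="",
                    pathology="",
                    payload="",
                )
            )
        return store


# ---------------------------------------------------------------------------
# Selection-criteria filtering


def _parse_iso(text: str, what: str) -> _dt.date:
    try:
        return _dt.date.fromisoformat(text)
    except (TypeError, ValueError) as exc:
        raise CriteriaError(f"malformed {what} date: {text!r}") from exc


def _overlaps(criteria_period: Tuple[str, str], hit: SearchHit) -> bool:
    lo = _parse_iso(criteria_period[0], "period start")
    hi = _parse_iso(criteria_period[1], "period end")
    if lo > hi:
        raise CriteriaError(f"inverted period {criteria_period!r}")
    start = _parse_iso(hit.record.stay_start, "stay start")
    end = _parse_iso(hit.record.stay_end, "stay end")
    return start <= hi and end >= lo


def filter_by_criteria(
    hits: Sequence[SearchHit], criteria: Optional[SelectionCriteria]
) -> List[SearchHit]:
    """Conjunctive refinement of search hits; empty criteria passes all.

    Adding a criterion can only shrink the hit set (monotonicity), which
    is what makes the tool a refinement rather than a second search.
    """
    if criteria is None:
        return list(hits)
    out = []
    for hit in hits:
        rec = hit.record
        if criteria.period is not None and not _overlaps(criteria.period, hit):
            continue
        if criteria.hospitals is not None and rec.hs_id not in criteria.hospitals:
            continue
        if (
            criteria.department is not None
            and criteria.department.lower() not in rec.department.lower()
        ):
            continue
        if (
            criteria.event is not None
            and criteria.event.lower() not in rec.payload.lower()
        ):
            continue
        if (
            criteria.pathology is not None
            and criteria.pathology.lower() not in rec.pathology.lower()
        ):
            continue
        out.append(hit)
    return out
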