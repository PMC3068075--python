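"""Patient identity pseudonymization.

The universal identity header every electronic medical record carries —
first name(s), last name(s), date of birth — is turned into a *list of
partial pseudonymous identifiers*: one SHA-256 digest per combination of
name components with the birth date, so that a record filed under
"David Smith" can still be found when the request says "David Roger
Smith", and a phonetic tier tolerates spelling variants ("Smyth" for
"Smith").

The pipeline is ``canonicalize`` (normalize the raw strings) →
``enumerate_bases`` (all name-component combinations, each an
:class:`IdentityBasis`) → ``hash_basis`` (digest each basis).  Hashing
is deterministic across all actors, so the requesting practitioner and
every hospital derive byte-identical digests from equal identities —
this is what makes hashed matching work without exchanging plaintext
names.

The hash is unkeyed by default: confidentiality in transit comes from
encrypting the digests, not from keying the hash.  A keyed mode (HMAC
under a secret shared by practitioners and hospitals) is available via
the ``hash_key`` argument for deployments that also want dictionary
attacks on stored digests to fail.
"""

from __future__ import annotations

import csv
import datetime as _dt
import hashlib
import hmac as _hmac
import itertools
import unicodedata
from dataclasses import dataclass
from enum import Enum
from typing import Callable, List, Optional, Sequence, Union

from .errors import InvalidDateError, InvalidIdentityError, InvalidTokenError

__all__ = [
    "Tier",
    "IdentityTraits",
    "CanonicalIdentity",
    "IdentityBasis",
    "PartialPseudonym",
    "PseudonymSet",
    "canonicalize",
    "soundex",
    "phonetic_encode",
    "enumerate_bases",
    "hash_basis",
    "derive_pseudonym_set",
    "read_traits_csv",
    "write_traits_csv",
]


class Tier(str, Enum):
    """Basis tier; matching confidence decreases FULL > TOKEN > PHONETIC."""

    FULL = "FULL"
    TOKEN = "TOKEN"
    PHONETIC = "PHONETIC"

    @property
    def rank(self) -> int:
        return {"FULL": 2, "TOKEN": 1, "PHONETIC": 0}[self.value]


_TIER_ORDER = (Tier.FULL, Tier.TOKEN, Tier.PHONETIC)


@dataclass(frozen=True)
class IdentityTraits:
    """Raw identity header as it appears in a record or a request."""

    first_name_raw: str
    last_name_raw: str
    birth_date: Union[_dt.date, str]


@dataclass(frozen=True)
class CanonicalIdentity:
    first_tokens: tuple
    last_tokens: tuple
    birth_date: str  # ISO-8601

    @property
    def first_joined(self) -> str:
        return " ".join(self.first_tokens)

    @property
    def last_joined(self) -> str:
        return " ".join(self.last_tokens)


@dataclass(frozen=True)
class IdentityBasis:
    first_part: str
    last_part: str
    birth_date: str
    tier: Tier


@dataclass(frozen=True)
class PartialPseudonym:
    digest: str
    basis: IdentityBasis


@dataclass(frozen=True)
class PseudonymSet:
    pseudonyms: tuple

    def digests(self) -> List[str]:
        return [p.digest for p in self.pseudonyms]

    def basis_for(self, digest: str) -> IdentityBasis:
        for p in self.pseudonyms:
            if p.digest == digest:
                return p.basis
        raise KeyError(digest)

    def __len__(self) -> int:
        return len(self.pseudonyms)

    def __iter__(self):
        return iter(self.pseudonyms)


# ---------------------------------------------------------------------------
# Canonicalization

_SEPARATORS = str.maketrans({"-": " ", "'": " ", "’": " "})


def _fold_token(raw: str) -> str:
    """Uppercase, strip diacritics, keep only A-Z."""
    upper = unicodedata.normalize("NFKD", raw).upper()
    return "".join(c for c in upper if "A" <= c <= "Z")


def _tokenize(raw: str) -> tuple:
    tokens = []
    for piece in raw.translate(_SEPARATORS).split():
        folded = _fold_token(piece)
        if folded:
            tokens.append(folded)
    return tuple(tokens)


def _parse_date(value: Union[_dt.date, str]) -> str:
    if isinstance(value, _dt.datetime):
        value = value.date()
    if isinstance(value, _dt.date):
        return value.isoformat()
    try:
        return _dt.date.fromisoformat(str(value).strip()).isoformat()
    except ValueError as exc:
        raise InvalidDateError(f"not a valid ISO-8601 date: {value!r}") from exc


def canonicalize(traits: IdentityTraits) -> CanonicalIdentity:
    """Normalize raw traits into the canonical matching form.

    Uppercases, folds diacritics to their base letters, treats hyphens
    and apostrophes as token separators, collapses whitespace, and
    preserves token order.  Raises :class:`InvalidIdentityError` when a
    name is empty after normalization, :class:`InvalidDateError` for a
    bad birth date.
    """
    first = _tokenize(traits.first_name_raw)
    last = _tokenize(traits.last_name_raw)
    if not first:
        raise InvalidIdentityError(
            f"first name empty after normalization: {traits.first_name_raw!r}"
        )
    if not last:
        raise InvalidIdentityError(
            f"last name empty after normalization: {traits.last_name_raw!r}"
        )
    return CanonicalIdentity(
        first_tokens=first, last_tokens=last, birth_date=_parse_date(traits.birth_date)
    )


# ---------------------------------------------------------------------------
# Phonetic encoding (classic 4-character Soundex; pluggable)

_SOUNDEX_CODES = {
    **dict.fromkeys("BFPV", "1"),
    **dict.fromkeys("CGJKQSXZ", "2"),
    **dict.fromkeys("DT", "3"),
    "L": "4",
    **dict.fromkeys("MN", "5"),
    "R": "6",
}


def soundex(token: str) -> str:
    """Classic American Soundex of an A-Z token (e.g. ``ROBERT -> R163``).

    Rules: keep the first letter; encode consonants by class; letters in
    the same class separated by H or W collapse; vowels (and Y) break a
    run; pad/truncate to one letter plus three digits.
    """
    if not token or not all("A" <= c <= "Z" for c in token):
        raise InvalidTokenError(f"not an A-Z token: {token!r}")
    out = token[0]
    prev = _SOUNDEX_CODES.get(token[0], "")
    for c in token[1:]:
        code = _SOUNDEX_CODES.get(c)
        if code is None:
            # H and W are transparent; vowels and Y reset the run.
            if c not in "HW":
                prev = ""
            continue
        if code != prev:
            out += code
            if len(out) == 4:
                break
        prev = code
    return (out + "000")[:4]


#: module-level hook: swap in another phonetic scheme if desired
phonetic_encoder: Callable[[str], str] = soundex


def phonetic_encode(token: str) -> str:
    """Encode one normalized token with the configured phonetic scheme."""
    return phonetic_encoder(token)


def _phonetic_part(part: str) -> str:
    return " ".join(phonetic_encode(tok) for tok in part.split())


# ---------------------------------------------------------------------------
# Basis enumeration and hashing


def enumerate_bases(
    canon: CanonicalIdentity, include_phonetic: bool = True
) -> List[IdentityBasis]:
    """All identity bases for one canonical identity.

    Non-phonetic bases are the Cartesian product of {each first token,
    plus the joined first name when multi-token} × {likewise for last
    names}, every combination paired with the birth date.  Exactly one
    basis — joined × joined — is the FULL tier.  With
    ``include_phonetic``, each non-phonetic basis additionally yields a
    PHONETIC basis whose name parts are phonetic codes.  The result is
    deduplicated and deterministically ordered: FULL, then TOKEN, then
    PHONETIC, lexicographic within tier.
    """
    firsts = list(canon.first_tokens)
    if len(canon.first_tokens) > 1:
        firsts.append(canon.first_joined)
    lasts = list(canon.last_tokens)
    if len(canon.last_tokens) > 1:
        lasts.append(canon.last_joined)

    seen = set()
    exact: List[IdentityBasis] = []
    for fp, lp in itertools.product(firsts, lasts):
        tier = (
            Tier.FULL
            if fp == canon.first_joined and lp == canon.last_joined
            else Tier.TOKEN
        )
        key = (fp, lp, tier)
        if key in seen:
            continue
        seen.add(key)
        exact.append(
            IdentityBasis(
                first_part=fp, last_part=lp, birth_date=canon.birth_date, tier=tier
            )
        )

    phonetic: List[IdentityBasis] = []
    if include_phonetic:
        pseen = set()
        for basis in exact:
            fp, lp = _phonetic_part(basis.first_part), _phonetic_part(basis.last_part)
            if (fp, lp) in pseen:
                continue
            pseen.add((fp, lp))
            phonetic.append(
                IdentityBasis(
                    first_part=fp,
                    last_part=lp,
                    birth_date=canon.birth_date,
                    tier=Tier.PHONETIC,
                )
            )

    def sort_key(b: IdentityBasis):
        return (_TIER_ORDER.index(b.tier), b.first_part, b.last_part)

    return sorted(exact + phonetic, key=sort_key)


def hash_basis(basis: IdentityBasis, hash_key: Optional[bytes] = None) -> str:
    """256-bit digest of the canonical serialization FIRST|LAST|DATE|TIER.

    SHA-256 unkeyed by default; HMAC-SHA256 when *hash_key* is given.
    Positional serialization keeps swapped first/last names distinct.
    """
    msg = "|".join(
        [basis.first_part, basis.last_part, basis.birth_date, basis.tier.value]
    ).encode("utf-8")
    if hash_key is not None:
        return _hmac.new(hash_key, msg, hashlib.sha256).hexdigest()
    return hashlib.sha256(msg).hexdigest()


def derive_pseudonym_set(
    traits: IdentityTraits,
    include_phonetic: bool = True,
    hash_key: Optional[bytes] = None,
) -> PseudonymSet:
    """Full pipeline: traits → canonical form → bases → hashed pseudonyms.

    A pure function of its inputs: equal traits give byte-identical
    pseudonym sets on every actor and every run.  Duplicate digests
    (colliding phonetic codes) are dropped, first occurrence kept.
    """
    canon = canonicalize(traits)
    pseudonyms = []
    seen = set()
    for basis in enumerate_bases(canon, include_phonetic=include_phonetic):
        digest = hash_basis(basis, hash_key=hash_key)
        if digest in seen:
            continue
        seen.add(digest)
        pseudonyms.append(PartialPseudonym(digest=digest, basis=basis))
    return PseudonymSet(pseudonyms=tuple(pseudonyms))


# ---------------------------------------------------------------------------
# CSV fixtures (columns: first_name,last_name,birth_date)


def read_traits_csv(path) -> List[IdentityTraits]:
    with open(path, newline="", encoding="utf-8") as fh:
        return [
            IdentityTraits(
                first_name_raw=row["first_name"],
                last_name_raw=row["last_name"],
                birth_date=row["birth_date"],
            )
            for row in csv.DictReader(fh)
        ]


def write_traits_csv(path, traits: Sequence[IdentityTraits]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["first_name", "last_name", "birth_date"])
        for t in traits:
            writer.writerow([t.first_name_raw, t.last_name_raw, _parse_date(t.birth_date)])
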