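"""The split-trust retrieval protocol over instrumented actors.

Actors: the requesting Medical Practitioner (MP), two mutually isolated
Medical Record Search Engines (MRSE1, MRSE2), the hospitals, and an
aggregator.  A request travels in two asymmetrically protected halves:

* MRSE1 receives ``(x, K, e_j)`` — the request number, a fresh session
  key, and the MP's public key — but never any pseudonym material;
* MRSE2 receives ``(x, E_K(digests + criteria))`` — the hashed patient
  identities symmetrically encrypted under K — but never K itself.

Each MRSE re-seals its half to every hospital in the directory and
signs it.  Only a hospital, holding both halves, can recover the digest
list, match it against its own hashed patient index, and answer with a
signed record whose confidential content (matched digest + the EMR) is
sealed to the MP key ``e_j``.  The aggregator groups all answers for
one request number and releases them to the MP after challenge-response
authentication; the MP verifies every hospital signature, decrypts, and
tags each record with a linkage level.

Everything runs over an in-process message bus that records a global
trace, and every actor keeps an :class:`ObservationLedger` of each
plaintext it ever held — the substrate on which the privacy
information-flow assertions (:func:`privacy_report`,
:func:`assert_no_channel`) are checked after any run.
"""

from __future__ import annotations

import uuid
from dataclasses import dataclass, field
from random import Random
from typing import Dict, List, Optional, Sequence, Tuple

from ._canonical import b64d, b64e, canonical_json, from_canonical_json
from .crypto import (
    ChallengeVerifier,
    Ciphertext,
    DEFAULT_GROUP,
    KeyPair,
    PublicKey,
    SessionKey,
    Signature,
    answer_challenge,
    generate_keypair,
    new_session_key,
    open_sealed,
    seal,
    sign_message,
    sym_open,
    sym_seal,
    verify_signature,
)
from .errors import (
    AuthenticationError,
    ConsentError,
    DecryptionError,
    IncompleteBundleError,
    IsolationViolationError,
    JoinFailureError,
    ProtocolAbortError,
)
from .hospital import EMRDocument, HospitalStore, SelectionCriteria, filter_by_criteria
from .identity import IdentityTraits, PseudonymSet, Tier, derive_pseudonym_set
from .linkage import LinkageLevel, RankedResult, assign_level, rank_results

__all__ = [
    "ProtocolConfig",
    "ObservationLedger",
    "Message",
    "MessageBus",
    "HSDirectory",
    "ResultRecord",
    "AggregatedBundle",
    "RunResult",
    "Simulation",
    "run_request",
    "mp_build_request",
    "mrse_forward",
    "hs_handle",
    "aggregator_collect",
    "mp_finalize",
    "assert_no_channel",
    "privacy_report",
    "collect_nonces",
]

MRSE1 = "MRSE1"
MRSE2 = "MRSE2"
AGGREGATOR = "AGG"


# ---------------------------------------------------------------------------
# Infrastructure: ledgers, bus, directory


@dataclass
class ObservationLedger:
    """Append-only record of every plaintext one actor ever held.

    Ciphertext an actor merely relays is not "held"; what lands here is
    exactly what the actor could read after its own decryptions.  The
    privacy suite greps these entries for material the actor must never
    see (digests, session keys, EMR bytes).
    """

    actor_id: str
    entries: List[Tuple[str, bytes]] = field(default_factory=list)

    def record(self, step: str, plaintext: bytes) -> None:
        self.entries.append((step, plaintext))

    def contains(self, needle: bytes) -> bool:
        return any(needle in data for _, data in self.entries)

    def to_jsonl(self) -> str:
        lines = [
            canonical_json({"actor": self.actor_id, "step": s, "data_b64": b64e(d)})
            for s, d in self.entries
        ]
        return b"\n".join(lines).decode("ascii")


@dataclass(frozen=True)
class Message:
    sender: str
    recipient: str
    step: str
    payload: bytes
    signature: Optional[Signature] = None

    def to_envelope(self) -> bytes:
        return canonical_json(
            {
                "sender": self.sender,
                "recipient": self.recipient,
                "step": self.step,
                "payload_b64": b64e(self.payload),
                "signature_b64": b64e(self.signature.data) if self.signature else None,
                "signer": self.signature.signer_id if self.signature else None,
            }
        )


class MessageBus:
    """In-process transport with a global trace.

    The architectural rule that the two MRSEs cannot communicate becomes
    executable here: in honest mode the bus refuses any MRSE1<->MRSE2
    send outright; an adversarial bus (``honest=False``) lets such a
    message through so tests can confirm the trace audit catches it.
    """

    def __init__(self, honest: bool = True):
        self.honest = honest
        self.trace: List[Message] = []

    def send(self, msg: Message) -> Message:
        if self.honest and {msg.sender, msg.recipient} == {MRSE1, MRSE2}:
            raise IsolationViolationError(
                f"forbidden channel {msg.sender} -> {msg.recipient}", offending=msg
            )
        self.trace.append(msg)
        return msg

    def trace_jsonl(self, trace: Optional[Sequence[Message]] = None) -> str:
        msgs = self.trace if trace is None else trace
        return b"\n".join(m.to_envelope() for m in msgs).decode("ascii")


@dataclass
class HSDirectory:
    """Directory of connected health structures: id, public key, endpoint."""

    entries: List[Tuple[str, PublicKey, object]] = field(default_factory=list)

    def __post_init__(self):
        ids = [hs_id for hs_id, _, _ in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate hospital ids in directory")
        self.entries.sort(key=lambda e: e[0])

    def ids(self) -> List[str]:
        return [hs_id for hs_id, _, _ in self.entries]

    def public_key(self, hs_id: str) -> Optional[PublicKey]:
        for eid, pub, _ in self.entries:
            if eid == hs_id:
                return pub
        return None


# ---------------------------------------------------------------------------
# Wire records


def _ct_to_dict(ct: Ciphertext) -> dict:
    return {"data_b64": b64e(ct.data), "scheme": ct.scheme_tag, "hint": ct.recipient_hint}


def _ct_from_dict(obj: dict) -> Ciphertext:
    return Ciphertext(
        data=b64d(obj["data_b64"]), scheme_tag=obj["scheme"], recipient_hint=obj["hint"]
    )


def _pub_to_dict(pub: PublicKey) -> dict:
    return {"y": pub.y, "owner_id": pub.owner_id, "group": pub.group}


def _pub_from_dict(obj: dict) -> PublicKey:
    return PublicKey(y=int(obj["y"]), owner_id=obj["owner_id"], group=obj["group"])


@dataclass(frozen=True)
class ResultRecord:
    """One hospital's signed contribution to a request.

    ``substantive`` distinguishes a real match from the signed
    empty-response a hospital emits when nothing matched, so the
    aggregator can tell "no match" from "no reply" without being able to
    read anything confidential.
    """

    x: str
    enc_confidential: Ciphertext
    hs_id: str
    signature: Signature
    substantive: bool

    def signed_payload(self) -> bytes:
        return canonical_json(
            {
                "x": self.x,
                "ct_b64": b64e(self.enc_confidential.data),
                "hs_id": self.hs_id,
                "substantive": self.substantive,
            }
        )

    def to_dict(self) -> dict:
        return {
            "x": self.x,
            "enc_confidential": _ct_to_dict(self.enc_confidential),
            "hs_id": self.hs_id,
            "signature_b64": b64e(self.signature.data),
            "signer": self.signature.signer_id,
            "substantive": self.substantive,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "ResultRecord":
        return cls(
            x=obj["x"],
            enc_confidential=_ct_from_dict(obj["enc_confidential"]),
            hs_id=obj["hs_id"],
            signature=Signature(data=b64d(obj["signature_b64"]), signer_id=obj["signer"]),
            substantive=obj["substantive"],
        )


@dataclass
class AggregatedBundle:
    x: str
    records: List[ResultRecord]
    responding_hs: List[str]
    mismatched: List[ResultRecord] = field(default_factory=list)


@dataclass
class ProtocolConfig:
    """Run-wide knobs: pseudonym tiers, hash keying, DH group, seeding."""

    include_phonetic: bool = True
    hash_key: Optional[bytes] = None
    group: str = DEFAULT_GROUP
    seed: Optional[int] = None


# ---------------------------------------------------------------------------
# Step 2: the MP splits the request between the MRSEs


def mp_build_request(
    pseudonyms: PseudonymSet,
    criteria: Optional[SelectionCriteria],
    mp_keys: KeyPair,
    mrse1_pub: PublicKey,
    mrse2_pub: PublicKey,
    x: str,
    rng: Optional[Random] = None,
    consent: bool = True,
    ledger: Optional[ObservationLedger] = None,
) -> Tuple[Ciphertext, Ciphertext, SessionKey]:
    """Build the two sealed request halves for request number *x*.

    Part 1 (to MRSE1): ``{x, K, e_j}``.  Part 2 (to MRSE2):
    ``{x, E_K(digests + criteria)}``.  The split guarantees neither
    relay alone can recover a pseudonym: MRSE1 never sees digests,
    MRSE2 never sees K.  Selection criteria travel inside the
    K-encrypted payload because pathology names are themselves
    confidential.  Refuses to build anything without patient consent.
    """
    if not consent:
        raise ConsentError("patient consent absent; request refused")
    session_key = new_session_key(request_number=x, rng=rng)

    part1_plain = canonical_json(
        {
            "x": x,
            "K_b64": b64e(session_key.key_bytes),
            "e_j": _pub_to_dict(mp_keys.public_part),
        }
    )
    inner_plain = canonical_json(
        {
            "digests": pseudonyms.digests(),
            "criteria": (criteria or SelectionCriteria()).to_dict(),
        }
    )
    enc_payload = sym_seal(inner_plain, session_key, rng=rng)
    part2_plain = canonical_json({"x": x, "enc_payload": _ct_to_dict(enc_payload)})

    if ledger is not None:
        ledger.record("mp_build_request.part1", part1_plain)
        ledger.record("mp_build_request.inner", inner_plain)

    sealed1 = seal(part1_plain, mrse1_pub, rng=rng)
    sealed2 = seal(part2_plain, mrse2_pub, rng=rng)
    return sealed1, sealed2, session_key


# ---------------------------------------------------------------------------
# Step 3: each MRSE fans its half out to every hospital


def mrse_forward(
    role: str,
    sealed_part: Ciphertext,
    directory: HSDirectory,
    mrse_keys: KeyPair,
    bus: MessageBus,
    rng: Optional[Random] = None,
    ledger: Optional[ObservationLedger] = None,
) -> List[Message]:
    """Decrypt one request half and re-seal it, signed, to every hospital.

    The MRSE's ledger records exactly the plaintext it decrypted — for
    MRSE1 that is ``(x, K, e_j)``; for MRSE2 ``(x, E_K(...))`` whose
    payload stays opaque to it.
    """
    if role not in (MRSE1, MRSE2):
        raise ValueError(f"unknown MRSE role {role!r}")
    try:
        plain = open_sealed(sealed_part, mrse_keys.private_part)
    except DecryptionError as exc:
        raise ProtocolAbortError(f"{role} could not decrypt its request part") from exc
    if ledger is not None:
        ledger.record(f"{role}.decrypted_part", plain)

    out = []
    for hs_id, hs_pub, _ in directory.entries:
        resealed = seal(plain, hs_pub, rng=rng)
        sig = sign_message(resealed.data, mrse_keys.private_part)
        msg = Message(
            sender=role,
            recipient=hs_id,
            step=f"{role.lower()}_to_hs",
            payload=canonical_json({"ct": _ct_to_dict(resealed)}),
            signature=sig,
        )
        bus.send(msg)
        out.append(msg)
    return out


def assert_no_channel(trace_or_bus) -> bool:
    """Verify the MRSE isolation constraint on a completed trace.

    Returns ``True`` on a clean trace; raises
    :class:`IsolationViolationError` naming the offending message if any
    edge between the two MRSEs exists, in either direction.
    """
    trace = trace_or_bus.trace if isinstance(trace_or_bus, MessageBus) else trace_or_bus
    for msg in trace:
        if {msg.sender, msg.recipient} == {MRSE1, MRSE2}:
            raise IsolationViolationError(
                f"isolation violated: {msg.sender} -> {msg.recipient} at step "
                f"{msg.step!r}",
                offending=msg,
            )
    return True


# ---------------------------------------------------------------------------
# Steps 4-5: hospital-side matching and signed, sealed results


def hs_handle(
    msg_from_mrse1: Message,
    msg_from_mrse2: Message,
    store: HospitalStore,
    hs_keys: KeyPair,
    mrse1_pub: PublicKey,
    mrse2_pub: PublicKey,
    rng: Optional[Random] = None,
    ledger: Optional[ObservationLedger] = None,
) -> Tuple[List[ResultRecord], List[str]]:
    """Join the two request halves, match, filter, and answer.

    Verifies both MRSE signatures (an invalid one rejects that message
    with an audit entry), joins the halves on the request number,
    recovers the digest list with K, searches the hashed index, applies
    the selection criteria, and emits one signed :class:`ResultRecord`
    per surviving match — confidential content sealed to the MP key
    ``e_j``.  With no match it emits one signed empty-response record so
    the aggregator can account for this hospital.
    """
    audit: List[str] = []

    def _open_checked(msg: Message, pub: PublicKey, role: str) -> Optional[dict]:
        obj = from_canonical_json(msg.payload)
        ct = _ct_from_dict(obj["ct"])
        if msg.signature is None or not verify_signature(ct.data, msg.signature, pub):
            audit.append(f"{store.hs_id}: invalid {role} signature; message rejected")
            return None
        plain = open_sealed(ct, hs_keys.private_part)
        if ledger is not None:
            ledger.record(f"hs.{role.lower()}_part", plain)
        return from_canonical_json(plain)

    part1 = _open_checked(msg_from_mrse1, mrse1_pub, MRSE1)
    part2 = _open_checked(msg_from_mrse2, mrse2_pub, MRSE2)
    if part1 is None or part2 is None:
        return [], audit

    if part1["x"] != part2["x"]:
        raise JoinFailureError(
            f"request number mismatch at {store.hs_id}: "
            f"{part1['x']!r} vs {part2['x']!r}"
        )
    x = part1["x"]
    session_key = SessionKey(key_bytes=b64d(part1["K_b64"]), request_number=x)
    e_j = _pub_from_dict(part1["e_j"])

    inner = from_canonical_json(
        sym_open(_ct_from_dict(part2["enc_payload"]), session_key)
    )
    if ledger is not None:
        ledger.record("hs.recovered_request", canonical_json(inner))
    digests = inner["digests"]
    criteria = SelectionCriteria.from_dict(inner["criteria"])

    hits = filter_by_criteria(store.search_by_digest(digests), criteria)

    records: List[ResultRecord] = []
    for hit in hits:
        confidential = canonical_json(
            {
                "empty": False,
                "digest": hit.matched_digest,
                "tier": hit.matched_tier.value,
                "matched_digests": list(hit.all_matched_digests),
                "emr": hit.record.to_dict(),
            }
        )
        if ledger is not None:
            ledger.record("hs.result_plain", confidential)
        records.append(
            _make_record(x, confidential, store.hs_id, hs_keys, e_j, rng, True)
        )
    if not records:
        confidential = canonical_json({"empty": True})
        records.append(
            _make_record(x, confidential, store.hs_id, hs_keys, e_j, rng, False)
        )
    return records, audit


def _make_record(
    x: str,
    confidential: bytes,
    hs_id: str,
    hs_keys: KeyPair,
    e_j: PublicKey,
    rng: Optional[Random],
    substantive: bool,
) -> ResultRecord:
    enc = seal(confidential, e_j, rng=rng)
    unsigned = ResultRecord(
        x=x,
        enc_confidential=enc,
        hs_id=hs_id,
        signature=Signature(data=b"", signer_id=hs_id),
        substantive=substantive,
    )
    sig = sign_message(unsigned.signed_payload(), hs_keys.private_part)
    return ResultRecord(
        x=x, enc_confidential=enc, hs_id=hs_id, signature=sig, substantive=substantive
    )


# ---------------------------------------------------------------------------
# Step 6: aggregation and authenticated delivery


def aggregator_collect(
    records: Sequence[ResultRecord],
    x: str,
    directory: HSDirectory,
    mp_keys: KeyPair,
    verifier: ChallengeVerifier,
    bus: MessageBus,
    mp_id: str,
    ledger: Optional[ObservationLedger] = None,
) -> AggregatedBundle:
    """Group all hospital answers for request *x* and deliver to the MP.

    Requires one response (possibly empty) per directory hospital;
    records carrying a foreign request number are set aside and flagged.
    Delivery happens only after the MP answers the aggregator's
    challenge with a signature under the key the aggregator trusts.
    The aggregator's ledger sees request numbers, hospital ids and
    substantive flags — never a digest, never an EMR byte.
    """
    matched = [r for r in records if r.x == x]
    mismatched = [r for r in records if r.x != x]
    responding = sorted({r.hs_id for r in matched})
    absentees = [hs for hs in directory.ids() if hs not in responding]
    if absentees:
        raise IncompleteBundleError(
            f"no response for request {x} from: {', '.join(absentees)}",
            absentees=absentees,
        )
    if ledger is not None:
        for r in matched:
            ledger.record(
                "agg.record_meta",
                canonical_json(
                    {"x": r.x, "hs_id": r.hs_id, "substantive": r.substantive}
                ),
            )

    # Challenge-response: the aggregator challenges the MP before release.
    nonce = verifier.issue_challenge()
    bus.send(
        Message(sender=AGGREGATOR, recipient=mp_id, step="agg_challenge", payload=nonce)
    )
    response = answer_challenge(nonce, mp_keys.private_part)
    bus.send(
        Message(
            sender=mp_id,
            recipient=AGGREGATOR,
            step="agg_challenge_response",
            payload=nonce,
            signature=response,
        )
    )
    if not verifier.verify_response(mp_id, nonce, response):
        raise AuthenticationError(f"MP {mp_id} failed challenge-response; delivery refused")

    bundle = AggregatedBundle(
        x=x,
        records=sorted(matched, key=lambda r: (r.hs_id, b64e(r.enc_confidential.data))),
        responding_hs=responding,
        mismatched=mismatched,
    )
    bus.send(
        Message(
            sender=AGGREGATOR,
            recipient=mp_id,
            step="bundle_delivery",
            payload=canonical_json(
                {"x": x, "records": [r.to_dict() for r in bundle.records]}
            ),
        )
    )
    return bundle


# ---------------------------------------------------------------------------
# Step 7 (MP side): verify, decrypt, tag with linkage levels


def mp_finalize(
    bundle: AggregatedBundle,
    mp_keys: KeyPair,
    pseudonyms: PseudonymSet,
    directory: HSDirectory,
    ledger: Optional[ObservationLedger] = None,
) -> Tuple[List[RankedResult], List[str]]:
    """Validate and open every record; tag survivors with linkage levels.

    Per record: the hospital signature must verify against a directory
    key *before* decryption; tampered, unverifiable or undecryptable
    records are dropped with an audit entry, never fatally.  Each
    surviving EMR is mapped back to the basis that generated its matched
    digest and levelled HIGH/MEDIUM/LOW for the validation workflow.
    """
    audit: List[str] = []
    results: List[RankedResult] = []
    for rec in bundle.records:
        pub = directory.public_key(rec.hs_id)
        if pub is None:
            audit.append(f"record from unknown hospital {rec.hs_id!r} rejected")
            continue
        if not verify_signature(rec.signed_payload(), rec.signature, pub):
            audit.append(f"signature failure on record from {rec.hs_id}; rejected")
            continue
        try:
            plain = open_sealed(rec.enc_confidential, mp_keys.private_part)
        except DecryptionError:
            audit.append(f"undecryptable confidential part from {rec.hs_id}; rejected")
            continue
        obj = from_canonical_json(plain)
        if obj.get("empty"):
            continue
        if ledger is not None:
            ledger.record("mp.opened_result", plain)
        try:
            basis = pseudonyms.basis_for(obj["digest"])
        except KeyError:
            audit.append(
                f"record from {rec.hs_id} matched a digest outside the request; rejected"
            )
            continue
        tier = Tier(obj["tier"])
        n_token = 1
        if tier is Tier.TOKEN:
            token_bases = set()
            for d in obj.get("matched_digests", []):
                try:
                    b = pseudonyms.basis_for(d)
                except KeyError:
                    continue
                if b.tier is Tier.TOKEN:
                    token_bases.add((b.first_part, b.last_part))
            n_token = max(1, len(token_bases))
        results.append(
            RankedResult(
                emr=EMRDocument.from_dict(obj["emr"]),
                hs_id=rec.hs_id,
                level=assign_level(tier, n_token),
                matched_basis=basis,
                matched_digest=obj["digest"],
            )
        )
    return rank_results(results), audit


# ---------------------------------------------------------------------------
# The whole seven-step routine


@dataclass
class RunResult:
    """Everything one request produced: results, trace slice, ledgers."""

    x: str
    results: List[RankedResult]
    bundle: AggregatedBundle
    trace: List[Message]
    ledgers: Dict[str, ObservationLedger]
    audit: List[str]
    pseudonyms: PseudonymSet
    session_key: SessionKey


class Simulation:
    """A keyed, instrumented world ready to serve requests.

    Builds keypairs for every actor (seeded and reproducible when
    ``config.seed`` is set), indexes every hospital store, wires the
    message bus, and exposes :meth:`run_request` for the end-to-end
    seven-step routine.  Request numbers are a monotone counter
    namespaced by the MP id under a seed, UUIDs otherwise.
    """

    def __init__(
        self,
        stores: Sequence[HospitalStore],
        mp_id: str = "MP-1",
        config: Optional[ProtocolConfig] = None,
        honest_bus: bool = True,
    ):
        self.config = config or ProtocolConfig()
        self.mp_id = mp_id
        self.rng = Random(self.config.seed) if self.config.seed is not None else None
        self.bus = MessageBus(honest=honest_bus)
        self._x_counter = 0

        grp = self.config.group
        self.mp_keys = generate_keypair(mp_id, rng=self.rng, group=grp)
        self.mrse1_keys = generate_keypair(MRSE1, rng=self.rng, group=grp)
        self.mrse2_keys = generate_keypair(MRSE2, rng=self.rng, group=grp)
        self.stores = {s.hs_id: s for s in sorted(stores, key=lambda s: s.hs_id)}
        self.hs_keys: Dict[str, KeyPair] = {
            hs_id: generate_keypair(hs_id, rng=self.rng, group=grp)
            for hs_id in self.stores
        }
        self.agg_keys = generate_keypair(AGGREGATOR, rng=self.rng, group=grp)

        for store in self.stores.values():
            store.build_index(
                include_phonetic=self.config.include_phonetic,
                hash_key=self.config.hash_key,
            )

        self.directory = HSDirectory(
            entries=[
                (hs_id, self.hs_keys[hs_id].public_part, self.stores[hs_id])
                for hs_id in self.stores
            ]
        )
        self.ledgers: Dict[str, ObservationLedger] = {
            actor: ObservationLedger(actor_id=actor)
            for actor in [mp_id, MRSE1, MRSE2, AGGREGATOR, *self.stores]
        }
        self.agg_verifier = ChallengeVerifier(
            trusted={mp_id: self.mp_keys.public_part}, rng=self.rng
        )
        self._mrse_verifiers = {
            role: ChallengeVerifier(trusted={mp_id: self.mp_keys.public_part}, rng=self.rng)
            for role in (MRSE1, MRSE2)
        }
        self.session_keys: List[bytes] = []

    # -- request numbering -------------------------------------------------

    def _next_x(self) -> str:
        if self.rng is not None:
            self._x_counter += 1
            return f"{self.mp_id}-x{self._x_counter:06d}"
        return f"{self.mp_id}-{uuid.uuid4()}"

    # -- the seven-step routine --------------------------------------------

    def run_request(
        self,
        patient_traits: IdentityTraits,
        criteria: Optional[SelectionCriteria] = None,
        consent: bool = True,
    ) -> RunResult:
        trace_start = len(self.bus.trace)
        mp_ledger = self.ledgers[self.mp_id]

        # Authentication: both MRSEs challenge the MP before accepting.
        for role in (MRSE1, MRSE2):
            verifier = self._mrse_verifiers[role]
            nonce = verifier.issue_challenge()
            self.bus.send(
                Message(sender=role, recipient=self.mp_id, step="mrse_challenge", payload=nonce)
            )
            response = answer_challenge(nonce, self.mp_keys.private_part)
            self.bus.send(
                Message(
                    sender=self.mp_id,
                    recipient=role,
                    step="mrse_challenge_response",
                    payload=nonce,
                    signature=response,
                )
            )
            if not verifier.verify_response(self.mp_id, nonce, response):
                raise AuthenticationError(f"MP authentication to {role} failed")

        # Step 1: pseudonymization.
        pseudonyms = derive_pseudonym_set(
            patient_traits,
            include_phonetic=self.config.include_phonetic,
            hash_key=self.config.hash_key,
        )

        # Step 2: split request.
        x = self._next_x()
        sealed1, sealed2, session_key = mp_build_request(
            pseudonyms,
            criteria,
            self.mp_keys,
            self.mrse1_keys.public_part,
            self.mrse2_keys.public_part,
            x=x,
            rng=self.rng,
            consent=consent,
            ledger=mp_ledger,
        )
        self.session_keys.append(session_key.key_bytes)
        msg_to_1 = self.bus.send(
            Message(
                sender=self.mp_id,
                recipient=MRSE1,
                step="request_part1",
                payload=canonical_json({"ct": _ct_to_dict(sealed1)}),
            )
        )
        msg_to_2 = self.bus.send(
            Message(
                sender=self.mp_id,
                recipient=MRSE2,
                step="request_part2",
                payload=canonical_json({"ct": _ct_to_dict(sealed2)}),
            )
        )
        del msg_to_1, msg_to_2  # relays read them off the bus in a real system

        # Step 3: MRSE fan-out.
        msgs1 = mrse_forward(
            MRSE1, sealed1, self.directory, self.mrse1_keys,
            self.bus, rng=self.rng, ledger=self.ledgers[MRSE1],
        )
        msgs2 = mrse_forward(
            MRSE2, sealed2, self.directory, self.mrse2_keys,
            self.bus, rng=self.rng, ledger=self.ledgers[MRSE2],
        )
        by_hs_1 = {m.recipient: m for m in msgs1}
        by_hs_2 = {m.recipient: m for m in msgs2}

        # Steps 4-5: hospital matching and signed results.
        all_records: List[ResultRecord] = []
        audit: List[str] = []
        for hs_id, store in self.stores.items():
            records, hs_audit = hs_handle(
                by_hs_1[hs_id],
                by_hs_2[hs_id],
                store,
                self.hs_keys[hs_id],
                self.mrse1_keys.public_part,
                self.mrse2_keys.public_part,
                rng=self.rng,
                ledger=self.ledgers[hs_id],
            )
            audit.extend(hs_audit)
            for rec in records:
                self.bus.send(
                    Message(
                        sender=hs_id,
                        recipient=AGGREGATOR,
                        step="result_record",
                        payload=canonical_json(rec.to_dict()),
                        signature=rec.signature,
                    )
                )
                all_records.append(rec)

        # Step 6: aggregation + authenticated delivery.
        bundle = aggregator_collect(
            all_records,
            x,
            self.directory,
            self.mp_keys,
            self.agg_verifier,
            self.bus,
            self.mp_id,
            ledger=self.ledgers[AGGREGATOR],
        )

        # Step 7: MP-side verification, decryption, linkage levels.
        results, final_audit = mp_finalize(
            bundle, self.mp_keys, pseudonyms, self.directory, ledger=mp_ledger
        )
        audit.extend(final_audit)

        return RunResult(
            x=x,
            results=results,
            bundle=bundle,
            trace=self.bus.trace[trace_start:],
            ledgers=self.ledgers,
            audit=audit,
            pseudonyms=pseudonyms,
            session_key=session_key,
        )


def run_request(
    stores: Sequence[HospitalStore],
    mp_id: str,
    patient_traits: IdentityTraits,
    criteria: Optional[SelectionCriteria] = None,
    config: Optional[ProtocolConfig] = None,
) -> RunResult:
    """One-shot convenience: build a :class:`Simulation` and run a request."""
    return Simulation(stores, mp_id=mp_id, config=config).run_request(
        patient_traits, criteria
    )


# ---------------------------------------------------------------------------
# Information-flow audit


def _needle_forms(data: bytes) -> List[bytes]:
    return [data, b64e(data).encode("ascii"), data.hex().encode("ascii")]


def privacy_report(sim: Simulation, runs: Sequence[RunResult]) -> List[str]:
    """Scan all ledgers for material each actor must never have held.

    Checks, for every run: MRSE1 holds no pseudonym digest and no EMR
    byte; MRSE2 holds neither the session key (in any encoding) nor any
    digest; the aggregator holds neither digests nor EMR plaintext; and
    each EMR plaintext appears only in its own hospital's ledger and the
    MP's.  Returns a list of human-readable violations (empty = clean).
    """
    violations: List[str] = []
    mrse1, mrse2 = sim.ledgers[MRSE1], sim.ledgers[MRSE2]
    agg = sim.ledgers[AGGREGATOR]

    for run in runs:
        for digest in run.pseudonyms.digests():
            needle = digest.encode("ascii")
            for ledger in (mrse1, mrse2, agg):
                if ledger.contains(needle):
                    violations.append(
                        f"{ledger.actor_id} ledger holds digest {digest[:12]}… (x={run.x})"
                    )
        for form in _needle_forms(run.session_key.key_bytes):
            for ledger in (mrse2, agg):
                if ledger.contains(form):
                    violations.append(
                        f"{ledger.actor_id} ledger holds session key K (x={run.x})"
                    )

    allowed_emr_holders = lambda hs_id: {hs_id, sim.mp_id}  # noqa: E731
    for hs_id, store in sim.stores.items():
        for doc in store.records:
            needle = doc.payload.encode("utf-8")
            if not needle:
                continue
            for actor, ledger in sim.ledgers.items():
                if ledger.contains(needle) and actor not in allowed_emr_holders(hs_id):
                    violations.append(
                        f"{actor} ledger holds EMR plaintext of {doc.record_id}"
                    )
    return violations


def collect_nonces(trace: Sequence[Message], group: str = DEFAULT_GROUP) -> List[bytes]:
    """Extract every symmetric-layer nonce from ciphertexts in a trace.

    Supports the freshness invariant: across one simulation no two
    *distinct* seals share a nonce.  A ciphertext relayed verbatim in
    several messages is one seal and counted once.  ASYM layout is
    ``R || nonce || ct || tag``; SYM is ``nonce || ct || tag``.
    """
    from .crypto import GROUPS, _NONCE_LEN, _element_len  # layout constants

    nonces = []
    seen_blobs = set()
    for msg in trace:
        try:
            obj = from_canonical_json(msg.payload)
        except Exception:
            continue
        stack = [obj]
        while stack:
            node = stack.pop()
            if isinstance(node, dict):
                if "data_b64" in node and "scheme" in node:
                    data = b64d(node["data_b64"])
                    if data in seen_blobs:
                        continue
                    seen_blobs.add(data)
                    if node["scheme"] == "SYM":
                        nonces.append(data[:_NONCE_LEN])
                    else:
                        elen = _element_len(GROUPS[group][0])
                        nonces.append(data[elen : elen + _NONCE_LEN])
                else:
                    stack.extend(node.values())
            elif isinstance(node, list):
                stack.extend(node)
    return nonces
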