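"""The seven-step routine: request splitting, fan-out, matching, aggregation,
finalization — plus the isolation and information-flow invariants."""

from random import Random

import pytest

from mrse_sim._canonical import b64d, from_canonical_json
from mrse_sim.crypto import (
    ChallengeVerifier,
    Ciphertext,
    SessionKey,
    Signature,
    generate_keypair,
    open_sealed,
    sym_open,
)
from mrse_sim.errors import (
    AuthenticationError,
    ConsentError,
    IncompleteBundleError,
    IsolationViolationError,
    JoinFailureError,
)
from mrse_sim.hospital import EMRDocument, HospitalStore, SelectionCriteria
from mrse_sim.identity import IdentityTraits, derive_pseudonym_set
from mrse_sim.linkage import LinkageLevel
from mrse_sim.protocol import (
    AGGREGATOR,
    MRSE1,
    MRSE2,
    Message,
    MessageBus,
    ProtocolConfig,
    ResultRecord,
    Simulation,
    aggregator_collect,
    assert_no_channel,
    collect_nonces,
    hs_handle,
    mp_build_request,
    mp_finalize,
    mrse_forward,
    privacy_report,
)

JEAN = IdentityTraits("Jean", "Dupont", "1970-01-01")


def _doc(hs, first="Jean", last="Dupont", bd="1970-01-01", start="2008-03-01",
         end="2008-03-05", dept="Cardiology", patho="myocardial infarction"):
    return EMRDocument(
        header=IdentityTraits(first, last, bd), hs_id=hs,
        stay_start=start, stay_end=end, department=dept, pathology=patho,
        payload=f"note for {first} {last} at {hs} starting {start}",
    )


def five_hospital_stores():
    """Jean Dupont hospitalized in HS-01 and HS-03 of five; decoys elsewhere."""
    stores = [HospitalStore(hs_id=f"HS-{i:02d}") for i in range(1, 6)]
    stores[0].add_record(_doc("HS-01"))
    stores[0].add_record(_doc("HS-01", first="Marie", last="Curie", bd="1930-11-07"))
    stores[2].add_record(_doc("HS-03", start="2010-07-01", end="2010-07-09", dept="Oncology"))
    stores[3].add_record(_doc("HS-04", first="Paul", last="Martin", bd="1980-04-04"))
    return stores


@pytest.fixture()
def sim():
    return Simulation(five_hospital_stores(), config=ProtocolConfig(seed=23))


# ---------------------------------------------------------------------------
# step 2: request splitting


def test_part1_opens_to_exactly_x_K_ej(sim):
    pset = derive_pseudonym_set(JEAN)
    sealed1, sealed2, K = mp_build_request(
        pset, None, sim.mp_keys, sim.mrse1_keys.public_part,
        sim.mrse2_keys.public_part, x="MP-1-x000001", rng=Random(1),
    )
    part1 = from_canonical_json(open_sealed(sealed1, sim.mrse1_keys.private_part))
    assert set(part1) == {"x", "K_b64", "e_j"}
    assert part1["x"] == "MP-1-x000001"
    assert b64d(part1["K_b64"]) == K.key_bytes
    assert part1["e_j"]["owner_id"] == sim.mp_id

    part2 = from_canonical_json(open_sealed(sealed2, sim.mrse2_keys.private_part))
    assert set(part2) == {"x", "enc_payload"}
    inner = from_canonical_json(
        sym_open(
            Ciphertext(b64d(part2["enc_payload"]["data_b64"]), "SYM"),
            SessionKey(K.key_bytes),
        )
    )
    assert inner["digests"] == pset.digests()


def test_consent_refusal(sim):
    with pytest.raises(ConsentError):
        mp_build_request(
            derive_pseudonym_set(JEAN), None, sim.mp_keys,
            sim.mrse1_keys.public_part, sim.mrse2_keys.public_part,
            x="x1", rng=Random(1), consent=False,
        )


def test_request_number_and_session_key_freshness(sim):
    pset = derive_pseudonym_set(JEAN)
    rng = Random(5)
    keys = set()
    for i in range(1000):
        _, _, K = mp_build_request(
            pset, None, sim.mp_keys, sim.mrse1_keys.public_part,
            sim.mrse2_keys.public_part, x=f"x{i}", rng=rng,
        )
        keys.add(K.key_bytes)
    assert len(keys) == 1000


# ---------------------------------------------------------------------------
# step 3: fan-out and isolation


def test_mrse_fanout_and_ledger_contents(sim):
    pset = derive_pseudonym_set(JEAN)
    rng = Random(2)
    sealed1, sealed2, K = mp_build_request(
        pset, None, sim.mp_keys, sim.mrse1_keys.public_part,
        sim.mrse2_keys.public_part, x="x9", rng=rng,
    )
    msgs1 = mrse_forward(MRSE1, sealed1, sim.directory, sim.mrse1_keys,
                         sim.bus, rng=rng, ledger=sim.ledgers[MRSE1])
    msgs2 = mrse_forward(MRSE2, sealed2, sim.directory, sim.mrse2_keys,
                         sim.bus, rng=rng, ledger=sim.ledgers[MRSE2])
    assert len(msgs1) == len(msgs2) == 5  # one per directory hospital

    ledger1, ledger2 = sim.ledgers[MRSE1], sim.ledgers[MRSE2]
    # MRSE1 saw K and e_j but never a digest
    assert ledger1.contains(__import__("base64").b64encode(K.key_bytes))
    for digest in pset.digests():
        assert not ledger1.contains(digest.encode())
        assert not ledger2.contains(digest.encode())
    # MRSE2 never saw K in any encoding
    for form in (K.key_bytes, K.key_bytes.hex().encode()):
        assert not ledger2.contains(form)


def test_honest_bus_refuses_mrse_channel():
    bus = MessageBus(honest=True)
    with pytest.raises(IsolationViolationError):
        bus.send(Message(sender=MRSE1, recipient=MRSE2, step="leak", payload=b"x"))
    assert bus.trace == []


def test_assert_no_channel_flags_adversarial_trace():
    bus = MessageBus(honest=False)
    bus.send(Message(sender="MP-1", recipient=MRSE1, step="ok", payload=b""))
    assert assert_no_channel(bus)
    leak = bus.send(Message(sender=MRSE2, recipient=MRSE1, step="leak", payload=b""))
    with pytest.raises(IsolationViolationError) as err:
        assert_no_channel(bus)
    assert err.value.offending is leak


# ---------------------------------------------------------------------------
# steps 4-5: hospital handling


def _fanout(sim, traits=JEAN, criteria=None, x="x1"):
    pset = derive_pseudonym_set(traits)
    rng = Random(11)
    sealed1, sealed2, _ = mp_build_request(
        pset, criteria, sim.mp_keys, sim.mrse1_keys.public_part,
        sim.mrse2_keys.public_part, x=x, rng=rng,
    )
    msgs1 = mrse_forward(MRSE1, sealed1, sim.directory, sim.mrse1_keys, sim.bus, rng=rng)
    msgs2 = mrse_forward(MRSE2, sealed2, sim.directory, sim.mrse2_keys, sim.bus, rng=rng)
    return pset, {m.recipient: m for m in msgs1}, {m.recipient: m for m in msgs2}, rng


def test_hs_with_match_returns_that_emr(sim):
    _, by1, by2, rng = _fanout(sim)
    store = sim.stores["HS-01"]
    records, audit = hs_handle(
        by1["HS-01"], by2["HS-01"], store, sim.hs_keys["HS-01"],
        sim.mrse1_keys.public_part, sim.mrse2_keys.public_part, rng=rng,
    )
    assert audit == []
    assert len(records) == 1 and records[0].substantive
    opened = from_canonical_json(
        open_sealed(records[0].enc_confidential, sim.mp_keys.private_part)
    )
    assert opened["emr"] == store.records[0].to_dict()


def test_hs_without_match_returns_signed_empty_response(sim):
    _, by1, by2, rng = _fanout(sim)
    records, _ = hs_handle(
        by1["HS-02"], by2["HS-02"], sim.stores["HS-02"], sim.hs_keys["HS-02"],
        sim.mrse1_keys.public_part, sim.mrse2_keys.public_part, rng=rng,
    )
    assert len(records) == 1 and not records[0].substantive
    from mrse_sim.crypto import verify_signature
    assert verify_signature(
        records[0].signed_payload(), records[0].signature,
        sim.hs_keys["HS-02"].public_part,
    )


def test_criteria_period_excludes_despite_digest_match(sim):
    crit = SelectionCriteria(period=("1999-01-01", "1999-12-31"))
    _, by1, by2, rng = _fanout(sim, criteria=crit)
    records, _ = hs_handle(
        by1["HS-01"], by2["HS-01"], sim.stores["HS-01"], sim.hs_keys["HS-01"],
        sim.mrse1_keys.public_part, sim.mrse2_keys.public_part, rng=rng,
    )
    assert len(records) == 1 and not records[0].substantive


def test_x_mismatch_is_a_join_failure(sim):
    _, by1a, _, rng = _fanout(sim, x="xA")
    _, _, by2b, _ = _fanout(sim, x="xB")
    with pytest.raises(JoinFailureError):
        hs_handle(
            by1a["HS-01"], by2b["HS-01"], sim.stores["HS-01"], sim.hs_keys["HS-01"],
            sim.mrse1_keys.public_part, sim.mrse2_keys.public_part, rng=rng,
        )


def test_invalid_mrse_signature_rejected_with_audit(sim):
    _, by1, by2, rng = _fanout(sim)
    good = by1["HS-01"]
    forged = Message(
        sender=good.sender, recipient=good.recipient, step=good.step,
        payload=good.payload, signature=Signature(data=b"junk", signer_id=MRSE1),
    )
    records, audit = hs_handle(
        forged, by2["HS-01"], sim.stores["HS-01"], sim.hs_keys["HS-01"],
        sim.mrse1_keys.public_part, sim.mrse2_keys.public_part, rng=rng,
    )
    assert records == [] and len(audit) == 1


# ---------------------------------------------------------------------------
# step 6: aggregation


def _bundle_fixture(sim):
    run = sim.run_request(JEAN)
    return run


def test_bundle_groups_substantive_and_empty(sim):
    run = _bundle_fixture(sim)
    subs = [r for r in run.bundle.records if r.substantive]
    empties = [r for r in run.bundle.records if not r.substantive]
    assert len(subs) == 2 and len(empties) == 3
    assert all(r.x == run.x for r in run.bundle.records)
    assert run.bundle.responding_hs == [f"HS-{i:02d}" for i in range(1, 6)]


def test_mixed_x_records_flagged_not_included(sim):
    run = _bundle_fixture(sim)
    stray = ResultRecord(
        x="other-x", enc_confidential=run.bundle.records[0].enc_confidential,
        hs_id="HS-01", signature=run.bundle.records[0].signature, substantive=True,
    )
    verifier = ChallengeVerifier(trusted={sim.mp_id: sim.mp_keys.public_part}, rng=Random(4))
    bundle = aggregator_collect(
        list(run.bundle.records) + [stray], run.x, sim.directory, sim.mp_keys,
        verifier, MessageBus(), sim.mp_id,
    )
    assert stray not in bundle.records and bundle.mismatched == [stray]


def test_missing_hospital_response_is_incomplete(sim):
    run = _bundle_fixture(sim)
    partial = [r for r in run.bundle.records if r.hs_id != "HS-05"]
    verifier = ChallengeVerifier(trusted={sim.mp_id: sim.mp_keys.public_part}, rng=Random(4))
    with pytest.raises(IncompleteBundleError) as err:
        aggregator_collect(
            partial, run.x, sim.directory, sim.mp_keys, verifier, MessageBus(), sim.mp_id
        )
    assert err.value.absentees == ["HS-05"]


def test_mp_with_wrong_key_refused(sim):
    run = _bundle_fixture(sim)
    impostor = generate_keypair(sim.mp_id, rng_seed=999)
    verifier = ChallengeVerifier(trusted={sim.mp_id: sim.mp_keys.public_part}, rng=Random(4))
    with pytest.raises(AuthenticationError):
        aggregator_collect(
            run.bundle.records, run.x, sim.directory, impostor,
            verifier, MessageBus(), sim.mp_id,
        )


# ---------------------------------------------------------------------------
# step 7: finalization


def _flip_bit(data: bytes, bit: int = 0) -> bytes:
    return bytes([data[0] ^ (1 << bit)]) + data[1:]


def test_untampered_bundle_yields_all_emrs(sim):
    run = _bundle_fixture(sim)
    assert len(run.results) == 2
    assert {r.hs_id for r in run.results} == {"HS-01", "HS-03"}
    assert all(r.level is LinkageLevel.HIGH for r in run.results)


def test_bitflipped_ciphertext_rejected_others_delivered(sim):
    run = _bundle_fixture(sim)
    records = list(run.bundle.records)
    victim = next(i for i, r in enumerate(records) if r.substantive)
    r = records[victim]
    records[victim] = ResultRecord(
        x=r.x,
        enc_confidential=Ciphertext(
            _flip_bit(r.enc_confidential.data), r.enc_confidential.scheme_tag,
            r.enc_confidential.recipient_hint,
        ),
        hs_id=r.hs_id, signature=r.signature, substantive=r.substantive,
    )
    run.bundle.records = records
    results, audit = mp_finalize(run.bundle, sim.mp_keys, run.pseudonyms, sim.directory)
    assert len(results) == 1 and len(audit) == 1


def test_record_signed_by_unknown_key_rejected(sim):
    run = _bundle_fixture(sim)
    rogue_keys = generate_keypair("HS-99", rng_seed=77)
    r = run.bundle.records[0]
    rogue = ResultRecord(
        x=r.x, enc_confidential=r.enc_confidential, hs_id="HS-99",
        signature=r.signature, substantive=True,
    )
    run.bundle.records = list(run.bundle.records) + [rogue]
    results, audit = mp_finalize(run.bundle, sim.mp_keys, run.pseudonyms, sim.directory)
    assert any("unknown hospital" in a for a in audit)
    assert len(results) == 2
    del rogue_keys


# ---------------------------------------------------------------------------
# end-to-end


def test_end_to_end_returns_exactly_ground_truth(sim):
    run = sim.run_request(JEAN)
    returned = {(r.hs_id, r.emr.stay_start) for r in run.results}
    assert returned == {("HS-01", "2008-03-01"), ("HS-03", "2010-07-01")}


def test_unknown_patient_empty_result_five_empty_responses(sim):
    run = sim.run_request(IdentityTraits("Zéphyrine", "Absente", "1999-12-31"))
    assert run.results == []
    assert len(run.bundle.records) == 5
    assert not any(r.substantive for r in run.bundle.records)


def test_same_seed_byte_identical_traces():
    runs = []
    for _ in range(2):
        s = Simulation(five_hospital_stores(), config=ProtocolConfig(seed=23))
        r = s.run_request(JEAN)
        runs.append((s.bus.trace_jsonl(r.trace), [x.to_dict() for x in r.results]))
    assert runs[0][0] == runs[1][0]
    assert runs[0][1] == runs[1][1]


def test_x_unique_and_nonces_fresh_across_simulation(sim):
    xs = [sim.run_request(JEAN).x for _ in range(5)]
    assert len(set(xs)) == 5
    nonces = collect_nonces(sim.bus.trace)
    assert len(nonces) == len(set(nonces)) and nonces
    assert len(set(sim.session_keys)) == len(sim.session_keys) == 5


def test_privacy_ledgers_clean_after_runs(sim):
    runs = [sim.run_request(JEAN), sim.run_request(IdentityTraits("Paul", "Martin", "1980-04-04"))]
    assert privacy_report(sim, runs) == []
    assert assert_no_channel(sim.bus)
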