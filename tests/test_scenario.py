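"""Synthetic worlds: generation, typo injection, ground-truth scoring."""

import math

import edlib
import numpy as np
import pytest

from mrse_sim.errors import UnknownPatientError
from mrse_sim.hospital import SelectionCriteria
from mrse_sim.identity import IdentityTraits, Tier, canonicalize, derive_pseudonym_set
from mrse_sim.linkage import LinkageLevel, RankedResult
from mrse_sim.protocol import ProtocolConfig, Simulation
from mrse_sim.scenario import (
    LinkageMetrics,
    ScenarioConfig,
    World,
    apply_typos,
    evaluate_run,
    generate_world,
    oracle_retrieve,
)


def test_config_validation():
    with pytest.raises(ValueError):
        ScenarioConfig(n_patients=0)
    with pytest.raises(ValueError):
        ScenarioConfig(typo_rate=1.5)
    with pytest.raises(ValueError):
        ScenarioConfig(mean_stays_per_patient=0)


def test_same_seed_identical_worlds():
    cfg = ScenarioConfig(n_patients=30, n_hospitals=3, seed=5)
    assert generate_world(cfg).to_json() == generate_world(cfg).to_json()


def test_zero_typo_headers_canonicalize_to_true_traits():
    world = generate_world(
        ScenarioConfig(n_patients=40, n_hospitals=3, typo_rate=0.0, seed=8)
    )
    traits_by_pid = dict(world.patients)
    for store in world.hospitals:
        for doc in store.records:
            pid = doc.payload.split("patient ")[1].split(" ")[0]
            assert canonicalize(doc.header) == canonicalize(traits_by_pid[pid])


def test_total_records_within_three_sd_of_poisson_mean():
    cfg = ScenarioConfig(n_patients=200, n_hospitals=5, mean_stays_per_patient=1.5, seed=3)
    total = generate_world(cfg).n_records()
    mean = 200 * 1.5
    sd = math.sqrt(mean)  # sum of independent Poissons is Poisson
    assert abs(total - mean) <= 3 * sd


def test_truth_covers_every_record_exactly_once():
    world = generate_world(ScenarioConfig(n_patients=50, n_hospitals=4, seed=9))
    all_truth = [rid for ids in world.truth.values() for rid in ids]
    assert len(all_truth) == len(set(all_truth)) == world.n_records()
    stored = {doc.record_id for h in world.hospitals for doc in h.records}
    assert set(all_truth) == stored


def test_world_json_round_trip(tmp_path):
    world = generate_world(ScenarioConfig(n_patients=10, n_hospitals=2, seed=4))
    loaded = World.from_json(world.to_json())
    assert loaded.to_json() == world.to_json()


# ---------------------------------------------------------------------------
# apply_typos


def test_typo_rate_zero_is_identity():
    rng = np.random.default_rng(0)
    t = IdentityTraits("David Roger", "Smith", "1960-02-02")
    assert apply_typos(t, 0.0, rng) == t


def test_typo_rate_one_changes_every_name_field():
    rng = np.random.default_rng(1)
    for _ in range(200):
        t = IdentityTraits("Hélène", "Durand-Martin", "1970-05-06")
        out = apply_typos(t, 1.0, rng)
        assert out.first_name_raw != t.first_name_raw
        assert out.last_name_raw != t.last_name_raw


def test_single_edits_have_small_edit_distance():
    # single-token names exclude token drops, so one edit is Levenshtein <= 2
    rng = np.random.default_rng(2)
    for _ in range(300):
        out = apply_typos(IdentityTraits("SMITH", "ROBERT", "1980-01-01"), 1.0, rng)
        for a, b in ((out.first_name_raw, "SMITH"), (out.last_name_raw, "ROBERT")):
            dist = edlib.align(a.upper(), b)["editDistance"]
            assert 1 <= dist <= 2


def test_date_perturbation_swaps_day_month():
    rng = np.random.default_rng(3)
    seen_dates = set()
    for _ in range(400):
        out = apply_typos(IdentityTraits("Jean", "Dupont", "1970-03-07"), 1.0, rng)
        seen_dates.add(str(out.birth_date))
    assert seen_dates == {"1970-03-07", "1970-07-03"}  # swap at rate/2, else untouched


# ---------------------------------------------------------------------------
# scoring


def _fake_results(world, record_ids):
    docs = {doc.record_id: doc for h in world.hospitals for doc in h.records}
    from mrse_sim.identity import IdentityBasis

    return [
        RankedResult(
            emr=docs[rid], hs_id=docs[rid].hs_id, level=LinkageLevel.HIGH,
            matched_basis=IdentityBasis("A", "B", "1970-01-01", Tier.FULL),
        )
        for rid in record_ids
    ]


@pytest.fixture(scope="module")
def world():
    return generate_world(
        ScenarioConfig(n_patients=30, n_hospitals=3, typo_rate=0.0, p_twin_identity=0.0, seed=12)
    )


def test_exact_truth_scores_perfect(world):
    pid = next(p for p, _ in world.patients if world.truth[p])
    m = evaluate_run(world, pid, _fake_results(world, world.truth[pid]))
    assert m == LinkageMetrics(recall=1.0, precision=1.0, doubloon_count=0, collision_count=0)


def test_missed_record_is_a_doubloon(world):
    pid = next(p for p, _ in world.patients if len(world.truth[p]) == 2)
    partial = sorted(world.truth[pid])[:1]
    m = evaluate_run(world, pid, _fake_results(world, partial))
    assert m.recall == 0.5 and m.doubloon_count == 1 and m.precision == 1.0


def test_foreign_record_is_a_collision(world):
    pid = next(p for p, _ in world.patients if len(world.truth[p]) == 2)
    other = next(
        rid for p, ids in world.truth.items() if p != pid for rid in ids
        if rid not in world.truth[pid]
    )
    returned = sorted(world.truth[pid]) + [other]
    m = evaluate_run(world, pid, _fake_results(world, returned))
    assert m.collision_count == 1 and m.precision == pytest.approx(2 / 3)
    assert m.recall == 1.0


def test_empty_truth_empty_return_scores_one(world):
    pid = next(p for p, _ in world.patients if not world.truth[p])
    m = evaluate_run(world, pid, [])
    assert m.recall == 1.0 and m.precision == 1.0


def test_unknown_patient_errors(world):
    with pytest.raises(UnknownPatientError):
        evaluate_run(world, "P9999", [])


# ---------------------------------------------------------------------------
# end-to-end properties on synthetic worlds


def test_zero_noise_perfect_linkage_all_patients(world):
    sim = Simulation(world.hospitals, config=ProtocolConfig(seed=99))
    for pid, traits in world.patients:
        run = sim.run_request(traits)
        m = evaluate_run(world, pid, run.results)
        assert m.recall == 1.0 and m.precision == 1.0, pid
        returned = {r.emr.record_id for r in run.results}
        assert returned == oracle_retrieve(world, traits)
        assert all(r.level is LinkageLevel.HIGH for r in run.results)


def test_oracle_respects_criteria(world):
    pid, traits = next(
        (p, t) for p, t in world.patients if len(world.truth[p]) >= 2
    )
    docs = {doc.record_id: doc for h in world.hospitals for doc in h.records}
    one = sorted(world.truth[pid])[0]
    crit = SelectionCriteria(hospitals=(docs[one].hs_id,))
    subset = oracle_retrieve(world, traits, crit)
    assert subset <= oracle_retrieve(world, traits)
    assert all(docs[rid].hs_id == docs[one].hs_id for rid in subset)


def test_token_bases_never_lower_recall_versus_full_only(world):
    # searching with the full pseudonym list can only add hits over the
    # FULL-tier digest alone
    for store in world.hospitals:
        store.build_index(include_phonetic=False)
    for pid, traits in world.patients[:10]:
        pset = derive_pseudonym_set(traits, include_phonetic=False)
        full_only = [p.digest for p in pset if p.basis.tier is Tier.FULL]
        for store in world.hospitals:
            with_tokens = {h.record.record_id for h in store.search_by_digest(pset.digests())}
            full_hits = {h.record.record_id for h in store.search_by_digest(full_only)}
            assert full_hits <= with_tokens


def test_twin_identities_necessarily_collide():
    # two distinct patients with byte-identical traits cannot be told apart
    # by any purely identity-based scheme; the protocol returns both
    cfg = ScenarioConfig(n_patients=2, n_hospitals=2, mean_stays_per_patient=2.0,
                         typo_rate=0.0, p_twin_identity=1.0, seed=21)
    world = generate_world(cfg)
    assert world.patients[0][1] == world.patients[1][1]
    assert world.truth["P0000"] and world.truth["P0001"]
    sim = Simulation(world.hospitals, config=ProtocolConfig(seed=5))
    run = sim.run_request(world.patients[0][1])
    m = evaluate_run(world, "P0000", run.results)
    assert m.collision_count == len(world.truth["P0001"]) > 0
    assert m.recall == 1.0  # own records are all there — the failure is purity
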