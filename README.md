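# mrse-sim

A simulator for **on-demand, privacy-preserving retrieval of scattered
medical records**. A patient's history is typically spread over the
electronic medical records (EMRs) of several hospitals, each stored "as
is" with no shared identifier beyond the universal identity header —
first name(s), last name(s), date of birth. `mrse-sim` implements, as
fully testable code, a split-trust protocol by which a medical
practitioner (MP) can gather all of a patient's records without any
intermediary ever learning who the patient is or what the records say.

It is aimed at health-informatics researchers who want to study the
behaviour of such an architecture — its completeness, its record-linkage
error modes (missed links and wrong links), and its information-flow
guarantees — on synthetic hospital populations with controllable name
structure and typo noise.

## The protocol

Identity never travels in clear. The MP derives a list of **hashed
partial patient identities** H(PI): every combination of first-name
tokens, last-name tokens (and their joined forms), each paired with the
birth date, is hashed with SHA-256; an optional phonetic tier adds
Soundex-coded variants. A request numbered *x* is then split between two
**Medical Record Search Engines** that are forbidden to communicate:

- MRSE1 receives `{x, K, e_j}` — a fresh session key K and the MP's
  public key — but no pseudonym material;
- MRSE2 receives `{x, E_K(H(PI) list + selection criteria)}` — the
  digests encrypted under K, which MRSE2 does not hold.

Each MRSE re-seals its half to every hospital in a directory and signs
it. Only a hospital, holding both halves, recovers the digest list,
matches it against the hashed identities of its own patients, applies
the selection criteria (period, department, pathology, …), and returns a
signed record whose confidential part — matched digest and the EMR — is
sealed to the MP key `e_j`. An aggregator groups all answers for *x*
and releases them after challenge-response authentication of the MP,
who verifies every hospital signature, decrypts, and sees each record
tagged with a **linkage level** for validation: HIGH (full identity
matched, or two distinct token combinations corroborate), MEDIUM (one
token combination), LOW (phonetic only).

Every actor keeps an append-only **observation ledger** of each
plaintext it ever held, and all messages cross an instrumented bus.
Privacy is therefore not an argument but an assertion: after any run
the ledgers are scanned for material each actor must never have seen,
and the trace for any MRSE1↔MRSE2 edge.

Synthetic worlds provide ground truth by construction, so runs are
scored exactly for *doubloons* (missed records, recall loss) and
*collisions* (foreign records, precision loss).

## Worked example

```bash
cat > scenario.yaml <<EOF
n_patients: 12
n_hospitals: 3
typo_rate: 0.0
p_twin_identity: 0.0
seed: 6
EOF
mrse-sim gen-world --config scenario.yaml --out world.json
mrse-sim run --world world.json --patient P0003 --seed 3 --out results.json
```

prints

```
world: 3 hospitals, 12 patients, 25 records -> world.json
request MP-1-x000001: 1 record(s)
[
  {
    "emr": { "first_name": "Agnès", "last_name": "Laurent",
             "birth_date": "1966-08-22", "hs_id": "HS-03",
             "stay_start": "2010-06-03", "stay_end": "2010-06-11",
             "department": "Gastroenterology", "...": "..." },
    "hs_id": "HS-03",
    "level": "HIGH",
    "matched_basis": { "first_part": "AGNES", "last_part": "LAURENT",
                       "birth_date": "1966-08-22", "tier": "FULL" },
    "matched_digest": "70e0bca3e276dbdd885eec04b2448cd92aa438bc..."
  }
]
```

Patient P0003's single record was found at hospital HS-03 because the
FULL-tier digest (joined names + birth date) matched, hence linkage
level HIGH; the practitioner also sees *which* identity combination
made the link. `results.json` additionally carries recall/precision
against the world's ground truth (here both 1.0), and the message trace
can be audited:

```bash
mrse-sim audit --trace results.trace.jsonl
# trace clean: 18 messages, no MRSE1<->MRSE2 edge, 11 fresh nonces
```

The same is available as a library:

```python
from mrse_sim import Simulation, ProtocolConfig, IdentityTraits
from mrse_sim.scenario import ScenarioConfig, generate_world, evaluate_run

world = generate_world(ScenarioConfig(seed=6))
sim = Simulation(world.hospitals, config=ProtocolConfig(seed=3))
run = sim.run_request(IdentityTraits("David Roger", "Smith", "1960-02-02"))
for r in run.results:
    print(r.hs_id, r.level.name, r.matched_basis.tier.value)
```

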