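# Methods

This note records the model the simulator implements, the choices made
where the design was genuinely open, the defaults and why, and what the
synthetic experiments do and do not show.

## Protocol model and assumptions

The simulator realizes a seven-stage routine: (1) pseudonymization of
the patient identity, (2) splitting the request between two relays,
(3) signed fan-out to all hospitals in a directory, (4) hospital-side
hashed matching, (5) signed results sealed to the practitioner,
(6) aggregation with challenge-response release, and (7)
practitioner-side verification, decryption and linkage levelling.

Assumptions baked into the model:

- **Honest-but-curious intermediaries.** The relays (MRSE1/MRSE2) and
  the aggregator follow the protocol but may inspect anything they can
  read. The privacy goal is that what they can read is useless: MRSE1
  holds a session key but no pseudonym; MRSE2 holds encrypted
  pseudonyms but no key; the aggregator holds sealed records only.
  Active network adversaries appear only as bit-flip tampering of
  result records, which signature verification must catch.
- **The only universal structure in an EMR is the identity header**
  (first name(s), last name(s), birth date) plus a thin metadata
  envelope (stay interval, department, pathology) for the
  selection-criteria tool. The clinical payload is opaque and is never
  parsed by any protocol component.
- **Transport is an in-process message bus** with a global trace. The
  architectural rule that the two relays cannot communicate is
  enforced twice: the bus refuses MRSE1↔MRSE2 sends in honest mode,
  and `assert_no_channel` independently audits completed traces (an
  adversarial bus mode exists so the audit itself can be tested).
  Real networking, timeouts and quorums are out of scope; aggregation
  is synchronous and every hospital answers, possibly with a signed
  empty-response record so "no match" is distinguishable from "no
  reply".

Open points resolved as package design choices:

- The stage list is longer than the six headed message exchanges; the
  final stage is taken to be practitioner-side verification and
  decryption (`mp_finalize`).
- Challenge-response at delivery: the aggregator challenges the
  practitioner (it must not release records to a key it does not
  trust). The relays likewise challenge the practitioner at request
  time.
- Selection criteria travel inside the session-key-encrypted payload:
  a pathology name is itself confidential, so only hospitals may read
  it.
- The practitioner's public key `e_j` reaches hospitals through
  MRSE1's half, which is where it already rides; hospitals need it to
  seal results.
- The matched digest (and the list of all digests that hit the record)
  is carried *inside* the sealed confidential part, so linkage levels
  can be computed by the practitioner without the aggregator learning
  anything. Computing levels at the aggregator would be impossible
  anyway — it cannot read the matched digest — so the levelling is
  practitioner-side by construction.

## Identity pseudonymization

Canonicalization is fixed: uppercase, diacritics folded to base
letters (NFKD), hyphens and apostrophes treated as token separators,
whitespace collapsed, token order preserved; birth dates are strict
ISO-8601 (no partial dates). The hash is SHA-256 over the positional
serialization `FIRST|LAST|DATE|TIER`, giving the 64-hex digests used
for matching everywhere. The hash is **unkeyed by default**: the
protocol's defence against dictionary attacks on identities in transit
is that digests travel encrypted, not that the hash is secret. A keyed
mode (HMAC-SHA256 under a secret shared by practitioners and
hospitals) is available for deployments that also want stored digests
to resist dictionary attacks.

Partial identifiers: with `f` first-name tokens and `l` last-name
tokens, the non-phonetic bases are the product of the tokens plus the
joined form on each side — `(f + 1{f>1})·(l + 1{l>1})` bases, exactly
one of which (joined × joined) is the FULL tier. The phonetic tier
re-encodes each basis's name parts with classic 4-character American
Soundex; the encoder is a module-level hook and can be swapped for any
other scheme. Tier order FULL > TOKEN > PHONETIC is fixed so that
best-tier annotation and linkage levels are deterministic. Phonetic
variants of the *birth date* (day/month swaps) are not enumerated; a
date typo therefore defeats all tiers, which the noise experiments
reflect.

## Cryptographic envelope

The protocol needs contracts, not a particular cipher suite:

- **Sealing** is hybrid: ephemeral Diffie-Hellman over a safe-prime
  MODP group (generator 4, prime-order subgroup) derives a one-off
  key for an authenticated symmetric layer. Raw asymmetric encryption
  of whole EMRs is impractical, so the hybrid construction is used
  wherever the protocol says "encrypted with X's public key".
- **Symmetric encryption** is a SHA-256-keystream stream cipher with
  an HMAC-SHA256 tag (encrypt-then-MAC), 24-byte nonce per sealing.
  Decryption is authenticated everywhere: tampered input raises, and
  no code path ever returns unauthenticated plaintext.
- **Signatures** are Schnorr in the same subgroup, with the
  per-message secret derived deterministically (HMAC of key and
  message), so signing is a pure function and traces reproduce
  byte-for-byte under a fixed seed.
- **Challenge-response** is nonce-sign-verify with single-use nonces;
  replaying a transcript fails.

The default group is the 1024-bit Oakley group 2, a deliberate
simulation-scale choice: a multi-hospital request costs on the order of
a hundred modular exponentiations, and the smaller modulus keeps
thousand-run experiments cheap. The 2048-bit RFC 3526 group is
selectable per keypair/config. Key generation draws from a seeded PRNG
in test mode and from OS entropy otherwise. None of this is intended
to protect real data; the implementation exists so the *contracts*
(round trips, authenticated failure, replay rejection, freshness) are
testable properties of the simulator.

## Linkage levels

The level rule is deterministic: FULL → HIGH; TOKEN → MEDIUM, promoted
to HIGH when at least two distinct token bases corroborate the same
record; PHONETIC → LOW. A probabilistic scorer calibrated on observed
match frequencies would slot into the same signature, but no observed
data exists to fit one, so the tier rule stands. Ranking is a stable
sort by level, hospital id, stay start — a permutation of its input.
Patient-assisted validation is represented only as a boolean annotation
field on results.

## Synthetic worlds

The generator emulates the phenomena that stress identity-based
linkage: multi-hospital patients, double first names, two-part married
or hyphenated last names, accented Latin-script names, per-field
typos, and occasional exact homonyms. Defaults — the study conditions
for all experiments — are 200 patients, 5 hospitals, Poisson(1.5)
stays per patient assigned uniformly, 10% double first names, 15%
double last names, 2% per-field typo rate (dates perturbed at half
that rate by day/month swap), 0.5% homonyms. No real population
underlies these figures; they are fixed documented constants chosen so
every tier and both error modes are exercised. Typos are single edits
(substitution, transposition, deletion, or whole-token drop for
multi-token names) applied to the raw strings.

What the worlds do **not** model: real name-frequency distributions,
non-Latin scripts, record-level missingness, date formats other than
ISO, and any calibrated estimate of how many patients attend many
hospitals. Perfect recall at zero noise therefore shows the protocol
machinery is lossless, not that real-world linkage would be; the
phonetic-benefit experiment shows the *direction* and rough size of
the tier's effect under the chosen noise model only.

## Numerical and procedural choices

- All inter-actor payloads are canonical JSON (sorted keys, compact
  separators), so "same seed ⇒ byte-identical trace" is well defined.
- Request numbers are a per-practitioner monotone counter under a
  seed, UUIDs otherwise; session keys and nonces come from the run's
  RNG; nonce freshness is audited per distinct seal (a ciphertext
  relayed verbatim counts once).
- Hospitals match pseudonyms first and then apply criteria as a
  conjunctive refinement (interval overlap for periods,
  case-insensitive substring for text); an inverted or unparsable
  period is an error, not an empty filter.
- A record hit by several digests is annotated with its best tier;
  ties inside a tier break lexicographically on the digest.
- Records whose header cannot be canonicalized are skipped at indexing
  with an audit entry rather than failing the store.
- Experiment sizes in the test suite and acceptance script (e.g. 100
  privacy runs on 10-patient/3-hospital worlds; 20 paired worlds of 25
  patients for the phonetic comparison) are the package's chosen
  simulation scales: large enough for the properties to be
  non-trivial, small enough to re-run routinely.

## Known limitations

- Exact homonyms collide by construction; no purely identity-based
  scheme can separate them. The simulator asserts this expected
  failure and leaves resolution to practitioner/patient validation.
- A birth-date typo defeats every pseudonym tier (no phonetic tier for
  dates).
- The bus is in-process; nothing is learned here about latency,
  partial failure, or a malicious (as opposed to curious) relay that
  forges its own fan-out.
- Ledger auditing detects plaintext *possession*, not inference; e.g.
  traffic-analysis side channels are out of scope.
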