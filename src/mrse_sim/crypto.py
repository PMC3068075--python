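"""Cryptographic envelope: sealing, session encryption, signatures, auth.

The protocol needs four contracts:

* **Asymmetric sealing** (``seal`` / ``open_sealed``): anyone holding an
  actor's public key can address bytes to it; only the private key opens
  them, and tampering is detected.  Implemented as a hybrid
  ElGamal/IES-style scheme over a multiplicative-group Diffie-Hellman
  exchange: an ephemeral exponent yields a shared secret with the static
  public key, from which a symmetric key is derived for the payload.
* **Symmetric session encryption** (``sym_seal`` / ``sym_open``): the
  per-request session key K.  A stream cipher keyed by SHA-256 with an
  HMAC-SHA256 tag (encrypt-then-MAC); fresh 24-byte nonce per sealing.
* **Digital signatures** (``sign_message`` / ``verify_signature``):
  Schnorr signatures in the prime-order subgroup, with the per-message
  secret derived deterministically from key and message so that signing
  is a pure function (traces are reproducible under a fixed seed).
* **Challenge-response authentication**: a verifier issues a fresh nonce
  and accepts exactly one signature over it; replays are refused.

Groups are the well-known MODP groups (safe primes); the subgroup
generator is ``4`` so all arithmetic happens in the prime-order-``q``
subgroup of quadratic residues.  The default 1024-bit group keeps a
simulated multi-hospital exchange cheap; the 2048-bit group is available
through :func:`generate_keypair`'s ``group`` argument for callers who
want contemporary key sizes.

Nothing here is a vetted production library and none of it should guard
real patient data; the point is faithful, testable *contracts* (round
trips, authenticated failure, replay rejection) inside the simulator.
"""

from __future__ import annotations

import hashlib
import hmac
import secrets
from dataclasses import dataclass, field
from random import Random
from typing import Optional, Union

from ._canonical import b64d, b64e, canonical_json, from_canonical_json
from .errors import AuthenticationError, ConfigurationError, DecryptionError

__all__ = [
    "KeyPair",
    "PublicKey",
    "PrivateKey",
    "SessionKey",
    "Ciphertext",
    "Signature",
    "ChallengeVerifier",
    "generate_keypair",
    "seal",
    "open_sealed",
    "sym_seal",
    "sym_open",
    "new_session_key",
    "sign_message",
    "verify_signature",
    "run_challenge_response",
    "public_key_to_pem",
    "public_key_from_pem",
    "private_key_to_pem",
    "private_key_from_pem",
    "GROUPS",
    "DEFAULT_GROUP",
]

# ---------------------------------------------------------------------------
# Groups: safe primes p = 2q + 1; generator 4 = 2^2 has order q.
# modp1024 is the Oakley group 2 prime, modp2048 the RFC 3526 group 14 prime.

_P_1024 = int(
    "FFFFFFFFFFFFFFFFC90FDAA22168C234C4C6628B80DC1CD129024E088A67CC74"
    "020BBEA63B139B22514A08798E3404DDEF9519B3CD3A431B302B0A6DF25F1437"
    "4FE1356D6D51C245E485B576625E7EC6F44C42E9A63A3620FFFFFFFFFFFFFFFF",
    16,
)
_P_2048 = int(
    "FFFFFFFFFFFFFFFFC90FDAA22168C234C4C6628B80DC1CD129024E088A67CC74"
    "020BBEA63B139B22514A08798E3404DDEF9519B3CD3A431B302B0A6DF25F1437"
    "4FE1356D6D51C245E485B576625E7EC6F44C42E9A637ED6B0BFF5CB6F406B7ED"
    "EE386BFB5A899FA5AE9F24117C4B1FE649286651ECE45B3DC2007CB8A163BF05"
    "98DA48361C55D39A69163FA8FD24CF5F83655D23DCA3AD961C62F356208552BB"
    "9ED529077096966D670C354E4ABC9804F1746C08CA18217C32905E462E36CE3B"
    "E39E772C180E86039B2783A2EC07A28FB5C55DF06F4C52C9DE2BCBF695581718"
    "3995497CEA956AE515D2261898FA051015728E5A8AACAA68FFFFFFFFFFFFFFFF",
    16,
)

#: group name -> (modulus p, subgroup generator g, subgroup order q)
GROUPS = {
    "modp1024": (_P_1024, 4, (_P_1024 - 1) // 2),
    "modp2048": (_P_2048, 4, (_P_2048 - 1) // 2),
}

DEFAULT_GROUP = "modp1024"

_NONCE_LEN = 24
_TAG_LEN = 32


def _group(name: str):
    try:
        return GROUPS[name]
    except KeyError:
        raise ConfigurationError(f"unknown DH group {name!r}") from None


def _int_to_bytes(n: int, length: int) -> bytes:
    return n.to_bytes(length, "big")


def _element_len(p: int) -> int:
    return (p.bit_length() + 7) // 8


# ---------------------------------------------------------------------------
# Key material


@dataclass(frozen=True)
class PublicKey:
    """Static public key: group element y = g^x mod p."""

    y: int
    owner_id: str
    group: str = DEFAULT_GROUP


@dataclass(frozen=True)
class PrivateKey:
    """Static private exponent x in [1, q)."""

    x: int
    owner_id: str
    group: str = DEFAULT_GROUP


@dataclass(frozen=True)
class KeyPair:
    public_part: PublicKey
    private_part: PrivateKey
    owner_id: str


@dataclass(frozen=True)
class SessionKey:
    """Fresh symmetric key serving exactly one request."""

    key_bytes: bytes
    request_number: str = ""


@dataclass(frozen=True)
class Ciphertext:
    data: bytes
    scheme_tag: str  # "ASYM" or "SYM"
    recipient_hint: str = ""


@dataclass(frozen=True)
class Signature:
    data: bytes
    signer_id: str


def generate_keypair(
    owner_id: str,
    rng_seed: Optional[int] = None,
    rng: Optional[Random] = None,
    group: str = DEFAULT_GROUP,
) -> KeyPair:
    """Generate a static keypair for *owner_id*.

    With ``rng_seed`` or ``rng`` the private exponent is drawn from a
    seeded PRNG (test/simulation mode, reproducible); otherwise from the
    operating system's entropy.
    """
    p, g, q = _group(group)
    if rng is None and rng_seed is not None:
        rng = Random(rng_seed)
    if rng is not None:
        x = rng.randrange(2, q)
    else:
        x = 2 + secrets.randbelow(q - 2)
    y = pow(g, x, p)
    return KeyPair(
        public_part=PublicKey(y=y, owner_id=owner_id, group=group),
        private_part=PrivateKey(x=x, owner_id=owner_id, group=group),
        owner_id=owner_id,
    )


# ---------------------------------------------------------------------------
# Symmetric authenticated encryption (encrypt-then-MAC)


def _derive(key: bytes, label: bytes) -> bytes:
    return hashlib.sha256(key + b"|" + label).digest()


def _keystream_xor(enc_key: bytes, nonce: bytes, data: bytes) -> bytes:
    out = bytearray(len(data))
    for block in range(0, len(data), 32):
        ks = hashlib.sha256(
            enc_key + nonce + (block // 32).to_bytes(8, "big")
        ).digest()
        chunk = data[block : block + 32]
        for i, b in enumerate(chunk):
            out[block + i] = b ^ ks[i]
    return bytes(out)


def _sym_encrypt(key: bytes, plaintext: bytes, nonce: bytes) -> bytes:
    enc_key = _derive(key, b"enc")
    mac_key = _derive(key, b"mac")
    ct = _keystream_xor(enc_key, nonce, plaintext)
    tag = hmac.new(mac_key, nonce + ct, hashlib.sha256).digest()
    return nonce + ct + tag


def _sym_decrypt(key: bytes, blob: bytes) -> bytes:
    if len(blob) < _NONCE_LEN + _TAG_LEN:
        raise DecryptionError("ciphertext too short")
    nonce = blob[:_NONCE_LEN]
    ct = blob[_NONCE_LEN : -_TAG_LEN]
    tag = blob[-_TAG_LEN:]
    mac_key = _derive(key, b"mac")
    expected = hmac.new(mac_key, nonce + ct, hashlib.sha256).digest()
    if not hmac.compare_digest(tag, expected):
        raise DecryptionError("authentication tag mismatch")
    enc_key = _derive(key, b"enc")
    return _keystream_xor(enc_key, nonce, ct)


def _fresh_nonce(rng: Optional[Random]) -> bytes:
    if rng is not None:
        return rng.getrandbits(_NONCE_LEN * 8).to_bytes(_NONCE_LEN, "big")
    return secrets.token_bytes(_NONCE_LEN)


def new_session_key(
    request_number: str = "", rng: Optional[Random] = None
) -> SessionKey:
    """Draw a fresh 256-bit session key K."""
    if rng is not None:
        kb = rng.getrandbits(256).to_bytes(32, "big")
    else:
        kb = secrets.token_bytes(32)
    return SessionKey(key_bytes=kb, request_number=request_number)


def sym_seal(
    plaintext: bytes,
    key: Union[SessionKey, bytes],
    rng: Optional[Random] = None,
    recipient_hint: str = "",
) -> Ciphertext:
    """Encrypt *plaintext* under a session key; fresh nonce per call."""
    kb = key.key_bytes if isinstance(key, SessionKey) else key
    nonce = _fresh_nonce(rng)
    return Ciphertext(
        data=_sym_encrypt(kb, plaintext, nonce),
        scheme_tag="SYM",
        recipient_hint=recipient_hint,
    )


def sym_open(ct: Ciphertext, key: Union[SessionKey, bytes]) -> bytes:
    """Decrypt and authenticate; raises :class:`DecryptionError` on any
    wrong key or modified byte — never returns unauthenticated garbage."""
    if ct.scheme_tag != "SYM":
        raise DecryptionError(f"expected SYM ciphertext, got {ct.scheme_tag}")
    kb = key.key_bytes if isinstance(key, SessionKey) else key
    return _sym_decrypt(kb, ct.data)


# ---------------------------------------------------------------------------
# Asymmetric sealing (hybrid: ephemeral DH + authenticated symmetric layer)


def seal(
    plaintext: bytes, public_key: PublicKey, rng: Optional[Random] = None
) -> Ciphertext:
    """Seal *plaintext* to a public key.

    An ephemeral exponent k gives R = g^k and shared secret S = y^k; the
    payload key is SHA-256(group | R | S).  Layout: R || sym-blob.
    """
    p, g, q = _group(public_key.group)
    elen = _element_len(p)
    if rng is not None:
        k = rng.randrange(2, q)
    else:
        k = 2 + secrets.randbelow(q - 2)
    big_r = pow(g, k, p)
    shared = pow(public_key.y, k, p)
    key = hashlib.sha256(
        public_key.group.encode()
        + _int_to_bytes(big_r, elen)
        + _int_to_bytes(shared, elen)
    ).digest()
    blob = _sym_encrypt(key, plaintext, _fresh_nonce(rng))
    return Ciphertext(
        data=_int_to_bytes(big_r, elen) + blob,
        scheme_tag="ASYM",
        recipient_hint=public_key.owner_id,
    )


def open_sealed(ct: Ciphertext, private_key: PrivateKey) -> bytes:
    """Open a sealed ciphertext with the matching private key."""
    if ct.scheme_tag != "ASYM":
        raise DecryptionError(f"expected ASYM ciphertext, got {ct.scheme_tag}")
    p, _, _ = _group(private_key.group)
    elen = _element_len(p)
    if len(ct.data) < elen + _NONCE_LEN + _TAG_LEN:
        raise DecryptionError("ciphertext too short")
    big_r = int.from_bytes(ct.data[:elen], "big")
    if not 1 < big_r < p:
        raise DecryptionError("ephemeral element out of range")
    shared = pow(big_r, private_key.x, p)
    key = hashlib.sha256(
        private_key.group.encode()
        + _int_to_bytes(big_r, elen)
        + _int_to_bytes(shared, elen)
    ).digest()
    return _sym_decrypt(key, ct.data[elen:])


# ---------------------------------------------------------------------------
# Schnorr signatures


def _hash_to_int(*parts: bytes, q: int) -> int:
    h = hashlib.sha256()
    for part in parts:
        h.update(part)
    return int.from_bytes(h.digest(), "big") % q


def sign_message(message: bytes, private_key: PrivateKey) -> Signature:
    """Schnorr-sign *message*.

    The per-message secret is derived with HMAC from the private key and
    the message (deterministic signing), so equal inputs give equal
    signatures and no signing-time randomness can leak the key.
    """
    p, g, q = _group(private_key.group)
    elen = _element_len(p)
    xb = _int_to_bytes(private_key.x, elen)
    k = (
        int.from_bytes(
            hmac.new(xb, b"schnorr-k|" + message, hashlib.sha512).digest(), "big"
        )
        % (q - 2)
    ) + 1
    r = pow(g, k, p)
    e = _hash_to_int(_int_to_bytes(r, elen), message, q=q)
    s = (k + private_key.x * e) % q
    payload = canonical_json({"r": r, "s": s})
    return Signature(data=payload, signer_id=private_key.owner_id)


def verify_signature(
    message: bytes, sig: Signature, public_key: PublicKey
) -> bool:
    """Check a signature; malformed input returns ``False``, never raises."""
    try:
        p, g, q = _group(public_key.group)
        obj = from_canonical_json(sig.data)
        r, s = int(obj["r"]), int(obj["s"])
        if not (1 < r < p and 0 < s < q):
            return False
        elen = _element_len(p)
        e = _hash_to_int(_int_to_bytes(r, elen), message, q=q)
        return pow(g, s, p) == (r * pow(public_key.y, e, p)) % p
    except Exception:
        return False


# ---------------------------------------------------------------------------
# Challenge-response authentication


@dataclass
class ChallengeVerifier:
    """Verifier side of nonce-based challenge-response.

    Holds the public keys it trusts and a cache of issued nonces; each
    nonce is accepted at most once, so replaying an old transcript fails.
    """

    trusted: dict  # prover id -> PublicKey
    rng: Optional[Random] = None
    _pending: set = field(default_factory=set)
    _spent: set = field(default_factory=set)

    def issue_challenge(self) -> bytes:
        nonce = _fresh_nonce(self.rng)
        self._pending.add(nonce)
        return nonce

    def verify_response(
        self, prover_id: str, nonce: bytes, response: Signature
    ) -> bool:
        if nonce not in self._pending or nonce in self._spent:
            return False
        self._spent.add(nonce)
        self._pending.discard(nonce)
        pub = self.trusted.get(prover_id)
        if pub is None:
            return False
        return verify_signature(b"challenge|" + nonce, response, pub)


def answer_challenge(nonce: bytes, private_key: PrivateKey) -> Signature:
    """Prover side: sign the verifier's fresh nonce."""
    return sign_message(b"challenge|" + nonce, private_key)


def run_challenge_response(
    prover_keys: KeyPair, verifier: ChallengeVerifier
) -> bool:
    """One honest round: verifier challenges, prover signs, verifier checks."""
    nonce = verifier.issue_challenge()
    response = answer_challenge(nonce, prover_keys.private_part)
    return verifier.verify_response(prover_keys.owner_id, nonce, response)


# ---------------------------------------------------------------------------
# PEM-style import/export

def _pem(label: str, payload: bytes) -> str:
    body = b64e(payload)
    lines = [body[i : i + 64] for i in range(0, len(body), 64)]
    return (
        f"-----BEGIN {label}-----\n"
        + "\n".join(lines)
        + f"\n-----END {label}-----\n"
    )


def _unpem(text: str, label: str) -> bytes:
    lines = [
        ln.strip()
        for ln in text.strip().splitlines()
        if ln.strip() and not ln.startswith("-----")
    ]
    if f"BEGIN {label}" not in text:
        raise ConfigurationError(f"not a {label} PEM block")
    return b64d("".join(lines))


def public_key_to_pem(pub: PublicKey) -> str:
    return _pem(
        "MRSE PUBLIC KEY",
        canonical_json({"y": pub.y, "owner_id": pub.owner_id, "group": pub.group}),
    )


def public_key_from_pem(text: str) -> PublicKey:
    obj = from_canonical_json(_unpem(text, "MRSE PUBLIC KEY"))
    return PublicKey(y=int(obj["y"]), owner_id=obj["owner_id"], group=obj["group"])


def private_key_to_pem(priv: PrivateKey) -> str:
    return _pem(
        "MRSE PRIVATE KEY",
        canonical_json({"x": priv.x, "owner_id": priv.owner_id, "group": priv.group}),
    )


def private_key_from_pem(text: str) -> PrivateKey:
    obj = from_canonical_json(_unpem(text, "MRSE PRIVATE KEY"))
    return PrivateKey(x=int(obj["x"]), owner_id=obj["owner_id"], group=obj["group"])
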