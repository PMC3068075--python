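"""Canonical serialization helpers.

All inter-actor payloads are canonical JSON (sorted keys, compact
separators, UTF-8) so that byte-identity of traces under a fixed seed is
well defined, and so signatures bind exactly one encoding of a message.
"""

from __future__ import annotations

import base64
import json
from typing import Any


def canonical_json(obj: Any) -> bytes:
    """Serialize *obj* to canonical JSON bytes (deterministic encoding)."""
    return json.dumps(
        obj, sort_keys=True, separators=(",", ":"), ensure_ascii=True
    ).encode("ascii")


def from_canonical_json(data: bytes) -> Any:
    return json.loads(data.decode("ascii"))


def b64e(data: bytes) -> str:
    return base64.b64encode(data).decode("ascii")


def b64d(text: str) -> bytes:
    return base64.b64decode(text.encode("ascii"))
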