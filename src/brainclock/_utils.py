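"""Small shared helpers (seed fan-out, hashing)."""

from __future__ import annotations

import hashlib


def child_seed(seed: int, name: str) -> int:
    """Derive a stable per-stage seed from a global seed and a stage name.

    Uses SHA-256 of ``"{seed}:{name}"`` truncated to 31 bits so the result is
    always a valid numpy seed and independent stages get decorrelated streams.
    """
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
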