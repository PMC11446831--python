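"""Deterministic seed derivation for pipeline stages."""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(base: int, name: str) -> int:
    """Derive a stage seed < 2**31 deterministically from a global seed and
    a stage name, so stages can be re-run in isolation."""
    digest = hashlib.blake2b(f"{base}:{name}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "little") % (2**31)
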