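"""Deterministic 32-bit hashing for fingerprint identifiers.

Fingerprint bit assignment must be stable across processes and platforms,
so Python's salted ``hash`` is never used. All identifiers are FNV-1a
hashes of a canonical byte serialization of the input tuple.
"""

from __future__ import annotations

_FNV_OFFSET = 0x811C9DC5
_FNV_PRIME = 0x01000193
_MASK32 = 0xFFFFFFFF


def fnv1a(data: bytes) -> int:
    """32-bit FNV-1a hash of ``data``."""
    h = _FNV_OFFSET
    for byte in data:
        h ^= byte
        h = (h * _FNV_PRIME) & _MASK32
    return h


def _serialize(obj) -> bytes:
    """Canonical byte serialization of nested tuples of ints/strs/bools."""
    if isinstance(obj, bool):
        return b"b" + (b"1" if obj else b"0")
    if isinstance(obj, int):
        return b"i" + str(obj).encode()
    if isinstance(obj, str):
        return b"s" + obj.encode()
    if isinstance(obj, (tuple, list)):
        parts = b"".join(_serialize(x) + b";" for x in obj)
        return b"(" + parts + b")"
    raise TypeError(f"unhashable component type: {type(obj)!r}")


def hash_tuple(obj) -> int:
    """Stable 32-bit identifier for a nested tuple of primitives."""
    return fnv1a(_serialize(obj))
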