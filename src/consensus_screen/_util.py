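"""Small shared helpers."""

from __future__ import annotations

import hashlib

MAX_SEED = 2**31 - 1


def stable_child_seed(seed: int, *keys: object) -> int:
    """Derive a deterministic child seed from a master seed and string keys.

    Hash-based, so adding an unrelated stream never perturbs existing ones.
    Result fits in a signed 32-bit integer.
    """
    digest = hashlib.sha256(("|".join([str(int(seed))] + [str(k) for k in keys])).encode())
    return int.from_bytes(digest.digest()[:4], "big") % MAX_SEED
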