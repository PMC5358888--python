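"""Deterministic seed derivation.

One global seed drives the whole pipeline. Each stochastic stage derives its
own child seed from (global seed, fixed stage tag), so adding or reordering
stages never perturbs another stage's random stream, and per-metabolite
Monte-Carlo streams are independent of metabolite processing order.
"""

from __future__ import annotations

import hashlib

_MOD = 2**31  # keep derived seeds in the range small-integer RNG seeds expect


def derive_seed(global_seed: int, *tags: object) -> int:
    """Derive a child seed from a global seed and a sequence of stage tags.

    Stable across runs and platforms (SHA-256 of the rendered tag tuple).
    """
    key = repr((int(global_seed),) + tuple(str(t) for t in tags)).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:8], "big") % _MOD
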