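"""Seeded-substream discipline.

Every source of randomness in a run is a named substream derived from small
integers (master seed, replicate index, condition key, generation, individual
index, stream tag), so any component — mutation of one child, transcription of
one individual, the epistasis exchange — can be replayed in isolation.
"""
from __future__ import annotations

import numpy as np

__all__ = ["substream", "stream_seed", "rate_key", "STREAM_GENOME",
           "STREAM_MUTATION", "STREAM_TRANSCRIPTION", "STREAM_EPISTASIS",
           "STREAM_EVALUATOR"]

# stream tags; keep stable across versions, they are part of the replay contract
STREAM_GENOME = 1
STREAM_MUTATION = 2
STREAM_TRANSCRIPTION = 3
STREAM_EPISTASIS = 4
STREAM_EVALUATOR = 5


def _as_keys(keys) -> list[int]:
    out = []
    for k in keys:
        k = int(k)
        if k < 0:
            k += 1 << 63
        out.append(k)
    return out


def stream_seed(*keys: int) -> int:
    """A stable 31-bit seed derived from a tuple of integers."""
    ss = np.random.SeedSequence(_as_keys(keys))
    return int(ss.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF


def substream(*keys: int) -> np.random.Generator:
    """A fresh Generator keyed by a tuple of integers."""
    return np.random.default_rng(np.random.SeedSequence(_as_keys(keys)))


def rate_key(rate: float) -> int:
    """Map an error rate to a stable integer key (1e-8 resolution)."""
    return int(round(float(rate) * 1e8))
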