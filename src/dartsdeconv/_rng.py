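"""Stable, key-addressed random substreams.

All stochastic generators in the package draw from substreams derived by
hashing a root seed together with a tuple of string keys. This makes every
draw independent of iteration order: adding a protein to a proteome, or a
condition to an experiment, does not perturb the random numbers any other
protein or condition sees.
"""

from __future__ import annotations

import hashlib

import numpy as np

_SEP = b"\x1f"


def _digest(seed: int, *keys: object) -> int:
    parts = [str(int(seed)).encode()] + [str(k).encode() for k in keys]
    h = hashlib.blake2b(_SEP.join(parts), digest_size=8).digest()
    return int.from_bytes(h, "little")


def substream(seed: int, *keys: object) -> np.random.Generator:
    """A NumPy Generator uniquely and reproducibly keyed by (seed, *keys)."""
    return np.random.default_rng(_digest(seed, *keys) % (2**31))


def stable_uniform(seed: int, *keys: object) -> float:
    """A single uniform in [0, 1) that is a pure function of (seed, *keys).

    Used for per-peptide detectability so that the same peptide (same
    protein, same coordinates) receives the same detection decision in every
    condition in which it is produced.
    """
    return _digest(seed, *keys) / 2.0**64
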