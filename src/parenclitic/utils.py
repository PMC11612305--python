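"""Low-level helpers: counter-based hashed random numbers.

The per-pair mixture fits must be reproducible as a pure function of
``(master_seed, i, j)`` regardless of the order in which pairs are processed.
A counter-based construction (splitmix64 finaliser) gives that directly and
vectorises over tens of thousands of pairs, unlike stateful generators.
"""

from __future__ import annotations

import numpy as np

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
_PRIME = np.uint64(0x100000001B3)  # FNV-ish odd multiplier for (i, j) folding
_INV53 = 1.0 / float(1 << 53)


def splitmix64(z: np.ndarray) -> np.ndarray:
    """splitmix64 finaliser applied elementwise to a uint64 array."""
    z = np.asarray(z, dtype=np.uint64)
    z = (z ^ (z >> np.uint64(30))) * _MIX1
    z = (z ^ (z >> np.uint64(27))) * _MIX2
    return z ^ (z >> np.uint64(31))


def pair_uniforms(master_seed: int, i: np.ndarray, j: np.ndarray, n_draws: int) -> np.ndarray:
    """Deterministic uniforms in [0, 1) keyed by ``(master_seed, i, j)``.

    Returns an array of shape ``(len(i), n_draws)``. The value at position
    ``(p, t)`` depends only on the key, never on evaluation order, so chunked
    or parallel schedules produce identical streams.
    """
    if master_seed < 0:
        raise ValueError("master_seed must be non-negative")
    i = np.asarray(i, dtype=np.uint64)
    j = np.asarray(j, dtype=np.uint64)
    base = splitmix64((np.uint64(master_seed) + _GOLDEN) ^ (i * _PRIME + j))
    t = np.arange(1, n_draws + 1, dtype=np.uint64)
    z = splitmix64(base[:, None] + t[None, :] * _GOLDEN)
    return (z >> np.uint64(11)).astype(np.float64) * _INV53


def sha256_file(path) -> str:
    """Hex digest of a file's contents (used for stage manifests)."""
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()
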