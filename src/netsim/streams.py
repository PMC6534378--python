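"""Replicable, purpose-keyed random streams.

Every stochastic decision made while instantiating or driving a network
draws from a private stream keyed by ``(globalSeed, purpose,
purposeSeed, id1, id2)``, where the ids are cell gids (or 0).  Streams
are counter-based (Philox) with the key derived by a splitmix64 hash
chain over the tuple, so:

* the same key always yields the same sequence, on any platform;
* results do not depend on the order in which cells or pairs are
  processed, nor on how work is partitioned across workers;
* changing the global seed changes every stream, while changing one
  purposive seed (e.g. ``seeds.conn``) re-randomizes only that aspect
  of the model.

Purposes: ``loc`` (cell positions), ``conn`` (connectivity decisions),
``synloc`` (subcellular synapse placement; shares the connectivity
purposive seed), ``stim`` (input spike trains and noise currents).
"""

from __future__ import annotations

import numpy as np

__all__ = ["stream", "StreamKey", "PURPOSES"]

PURPOSES = {"loc": 0x1D, "conn": 0x2C, "synloc": 0x3A, "stim": 0x4E}

_MASK64 = (1 << 64) - 1


def _splitmix64(x):
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK64
    return x ^ (x >> 31)


def _mix(values):
    h = 0x243F6A8885A308D3
    for v in values:
        h = _splitmix64(h ^ (int(v) & _MASK64))
    return h


class StreamKey(tuple):
    """(purpose, id1, id2) triple naming one random stream."""

    def __new__(cls, purpose, id1=0, id2=0):
        if purpose not in PURPOSES:
            raise ValueError(f"unknown stream purpose {purpose!r}")
        return super().__new__(cls, (purpose, int(id1), int(id2)))

    purpose = property(lambda self: self[0])
    id1 = property(lambda self: self[1])
    id2 = property(lambda self: self[2])


def stream(global_seed, purpose, purpose_seed=0, id1=0, id2=0):
    """Return a fresh ``numpy.random.Generator`` for the given key."""
    key = _mix((global_seed, PURPOSES[purpose], purpose_seed, id1, id2))
    key2 = _splitmix64(key)
    return np.random.Generator(np.random.Philox(key=(key | (key2 << 64))))


class StreamSet:
    """Stream factory bound to one simulation's seed configuration."""

    def __init__(self, seeds):
        self.global_seed = int(seeds.get("global", 1))
        self.purpose_seeds = {
            "loc": int(seeds.get("loc", 1)),
            "conn": int(seeds.get("conn", 1)),
            "synloc": int(seeds.get("conn", 1)),  # subcellular placement follows conn
            "stim": int(seeds.get("stim", 1)),
        }

    def __call__(self, purpose, id1=0, id2=0):
        return stream(self.global_seed, purpose,
                      self.purpose_seeds[purpose], id1, id2)
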