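"""Explicit-state random streams for common-random-number simulation.

Each stream is a xoshiro256** generator whose state is four uint64 words in a
row of a 2-D array, so stream states can be copied, stored in a snapshot and
restored exactly.  Child streams are derived from a master seed through
``numpy.random.SeedSequence`` with ``spawn_key=(key,)``; the key is the
1-based channel id for slow-channel streams and 0 for the stream shared by
all fast channels.  The derivation is stable across runs and platforms.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["make_streams", "stream_state", "set_stream_state",
           "next_uint64", "next_double", "next_exponential"]

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)


def make_streams(master_seed: int, keys) -> np.ndarray:
    """Allocate one stream per key; returns the (n, 4) uint64 state array."""
    states = np.empty((len(keys), 4), dtype=np.uint64)
    for i, key in enumerate(keys):
        ss = np.random.SeedSequence(master_seed, spawn_key=(int(key),))
        words = ss.generate_state(4, np.uint64)
        if not words.any():  # all-zero is the one invalid xoshiro state
            words[0] = _GOLDEN
        states[i] = words
    return states


def stream_state(states: np.ndarray, i: int) -> np.ndarray:
    return states[i].copy()


def set_stream_state(states: np.ndarray, i: int, saved: np.ndarray) -> None:
    states[i] = saved


@njit(cache=True, inline="always")
def _rotl(x, k):
    return np.uint64((x << np.uint64(k)) | (x >> np.uint64(64 - k)))


@njit(cache=True)
def next_uint64(states, i):
    s0 = states[i, 0]
    s1 = states[i, 1]
    s2 = states[i, 2]
    s3 = states[i, 3]
    result = _rotl(s1 * np.uint64(5), 7) * np.uint64(9)
    t = np.uint64(s1 << np.uint64(17))
    s2 ^= s0
    s3 ^= s1
    s1 ^= s2
    s0 ^= s3
    s2 ^= t
    s3 = _rotl(s3, 45)
    states[i, 0] = s0
    states[i, 1] = s1
    states[i, 2] = s2
    states[i, 3] = s3
    return result


@njit(cache=True)
def next_double(states, i):
    """Uniform double in [0, 1) with 53-bit resolution."""
    return (next_uint64(states, i) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def next_exponential(states, i):
    """Unit-mean exponential variate; guards against log(0)."""
    u = next_double(states, i)
    while u <= 0.0:
        u = next_double(states, i)
    return -np.log(u)
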