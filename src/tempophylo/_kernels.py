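"""Compiled inner loops for the swap chain and per-row statistics.

The independent-swap null requires millions of trial swaps per analysis, and
every retained null matrix needs MPD/MNTD for every row. These kernels keep
that affordable. Randomness comes from an own xorshift64* generator so null
streams are bit-reproducible for a given seed, independent of numpy/numba
internals. The pure-Python counterparts in :mod:`metrics` and
:mod:`null_models` are the reference implementations the tests compare
against.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_U64 = np.uint64
_MASK = _U64(0xFFFFFFFFFFFFFFFF)
_MULT = _U64(0x2545F4914F6CDD1D)


def seed_state(seed: int) -> np.uint64:
    """Derive a nonzero 64-bit xorshift state from a small integer seed."""
    # splitmix64 step; avoids the all-zero fixed point
    mask = 0xFFFFFFFFFFFFFFFF
    z = (int(seed) + 0x9E3779B97F4A7C15) & mask
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
    z = z ^ (z >> 31)
    return _U64(z) if z != 0 else _U64(1)


@njit(inline="always", cache=False)
def _next(state):
    state ^= state << _U64(13)
    state &= _MASK
    state ^= state >> _U64(7)
    state ^= state << _U64(17)
    state &= _MASK
    return state


@njit(cache=False)
def swap_trials(mat, n_trials, state):
    """Run ``n_trials`` trial swaps of the fixed-fixed chain, in place.

    Each trial picks two distinct rows and two distinct columns uniformly; if
    the 2x2 submatrix is a checkerboard its diagonals are exchanged, otherwise
    the matrix is left unchanged. Row and column sums are conserved exactly.
    Returns the advanced RNG state.
    """
    n_r, n_c = mat.shape
    for _ in range(n_trials):
        state = _next(state)
        r1 = np.int64((state * _MULT) % _U64(n_r))
        state = _next(state)
        r2 = np.int64((state * _MULT) % _U64(n_r - 1))
        if r2 >= r1:
            r2 += np.int64(1)
        state = _next(state)
        c1 = np.int64((state * _MULT) % _U64(n_c))
        state = _next(state)
        c2 = np.int64((state * _MULT) % _U64(n_c - 1))
        if c2 >= c1:
            c2 += np.int64(1)
        a = mat[r1, c1]
        b = mat[r1, c2]
        c = mat[r2, c1]
        d = mat[r2, c2]
        if a == 1 and d == 1 and b == 0 and c == 0:
            mat[r1, c1] = 0
            mat[r2, c2] = 0
            mat[r1, c2] = 1
            mat[r2, c1] = 1
        elif a == 0 and d == 0 and b == 1 and c == 1:
            mat[r1, c1] = 1
            mat[r2, c2] = 1
            mat[r1, c2] = 0
            mat[r2, c1] = 0
    return state


@njit(cache=False)
def row_stats(mat, dist):
    """MPD and MNTD for every row of a binary matrix against ``dist``.

    Rows with richness < 2 yield NaN in both outputs.
    """
    n_units, n_sp = mat.shape
    mpd_out = np.full(n_units, np.nan)
    mntd_out = np.full(n_units, np.nan)
    idx = np.empty(n_sp, np.int64)
    for r in range(n_units):
        k = 0
        for c in range(n_sp):
            if mat[r, c] != 0:
                idx[k] = c
                k += 1
        if k < 2:
            continue
        pair_sum = 0.0
        nn_sum = 0.0
        for a in range(k):
            best = np.inf
            ia = idx[a]
            for b in range(k):
                if b == a:
                    continue
                d = dist[ia, idx[b]]
                if b > a:
                    pair_sum += d
                if d < best:
                    best = d
            nn_sum += best
        mpd_out[r] = pair_sum / (k * (k - 1) / 2.0)
        mntd_out[r] = nn_sum / k
    return mpd_out, mntd_out
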