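"""Observed community phylogenetic structure: MPD and MNTD.

MPD (mean pairwise distance) is the mean of d(i, j) over all unordered pairs
of species present in a community; it responds to tree-wide relatedness.
MNTD (mean nearest-taxon distance) averages, over present species, each
species' distance to its closest present relative; it responds to structure
near the tips. Both are undefined for communities with fewer than two
species, which callers record as a gap rather than an error.
"""

from __future__ import annotations

import math

import numpy as np

from .phylogeny import DistanceMatrix


def _select(present, d: DistanceMatrix) -> np.ndarray:
    idx = d.index
    try:
        sel = [idx[sp] for sp in sorted(present)]
    except KeyError as e:
        raise KeyError(f"species not in distance matrix: {e.args[0]!r}") from e
    return d.values[np.ix_(sel, sel)]


def mpd(present, d: DistanceMatrix) -> float:
    """Mean pairwise distance among present species; NaN if richness < 2."""
    if len(set(present)) < 2:
        return math.nan
    sub = _select(present, d)
    k = sub.shape[0]
    iu = np.triu_indices(k, 1)
    return float(sub[iu].mean())


def mntd(present, d: DistanceMatrix) -> float:
    """Mean distance to the nearest present relative; NaN if richness < 2."""
    if len(set(present)) < 2:
        return math.nan
    sub = _select(present, d).astype(float)
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())
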