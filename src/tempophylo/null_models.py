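"""Co-occurrence null models, NRI/NTI standardized effect sizes, patterns.

The primary null is the *independent swap*: a Markov chain on binary
community matrices that repeatedly exchanges the diagonals of randomly chosen
2x2 checkerboard submatrices, preserving both row sums (unit richness) and
column sums (species frequencies). The chain randomizes the whole matrix
jointly; per-unit statistics are then read off each retained null matrix.

Standardization follows the usual sign convention:

    NRI = -(MPD_obs - mean(MPD_null)) / sd(MPD_null)
    NTI = -(MNTD_obs - mean(MNTD_null)) / sd(MNTD_null)

so positive values mean co-occurring species are more closely related than
the null expects (phylogenetic clustering) and negative values mean they are
less related (overdispersion). Significance is decided by the observed
value's mid-rank position in the null distribution, not by a Gaussian
approximation from the standardized value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterator, Optional

import numpy as np

from . import _kernels
from .community import CommunityMatrix
from .phylogeny import DistanceMatrix

NULL_MODELS = ("independent_swap", "taxa_labels", "richness", "frequency")
PATTERNS = ("clustered", "random", "overdispersed", "undefined")

_TIE_TOL = 1e-9


@dataclass(frozen=True)
class NullConfig:
    """Parameters of the randomization scheme.

    ``burn_in`` and ``thinning`` are trial-swap counts for the swap chain;
    when None they default to 10 * (rows * columns) and rows * columns
    respectively, the usual prescription for fixed-fixed chains (adequacy is
    checked by the uniformity tests).
    """

    model: str = "independent_swap"
    n_rand: int = 10000
    burn_in: Optional[int] = None
    thinning: Optional[int] = None
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.model not in NULL_MODELS:
            raise ValueError(f"unknown null model {self.model!r}; expected one of {NULL_MODELS}")
        if self.n_rand < 1:
            raise ValueError("n_rand must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("burn_in", "thinning"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SESResult:
    """Standardized effect size of one index for one sample unit."""

    unit: str
    index: str  # "NRI" or "NTI"
    observed: float
    null_mean: float
    null_sd: float
    ses: float
    rank: float  # null-quantile rank of the observed value, mid-rank for ties
    pattern: str
    richness: int


def _as_binary(matrix: CommunityMatrix) -> np.ndarray:
    m = matrix.values
    if not np.isin(m, (0, 1)).all():
        raise ValueError("community matrix must be binary (0/1)")
    return m.astype(np.int8)


def independent_swap_step(matrix: CommunityMatrix, rng: np.random.Generator) -> CommunityMatrix:
    """One trial swap (pure-Python reference for the compiled chain).

    Picks 2 distinct rows and 2 distinct columns uniformly at random; if the
    2x2 submatrix is a checkerboard, exchanges its diagonals, otherwise
    returns the matrix unchanged. Marginals are conserved either way.
    """
    m = _as_binary(matrix)
    n_r, n_c = m.shape
    if n_r < 2 or n_c < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    r1, r2 = rng.choice(n_r, size=2, replace=False)
    c1, c2 = rng.choice(n_c, size=2, replace=False)
    sub = m[np.ix_([r1, r2], [c1, c2])]
    if sub[0, 0] == sub[1, 1] and sub[0, 1] == sub[1, 0] and sub[0, 0] != sub[0, 1]:
        m[np.ix_([r1, r2], [c1, c2])] = sub[::-1]
    out = matrix.data.copy()
    out.loc[:, :] = m
    return CommunityMatrix(out, matrix.scale)


def _swap_defaults(shape: tuple[int, int], config: NullConfig) -> tuple[int, int]:
    cells = shape[0] * shape[1]
    burn = config.burn_in if config.burn_in is not None else 10 * cells
    thin = config.thinning if config.thinning is not None else max(cells, 1)
    return burn, thin


def randomize(
    matrix: CommunityMatrix, config: NullConfig, rng: Optional[np.random.Generator] = None
) -> Iterator[np.ndarray]:
    """Stream ``config.n_rand`` null occurrence matrices.

    ``independent_swap`` walks one Markov chain (burn-in, then one sample
    every ``thinning`` trial swaps); ``richness`` refills each row with its
    observed richness uniformly among columns; ``frequency`` refills each
    column with its observed frequency among rows. For ``taxa_labels`` the
    communities are fixed and the randomness lives in the distance matrix:
    use :func:`label_permutations` (``ses_indices`` does so internally).
    """
    m = _as_binary(matrix)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.model == "independent_swap":
        if m.shape[0] < 2 or m.shape[1] < 2:
            raise ValueError("independent swap needs >= 2 rows and >= 2 columns")
        burn, thin = _swap_defaults(m.shape, config)
        work = m.copy()
        state = _kernels.seed_state(config.seed)
        state = np.uint64(_kernels.swap_trials(work, burn, state))
        for _ in range(config.n_rand):
            state = np.uint64(_kernels.swap_trials(work, thin, state))
            yield work.copy()
    elif config.model == "richness":
        n_r, n_c = m.shape
        rowsums = m.sum(axis=1)
        for _ in range(config.n_rand):
            out = np.zeros_like(m)
            order = np.argsort(rng.random((n_r, n_c)), axis=1)
            for r in range(n_r):
                out[r, order[r, : rowsums[r]]] = 1
            yield out
    elif config.model == "frequency":
        n_r, n_c = m.shape
        colsums = m.sum(axis=0)
        for _ in range(config.n_rand):
            out = np.zeros_like(m)
            order = np.argsort(rng.random((n_c, n_r)), axis=1)
            for c in range(n_c):
                out[order[c, : colsums[c]], c] = 1
            yield out
    elif config.model == "taxa_labels":
        for _ in range(config.n_rand):
            yield m.copy()
    else:  # pragma: no cover - guarded by NullConfig
        raise ValueError(f"unknown null model {config.model!r}")


def label_permutations(
    n_pool: int, config: NullConfig, rng: Optional[np.random.Generator] = None
) -> Iterator[np.ndarray]:
    """Stream permutations of the species pool for the taxa-labels null."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    for _ in range(config.n_rand):
        yield rng.permutation(n_pool)


def classify_pattern(rank: float, alpha: float = 0.05) -> str:
    """Map a null-quantile rank to a phylogenetic pattern label.

    Small observed distances (low rank) mean closer relatives than the null:
    clustering. Large distances (high rank) mean overdispersion.
    """
    if math.isnan(rank):
        return "undefined"
    if rank <= alpha / 2:
        return "clustered"
    if rank >= 1 - alpha / 2:
        return "overdispersed"
    return "random"


def ses_indices(
    matrix: CommunityMatrix, d: DistanceMatrix, config: NullConfig
) -> list[SESResult]:
    """NRI and NTI for every sample unit of ``matrix`` under ``config``.

    Returns two :class:`SESResult` per unit (NRI from MPD, NTI from MNTD), in
    unit order. Units with richness < 2, or whose null distribution is
    degenerate (sd = 0, e.g. a unit whose membership is fixed by the
    marginals), get ``pattern="undefined"``.
    """
    missing = [sp for sp in matrix.species if sp not in d.index]
    if missing:
        raise KeyError(f"species not in distance matrix: {missing}")
    sub = d.submatrix(matrix.species)
    dist = sub.values.astype(np.float64)
    m = _as_binary(matrix)
    n_units = m.shape[0]
    richness = m.sum(axis=1)

    obs_mpd, obs_mntd = _kernels.row_stats(m, dist)

    sums = np.zeros((2, n_units))
    sumsq = np.zeros((2, n_units))
    n_less = np.zeros((2, n_units))
    n_eq = np.zeros((2, n_units))
    n_valid = np.zeros((2, n_units))  # frequency null can degenerate single rows
    acc = (sums, sumsq, n_less, n_eq, n_valid)
    obs = np.vstack([obs_mpd, obs_mntd])

    if config.model == "taxa_labels":
        rng = np.random.default_rng(config.seed)
        for perm in label_permutations(len(matrix.species), config, rng):
            null_stats = _kernels.row_stats(m, dist[np.ix_(perm, perm)])
            _accumulate(null_stats, obs, acc)
    else:
        for null_m in randomize(matrix, config):
            null_stats = _kernels.row_stats(null_m, dist)
            _accumulate(null_stats, obs, acc)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / n_valid
        var = np.maximum(sumsq / n_valid - mean**2, 0.0)
        sd = np.sqrt(var * n_valid / np.maximum(n_valid - 1, 1))
        rank = (n_less + 0.5 * n_eq) / np.maximum(n_valid, 1)

    results: list[SESResult] = []
    for u, unit in enumerate(matrix.units):
        for s, index in enumerate(("NRI", "NTI")):
            o = obs[s, u]
            if math.isnan(o):
                results.append(
                    SESResult(unit, index, math.nan, math.nan, math.nan, math.nan, math.nan,
                              "undefined", int(richness[u])))
                continue
            if not n_valid[s, u] or sd[s, u] <= 0 or math.isnan(sd[s, u]):
                warnings.warn(
                    f"degenerate null (sd = 0) for unit {unit!r}, index {index}; "
                    "pattern is undefined", RuntimeWarning, stacklevel=2)
                results.append(
                    SESResult(unit, index, o, mean[s, u], 0.0, math.nan, math.nan,
                              "undefined", int(richness[u])))
                continue
            ses = -(o - mean[s, u]) / sd[s, u]
            rk = rank[s, u]
            results.append(
                SESResult(unit, index, o, mean[s, u], sd[s, u], ses, rk,
                          classify_pattern(rk, config.alpha), int(richness[u])))
    return results


def _accumulate(null_stats, obs, acc) -> None:
    sums, sumsq, n_less, n_eq, n_valid = acc
    for s in range(2):
        v = null_stats[s]
        ok = np.isfinite(v)
        vv = np.where(ok, v, 0.0)
        sums[s] += vv
        sumsq[s] += vv * vv
        n_valid[s] += ok
        with np.errstate(invalid="ignore"):
            diff = v - obs[s]
            n_less[s] += ok & (diff < -_TIE_TOL)
            n_eq[s] += ok & (np.abs(diff) <= _TIE_TOL)


def with_seed(config: NullConfig, seed: int) -> NullConfig:
    """A copy of ``config`` with a different seed (convenience for pipelines)."""
    return replace(config, seed=seed)
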