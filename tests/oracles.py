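"""Independent brute-force oracles used only by the tests.

Deliberately written with different algorithms from the package: distances by
breadth-first search over the undirected tree, MPD/MNTD by direct pair
enumeration on label dictionaries, the runs-test distribution by exhaustive
arrangement enumeration, and fixed-marginal matrix sets by exhaustive search.
"""

from __future__ import annotations

import itertools
from collections import Counter, deque

import numpy as np


def bfs_distance_matrix(phylo):
    """Tip-to-tip edge counts via BFS from every tip over the node graph."""
    adj: dict[int, list[int]] = {}
    tips: dict[int, str] = {}
    for node in phylo.tree.preorder_node_iter():
        adj.setdefault(id(node), [])
        for child in node.child_nodes():
            adj[id(node)].append(id(child))
            adj.setdefault(id(child), []).append(id(node))
        if node.is_leaf():
            tips[id(node)] = node.taxon.label
    labels = list(phylo.tip_labels)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    out = np.zeros((n, n), dtype=int)
    for start, lab in tips.items():
        dist = {start: 0}
        q = deque([start])
        while q:
            cur = q.popleft()
            for nxt in adj[cur]:
                if nxt not in dist:
                    dist[nxt] = dist[cur] + 1
                    q.append(nxt)
        for other, olab in tips.items():
            out[index[lab], index[olab]] = dist[other]
    return labels, out


def brute_mpd(present, labels, matrix) -> float:
    idx = {lab: i for i, lab in enumerate(labels)}
    pairs = list(itertools.combinations(sorted(present), 2))
    return sum(matrix[idx[a], idx[b]] for a, b in pairs) / len(pairs)


def brute_mntd(present, labels, matrix) -> float:
    idx = {lab: i for i, lab in enumerate(labels)}
    total = 0.0
    for a in present:
        total += min(matrix[idx[a], idx[b]] for b in present if b != a)
    return total / len(present)


def enum_runs_pmf(n_plus: int, n_minus: int) -> dict[int, float]:
    """Distribution of the run count by enumerating every arrangement."""
    n = n_plus + n_minus
    counts: Counter[int] = Counter()
    total = 0
    for positions in itertools.combinations(range(n), n_plus):
        seq = [-1] * n
        for p in positions:
            seq[p] = 1
        runs = 1 + sum(seq[i] != seq[i + 1] for i in range(n - 1))
        counts[runs] += 1
        total += 1
    return {u: c / total for u, c in counts.items()}


def enum_runs_tail_p(signs: list[int]) -> float:
    """Exact p: share of arrangements at least as extreme as observed,
    in the direction of the observed departure (min of the two tails)."""
    n_plus = sum(1 for s in signs if s > 0)
    n_minus = len(signs) - n_plus
    u = 1 + sum(signs[i] != signs[i + 1] for i in range(len(signs) - 1))
    pmf = enum_runs_pmf(n_plus, n_minus)
    lo = sum(p for v, p in pmf.items() if v <= u)
    hi = sum(p for v, p in pmf.items() if v >= u)
    return min(lo, hi)


def enum_fixed_marginal_matrices(row_sums, col_sums) -> list[bytes]:
    """Every binary matrix with the given marginals, as canonical bytes."""
    n_r, n_c = len(row_sums), len(col_sums)
    rows_options = [
        [row for row in itertools.product((0, 1), repeat=n_c) if sum(row) == rs]
        for rs in row_sums
    ]
    out = []
    for combo in itertools.product(*rows_options):
        m = np.array(combo, dtype=np.int8)
        if (m.sum(axis=0) == np.asarray(col_sums)).all():
            out.append(m.tobytes())
    return out
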