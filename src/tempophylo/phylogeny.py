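"""Rooted phylogenies and node-count (topology-only) distance matrices.

The analyses in this package measure relatedness as the number of edges on
the tip-to-tip path of a rooted phylogeny, i.e. the path length obtained by
setting every branch length to one.  Branch lengths present in the input
Newick are retained on the tree but never enter the distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np


class PhylogenyError(ValueError):
    """Malformed or invalid phylogeny input."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric integer matrix of tip-to-tip path lengths, in edges.

    ``labels`` fixes the row/column order; entries on the diagonal are 0 and
    every off-diagonal entry is >= 2 (two distinct tips are separated by at
    least the two edges through their parent or parents).
    """

    labels: tuple[str, ...]
    values: np.ndarray  # (n, n) int64

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")

    @property
    def index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}

    def submatrix(self, labels: list[str] | tuple[str, ...]) -> "DistanceMatrix":
        """Restrict to ``labels`` (order preserved) without recomputing paths.

        Guild analyses use submatrices of the full-tree distances rather than
        distances on a pruned guild tree: pruning collapses internal nodes and
        changes node counts, whereas one fixed tree keeps a single
        evolutionary reference frame across guilds.
        """
        idx = self.index
        try:
            sel = [idx[lab] for lab in labels]
        except KeyError as e:
            raise KeyError(f"label not in distance matrix: {e.args[0]!r}") from e
        return DistanceMatrix(tuple(labels), self.values[np.ix_(sel, sel)])

    def to_delimited(self, sep: str = "\t") -> str:
        lines = [sep.join(["", *self.labels])]
        for lab, row in zip(self.labels, self.values):
            lines.append(sep.join([lab, *(str(int(x)) for x in row)]))
        return "\n".join(lines) + "\n"


class Phylogeny:
    """A rooted, possibly polytomous tree with uniquely labeled tips.

    Wraps a :class:`dendropy.Tree`. On ingest, degree-2 internal chains are
    collapsed (they carry no topological information for node counts) and tip
    labels are checked to be non-empty and unique.
    """

    def __init__(self, tree: dendropy.Tree):
        tree.suppress_unifurcations()
        self._tree = tree
        labels = [leaf.taxon.label if leaf.taxon else "" for leaf in tree.leaf_node_iter()]
        empties = [i for i, lab in enumerate(labels) if not lab]
        if empties:
            raise PhylogenyError("tree has unlabeled tips")
        seen: set[str] = set()
        dups = sorted({lab for lab in labels if lab in seen or seen.add(lab)})
        if dups:
            raise PhylogenyError(f"duplicate tip labels: {', '.join(dups)}")
        self._tip_labels = tuple(labels)

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> tuple[str, ...]:
        """Tip labels in tree (leaf-iteration) order; stable for a given tree."""
        return self._tip_labels

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny(n_tips={self.n_tips})"


def read_newick(text: str) -> Phylogeny:
    """Parse a single rooted Newick statement into a :class:`Phylogeny`."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as e:  # dendropy raises several error types
        raise PhylogenyError(f"could not parse Newick: {e}") from e
    return Phylogeny(tree)


def write_newick(phylo: Phylogeny) -> str:
    """Serialize to Newick; ``read_newick`` of the result restores the topology."""
    s = phylo.tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
    return s.strip() + ("" if s.strip().endswith(";") else ";")


def node_count_distance_matrix(phylo: Phylogeny) -> DistanceMatrix:
    """Pairwise tip distances as edge counts on the unique tip-to-tip path.

    Computed from node depths: d(i, j) = depth(i) + depth(j) - 2 depth(lca),
    accumulating pairs across the child subtrees of each internal node, which
    visits every unordered tip pair exactly once (O(n^2) total).
    """
    if phylo.n_tips < 2:
        raise PhylogenyError("need at least 2 tips for a distance matrix")
    labels = phylo.tip_labels
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    out = np.zeros((n, n), dtype=np.int64)

    depth: dict[int, int] = {}
    tipsets: dict[int, list[tuple[int, int]]] = {}  # node id -> [(tip index, tip depth)]
    root = phylo.tree.seed_node
    depth[id(root)] = 0
    for node in phylo.tree.preorder_node_iter():
        if node is not root:
            depth[id(node)] = depth[id(node.parent_node)] + 1
    for node in phylo.tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[id(node)] = [(index[node.taxon.label], depth[id(node)])]
            continue
        children = [tipsets.pop(id(c)) for c in node.child_nodes()]
        dv = depth[id(node)]
        # pairs whose most recent common ancestor is this node
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for i, di in children[a]:
                    for j, dj in children[b]:
                        d = di + dj - 2 * dv
                        out[i, j] = d
                        out[j, i] = d
        merged = children[0]
        for c in children[1:]:
            merged.extend(c)
        tipsets[id(node)] = merged
    return DistanceMatrix(labels, out)
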