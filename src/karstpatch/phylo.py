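"""Phylogenetic primitives: Newick trees, cophenetic distances, PD, MPD, MNTD.

Tree storage and (de)serialization are delegated to :mod:`dendropy`; the
metrics themselves — cophenetic path lengths, Faith's phylogenetic diversity,
mean pairwise distance (MPD) and mean nearest-taxon distance (MNTD) — are
computed here from first principles so they can be cross-checked against
independent implementations.
"""

from __future__ import annotations

import logging
import math

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "NewickParseError",
    "PhyloTree",
    "DistanceMatrix",
    "parse_newick",
    "cophenetic",
    "faith_pd",
    "mpd",
    "mntd",
]


class NewickParseError(ValueError):
    """Malformed Newick input; message carries the parser's position info."""


class PhyloTree:
    """Rooted tree with branch lengths and uniquely labeled tips."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("tip labels must be unique")
        if any(label is None for label in labels):
            raise ValueError("every tip must be labeled")
        self._tip_labels = labels

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return cls(_parse(text))

    @classmethod
    def from_file(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in tree (left-to-right) order."""
        return list(self._tip_labels)

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    def total_branch_length(self) -> float:
        return float(
            sum(
                node.edge.length or 0.0
                for node in self._tree.preorder_node_iter()
                if node.parent_node is not None
            )
        )

    def to_newick(self) -> str:
        text = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
        return text + ("" if text.endswith(";") else ";")

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def cophenetic(self) -> "DistanceMatrix":
        """Tip-to-tip path-length (cophenetic) distance matrix.

        Computed by a single postorder sweep: at each internal node, pairs of
        tips first united there are at distance depth_i + depth_j measured
        below that node.
        """
        labels = self._tip_labels
        index = {label: i for i, label in enumerate(labels)}
        n = len(labels)
        dist = np.zeros((n, n), dtype=float)
        below: dict[int, dict[int, float]] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                below[id(node)] = {index[node.taxon.label]: 0.0}
                continue
            merged: dict[int, float] = {}
            for child in node.child_nodes():
                child_depths = below.pop(id(child))
                edge = child.edge.length or 0.0
                shifted = {tip: d + edge for tip, d in child_depths.items()}
                for tip_i, d_i in merged.items():
                    for tip_j, d_j in shifted.items():
                        dist[tip_i, tip_j] = dist[tip_j, tip_i] = d_i + d_j
                merged.update(shifted)
            below[id(node)] = merged
        return DistanceMatrix(labels=labels, values=dist)

    def _tip_node(self, label: str) -> dendropy.Node:
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon.label == label:
                return leaf
        raise KeyError(f"unknown taxon: {label!r}")

    def faith_pd(self, taxa, rooted: bool = True) -> float:
        """Faith's PD: branch-length sum of the minimal subtree spanning ``taxa``.

        With ``rooted=True`` (classic convention, the default) the subtree is
        anchored at the root, so a single taxon scores its root-to-tip path
        length. With ``rooted=False`` only edges strictly between the taxa
        (below their most recent common ancestor) are counted.
        """
        taxa = list(taxa)
        if not taxa:
            raise ValueError("taxa must be non-empty")
        if len(set(taxa)) != len(taxa):
            raise ValueError("taxa must be distinct")
        tip_of = {
            leaf.taxon.label: leaf for leaf in self._tree.leaf_node_iter()
        }
        counts: dict[int, int] = {}
        lengths: dict[int, float] = {}
        for label in taxa:
            node = tip_of.get(label)
            if node is None:
                raise KeyError(f"unknown taxon: {label!r}")
            while node is not None:
                key = id(node)
                counts[key] = counts.get(key, 0) + 1
                lengths[key] = node.edge.length or 0.0
                node = node.parent_node
        k = len(taxa)
        total = 0.0
        for key, count in counts.items():
            if rooted or count < k:
                total += lengths[key]
        return float(total)


def _parse(text: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return tree


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string (branch lengths expected) into a PhyloTree."""
    return PhyloTree.from_newick(text)


class DistanceMatrix:
    """Symmetric tip × tip distance matrix with labels."""

    def __init__(self, labels: list[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("values must be square")
        if len(labels) != values.shape[0]:
            raise ValueError("labels must match matrix size")
        if not np.allclose(values, values.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(values), 0.0):
            raise ValueError("diagonal must be zero")
        self.labels = list(labels)
        self.values = values
        self._index = {label: i for i, label in enumerate(self.labels)}

    @property
    def n(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair) -> float:
        a, b = pair
        return float(self.values[self._index[a], self._index[b]])

    def indices(self, taxa) -> np.ndarray:
        try:
            return np.asarray([self._index[t] for t in taxa], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown taxon: {exc.args[0]!r}") from None

    def submatrix(self, taxa) -> np.ndarray:
        idx = self.indices(taxa)
        return self.values[np.ix_(idx, idx)]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(labels=list(frame.columns), values=frame.to_numpy(dtype=float))


def cophenetic(tree: PhyloTree) -> DistanceMatrix:
    """Cophenetic distances d(i,j) = branch-length sum on the path i→j."""
    return tree.cophenetic()


def faith_pd(tree: PhyloTree, taxa, rooted: bool = True) -> float:
    """Faith's phylogenetic diversity of a species set (see PhyloTree.faith_pd)."""
    return tree.faith_pd(taxa, rooted=rooted)


def mpd(dist: DistanceMatrix, taxa) -> float:
    """Mean pairwise cophenetic distance over unordered pairs of ``taxa``.

    Presence-weighted (each species counts once); NaN for fewer than two taxa.
    """
    taxa = list(taxa)
    if len(taxa) < 2:
        logger.warning("MPD undefined for fewer than 2 taxa")
        return math.nan
    sub = dist.submatrix(taxa)
    k = len(taxa)
    return float(sub.sum() / (k * (k - 1)))


def mntd(dist: DistanceMatrix, taxa) -> float:
    """Mean distance from each taxon to its nearest neighbor in ``taxa``."""
    taxa = list(taxa)
    if len(taxa) < 2:
        logger.warning("MNTD undefined for fewer than 2 taxa")
        return math.nan
    sub = dist.submatrix(taxa).copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())
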