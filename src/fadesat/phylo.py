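"""Phylogeny handling: Newick I/O, pruning, polytomy resolution, VCV matrices.

Trees are wrapped dendropy trees.  The phylogenetic variance-covariance (VCV)
matrix under Brownian motion has V[i,j] = shared root-to-MRCA path length of
tips i and j and V[i,i] = root-to-tip depth; Pagel's λ rescales the
off-diagonal by λ ∈ [0,1], interpolating between star-like independence
(λ = 0) and full Brownian covariance (λ = 1).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "TreeError",
    "read_newick",
    "vcv_from_tree",
    "apply_lambda",
]

logger = logging.getLogger(__name__)


class TreeError(ValueError):
    """Malformed tree input or an operation on taxa the tree lacks."""


def normalize_taxon(name: str) -> str:
    """Case-folded, underscore/space-insensitive form used for matching."""
    return name.strip().replace("_", " ").casefold()


class PhyloTree:
    """A rooted tree with branch lengths and unique tip labels."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {', '.join(dupes)}")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise TreeError(
                    f"negative branch length {edge.length} on edge to "
                    f"{edge.head_node.taxon.label if edge.head_node.taxon else 'internal node'}"
                )

    # -- construction ----------------------------------------------------
    @classmethod
    def from_newick(cls, text: str, missing_length: float | None = None) -> "PhyloTree":
        """Parse a Newick string.

        ``missing_length``: value substituted (with a warning) for edges
        without a length; ``None`` (default) makes missing lengths an error.
        Underscores in labels are preserved verbatim.
        """
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
            raise TreeError(f"duplicate tip labels in Newick input: {e}") from e
        except Exception as e:  # dendropy raises several parse-error types
            raise TreeError(f"malformed Newick input: {e}") from e
        n_missing = 0
        for edge in tree.preorder_edge_iter():
            if edge.tail_node is None:  # root edge
                continue
            if edge.length is None:
                if missing_length is None:
                    raise TreeError(
                        "edge without branch length; pass missing_length to default it"
                    )
                edge.length = missing_length
                n_missing += 1
        if n_missing:
            logger.warning("%d missing branch lengths set to %s", n_missing, missing_length)
        return cls(tree)

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    # -- basic properties -------------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    @property
    def is_binary(self) -> bool:
        for node in self._tree.preorder_node_iter():
            if len(node.child_nodes()) > 2:
                return False
        return True

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip label."""
        depths: dict[str, float] = {}
        self._assign_depths()
        for leaf in self._tree.leaf_node_iter():
            depths[leaf.taxon.label] = leaf._depth
        return depths

    def _assign_depths(self) -> None:
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                node._depth = 0.0
            else:
                node._depth = node.parent_node._depth + (node.edge.length or 0.0)

    # -- operations -------------------------------------------------------
    def prune_to(self, taxa: Iterable[str]) -> "PhyloTree":
        """Induced subtree on ``taxa``; unifurcations collapsed, path lengths kept.

        Taxon matching is exact after underscore/space and case normalisation.
        Missing taxa raise :class:`TreeError` listing every absent name.
        """
        wanted = list(taxa)
        by_norm = {normalize_taxon(l): l for l in self.tip_labels}
        missing = [t for t in wanted if normalize_taxon(t) not in by_norm]
        if missing:
            raise TreeError(f"taxa absent from tree: {', '.join(sorted(missing))}")
        keep = [by_norm[normalize_taxon(t)] for t in wanted]
        clone = self._tree.clone(depth=1)
        clone.retain_taxa_with_labels(keep)
        # dendropy may leave a unifurcating root carrying the stem length
        clone.suppress_unifurcations()
        root = clone.seed_node
        while len(root.child_nodes()) == 1:
            child = root.child_nodes()[0]
            for gc in list(child.child_nodes()):
                child.remove_child(gc)
                root.add_child(gc)
                gc.edge.length = (gc.edge.length or 0.0) + (child.edge.length or 0.0)
            root.remove_child(child)
        return PhyloTree(clone)

    def resolve_polytomies(self, seed: int) -> "PhyloTree":
        """Replace each multifurcation by a random binary arrangement.

        New internal edges get length zero, so every pairwise tip path
        distance — and hence the VCV — is unchanged.  Resolution joins a
        uniformly chosen pair of children under a new node until each node is
        binary (for a trichotomy the three rooted shapes are equiprobable).
        Deterministic for a given ``seed``; a binary tree is returned as a
        copy unchanged.
        """
        out = self.copy()
        rng = np.random.default_rng(seed)
        for node in list(out._tree.preorder_node_iter()):
            children = node.child_nodes()
            while len(children) > 2:
                i, j = sorted(rng.choice(len(children), size=2, replace=False))
                a, b = children[i], children[j]
                node.remove_child(a)
                node.remove_child(b)
                merged = out._tree.node_factory()
                merged.edge.length = 0.0
                merged.add_child(a)
                merged.add_child(b)
                node.add_child(merged)
                children = node.child_nodes()
        return out

    def has_polytomies(self) -> bool:
        return not self.is_binary

    def vcv(self, order: Sequence[str] | None = None) -> tuple[list[str], np.ndarray]:
        """Phylogenetic VCV matrix; rows/columns in ``order`` if given.

        V[i,j] is the root depth of MRCA(i,j); V[i,i] the tip depth.
        """
        self._assign_depths()
        leaves = list(self._tree.leaf_node_iter())
        labels = [lf.taxon.label for lf in leaves]
        idx = {id(lf): k for k, lf in enumerate(leaves)}
        n = len(leaves)
        V = np.zeros((n, n))
        for lf in leaves:
            V[idx[id(lf)], idx[id(lf)]] = lf._depth
        # postorder: for each internal node, tips in different child subtrees
        # have that node as MRCA
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                node._tipset = [idx[id(node)]]
                continue
            childsets = [c._tipset for c in node.child_nodes()]
            for a in range(len(childsets)):
                for b in range(a + 1, len(childsets)):
                    for i in childsets[a]:
                        for j in childsets[b]:
                            V[i, j] = V[j, i] = node._depth
            node._tipset = [i for s in childsets for i in s]
        if order is not None:
            by_norm = {normalize_taxon(l): k for k, l in enumerate(labels)}
            missing = [t for t in order if normalize_taxon(t) not in by_norm]
            if missing:
                raise TreeError(f"taxa absent from tree: {', '.join(sorted(missing))}")
            perm = [by_norm[normalize_taxon(t)] for t in order]
            V = V[np.ix_(perm, perm)]
            labels = list(order)
        return labels, V


def read_newick(text: str, missing_length: float | None = None) -> PhyloTree:
    """Module-level convenience for :meth:`PhyloTree.from_newick`."""
    return PhyloTree.from_newick(text, missing_length=missing_length)


def vcv_from_tree(
    tree: PhyloTree, order: Sequence[str] | None = None
) -> tuple[list[str], np.ndarray]:
    """Taxon labels and Brownian VCV matrix of ``tree``."""
    return tree.vcv(order=order)


def apply_lambda(V: np.ndarray, lam: float) -> np.ndarray:
    """Pagel-λ transform: off-diagonal entries scaled by λ, diagonal kept.

    λ = 1 returns V unchanged; λ = 0 removes all phylogenetic covariance.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    out = V * lam
    np.fill_diagonal(out, np.diag(V))
    return out
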