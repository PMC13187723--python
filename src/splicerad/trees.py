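"""Phylogenetic tree utilities.

Trees are handled as :class:`dendropy.Tree` objects throughout the package.
Species-to-tip matching is exact-string (underscores preserved); the only
remapping mechanism is an explicit alias table applied by the caller before
tree reading.  All comparative methods in :mod:`splicerad.phylo` consume the
two matrices produced by :func:`phylo_matrices`:

``C``
    shared-path matrix, ``C[i, j]`` = branch length from the root to the most
    recent common ancestor of tips *i* and *j* (``C[i, i]`` = root-to-tip
    depth).  Under Brownian motion the trait covariance is ``sigma2 * C``.
``D``
    patristic distance matrix, ``D[i, j] = C[i, i] + C[j, j] - 2 C[i, j]``.
"""

from __future__ import annotations

import logging
from typing import Sequence

import dendropy
import numpy as np

log = logging.getLogger(__name__)


class TreeError(ValueError):
    """Raised for malformed or inconsistent tree input."""


def read_tree(
    source: str,
    *,
    is_path: bool = True,
    strict_species: Sequence[str] | None = None,
) -> dendropy.Tree:
    """Read a Newick tree with branch lengths.

    Parameters
    ----------
    source
        Path to a Newick file, or a Newick string if ``is_path`` is False.
    strict_species
        If given, every species label in this collection must appear as a
        tip (exact, case-sensitive string match), otherwise a
        :class:`TreeError` is raised.

    Returns
    -------
    dendropy.Tree
        The parsed tree.  A basal trifurcation (classic unrooted Newick) is
        accepted and flagged in the log, not treated as an error.
    """
    kwargs = {"path": source} if is_path else {"data": source}
    try:
        tree = dendropy.Tree.get(
            schema="newick", preserve_underscores=True, **kwargs
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"could not parse Newick input: {exc}") from exc

    labels = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None:
            raise TreeError("tree contains an unlabeled tip")
        labels.append(leaf.taxon.label)
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise TreeError(f"duplicate tip labels: {dupes}")

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue  # the root edge may legitimately lack a length
        if node.edge.length is None:
            who = node.taxon.label if node.taxon else "an internal node"
            raise TreeError(f"missing branch length on the edge above {who}")
        if node.edge.length < 0:
            raise TreeError("negative branch length in tree")

    if len(tree.seed_node.child_nodes()) > 2:
        log.info("tree has a basal multifurcation; treating as unrooted")

    if strict_species is not None:
        missing = sorted(set(strict_species) - set(labels))
        if missing:
            raise TreeError(f"species not found among tree tips: {missing}")
    return tree


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Tip labels in a fixed, deterministic (preorder) traversal order."""
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def node_depths(tree: dendropy.Tree) -> dict:
    """Root-to-node path length for every node (root depth 0)."""
    depths: dict = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def tree_height(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip depth."""
    depths = node_depths(tree)
    return max(depths[leaf] for leaf in tree.leaf_node_iter())


def phylo_matrices(
    tree: dendropy.Tree, labels: Sequence[str] | None = None
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Shared-path matrix ``C`` and patristic distance matrix ``D``.

    Parameters
    ----------
    labels
        Tip order for the returned matrices.  Defaults to
        :func:`tip_labels` order.  Must be a subset of the tree's tips;
        matrices are computed on the induced subtree (paths measured on the
        full tree, which is what the induced-subtree covariance requires).
    """
    all_labels = tip_labels(tree)
    if labels is None:
        labels = all_labels
    missing = sorted(set(labels) - set(all_labels))
    if missing:
        raise TreeError(f"labels not in tree: {missing}")
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    depths = node_depths(tree)

    C = np.zeros((n, n))
    for leaf in tree.leaf_node_iter():
        i = index.get(leaf.taxon.label)
        if i is not None:
            C[i, i] = depths[leaf]

    # leaf index sets per node, computed postorder
    leafsets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index.get(node.taxon.label)
            leafsets[node] = [i] if i is not None else []
        else:
            kids = [leafsets[c] for c in node.child_nodes()]
            # tips in different child subtrees coalesce exactly here
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        for j in kids[b]:
                            C[i, j] = C[j, i] = depths[node]
            leafsets[node] = [i for ks in kids for i in ks]

    d = np.diag(C)
    D = d[:, None] + d[None, :] - 2.0 * C
    np.fill_diagonal(D, 0.0)
    return list(labels), C, D


def robinson_foulds(newick_a: str, newick_b: str) -> int:
    """Unrooted Robinson–Foulds (symmetric bipartition) distance.

    Both inputs are Newick strings over the same taxon set.
    """
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=newick_a, schema="newick", taxon_namespace=tns,
        preserve_underscores=True,
    )
    b = dendropy.Tree.get(
        data=newick_b, schema="newick", taxon_namespace=tns,
        preserve_underscores=True,
    )
    a.encode_bipartitions()
    b.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(a, b)
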