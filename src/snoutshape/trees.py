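"""Phylogenetic tree utilities shared by the ordination and signal modules.

Trees are dendropy ``Tree`` objects, rooted, with tip labels acting as
species identifiers and branch lengths in arbitrary (typically time)
units.  A missing branch length is treated as zero.
"""

from __future__ import annotations

import dendropy
import numpy as np


def _edge_length(node) -> float:
    return float(node.edge.length) if node.edge.length is not None else 0.0


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def tree_vcv(tree: dendropy.Tree, taxa_order: list[str]) -> np.ndarray:
    """Brownian-motion covariance matrix C for the given tip order.

    C[i, j] is the shared root-to-MRCA path length of tips i and j; the
    diagonal holds root-to-tip depths.
    """
    index = {label: k for k, label in enumerate(taxa_order)}
    n = len(taxa_order)
    c = np.zeros((n, n))

    depth = {}
    for node in tree.preorder_node_iter():
        parent_depth = depth[node.parent_node] if node.parent_node else 0.0
        depth[node] = parent_depth + (_edge_length(node) if node.parent_node else 0.0)

    leafset = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in index:
                raise ValueError(f"tree tip {label!r} not present in taxa_order")
            leafset[node] = [index[label]]
            c[index[label], index[label]] = depth[node]
        else:
            children = node.child_nodes()
            sets = [leafset[ch] for ch in children]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    for i in sets[a]:
                        for j in sets[b]:
                            c[i, j] = c[j, i] = depth[node]
            merged = [i for s in sets for i in s]
            leafset[node] = merged
    if sorted(leafset[tree.seed_node]) != list(range(n)):
        raise ValueError("tree tips do not match taxa_order exactly")
    return c


def prune_to(tree: dendropy.Tree, labels: list[str]) -> dendropy.Tree:
    """Return a copy of the tree pruned to the given tip labels.

    Degree-two nodes created by pruning are suppressed with their
    subtending branch lengths summed.
    """
    pruned = tree.clone(depth=1)
    keep = set(labels)
    taxa = [t for t in pruned.taxon_namespace if t.label in keep]
    if not taxa:
        raise ValueError("no tree tips match the requested labels")
    pruned.retain_taxa(taxa)
    pruned.purge_taxon_namespace()
    return pruned


def parse_newick(text: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=True
    )
    if len(tree.leaf_nodes()) < 2:
        raise ValueError("tree must have at least 2 tips")
    labels = tip_labels(tree)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels in tree")
    for node in tree.preorder_node_iter():
        if node.parent_node and node.edge.length is not None and node.edge.length < 0:
            raise ValueError("negative branch length in tree")
    return tree
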