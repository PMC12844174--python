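"""Phylogeny utilities: newick I/O, patristic distances, Brownian trait evolution."""

from __future__ import annotations

import numpy as np
import pandas as pd
import dendropy


def read_tree(path) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("tree tip labels are not unique")
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree))


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def patristic_distance_matrix(tree: dendropy.Tree, taxa: list[str] | None = None) -> pd.DataFrame:
    """Pairwise tip-to-tip branch-length distances as a labelled DataFrame.

    If ``taxa`` is given, the matrix is restricted to (and ordered by) those
    labels; a taxon absent from the tree raises with its name.
    """
    pdm = tree.phylogenetic_distance_matrix()
    by_label = {t.label: t for t in pdm.taxon_iter()}
    if taxa is None:
        taxa = tip_labels(tree)
    missing = [t for t in taxa if t not in by_label]
    if missing:
        raise KeyError(f"taxa not found on tree: {missing}")
    n = len(taxa)
    out = np.zeros((n, n))
    objs = [by_label[t] for t in taxa]
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(objs[i], objs[j])
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=taxa, columns=taxa)


def brownian_tip_values(tree: dendropy.Tree, rng: np.random.Generator, sigma2: float = 1.0) -> pd.Series:
    """Evolve a continuous trait along the tree by Brownian motion.

    The root starts at 0; each branch adds a Normal(0, sigma2 * length)
    increment, so phylogenetically close tips get correlated values — the
    phylogenetic niche conservatism that betaNTI-style inference relies on.
    """
    values: dict[int, float] = {id(tree.seed_node): 0.0}
    out = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            pass
        else:
            length = node.edge.length or 0.0
            values[id(node)] = values[id(node.parent_node)] + rng.normal(0.0, np.sqrt(sigma2 * length))
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return pd.Series(out)
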