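"""Neighbor-joining trees, bootstrap support, outgroup rooting, monophyly tests.

Trees are ``dendropy.Tree`` objects with leaf taxa labeled by sequence id.
The NJ construction is authored here so that tie-breaking is deterministic
(candidate pairs are scanned in a fixed order with labels pre-sorted);
Newick serialization, rerooting and traversal go through dendropy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .dist import DistanceMatrix, distance_matrix
from .seqio import Alignment

logger = logging.getLogger(__name__)


@dataclass
class BootstrapConfig:
    """Column-resampling bootstrap settings (B replicates, fixed seed)."""

    replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("bootstrap requires at least 1 replicate")


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; returns an unrooted tree.

    Exact on additive matrices. Ties in the Q-criterion break toward the
    first candidate pair with labels in sorted order, so the result is
    deterministic. Negative branch-length estimates are clamped to zero.
    """
    if len(dm.labels) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if np.isnan(dm.values).any():
        raise ValueError(
            "distance matrix has undefined (saturated) entries; exclude those pairs first"
        )
    order = sorted(range(len(dm.labels)), key=lambda i: dm.labels[i])
    labels = [dm.labels[i] for i in order]
    D = dm.values[np.ix_(order, order)].astype(float).copy()

    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = [
        dendropy.Node(taxon=tns.get_taxon(lab)) for lab in labels
    ]

    def clamp(x: float) -> float:
        if x < 0:
            logger.debug("negative NJ branch length %.4g clamped to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = clamp(li)
        nodes[j].edge.length = clamp(lj)
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], dnew[keep]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # resolve the last three nodes around a central vertex (three-point formulas)
    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    center = dendropy.Node()
    for node, length in (
        (a, 0.5 * (dab + dac - dbc)),
        (b, 0.5 * (dab + dbc - dac)),
        (c, 0.5 * (dac + dbc - dab)),
    ):
        center.add_child(node)
        node.edge.length = clamp(length)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial bipartitions, each normalized to the side excluding the
    lexicographically smallest leaf. Invariant to rooting and leaf order."""
    leaves = frozenset(leaf_labels(tree))
    ref = min(leaves)
    n = len(leaves)
    parts: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = leaves - side
        if 2 <= len(side) <= n - 2:
            parts.add(side)
    return parts


def tree_length(tree: dendropy.Tree) -> float:
    return sum(
        e.length or 0.0 for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node
    )


def root_with_outgroup(tree: dendropy.Tree, outgroup_id: str) -> dendropy.Tree:
    """Root the tree on the outgroup's pendant edge (split at its midpoint)."""
    node = None
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label == outgroup_id:
            node = leaf
            break
    if node is None:
        raise ValueError(f"outgroup {outgroup_id!r} is not a leaf of the tree")
    length = node.edge.length or 0.0
    tree.reroot_at_edge(node.edge, length1=length / 2.0, length2=length / 2.0)
    tree.is_rooted = True
    return tree


def is_monophyletic(tree: dendropy.Tree, leaf_set: set[str]) -> bool:
    """True iff some node's descendant leaves are exactly ``leaf_set``.

    Singleton sets are monophyletic by convention. The tree should be
    rooted for the result to carry its usual meaning.
    """
    leaves = leaf_labels(tree)
    unknown = set(leaf_set) - leaves
    if unknown:
        raise ValueError(f"labels not in tree: {sorted(unknown)}")
    if len(leaf_set) <= 1:
        return True
    target = frozenset(leaf_set)
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if frozenset(lf.taxon.label for lf in node.leaf_iter()) == target:
            return True
    return False


def bootstrap_bipartition_counts(
    alignment: Alignment, config: BootstrapConfig, method: str = "k2p"
) -> tuple[dict[frozenset[str], int], int]:
    """Resample alignment columns B times, rebuild NJ, count bipartitions.

    Replicates whose resampled matrix contains an undefined (saturated or
    incomparable) pair are skipped and logged; the support denominator is
    the number of completed replicates.
    """
    rng = np.random.default_rng(config.seed)
    counts: dict[frozenset[str], int] = {}
    completed = 0
    for b in range(config.replicates):
        rep = alignment.resample_columns(rng)
        try:
            dm = distance_matrix(rep, method=method)
            rep_tree = nj_tree(dm)
        except ValueError as exc:
            logger.warning("bootstrap replicate %d skipped: %s", b, exc)
            continue
        completed += 1
        for part in bipartitions(rep_tree):
            counts[part] = counts.get(part, 0) + 1
    if completed == 0:
        raise ValueError("all bootstrap replicates failed")
    return counts, completed


def attach_support(
    tree: dendropy.Tree,
    counts: dict[frozenset[str], int],
    denominator: int,
) -> dendropy.Tree:
    """Label internal nodes with bootstrap support (integer percent)."""
    leaves = frozenset(leaf_labels(tree))
    ref = min(leaves)
    n = len(leaves)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = leaves - side
        if not (2 <= len(side) <= n - 2):
            continue
        support = 100.0 * counts.get(side, 0) / denominator
        node.label = str(int(round(support)))
    return tree


def bootstrap_support(
    alignment: Alignment,
    config: BootstrapConfig,
    method: str = "k2p",
    outgroup_id: str | None = None,
) -> dendropy.Tree:
    """Point NJ tree with bootstrap supports on internal nodes.

    The point tree is built from the full alignment, rooted on the
    outgroup when given, and each internal edge is labeled with the
    percentage of completed replicates containing its bipartition.
    """
    dm = distance_matrix(alignment, method=method)
    tree = nj_tree(dm)
    if outgroup_id is not None:
        tree = root_with_outgroup(tree, outgroup_id)
    counts, completed = bootstrap_bipartition_counts(alignment, config, method=method)
    return attach_support(tree, counts, completed)


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=False,
        unquoted_underscores=True,
    )


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
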