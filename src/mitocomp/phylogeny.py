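"""Distance-based phylogeny: neighbor joining, bootstrap, outgroup rooting.

Neighbor joining (Saitou & Nei 1987) agglomerates taxa by minimising the
Q-criterion and is exact on additive distance matrices: if the input
distances are path lengths on a tree, that tree (topology and branch
lengths) is recovered.  Nonparametric bootstrap support is computed by
resampling alignment columns with replacement, recomputing the K2P
distance matrix and NJ tree per replicate, and scoring each internal
bipartition of the full-data tree by the percentage of replicates that
contain it.  Trees are dendropy objects; Newick output carries supports
as internal node labels.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import dendropy
import numpy as np

from .divergence import (
    DistanceMatrix,
    SaturationError,
    encode_sequence,
    k2p_matrix_from_encoded,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Classic NJ on a symmetric distance matrix (n >= 3).

    Deterministic: ties in the Q-criterion break to the lexicographically
    lowest pair of cluster representatives (a cluster is represented by
    its lexicographically smallest leaf label).  Negative branch-length
    estimates are clamped to zero with a logged flag.
    """
    n = len(dm)
    if n < 3:
        raise ValueError(f"neighbor joining needs >= 3 taxa, got {n}")

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)

    nodes: list[dendropy.Node] = []
    reprs: list[str] = []
    for label in dm.labels:
        node = dendropy.Node(taxon=tns.new_taxon(label))
        nodes.append(node)
        reprs.append(label)
    D = dm.values.copy()
    active = list(range(n))
    clamped: list[str] = []

    while len(active) > 3:
        r = len(active)
        R = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        best_q = np.inf
        for i, j in itertools.combinations(active, 2):
            q = (r - 2) * D[i, j] - R[i] - R[j]
            key = tuple(sorted((reprs[i], reprs[j])))
            if q < best_q - 1e-12 or (
                abs(q - best_q) <= 1e-12 and best is not None and key < best[2]
            ):
                best_q = q
                best = (i, j, key)
        i, j, _ = best
        li = 0.5 * D[i, j] + (R[i] - R[j]) / (2.0 * (r - 2))
        lj = D[i, j] - li
        parent = dendropy.Node()
        for child, length in ((nodes[i], li), (nodes[j], lj)):
            parent.add_child(child)
            if length < -1e-12:
                clamped.append("edge above " + reprs[i if child is nodes[i] else j])
            child.edge.length = max(length, 0.0)
        # distances from the new cluster to all remaining clusters
        newD = {k: 0.5 * (D[i, k] + D[j, k] - D[i, j]) for k in active if k not in (i, j)}
        nodes[i] = parent
        reprs[i] = min(reprs[i], reprs[j])
        for k, v in newD.items():
            D[i, k] = D[k, i] = v
        active.remove(j)

    # final three clusters join at an unrooted (trifurcating) central node
    a, b, c = sorted(active, key=lambda k: reprs[k])
    center = dendropy.Node()
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, length in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[idx])
        if length < -1e-12:
            clamped.append("edge above " + reprs[idx])
        nodes[idx].edge.length = max(length, 0.0)

    tree.seed_node = center
    tree.is_rooted = False
    if clamped:
        logger.warning("NJ clamped %d negative branch length(s): %s",
                       len(clamped), ", ".join(clamped))
        tree.clamped_edges = clamped
    return tree


# ---------------------------------------------------------------------------
# Bipartitions and bootstrap
# ---------------------------------------------------------------------------

def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial unrooted splits of a tree, each canonicalised as the
    side NOT containing the alphabetically first taxon."""
    labels = sorted(t.label for t in tree.taxon_namespace)
    anchor = labels[0]
    all_set = frozenset(labels)
    splits: set[frozenset[str]] = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if anchor in side:
            side = all_set - side
        if 1 < len(side) < len(all_set) - 1:
            splits.add(side)
    return splits


@dataclass
class BootstrapResult:
    """NJ tree of the full data with per-node bootstrap support."""

    tree: dendropy.Tree
    support: dict[frozenset[str], float]
    replicates_kept: int
    replicates_dropped: int


def bootstrap_support(alignment: Mapping[str, str], replicates: int = 1000,
                      seed: int = 0) -> BootstrapResult:
    """Nonparametric bootstrap of the NJ tree on K2P distances.

    Columns are resampled with replacement per replicate; the per-replicate
    RNG stream is ``numpy.random.default_rng([seed, replicate_index])`` so
    results are reproducible and invariant to taxon input order (taxa are
    sorted internally).  Replicates whose distance matrix saturates are
    dropped; a warning is issued if more than 5% are lost.
    """
    if replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    labels = sorted(alignment)
    lengths = {len(alignment[l]) for l in labels}
    if len(lengths) != 1:
        raise ValueError("alignment sequences must have equal length")
    (L,) = lengths
    encoded = np.vstack([encode_sequence(alignment[l]) for l in labels])

    full_tree = neighbor_joining(k2p_matrix_from_encoded(labels, encoded))
    target_splits = tree_bipartitions(full_tree)
    hits = {s: 0 for s in target_splits}

    kept = dropped = 0
    for rep in range(replicates):
        rng = np.random.default_rng([seed, rep])
        cols = rng.integers(0, L, size=L)
        sample = encoded[:, cols]
        try:
            rep_tree = neighbor_joining(k2p_matrix_from_encoded(labels, sample))
        except (SaturationError, ValueError):
            dropped += 1
            continue
        kept += 1
        rep_splits = tree_bipartitions(rep_tree)
        for s in target_splits:
            if s in rep_splits:
                hits[s] += 1

    if kept == 0:
        raise SaturationError("all bootstrap replicates saturated")
    if dropped > 0.05 * replicates:
        warnings.warn(f"{dropped}/{replicates} bootstrap replicates dropped "
                      "(saturated distances)", stacklevel=2)
    support = {s: 100.0 * h / kept for s, h in hits.items()}
    annotate_support(full_tree, support)
    return BootstrapResult(tree=full_tree, support=support,
                           replicates_kept=kept, replicates_dropped=dropped)


def annotate_support(tree: dendropy.Tree, support: Mapping[frozenset[str], float]) -> None:
    """Write split supports onto internal node labels (whole percents)."""
    labels = sorted(t.label for t in tree.taxon_namespace)
    anchor = labels[0]
    all_set = frozenset(labels)
    for node in tree.postorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if anchor in side:
            side = all_set - side
        if side in support:
            node.label = f"{support[side]:.0f}"


# ---------------------------------------------------------------------------
# Rooting and IO
# ---------------------------------------------------------------------------

def root_on_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Root a tree on the branch leading to the outgroup taxon (midpoint of
    that branch).  Idempotent: an input already rooted there is returned
    unchanged (as a clone)."""
    tree = tree.clone(depth=1)
    leaf = None
    for lf in tree.leaf_node_iter():
        if lf.taxon is not None and lf.taxon.label == outgroup:
            leaf = lf
            break
    if leaf is None:
        raise KeyError(f"outgroup taxon {outgroup!r} not in tree")
    root = tree.seed_node
    if tree.is_rooted and len(root.child_nodes()) == 2 and leaf in root.child_nodes():
        return tree
    edge_len = leaf.edge.length if leaf.edge.length is not None else 0.0
    tree.reroot_at_edge(leaf.edge, length1=edge_len / 2.0, length2=edge_len / 2.0,
                        update_bipartitions=False)
    tree.is_rooted = True
    # collapse any unifurcation left behind by the reroot
    tree.suppress_unifurcations()
    return tree


def to_newick(tree: dendropy.Tree) -> str:
    """Newick string with supports as internal node labels."""
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()


def write_phylip_dm(dm: DistanceMatrix, path) -> None:
    """Square PHYLIP-style distance matrix writer."""
    lines = [str(len(dm))]
    for label, row in zip(dm.labels, dm.values):
        lines.append(label + "  " + "  ".join(f"{v:.6f}" for v in row))
    from pathlib import Path
    Path(path).write_text("\n".join(lines) + "\n")


def read_phylip_dm(path) -> DistanceMatrix:
    """Square PHYLIP-style distance matrix reader."""
    from pathlib import Path
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    n = int(lines[0].split()[0])
    labels, rows = [], []
    for line in lines[1:n + 1]:
        parts = line.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:n + 1]])
    return DistanceMatrix(labels=labels, values=np.array(rows))
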