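"""Neighbor-joining trees, non-parametric bootstrap, outgroup rooting.

The agglomeration is the classic Saitou-Nei algorithm: repeatedly join the
pair (i, j) minimizing Q(i,j) = (m-2) d(i,j) - r_i - r_j, with branch lengths
l_i = d(i,j)/2 + (r_i - r_j) / (2(m-2)). Ties in Q are broken by the lowest
(row, column) index pair, making the construction deterministic. Negative
branch-length estimates are clamped to zero by default (the common default of
mainstream distance-tree software); pass ``clamp_negative=False`` for the raw
estimates. On an additive matrix NJ recovers the generating topology and
branch lengths exactly.

Bootstrap supports are computed by resampling alignment columns with
replacement, rebuilding the NJ tree per replicate, and reporting for each
internal edge of the full-data tree the percentage of replicates containing
its bipartition. Replicates in which some pair has an undefined K2P distance
are dropped with a warning and the percentage denominator adjusted.

Tree storage, traversal and Newick serialization ride on dendropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import numpy as np

from .distance import (
    DistanceError,
    DistanceMatrix,
    SaturationError,
    encode_alignment,
    k2p_from_proportions,
)
from .seqio import LabeledAlignment

__all__ = ["PhylogenyError", "PhyloTree", "nj_tree", "bootstrap_nj", "root_tree"]


class PhylogenyError(ValueError):
    """Raised for invalid tree-building input."""


Bipartition = frozenset  # frozenset of leaf names on the side away from the reference leaf


@dataclass
class PhyloTree:
    """A tree over sequence ids with branch lengths in substitutions/site.

    ``supports`` maps normalized internal-edge bipartitions to bootstrap
    percentages; ``annotate_supports`` copies them onto internal node labels
    so they appear in Newick output.
    """

    tree: dendropy.Tree
    supports: dict[Bipartition, float] | None = None
    n_bootstrap_used: int | None = None
    n_bootstrap_dropped: int = 0

    @property
    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.taxon.label for l in self.tree.leaf_node_iter())

    def _normalize(self, side: frozenset[str]) -> Bipartition:
        all_leaves = self.leaf_names
        ref = min(all_leaves)
        return frozenset(all_leaves - side) if ref in side else frozenset(side)

    def bipartitions(self) -> set[Bipartition]:
        """Non-trivial bipartitions, each as the normalized leaf-name set."""
        n = len(self.leaf_names)
        out: set[Bipartition] = set()
        for edge in self.tree.preorder_edge_iter():
            if edge.tail_node is None or edge.head_node.is_leaf():
                continue
            side = frozenset(l.taxon.label for l in edge.head_node.leaf_iter())
            if 2 <= len(side) <= n - 2:
                out.add(self._normalize(side))
        return out

    def annotate_supports(self, decimals: int = 0) -> None:
        if self.supports is None:
            return
        n = len(self.leaf_names)
        for edge in self.tree.preorder_edge_iter():
            if edge.tail_node is None or edge.head_node.is_leaf():
                continue
            side = frozenset(l.taxon.label for l in edge.head_node.leaf_iter())
            if not (2 <= len(side) <= n - 2):
                continue
            sup = self.supports.get(self._normalize(side))
            if sup is not None:
                edge.head_node.label = f"{sup:.{decimals}f}" if decimals else str(int(round(sup)))

    def total_length(self) -> float:
        return float(sum(e.length or 0.0 for e in self.tree.preorder_edge_iter()
                         if e.tail_node is not None))

    def to_newick(self) -> str:
        self.annotate_supports()
        return self.tree.as_string(schema="newick").strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


def _nj_from_matrix(ids: list[str], matrix: np.ndarray, clamp_negative: bool) -> dendropy.Tree:
    n = len(ids)
    taxon_ns = dendropy.TaxonNamespace(ids)
    nodes: list[dendropy.Node] = []
    for sid in ids:
        node = dendropy.Node(taxon=taxon_ns.get_taxon(sid))
        nodes.append(node)
    D = matrix.astype(float).copy()

    def _clamp(x: float) -> float:
        return max(0.0, x) if clamp_negative else x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        k = int(np.argmin(Q[iu]))  # first occurrence in row-major order = lowest (i, j)
        i, j = int(iu[0][k]), int(iu[1][k])
        d_ij = D[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d_ij - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = _clamp(li)
        parent.add_child(nodes[j])
        nodes[j].edge.length = _clamp(lj)
        dnew = 0.5 * (D[i, :] + D[j, :] - d_ij)
        keep = [x for x in range(m) if x not in (i, j)]
        D = np.vstack([D[keep][:, keep],
                       dnew[keep][None, :]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[x] for x in keep] + [parent]

    root = dendropy.Node()
    if len(nodes) == 3:
        d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
        lengths = [
            0.5 * (d01 + d02 - d12),
            0.5 * (d01 + d12 - d02),
            0.5 * (d02 + d12 - d01),
        ]
        for node, length in zip(nodes, lengths):
            root.add_child(node)
            node.edge.length = _clamp(length)
    else:  # exactly 2 remain only if the input had n == 2 (guarded upstream)
        root.add_child(nodes[0])
        nodes[0].edge.length = _clamp(D[0, 1] / 2)
        root.add_child(nodes[1])
        nodes[1].edge.length = _clamp(D[0, 1] / 2)
    tree = dendropy.Tree(taxon_namespace=taxon_ns, seed_node=root)
    tree.is_rooted = False
    return tree


def nj_tree(dm: DistanceMatrix, clamp_negative: bool = True) -> PhyloTree:
    """Neighbor-joining tree from a complete distance matrix.

    Deterministic: Q-ties are broken by the lowest (row, column) index pair.
    """
    if len(dm) < 3:
        raise PhylogenyError("neighbor-joining needs at least 3 taxa")
    if np.isnan(dm.values).any():
        raise PhylogenyError("distance matrix contains missing entries")
    return PhyloTree(_nj_from_matrix(list(dm.ids), dm.values, clamp_negative))


def _k2p_matrix_from_encoding(enc: np.ndarray) -> np.ndarray:
    """Dense K2P matrix from a coded alignment; raises on undefined pairs."""
    n = enc.shape[0]
    values = np.zeros((n, n), dtype=float)
    valid = enc != 255
    for i in range(n - 1):
        both = valid[i] & valid[i + 1:]
        nn = both.sum(axis=1)
        if (nn == 0).any():
            raise DistanceError("replicate pair with zero comparable sites")
        diff = both & (enc[i] != enc[i + 1:])
        ts = (diff & ((enc[i] >> 1) == (enc[i + 1:] >> 1))).sum(axis=1)
        tv = diff.sum(axis=1) - ts
        for k2, j in enumerate(range(i + 1, n)):
            d = k2p_from_proportions(ts[k2] / nn[k2], tv[k2] / nn[k2])
            values[i, j] = values[j, i] = d
    return values


def bootstrap_nj(aln: LabeledAlignment, n_replicates: int = 1000,
                 seed: int | None = None, clamp_negative: bool = True) -> PhyloTree:
    """Full-data NJ tree with bootstrap supports on its internal edges.

    Alignment columns are resampled with replacement ``n_replicates`` times;
    each replicate tree's bipartitions are tallied against the full-data
    tree. Replicates with an undefined pairwise distance are dropped (with a
    warning); supports are percentages of the replicates actually used.
    """
    if len(aln) < 3:
        raise PhylogenyError("bootstrap needs at least 3 sequences")
    enc = encode_alignment(aln)
    ids = list(aln.ids)
    full = PhyloTree(_nj_from_matrix(ids, _k2p_matrix_from_encoding(enc), clamp_negative))
    target = full.bipartitions()
    tally = {bp: 0 for bp in target}

    rng = np.random.default_rng(seed)
    n_sites = enc.shape[1]
    used = 0
    dropped = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, n_sites, size=n_sites)
        try:
            rep_matrix = _k2p_matrix_from_encoding(enc[:, cols])
        except (SaturationError, DistanceError):
            dropped += 1
            continue
        rep = PhyloTree(_nj_from_matrix(ids, rep_matrix, clamp_negative))
        rep_bps = rep.bipartitions()
        for bp in target:
            if bp in rep_bps:
                tally[bp] += 1
        used += 1
    if dropped:
        warnings.warn(
            f"{dropped} of {n_replicates} bootstrap replicates dropped "
            f"(undefined distances); supports use {used} replicates"
        )
    if used == 0:
        raise PhylogenyError("all bootstrap replicates had undefined distances")
    supports = {bp: 100.0 * c / used for bp, c in tally.items()}
    return PhyloTree(full.tree, supports=supports,
                     n_bootstrap_used=used, n_bootstrap_dropped=dropped)


def root_tree(tree: PhyloTree, outgroup_species: Iterable[str],
              labels: Mapping[str, str]) -> PhyloTree:
    """Root on the edge separating the outgroup leaves from the ingroup.

    The outgroup must form one side of a bipartition of the unrooted tree
    (monophyly in the unrooted sense); the separating edge is split at its
    midpoint. Bootstrap supports are re-mapped onto the rooted tree.
    """
    outgroup_species = set(outgroup_species)
    og_leaves = frozenset(sid for sid, sp in labels.items() if sp in outgroup_species)
    leaves = tree.leaf_names
    og = og_leaves & leaves
    if not og:
        raise PhylogenyError("no outgroup leaves present in the tree")
    if og == leaves:
        raise PhylogenyError("outgroup covers every leaf; nothing to root against")

    rooted = dendropy.Tree(tree.tree)  # deep clone
    rooted.is_rooted = False
    target_edge = None
    for edge in rooted.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        side = frozenset(l.taxon.label for l in edge.head_node.leaf_iter())
        if side == og or side == leaves - og:
            target_edge = edge
            break
    if target_edge is None:
        raise PhylogenyError(
            f"outgroup is not monophyletic in the unrooted tree; "
            f"no bipartition separates {sorted(og)} from the ingroup"
        )
    length = target_edge.length or 0.0
    rooted.reroot_at_edge(target_edge, length1=length / 2, length2=length / 2,
                          update_bipartitions=False)
    rooted.is_rooted = True
    return PhyloTree(rooted, supports=dict(tree.supports) if tree.supports else None,
                     n_bootstrap_used=tree.n_bootstrap_used,
                     n_bootstrap_dropped=tree.n_bootstrap_dropped)
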