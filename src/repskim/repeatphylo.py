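"""Phylogeny inference from comparative repeat clustering.

Each multi-species read cluster is a sample of one repeat family
across genomes. Within such a cluster, the number of similarity edges
observed between two species, relative to the number expected if
edges ignored species (random placement conditional on the cluster's
composition), measures how alike the two genomes' copies of that
repeat are:

    S_ij = O_ij / E_ij,   E_ij = M * 2 n_i n_j / (N (N - 1))

with n_i reads of species i in the cluster, N the cluster size, M its
edge count, and O_ij the observed inter-species edges. Inverting the
similarities gives per-cluster distance matrices; neighbor-joining
trees over the clusters that contain all species are summarized by a
majority-rule consensus. A second, independent view clusters species
hierarchically on the cluster-abundance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from skbio import TreeNode

from .graphclust import ComparativeResult, RepeatCluster


@dataclass
class SpeciesMatrix:
    """Symmetric species x species similarity or distance matrix."""

    species: list[str]
    values: np.ndarray
    kind: str = "similarity"  # or "distance"
    cluster_id: int | str | None = None
    complete: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species, columns=self.species)


def edge_similarity_matrix(
    cluster: RepeatCluster, species: list[str]
) -> SpeciesMatrix:
    """Observed/expected inter-species edge similarity of one cluster.

    The expectation places the cluster's M edges uniformly over all
    read pairs, so E_ij is M times the probability a random pair
    spans species i and j. The matrix is flagged complete only when
    every species has reads in the cluster and every pair has at
    least one observed edge.
    """
    n = {s: cluster.species_counts.get(s, 0) for s in species}
    N = cluster.size
    M = cluster.n_edges
    k = len(species)
    S = np.full((k, k), np.nan)
    complete = all(n[s] > 0 for s in species)
    for i, si in enumerate(species):
        for j in range(i + 1, k):
            sj = species[j]
            if n[si] == 0 or n[sj] == 0 or M == 0 or N < 2:
                continue
            e_ij = M * 2.0 * n[si] * n[sj] / (N * (N - 1))
            o_ij = cluster.inter_species_edges.get(tuple(sorted((si, sj))), 0)
            S[i, j] = S[j, i] = o_ij / e_ij
            if o_ij == 0:
                complete = False
    return SpeciesMatrix(species=list(species), values=S, kind="similarity",
                         cluster_id=cluster.cluster_id, complete=complete)


def to_distance(S: SpeciesMatrix) -> SpeciesMatrix:
    """Inverse-similarity distances, D_ij = 1 / S_ij."""
    k = len(S.species)
    off = ~np.eye(k, dtype=bool)
    vals = S.values[off]
    if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError(
            "similarity matrix has zero/undefined entries; exclude incomplete clusters"
        )
    D = np.zeros_like(S.values)
    D[off] = 1.0 / S.values[off]
    return SpeciesMatrix(species=list(S.species), values=D, kind="distance",
                         cluster_id=S.cluster_id, complete=S.complete)


def neighbor_joining(D: SpeciesMatrix, clamp_negative: bool = False) -> TreeNode:
    """Standard neighbor joining (Saitou-Nei, Q-criterion).

    Produces an unrooted tree (trifurcating root) with branch lengths;
    ties in the Q matrix are broken toward the smallest species
    indices, so output is deterministic. Negative branch lengths are
    kept unless ``clamp_negative``.
    """
    species = list(D.species)
    if len(species) < 3:
        raise ValueError("neighbor joining needs >= 3 species")
    d = np.array(D.values, dtype=float)
    if not np.allclose(d, d.T, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")
    np.fill_diagonal(d, 0.0)
    nodes = [TreeNode(name=s) for s in species]

    def _edge(x: float) -> float:
        return max(0.0, x) if clamp_negative else x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        a, b = nodes[i], nodes[j]
        a.length, b.length = _edge(li), _edge(lj)
        new = TreeNode(children=[a, b])
        dn = np.zeros(m - 2)
        keep = [x for x in range(m) if x not in (i, j)]
        for t, kx in enumerate(keep):
            dn[t] = 0.5 * (d[i, kx] + d[j, kx] - d[i, j])
        d = d[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = dn
        d[:-1, -1] = dn
        nodes = [nodes[x] for x in keep] + [new]
    # resolve the final three nodes around the central vertex
    (a, b, c) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    a.length, b.length, c.length = _edge(la), _edge(lb), _edge(lc)
    return TreeNode(children=[a, b, c])


# ---------------------------------------------------------------------------
# splits and consensus


def tree_splits(tree: TreeNode, with_lengths: bool = False):
    """Nontrivial splits of a tree, as frozensets of the side that
    does not contain the lexicographically first taxon.

    With ``with_lengths`` returns ``{split: edge_length}``; in a
    rooted binary tree the two root children describe the same split
    and their lengths are summed (the root subdivides that edge).
    """
    taxa = frozenset(t.name for t in tree.tips())
    ref = min(taxa)
    n = len(taxa)
    out: dict[frozenset, float] = {}
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            continue
        below = frozenset(t.name for t in node.tips())
        side = below if ref not in below else taxa - below
        if not (2 <= len(side) <= n - 2):
            continue
        length = float(node.length or 0.0)
        out[side] = out.get(side, 0.0) + length
    return out if with_lengths else set(out)


def _compatible(a: frozenset, b: frozenset) -> bool:
    return a <= b or b <= a or not (a & b)


def consensus_tree(trees: list[TreeNode], support_threshold: float = 0.5) -> TreeNode:
    """Greedy majority-rule consensus of trees on one leaf set.

    Splits present in more than ``support_threshold`` of the trees are
    retained in order of decreasing frequency, skipping any split
    incompatible with those already accepted. Each consensus branch
    gets the mean length of that edge over the supporting trees; leaf
    branches average over all trees. Split supports (fractions) are
    stored in ``node.support`` and written as internal node labels.
    """
    if not trees:
        raise ValueError("no trees given")
    taxa = frozenset(t.name for t in trees[0].tips())
    for t in trees[1:]:
        if frozenset(x.name for x in t.tips()) != taxa:
            raise ValueError("trees have mismatched leaf sets")
    n_trees = len(trees)
    split_lengths: dict[frozenset, list[float]] = {}
    for t in trees:
        for s, ln in tree_splits(t, with_lengths=True).items():
            split_lengths.setdefault(s, []).append(ln)
    leaf_lengths = {
        name: [] for name in taxa
    }
    for t in trees:
        for tip in t.tips():
            leaf_lengths[tip.name].append(float(tip.length or 0.0))

    candidates = sorted(
        ((len(lens) / n_trees, s) for s, lens in split_lengths.items()),
        key=lambda fs: (-fs[0], -len(fs[1]), sorted(fs[1])),
    )
    accepted: list[tuple[frozenset, float]] = []
    for freq, s in candidates:
        if freq <= support_threshold:
            continue
        if all(_compatible(s, a) for a, _ in accepted):
            accepted.append((s, freq))

    ref = min(taxa)
    rest = frozenset(taxa - {ref})
    # nest accepted clusters (all subsets of `rest`) inside each other
    nodes: dict[frozenset, TreeNode] = {}
    for s, freq in accepted:
        node = TreeNode()
        node.support = freq  # written as the internal-node label
        node.length = float(np.mean(split_lengths[s]))
        nodes[s] = node
    root_inner = TreeNode()
    root_inner.length = 0.0
    containers = sorted(nodes, key=len, reverse=True)

    def _parent_of(item: frozenset) -> TreeNode:
        best = None
        for c in containers:
            if item < c and (best is None or len(c) < len(best)):
                best = c
        return nodes[best] if best is not None else root_inner

    for s in containers:
        _parent_of(s).append(nodes[s])
    for name in sorted(rest):
        leaf = TreeNode(name=name)
        leaf.length = float(np.mean(leaf_lengths[name]))
        _parent_of(frozenset([name])).append(leaf)
    ref_leaf = TreeNode(name=ref)
    ref_leaf.length = float(np.mean(leaf_lengths[ref]))
    root = TreeNode(children=[ref_leaf, root_inner])
    return root


# ---------------------------------------------------------------------------
# pipeline helpers


def repeat_similarity_trees(
    result: ComparativeResult,
    species: list[str] | None = None,
    max_clusters: int = 100,
) -> tuple[list[TreeNode], list[int]]:
    """NJ trees for the complete-matrix clusters among the largest.

    Only the ``max_clusters`` largest clusters are considered, and of
    those only clusters whose similarity matrix is complete (reads
    and inter-species edges for every species pair) yield a tree.
    Returns the trees and the contributing cluster ids.
    """
    if species is None:
        species = sorted(result.sampled_counts)
    trees, used = [], []
    for c in result.clusters[:max_clusters]:
        S = edge_similarity_matrix(c, species)
        if not S.complete:
            continue
        D = to_distance(S)
        trees.append(neighbor_joining(D))
        used.append(c.cluster_id)
    return trees, used


def abundance_dendrogram(
    abundance: pd.DataFrame,
    min_proportion: float = 0.01,
    proportions: dict | None = None,
) -> TreeNode:
    """Hierarchical clustering of species on the abundance matrix.

    Rows (clusters) are filtered at ``min_proportion`` percent —
    using the supplied overall cluster proportions when given,
    otherwise each row's maximum — then species are joined by
    complete linkage on Euclidean distances between their abundance
    profiles. Returns a rooted dendrogram with heights as branch
    lengths.
    """
    if abundance.shape[1] < 2:
        raise ValueError("need >= 2 species")
    if proportions is not None:
        keep = [cid for cid in abundance.index if proportions.get(cid, 0.0) > min_proportion]
        mat = abundance.loc[keep]
    else:
        mat = abundance[abundance.max(axis=1) > min_proportion]
    if mat.empty:
        raise ValueError("no clusters above the proportion threshold")
    species = list(mat.columns)
    X = mat.to_numpy().T  # species x clusters
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method="complete")
    root_node, _ = hierarchy.to_tree(Z, rd=False), None

    def _convert(cn, parent_height: float | None) -> TreeNode:
        if cn.is_leaf():
            node = TreeNode(name=species[cn.id])
            node.length = float(parent_height or 0.0)
            return node
        node = TreeNode(children=[
            _convert(cn.get_left(), cn.dist),
            _convert(cn.get_right(), cn.dist),
        ])
        node.length = float((parent_height - cn.dist) if parent_height is not None else 0.0)
        node.height = float(cn.dist)
        return node

    return _convert(root_node, None)


def write_phylip_square(D: SpeciesMatrix, path) -> None:
    """Square PHYLIP distance-matrix format."""
    with open(path, "w") as fh:
        fh.write(f"{len(D.species)}\n")
        for i, sp in enumerate(D.species):
            row = " ".join(f"{x:.6f}" for x in D.values[i])
            fh.write(f"{sp:<10s} {row}\n")


def write_newick(tree: TreeNode, path) -> None:
    import io as _io

    buf = _io.StringIO()
    tree.write(buf)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
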