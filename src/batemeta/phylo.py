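"""Ultrametric trees and phylogenetic correlation matrices.

A species-by-species divergence-time matrix (e.g. exported from TimeTree)
is clustered with UPGMA into an ultrametric tree, and any ultrametric tree
is converted into the Brownian-motion expected-correlation matrix used as
the phylogenetic random-effect structure: after scaling tree depth to 1,
entry (i, j) is the fraction of the root-to-tip path the two species share
(root to their most recent common ancestor).

UPGMA ties are broken by merging the pair with the lowest label indices, so
trees are reproducible; polytomies arising from tied divergence times are
therefore resolved deterministically into binary nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "DivergenceMatrix",
    "PhyloCorrelationMatrix",
    "read_divergence_matrix",
    "upgma",
    "is_ultrametric",
    "tree_depth",
    "phylo_correlation",
    "prune_and_align",
    "read_tree",
    "write_tree",
]

_ULTRAMETRIC_RTOL = 1e-9


@dataclass(frozen=True)
class DivergenceMatrix:
    """Symmetric pairwise divergence times (million years) between species."""

    labels: list
    distances: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.distances, dtype=float)
        labels = list(self.labels)
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate species labels")
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(labels):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        off = d[~np.eye(len(labels), dtype=bool)]
        if len(off) and np.any(off <= 0):
            raise ValueError("off-diagonal divergence times must be positive")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "distances", d)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class PhyloCorrelationMatrix:
    """Expected trait correlations between species under Brownian motion."""

    labels: list
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        labels = list(self.labels)
        if v.shape != (len(labels), len(labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("correlation matrix diagonal must be 1")
        if np.linalg.eigvalsh(v).min() < -1e-8:
            raise ValueError("correlation matrix is not positive semidefinite")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", v)

    def submatrix(self, labels) -> "PhyloCorrelationMatrix":
        idx = [self.labels.index(l) for l in labels]
        return PhyloCorrelationMatrix(list(labels), self.values[np.ix_(idx, idx)])


def read_divergence_matrix(path: str | Path, delimiter: str = ",") -> DivergenceMatrix:
    """Read a delimited divergence matrix with a header row of species labels."""
    df = pd.read_csv(path, sep=delimiter, index_col=0, encoding="utf-8")
    return DivergenceMatrix(list(df.columns), df.to_numpy(dtype=float))


def upgma(matrix: DivergenceMatrix) -> dendropy.Tree:
    """Cluster a divergence matrix into an ultrametric tree.

    Standard unweighted pair-group agglomeration: repeatedly merge the two
    closest clusters at a node of height d/2, updating distances by the
    cluster-size-weighted arithmetic mean.  Ties go to the pair with the
    lowest label indices.
    """
    n = len(matrix)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    tns = dendropy.TaxonNamespace(matrix.labels)
    nodes: dict[int, dendropy.Node] = {
        i: dendropy.Node(taxon=tns.get_taxon(lab)) for i, lab in enumerate(matrix.labels)
    }
    heights = {i: 0.0 for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    d = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = matrix.distances[i, j]
    active = list(range(n))
    next_id = n
    while len(active) > 1:
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                key = (i, j) if i < j else (j, i)
                if best is None or d[key] < best[0]:
                    best = (d[key], i, j)
        dist, i, j = best
        h = dist / 2.0
        parent = dendropy.Node()
        for child in (i, j):
            node = nodes[child]
            node.edge.length = h - heights[child]
            parent.add_child(node)
        nodes[next_id] = parent
        heights[next_id] = h
        sizes[next_id] = sizes[i] + sizes[j]
        for k in active:
            if k in (i, j):
                continue
            dik = d[(min(i, k), max(i, k))]
            djk = d[(min(j, k), max(j, k))]
            d[(min(next_id, k), max(next_id, k))] = (
                sizes[i] * dik + sizes[j] * djk
            ) / (sizes[i] + sizes[j])
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=nodes[active[0]])
    tree.is_rooted = True
    return tree


def _leaf_depths(tree: dendropy.Tree) -> dict:
    return {leaf.taxon.label: leaf.distance_from_root() for leaf in tree.leaf_node_iter()}


def tree_depth(tree: dendropy.Tree) -> float:
    """Root-to-tip path length (the tree must be ultrametric)."""
    depths = np.array(list(_leaf_depths(tree).values()))
    return float(depths.max())


def is_ultrametric(tree: dendropy.Tree, rtol: float = _ULTRAMETRIC_RTOL) -> bool:
    depths = np.array(list(_leaf_depths(tree).values()))
    scale = depths.max()
    if scale <= 0:
        return False
    return bool(np.all(np.abs(depths - scale) <= rtol * scale))


def phylo_correlation(tree: dendropy.Tree) -> PhyloCorrelationMatrix:
    """Brownian-motion expected correlations from an ultrametric tree.

    Depth is scaled to 1; corr(i, j) is the root-to-MRCA path fraction the
    two tips share.  A star tree gives the identity matrix.
    """
    if not is_ultrametric(tree):
        raise ValueError("tree is not ultrametric")
    depth = tree_depth(tree)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    corr = np.eye(n)
    # single post/pre-order pass: for every internal node, tips in distinct
    # child subtrees coalesce exactly there
    root_dist = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0
        root_dist[node] = (root_dist[parent] + edge) if parent is not None else 0.0
    tips_below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tips_below[node] = [index[node.taxon.label]]
            continue
        child_sets = [tips_below[c] for c in node.child_nodes()]
        shared = root_dist[node] / depth
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                for i in child_sets[a]:
                    corr[i, child_sets[b]] = shared
                    corr[np.asarray(child_sets[b]), i] = shared
        tips_below[node] = [i for s in child_sets for i in s]
    return PhyloCorrelationMatrix(labels, corr)


def prune_and_align(tree: dendropy.Tree, species) -> tuple[dendropy.Tree, dict]:
    """Restrict a tree to the listed tips and map species names to matrix rows.

    Branch lengths are preserved (unbranched internal paths are fused), so
    correlations among retained species are unchanged.
    """
    species = list(species)
    tip_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = [s for s in species if s not in tip_labels]
    if missing:
        raise ValueError(f"species not in tree: {missing}")
    pruned = tree.extract_tree_with_taxa_labels(labels=set(species))
    pruned.is_rooted = True
    order = [leaf.taxon.label for leaf in pruned.leaf_node_iter()]
    return pruned, {lab: i for i, lab in enumerate(order)}


def read_tree(source: str | Path) -> dendropy.Tree:
    """Read a newick tree from a path or a newick string; quoted labels are unquoted."""
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
    )
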