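"""Phylogenetic tree space: simulation, vectorization, ultrametric projection.

A rooted tree with L leaves is vectorized as its cophenetic vector — the
pairwise leaf-to-leaf path lengths in lexicographic leaf-pair order — giving
a point in R^N with N = L(L-1)/2 (4 leaves -> N=6, 8 leaves -> N=28).
Ultrametric (clock-like) trees satisfy the three-point condition and their
cophenetic vectors lie on a tropical hyperplane, which is what makes the
minimized linear-regression objective vanish on coalescent data.

Generators cover the study conditions: Yule-topology branching trees with
i.i.d. exponential edge lengths (non-clock-like), Kingman coalescent trees
(ultrametric), multi-species-coalescent gene trees inside a species tree,
and Gaussian point clouds.  The single-linkage projection returns the
subdominant ultrametric, which coincides with tropical projection onto
ultrametric tree space.
"""

from __future__ import annotations

import itertools
import random
from typing import Literal

import dendropy
import numpy as np
from dendropy.simulate import treesim
from scipy.cluster.hierarchy import cophenet, linkage

from .core import as_point_set, trop_norm

__all__ = [
    "sample_tree",
    "msc_gene_trees",
    "default_species_tree",
    "cophenetic_vector",
    "leaf_pair_labels",
    "sample_gaussian_points",
    "tree_data_matrix",
    "normalize_avg_norm",
    "single_linkage_ultrametric",
    "three_point_defect",
    "is_ultrametric_vector",
    "topology_string",
    "newick_read",
    "newick_write",
]


def _leaf_labels(n_leaves: int) -> list[str]:
    if n_leaves <= 26:
        return [chr(ord("A") + i) for i in range(n_leaves)]
    return [f"T{i + 1}" for i in range(n_leaves)]


def _py_rng(rng) -> random.Random:
    """Derive a seeded stdlib Random for dendropy from a numpy Generator."""
    rng = np.random.default_rng(rng)
    return random.Random(int(rng.integers(2**31)))


def sample_tree(
    kind: Literal["branching", "coalescent"], n_leaves: int, rng=None
) -> dendropy.Tree:
    """Sample one random tree on ``n_leaves`` labeled leaves.

    ``coalescent`` — Kingman coalescent (rate 1 per lineage pair), which is
    always ultrametric.  ``branching`` — rate-1 Yule pure-birth topology
    whose edges are then assigned i.i.d. Exp(1) lengths, so path lengths are
    not clock-like and the cophenetic vectors fall off the ultrametric
    hyperplane.
    """
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    rng = np.random.default_rng(rng)
    prng = _py_rng(rng)
    taxa = dendropy.TaxonNamespace(_leaf_labels(n_leaves))
    if kind == "coalescent":
        return treesim.pure_kingman_tree(
            taxon_namespace=taxa, pop_size=1.0, rng=prng
        )
    if kind == "branching":
        tree = treesim.birth_death_tree(
            birth_rate=1.0,
            death_rate=0.0,
            num_extant_tips=n_leaves,
            taxon_namespace=taxa,
            rng=prng,
        )
        for edge in tree.preorder_edge_iter():
            if edge.head_node is not tree.seed_node:
                edge.length = float(rng.exponential(1.0))
        tree.seed_node.edge.length = None
        return tree
    raise ValueError(f"unknown tree kind {kind!r}")


def _node_ages(tree: dendropy.Tree) -> dict:
    """Leaf-to-node path lengths measured from the tips (assumes clock)."""
    depth: dict = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0
        depth[node] = (depth[parent] if parent is not None else 0.0) + edge
    max_depth = max(depth[leaf] for leaf in tree.leaf_node_iter())
    return {node: max_depth - d for node, d in depth.items()}


def _assert_ultrametric(tree: dendropy.Tree, tol: float = 1e-9) -> None:
    depths = []
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    if max(depths) - min(depths) > tol:
        raise ValueError("species tree must be ultrametric")


def msc_gene_trees(
    species_tree: dendropy.Tree, n_genes: int, rng=None
) -> list[dendropy.Tree]:
    """Sample gene trees under the multi-species coalescent.

    One lineage per species; lineages coalesce at Kingman rate within each
    species-tree branch (population size 1 in coalescent units) and
    unmerged lineages are passed rootward, so gene divergences are never
    younger than the species divergences.  Gene-tree leaves are relabeled
    with the species labels.
    """
    if n_genes < 1:
        raise ValueError("need at least one gene tree")
    _assert_ultrametric(species_tree)
    prng = _py_rng(rng)
    mapping = dendropy.TaxonNamespaceMapping.create_contained_taxon_mapping(
        species_tree.taxon_namespace, 1
    )
    genes = []
    for _ in range(n_genes):
        gt = treesim.contained_coalescent_tree(
            containing_tree=species_tree,
            gene_to_containing_taxon_map=mapping,
            default_pop_size=1.0,
            rng=prng,
        )
        for leaf in gt.leaf_node_iter():
            leaf.taxon.label = mapping[leaf.taxon].label
        genes.append(gt)
    return genes


def default_species_tree(internal_branch: float = 1.0) -> dendropy.Tree:
    """Caterpillar-with-cherries 8-leaf species tree used in the
    species-tree estimation study, topology (((((F,E),(H,G)),(D,C)),B),A).

    Consecutive divergences are spaced by ``internal_branch`` coalescent
    units and leaf edges are extended to make the tree ultrametric.
    """
    b = float(internal_branch)
    newick = (
        f"(((((F:{b},E:{b}):{b},(H:{b},G:{b}):{b}):{b},"
        f"(D:{b},C:{b}):{2 * b}):{b},B:{4 * b}):{b},A:{5 * b});"
    )
    return dendropy.Tree.get(data=newick, schema="newick")


def leaf_pair_labels(labels) -> list[str]:
    """Column names "A|B", "A|C", ... for the cophenetic coordinates."""
    labels = sorted(labels)
    return [f"{a}|{b}" for a, b in itertools.combinations(labels, 2)]


def cophenetic_vector(tree: dendropy.Tree) -> np.ndarray:
    """Pairwise leaf-to-leaf path lengths, lexicographic leaf-pair order.

    The raw vector is nonnegative; canonicalization onto the sum-zero
    representative is left to the point-set constructors since every
    objective is invariant under it.
    """
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda tx: tx.label)
    if len(taxa) < 3:
        raise ValueError("need at least 3 leaves")
    return np.array(
        [
            pdm.patristic_distance(a, b)
            for a, b in itertools.combinations(taxa, 2)
        ],
        dtype=float,
    )


def tree_data_matrix(trees) -> np.ndarray:
    """Stack cophenetic vectors of trees sharing a leaf set into (K, N)."""
    return np.array([cophenetic_vector(t) for t in trees])


def sample_gaussian_points(n_dim: int, n_samples: int, rng=None) -> np.ndarray:
    """K i.i.d. standard-normal points in R^N, canonicalized row-wise."""
    if n_dim < 2 or n_samples < 1:
        raise ValueError("need n_dim >= 2 and n_samples >= 1")
    rng = np.random.default_rng(rng)
    return as_point_set(rng.standard_normal((n_samples, n_dim)))


def normalize_avg_norm(X) -> np.ndarray:
    """Scale a point set so the mean tropical norm of its rows is 1."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    norms = X.max(axis=1) - X.min(axis=1)
    mean = norms.mean()
    if mean <= 0:
        raise ValueError("cannot normalize an all-zero dataset")
    return X / mean


def _n_leaves_from_vector(n_entries: int) -> int:
    n_leaves = int(round((1 + np.sqrt(1 + 8 * n_entries)) / 2))
    if n_leaves * (n_leaves - 1) // 2 != n_entries:
        raise ValueError(
            f"vector length {n_entries} is not a leaf-pair count L(L-1)/2"
        )
    return n_leaves


def three_point_defect(v) -> float:
    """Worst violation of the ultrametric three-point condition.

    For every leaf triple the largest of the three pairwise distances must
    be attained (at least) twice; returns the maximal gap between the top
    two values over all triples (0 for an ultrametric vector).  Invariant
    under adding a constant to all entries.
    """
    v = np.asarray(v, dtype=float)
    n_leaves = _n_leaves_from_vector(v.shape[0])
    idx = {
        pair: a
        for a, pair in enumerate(itertools.combinations(range(n_leaves), 2))
    }
    worst = 0.0
    for a, b, c in itertools.combinations(range(n_leaves), 3):
        d = sorted([v[idx[(a, b)]], v[idx[(a, c)]], v[idx[(b, c)]]])
        worst = max(worst, d[2] - d[1])
    return worst


def is_ultrametric_vector(v, tol: float = 1e-9) -> bool:
    return three_point_defect(v) <= tol


def single_linkage_ultrametric(
    v, labels=None
) -> tuple[np.ndarray, dendropy.Tree]:
    """Subdominant ultrametric of a dissimilarity vector via single linkage.

    Single-linkage merge heights give the largest ultrametric below the
    input (entrywise), which coincides with the tropical projection onto
    ultrametric tree space.  Returns the projected vector (same pair order
    and additive gauge as the input — entries may be negative for canonical
    inputs) and the corresponding rooted ultrametric tree, built in a
    shifted-positive gauge with node ages at half the merge heights.
    """
    v = np.asarray(v, dtype=float)
    n_leaves = _n_leaves_from_vector(v.shape[0])
    if labels is None:
        labels = _leaf_labels(n_leaves)
    labels = sorted(labels)
    # single linkage commutes with adding a constant to every entry, so a
    # shift into the positive range changes nothing but the gauge
    shift = min(0.0, float(v.min()) - 1.0)
    Z = linkage(v - shift, method="single")
    u = cophenet(Z) + shift

    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes, ages = [], []
    for label in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
        ages.append(0.0)
    for left, right, height, _ in Z:
        parent = dendropy.Node()
        age = height / 2.0
        for child_idx in (int(left), int(right)):
            child = nodes[child_idx]
            child.edge.length = age - ages[child_idx]
            parent.add_child(child)
        nodes.append(parent)
        ages.append(age)
    tree.seed_node = nodes[-1]
    return u, tree


def topology_string(tree: dendropy.Tree) -> str:
    """Canonical Newick topology string (no branch lengths).

    Children are ordered by their smallest descendant leaf label, so
    topologically identical trees map to identical strings.
    """

    def walk(node) -> tuple[str, str]:
        if node.is_leaf():
            return node.taxon.label, node.taxon.label
        subs = sorted(walk(child) for child in node.child_nodes())
        return subs[0][0], "(" + ",".join(s for _, s in subs) + ")"

    return walk(tree.seed_node)[1] + ";"


def newick_read(path) -> dendropy.Tree:
    """Read a rooted tree from a Newick file."""
    return dendropy.Tree.get(path=str(path), schema="newick")


def newick_write(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick")
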