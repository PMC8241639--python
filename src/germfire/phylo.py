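"""Phylogenetic signal of binary germination responses: Blomberg's K.

K compares the variance of phylogenetically independent contrasts implied by
the tree with the raw trait variance, scaled so that K = 1 matches the
expectation under Brownian motion on that tree.  With trait vector x, tree
covariance matrix V (shared root-to-MRCA branch length between tips) and GLS
ancestral mean a = (1'V^-1 x)/(1'V^-1 1):

    MSE0 = (x - a)'(x - a) / (n - 1)
    MSE  = (x - a)' V^-1 (x - a) / (n - 1)
    K    = (MSE0 / MSE) / [(tr V - n / (1'V^-1 1)) / (n - 1)]

Significance is assessed by shuffling trait values across tips; binary
response/no-response traits are treated as 0/1 values, the common practice
for this statistic.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import Mapping

import dendropy
import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "Tree",
    "KResult",
    "parse_newick",
    "write_newick",
    "tip_labels",
    "is_ultrametric",
    "phylo_vcv",
    "blomberg_k",
    "k_permutation_test",
    "substitute_taxa",
]

Tree = dendropy.Tree


@dataclass(frozen=True)
class KResult:
    K: float
    p_value: float
    n_permutations: int
    seed: int
    ultrametric: bool


def parse_newick(text: str) -> Tree:
    """Parse a Newick string into a rooted tree with branch lengths."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as e:  # dendropy raises assorted DataError subclasses
        raise ValueError(f"Newick parse error: {e}") from e
    labels = tip_labels(tree)
    if len(labels) != len(set(labels)):
        dups = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip label(s): {', '.join(dups)}")
    return tree


def write_newick(tree: Tree) -> str:
    s = tree.as_string(schema="newick", suppress_rooting=True)
    return s.strip()


def tip_labels(tree: Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _node_depths(tree: Tree) -> dict:
    """Distance from the root to every node (root edge ignored)."""
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            el = node.edge.length
            if el is None:
                raise ValueError("tree has an edge without a branch length")
            if el < 0:
                raise ValueError("negative branch length")
            depths[node] = depths[node.parent_node] + el
    return depths


def is_ultrametric(tree: Tree, rtol: float = 1e-6) -> bool:
    depths = _node_depths(tree)
    d = np.array([depths[l] for l in tree.leaf_node_iter()])
    return bool(np.allclose(d, d[0], rtol=rtol, atol=rtol * max(1.0, abs(d[0]))))


def phylo_vcv(tree: Tree) -> tuple[np.ndarray, list[str]]:
    """Tip-by-tip phylogenetic covariance matrix.

    V[i, j] is the branch length shared from the root down to the most recent
    common ancestor of tips i and j; the diagonal holds root-to-tip
    distances.  Returns ``(V, labels)`` with labels in tree leaf order.
    """
    depths = _node_depths(tree)
    leaves = list(tree.leaf_node_iter())
    labels = [l.taxon.label for l in leaves]
    index = {l: i for i, l in enumerate(leaves)}
    n = len(leaves)
    V = np.zeros((n, n))
    for leaf in leaves:
        V[index[leaf], index[leaf]] = depths[leaf]
    for node in tree.preorder_internal_node_iter():
        children = node.child_nodes()
        # leaves under each child subtree
        sets = [[index[l] for l in ch.leaf_iter()] for ch in children]
        d = depths[node]
        for a in range(len(sets)):
            for b in range(a + 1, len(sets)):
                for i in sets[a]:
                    for j in sets[b]:
                        V[i, j] = V[j, i] = d
    return V, labels


def _trait_array(trait: Mapping[str, float], labels: list[str]) -> np.ndarray:
    missing = [l for l in labels if l not in trait]
    extra = [l for l in trait if l not in labels]
    if missing or extra:
        raise ValueError(
            f"trait/tip mismatch (missing: {missing or '-'}, extra: {extra or '-'})"
        )
    x = np.array([float(trait[l]) for l in labels])
    if np.ptp(x) == 0:
        raise ValueError("K is undefined for a constant trait")
    return x


def _k_stats(V: np.ndarray):
    n = V.shape[0]
    try:
        cf = cho_factor(V)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"singular phylogenetic covariance matrix: {e}") from e
    ones = np.ones(n)
    w = cho_solve(cf, ones)          # V^-1 1
    denom = ones @ w                 # 1' V^-1 1
    expected = (np.trace(V) - n / denom) / (n - 1)
    return cf, w, denom, expected


def _k_many(X: np.ndarray, V: np.ndarray, cf, w, denom, expected) -> np.ndarray:
    """K for each row of trait matrix X (m, n) on a fixed tree."""
    n = V.shape[0]
    a = (X @ w) / denom
    R = X - a[:, None]
    mse0 = np.sum(R * R, axis=1) / (n - 1)
    VinvR = cho_solve(cf, R.T).T
    mse = np.sum(R * VinvR, axis=1) / (n - 1)
    return (mse0 / mse) / expected


def blomberg_k(tree: Tree, trait: Mapping[str, float]) -> float:
    """Blomberg's K for a (0/1 or continuous) trait on a rooted tree."""
    V, labels = phylo_vcv(tree)
    if len(labels) < 3:
        raise ValueError("K needs at least 3 tips")
    x = _trait_array(trait, labels)
    cf, w, denom, expected = _k_stats(V)
    return float(_k_many(x[None, :], V, cf, w, denom, expected)[0])


def k_permutation_test(
    tree: Tree,
    trait: Mapping[str, float],
    n_perm: int = 999,
    seed: int = 0,
) -> KResult:
    """Randomisation test for K: shuffle trait values across tips.

    One-sided p for signal stronger than random:
    p = (#{K_perm >= K_obs} + 1) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    V, labels = phylo_vcv(tree)
    if len(labels) < 3:
        raise ValueError("K needs at least 3 tips")
    x = _trait_array(trait, labels)
    cf, w, denom, expected = _k_stats(V)
    k_obs = float(_k_many(x[None, :], V, cf, w, denom, expected)[0])

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(x) for _ in range(n_perm)])
    k_perm = _k_many(perms, V, cf, w, denom, expected)
    p = (np.sum(k_perm >= k_obs) + 1) / (n_perm + 1)
    return KResult(
        K=k_obs,
        p_value=float(p),
        n_permutations=n_perm,
        seed=seed,
        ultrametric=is_ultrametric(tree),
    )


def substitute_taxa(tree: Tree, mapping: Mapping[str, str]) -> Tree:
    """Relabel tips (taxon surrogation); topology and lengths unchanged.

    Raises when an old label is absent or a new label would collide with an
    existing (unrenamed) tip or another new label.
    """
    clone = tree.clone(depth=1)
    labels = set(tip_labels(clone))
    missing = [o for o in mapping if o not in labels]
    if missing:
        raise ValueError(f"label(s) not in tree: {', '.join(sorted(missing))}")
    news = list(mapping.values())
    if len(news) != len(set(news)):
        raise ValueError("duplicate replacement labels")
    surviving = labels - set(mapping)
    collide = surviving & set(news)
    if collide:
        raise ValueError(
            f"replacement label(s) collide with existing tips: "
            f"{', '.join(sorted(collide))}"
        )
    # clone(depth=1) shares the taxon namespace; migrate to a fresh one so
    # renames do not leak back into the source tree
    clone.migrate_taxon_namespace(dendropy.TaxonNamespace())
    for leaf in clone.leaf_node_iter():
        if leaf.taxon.label in mapping:
            leaf.taxon.label = mapping[leaf.taxon.label]
    return clone
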