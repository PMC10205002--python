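"""Phylogenetic trees and the Brownian-motion covariance machinery.

The statistical stages of the pipeline (two-block PLS, generalized-least-squares
regression) all correct for shared ancestry by transforming trait matrices with
the inverse square root of the Brownian-motion (BM) trait covariance ``C``,
whose entry ``C[i, j]`` is the branch length shared by tips *i* and *j* on their
path from the root (their root-to-MRCA distance). This module reads and prunes
rooted Newick trees and builds ``C``, its symmetric whitener ``E`` with
``E @ C @ E.T = I``, and the GLS (phylogenetic) mean.

Trees are thin wrappers around :mod:`dendropy` trees; tip order is canonicalized
to the postorder tip sequence so that every matrix in the pipeline shares one
row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    ConditioningError,
    DuplicateTipLabelError,
    MissingBranchLengthError,
    MissingTaxonError,
    NewickParseError,
)

__all__ = [
    "Tree",
    "PhyloCovariance",
    "read_newick",
    "prune_to",
    "bm_covariance",
    "whitener",
    "gls_mean",
]

#: relative eigenvalue floor below which a covariance is treated as singular
EIG_FLOOR = 1e-12


@dataclass
class Tree:
    """A rooted phylogeny with branch lengths.

    ``tips`` is the postorder tip-label sequence and is the canonical row
    order for every trait matrix aligned to this tree. Branch lengths are in
    arbitrary (but consistent) time units.
    """

    _dtree: dendropy.Tree
    tips: list[str] = field(init=False)

    def __post_init__(self) -> None:
        labels = [lf.taxon.label for lf in self._dtree.leaf_node_iter()]
        if len(labels) < 2:
            raise NewickParseError("a tree needs at least 2 tips")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise DuplicateTipLabelError(f"duplicate tip labels: {dupes}")
        for edge in self._dtree.preorder_edge_iter():
            if edge.head_node is self._dtree.seed_node:
                continue  # the root stem may be absent; it is ignored anyway
            if edge.length is None:
                raise MissingBranchLengthError(
                    "every non-root edge must have a branch length"
                )
            if not np.isfinite(edge.length) or edge.length < 0:
                raise MissingBranchLengthError(
                    f"invalid branch length {edge.length!r}"
                )
        self.tips = labels

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        try:
            dt = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            if "Duplicate taxon labels" in str(exc):
                raise DuplicateTipLabelError(str(exc)) from exc
            raise NewickParseError(str(exc)) from exc
        return cls(dt)

    # -- basic queries -----------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def root_to_tip_distances(self) -> pd.Series:
        """Sum of branch lengths from the root to each tip (root stem excluded)."""
        d = {}
        for leaf in self._dtree.leaf_node_iter():
            dist = 0.0
            node = leaf
            while node.parent_node is not None:
                dist += node.edge.length or 0.0
                node = node.parent_node
            d[leaf.taxon.label] = dist
        return pd.Series(d).reindex(self.tips)

    def tip_distance_matrix(self) -> pd.DataFrame:
        """Pairwise patristic (path-length) distances between tips."""
        pdm = self._dtree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self._dtree.taxon_namespace}
        n = self.n_tips
        D = np.zeros((n, n))
        for i, a in enumerate(self.tips):
            for j, b in enumerate(self.tips):
                if i < j:
                    D[i, j] = D[j, i] = pdm.patristic_distance(taxa[a], taxa[b])
        return pd.DataFrame(D, index=self.tips, columns=self.tips)

    def to_newick(self) -> str:
        return self._dtree.as_string(schema="newick", suppress_rooting=True).strip()

    def is_ultrametric(self, rel_tol: float = 1e-8) -> bool:
        d = self.root_to_tip_distances().to_numpy()
        return bool(np.ptp(d) <= rel_tol * max(d.max(), 1.0))


@dataclass
class PhyloCovariance:
    """The BM trait covariance ``C`` for a fixed tip order, plus its whitener.

    ``C[i, j]`` is the root-to-MRCA shared path length of tips ``labels[i]``
    and ``labels[j]``; ``diag(C)`` holds root-to-tip distances. ``E`` is the
    symmetric inverse square root of ``C`` (computed lazily), which transforms
    BM-correlated species data into uncorrelated, unit-variance rows.
    """

    labels: list[str]
    C: np.ndarray
    _E: np.ndarray | None = field(default=None, repr=False)

    @property
    def E(self) -> np.ndarray:
        if self._E is None:
            self._E = whitener(self.C)
        return self._E


def read_newick(path: str | Path) -> Tree:
    """Read a single rooted Newick tree with branch lengths from ``path``."""
    path = Path(path)
    if not path.exists():
        raise NewickParseError(f"no such file: {path}")
    return Tree.from_newick(path.read_text())


def prune_to(tree: Tree, keep) -> Tree:
    """Restrict ``tree`` to the tip set ``keep``.

    Path lengths between retained tips are preserved exactly: unifurcations
    created by pruning are collapsed with their edge lengths summed.
    """
    keep = set(keep)
    missing = keep - set(tree.tips)
    if missing:
        raise MissingTaxonError(missing)
    if len(keep) < 2:
        raise MissingTaxonError(set(), "keep set (need >= 2 tips)")
    sub = tree._dtree.extract_tree_with_taxa_labels(
        labels=keep, suppress_unifurcations=True
    )
    return Tree(sub)


def bm_covariance(tree: Tree, order: list[str] | None = None) -> PhyloCovariance:
    """Brownian-motion trait covariance for the given tip order.

    ``C[i, j]`` = total branch length from the root to the MRCA of tips *i*
    and *j*; the root stem (if any) is excluded, so the clock starts at the
    root split. Computed by a single preorder pass: at an internal node of
    depth *d*, every tip pair split across two of its child subtrees shares
    exactly depth *d* of path.
    """
    if order is None:
        order = tree.tips
    if sorted(order) != sorted(tree.tips):
        raise AlignmentError(
            "requested order is not a permutation of the tree's tips"
        )
    idx = {lab: i for i, lab in enumerate(order)}
    n = len(order)
    C = np.zeros((n, n))

    # preorder depths; postorder tip sets per node
    depth = {tree._dtree.seed_node: 0.0}
    for node in tree._dtree.preorder_node_iter():
        if node.parent_node is not None:
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)

    tipsets: dict = {}
    for node in tree._dtree.postorder_node_iter():
        if node.is_leaf():
            i = idx[node.taxon.label]
            tipsets[node] = [i]
            C[i, i] = depth[node]
        else:
            children = [tipsets[ch] for ch in node.child_nodes()]
            d = depth[node]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            C[i, j] = C[j, i] = d
            tipsets[node] = [i for ch in children for i in ch]
    return PhyloCovariance(labels=list(order), C=C)


def whitener(C: np.ndarray, tol: float = EIG_FLOOR) -> np.ndarray:
    """Symmetric inverse square root ``E = U Λ^{-1/2} Uᵀ`` of an SPD matrix.

    Satisfies ``E @ C @ E.T = I`` and ``E = E.T``. Fails loudly (rather than
    regularizing) when any eigenvalue falls below ``tol`` times the largest.
    """
    C = np.asarray(C, dtype=float)
    if not np.allclose(C, C.T, atol=1e-10):
        raise ConditioningError("covariance matrix is not symmetric")
    w, U = np.linalg.eigh(C)
    if w[-1] <= 0 or w[0] <= tol * w[-1]:
        raise ConditioningError(
            f"covariance nearly singular (min/max eigenvalue = {w[0]:.3e}/{w[-1]:.3e})"
        )
    return (U * (1.0 / np.sqrt(w))) @ U.T


def gls_mean(C: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Generalized-least-squares (phylogenetic) mean of each column of ``Y``.

    ``a = (1ᵀ C⁻¹ 1)⁻¹ 1ᵀ C⁻¹ Y`` — the BM estimate of the trait value at the
    root, which is the correct centering constant for phylogenetically
    transformed data. Reduces to the arithmetic column mean when ``C ∝ I``.
    """
    C = np.asarray(C, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1 and C.shape[0] != 1:
        Y = Y.T
    if Y.shape[0] != C.shape[0]:
        raise AlignmentError(
            f"C is {C.shape[0]}x{C.shape[0]} but Y has {Y.shape[0]} rows"
        )
    ones = np.ones(C.shape[0])
    try:
        Ci1 = np.linalg.solve(C, ones)
        CiY = np.linalg.solve(C, Y)
    except np.linalg.LinAlgError as exc:
        raise ConditioningError("singular covariance in gls_mean") from exc
    return (ones @ CiY) / (ones @ Ci1)
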