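"""Phylogenetic two-block partial least squares.

Quantifies the covariation between two species-level trait blocks (e.g. the
CLR-transformed protein profiles and a lipid table) while correcting for
shared ancestry under a Brownian-motion model. Both blocks are centered at
their phylogenetic (GLS) mean and premultiplied by the whitener ``E`` of the
BM covariance; the first singular pair of the cross-covariance of the
transformed blocks defines one axis per block, and the statistic is

    r_PLS = |cor(X̃1 u, X̃2 v)|,

the correlation of the paired axis scores. Significance comes from a
permutation test that shuffles the rows of the transformed second block,
breaking the trait association while holding the phylogenetic structure (the
transform) fixed — the standard residual-randomization style null for
phylogenetically transformed data. The method is well suited to blocks with
many more variables than species, since only the p1×p2 cross-covariance is
ever decomposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import align_block, permutation_indices, resolve_cov
from .errors import DegenerateDataError, GlandcovError
from .treeops import PhyloCovariance, Tree, gls_mean

__all__ = ["PLSResult", "phylo_pls"]

#: permutations are processed in batches of this many to bound memory
_CHUNK = 256


@dataclass
class PLSResult:
    """First-axis summary of a two-block PLS.

    ``r_pls`` is the absolute correlation of the paired scores; loadings are
    unit vectors on the transformed (whitened, CLR where applicable)
    variables; scores are one value per species, in tree tip order. The sign
    convention makes ``cor(left_scores, right_scores) >= 0``.
    """

    r_pls: float
    p_value: float
    left_loadings: np.ndarray
    right_loadings: np.ndarray
    left_scores: np.ndarray
    right_scores: np.ndarray
    n_perm: int
    seed: int
    singular_values: np.ndarray = field(repr=False, default=None)
    perm_r: np.ndarray = field(repr=False, default=None)
    labels: list = field(default=None)


def _first_axis(X1t: np.ndarray, X2t: np.ndarray):
    """First singular triplet of the cross-covariance; returns (u, v, r, svals)."""
    n = X1t.shape[0]
    R12 = X1t.T @ X2t / (n - 1)
    U, s, Vt = np.linalg.svd(R12, full_matrices=False)
    u, v = U[:, 0], Vt[0]
    s1, s2 = X1t @ u, X2t @ v
    c = np.corrcoef(s1, s2)[0, 1]
    if c < 0:
        v, s2, c = -v, -s2, -c
    return u, v, s1, s2, abs(c), s


def _batched_r(X1t: np.ndarray, X2t: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """r_PLS for each row-permutation of X2t, in memory-bounded batches."""
    out = np.empty(perms.shape[0])
    for start in range(0, perms.shape[0], _CHUNK):
        P = perms[start : start + _CHUNK]
        X2p = X2t[P]  # (m, n, p2)
        R = np.einsum("na,mnb->mab", X1t, X2p) / (X1t.shape[0] - 1)
        U, _, Vt = np.linalg.svd(R)
        s1 = X1t @ U[:, :, 0].T  # (n, m)
        s2 = np.einsum("mnb,mb->nm", X2p, Vt[:, 0, :])
        s1c = s1 - s1.mean(axis=0)
        s2c = s2 - s2.mean(axis=0)
        num = (s1c * s2c).sum(axis=0)
        den = np.sqrt((s1c**2).sum(axis=0) * (s2c**2).sum(axis=0))
        out[start : start + P.shape[0]] = np.abs(num / den)
    return out


def phylo_pls(
    X1,
    X2,
    tree: Tree | PhyloCovariance,
    n_perm: int = 999,
    seed: int = 0,
) -> PLSResult:
    """Two-block PLS between ``X1`` and ``X2`` under BM phylogenetic correction.

    Parameters
    ----------
    X1, X2
        Species × variables blocks — DataFrames indexed by species label or
        arrays already in tree tip order. At least 4 species.
    tree
        The phylogeny (or a precomputed :class:`PhyloCovariance`).
    n_perm
        Number of row permutations for the significance test (>= 1). The
        p-value uses the ``(b + 1) / (n_perm + 1)`` convention, counting the
        observed statistic; ties count as exceedances.
    seed
        Governs the whole permutation stream; identical seeds give identical
        permutation order and hence identical p-values.
    """
    cov = resolve_cov(tree)
    labels = cov.labels
    A1 = align_block(X1, labels, "block 1")
    A2 = align_block(X2, labels, "block 2")
    n = len(labels)
    if n < 4:
        raise GlandcovError("phylo_pls needs at least 4 species")
    if n_perm < 1:
        raise GlandcovError("n_perm must be >= 1")

    E = cov.E
    X1t = E @ (A1 - gls_mean(cov.C, A1))
    X2t = E @ (A2 - gls_mean(cov.C, A2))
    for name, Xt in (("block 1", X1t), ("block 2", X2t)):
        if np.linalg.norm(Xt) < 1e-12:
            raise DegenerateDataError(f"{name} has no variance after centering")

    u, v, s1, s2, r_obs, svals = _first_axis(X1t, X2t)

    perms = permutation_indices(n, n_perm, seed)
    r_perm = _batched_r(X1t, X2t, perms)
    p = (1 + int(np.sum(r_perm >= r_obs - 1e-12))) / (n_perm + 1)

    return PLSResult(
        r_pls=float(r_obs),
        p_value=float(p),
        left_loadings=u,
        right_loadings=v,
        left_scores=s1,
        right_scores=s2,
        n_perm=n_perm,
        seed=seed,
        singular_values=svals,
        perm_r=r_perm,
        labels=list(labels),
    )
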