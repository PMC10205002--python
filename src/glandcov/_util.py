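"""Internal helpers shared by the statistical modules."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import AlignmentError
from .treeops import PhyloCovariance, Tree, bm_covariance


def align_block(X, labels: list[str], name: str = "block") -> np.ndarray:
    """Return ``X`` as a float ndarray whose rows follow ``labels``.

    DataFrames are reindexed by species label (exact, case-sensitive match
    required both ways); bare arrays are assumed already aligned and only
    shape-checked.
    """
    if isinstance(X, pd.DataFrame):
        missing = set(labels) - set(X.index)
        extra = set(X.index) - set(labels)
        if missing or extra:
            raise AlignmentError(
                f"{name}: species mismatch with tree "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )
        X = X.loc[labels]
    elif isinstance(X, pd.Series):
        return align_block(X.to_frame(), labels, name)
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] != len(labels):
        raise AlignmentError(
            f"{name}: {arr.shape[0]} rows but tree has {len(labels)} tips"
        )
    if not np.all(np.isfinite(arr)):
        raise AlignmentError(f"{name}: non-finite values present")
    return arr


def resolve_cov(tree_or_cov: Tree | PhyloCovariance) -> PhyloCovariance:
    if isinstance(tree_or_cov, PhyloCovariance):
        return tree_or_cov
    return bm_covariance(tree_or_cov)


def permutation_indices(n: int, n_perm: int, seed: int) -> np.ndarray:
    """Deterministic (n_perm, n) array of row permutations for a seed."""
    rng = np.random.default_rng(seed)
    return np.array([rng.permutation(n) for _ in range(n_perm)])
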