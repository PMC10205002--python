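"""Compositional-data transforms: closure, zero replacement, CLR and its inverse.

Relative-abundance data (the 300-bin electrophoretic profiles, the 11-class
lipid table, the closed 8-compound table) live on the simplex, where ordinary
Euclidean statistics are distorted. The pipeline therefore maps compositions to
real space with the centred-log-ratio (CLR) transform before any covariance- or
regression-based analysis, and back-transforms for interpretation. Natural
logarithms throughout.

CLR needs strictly positive parts, so zeros are first replaced by a small
multiplicative replacement that preserves the ratios among the observed parts.
All functions act row-wise on 1-D or 2-D arrays and return plain ndarrays
(pandas alignment lives in :mod:`glandcov.pipeline`).
"""

from __future__ import annotations

import numpy as np

from .errors import CompositionError

__all__ = ["closure", "replace_zeros", "clr", "clr_inverse", "auto_delta"]


def _as2d(x):
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    return np.atleast_2d(x), squeeze


def closure(x: np.ndarray) -> np.ndarray:
    """Normalize each row of ``x`` to sum to one.

    Raises :class:`CompositionError` on negative entries or all-zero rows.
    Idempotent on already-closed rows.
    """
    X, squeeze = _as2d(x)
    if np.any(X < 0):
        raise CompositionError("negative entries are not a composition")
    s = X.sum(axis=1, keepdims=True)
    if np.any(s == 0):
        raise CompositionError("all-zero row cannot be closed")
    out = X / s
    return out[0] if squeeze else out


def auto_delta(X: np.ndarray) -> float:
    """Default zero-replacement value: half the smallest positive entry of ``X``."""
    X = np.asarray(X, dtype=float)
    pos = X[X > 0]
    if pos.size == 0:
        raise CompositionError("matrix has no positive entries")
    return 0.5 * float(pos.min())


def replace_zeros(x: np.ndarray, delta: float | str = "auto") -> np.ndarray:
    """Multiplicative simple zero replacement on row-closed data.

    Each zero becomes ``delta`` and the positive entries of that row are scaled
    by ``1 - k*delta`` (``k`` = number of zeros in the row), so rows still sum
    to one and ratios among the observed parts are untouched. ``delta="auto"``
    resolves to :func:`auto_delta`. Rows without zeros pass through unchanged.
    """
    X, squeeze = _as2d(x)
    if np.any(X < 0):
        raise CompositionError("negative entries")
    if delta == "auto":
        delta = auto_delta(X)
    delta = float(delta)
    if delta <= 0:
        raise CompositionError("delta must be positive")
    pos = X[X > 0]
    if pos.size and delta >= pos.min():
        raise CompositionError(
            f"delta={delta:g} is not smaller than the smallest positive entry "
            f"({pos.min():g})"
        )
    k = (X == 0).sum(axis=1, keepdims=True)
    out = np.where(X == 0, delta, X * (1.0 - k * delta))
    return out[0] if squeeze else out


def clr(x: np.ndarray) -> np.ndarray:
    """Centred-log-ratio transform: ``z_ij = ln(x_ij / g_i)``, ``g_i`` the row
    geometric mean. Output rows sum to zero. Requires strictly positive input
    (apply :func:`replace_zeros` first)."""
    X, squeeze = _as2d(x)
    if np.any(X <= 0):
        raise CompositionError("clr requires strictly positive entries")
    L = np.log(X)
    out = L - L.mean(axis=1, keepdims=True)
    return out[0] if squeeze else out


def clr_inverse(z: np.ndarray) -> np.ndarray:
    """Map CLR coordinates back to the simplex: row-closed ``exp(z)``.

    The row maximum is subtracted before exponentiation so extreme coordinates
    cannot overflow; closure cancels the shift exactly.
    """
    Z, squeeze = _as2d(z)
    if not np.all(np.isfinite(Z)):
        raise CompositionError("non-finite CLR coordinates")
    out = np.exp(Z - Z.max(axis=1, keepdims=True))
    out /= out.sum(axis=1, keepdims=True)
    return out[0] if squeeze else out
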