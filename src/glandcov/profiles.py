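"""Electrophoretic-profile statistics: normalization, entropy, peak richness.

A species' protein secretion is summarized as a 300-bin electrophoretogram
(EPG): relative protein abundance per molecular-weight bin, summing to one.
Two complexity indices are derived from a profile:

* richness ``R`` — the number of identifiable peaks, found as strict local
  maxima within a sliding window (default width 3) and filtered to those at
  least 10% as high as the tallest detected peak;
* Shannon entropy ``H = -Σ p_i ln p_i`` (nats) — an evenness-weighted measure
  of profile complexity, 0 for a single-band profile and ln(n_bins) for a
  perfectly uniform one.

The same entropy applies to closed lipid profiles (H_L); lipid richness R_L is
simply the count of compounds present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GlandcovError

__all__ = [
    "N_BINS",
    "PeakConfig",
    "normalize_profile",
    "shannon_entropy",
    "detect_peaks",
    "lipid_richness",
]

#: default profile width (molecular-weight bins)
N_BINS = 300


@dataclass(frozen=True)
class PeakConfig:
    """Peak-detection settings: odd search ``window`` width and the minimum
    height of a retained peak as a fraction of the tallest detected peak."""

    window: int = 3
    rel_height: float = 0.10

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise GlandcovError("window must be an odd integer >= 3")
        if not 0 < self.rel_height < 1:
            raise GlandcovError("rel_height must be in (0, 1)")


def normalize_profile(raw: np.ndarray, n_bins: int | None = None) -> np.ndarray:
    """Close a nonnegative raw profile to sum to one.

    ``n_bins`` (default: accept any length) enforces the expected width.
    """
    p = np.asarray(raw, dtype=float)
    if p.ndim != 1:
        raise GlandcovError("profile must be one-dimensional")
    if n_bins is not None and p.size != n_bins:
        raise GlandcovError(f"expected {n_bins} bins, got {p.size}")
    if np.any(p < 0):
        raise GlandcovError("profile has negative entries")
    s = p.sum()
    if s == 0:
        raise GlandcovError("all-zero profile cannot be normalized")
    return p / s


def shannon_entropy(profile: np.ndarray) -> float:
    """Shannon entropy ``-Σ p ln p`` in nats of a normalized profile.

    Zero bins contribute nothing (0·ln 0 = 0). Raises if the profile does not
    sum to one, since entropy of an unnormalized vector is meaningless here.
    """
    p = np.asarray(profile, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise GlandcovError("shannon_entropy expects a normalized profile")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def detect_peaks(
    profile: np.ndarray, cfg: PeakConfig = PeakConfig()
) -> tuple[int, list[int]]:
    """Count identifiable peaks in a normalized profile.

    Bin *i* is a candidate peak iff it is strictly greater than every other
    bin in the centered window of width ``cfg.window`` (truncated near the
    boundary); the first and last bins are never peaks. Candidates shorter
    than ``cfg.rel_height`` times the tallest candidate are discarded.
    Plateaus yield no peak (strict inequality). Returns ``(count, indices)``;
    the count is the profile's richness R.
    """
    p = np.asarray(profile, dtype=float)
    n = p.size
    half = cfg.window // 2
    candidates = []
    for i in range(1, n - 1):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        window = p[lo:hi]
        # strict local maximum: p_i beats every neighbor in the window
        if np.all(p[i] > np.delete(window, i - lo)):
            candidates.append(i)
    if not candidates:
        return 0, []
    tallest = max(p[i] for i in candidates)
    kept = [i for i in candidates if p[i] >= cfg.rel_height * tallest]
    return len(kept), kept


def lipid_richness(abundances: np.ndarray) -> int:
    """Number of compounds present (strictly positive abundance)."""
    a = np.asarray(abundances, dtype=float)
    if np.any(a < 0):
        raise GlandcovError("negative abundance")
    return int((a > 0).sum())
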