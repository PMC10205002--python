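"""Synthetic trees and trait datasets with known ground truth.

The study system is 36 lizard species whose femoral-gland secretions are
profiled two ways: a 300-bin electrophoretic protein profile (a composition)
and a lipid fraction (11 chemical classes, 8 focal compound abundances).
This module simulates datasets with the same shapes and the statistical
structure the analysis assumes — traits evolving by Brownian motion (BM) on
a phylogeny, a configurable latent coupling between the protein and lipid
blocks, and a known injected effect of one compound on a chosen set of
profile bins — so every stage of the pipeline can be tested against a
recorded truth.

All generators are pure functions of (configuration, seed): the same inputs
reproduce byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import composition, profiles
from .errors import GlandcovError
from .treeops import Tree, bm_covariance

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "simulate_tree",
    "simulate_bm",
    "simulate_coupled_blocks",
    "simulate_epg_dataset",
]


def _sym_sqrt(A: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root with eigenvalue clipping at zero."""
    A = np.asarray(A, dtype=float)
    if not np.allclose(A, A.T, atol=1e-10):
        raise GlandcovError("covariance must be symmetric")
    w, U = np.linalg.eigh(A)
    if w.min() < -1e-10 * max(w.max(), 1.0):
        raise GlandcovError("covariance is not positive semidefinite")
    return (U * np.sqrt(np.clip(w, 0.0, None))) @ U.T


@dataclass(frozen=True)
class SimConfig:
    """Study-scale defaults for the full synthetic dataset.

    ``rho`` couples a shared latent BM factor into both the profile baseline
    and the compound abundances; ``beta`` (CLR units per unit abundance) is
    the direct linear effect of compound 1 on ``effect_bins``; ``noise_sd``
    is iid within-species deviation added to the latent profile.
    """

    n_taxa: int = 36
    n_bins: int = 300
    n_compounds: int = 8
    n_classes: int = 11
    rho: float = 0.5
    effect_bins: tuple = tuple(range(40, 46))
    beta: float = 2.0
    noise_sd: float = 0.25
    birth_rate: float = 1.0
    profile_sd: float = 0.5
    compound_sd: float = 0.5
    detection_limit: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 4:
            raise GlandcovError("n_taxa must be >= 4")
        if not 0 <= self.rho <= 1:
            raise GlandcovError("rho must be in [0, 1]")
        if any(b < 0 or b >= self.n_bins for b in self.effect_bins):
            raise GlandcovError("effect_bins out of range")


@dataclass
class SyntheticDataset:
    """A complete simulated study with its generating truth."""

    tree: Tree
    epg: pd.DataFrame  # rows closed, n_bins columns
    compounds: pd.DataFrame  # strictly positive abundances
    classes: pd.DataFrame  # rows closed, n_classes columns
    complexity: pd.DataFrame  # R_P, H_P, R_L, H_L per species
    truth: dict

    def to_csv(self, outdir: str | Path) -> None:
        """Write tree.nwk plus one CSV per table and truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "tree.nwk").write_text(self.tree.to_newick() + "\n")
        for name in ("epg", "compounds", "classes", "complexity"):
            getattr(self, name).rename_axis("species").to_csv(outdir / f"{name}.csv")
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2) + "\n")


def simulate_tree(n_taxa: int, birth_rate: float = 1.0, seed: int = 0) -> Tree:
    """Pure-birth (Yule) tree with ``n_taxa`` tips, labelled sp001…spNNN.

    Starts from the root split (two lineages); at ``k`` lineages the waiting
    time to the next split is Exp(k·birth_rate) and the splitting lineage is
    uniform. After the last split all pendant edges are extended by one more
    Exp(n·birth_rate) draw so every terminal branch is strictly positive.
    The result is ultrametric by construction.
    """
    if n_taxa < 2:
        raise GlandcovError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    next_id = iter(range(10**6))

    def node():
        return {"id": next(next_id), "len": 0.0, "children": []}

    root = node()
    a, b = node(), node()
    root["children"] = [a, b]
    active = [a, b]
    while len(active) < n_taxa:
        dt = rng.exponential(1.0 / (len(active) * birth_rate))
        for v in active:
            v["len"] += dt
        v = active.pop(rng.integers(len(active)))
        c1, c2 = node(), node()
        v["children"] = [c1, c2]
        active.extend([c1, c2])
    dt = rng.exponential(1.0 / (len(active) * birth_rate))
    for v in active:
        v["len"] += dt

    leaves = [v for v in _iter_leaves(root)]
    for i, v in enumerate(leaves):
        v["label"] = f"sp{i + 1:03d}"
    return Tree.from_newick(_to_newick(root) + ";")


def _iter_leaves(v):
    if not v["children"]:
        yield v
    else:
        for c in v["children"]:
            yield from _iter_leaves(c)


def _to_newick(v):
    if not v["children"]:
        return f"{v['label']}:{v['len']:.10g}"
    inner = ",".join(_to_newick(c) for c in v["children"])
    return f"({inner}):{v['len']:.10g}"


def simulate_bm(tree: Tree, Sigma: np.ndarray, seed: int = 0) -> np.ndarray:
    """Multivariate Brownian motion on ``tree``: one matrix-normal draw.

    Returns an (n_tips × q) array in tree tip order with row covariance ``C``
    (the BM tree covariance) and column covariance ``Sigma``, generated as
    ``X = L_C Z L_Σᵀ`` with iid standard-normal ``Z`` and symmetric PSD
    square roots ``L``. The root state is zero.
    """
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    C = bm_covariance(tree).C
    Lc = _sym_sqrt(C)
    Ls = _sym_sqrt(Sigma)
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((C.shape[0], Sigma.shape[0]))
    return Lc @ Z @ Ls.T


def simulate_coupled_blocks(
    tree: Tree, p1: int, p2: int, rho: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Two trait blocks sharing one latent BM factor with correlation ``rho``.

    Block *j* = rho · f wⱼᵀ + sqrt(1 − rho²) · (independent BM noise), with
    ``f`` a scalar BM trait and fixed unit loading vectors ``wⱼ``. ``rho = 0``
    gives exact independence; ``rho = 1`` makes both blocks rank one in ``f``
    so the PLS correlation is exactly 1.
    """
    if not 0 <= rho <= 1:
        raise GlandcovError("rho must be in [0, 1]")
    ss = np.random.SeedSequence(seed).spawn(3)
    f = simulate_bm(tree, np.eye(1), seed=ss[0]).ravel()
    blocks = []
    for p, child in zip((p1, p2), ss[1:]):
        w = np.ones(p) / np.sqrt(p)
        noise = simulate_bm(tree, np.eye(p), seed=child)
        blocks.append(rho * np.outer(f, w) + np.sqrt(1 - rho**2) * noise)
    return blocks[0], blocks[1]


def simulate_epg_dataset(cfg: SimConfig = SimConfig()) -> SyntheticDataset:
    """Full synthetic study: tree, profiles, lipids, complexity, truth.

    Construction, all on the tree from :func:`simulate_tree`:

    * compound abundances = exp(latent BM) — strictly positive, log-normal
      marginals, as real abundances are;
    * latent (CLR-scale) profile = BM baseline + rho-weighted shared factor
      + ``beta`` × abundance of compound 1 on ``effect_bins`` + iid noise;
      the observed profile is its CLR inverse, hence row-closed;
    * class table = closure of folded-normal BM draws over ``n_classes``
      columns (a neutral compositional stand-in);
    * complexity indices computed from the generated data by the profiles
      module; lipid richness counts compounds above ``detection_limit``
      (emulating a chromatographic detection floor — without one, exp(BM)
      abundances are never exactly zero and richness would be constant).
    """
    ss = np.random.SeedSequence(cfg.seed).spawn(6)
    tree = simulate_tree(cfg.n_taxa, cfg.birth_rate, seed=ss[0])
    sp = tree.tips
    n = cfg.n_taxa

    f = simulate_bm(tree, np.eye(1), seed=ss[1]).ravel()
    rc = np.sqrt(1 - cfg.rho**2)

    w_c = np.ones(cfg.n_compounds) / np.sqrt(cfg.n_compounds)
    lat_c = cfg.compound_sd * (
        cfg.rho * np.outer(f, w_c)
        + rc * simulate_bm(tree, np.eye(cfg.n_compounds), seed=ss[2])
    )
    compounds = np.exp(lat_c)

    rng = np.random.default_rng(ss[3])
    w_p = rng.standard_normal(cfg.n_bins)
    w_p /= np.linalg.norm(w_p)
    baseline = cfg.profile_sd * (
        cfg.rho * np.outer(f, w_p)
        + rc * simulate_bm(tree, np.eye(cfg.n_bins), seed=ss[4])
    )
    latent = baseline + cfg.noise_sd * rng.standard_normal((n, cfg.n_bins))
    latent[:, list(cfg.effect_bins)] += cfg.beta * compounds[:, [0]]
    epg = composition.clr_inverse(latent)

    classes = composition.closure(
        np.abs(simulate_bm(tree, np.eye(cfg.n_classes), seed=ss[5]))
    )

    pk = profiles.PeakConfig()
    complexity = pd.DataFrame(
        {
            "R_P": [profiles.detect_peaks(row, pk)[0] for row in epg],
            "H_P": [profiles.shannon_entropy(row) for row in epg],
            "R_L": [
                profiles.lipid_richness(
                    np.where(row >= cfg.detection_limit, row, 0.0)
                )
                for row in compounds
            ],
            "H_L": [
                profiles.shannon_entropy(composition.closure(row))
                for row in compounds
            ],
        },
        index=sp,
    )

    cols_c = [f"compound_{j+1}" for j in range(cfg.n_compounds)]
    return SyntheticDataset(
        tree=tree,
        epg=pd.DataFrame(epg, index=sp, columns=[f"bin_{i}" for i in range(cfg.n_bins)]),
        compounds=pd.DataFrame(compounds, index=sp, columns=cols_c),
        classes=pd.DataFrame(
            classes, index=sp, columns=[f"class_{j+1}" for j in range(cfg.n_classes)]
        ),
        complexity=complexity,
        truth={
            "rho": cfg.rho,
            "effect_bins": list(cfg.effect_bins),
            "beta": cfg.beta,
            "config": asdict(cfg) | {"effect_bins": list(cfg.effect_bins)},
        },
    )
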