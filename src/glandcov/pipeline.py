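"""Dataset I/O, configuration, and end-to-end orchestration.

Reproduces the three-stage analysis on any dataset with the study's shapes,
real or simulated:

1. two-block phylogenetic PLS of the CLR protein profiles against (a) the
   CLR class-level lipid composition and (b) the CLR-closed abundances of
   the eight focal compounds;
2. multivariate phylogenetic regression of the profiles on the eight
   absolute compound abundances with marginal (type III) RRPP tests, plus
   predicted profiles and responsive regions for every significant compound;
3. univariate phylogenetic regressions of protein on lipid complexity
   (richness on richness, entropy on entropy).

CSV conventions: comma-separated UTF-8, first column ``species``, header row
mandatory. All randomness flows from the single config seed; stage seeds are
spawned deterministically from it. Every mismatch between tables and the
tree is an error — nothing is imputed or silently dropped.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, composition
from .errors import AlignmentError, GlandcovError
from .phylopls import PLSResult, phylo_pls
from .phyloreg import (
    anova_type3,
    complexity_regression,
    default_kda_calibration,
    pgls_fit,
    predict_response,
    responsive_regions,
)
from .treeops import Tree, bm_covariance, prune_to, read_newick

__all__ = ["Dataset", "RunConfig", "load_dataset", "run_full_analysis"]


@dataclass
class Dataset:
    """All inputs aligned to the tree's canonical (postorder) tip sequence."""

    tree: Tree
    epg: pd.DataFrame
    classes: pd.DataFrame
    compounds: pd.DataFrame
    complexity: pd.DataFrame

    @property
    def species(self) -> list[str]:
        return self.tree.tips


@dataclass(frozen=True)
class RunConfig:
    """Analysis settings; defaults follow the published configuration
    (9999 permutations) with this package's explicit choices for the points
    the original description leaves open (zero replacement, transforms)."""

    n_perm: int = 9999
    seed: int = 0
    response_transform: str = "clr"  # clr | none
    predictor_transform: str = "none"  # none | clr
    zero_delta: float | str = "auto"
    peak_window: int = 3
    peak_rel_height: float = 0.10
    region_min_run: int = 2
    region_frac_of_max: float = 0.5
    alpha: float = 0.05

    def __post_init__(self):
        if self.n_perm < 99:
            raise GlandcovError("reported runs need n_perm >= 99")
        if self.response_transform not in ("clr", "none"):
            raise GlandcovError("response_transform must be 'clr' or 'none'")
        if self.predictor_transform not in ("clr", "none"):
            raise GlandcovError("predictor_transform must be 'none' or 'clr'")


def _read_table(path: str | Path, name: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.columns[0] != "species":
        raise AlignmentError(f"{name}: first column must be 'species'")
    if df["species"].duplicated().any():
        dupes = sorted(df.loc[df["species"].duplicated(), "species"])
        raise AlignmentError(f"{name}: duplicate species rows {dupes}")
    df = df.set_index("species")
    num = df.apply(pd.to_numeric, errors="coerce")
    if num.isna().any().any():
        bad = num.columns[num.isna().any()].tolist()
        raise AlignmentError(f"{name}: non-numeric or missing cells in {bad}")
    return num


def load_dataset(
    tree: str | Path | Tree,
    epg: str | Path,
    classes: str | Path,
    compounds: str | Path,
    complexity: str | Path,
    prune_tree: bool = False,
) -> Dataset:
    """Load and align all tables to the tree's tip order.

    With ``prune_tree=True`` the tree may contain extra taxa, which are
    pruned to the species shared by all tables; otherwise any mismatch in
    either direction is an error.
    """
    if not isinstance(tree, Tree):
        tree = read_newick(tree)
    tables = {
        "epg": _read_table(epg, "epg"),
        "classes": _read_table(classes, "classes"),
        "compounds": _read_table(compounds, "compounds"),
        "complexity": _read_table(complexity, "complexity"),
    }
    species = set(tables["epg"].index)
    for name, df in tables.items():
        if set(df.index) != species:
            diff = sorted(set(df.index) ^ species)
            raise AlignmentError(
                f"{name}: species set differs from epg table ({diff})"
            )
    if prune_tree and species < set(tree.tips):
        tree = prune_to(tree, species)
    extra_in_tree = set(tree.tips) - species
    missing_from_tree = species - set(tree.tips)
    if extra_in_tree or missing_from_tree:
        raise AlignmentError(
            f"tree/table species mismatch (tree-only={sorted(extra_in_tree)}, "
            f"table-only={sorted(missing_from_tree)})"
        )
    order = tree.tips
    return Dataset(tree=tree, **{k: v.loc[order] for k, v in tables.items()})


def _clr_pipeline(df: pd.DataFrame, delta, close_first: bool) -> pd.DataFrame:
    X = df.to_numpy(dtype=float)
    if close_first:
        X = composition.closure(X)
    if np.any(X == 0):
        X = composition.replace_zeros(X, delta)
    return pd.DataFrame(composition.clr(X), index=df.index, columns=df.columns)


def _stage_seeds(seed: int, n: int) -> list[int]:
    # deterministic per-stage seeds; kept below 2**31 for portability
    return [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(n)
    ]


def run_full_analysis(
    ds: Dataset, cfg: RunConfig = RunConfig(), out_dir: str | Path | None = None
) -> dict:
    """Run the three analysis stages and (optionally) write the report bundle.

    Returns a dict with keys ``pls_classes``, ``pls_compounds`` (PLSResult),
    ``anova`` (AnovaTable), ``regions`` (term → RegionReport), ``predictions``
    (term → lo/hi profiles), ``complexity`` (pair → ComplexityRegression) and
    ``manifest``. When ``out_dir`` is given, result TSVs plus a JSON manifest
    (config, seed, package version, input checksums) are written there;
    identical inputs and seed reproduce byte-identical files.
    """
    seeds = _stage_seeds(cfg.seed, 5)
    cov = bm_covariance(ds.tree)

    epg_clr = _clr_pipeline(ds.epg, cfg.zero_delta, close_first=False)
    classes_clr = _clr_pipeline(ds.classes, cfg.zero_delta, close_first=False)
    compounds_clr = _clr_pipeline(ds.compounds, cfg.zero_delta, close_first=True)

    pls_classes = phylo_pls(epg_clr, classes_clr, cov, cfg.n_perm, seeds[0])
    pls_compounds = phylo_pls(epg_clr, compounds_clr, cov, cfg.n_perm, seeds[1])

    response = epg_clr if cfg.response_transform == "clr" else ds.epg
    predictors = compounds_clr if cfg.predictor_transform == "clr" else ds.compounds
    fit = pgls_fit(response, predictors, cov)
    anova = anova_type3(fit, cfg.n_perm, seeds[2])

    kda = default_kda_calibration(ds.epg.shape[1])
    predictions, regions = {}, {}
    for term in anova.significant_terms(cfg.alpha):
        x = ds.compounds[term] if term in ds.compounds else predictors[term]
        lo, hi = float(x.min()), float(x.max())
        pred = predict_response(fit, term, [lo, hi])
        predictions[term] = {"at": (lo, hi), "profiles": pred}
        regions[term] = responsive_regions(
            pred[0], pred[1], cfg.region_min_run, cfg.region_frac_of_max, kda
        )

    complexity = {
        "R_P~R_L": complexity_regression(
            ds.complexity["R_P"], ds.complexity["R_L"], cov, cfg.n_perm, seeds[3]
        ),
        "H_P~H_L": complexity_regression(
            ds.complexity["H_P"], ds.complexity["H_L"], cov, cfg.n_perm, seeds[4]
        ),
    }

    manifest = {
        "package": "glandcov",
        "version": __version__,
        "config": {**asdict(cfg)},
        "stage_seeds": seeds,
        "n_species": len(ds.species),
        "decisions": {
            "zero_delta": cfg.zero_delta
            if cfg.zero_delta != "auto"
            else "auto (0.5 x smallest positive entry per matrix)",
            "response_transform": cfg.response_transform,
            "predictor_transform": cfg.predictor_transform,
            "permutation_scheme": "rows of transformed block / reduced-model "
            "residuals (RRPP); phylogenetic mean and whitener held fixed",
        },
    }
    report = {
        "pls_classes": pls_classes,
        "pls_compounds": pls_compounds,
        "anova": anova,
        "fit": fit,
        "predictions": predictions,
        "regions": regions,
        "complexity": complexity,
        "manifest": manifest,
    }
    if out_dir is not None:
        _write_bundle(report, ds, cfg, Path(out_dir))
    return report


def _checksum(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.round(12).to_csv().encode("utf-8")
    ).hexdigest()[:16]


def _pls_frame(r: PLSResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species": r.labels,
            "left_score": r.left_scores,
            "right_score": r.right_scores,
        }
    )


def _write_bundle(report: dict, ds: Dataset, cfg: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    manifest = dict(report["manifest"])
    manifest["input_checksums"] = {
        name: _checksum(getattr(ds, name))
        for name in ("epg", "classes", "compounds", "complexity")
    }
    cfg_hash = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()[:12]
    manifest["config_hash"] = cfg_hash

    def save(df: pd.DataFrame, name: str) -> None:
        with open(out / name, "w") as fh:
            fh.write(f"# config_hash={cfg_hash}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.10g")

    for key in ("pls_classes", "pls_compounds"):
        r: PLSResult = report[key]
        save(
            pd.DataFrame(
                [{"r_pls": r.r_pls, "p_value": r.p_value, "n_perm": r.n_perm}]
            ),
            f"{key}_summary.tsv",
        )
        save(_pls_frame(r), f"{key}_scores.tsv")
    save(report["anova"].table, "anova_type3.tsv")
    for term, rep in report["regions"].items():
        frame = rep.to_frame()
        if frame.empty:
            frame = pd.DataFrame(
                columns=["start_bin", "end_bin", "start_kda", "end_kda", "delta"]
            )
        save(frame, f"regions_{term}.tsv")
    for pair, creg in report["complexity"].items():
        save(
            creg.anova.table.assign(slope=creg.slope, intercept=creg.intercept),
            f"complexity_{pair.replace('~', '_on_')}.tsv",
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
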