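"""Phylogenetic regression with marginal (type III) tests by residual permutation.

Fits a multivariate generalized-least-squares regression under Brownian
motion: response and design (with intercept) are premultiplied by the
whitener ``E`` of the BM covariance and the transformed system is solved by
ordinary least squares. Each predictor's marginal contribution is the rise in
residual sum of squares when that predictor alone is dropped (type III), and

    pseudo-F_k = (SS_k / df_k) / (RSS_full / df_res)

is referred to a null distribution built by RRPP — residual randomization in
a permutation procedure: the reduced (term-dropped) model's residual rows are
permuted, added back to its fitted values, and the statistic recomputed. For a
univariate response with ``C = I`` this reproduces the classical partial
F statistic exactly.

The module also turns a fitted model into interpretable output: predicted
response profiles along one predictor's gradient (others held at their
phylogenetic mean), contiguous "responsive regions" of the profile where the
predicted change concentrates, and univariate complexity regressions with a
confidence band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import align_block, permutation_indices, resolve_cov
from .errors import DegenerateDataError, GlandcovError, RankDeficientError
from .treeops import PhyloCovariance, Tree, gls_mean

__all__ = [
    "PGLSFit",
    "AnovaTable",
    "Region",
    "RegionReport",
    "ComplexityRegression",
    "pgls_fit",
    "anova_type3",
    "predict_response",
    "responsive_regions",
    "complexity_regression",
    "default_kda_calibration",
]

_CHUNK = 256
#: relative floor below which a residual sum of squares counts as an exact fit
_RSS_EPS = 1e-12


@dataclass
class PGLSFit:
    """A fitted phylogenetic regression.

    ``coefficients`` is (1 + k) × q (intercept row first) and applies on the
    *untransformed* design scale — GLS estimates the same linear map as the
    transformed OLS solve. ``fitted``/``residuals`` live in transformed
    (whitened) space, where the permutation machinery operates.
    """

    coefficients: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    rss_full: float
    design_labels: list[str]
    cov: PhyloCovariance = field(repr=False)
    design_t: np.ndarray = field(repr=False)
    response_t: np.ndarray = field(repr=False)
    X_raw: np.ndarray = field(repr=False)
    response_labels: list = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.response_t.shape[0]

    @property
    def df_residual(self) -> int:
        return self.n - self.design_t.shape[1]


@dataclass
class AnovaTable:
    """Per-term marginal SS, pseudo-F and RRPP p-values."""

    table: pd.DataFrame  # term, df, SS, pseudo_F, p_perm
    n_perm: int
    seed: int
    df_residual: int
    rss_full: float

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.set_index("term").loc[term]

    def p_adjusted(self) -> pd.Series:
        """Holm step-down familywise adjustment of the per-term p-values."""
        p = self.table["p_perm"].to_numpy()
        m = p.size
        order = np.argsort(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(running, 1.0)
        return pd.Series(adj, index=self.table["term"], name="p_holm")

    def significant_terms(self, alpha: float = 0.05, adjust: str = "none") -> list[str]:
        """Terms significant at ``alpha``.

        ``adjust="none"`` reads each term's raw permutation p (how a
        single-predictor table is conventionally read); ``adjust="holm"``
        controls the familywise error over the whole predictor scan, the
        appropriate rule when claiming one predictor is *the* significant one
        among many.
        """
        if adjust == "none":
            t = self.table
            return list(t.loc[t["p_perm"] <= alpha, "term"])
        if adjust == "holm":
            adj = self.p_adjusted()
            return list(adj.index[adj <= alpha])
        raise GlandcovError("adjust must be 'none' or 'holm'")


def pgls_fit(Y, X, tree: Tree | PhyloCovariance) -> PGLSFit:
    """Fit ``Y ~ 1 + X`` by phylogenetic GLS under Brownian motion.

    ``Y`` (n × q) and ``X`` (n × k) are DataFrames indexed by species or
    arrays in tree tip order. The design must be full rank; collinear
    predictors raise :class:`RankDeficientError` rather than being dropped.
    """
    cov = resolve_cov(tree)
    labels = cov.labels
    Ya = align_block(Y, labels, "response")
    Xa = align_block(X, labels, "predictors")
    n, k = Xa.shape
    if n <= k + 1:
        raise GlandcovError(f"need n > k+1 observations (n={n}, k={k})")
    design_labels = (
        list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{j+1}" for j in range(k)]
    )
    response_labels = list(Y.columns) if isinstance(Y, pd.DataFrame) else None

    E = cov.E
    D = np.column_stack([np.ones(n), Xa])
    Dt = E @ D
    Yt = E @ Ya
    if np.linalg.matrix_rank(Dt) < k + 1:
        raise RankDeficientError("design matrix is rank deficient")
    B, *_ = np.linalg.lstsq(Dt, Yt, rcond=None)
    fitted = Dt @ B
    resid = Yt - fitted
    return PGLSFit(
        coefficients=B,
        fitted=fitted,
        residuals=resid,
        rss_full=float((resid**2).sum()),
        design_labels=design_labels,
        cov=cov,
        design_t=Dt,
        response_t=Yt,
        X_raw=Xa,
        response_labels=response_labels,
    )


def _resid_maker(D: np.ndarray) -> np.ndarray:
    """I - D (DᵀD)⁻¹ Dᵀ via a thin QR (numerically stable projector)."""
    Q, _ = np.linalg.qr(D)
    return np.eye(D.shape[0]) - Q @ Q.T


def _rss_batch(M: np.ndarray, Yb: np.ndarray) -> np.ndarray:
    """Residual SS of each (n × q) slab in the (m, n, q) batch under projector M."""
    R = np.einsum("ij,mjq->miq", M, Yb)
    return (R**2).sum(axis=(1, 2))


def anova_type3(fit: PGLSFit, n_perm: int = 999, seed: int = 0) -> AnovaTable:
    """Marginal (type III) tests of every predictor in ``fit`` by RRPP.

    For each term the reduced model drops that single column (intercept and
    all other terms retained). One shared permutation-index stream per seed is
    used across terms, so p-values are comparable within a run. A perfect fit
    (RSS_full ≈ 0) reports infinite pseudo-F and the minimal attainable p.
    """
    if n_perm < 1:
        raise GlandcovError("n_perm must be >= 1")
    Dt, Yt = fit.design_t, fit.response_t
    n = fit.n
    df_res = fit.df_residual
    if df_res <= 0:
        raise GlandcovError("no residual degrees of freedom")
    terms = fit.design_labels
    M_full = _resid_maker(Dt)
    rss_full = float(_rss_batch(M_full, Yt[None])[0])
    scale = float((Yt**2).sum()) or 1.0
    exact_fit = rss_full < _RSS_EPS * scale

    perms = permutation_indices(n, n_perm, seed)
    rows = []
    for j, term in enumerate(terms):
        D_red = np.delete(Dt, j + 1, axis=1)
        M_red = _resid_maker(D_red)
        rss_red = float(_rss_batch(M_red, Yt[None])[0])
        ss = max(rss_red - rss_full, 0.0)
        if exact_fit:
            f_obs = np.inf
        else:
            f_obs = (ss / 1.0) / (rss_full / df_res)

        fitted_red = Yt - M_red @ Yt
        resid_red = M_red @ Yt
        exceed = 0
        for start in range(0, n_perm, _CHUNK):
            P = perms[start : start + _CHUNK]
            Yp = fitted_red[None] + resid_red[P]
            rf = _rss_batch(M_full, Yp)
            rr = _rss_batch(M_red, Yp)
            with np.errstate(divide="ignore", invalid="ignore"):
                fp = np.where(
                    rf < _RSS_EPS * scale,
                    np.inf,
                    np.maximum(rr - rf, 0.0) / (rf / df_res),
                )
            exceed += int(np.sum(fp >= f_obs * (1 - 1e-12)))
        p = (1 + exceed) / (n_perm + 1)
        rows.append((term, 1, ss, f_obs, p))

    table = pd.DataFrame(rows, columns=["term", "df", "SS", "pseudo_F", "p_perm"])
    return AnovaTable(
        table=table, n_perm=n_perm, seed=seed, df_residual=df_res, rss_full=rss_full
    )


def predict_response(
    fit: PGLSFit, term: str, at_values, display: str = "analysis"
) -> np.ndarray:
    """Predicted response profiles along one predictor's gradient.

    The focal ``term`` sweeps ``at_values`` while every other predictor is
    held at its phylogenetic (GLS) mean; the prediction is the fitted linear
    map on the untransformed design scale, so the output rows live on the
    response's analysis scale (CLR for compositional responses). Pass
    ``display="simplex"`` to view each predicted row as a closed composition
    (CLR inverse), for plotting only.
    """
    if term not in fit.design_labels:
        raise GlandcovError(
            f"unknown term {term!r}; design has {fit.design_labels}"
        )
    at_values = np.asarray(at_values, dtype=float)
    if not np.all(np.isfinite(at_values)):
        raise GlandcovError("at_values must be finite")
    j = fit.design_labels.index(term)
    x_base = gls_mean(fit.cov.C, fit.X_raw)  # (k,)
    rows = np.tile(np.concatenate([[1.0], x_base]), (at_values.size, 1))
    rows[:, j + 1] = at_values
    pred = rows @ fit.coefficients
    if display == "simplex":
        from .composition import clr_inverse

        return clr_inverse(pred)
    return pred


def default_kda_calibration(
    n_bins: int = 300, kda_hi: float = 260.0, kda_lo: float = 3.5
) -> np.ndarray:
    """Log-linear bin → kDa mapping from high to low molecular weight.

    A synthetic stand-in for a real gel calibration (migration distance is
    roughly linear in log molecular weight); supply a measured two-column
    calibration whenever one exists.
    """
    return np.exp(np.linspace(np.log(kda_hi), np.log(kda_lo), n_bins))


@dataclass(frozen=True)
class Region:
    """One contiguous responsive stretch of the profile."""

    start_bin: int
    end_bin: int  # inclusive
    start_kda: float | None
    end_kda: float | None
    delta: float  # peak predicted change (CLR units) within the region


@dataclass
class RegionReport:
    regions: list[Region]
    threshold: float
    delta: np.ndarray = field(repr=False, default=None)

    def __iter__(self):
        return iter(self.regions)

    def __len__(self):
        return len(self.regions)

    def bins(self) -> set[int]:
        return {
            b for r in self.regions for b in range(r.start_bin, r.end_bin + 1)
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.regions])


def responsive_regions(
    pred_lo: np.ndarray,
    pred_hi: np.ndarray,
    min_run: int = 2,
    frac_of_max: float = 0.5,
    bin_kda: np.ndarray | None = None,
) -> RegionReport:
    """Locate profile regions that respond most to the predictor gradient.

    ``delta = pred_hi - pred_lo`` (analysis/CLR scale); a region is a maximal
    run of at least ``min_run`` consecutive bins with ``delta`` at or above
    ``frac_of_max`` times the maximum delta. Regions come back sorted by
    their peak |delta|, with kDa bounds when a calibration is given. A
    non-positive maximum delta yields an empty report.
    """
    lo = np.asarray(pred_lo, dtype=float).ravel()
    hi = np.asarray(pred_hi, dtype=float).ravel()
    if lo.shape != hi.shape:
        raise GlandcovError("profiles must have equal length")
    if not 0 < frac_of_max < 1:
        raise GlandcovError("frac_of_max must be in (0, 1)")
    delta = hi - lo
    dmax = delta.max()
    if dmax <= 0:
        return RegionReport(regions=[], threshold=np.nan, delta=delta)
    if np.ptp(delta) == 0:
        warnings.warn(
            "predicted change is flat across all bins; one degenerate region"
        )
    thr = frac_of_max * dmax
    mask = delta >= thr
    regions: list[Region] = []
    i, n = 0, delta.size
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                regions.append(
                    Region(
                        start_bin=i,
                        end_bin=j,
                        start_kda=float(bin_kda[i]) if bin_kda is not None else None,
                        end_kda=float(bin_kda[j]) if bin_kda is not None else None,
                        delta=float(delta[i : j + 1].max()),
                    )
                )
            i = j + 1
        else:
            i += 1
    regions.sort(key=lambda r: abs(r.delta), reverse=True)
    return RegionReport(regions=regions, threshold=float(thr), delta=delta)


@dataclass
class ComplexityRegression:
    """Univariate phylogenetic regression of one complexity index on another."""

    anova: AnovaTable
    slope: float
    intercept: float
    x_grid: np.ndarray
    y_hat: np.ndarray
    band_lo: np.ndarray
    band_hi: np.ndarray
    fit: PGLSFit = field(repr=False, default=None)


def complexity_regression(
    y,
    x,
    tree: Tree | PhyloCovariance,
    n_perm: int = 999,
    seed: int = 0,
    n_grid: int = 100,
) -> ComplexityRegression:
    """Regress a scalar complexity index ``y`` on ``x`` with BM correction.

    Wraps :func:`pgls_fit` + :func:`anova_type3` for a univariate response and
    single predictor, and adds the prediction line over the observed ``x``
    range with a pointwise 95% confidence band (t quantile on the
    transformed-space standard errors). A perfect fit reports capped
    statistics (infinite pseudo-F, minimal p) instead of failing.
    """
    cov = resolve_cov(tree)
    ya = align_block(y, cov.labels, "y")
    xa = align_block(x, cov.labels, "x")
    xname = (
        list(x.columns)[0]
        if isinstance(x, pd.DataFrame)
        else (x.name if isinstance(x, pd.Series) and x.name else "x1")
    )
    fit = pgls_fit(ya, pd.DataFrame(xa, index=cov.labels, columns=[xname]), cov)
    table = anova_type3(fit, n_perm=n_perm, seed=seed)

    intercept, slope = float(fit.coefficients[0, 0]), float(fit.coefficients[1, 0])
    xg = np.linspace(xa.min(), xa.max(), n_grid)
    D0 = np.column_stack([np.ones(n_grid), xg])
    y_hat = D0 @ fit.coefficients[:, 0]
    df = fit.df_residual
    sigma2 = fit.rss_full / df
    XtX_inv = np.linalg.inv(fit.design_t.T @ fit.design_t)
    se = np.sqrt(sigma2 * np.einsum("gi,ij,gj->g", D0, XtX_inv, D0))
    tq = stats.t.ppf(0.975, df)
    return ComplexityRegression(
        anova=table,
        slope=slope,
        intercept=intercept,
        x_grid=xg,
        y_hat=y_hat,
        band_lo=y_hat - tq * se,
        band_hi=y_hat + tq * se,
        fit=fit,
    )
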