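"""Comparative statistics: PGLS with ML Pagel's lambda, Welch t, pooling.

The regression model is y = b0 + b1 x + e with residual covariance
sigma^2 * V(lambda), where V is the phylogenetic (shared branch length)
matrix and Pagel's lambda multiplies its off-diagonal entries.  lambda is
profiled by maximum likelihood on [0, 1]; at lambda = 0 the model
collapses to an ordinary (non-phylogenetic) generalized least squares
fit with independent residuals whose variances are the tip depths.
lambda = 1 is the full Brownian-motion expectation.  Confidence
intervals come from the chi-square(1) likelihood-ratio drop of 1.92
log-likelihood units; an interval endpoint that sits on the search
boundary is reported as absent (no finite bound), mirroring the NA
convention of comparative-methods software.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import linalg, optimize, stats

from .phylo import PhyloCovariance
from .trace_io import SpeciesSummary

logger = logging.getLogger(__name__)

#: chi2(1)/2 drop defining the 95% profile-likelihood interval
_LR_DROP = stats.chi2.ppf(0.95, df=1) / 2.0  # = 1.9207...


@dataclass
class ComparativeDataset:
    """Species-level trait rows matched to tree tips.

    ``x`` is the predictor (occlusal area, cm^2, species mean) and ``y``
    the response (species-mean D).  No missing values are allowed: rows
    lacking area must be excluded before fitting.
    """

    taxa: list[str]
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.taxa)
        if self.x.shape != (n,) or self.y.shape != (n,):
            raise ValueError("x and y must be 1-D with one value per taxon")
        if np.any(~np.isfinite(self.x)) or np.any(~np.isfinite(self.y)):
            raise ValueError("missing/non-finite trait values are not allowed")

    @property
    def n(self) -> int:
        return len(self.taxa)


@dataclass
class RegressionFit:
    """GLS/PGLS coefficients and diagnostics (Table-3-shaped)."""

    slope: float
    intercept: float
    se_slope: float
    t_slope: float
    p_slope: float
    r2_multiple: float
    r2_adjusted: float
    lambda_hat: float
    lambda_ci: tuple[float | None, float | None]
    n: int
    loglik: float
    se_intercept: float = float("nan")


@dataclass
class GroupStats:
    """Sample size, mean and variance of one group of observations."""

    label: str
    n: int
    mean: float
    var: float


def lambda_transform(V: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Scale the off-diagonal of V by Pagel's lambda (diagonal unchanged)."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    Vl = lam * V.V
    np.fill_diagonal(Vl, np.diag(V.V))
    return PhyloCovariance(list(V.taxa), Vl)


def _align(data: ComparativeDataset, V: PhyloCovariance) -> np.ndarray:
    missing = [t for t in data.taxa if t not in V.taxa]
    if missing:
        raise ValueError(f"taxa absent from covariance matrix: {missing}")
    return V.subset(data.taxa).V


def _gls_core(X: np.ndarray, y: np.ndarray, V: np.ndarray):
    """Whitened least squares; returns beta, cov(beta), RSS_w, TSS_w, logdetV."""
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("covariance matrix is singular / not PD") from exc
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    XtX = Xw.T @ Xw
    beta = linalg.solve(XtX, Xw.T @ yw, assume_a="pos")
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    # whitened total SS about the GLS intercept-only mean
    ones_w = linalg.solve_triangular(L, np.ones_like(y), lower=True)
    mu = float(ones_w @ yw) / float(ones_w @ ones_w)
    tss = float(((yw - mu * ones_w) ** 2).sum())
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    cov_unit = linalg.inv(XtX)  # multiply by sigma2_hat for cov(beta)
    return beta, cov_unit, rss, tss, logdet


def _loglik(rss: float, logdet: float, n: int) -> float:
    """Maximized Gaussian log-likelihood with sigma^2 profiled out (ML)."""
    sigma2 = rss / n
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


def gls_fit(
    data: ComparativeDataset,
    V: PhyloCovariance,
    lam: float | None = None,
) -> RegressionFit:
    """Generalized least squares of y on x under covariance V.

    If ``lam`` is given, V's off-diagonal is lambda-scaled first (the
    returned ``lambda_hat`` records the value; the CI is left absent).
    With V = identity this reproduces ordinary least squares.  Standard
    errors use sigma2_hat = RSS_w/(n-2); p-values are two-sided Student t
    with n-2 degrees of freedom; R^2 values are computed in the whitened
    space against the GLS intercept-only mean.
    """
    if data.n < 3:
        raise ValueError("need at least 3 species to fit a regression")
    Vm = _align(data, V)
    if lam is not None:
        Vl = lam * Vm
        np.fill_diagonal(Vl, np.diag(Vm))
        Vm = Vl
    n = data.n
    X = np.column_stack([np.ones(n), data.x])
    beta, cov_unit, rss, tss, logdet = _gls_core(X, data.y, Vm)
    df = n - 2
    sigma2 = rss / df
    se = np.sqrt(sigma2 * np.diag(cov_unit))
    t_slope = float(beta[1] / se[1])
    p_slope = float(2 * stats.t.sf(abs(t_slope), df))
    r2 = 1.0 - rss / tss
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / df
    return RegressionFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        se_slope=float(se[1]),
        se_intercept=float(se[0]),
        t_slope=t_slope,
        p_slope=p_slope,
        r2_multiple=float(r2),
        r2_adjusted=float(r2_adj),
        lambda_hat=float(lam) if lam is not None else float("nan"),
        lambda_ci=(None, None),
        n=n,
        loglik=_loglik(rss, logdet, n),
    )


def _profile(
    X: np.ndarray, y: np.ndarray, Vm: np.ndarray, grid_points: int = 21,
    tol: float = 1e-6,
) -> tuple[float, float, "np.ndarray", "np.ndarray"]:
    """ML profile of lambda on [0, 1]: coarse grid + golden-section refine."""
    diag = np.diag(Vm).copy()

    def nll(lam: float) -> float:
        Vl = lam * Vm
        np.fill_diagonal(Vl, diag)
        _, _, rss, _, logdet = _gls_core(X, y, Vl)
        return -_loglik(rss, logdet, len(y))

    grid = np.linspace(0.0, 1.0, grid_points)
    vals = np.array([nll(g) for g in grid])
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid_points - 1)]
    res = optimize.minimize_scalar(
        nll, bounds=(lo, hi), method="bounded", options={"xatol": tol}
    )
    lam_hat, ll_hat = float(res.x), -float(res.fun)
    # keep boundary optima exact
    for edge in (0.0, 1.0):
        if -nll(edge) >= ll_hat - 1e-9:
            lam_edge_ll = -nll(edge)
            if lam_edge_ll >= ll_hat:
                lam_hat, ll_hat = edge, lam_edge_ll
    return lam_hat, ll_hat, grid, -vals


def _lr_ci(
    nll_at, lam_hat: float, ll_hat: float
) -> tuple[float | None, float | None]:
    """95% profile-likelihood interval; boundary endpoints reported absent."""
    target = ll_hat - _LR_DROP

    def g(lam: float) -> float:
        return -nll_at(lam) - target

    lower: float | None
    upper: float | None
    if lam_hat > 0.0 and g(0.0) < 0:
        lower = float(optimize.brentq(g, 0.0, lam_hat, xtol=1e-6))
    else:
        lower = None  # interval touches the 0 boundary
    if lam_hat < 1.0 and g(1.0) < 0:
        upper = float(optimize.brentq(g, lam_hat, 1.0, xtol=1e-6))
    else:
        upper = None  # interval touches the 1 boundary
    return lower, upper


def profile_lambda(
    data: ComparativeDataset, V: PhyloCovariance, grid_points: int = 21
) -> RegressionFit:
    """PGLS with Pagel's lambda estimated by maximum likelihood.

    lambda is profiled on [0, 1] (coarse grid, then golden-section/
    Brent refinement to 1e-6); the regression is refit at lambda-hat and
    the 95% CI is the set of lambda within 1.92 log-likelihood units of
    the maximum, with boundary endpoints reported as absent.
    """
    if data.n < 3:
        raise ValueError("need at least 3 species to fit a regression")
    Vm = _align(data, V)
    X = np.column_stack([np.ones(data.n), data.x])
    lam_hat, ll_hat, _, _ = _profile(X, data.y, Vm, grid_points)

    diag = np.diag(Vm).copy()

    def nll(lam: float) -> float:
        Vl = lam * Vm
        np.fill_diagonal(Vl, diag)
        _, _, rss, _, logdet = _gls_core(X, data.y, Vl)
        return -_loglik(rss, logdet, len(data.y))

    ci = _lr_ci(nll, lam_hat, ll_hat)
    fit = gls_fit(data, V, lam=lam_hat)
    fit.lambda_ci = ci
    # the profile maximum dominates both endpoints by construction
    assert fit.loglik >= -nll(0.0) - 1e-6 and fit.loglik >= -nll(1.0) - 1e-6
    return fit


def lambda_signal(
    trait: Mapping[str, float] | ComparativeDataset,
    V: PhyloCovariance,
    grid_points: int = 21,
) -> tuple[float, tuple[float | None, float | None]]:
    """Phylogenetic signal of a single trait: ML lambda of the
    intercept-only model.

    ``trait`` maps taxon -> value (or a ComparativeDataset whose y is
    used).  A constant trait makes lambda unidentifiable; 0 is returned
    with a warning.
    """
    if isinstance(trait, ComparativeDataset):
        taxa, y = trait.taxa, trait.y
    else:
        taxa = list(trait.keys())
        y = np.array([trait[t] for t in taxa], dtype=float)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    if np.allclose(y, y[0]):
        warnings.warn(
            "constant trait: lambda unidentifiable, returning 0", stacklevel=2
        )
        return 0.0, (None, None)
    Vm = V.subset(taxa).V
    X = np.ones((len(taxa), 1))
    lam_hat, ll_hat, _, _ = _profile(X, y, Vm, grid_points)

    diag = np.diag(Vm).copy()

    def nll(lam: float) -> float:
        Vl = lam * Vm
        np.fill_diagonal(Vl, diag)
        _, _, rss, _, logdet = _gls_core(X, y, Vl)
        return -_loglik(rss, logdet, len(y))

    ci = _lr_ci(nll, lam_hat, ll_hat)
    return lam_hat, ci


def welch_t(a: GroupStats, b: GroupStats) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test from group summaries.

    Returns (t, Welch-Satterthwaite df, two-sided p).  Identical groups
    give t = 0, p = 1.  Antisymmetric under exchange of the groups.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("both groups need n >= 2")
    if a.var <= 0 or b.var <= 0:
        raise ValueError("degenerate (non-positive) group variance")
    va, vb = a.var / a.n, b.var / b.n
    t = (a.mean - b.mean) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = float(2 * stats.t.sf(abs(t), df))
    return float(t), float(df), p


def pooled_from_species(
    summaries: Iterable[SpeciesSummary], tribe: str, trait: str = "D"
) -> GroupStats:
    """Reconstruct specimen-level group stats from species summaries.

    Uses the exact decomposition of the total sum of squares into
    within-species (sum (n_i - 1) sd_i^2) and between-species
    (sum n_i (m_i - m)^2) parts; species with n = 1 contribute no
    within-species term.  ``trait`` is "D" or "area".
    """
    if trait not in ("D", "area"):
        raise ValueError("trait must be 'D' or 'area'")
    rows = []
    for s in summaries:
        if s.tribe != tribe:
            continue
        if trait == "D":
            rows.append((s.n_D, s.mean_D, s.sd_D))
        elif s.n_area > 0:
            rows.append((s.n_area, s.mean_area, s.sd_area))
    if not rows:
        raise ValueError(f"no {trait} observations for tribe {tribe!r}")
    n_tot = sum(n for n, _, _ in rows)
    mean = sum(n * m for n, m, _ in rows) / n_tot
    within = sum((n - 1) * sd**2 for n, _, sd in rows if sd is not None)
    between = sum(n * (m - mean) ** 2 for n, m, _ in rows)
    var = (within + between) / (n_tot - 1) if n_tot > 1 else float("nan")
    return GroupStats(label=tribe, n=n_tot, mean=float(mean), var=float(var))


def compare_slopes(
    fit1: RegressionFit, fit2: RegressionFit
) -> tuple[float, float, float]:
    """t-test for equality of two independent regression slopes.

    t = (b1 - b2)/sqrt(se1^2 + se2^2) with the classical parallel-slopes
    df = n1 + n2 - 4; two-sided p.
    """
    t = (fit1.slope - fit2.slope) / np.sqrt(fit1.se_slope**2 + fit2.se_slope**2)
    df = fit1.n + fit2.n - 4
    p = float(2 * stats.t.sf(abs(t), df))
    return float(t), float(df), p


def distribution_checks(
    values_by_group: Mapping[str, Sequence[float]],
) -> dict:
    """Shapiro-Wilk normality per group and Bartlett equal-variance test.

    Each group needs n >= 3.  Groups of identical values are flagged as
    degenerate and excluded from the Bartlett test.
    """
    report: dict = {"shapiro": {}, "bartlett": None}
    usable = []
    for label, vals in values_by_group.items():
        v = np.asarray(vals, dtype=float)
        if len(v) < 3:
            raise ValueError(f"group {label!r} needs n >= 3")
        if np.allclose(v, v[0]):
            report["shapiro"][label] = {"W": None, "p": None, "degenerate": True}
            continue
        W, p = stats.shapiro(v)
        report["shapiro"][label] = {"W": float(W), "p": float(p), "degenerate": False}
        usable.append(v)
    if len(usable) >= 2:
        stat, p = stats.bartlett(*usable)
        report["bartlett"] = {"statistic": float(stat), "p": float(p)}
    return report
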