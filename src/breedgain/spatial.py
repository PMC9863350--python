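"""Single-trial spatial mixed models with separable AR1 x AR1 residuals.

Field-trial plots lie on a (range x row) grid.  The model for one trait at
one site is

    y = X b + Z_g u_g [+ Z_r u_r + Z_c u_c] + e

with genotype effects u_g ~ N(0, s2_g I) random, optional random range and
row main effects, optional fixed linear trends along the grid axes, and a
residual whose correlation is the Kronecker product of two first-order
autoregressive processes: corr(e_i, e_j) = rho_range**|dr| * rho_row**|dc|.

Variance parameters are estimated by REML: the residual variance is
profiled out and the residual log-likelihood is maximised over
(atanh rho, log variance-ratios) with a bounded quasi-Newton optimizer.
Missing plots are simply dropped; the correlation is computed from grid
coordinates, so gaps are handled exactly.

A forward model-selection ladder (iid -> AR1xAR1 -> +random range ->
+random row -> +linear trends) screens spatial terms per site; the chosen
term list is what the multi-environment stage consumes.  Variance terms
are compared by REML likelihood-ratio tests; fixed trends by Wald z-tests
(REML likelihoods are not comparable across fixed-effect structures).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "TrialLayout",
    "SpatialFitResult",
    "fit_single_site",
    "select_spatial_model",
    "sample_variogram",
    "flag_outliers",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class TrialLayout:
    """Plot coordinates for one trial: integer range/row indices per plot."""

    ranges: np.ndarray
    rows: np.ndarray
    genotypes: np.ndarray

    def __post_init__(self):
        self.ranges = np.asarray(self.ranges, int)
        self.rows = np.asarray(self.rows, int)
        self.genotypes = np.asarray(self.genotypes)
        coords = set(zip(self.ranges.tolist(), self.rows.tolist()))
        if len(coords) != len(self.ranges):
            raise ValueError("duplicate (range, row) plot coordinates")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrialLayout":
        return cls(
            frame["range"].to_numpy(),
            frame["row"].to_numpy(),
            frame["genotype"].to_numpy(),
        )

    def __len__(self) -> int:
        return len(self.ranges)


@dataclass
class SpatialFitResult:
    rho_range: float
    rho_row: float
    sigma2_e: float
    sigma2_g: float
    sigma2_range: float
    sigma2_row: float
    beta: np.ndarray
    beta_se: np.ndarray
    beta_names: list[str]
    rll: float
    n_vparams: int
    aic: float
    bic: float
    genotype_blups: pd.Series
    residuals: np.ndarray  # conditional residuals, plot order
    std_residuals: np.ndarray
    terms: dict = field(default_factory=dict)
    converged: bool = True
    n: int = 0

    def heritability_line(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else 0.0


def _ar1_corr(coord_a: np.ndarray, coord_b: np.ndarray, rho_a: float, rho_b: float):
    da = np.abs(coord_a[:, None] - coord_a[None, :])
    db = np.abs(coord_b[:, None] - coord_b[None, :])
    if rho_a == 0.0 and rho_b == 0.0:
        return np.eye(len(coord_a))
    ka = np.power(rho_a, da) if rho_a != 0.0 else (da == 0).astype(float)
    kb = np.power(rho_b, db) if rho_b != 0.0 else (db == 0).astype(float)
    return ka * kb


def _design(layout: TrialLayout, linear_trends: bool):
    n = len(layout)
    cols = [np.ones(n)]
    names = ["intercept"]
    if linear_trends:
        cols.append(layout.ranges - layout.ranges.mean())
        names.append("lin_range")
        cols.append(layout.rows - layout.rows.mean())
        names.append("lin_row")
    X = np.column_stack(cols)
    geno_levels, geno_idx = np.unique(layout.genotypes, return_inverse=True)
    Zg = np.zeros((n, len(geno_levels)))
    Zg[np.arange(n), geno_idx] = 1.0
    return X, names, Zg, geno_levels


def _profile_rll(C, X, y):
    """REML log-likelihood with residual variance profiled out."""
    n, p = X.shape
    cf = cho_factor(C, lower=True)
    logdet_C = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Ci_X = cho_solve(cf, X)
    Ci_y = cho_solve(cf, y)
    XtCiX = X.T @ Ci_X
    sign, logdet_XX = np.linalg.slogdet(XtCiX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'C^-1X not positive definite")
    beta = np.linalg.solve(XtCiX, X.T @ Ci_y)
    r = y - X @ beta
    Ci_r = cho_solve(cf, r)
    quad = float(r @ Ci_r)
    nu = n - p
    s2 = quad / nu
    rll = -0.5 * (nu * (_LOG2PI + np.log(s2) + 1.0) + logdet_C + logdet_XX)
    return rll, s2, beta, XtCiX, cf, Ci_r


def fit_single_site(
    layout: TrialLayout,
    y: np.ndarray,
    ar1: bool = True,
    random_range: bool = False,
    random_row: bool = False,
    linear_trends: bool = False,
    max_iter: int = 200,
) -> SpatialFitResult:
    """REML fit of the single-site spatial model.

    Genotype is always a random effect; the remaining terms are switched on
    by the keyword flags.  Raises on non-convergence; a variance ratio
    driven to the zero boundary is reported, not an error.
    """
    y = np.asarray(y, float)
    ok = np.isfinite(y)
    if ok.sum() < 20:
        raise ValueError("need at least 20 non-missing plots")
    lay = TrialLayout(layout.ranges[ok], layout.rows[ok], layout.genotypes[ok])
    y = y[ok]
    n = len(y)

    X, beta_names, Zg, geno_levels = _design(lay, linear_trends)
    Zr = Zc = None
    if random_range:
        lev, idx = np.unique(lay.ranges, return_inverse=True)
        Zr = np.zeros((n, len(lev)))
        Zr[np.arange(n), idx] = 1.0
    if random_row:
        lev, idx = np.unique(lay.rows, return_inverse=True)
        Zc = np.zeros((n, len(lev)))
        Zc[np.arange(n), idx] = 1.0

    # parameter vector: [atanh rho_range, atanh rho_row]? + log gamma terms
    names = []
    if ar1:
        names += ["rho_range", "rho_row"]
    names += ["gamma_g"]
    if random_range:
        names += ["gamma_range"]
    if random_row:
        names += ["gamma_row"]

    GgGt = Zg @ Zg.T
    GrGt = Zr @ Zr.T if Zr is not None else None
    GcGt = Zc @ Zc.T if Zc is not None else None

    def unpack(theta):
        i = 0
        if ar1:
            rr, rc = np.tanh(theta[0]), np.tanh(theta[1])
            i = 2
        else:
            rr = rc = 0.0
        gammas = np.exp(theta[i:])
        return rr, rc, gammas

    def build_C(theta):
        rr, rc, gammas = unpack(theta)
        C = _ar1_corr(lay.ranges, lay.rows, rr, rc)
        j = 0
        C = C + gammas[j] * GgGt
        j += 1
        if GrGt is not None:
            C = C + gammas[j] * GrGt
            j += 1
        if GcGt is not None:
            C = C + gammas[j] * GcGt
        return C

    def negrll(theta):
        try:
            rll, *_ = _profile_rll(build_C(theta), X, y)
        except np.linalg.LinAlgError:
            return 1e10
        return -rll

    x0 = np.zeros(len(names))
    x0[-(1 + int(random_range) + int(random_row)):] = np.log(0.5)
    bounds = []
    for nm in names:
        if nm.startswith("rho"):
            bounds.append((-3.8, 3.8))  # |rho| < 0.9993
        else:
            bounds.append((np.log(1e-8), np.log(1e4)))
    res = optimize.minimize(
        negrll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(f"REML did not converge: {res.message}; last iterate {res.x}")

    theta = res.x
    rr, rc, gammas = unpack(theta)
    C = build_C(theta)
    rll, s2, beta, XtCiX, cf, Ci_r = _profile_rll(C, X, y)
    beta_cov = np.linalg.inv(XtCiX) * s2
    beta_se = np.sqrt(np.diag(beta_cov))

    j = 0
    s2_g = s2 * gammas[j]; j += 1
    s2_r = s2 * gammas[j] if random_range else 0.0
    if random_range:
        j += 1
    s2_c = s2 * gammas[j] if random_row else 0.0

    # BLUPs and conditional residuals: u = s2_g Z' V^-1 (y - Xb) = gamma_g Z' C^-1 r
    u_g = gammas[0] * (Zg.T @ Ci_r)
    K = _ar1_corr(lay.ranges, lay.rows, rr, rc)
    e_hat = K @ Ci_r  # conditional residual BLUP (in y units)
    KCiK = K @ cho_solve(cf, K)
    sd = np.sqrt(np.maximum(np.diag(KCiK), 1e-12) * s2)
    z = e_hat / sd

    # residuals mapped back to the original (pre-missing-filter) order
    resid_full = np.full(len(layout), np.nan)
    z_full = np.full(len(layout), np.nan)
    resid_full[ok] = e_hat
    z_full[ok] = z

    n_vp = 1 + len(gammas) + (2 if ar1 else 0)
    fit = SpatialFitResult(
        rho_range=rr,
        rho_row=rc,
        sigma2_e=s2,
        sigma2_g=s2_g,
        sigma2_range=s2_r,
        sigma2_row=s2_c,
        beta=beta,
        beta_se=beta_se,
        beta_names=beta_names,
        rll=rll,
        n_vparams=n_vp,
        aic=-2.0 * rll + 2.0 * n_vp,
        bic=-2.0 * rll + np.log(n - X.shape[1]) * n_vp,
        genotype_blups=pd.Series(u_g, index=geno_levels),
        residuals=resid_full,
        std_residuals=z_full,
        terms={
            "ar1": ar1,
            "random_range": random_range,
            "random_row": random_row,
            "linear_trends": linear_trends,
        },
        converged=bool(res.success),
        n=n,
    )
    return fit


def select_spatial_model(
    layout: TrialLayout, y: np.ndarray, alpha: float = 0.05
) -> SpatialFitResult:
    """Forward ladder: iid -> AR1xAR1 -> +random range -> +random row ->
    +linear trends; keeps a term when it significantly improves the model."""
    current = fit_single_site(layout, y, ar1=False)
    kw = {"ar1": False, "random_range": False, "random_row": False, "linear_trends": False}

    for term, df in (("ar1", 2), ("random_range", 1), ("random_row", 1)):
        trial_kw = dict(kw)
        trial_kw[term] = True
        try:
            cand = fit_single_site(layout, y, **trial_kw)
        except (RuntimeError, np.linalg.LinAlgError):
            continue
        lrt = 2.0 * (cand.rll - current.rll)
        if lrt > stats.chi2.ppf(1.0 - alpha, df):
            current, kw = cand, trial_kw

    trial_kw = dict(kw)
    trial_kw["linear_trends"] = True
    try:
        cand = fit_single_site(layout, y, **trial_kw)
        wald = np.abs(cand.beta[1:3] / cand.beta_se[1:3])
        if np.any(wald > stats.norm.ppf(1.0 - alpha / 2.0)):
            current = cand
    except (RuntimeError, np.linalg.LinAlgError):
        pass
    return current


def sample_variogram(
    residuals: np.ndarray, layout: TrialLayout, max_lag: int | None = None
) -> pd.DataFrame:
    """Empirical semivariogram of plot residuals on the trial grid.

    gamma(l1, l2) = half the mean squared difference of residual pairs at
    absolute range-lag l1 and row-lag l2.  Empty lag bins get count 0.
    """
    r = np.asarray(residuals, float)
    ok = np.isfinite(r)
    r = r[ok]
    ra = layout.ranges[ok]
    ro = layout.rows[ok]
    if r.size < 20:
        raise ValueError("need residuals for at least 20 plots")
    d1 = np.abs(ra[:, None] - ra[None, :])
    d2 = np.abs(ro[:, None] - ro[None, :])
    sq = 0.5 * (r[:, None] - r[None, :]) ** 2
    iu = np.triu_indices(r.size, k=1)
    d1, d2, sq = d1[iu], d2[iu], sq[iu]
    m1 = int(d1.max()) if max_lag is None else max_lag
    m2 = int(d2.max()) if max_lag is None else max_lag
    rows = []
    for l1 in range(m1 + 1):
        sel1 = d1 == l1
        for l2 in range(m2 + 1):
            if l1 == 0 and l2 == 0:
                continue
            sel = sel1 & (d2 == l2)
            cnt = int(sel.sum())
            rows.append(
                {
                    "range_lag": l1,
                    "row_lag": l2,
                    "semivariance": float(sq[sel].mean()) if cnt else np.nan,
                    "count": cnt,
                }
            )
    return pd.DataFrame(rows)


def flag_outliers(fit: SpatialFitResult, threshold: float = 3.5) -> np.ndarray:
    """Indices of plots whose |standardized conditional residual| exceeds
    the threshold.  Removal is the caller's choice."""
    z = fit.std_residuals
    return np.flatnonzero(np.abs(z) > threshold)
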