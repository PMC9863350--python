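"""Multi-environment pedigree mixed models with factor-analytic G x E.

The across-site model for one trait treats 'site' as fixed and
'genotype x site' as random:

    y_(gsr) = tau_s + ua_(gs) + una_(gs) + e_(gsr)

* ua: additive genotype-by-site effects.  Across genotypes they are
  correlated through the pedigree relationship matrix A; across sites
  through a p x p genetic covariance G_a.  The base model uses a diagonal
  G_a (independent sites); the factor-analytic model of order k writes
  G_a = Lambda Lambda' + Psi with site loadings Lambda (p x k) and
  site-specific variances Psi, so vec(ua) ~ N(0, G_a kron A).
* una: nonadditive genotype-within-site effects, independent with
  site-specific variance (a diagonal term absorbing dominance/epistasis
  and family-bulk effects).
* e: plot residuals, iid within site with site-specific variance.

Estimation is REML.  Plot records are collapsed exactly to genotype-by-site
cell means: the within-cell contrasts contribute a closed-form chi-square
term in the residual variances, and the cell means carry everything else.
The residual log-likelihood is maximised over an unconstrained
parametrization (free loadings, log variances) by L-BFGS-B with the
analytic REML score; loadings are identified after fitting by rotation to
the canonical orientation in which Lambda' Psi^-1 Lambda is diagonal.

BLUPs of the additive effects (and their prediction error variances) are
recovered for every genotype at every site by conditional-mean algebra,
including genotypes with no records, whose information flows through A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from breedgain.pedigree import RelationshipMatrix

__all__ = [
    "METDataset",
    "FAFit",
    "fit_base_model",
    "fit_fa_model",
    "select_optimum_model",
    "rotate_loadings",
    "pbv_across_env",
    "env_genetic_correlations",
    "heritability_and_accuracy",
    "solve_blup",
]

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# data container


@dataclass
class METDataset:
    """Genotype-by-site cell means plus within-cell residual information.

    Built from a stacked plot table (columns site, genotype, value); every
    genotype must appear in the pedigree.  Sites with fewer than
    ``min_records`` non-missing plots are dropped with a warning.
    """

    sites: list[str]
    genotypes: list[str]  # observed genotypes (order of A submatrix)
    cell_site: np.ndarray  # site index per cell
    cell_geno: np.ndarray  # genotype index per cell
    cell_mean: np.ndarray
    cell_n: np.ndarray
    rss_site: np.ndarray  # pooled within-cell residual SS per site
    df_site: np.ndarray  # within-cell residual df per site
    A: np.ndarray  # relationship submatrix over observed genotypes
    F: np.ndarray  # inbreeding per observed genotype
    pedigree: RelationshipMatrix | None = None

    @classmethod
    def from_plots(
        cls,
        plots: pd.DataFrame,
        pedigree: RelationshipMatrix,
        value_col: str = "value",
        min_records: int = 20,
    ) -> "METDataset":
        frame = plots[["site", "genotype", value_col]].dropna(subset=[value_col]).copy()
        counts = frame.groupby("site").size()
        small = counts[counts < min_records].index.tolist()
        if small:
            warnings.warn(f"dropping sites with < {min_records} records: {small}",
                          stacklevel=2)
            frame = frame[~frame["site"].isin(small)]
        if frame.empty:
            raise ValueError("no data left after filtering")
        missing = sorted(set(frame["genotype"].astype(str)) - set(pedigree.ids))
        if missing:
            raise ValueError(f"genotypes absent from pedigree: {missing[:10]}")

        sites = sorted(frame["site"].astype(str).unique())
        genotypes = sorted(frame["genotype"].astype(str).unique())
        sidx = {s: i for i, s in enumerate(sites)}
        gidx = {g: i for i, g in enumerate(genotypes)}

        grp = frame.groupby(["site", "genotype"])[value_col]
        agg = grp.agg(["mean", "count", "var"]).reset_index()
        cell_site = agg["site"].map(sidx).to_numpy()
        cell_geno = agg["genotype"].map(gidx).to_numpy()
        cell_mean = agg["mean"].to_numpy(float)
        cell_n = agg["count"].to_numpy(float)
        within_ss = np.where(agg["count"] > 1, agg["var"].fillna(0.0) * (agg["count"] - 1), 0.0)
        rss = np.zeros(len(sites))
        df = np.zeros(len(sites))
        for j in range(len(sites)):
            sel = cell_site == j
            rss[j] = within_ss[sel].sum()
            df[j] = (cell_n[sel] - 1).sum()

        sub = pedigree.submatrix(genotypes)
        return cls(
            sites=sites,
            genotypes=genotypes,
            cell_site=cell_site,
            cell_geno=cell_geno,
            cell_mean=cell_mean,
            cell_n=cell_n,
            rss_site=rss,
            df_site=df,
            A=sub.a,
            F=np.diag(sub.a) - 1.0,
            pedigree=pedigree,
        )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_cells(self) -> int:
        return len(self.cell_mean)


# ---------------------------------------------------------------------------
# fit container


@dataclass
class FAFit:
    k: int
    sites: list[str]
    genotypes: list[str]
    loadings: np.ndarray  # p x k (empty for k = 0)
    psi: np.ndarray  # p specific/site variances
    sigma2_na: np.ndarray  # p
    sigma2_e: np.ndarray  # p
    site_means: np.ndarray  # fixed site effects
    rll: float
    n_vparams: int
    aic: float
    bic: float
    u: np.ndarray  # additive BLUPs, genotypes x sites
    u_na: np.ndarray  # nonadditive BLUPs per cell
    pev: np.ndarray  # PEV of additive effects, genotypes x sites
    scores: np.ndarray  # genotype factor scores, genotypes x k
    F: np.ndarray  # inbreeding per genotype
    dataset: METDataset = field(repr=False)
    converged: bool = True
    rotated: bool = False

    @property
    def genetic_covariance(self) -> np.ndarray:
        """Fitted between-site additive covariance Lambda Lambda' + Psi."""
        g = np.diag(self.psi).astype(float)
        if self.k:
            g = g + self.loadings @ self.loadings.T
        return g

    @property
    def pvaf(self) -> float:
        """% additive variance accounted for by the common factors,
        site-summed: 100 * sum_j (LL')_jj / sum_j (LL' + Psi)_jj."""
        if self.k == 0:
            return 0.0
        common = float(np.sum(np.sum(self.loadings**2, axis=1)))
        total = float(np.sum(np.sum(self.loadings**2, axis=1) + self.psi))
        return 100.0 * common / total


# ---------------------------------------------------------------------------
# REML engine


def _n_vparams(p: int, k: int) -> int:
    # psi/sigma_a (p) + sigma_na (p) + sigma_e (p) + loadings net of rotation
    return 3 * p + p * k - k * (k - 1) // 2


class _Engine:
    def __init__(self, data: METDataset, k: int):
        self.d = data
        self.k = k
        self.p = data.n_sites
        n = data.n_cells
        self.A_big = data.A[np.ix_(data.cell_geno, data.cell_geno)]
        self.M = np.zeros((n, self.p))
        self.M[np.arange(n), data.cell_site] = 1.0
        self.X = self.M  # site means are the fixed effects
        self.y = data.cell_mean

    # parameter layout: [lambda (p*k)] + [log psi (p)] + [log s2_na (p)] + [log s2_e (p)]
    def unpack(self, theta):
        p, k = self.p, self.k
        i = p * k
        lam = theta[:i].reshape(p, k) if k else np.zeros((p, 0))
        psi = np.exp(theta[i : i + p])
        s2na = np.exp(theta[i + p : i + 2 * p])
        s2e = np.exp(theta[i + 2 * p : i + 3 * p])
        return lam, psi, s2na, s2e

    def build_V(self, lam, psi, s2na, s2e):
        d = self.d
        G = np.diag(psi) + (lam @ lam.T if self.k else 0.0)
        Gm = G[np.ix_(d.cell_site, d.cell_site)]
        V = Gm * self.A_big
        diag = s2na[d.cell_site] + s2e[d.cell_site] / d.cell_n
        V[np.diag_indices_from(V)] += diag
        return V, G

    def _within_ll(self, s2e):
        # within-cell contrasts plus the mean-collapse Jacobian constant,
        # so the value matches the plot-level residual log-likelihood
        d = self.d
        ll = -0.5 * float(np.sum(np.log(d.cell_n)))
        for j in range(self.p):
            if d.df_site[j] > 0:
                ll -= 0.5 * (
                    d.df_site[j] * (_LOG2PI + np.log(s2e[j])) + d.rss_site[j] / s2e[j]
                )
        return ll

    def rll(self, theta):
        lam, psi, s2na, s2e = self.unpack(theta)
        V, _ = self.build_V(lam, psi, s2na, s2e)
        X, y = self.X, self.y
        try:
            cf = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf, None
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        ViX = cho_solve(cf, X)
        Viy = cho_solve(cf, y)
        XtViX = X.T @ ViX
        sign, logdet_xx = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return -np.inf, None
        beta = np.linalg.solve(XtViX, X.T @ Viy)
        r = y - X @ beta
        Vir = cho_solve(cf, r)
        quad = float(r @ Vir)
        n, pf = X.shape
        rll = -0.5 * ((n - pf) * _LOG2PI + logdet + logdet_xx + quad)
        rll += self._within_ll(s2e)
        return rll, (cf, beta, Vir, ViX, XtViX)

    def rll_and_grad(self, theta):
        lam, psi, s2na, s2e = self.unpack(theta)
        V, _ = self.build_V(lam, psi, s2na, s2e)
        X, y, d = self.X, self.y, self.d
        try:
            cf = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf, np.zeros_like(theta)
        n = V.shape[0]
        Vi = cho_solve(cf, np.eye(n))
        ViX = Vi @ X
        XtViX = X.T @ ViX
        sign, logdet_xx = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return -np.inf, np.zeros_like(theta)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        beta = np.linalg.solve(XtViX, ViX.T @ y)
        r = y - X @ beta
        Vir = Vi @ r
        rll = -0.5 * ((n - X.shape[1]) * _LOG2PI + logdet + logdet_xx + float(r @ Vir))
        rll += self._within_ll(s2e)

        P = Vi - ViX @ np.linalg.solve(XtViX, ViX.T)
        q = P @ y  # equals Vir for this X, but keep general
        # block sums S[j1,j2] = sum P*A over site blocks; Q likewise with qq'
        PA = P * self.A_big
        S = self.M.T @ PA @ self.M
        qA = (q[:, None] * self.A_big) * q[None, :]
        Q = self.M.T @ qA @ self.M
        diagP = np.diag(P)
        diagq2 = q**2

        grad = np.zeros_like(theta)
        p, k = self.p, self.k
        # loadings
        for rcol in range(k):
            lr = lam[:, rcol]
            # dG/dlam_{j r} = e_j lr' + lr e_j'
            tr = 2.0 * (S @ lr)  # vector over j
            qu = 2.0 * (Q @ lr)
            for j in range(p):
                grad[j * k + rcol] = -0.5 * (tr[j] - qu[j])
        i = p * k
        # log psi
        for j in range(p):
            grad[i + j] = -0.5 * psi[j] * (S[j, j] - Q[j, j])
        # log s2_na
        for j in range(p):
            sel = d.cell_site == j
            grad[i + p + j] = -0.5 * s2na[j] * (diagP[sel].sum() - diagq2[sel].sum())
        # log s2_e
        for j in range(p):
            sel = d.cell_site == j
            w = 1.0 / d.cell_n[sel]
            tr = (diagP[sel] * w).sum()
            qu = (diagq2[sel] * w).sum()
            g = -0.5 * s2e[j] * (tr - qu)
            if d.df_site[j] > 0:
                g += -0.5 * (d.df_site[j] - d.rss_site[j] / s2e[j])
            grad[i + 2 * p + j] = g
        return rll, grad

    def _empirical_site_cov(self) -> np.ndarray:
        """Pairwise between-site covariance of cell means across genotypes;
        its off-diagonals estimate the additive covariance directly."""
        d = self.d
        wide = pd.DataFrame(
            {
                "geno": d.cell_geno,
                "site": d.cell_site,
                "y": d.cell_mean,
            }
        ).pivot_table(index="geno", columns="site", values="y")
        S = wide.cov().reindex(index=range(self.p), columns=range(self.p)).to_numpy()
        S = np.where(np.isfinite(S), S, 0.0)
        return 0.5 * (S + S.T)

    def initial(self, base: "FAFit | None" = None) -> np.ndarray:
        d, p, k = self.d, self.p, self.k
        theta = np.zeros(p * k + 3 * p)
        S = self._empirical_site_cov()
        var_site = np.maximum(np.diag(S), 1e-8)
        if base is not None:
            sa = np.maximum(base.genetic_covariance.diagonal().copy(), 1e-8)
            s2na = np.maximum(base.sigma2_na.copy(), 1e-8)
            s2e = np.maximum(base.sigma2_e.copy(), 1e-8)
        else:
            s2e = np.empty(p)
            for j in range(p):
                if d.df_site[j] > 0:
                    s2e[j] = max(d.rss_site[j] / d.df_site[j], 1e-4 * var_site[j])
                else:
                    s2e[j] = 0.4 * var_site[j]
            sa = np.maximum(0.5 * var_site, 1e-8)
            s2na = np.maximum(0.2 * var_site, 1e-8)
        if k:
            # eigen-initialize the loadings from the empirical covariance,
            # keeping the (better) diagonal from the base fit
            G0 = S.copy()
            np.fill_diagonal(G0, sa)
            w, V = np.linalg.eigh(G0)
            order = np.argsort(w)[::-1][:k]
            lam = V[:, order] * np.sqrt(np.maximum(w[order], 0.01 * sa.mean()))
            sign = np.where(lam.sum(axis=0) >= 0, 1.0, -1.0)
            lam = lam * sign[None, :]
            theta[: p * k] = lam.ravel()
            psi0 = np.maximum(sa - np.sum(lam**2, axis=1), 0.05 * sa)
        else:
            psi0 = sa
        theta[p * k : p * k + p] = np.log(np.maximum(psi0, 1e-8))
        theta[p * k + p : p * k + 2 * p] = np.log(np.maximum(s2na, 1e-8))
        theta[p * k + 2 * p :] = np.log(np.maximum(s2e, 1e-8))
        return theta


def _fit(data: METDataset, k: int, base: FAFit | None, max_iter: int,
         theta0: np.ndarray | None = None) -> FAFit:
    eng = _Engine(data, k)
    x0 = theta0 if theta0 is not None else eng.initial(base)
    p = data.n_sites
    lb = np.full_like(x0, -np.inf)
    ub = np.full_like(x0, np.inf)
    lb[p * k :] = np.log(1e-10)
    ub[p * k :] = np.log(1e8)

    def fun(theta):
        rll, grad = eng.rll_and_grad(theta)
        if not np.isfinite(rll):
            return 1e10, np.zeros_like(theta)
        return -rll, -grad

    res = optimize.minimize(
        fun, x0, jac=True, method="L-BFGS-B",
        bounds=list(zip(lb, ub)),
        options={"maxiter": max_iter, "ftol": 1e-11, "gtol": 1e-6},
    )
    if not np.isfinite(res.fun) or res.fun >= 1e9:
        raise RuntimeError(f"REML did not converge for FA({k}): {res.message}")

    theta = res.x
    lam, psi, s2na, s2e = eng.unpack(theta)
    if k and np.any(psi < 1e-8):
        warnings.warn("specific variance collapsed to the boundary (Heywood case)",
                      stacklevel=2)
    rll, aux = eng.rll(theta)
    cf, beta, Vir, ViX, XtViX = aux

    G = np.diag(psi) + (lam @ lam.T if k else 0.0)
    fit = _finish_fit(data, k, lam, psi, s2na, s2e, beta, rll, G, cf, Vir)
    fit.converged = bool(res.success)
    return fit


def _finish_fit(data, k, lam, psi, s2na, s2e, beta, rll, G, cf, Vir) -> FAFit:
    d = data
    p = d.n_sites
    ng = len(d.genotypes)
    # additive BLUPs for every observed genotype at every site:
    # U[:, j] = A[:, g_c] @ (G[j, s_c] * Vir_c)
    A_cols = d.A[:, d.cell_geno]  # ng x n_cells
    U = np.empty((ng, p))
    for j in range(p):
        U[:, j] = A_cols @ (G[j, d.cell_site] * Vir)
    u_na = s2na[d.cell_site] * Vir  # nonadditive BLUP per observed cell

    # PEV diagonal: G_jj*A_ii - c'V^-1 c with c the covariance row
    L = cf[0]  # lower Cholesky of V
    pev = np.empty((ng, p))
    # solve L Z = C' where C rows are cov(u_ij, y): do per site to bound memory
    for j in range(p):
        C = G[j, d.cell_site][None, :] * A_cols  # ng x n_cells
        W = solve_triangular(L, C.T, lower=True)  # n_cells x ng
        pev[:, j] = G[j, j] * np.diag(d.A) - np.sum(W**2, axis=0)
    pev = np.maximum(pev, 0.0)

    scores = _project_scores(lam, psi, U) if k else np.zeros((ng, 0))
    n_vp = _n_vparams(p, k)
    n_eff = d.n_cells + int(d.df_site.sum()) - p
    fit = FAFit(
        k=k,
        sites=list(d.sites),
        genotypes=list(d.genotypes),
        loadings=lam,
        psi=psi,
        sigma2_na=s2na,
        sigma2_e=s2e,
        site_means=beta,
        rll=rll,
        n_vparams=n_vp,
        aic=-2.0 * rll + 2.0 * n_vp,
        bic=-2.0 * rll + np.log(max(n_eff, 2)) * n_vp,
        u=U,
        u_na=u_na,
        pev=pev,
        scores=scores,
        F=d.F.copy(),
        dataset=d,
    )
    return fit


def _project_scores(lam, psi, U) -> np.ndarray:
    """Generalized least-squares projection of per-site effects onto the
    loadings: f_i = (L'Psi^-1 L)^-1 L'Psi^-1 u_i."""
    w = 1.0 / np.maximum(psi, 1e-8)
    lt_w = lam.T * w[None, :]
    H = np.linalg.solve(lt_w @ lam, lt_w)
    return U @ H.T


def fit_base_model(data: METDataset, max_iter: int = 500) -> FAFit:
    """Diagonal (between-site independent) additive model, k = 0."""
    return _fit(data, 0, None, max_iter)


def fit_fa_model(
    data: METDataset,
    k: int,
    base: FAFit | None = None,
    max_iter: int = 500,
    theta0: np.ndarray | None = None,
) -> FAFit:
    """Factor-analytic model of order k (1 <= k < number of sites)."""
    if k < 1:
        raise ValueError("k must be >= 1 (use fit_base_model for k = 0)")
    if k >= data.n_sites:
        raise ValueError("k must be smaller than the number of sites")
    if base is None:
        base = fit_base_model(data, max_iter=max_iter)
    return _fit(data, k, base, max_iter, theta0=theta0)


def select_optimum_model(
    data: METDataset,
    max_k: int = 2,
    alpha: float = 0.05,
    min_pvaf_gain: float = 2.0,
    max_iter: int = 500,
) -> tuple[FAFit, pd.DataFrame]:
    """Sequential fits base -> FA(1) -> ... with a stop rule.

    Order k+1 is preferred over k only when the REML LRT is significant at
    ``alpha`` and the %VAF gain exceeds ``min_pvaf_gain`` percentage points
    (the base model has no common factors, so the first step is judged by
    the LRT alone).  Returns the chosen fit and the selection table.
    """
    fits = [fit_base_model(data, max_iter=max_iter)]
    rows = [_sel_row(fits[0])]
    chosen = 0
    for k in range(1, max_k + 1):
        if k >= data.n_sites:
            break
        try:
            cand = fit_fa_model(data, k, base=fits[0], max_iter=max_iter)
        except RuntimeError:
            break
        fits.append(cand)
        rows.append(_sel_row(cand))
        prev = fits[chosen]
        df = cand.n_vparams - prev.n_vparams
        lrt = 2.0 * (cand.rll - prev.rll)
        sig = lrt > stats.chi2.ppf(1.0 - alpha, max(df, 1))
        gain = cand.pvaf - prev.pvaf
        if sig and (prev.k == 0 or gain > min_pvaf_gain):
            chosen = len(fits) - 1
        else:
            break
    table = pd.DataFrame(rows)
    table["selected"] = [i == chosen for i in range(len(rows))]
    return fits[chosen], table


def _sel_row(fit: FAFit) -> dict:
    return {
        "model": "base" if fit.k == 0 else f"FA({fit.k})",
        "n_vparams": fit.n_vparams,
        "rll": fit.rll,
        "aic": fit.aic,
        "bic": fit.bic,
        "pvaf": fit.pvaf if fit.k else np.nan,
    }


# ---------------------------------------------------------------------------
# post-fit operations


def rotate_loadings(fit: FAFit) -> FAFit:
    """Rotate to the canonical orientation and fix signs.

    The loadings are rotated by the right singular vectors of
    Psi^{-1/2} Lambda, which orders factors by explained variance in the
    fitted metric and makes Lambda' Psi^-1 Lambda diagonal; scores are
    counter-rotated so the fitted covariance and all site effects are
    unchanged.  Each factor's sign is chosen so its mean loading is >= 0.
    """
    if fit.k == 0:
        return fit
    w = 1.0 / np.sqrt(np.maximum(fit.psi, 1e-10))
    _, _, vt = np.linalg.svd(w[:, None] * fit.loadings, full_matrices=False)
    R = vt.T  # k x k orthogonal
    lam = fit.loadings @ R
    scores = fit.scores @ R
    signs = np.where(lam.mean(axis=0) >= 0, 1.0, -1.0)
    lam = lam * signs[None, :]
    scores = scores * signs[None, :]
    return FAFit(**{**fit.__dict__, "loadings": lam, "scores": scores, "rotated": True})


def pbv_across_env(fit: FAFit) -> pd.Series:
    """PBV per genotype: the additive effect averaged over the trait's
    sites, in trait units."""
    return pd.Series(fit.u.mean(axis=1), index=fit.genotypes, name="PBV")


def predict_u(fit: FAFit, ids: list[str]) -> pd.DataFrame:
    """Additive site effects for arbitrary pedigree genotypes (e.g. ancestors
    or unobserved controls), by conditional-mean algebra through A."""
    d = fit.dataset
    if d.pedigree is None:
        raise ValueError("dataset carries no full pedigree")
    eng = _Engine(d, fit.k)
    V, G = eng.build_V(fit.loadings, fit.psi, fit.sigma2_na, fit.sigma2_e)
    cf = cho_factor(V, lower=True)
    r = d.cell_mean - fit.site_means[d.cell_site]
    Vir = cho_solve(cf, r)
    rows_idx = [d.pedigree.index[g] for g in ids]
    cols_idx = [d.pedigree.index[g] for g in np.array(d.genotypes)[d.cell_geno]]
    A_cross = d.pedigree.a[np.ix_(rows_idx, cols_idx)]
    U = np.empty((len(ids), d.n_sites))
    for j in range(d.n_sites):
        U[:, j] = A_cross @ (G[j, d.cell_site] * Vir)
    return pd.DataFrame(U, index=ids, columns=fit.sites)


def env_genetic_correlations(fit: FAFit) -> pd.DataFrame:
    """Between-site additive genetic correlation matrix from LL' + Psi."""
    if fit.k == 0:
        raise ValueError("genetic correlations require a factor-analytic fit")
    G = fit.genetic_covariance
    sd = np.sqrt(np.diag(G))
    zero = sd <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = G / np.outer(sd, sd)
    corr[np.ix_(zero, zero)] = np.nan
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return pd.DataFrame(corr, index=fit.sites, columns=fit.sites)


def heritability_and_accuracy(fit: FAFit) -> tuple[pd.Series, pd.Series]:
    """Per-site narrow-sense heritability and per-genotype accuracy.

    h2_j = s2_a,j / (s2_a,j + s2_na,j + s2_e,j);
    r_ij = sqrt(max(0, 1 - PEV_ij / ((1 + F_i) s2_a,j))), averaged over sites.
    """
    s2a = np.diag(fit.genetic_covariance)
    denom = s2a + fit.sigma2_na + fit.sigma2_e
    if np.all(denom == 0):
        raise ValueError("all variance components are zero")
    h2 = pd.Series(s2a / denom, index=fit.sites, name="h2")

    with np.errstate(divide="ignore", invalid="ignore"):
        rel = 1.0 - fit.pev / ((1.0 + fit.F)[:, None] * s2a[None, :])
    r = np.sqrt(np.clip(rel, 0.0, 1.0))
    r = np.where(s2a[None, :] > 0, r, np.nan)
    acc = pd.Series(np.nanmean(r, axis=1), index=fit.genotypes, name="accuracy")
    return h2, acc


def evaluate_at(
    data: METDataset,
    loadings: np.ndarray,
    psi: np.ndarray,
    sigma2_na: np.ndarray,
    sigma2_e: np.ndarray,
) -> FAFit:
    """FAFit evaluated at fixed variance parameters (no estimation).

    Useful for validating BLUPs, PEVs and accuracies against closed-form
    expectations when the variance components are known.
    """
    loadings = np.atleast_2d(np.asarray(loadings, float))
    if loadings.shape[1] == 0:
        k = 0
        loadings = np.zeros((data.n_sites, 0))
    else:
        k = loadings.shape[1]
    eng = _Engine(data, k)
    theta = np.concatenate(
        [loadings.ravel(), np.log(np.maximum(psi, 1e-12)),
         np.log(np.maximum(sigma2_na, 1e-12)), np.log(np.maximum(sigma2_e, 1e-12))]
    )
    rll, aux = eng.rll(theta)
    if aux is None:
        raise np.linalg.LinAlgError("covariance not positive definite at "
                                    "the supplied parameters")
    cf, beta, Vir, ViX, XtViX = aux
    G = np.diag(np.asarray(psi, float)) + (loadings @ loadings.T if k else 0.0)
    return _finish_fit(data, k, loadings, np.asarray(psi, float),
                       np.asarray(sigma2_na, float), np.asarray(sigma2_e, float),
                       beta, rll, G, cf, Vir)


def solve_blup(
    data: METDataset,
    G: np.ndarray,
    sigma2_na: np.ndarray,
    sigma2_e: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """BLUP of additive effects with variance components held fixed.

    Returns (site_means, U).  Useful for validating the mixed-model
    solutions against direct joint-Gaussian conditioning on small cases.
    """
    eng = _Engine(data, 0)
    d = data
    Gm = G[np.ix_(d.cell_site, d.cell_site)]
    V = Gm * eng.A_big
    V[np.diag_indices_from(V)] += sigma2_na[d.cell_site] + sigma2_e[d.cell_site] / d.cell_n
    cf = cho_factor(V, lower=True)
    X, y = eng.X, eng.y
    ViX = cho_solve(cf, X)
    beta = np.linalg.solve(X.T @ ViX, ViX.T @ y)
    Vir = cho_solve(cf, y - X @ beta)
    A_cols = d.A[:, d.cell_geno]
    U = np.empty((len(d.genotypes), d.n_sites))
    for j in range(d.n_sites):
        U[:, j] = A_cols @ (G[j, d.cell_site] * Vir)
    return beta, U
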