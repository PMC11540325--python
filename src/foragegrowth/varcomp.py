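"""Per-time-point genetic analysis: single-trait REML, heritability, bivariate
genetic correlation, and plain phenotypic correlations.

The single-trait plot model is

    y = 1 mu + X b + Z g + e,     g ~ N(0, I sigma2_g),  e ~ N(0, I sigma2_e),

with replicate fixed (the intercept absorbed into the replicate cells) and
genotype random; plot-level broad-sense heritability is
H2 = sigma2_g / (sigma2_g + sigma2_e).  The bivariate model stacks two traits
observed on the same plots with an unstructured 2x2 genetic covariance
Sigma (x) I and an unstructured 2x2 residual covariance per plot, from which
the genetic correlation r_g = sigma_g12 / sqrt(sigma_g1^2 sigma_g2^2) follows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .reml import MixedModelREML, RandomTerm, solve_blups

__all__ = [
    "VarianceComponents",
    "fit_st_blup",
    "st_blups_at",
    "heritability",
    "fit_bivariate",
    "BivariateFit",
    "phenotypic_correlation",
]

_VAR_FLOOR = 1e-8


@dataclass
class VarianceComponents:
    """Univariate REML variance components with convergence metadata."""

    sigma2_g: float
    sigma2_e: float
    loglik: float
    n_iter: int
    converged: bool
    blups: pd.Series | None = None
    beta: pd.Series | None = None
    loglik_path: np.ndarray | None = None


def _design_matrices(data: pd.DataFrame, response: str, genotype: str, replicate: str):
    y = data[response].to_numpy(dtype=float)
    reps = pd.Categorical(data[replicate])
    X = pd.get_dummies(reps, dtype=float).to_numpy()  # cell means: intercept absorbed
    rep_names = [f"{replicate}={c}" for c in reps.categories]
    genos = pd.Categorical(data[genotype])
    Z = pd.get_dummies(genos, dtype=float).to_numpy()
    return y, X, rep_names, Z, list(genos.categories)


def fit_st_blup(
    data: pd.DataFrame,
    response: str,
    *,
    genotype: str = "genotype",
    replicate: str = "replicate",
    tol: float = 1e-8,
    max_iter: int = 500,
) -> VarianceComponents:
    """REML fit of the single-trait genotype-random plot model.

    EM-REML with average-information acceleration; the restricted
    log-likelihood path is non-decreasing.  Non-convergence is flagged on the
    result, never raised; a singular fixed design raises naming the aliased
    columns.
    """
    data = data.dropna(subset=[response])
    if data[genotype].nunique() < 2:
        raise ValueError("need at least 2 genotypes")
    y, X, rep_names, Z, geno_levels = _design_matrices(data, response, genotype, replicate)
    if np.var(y) < 1e-14:
        # Degenerate constant response: both components at the zero boundary.
        return VarianceComponents(
            sigma2_g=0.0,
            sigma2_e=0.0,
            loglik=np.nan,
            n_iter=0,
            converged=True,
            blups=pd.Series(np.zeros(len(geno_levels)), index=geno_levels),
            beta=pd.Series(np.full(X.shape[1], y.mean() if y.size else np.nan), index=rep_names),
        )
    term = RandomTerm(name="genotype", Z=Z, n_levels=Z.shape[1], n_coef=1)
    model = MixedModelREML(y, X, [term], fixed_names=rep_names)
    res = model.fit(tol=tol, max_iter=max_iter)
    sg = float(res.K["genotype"][0, 0])
    se = res.sigma2_e_scalar
    return VarianceComponents(
        sigma2_g=0.0 if sg <= 2 * _VAR_FLOOR else sg,
        sigma2_e=se,
        loglik=res.loglik,
        n_iter=res.n_iter,
        converged=res.converged,
        blups=pd.Series(res.u["genotype"][:, 0], index=geno_levels),
        beta=pd.Series(res.beta, index=rep_names),
        loglik_path=res.loglik_path,
    )


def st_blups_at(
    data: pd.DataFrame,
    response: str,
    sigma2_g: float,
    sigma2_e: float,
    *,
    genotype: str = "genotype",
    replicate: str = "replicate",
) -> pd.Series:
    """Genotype BLUPs from the mixed-model equations at given components."""
    y, X, rep_names, Z, geno_levels = _design_matrices(data, response, genotype, replicate)
    term = RandomTerm(name="genotype", Z=Z, n_levels=Z.shape[1], n_coef=1)
    _, u = solve_blups(y, X, [term], [np.array([[sigma2_g]])], sigma2_e)
    return pd.Series(u["genotype"][:, 0], index=geno_levels)


def heritability(vc: VarianceComponents | tuple[float, float]) -> float:
    """Plot-level broad-sense H2 = sigma2_g / (sigma2_g + sigma2_e).

    Returns NaN when the total variance is zero (undefined, not silently 0).
    """
    if isinstance(vc, VarianceComponents):
        sg, se = vc.sigma2_g, vc.sigma2_e
    else:
        sg, se = vc
    total = sg + se
    if not np.isfinite(total) or total <= 1e-12:
        return float("nan")
    return float(sg / total)


# ---------------------------------------------------------------------------
# Bivariate unstructured model
# ---------------------------------------------------------------------------


@dataclass
class BivariateFit:
    """Bivariate REML fit: 2x2 genetic (G) and residual (R) covariances."""

    G: np.ndarray
    R: np.ndarray
    loglik: float
    converged: bool
    n_iter: int

    @property
    def r_g(self) -> float:
        """Genetic correlation; NaN if either genetic variance is at the zero
        boundary (correlation undefined there)."""
        v1, v2 = self.G[0, 0], self.G[1, 1]
        if v1 <= 2 * _VAR_FLOOR or v2 <= 2 * _VAR_FLOOR:
            return float("nan")
        return float(np.clip(self.G[0, 1] / np.sqrt(v1 * v2), -1.0, 1.0))

    @property
    def r_e(self) -> float:
        v1, v2 = self.R[0, 0], self.R[1, 1]
        if v1 <= 2 * _VAR_FLOOR or v2 <= 2 * _VAR_FLOOR:
            return float("nan")
        return float(np.clip(self.R[0, 1] / np.sqrt(v1 * v2), -1.0, 1.0))


def _chol_from_params(p3: np.ndarray) -> np.ndarray:
    l11, l21, l22 = p3
    L = np.array([[np.exp(l11), 0.0], [l21, np.exp(l22)]])
    return L @ L.T


def _bivariate_neg2ll(params, lam, ytil, xtil, n_pairs, p_fix):
    """-2 restricted log-likelihood profiled on the eigenbasis of ZZ'.

    With both traits observed on the same plots, V = Sigma (x) ZZ' + R0 (x) I;
    on the eigenbasis of ZZ' it splits into independent 2x2 blocks
    V_i = lam_i Sigma + R0, giving an O(n) likelihood evaluation.
    """
    G = _chol_from_params(params[:3])
    R0 = _chol_from_params(params[3:]) + 1e-10 * np.eye(2)
    V = lam[:, None, None] * G[None, :, :] + R0[None, :, :]  # (n, 2, 2)
    det = V[:, 0, 0] * V[:, 1, 1] - V[:, 0, 1] ** 2
    if np.any(det <= 0) or np.any(V[:, 0, 0] <= 0):
        return np.inf
    inv = np.empty_like(V)
    inv[:, 0, 0] = V[:, 1, 1]
    inv[:, 1, 1] = V[:, 0, 0]
    inv[:, 0, 1] = inv[:, 1, 0] = -V[:, 0, 1]
    inv /= det[:, None, None]

    logdet_v = float(np.sum(np.log(det)))
    # X'V^-1X, X'V^-1y, y'V^-1y accumulated over the 2x2 blocks.
    # ytil: (n, 2); xtil: (n, p_fix)
    iy = np.einsum("nab,nb->na", inv, ytil)
    y_v_y = float(np.einsum("na,na->", ytil, iy))
    x_v_y = np.einsum("np,na->ap", xtil, iy).ravel()  # (2*p_fix,) trait-major
    xx = np.einsum("np,nq->npq", xtil, xtil)
    x_v_x = np.einsum("nab,npq->apbq", inv, xx).reshape(2 * p_fix, 2 * p_fix)
    try:
        cf = np.linalg.cholesky(x_v_x)
    except np.linalg.LinAlgError:
        return np.inf
    sol = np.linalg.solve(x_v_x, x_v_y)
    y_p_y = y_v_y - float(x_v_y @ sol)
    logdet_xvx = 2.0 * float(np.sum(np.log(np.diag(cf))))
    n2ll = logdet_v + logdet_xvx + y_p_y
    return n2ll if np.isfinite(n2ll) else np.inf


def fit_bivariate(
    data: pd.DataFrame,
    trait1: str,
    trait2: str,
    *,
    genotype: str = "genotype",
    replicate: str = "replicate",
) -> BivariateFit:
    """REML fit of the paired bivariate genotype model by direct maximization.

    Requires both traits on the same plots (rows with either trait missing are
    dropped).  The restricted likelihood is maximized over
    Cholesky-parameterized G and R with multiple starts.
    """
    d = data.dropna(subset=[trait1, trait2])
    y1 = d[trait1].to_numpy(dtype=float)
    y2 = d[trait2].to_numpy(dtype=float)
    reps = pd.Categorical(d[replicate])
    X = pd.get_dummies(reps, dtype=float).to_numpy()
    genos = pd.Categorical(d[genotype])
    Z = pd.get_dummies(genos, dtype=float).to_numpy()
    if Z.shape[1] < 2:
        raise ValueError("need at least 2 genotypes")

    M = Z @ Z.T
    lam, Q = np.linalg.eigh(M)
    ytil = np.column_stack([Q.T @ y1, Q.T @ y2])
    xtil = Q.T @ X
    p_fix = X.shape[1]

    # Moment-based start: genotype-mean covariance for G, residual for R.
    gm = d.groupby(genotype, observed=True)[[trait1, trait2]].transform("mean")
    resid = d[[trait1, trait2]].to_numpy(dtype=float) - gm.to_numpy(dtype=float)
    means = d.groupby(genotype, observed=True)[[trait1, trait2]].mean().to_numpy()
    G0 = np.cov(means.T) if means.shape[0] > 1 else np.eye(2)
    R0 = np.cov(resid.T)
    vy = max(np.var(y1) + np.var(y2), 1e-8) / 2.0

    def pack(S):
        S = 0.5 * (S + S.T) + 1e-6 * vy * np.eye(2)
        L = np.linalg.cholesky(S)
        return np.array([np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])])

    starts = [
        np.concatenate([pack(np.atleast_2d(G0)), pack(np.atleast_2d(R0))]),
        np.concatenate([pack(0.3 * vy * np.eye(2)), pack(0.7 * vy * np.eye(2))]),
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _bivariate_neg2ll,
            x0,
            args=(lam, ytil, xtil, len(lam), p_fix),
            method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    G = _chol_from_params(best.x[:3])
    R = _chol_from_params(best.x[3:])
    n = 2 * len(lam)
    ll = -0.5 * (best.fun + (n - 2 * p_fix) * np.log(2 * np.pi))
    return BivariateFit(G=G, R=R, loglik=ll, converged=bool(best.success), n_iter=int(best.nit))


# ---------------------------------------------------------------------------
# Phenotypic correlation
# ---------------------------------------------------------------------------


def phenotypic_correlation(
    records: pd.DataFrame,
    trait: str,
    *,
    harvest: str = "harvest",
    plot: str = "plot",
) -> pd.DataFrame:
    """Pearson correlation of plot-level VI with yield, per harvest.

    Uses the flight closest to harvest (the last flight of each cycle) paired
    with the terminal yield rows (``is_yield``).  Needs >= 3 paired plots;
    returns NaN where either variable is constant.
    """
    out = []
    for h, grp in records.groupby(harvest, observed=True):
        vi = grp[~grp["is_yield"]]
        fy = grp[grp["is_yield"]]
        if vi.empty or fy.empty:
            continue
        last_gdd = vi["gdd"].max()
        last = vi[vi["gdd"] == last_gdd].set_index(plot)[trait]
        ydat = fy.set_index(plot)[trait]
        common = last.index.intersection(ydat.index)
        if len(common) < 3:
            raise ValueError(f"harvest {h}: fewer than 3 paired plots")
        x = last.loc[common].to_numpy(dtype=float)
        yv = ydat.loc[common].to_numpy(dtype=float)
        if np.std(x) < 1e-14 or np.std(yv) < 1e-14:
            r = float("nan")
        else:
            r = float(np.corrcoef(x, yv)[0, 1])
        out.append({"harvest": h, "trait": trait, "flight_gdd": last_gdd, "n": len(common), "r": r})
    return pd.DataFrame(out)
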