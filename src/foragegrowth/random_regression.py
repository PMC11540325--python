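"""Random-regression growth-curve model on the Legendre basis.

Fits, by REML, the longitudinal plot model

    VI_tjr = beta_r(t) + sum_k phi_k(t*) u_jk + sum_k phi_k(t*) p_jrk + eps,

with replicate fixed effects nested within time points, per-genotype genetic
coefficient vectors u_j ~ N(0, K_g), per-plot permanent-environment vectors
p_jr ~ N(0, K_p), and a homogeneous (default) or per-time-point residual.
The coefficient covariances induce continuous covariance functions
Cov(t, s) = phi(t)' K phi(s), from which time-resolved genetic variances,
heritabilities, genetic correlations (including with terminal yield appended
as a final, variance-scaled time point) and per-genotype breeding-value
trajectories all derive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import LegendreBasis, legendre_basis
from .reml import MixedModelREML, RandomTerm

__all__ = [
    "RRSpec",
    "RRFit",
    "CovFunction",
    "scale_terminal_yield",
    "fit_rr",
    "covariance_surface",
    "genetic_correlation_curve",
    "growth_curves",
    "heritability_curve",
]


def scale_terminal_yield(yield_values, last_vi_values) -> tuple[np.ndarray, float]:
    """Rescale yield so its sample variance matches the final VI observation.

    Returns ``(scaled_yield, factor)`` with ``factor = sd(last VI)/sd(yield)``.
    Multiplicative, so plot rankings and correlations with anything are
    unchanged.  Zero yield variance is an error (nothing to scale onto).
    """
    yv = np.asarray(yield_values, dtype=float)
    vi = np.asarray(last_vi_values, dtype=float)
    sd_y = float(np.std(yv, ddof=1))
    sd_vi = float(np.std(vi, ddof=1))
    if sd_y <= 0 or not np.isfinite(sd_y):
        raise ValueError("yield variance is zero; cannot scale")
    if sd_vi <= 0 or not np.isfinite(sd_vi):
        raise ValueError("final VI variance is zero; cannot scale onto it")
    factor = sd_vi / sd_y
    return yv * factor, factor


@dataclass
class RRSpec:
    """What to fit: one harvest cycle of one trait.

    ``data`` is a long plot table (one row per plot x flight, plus optional
    ``is_yield`` terminal rows).  ``order`` is the polynomial degree of the
    Legendre basis (degree 3 = 4 coefficients).  ``include_yield`` appends the
    variance-scaled terminal yield as the final time point at its harvest GDD.
    """

    data: pd.DataFrame
    trait: str
    order: int = 3
    order_pe: int | None = None  # defaults to `order`
    include_yield: bool = False
    residual_structure: str = "homogeneous"  # or "per_time_point"

    def __post_init__(self) -> None:
        if self.residual_structure not in ("homogeneous", "per_time_point"):
            raise ValueError("residual_structure must be homogeneous or per_time_point")


@dataclass
class RRFit:
    """Fitted random regression: coefficient covariances and BLUP coefficients."""

    K_g: np.ndarray
    K_p: np.ndarray
    sigma2_e: np.ndarray  # scalar (length 1) or per time point
    beta: pd.Series
    u_hat: pd.DataFrame  # genotypes x coefficients
    p_hat: pd.DataFrame  # plots x coefficients
    basis: LegendreBasis
    basis_pe: LegendreBasis
    time_points: np.ndarray  # flight GDDs used
    terminal_gdd: float | None  # GDD of the appended yield point, if any
    yield_scale: float | None
    loglik: float
    n_iter: int
    converged: bool
    n_psd_clips: int
    residual_groups: list | None = None

    @property
    def genotypes(self) -> list:
        return list(self.u_hat.index)

    def sigma2_e_at(self, _t=None) -> float:
        return float(np.mean(self.sigma2_e))


def _fixed_design(rep: pd.Series, time_label: pd.Series):
    cells = pd.Categorical(
        rep.astype(str).str.cat(time_label.astype(str), sep=":")
    )
    X = pd.get_dummies(cells, dtype=float).to_numpy()
    return X, [f"rep:time={c}" for c in cells.categories]


def _coef_design(levels: pd.Series, phi: np.ndarray):
    cat = pd.Categorical(levels)
    q = len(cat.categories)
    m = phi.shape[1]
    Z = np.zeros((len(levels), q * m))
    codes = np.asarray(cat.codes, dtype=np.int64)  # codes can be int8: widen before arithmetic
    cols = codes[:, None] * m + np.arange(m)[None, :]
    np.put_along_axis(Z, cols, phi, axis=1)
    return Z, list(cat.categories)


def fit_rr(spec: RRSpec, *, tol: float = 1e-8, max_iter: int = 500) -> RRFit:
    """REML fit (EM with average-information acceleration) of the growth model.

    Raises on identifiability problems (too few distinct time points for the
    requested order, plots seen at fewer than two time points, rank-deficient
    replicate-by-time design); flags but does not raise on non-convergence.
    """
    d = spec.data
    vi = d[~d["is_yield"]].copy() if "is_yield" in d.columns else d.copy()
    vi = vi.dropna(subset=[spec.trait])
    if vi["harvest"].nunique() > 1:
        raise ValueError("fit one harvest cycle at a time")
    times = np.sort(vi["gdd"].unique())
    order_pe = spec.order if spec.order_pe is None else spec.order_pe
    if times.size <= max(spec.order, order_pe) + 1:
        raise ValueError(
            f"only {times.size} distinct time points for basis degree "
            f"{max(spec.order, order_pe)}: model not identifiable "
            f"(need more than order+1 distinct times)"
        )
    counts = vi.groupby("plot", observed=True)["gdd"].nunique()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"plots observed at < 2 time points: {bad[:10]}")

    terminal_gdd = None
    yield_scale = None
    rows = vi
    domain = (float(times.min()), float(times.max()))
    if spec.include_yield:
        fy = d[d["is_yield"]].dropna(subset=[spec.trait]).copy()
        if fy.empty:
            raise ValueError("include_yield=True but the table has no yield rows")
        terminal_gdd = float(fy["gdd"].iloc[0])
        if terminal_gdd < domain[1] - 1e-9:
            raise ValueError("terminal yield GDD precedes the last flight")
        last = vi[vi["gdd"] == times.max()]
        merged = fy.merge(
            last[["plot", spec.trait]].rename(columns={spec.trait: "_last_vi"}),
            on="plot",
            how="inner",
        )
        scaled, yield_scale = scale_terminal_yield(
            merged[spec.trait].to_numpy(), merged["_last_vi"].to_numpy()
        )
        fy = merged.drop(columns=["_last_vi"])
        fy[spec.trait] = scaled
        fy["_timelabel"] = "yield"
        domain = (domain[0], terminal_gdd)
        rows = pd.concat([vi.assign(_timelabel=vi["gdd"].astype(str)), fy], ignore_index=True)
    else:
        rows = vi.assign(_timelabel=vi["gdd"].astype(str))

    basis = legendre_basis(times, order=spec.order, domain=domain)
    basis_pe = legendre_basis(times, order=order_pe, domain=domain)
    phi_g = basis.evaluate(rows["gdd"].to_numpy(dtype=float))
    phi_p = basis_pe.evaluate(rows["gdd"].to_numpy(dtype=float))

    X, fixed_names = _fixed_design(rows["replicate"], rows["_timelabel"])
    Zg, genotypes = _coef_design(rows["genotype"], phi_g)
    Zp, plots = _coef_design(rows["plot"], phi_p)
    terms = [
        RandomTerm(name="genetic", Z=Zg, n_levels=len(genotypes), n_coef=spec.order + 1),
        RandomTerm(name="permanent", Z=Zp, n_levels=len(plots), n_coef=order_pe + 1),
    ]
    groups = None
    group_levels = None
    if spec.residual_structure == "per_time_point":
        # order groups by time (yield point last), not by label string
        key = list(zip(rows["gdd"], rows["_timelabel"] == "yield"))
        ordered = sorted(set(key))
        lookup = {k: i for i, k in enumerate(ordered)}
        groups = np.array([lookup[k] for k in key])
        group_levels = ["yield" if flag else f"{g:g}" for g, flag in ordered]
        n_per = np.bincount(groups)
        thin = n_per < 2 * (spec.order + 1)
        if thin.any():
            warnings.warn(
                "per-time-point residual: time points with few records may be "
                f"weakly identified: {list(np.asarray(group_levels)[thin])}",
                stacklevel=2,
            )

    y = rows[spec.trait].to_numpy(dtype=float)
    model = MixedModelREML(
        y, X, terms, residual_groups=groups, fixed_names=fixed_names
    )
    res = model.fit(tol=tol, max_iter=max_iter)

    return RRFit(
        K_g=res.K["genetic"],
        K_p=res.K["permanent"],
        sigma2_e=res.sigma2_e,
        beta=pd.Series(res.beta, index=fixed_names),
        u_hat=pd.DataFrame(res.u["genetic"], index=genotypes),
        p_hat=pd.DataFrame(res.u["permanent"], index=plots),
        basis=basis,
        basis_pe=basis_pe,
        time_points=times,
        terminal_gdd=terminal_gdd,
        yield_scale=yield_scale,
        loglik=res.loglik,
        n_iter=res.n_iter,
        converged=res.converged,
        n_psd_clips=res.n_psd_clips,
        residual_groups=None if group_levels is None else list(group_levels),
    )


@dataclass
class CovFunction:
    """Continuous-time covariance function Cov(t, s) = phi(t)' K phi(s)."""

    source: str  # "genetic" or "permanent"
    K: np.ndarray
    basis: LegendreBasis

    def __call__(self, t, s) -> np.ndarray:
        ts = self.basis.standardize(np.asarray(t, dtype=float))
        ss = self.basis.standardize(np.asarray(s, dtype=float))
        if np.any(np.abs(ts) > 1 + 1e-9) or np.any(np.abs(ss) > 1 + 1e-9):
            warnings.warn(
                "evaluating the covariance function outside the fitted time "
                "domain (extrapolation)",
                stacklevel=2,
            )
        pt = self.basis.evaluate_tstar(np.atleast_1d(ts))
        ps = self.basis.evaluate_tstar(np.atleast_1d(ss))
        out = np.einsum("ia,ab,ib->i", pt, self.K, ps)
        return out if np.ndim(t) else float(out[0])

    def variance(self, t) -> np.ndarray:
        return self(t, t)


def covariance_surface(fit: RRFit, source: str = "genetic") -> CovFunction:
    """Covariance function of the genetic or permanent-environment curves."""
    if source == "genetic":
        return CovFunction(source=source, K=fit.K_g, basis=fit.basis)
    if source == "permanent":
        return CovFunction(source=source, K=fit.K_p, basis=fit.basis_pe)
    raise ValueError("source must be 'genetic' or 'permanent'")


def genetic_correlation_curve(
    fit: RRFit,
    t_grid=None,
    reference: float | str = "terminal",
) -> pd.DataFrame:
    """Genetic correlation r(t, T) between the trait at time t and at T.

    ``reference='terminal'`` uses the appended yield point (requires a fit with
    ``include_yield``).  Grid points where the genetic variance vanishes get
    NaN.  Values are clipped to [-1, 1] only against roundoff, never bias.
    """
    if isinstance(reference, str):
        if reference != "terminal":
            raise ValueError("reference must be 'terminal' or a GDD value")
        if fit.terminal_gdd is None:
            raise ValueError("fit has no terminal yield point; pass a GDD reference")
        t_ref = fit.terminal_gdd
    else:
        t_ref = float(reference)
    if t_grid is None:
        lo = fit.basis.gdd_min
        t_grid = np.linspace(lo, fit.basis.gdd_max, 50)
    t_grid = np.asarray(t_grid, dtype=float)
    cov = covariance_surface(fit, "genetic")
    var_t = cov.variance(t_grid)
    var_ref = float(cov.variance(np.array([t_ref]))[0])
    cval = cov(t_grid, np.full_like(t_grid, t_ref))
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(var_t * var_ref)
        r = np.where(denom > 1e-12, cval / np.where(denom > 1e-12, denom, 1.0), np.nan)
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame({"gdd": t_grid, "r_g": r, "reference_gdd": t_ref})


def growth_curves(fit: RRFit, t_grid=None, decile: float = 0.1) -> pd.DataFrame:
    """Per-genotype breeding-value trajectories g_j(t) = phi(t)' u_hat_j.

    Long table (genotype, gdd, bv, rank_group) with the top/bottom decile by
    terminal breeding value flagged for plotting.
    """
    if t_grid is None:
        t_grid = np.linspace(fit.basis.gdd_min, fit.basis.gdd_max, 100)
    t_grid = np.asarray(t_grid, dtype=float)
    phi = fit.basis.evaluate(t_grid)  # (T, m)
    bv = fit.u_hat.to_numpy() @ phi.T  # (q, T)
    terminal = bv[:, -1]
    q = len(fit.genotypes)
    order = np.argsort(terminal)
    n_tail = max(int(np.floor(decile * q)), 1)
    group = np.array(["mid"] * q, dtype=object)
    group[order[:n_tail]] = "bottom"
    group[order[-n_tail:]] = "top"
    frames = []
    for i, g in enumerate(fit.genotypes):
        frames.append(
            pd.DataFrame(
                {"genotype": g, "gdd": t_grid, "bv": bv[i], "rank_group": group[i]}
            )
        )
    return pd.concat(frames, ignore_index=True)


def heritability_curve(fit: RRFit, t_grid=None) -> pd.DataFrame:
    """Time-resolved plot-level H2(t) = Vg(t) / (Vg(t) + Vp(t) + sigma2_e)."""
    if t_grid is None:
        t_grid = np.linspace(fit.basis.gdd_min, fit.basis.gdd_max, 50)
    t_grid = np.asarray(t_grid, dtype=float)
    vg = covariance_surface(fit, "genetic").variance(t_grid)
    vp = covariance_surface(fit, "permanent").variance(t_grid)
    se = fit.sigma2_e_at()
    h2 = vg / (vg + vp + se)
    return pd.DataFrame({"gdd": t_grid, "var_g": vg, "var_p": vp, "h2": h2})
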