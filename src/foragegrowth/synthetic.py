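"""Synthetic multi-harvest forage trials with known genetic architecture.

The generator emulates the data structure of a UAV-phenotyped perennial forage
trial: an RCBD of cultivars measured by repeated flights within each harvest
(cutting) cycle on a growing-degree-day time axis, plus a terminal forage
biomass yield per plot and harvest.  Plot-level vegetation-index trajectories
are drawn from the random-regression model the analysis modules fit,

    VI(t, j, r) = beta_r(t) + phi(t)' u_j + phi(t)' p_jr + eps,

with phi the orthonormal Legendre basis on standardized time, u_j per-genotype
coefficient vectors with covariance K_g, p_jr per-plot permanent-environment
coefficients with covariance K_p, and iid residual.  Every drawn effect is
recorded in a :class:`GroundTruth` so downstream estimators can be tested by
parameter recovery without any external data.

Cross-cutting instability is controlled per genotype: cutting-specific genetic
coefficients are u_jh = u_j + s_j * eta_jh with eta drawn from K_g, so s_j = 0
gives a perfectly persistent cultivar and larger s_j a plastic one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import LegendreBasis, legendre_basis

__all__ = [
    "TrialDesign",
    "GroundTruthSpec",
    "GroundTruth",
    "simulate_trial",
    "simulate_yield_from_curve",
    "simulate_ge_yield",
    "default_gdd_grid",
]


def default_gdd_grid(n_harvests: int, flights_per_harvest: int) -> tuple[tuple[float, ...], ...]:
    """Per-harvest cumulative GDD (deg C day) at flight dates.

    Roughly weekly flights over regrowth cycles of ~450-550 GDD, the scale of
    temperate alfalfa cuttings; the first cycle starts a little later because
    accumulation begins at green-up.
    """
    grids = []
    for h in range(n_harvests):
        start = 80.0 + 10.0 * h
        end = 560.0 - 15.0 * h
        grids.append(tuple(np.linspace(start, end, flights_per_harvest)))
    return tuple(grids)


@dataclass(frozen=True)
class TrialDesign:
    """Layout of a randomized complete block, multi-cutting trial."""

    n_genotypes: int = 36
    n_replicates: int = 5
    n_harvests: int = 3
    flights_per_harvest: int = 7
    design: str = "RCBD"
    gdd_grid: tuple[tuple[float, ...], ...] | None = None
    seed: int = 20240821

    def __post_init__(self) -> None:
        if self.n_genotypes < 2:
            raise ValueError("need at least 2 genotypes")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        if self.design != "RCBD":
            raise ValueError(f"unsupported design {self.design!r}")
        if self.gdd_grid is not None:
            if len(self.gdd_grid) != self.n_harvests:
                raise ValueError("gdd_grid must have one entry per harvest")
            for g in self.gdd_grid:
                arr = np.asarray(g, dtype=float)
                if arr.size < 2 or np.any(np.diff(arr) <= 0):
                    raise ValueError("each harvest's GDD grid must be strictly increasing")

    @property
    def grids(self) -> tuple[tuple[float, ...], ...]:
        if self.gdd_grid is not None:
            return tuple(tuple(float(x) for x in g) for g in self.gdd_grid)
        return default_gdd_grid(self.n_harvests, self.flights_per_harvest)

    @property
    def genotypes(self) -> list[str]:
        return [f"g{j + 1:02d}" for j in range(self.n_genotypes)]

    @property
    def harvests(self) -> list[str]:
        return [f"cut{h + 1}" for h in range(self.n_harvests)]


def _default_kg(order: int = 3) -> np.ndarray:
    # Decaying coefficient variances: most genetic signal in the mean level and
    # linear trend of the curve, little in the curvature terms.
    base = np.array([1.0, 0.5, 0.2, 0.1])
    if order + 1 <= 4:
        return np.diag(base[: order + 1])
    return np.diag(np.concatenate([base, np.full(order + 1 - 4, 0.05)]))


@dataclass
class GroundTruthSpec:
    """Generating parameters.  Defaults give moderate heritability (~0.5 late
    in the cycle) with a plot permanent-environment component, the regime the
    field trials this emulates operate in."""

    K_g: np.ndarray = field(default_factory=_default_kg)
    K_p: np.ndarray = field(default_factory=lambda: 0.2 * np.eye(4))
    sigma2_e: float | np.ndarray = 0.5
    beta_sd: float = 0.05
    instability_sd: float | np.ndarray = 0.0
    order: int = 3

    def validate(self) -> None:
        for name, K in (("K_g", self.K_g), ("K_p", self.K_p)):
            K = np.asarray(K, dtype=float)
            if K.shape != (self.order + 1, self.order + 1):
                raise ValueError(f"{name} must be {(self.order + 1)}x{(self.order + 1)}")
            if not np.allclose(K, K.T, atol=1e-10):
                raise ValueError(f"{name} is not symmetric")
            w = np.linalg.eigvalsh(0.5 * (K + K.T))
            if w.min() < -1e-10:
                raise ValueError(
                    f"{name} is not positive semidefinite (min eigenvalue {w.min():.3e})"
                )
        if np.any(np.asarray(self.sigma2_e, dtype=float) < 0):
            raise ValueError("sigma2_e must be >= 0")
        if np.any(np.asarray(self.instability_sd, dtype=float) < 0):
            raise ValueError("instability_sd must be >= 0")


@dataclass
class GroundTruth:
    """All drawn effects of one simulated trial, for parameter-recovery tests."""

    spec: GroundTruthSpec
    design: TrialDesign
    beta: dict[str, np.ndarray]  # harvest -> (n_replicates, n_times)
    u_base: np.ndarray  # (n_genotypes, order+1), persistent component
    u_coeffs: np.ndarray  # (n_harvests, n_genotypes, order+1)
    p_coeffs: np.ndarray  # (n_harvests, n_genotypes, n_replicates, order+1)
    instability_sd: np.ndarray  # per genotype
    bases: dict[str, LegendreBasis]
    seed: int


def _chol_psd(K: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(0.5 * (K + K.T))
    return v @ np.diag(np.sqrt(np.maximum(w, 0.0)))


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("genetic", "instability", "permenv", "residual", "fixed", "yield", "ge")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def simulate_trial(
    design: TrialDesign,
    truth_spec: GroundTruthSpec | None = None,
    *,
    trait: str = "ndvi",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw one trial.  Identical seed => byte-identical table.

    Returns a long-format plot table (one row per plot x flight) and the
    :class:`GroundTruth` holding every drawn effect.  The master seed spawns
    independent named streams per component (genetic, permanent-environment,
    residual, fixed, yield) so switching one component off does not perturb
    the draws of the others.
    """
    spec = truth_spec if truth_spec is not None else GroundTruthSpec()
    spec.validate()
    rngs = _streams(design.seed)
    m = spec.order + 1
    n_g, n_r = design.n_genotypes, design.n_replicates
    lg = _chol_psd(np.asarray(spec.K_g, dtype=float))
    lp = _chol_psd(np.asarray(spec.K_p, dtype=float))
    s_j = np.broadcast_to(
        np.asarray(spec.instability_sd, dtype=float), (n_g,)
    ).astype(float)

    u_base = rngs["genetic"].standard_normal((n_g, m)) @ lg.T
    eta = rngs["instability"].standard_normal((design.n_harvests, n_g, m)) @ lg.T
    u_coeffs = u_base[None, :, :] + s_j[None, :, None] * eta

    p_coeffs = rngs["permenv"].standard_normal((design.n_harvests, n_g, n_r, m)) @ lp.T

    sig_e = np.asarray(spec.sigma2_e, dtype=float)

    rows = []
    beta: dict[str, np.ndarray] = {}
    bases: dict[str, LegendreBasis] = {}
    genotypes = design.genotypes
    for h, harvest in enumerate(design.harvests):
        grid = np.asarray(design.grids[h], dtype=float)
        n_t = grid.size
        basis = legendre_basis(grid, order=spec.order)
        bases[harvest] = basis
        phi = basis.evaluate(grid)  # (n_t, m)
        b_h = rngs["fixed"].normal(0.0, spec.beta_sd, size=(n_r, n_t))
        beta[harvest] = b_h
        if sig_e.ndim == 0:
            sd_t = np.full(n_t, float(np.sqrt(sig_e)))
        else:
            sd_t = np.sqrt(np.broadcast_to(sig_e, (n_t,)).astype(float))
        eps = rngs["residual"].standard_normal((n_g, n_r, n_t))

        gen_part = u_coeffs[h] @ phi.T  # (n_g, n_t)
        pe_part = np.einsum("grm,tm->grt", p_coeffs[h], phi)
        vals = (
            b_h[None, :, :]
            + gen_part[:, None, :]
            + pe_part
            + eps * sd_t[None, None, :]
        )
        for j in range(n_g):
            for r in range(n_r):
                for t_i in range(n_t):
                    rows.append(
                        (
                            genotypes[j],
                            r + 1,
                            f"r{r + 1}_{genotypes[j]}",
                            harvest,
                            t_i + 1,
                            grid[t_i],
                            vals[j, r, t_i],
                            False,
                        )
                    )

    records = pd.DataFrame(
        rows,
        columns=["genotype", "replicate", "plot", "harvest", "flight", "gdd", trait, "is_yield"],
    )
    truth = GroundTruth(
        spec=spec,
        design=design,
        beta=beta,
        u_base=u_base,
        u_coeffs=u_coeffs,
        p_coeffs=p_coeffs,
        instability_sd=s_j,
        bases=bases,
        seed=design.seed,
    )
    return records, truth


def simulate_yield_from_curve(
    records: pd.DataFrame,
    truth: GroundTruth,
    harvest_gdd: float | dict[str, float] | None = None,
    *,
    noise_sd: float | None = None,
    include_perm_env: bool = True,
    trait: str | None = None,
) -> pd.DataFrame:
    """Append terminal forage-yield rows generated from the genetic curves.

    Per plot and harvest the yield is the plot's fitted trajectory evaluated at
    the harvest GDD (genetic plus, by default, permanent-environment
    contribution) plus fresh noise, so the true genetic correlation between the
    index at any time and yield is computable in closed form from K_g and the
    basis.  ``harvest_gdd`` defaults to the last flight GDD of each harvest
    (flights right up to cutting); it may not precede the last flight.
    """
    design, spec = truth.design, truth.spec
    if trait is None:
        value_cols = [
            c
            for c in records.columns
            if c not in ("genotype", "replicate", "plot", "harvest", "flight", "gdd", "is_yield")
        ]
        trait = value_cols[0]
    rng = _streams(truth.seed)["yield"]
    sd = float(np.sqrt(np.mean(np.asarray(spec.sigma2_e, float)))) if noise_sd is None else float(noise_sd)

    harvests = design.harvests
    if harvest_gdd is None:
        hg = {h: float(np.max(design.grids[i])) for i, h in enumerate(harvests)}
    elif isinstance(harvest_gdd, dict):
        hg = {h: float(v) for h, v in harvest_gdd.items()}
    else:
        hg = {h: float(harvest_gdd) for h in harvests}

    rows = []
    genotypes = design.genotypes
    for h, harvest in enumerate(harvests):
        if harvest not in hg:
            continue
        last_flight = float(np.max(design.grids[h]))
        if hg[harvest] < last_flight - 1e-9:
            raise ValueError(
                f"harvest {harvest}: harvest_gdd {hg[harvest]} precedes last flight GDD {last_flight}"
            )
        basis = truth.bases[harvest]
        phi_t = basis.evaluate(np.array([hg[harvest]]))[0]
        eps = rng.standard_normal((design.n_genotypes, design.n_replicates)) * sd
        for j in range(design.n_genotypes):
            for r in range(design.n_replicates):
                val = float(truth.u_coeffs[h, j] @ phi_t)
                if include_perm_env:
                    val += float(truth.p_coeffs[h, j, r] @ phi_t)
                val += float(eps[j, r])
                rows.append(
                    (
                        genotypes[j],
                        r + 1,
                        f"r{r + 1}_{genotypes[j]}",
                        harvest,
                        0,
                        hg[harvest],
                        val,
                        True,
                    )
                )
    yields = pd.DataFrame(rows, columns=list(records.columns))
    return pd.concat([records, yields], ignore_index=True)


def simulate_ge_yield(
    n_genotypes: int,
    n_envs: int,
    stability_profile=0.0,
    seed: int = 0,
    *,
    mu: float = 4.0,
    sd_genotype: float = 0.5,
    sd_environment: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Genotype x environment mean-yield matrix with known interaction SDs.

    ``Y_ij = mu + g_i + e_j + w_ij`` with ``w_ij ~ N(0, stability_profile[i]^2)``:
    a genotype's interaction SD is its true instability.  Returns the matrix
    (genotype rows, environment columns) and a dict of the drawn truth.
    """
    if n_envs < 2:
        raise ValueError("need at least 2 environments")
    if n_genotypes < 3:
        raise ValueError("need at least 3 genotypes")
    sds = np.broadcast_to(np.asarray(stability_profile, dtype=float), (n_genotypes,)).astype(float)
    if np.any(sds < 0):
        raise ValueError("stability_profile SDs must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    g = rng.normal(0.0, sd_genotype, n_genotypes)
    e = rng.normal(0.0, sd_environment, n_envs)
    w = rng.standard_normal((n_genotypes, n_envs)) * sds[:, None]
    values = mu + g[:, None] + e[None, :] + w
    gen = [f"g{i + 1:02d}" for i in range(n_genotypes)]
    env = [f"env{j + 1}" for j in range(n_envs)]
    df = pd.DataFrame(values, index=pd.Index(gen, name="genotype"), columns=env)
    truth = {"mu": mu, "g": g, "e": e, "interaction": w, "stability_sd": sds}
    return df, truth
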