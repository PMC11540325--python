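"""Selection efficiency and stability: RSE, GGE biplot, growth-curve stability.

Relative selection efficiency compares indirect selection on a vegetation
index against direct selection on forage yield:
RSE = (h_VI / h_FY) r_g, with h the square roots of the plot-level
heritabilities and r_g the genetic correlation between index and yield.

The GGE biplot is the rank-2 SVD of the environment-centered genotype x
environment mean-yield matrix, genotype-focused scaling (singular values
absorbed into the genotype scores).  Projections on the average-environment
axis (AEA) rank mean performance; the perpendicular projection measures
instability.

Growth-curve stability summarizes, per cultivar, how much its estimated
genetic growth curve moves between cuttings: genetic effects at selected
standardized GDD points are z-scored across cultivars within each cutting,
and the per-cultivar SD of those standardized effects across cuttings is the
instability statistic (same construction applied to yield BLUPs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "rse",
    "GEMatrix",
    "BiplotResult",
    "gge_biplot",
    "StabilityProfile",
    "growth_stability",
    "mean_vs_stability_report",
]


def rse(h2_vi: float, h2_fy: float, r_g: float) -> float:
    """Relative selection efficiency sqrt(h2_vi / h2_fy) * r_g.

    ``h2_vi`` and ``h2_fy`` are plot-level heritabilities (the formula uses
    their square roots); depends on the heritabilities only through their
    ratio.  Returns NaN when the yield heritability is zero (undefined).
    """
    for name, h2 in (("h2_vi", h2_vi), ("h2_fy", h2_fy)):
        if np.isfinite(h2) and (h2 < 0 or h2 > 1):
            raise ValueError(f"{name} must lie in [0, 1], got {h2}")
    if not -1.0 <= r_g <= 1.0:
        raise ValueError(f"r_g must lie in [-1, 1], got {r_g}")
    if not np.isfinite(h2_fy) or h2_fy <= 0 or not np.isfinite(h2_vi):
        return float("nan")
    return float(np.sqrt(h2_vi / h2_fy) * r_g)


@dataclass
class GEMatrix:
    """Complete genotype x environment mean-yield table."""

    values: pd.DataFrame  # genotypes as index, environments as columns

    def __post_init__(self) -> None:
        v = self.values
        if v.isna().any().any():
            raise ValueError("GE matrix has missing cells; a complete two-way table is required")
        if v.shape[0] < 3:
            raise ValueError("need at least 3 genotypes")
        if v.shape[1] < 2:
            raise ValueError("need at least 2 environments")

    @property
    def genotypes(self) -> list:
        return list(self.values.index)

    @property
    def environments(self) -> list:
        return list(self.values.columns)


@dataclass
class BiplotResult:
    """Rank-2 GGE decomposition with average-environment-axis projections."""

    genotype_scores: pd.DataFrame  # PC1, PC2 (singular values absorbed)
    environment_scores: pd.DataFrame  # PC1, PC2 (unit-scaled)
    singular_values: np.ndarray
    explained_fraction: float
    aea_mean: pd.Series  # projection on the average-environment axis
    aea_stability: pd.Series  # signed perpendicular projection (NaN if undefined)

    def reconstruction_rank2(self) -> np.ndarray:
        g = self.genotype_scores.to_numpy()
        e = self.environment_scores.to_numpy()
        return g @ e.T


def gge_biplot(ge: GEMatrix | pd.DataFrame) -> BiplotResult:
    """Genotype-focused SVD of the environment-centered GE matrix.

    Sign convention: PC1 is oriented so the mean environment score is positive
    (the AEA arrow points toward higher mean yield); PC2 so the first
    genotype's score is non-negative.  With fewer than two positive singular
    values the stability axis is undefined and reported as NaN.
    """
    if isinstance(ge, pd.DataFrame):
        ge = GEMatrix(values=ge)
    Y = ge.values.to_numpy(dtype=float)
    centered = Y - Y.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)

    # genotype-focused scaling: scores l_k * x_ik for genotypes, h_jk for envs
    G2 = U[:, :2] * s[:2]
    E2 = Vt[:2].T.copy()
    if s.size < 2:  # only possible with 2 environments collapsing; guard
        G2 = np.column_stack([G2, np.zeros(len(G2))])
        E2 = np.column_stack([E2, np.zeros(len(E2))])
        s = np.append(s, 0.0)

    if E2[:, 0].mean() < 0:
        G2[:, 0] *= -1
        E2[:, 0] *= -1
    if G2[0, 1] < 0:
        G2[:, 1] *= -1
        E2[:, 1] *= -1

    total = float(np.sum(s**2))
    explained = float(np.sum(s[:2] ** 2) / total) if total > 0 else 1.0

    aea = E2.mean(axis=0)
    norm = np.linalg.norm(aea)
    if norm < 1e-12:
        aea_unit = np.array([1.0, 0.0])
    else:
        aea_unit = aea / norm
    perp_unit = np.array([-aea_unit[1], aea_unit[0]])
    mean_proj = G2 @ aea_unit
    if s[1] > 1e-12 * max(s[0], 1.0):
        stab_proj = G2 @ perp_unit
    else:
        # No second dimension: the data are additive to rank 1, nothing
        # perpendicular to project onto -> stability identically zero.
        stab_proj = np.zeros(len(G2))

    idx = pd.Index(ge.genotypes, name="genotype")
    cols = ["PC1", "PC2"]
    return BiplotResult(
        genotype_scores=pd.DataFrame(G2, index=idx, columns=cols),
        environment_scores=pd.DataFrame(
            E2, index=pd.Index(ge.environments, name="environment"), columns=cols
        ),
        singular_values=s[:2].copy(),
        explained_fraction=explained,
        aea_mean=pd.Series(mean_proj, index=idx, name="aea_mean"),
        aea_stability=pd.Series(stab_proj, index=idx, name="aea_stability"),
    )


@dataclass
class StabilityProfile:
    """Per-cultivar cross-cutting instability of growth and of yield."""

    growth_sd: pd.DataFrame  # genotypes x selected time points (SD across cuttings)
    growth_sd_mean: pd.Series  # mean over the selected points
    yield_sd: pd.Series | None
    t_points: np.ndarray  # standardized time points used
    excluded: list


def growth_stability(
    fits,
    t_points=None,
    yield_blups: dict | None = None,
    *,
    n_points: int = 5,
) -> StabilityProfile:
    """Cross-cutting stability of the estimated genetic growth curves.

    Parameters
    ----------
    fits
        Per-cutting random-regression fits (RRFit).  All cuttings should share
        a genotype set; genotypes missing from any cutting are excluded (and
        listed in the result).
    t_points
        Standardized time points t* in [-1, 1] at which genetic effects are
        compared; default is an evenly spaced ``n_points`` grid.
    yield_blups
        Optional mapping cutting -> Series of genotype yield BLUPs; the same
        standardize-then-SD construction is applied to them.

    At each point the genetic effects are standardized to unit variance across
    genotypes within each cutting (so the statistic is invariant to affine
    rescaling of the raw trait units), deviations from each genotype's own
    cross-cutting mean are taken, and their SD across cuttings is returned.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need at least 2 cuttings")
    if t_points is None:
        t_points = np.linspace(-1.0, 1.0, n_points)
    t_points = np.asarray(t_points, dtype=float)

    genotype_sets = [set(f.genotypes) for f in fits]
    common = sorted(set.intersection(*genotype_sets))
    excluded = sorted(set.union(*genotype_sets) - set(common))
    if len(common) < 2:
        raise ValueError("fewer than 2 genotypes common to all cuttings")

    effects = []  # (n_cuttings, n_genotypes, n_points), standardized
    for f in fits:
        phi = f.basis.evaluate_tstar(t_points)  # (T, m)
        u = f.u_hat.loc[common].to_numpy()
        g = u @ phi.T  # (q, T)
        sd = g.std(axis=0, ddof=1)
        sd = np.where(sd > 1e-12, sd, np.nan)
        effects.append((g - g.mean(axis=0)) / sd)
    arr = np.stack(effects, axis=0)

    dev = arr - arr.mean(axis=0, keepdims=True)
    sd_growth = dev.std(axis=0, ddof=1)  # (q, T)

    growth_sd = pd.DataFrame(
        sd_growth,
        index=pd.Index(common, name="genotype"),
        columns=[f"t{k}" for k in range(len(t_points))],
    )
    growth_mean = growth_sd.mean(axis=1)
    growth_mean.name = "growth_sd"

    yield_sd = None
    if yield_blups is not None:
        zs = []
        for key in sorted(yield_blups):
            s = pd.Series(yield_blups[key]).loc[common].to_numpy(dtype=float)
            sd = s.std(ddof=1)
            zs.append((s - s.mean()) / (sd if sd > 1e-12 else np.nan))
        zarr = np.stack(zs, axis=0)
        ydev = zarr - zarr.mean(axis=0, keepdims=True)
        yield_sd = pd.Series(
            ydev.std(axis=0, ddof=1), index=pd.Index(common, name="genotype"), name="yield_sd"
        )

    return StabilityProfile(
        growth_sd=growth_sd,
        growth_sd_mean=growth_mean,
        yield_sd=yield_sd,
        t_points=t_points,
        excluded=excluded,
    )


def mean_vs_stability_report(
    biplot: BiplotResult,
    profile: StabilityProfile | None = None,
    *,
    mean_threshold: float | None = None,
    stability_threshold: float | None = None,
) -> pd.DataFrame:
    """Classify cultivars into mean-performance x stability quadrants.

    Median splits by default (thresholds overridable): ``high`` mean if the
    AEA projection exceeds the threshold, ``stable`` if the absolute
    perpendicular projection does not exceed it.  Joins the growth-stability
    summary when a profile is given.  Invariant to environment relabeling
    (the biplot only sees the matrix).
    """
    mean = biplot.aea_mean
    stab = biplot.aea_stability.abs()
    m_thr = float(mean.median()) if mean_threshold is None else float(mean_threshold)
    s_thr = float(stab.median()) if stability_threshold is None else float(stability_threshold)
    out = pd.DataFrame(
        {
            "aea_mean": mean,
            "aea_stability": biplot.aea_stability,
            "abs_stability": stab,
            "mean_class": np.where(mean > m_thr, "high", "low"),
            "stability_class": np.where(stab <= s_thr, "stable", "unstable"),
        }
    )
    out["label"] = out["mean_class"] + "-yielding, " + out["stability_class"]
    if profile is not None:
        out = out.join(profile.growth_sd_mean, how="left")
        if profile.yield_sd is not None:
            out = out.join(profile.yield_sd, how="left")
    return out
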