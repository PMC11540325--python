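"""Plot-level phenotype features: vegetation indices, thermal time, Legendre basis.

Vegetation indices are scalar combinations of mean plot reflectances from a
multispectral camera (blue/green/red/red-edge/NIR).  Thermal time is accumulated
as growing degree days (GDD) above a base temperature, reset at each harvest of a
multi-cut forage trial.  The Legendre basis evaluates orthonormal polynomials on
standardized time t* in [-1, 1], the covariate basis of the random-regression
growth model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import legendre as npleg

__all__ = [
    "ndvi",
    "gndvi",
    "ndre",
    "simple_ratio",
    "compute_indices",
    "cumulative_gdd",
    "GDDSeries",
    "legendre_basis",
    "LegendreBasis",
    "VI_NAMES",
]

#: The five indices analyzed throughout the package. "nir" is the raw NIR band
#: mean treated as an index in its own right.
VI_NAMES = ("ndvi", "gndvi", "ndre", "nir", "ratio")


def _check_bands(*bands: np.ndarray) -> tuple[np.ndarray, ...]:
    out = []
    for b in bands:
        arr = np.asarray(b, dtype=float)
        if np.any(arr < 0):
            raise ValueError("reflectance band means must be non-negative")
        if np.any(arr > 1.0):
            warnings.warn(
                "band mean > 1 encountered; treating as uncalibrated digital "
                "numbers, indices are still well defined",
                stacklevel=3,
            )
        out.append(arr)
    return tuple(out)


def _normalized_difference(a, b):
    a, b = _check_bands(a, b)
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        nd = np.where(denom > 0, (a - b) / np.where(denom > 0, denom, 1.0), np.nan)
    return nd if nd.ndim else float(nd)


def ndvi(r_nir, r_red):
    """Normalized difference vegetation index (NIR - Red)/(NIR + Red).

    Returns NaN (an explicit undefined marker) where the denominator is zero.
    Antisymmetric under swapping the two bands; in [-1, 1] for non-negative bands.
    """
    return _normalized_difference(r_nir, r_red)


def gndvi(r_nir, r_green):
    """Green NDVI: the red band of :func:`ndvi` replaced by the green band."""
    return _normalized_difference(r_nir, r_green)


def ndre(r_nir, r_rededge):
    """Normalized difference red edge: red replaced by the red-edge band."""
    return _normalized_difference(r_nir, r_rededge)


def simple_ratio(r_nir, r_red):
    """Simple ratio NIR/Red.  Related to NDVI by NDVI = (SR - 1)/(SR + 1).

    Returns NaN where the red band is zero.
    """
    a, b = _check_bands(r_nir, r_red)
    with np.errstate(divide="ignore", invalid="ignore"):
        sr = np.where(b > 0, a / np.where(b > 0, b, 1.0), np.nan)
    return sr if sr.ndim else float(sr)


def compute_indices(
    plots: pd.DataFrame,
    *,
    nir: str = "band_nir",
    red: str = "band_red",
    green: str = "band_green",
    rededge: str = "band_rededge",
) -> pd.DataFrame:
    """Append the five vegetation-index columns to a plot table of band means.

    Adds columns ``ndvi, gndvi, ndre, nir, ratio``; ``nir`` is the raw NIR band
    mean.  Missing band columns simply skip the indices that need them.
    """
    out = plots.copy()
    have = set(plots.columns)
    if {nir, red} <= have:
        out["ndvi"] = ndvi(plots[nir].to_numpy(), plots[red].to_numpy())
        out["ratio"] = simple_ratio(plots[nir].to_numpy(), plots[red].to_numpy())
    if {nir, green} <= have:
        out["gndvi"] = gndvi(plots[nir].to_numpy(), plots[green].to_numpy())
    if {nir, rededge} <= have:
        out["ndre"] = ndre(plots[nir].to_numpy(), plots[rededge].to_numpy())
    if nir in have:
        out["nir"] = plots[nir].astype(float)
    return out


# ---------------------------------------------------------------------------
# Growing degree days
# ---------------------------------------------------------------------------


@dataclass
class GDDSeries:
    """Daily and cumulative growing degree days, reset at each harvest cycle.

    ``table`` has one row per day with columns ``date, cycle, gdd_daily,
    gdd_cum``; ``cycle`` is 1-based.  ``t_base`` is the base temperature in
    degrees Celsius and ``clamp`` records whether negative daily increments were
    clamped at zero (the agronomic convention; configurable).
    """

    table: pd.DataFrame
    t_base: float
    clamp: bool

    def gdd_at(self, dates) -> np.ndarray:
        """Cumulative GDD (within cycle) at the given dates."""
        idx = self.table.set_index("date")["gdd_cum"]
        dates = pd.to_datetime(pd.Series(dates))
        missing = [d for d in dates if d not in idx.index]
        if missing:
            raise KeyError(f"dates outside the weather record: {missing}")
        return idx.loc[dates].to_numpy()


def cumulative_gdd(
    weather: pd.DataFrame,
    cycle_boundaries,
    t_base: float = 4.0,
    *,
    clamp: bool = True,
) -> GDDSeries:
    """Accumulate growing degree days per harvest cycle from daily temperatures.

    The daily increment is ``(t_max + t_min)/2 - t_base``, clamped at zero by
    default (cold days accumulate nothing).  Accumulation starts at the first
    day of the weather record (planting for the first cycle) and restarts the
    day after each harvest date in ``cycle_boundaries``.

    Parameters
    ----------
    weather
        Daily table with columns ``date, tmax, tmin``.  Days must be complete;
        gaps raise with a list of the missing dates (no silent interpolation).
    cycle_boundaries
        Harvest dates.  Each must fall inside the weather record.
    t_base
        Base temperature in deg C (default 4, the alfalfa convention).
    """
    w = weather.copy()
    for col in ("date", "tmax", "tmin"):
        if col not in w.columns:
            raise ValueError(f"weather table missing column {col!r}")
    w["date"] = pd.to_datetime(w["date"])
    w = w.sort_values("date").reset_index(drop=True)
    full = pd.date_range(w["date"].iloc[0], w["date"].iloc[-1], freq="D")
    gaps = full.difference(w["date"])
    if len(gaps):
        raise ValueError(
            "weather record has missing days: "
            + ", ".join(str(d.date()) for d in gaps[:20])
            + ("..." if len(gaps) > 20 else "")
        )
    if (w["tmax"] < w["tmin"]).any():
        bad = w.loc[w["tmax"] < w["tmin"], "date"].dt.date.tolist()
        raise ValueError(f"tmax < tmin on {bad}")

    inc = (w["tmax"].to_numpy() + w["tmin"].to_numpy()) / 2.0 - t_base
    if clamp:
        inc = np.maximum(inc, 0.0)

    boundaries = sorted(pd.to_datetime(pd.Series(list(cycle_boundaries))))
    cycle = np.ones(len(w), dtype=int)
    for b in boundaries:
        cycle[w["date"] > b] += 1

    out = pd.DataFrame({"date": w["date"], "cycle": cycle, "gdd_daily": inc})
    out["gdd_cum"] = out.groupby("cycle")["gdd_daily"].cumsum()
    return GDDSeries(table=out, t_base=t_base, clamp=clamp)


# ---------------------------------------------------------------------------
# Legendre basis on standardized time
# ---------------------------------------------------------------------------


def _phi_matrix(tstar: np.ndarray, order: int, normalized: bool) -> np.ndarray:
    t = np.atleast_1d(np.asarray(tstar, dtype=float))
    cols = []
    for k in range(order + 1):
        coef = np.zeros(order + 1)
        coef[k] = 1.0
        cols.append(npleg.legval(t, coef))
    phi = np.stack(cols, axis=-1)
    if normalized:
        phi = phi * np.sqrt((2 * np.arange(order + 1) + 1) / 2.0)
    return phi


@dataclass
class LegendreBasis:
    """Orthonormal Legendre polynomials on standardized time.

    Time t (GDD) is mapped affinely onto t* = 2(t - t_min)/(t_max - t_min) - 1
    and the basis functions are phi_k(t*) = sqrt((2k+1)/2) P_k(t*), which are
    orthonormal on [-1, 1].  ``normalized=False`` falls back to plain P_k.
    """

    order: int
    gdd_min: float
    gdd_max: float
    normalized: bool = True

    @property
    def n_coef(self) -> int:
        return self.order + 1

    def standardize(self, gdd) -> np.ndarray:
        gdd = np.asarray(gdd, dtype=float)
        return 2.0 * (gdd - self.gdd_min) / (self.gdd_max - self.gdd_min) - 1.0

    def unstandardize(self, tstar) -> np.ndarray:
        tstar = np.asarray(tstar, dtype=float)
        return self.gdd_min + (tstar + 1.0) * (self.gdd_max - self.gdd_min) / 2.0

    def evaluate(self, gdd) -> np.ndarray:
        """Basis matrix phi with one row per time, one column per k = 0..order."""
        return self.evaluate_tstar(self.standardize(gdd))

    def evaluate_tstar(self, tstar) -> np.ndarray:
        return _phi_matrix(tstar, self.order, self.normalized)


def legendre_basis(
    gdd_values,
    order: int = 3,
    *,
    domain: tuple[float, float] | None = None,
    normalized: bool = True,
) -> LegendreBasis:
    """Build the standardized Legendre basis for a set of flight times.

    ``domain`` overrides the (min, max) GDD used for standardization — e.g. to
    extend the support to the harvest GDD when a terminal yield point is
    appended.  At least two distinct times are required; a constant time vector
    has no usable support and is rejected.
    """
    gdd = np.asarray(list(gdd_values), dtype=float)
    if domain is None:
        lo, hi = float(np.min(gdd)), float(np.max(gdd))
    else:
        lo, hi = float(domain[0]), float(domain[1])
    if not hi > lo:
        raise ValueError("time values are constant; cannot standardize the basis domain")
    if np.unique(gdd).size < 2 and domain is None:
        raise ValueError("need at least 2 distinct time values")
    if order < 0:
        raise ValueError("order must be >= 0")
    return LegendreBasis(order=order, gdd_min=lo, gdd_max=hi, normalized=normalized)
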