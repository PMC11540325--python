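"""File formats: the canonical long plot table, weather CSV, ground truth.

A single long-format CSV is the interchange format for plot data (plot-level
phenomics has no entrenched binary standard).  Columns:

    genotype, replicate, plot, harvest, flight, gdd, <trait...>, is_yield

one row per plot x flight, plus terminal yield rows flagged ``is_yield``.
Output CSVs written by the pipeline carry a ``# config_hash=...`` comment
header line; readers here skip ``#`` comments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

REQUIRED_COLUMNS = ("genotype", "replicate", "plot", "harvest", "gdd")

__all__ = [
    "REQUIRED_COLUMNS",
    "read_plot_table",
    "write_plot_table",
    "read_weather",
    "ValidationReport",
    "validate_plot_table",
    "write_ground_truth",
    "read_ground_truth",
]


def read_plot_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if "is_yield" in df.columns:
        df["is_yield"] = df["is_yield"].astype(bool)
    else:
        df["is_yield"] = False
    return df


def write_plot_table(df: pd.DataFrame, path, *, header_comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def read_weather(path) -> pd.DataFrame:
    """Daily weather CSV with columns date, tmax, tmin."""
    df = pd.read_csv(path, comment="#")
    missing = {"date", "tmax", "tmin"} - set(df.columns)
    if missing:
        raise ValueError(f"weather CSV missing columns: {sorted(missing)}")
    return df


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"ERROR: {e}" for e in self.errors] + [f"WARNING: {w}" for w in self.warnings]
        return "\n".join(lines) if lines else "OK"


def validate_plot_table(table: pd.DataFrame | str | Path) -> tuple[pd.DataFrame, ValidationReport]:
    """Schema and design checks for a long plot table.

    Errors (malformed data): missing required columns, duplicated
    plot x harvest x flight-time rows, non-numeric GDD.  Warnings (tolerated
    designs): a genotype missing from some replicate (augmented designs leave
    test entries unreplicated), plots whose GDD values deviate from the
    harvest's common flight grid.
    """
    if not isinstance(table, pd.DataFrame):
        table = read_plot_table(table)
    report = ValidationReport()
    df = table.copy()

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        report.errors.append(f"missing required columns: {missing}")
        return df, report
    if "is_yield" not in df.columns:
        df["is_yield"] = False

    if not np.issubdtype(np.asarray(df["gdd"]).dtype, np.number):
        report.errors.append("gdd column is not numeric")
        return df, report

    key = ["plot", "harvest", "gdd", "is_yield"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        rows = df.loc[dup, key].drop_duplicates().head(10)
        report.errors.append(
            f"duplicated plot x flight rows ({int(dup.sum())} rows), e.g.: "
            + "; ".join(str(tuple(r)) for r in rows.itertuples(index=False))
        )

    vi = df[~df["is_yield"]]
    for h, grp in vi.groupby("harvest", observed=True):
        pivot = grp.pivot_table(index="genotype", columns="replicate", values="gdd", aggfunc="size")
        absent = pivot.isna()
        if absent.any().any():
            pairs = [
                (g, r)
                for g in pivot.index
                for r in pivot.columns
                if pd.isna(pivot.loc[g, r])
            ]
            report.warnings.append(
                f"harvest {h}: genotype missing from replicate (augmented-design "
                f"tolerance): {pairs[:10]}"
            )
        grid = grp.groupby("gdd").size()
        modal = grid[grid == grid.max()].index
        n_plots = grp["plot"].nunique()
        off = grid[grid < 0.5 * grid.max()]
        if len(off) and n_plots > 2:
            report.warnings.append(
                f"harvest {h}: off-grid GDD values observed on few plots: "
                f"{list(off.index)[:10]}"
            )
    return df, report


def write_ground_truth(truth, outdir) -> None:
    """Ground truth as YAML (parameters) plus CSV sidecars (drawn effects)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = truth.spec
    meta = {
        "seed": int(truth.seed),
        "order": int(spec.order),
        "K_g": np.asarray(spec.K_g, dtype=float).tolist(),
        "K_p": np.asarray(spec.K_p, dtype=float).tolist(),
        "sigma2_e": np.asarray(spec.sigma2_e, dtype=float).tolist(),
        "beta_sd": float(spec.beta_sd),
        "instability_sd": np.asarray(truth.instability_sd, dtype=float).tolist(),
        "design": {
            "n_genotypes": truth.design.n_genotypes,
            "n_replicates": truth.design.n_replicates,
            "n_harvests": truth.design.n_harvests,
            "gdd_grid": [list(map(float, g)) for g in truth.design.grids],
        },
    }
    with open(outdir / "ground_truth.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)

    m = spec.order + 1
    genotypes = truth.design.genotypes
    harvests = truth.design.harvests
    rows = []
    for h, harvest in enumerate(harvests):
        for j, g in enumerate(genotypes):
            rows.append({"harvest": harvest, "genotype": g}
                        | {f"u{k}": truth.u_coeffs[h, j, k] for k in range(m)})
    pd.DataFrame(rows).to_csv(outdir / "u_coeffs.csv", index=False)
    rows = []
    for h, harvest in enumerate(harvests):
        for j, g in enumerate(genotypes):
            for r in range(truth.design.n_replicates):
                rows.append(
                    {"harvest": harvest, "genotype": g, "replicate": r + 1}
                    | {f"p{k}": truth.p_coeffs[h, j, r, k] for k in range(m)}
                )
    pd.DataFrame(rows).to_csv(outdir / "p_coeffs.csv", index=False)


def read_ground_truth(outdir) -> dict:
    outdir = Path(outdir)
    with open(outdir / "ground_truth.yaml") as fh:
        meta = yaml.safe_load(fh)
    meta["u_coeffs"] = pd.read_csv(outdir / "u_coeffs.csv")
    meta["p_coeffs"] = pd.read_csv(outdir / "p_coeffs.csv")
    return meta
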