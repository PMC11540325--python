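"""End-to-end driver: simulation -> features -> per-time-point models ->
random regression -> selection efficiency -> stability.

Each stage writes tidy CSV artifacts (figures are optional; all figure data is
always emitted as CSV) and a manifest records the configuration hash, seeds,
library versions and per-stage status, so a rerun with an unchanged
configuration reproduces every number.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import validate_plot_table, write_ground_truth, write_plot_table
from .random_regression import (
    RRSpec,
    fit_rr,
    genetic_correlation_curve,
    growth_curves,
    heritability_curve,
)
from .stability import gge_biplot, growth_stability, mean_vs_stability_report, rse
from .synthetic import GroundTruthSpec, TrialDesign, simulate_trial, simulate_yield_from_curve
from .varcomp import fit_bivariate, fit_st_blup, heritability, phenotypic_correlation

logger = logging.getLogger("foragegrowth")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Pipeline settings; everything needed to reproduce a run."""

    input_csv: str | None = None  # None -> simulate
    trait: str = "ndvi"
    seed: int = 20240821
    n_genotypes: int = 36
    n_replicates: int = 5
    n_harvests: int = 3
    flights_per_harvest: int = 7
    order: int = 3
    residual_structure: str = "homogeneous"
    include_yield: bool = True
    tol: float = 1e-8
    max_iter: int = 500
    stability_points: int = 5
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def validate(self) -> None:
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise FileNotFoundError(self.input_csv)
        if self.flights_per_harvest <= self.order + 1:
            raise ValueError(
                f"order={self.order} needs more than {self.order + 1} distinct "
                f"time points; got flights_per_harvest={self.flights_per_harvest}"
            )


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str, index=False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=index)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json).

    A stage failure is recorded in the manifest and later stages that do not
    depend on it still run; partial outputs are retained.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    fitlog_path = outdir / "fits.log.jsonl"
    fitlog = open(fitlog_path, "w")

    def log_fit(stage, **kv):
        rec = {"stage": stage, **kv}
        fitlog.write(json.dumps(rec) + "\n")
        logger.info("fit %s", rec)

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": asdict(config),
        "config_hash": cfg_hash,
        "seed": config.seed,
        "stages": {},
        "outputs": [],
    }

    def stage(name):
        def deco(fn):
            def run(*a, **kw):
                try:
                    out = fn(*a, **kw)
                    manifest["stages"][name] = "ok"
                    return out
                except Exception as exc:  # noqa: BLE001 - manifest records it
                    logger.exception("stage %s failed", name)
                    manifest["stages"][name] = f"failed: {exc}"
                    return None
            return run
        return deco

    trait = config.trait

    @stage("simulate")
    def _simulate():
        if config.input_csv is not None:
            from .io import read_plot_table

            return read_plot_table(config.input_csv), None
        design = TrialDesign(
            n_genotypes=config.n_genotypes,
            n_replicates=config.n_replicates,
            n_harvests=config.n_harvests,
            flights_per_harvest=config.flights_per_harvest,
            seed=config.seed,
        )
        records, truth = simulate_trial(design, GroundTruthSpec(order=config.order), trait=trait)
        records = simulate_yield_from_curve(records, truth)
        write_plot_table(records, outdir / "plots.csv", header_comment=f"config_hash={cfg_hash}")
        write_ground_truth(truth, outdir / "truth")
        manifest["outputs"].append("plots.csv")
        return records, truth

    sim = _simulate()
    if sim is None:
        manifest["stages"]["validate"] = "skipped"
        _finish(manifest, outdir, fitlog)
        return manifest
    records, _truth = sim

    @stage("validate")
    def _validate():
        df, report = validate_plot_table(records)
        if not report.ok:
            raise ValueError("; ".join(report.errors))
        for w in report.warnings:
            logger.warning(w)
        return df

    records = _validate()
    if records is None:
        _finish(manifest, outdir, fitlog)
        return manifest

    harvests = sorted(records["harvest"].unique())

    @stage("heritability")
    def _heritability():
        rows = []
        for h in harvests:
            grp = records[records["harvest"] == h]
            for (gdd, is_y), flight in grp.groupby(["gdd", "is_yield"], observed=True):
                label = "yield" if is_y else f"{gdd:g}"
                vc = fit_st_blup(flight, trait, tol=config.tol, max_iter=config.max_iter)
                log_fit("heritability", harvest=str(h), flight=label,
                        converged=bool(vc.converged), n_iter=vc.n_iter,
                        loglik=None if np.isnan(vc.loglik) else vc.loglik)
                rows.append(
                    {
                        "harvest": h,
                        "flight": label,
                        "gdd": gdd,
                        "trait": trait if label != "yield" else "yield",
                        "sigma2_g": vc.sigma2_g,
                        "sigma2_e": vc.sigma2_e,
                        "H2": heritability(vc),
                        "converged": vc.converged,
                    }
                )
        df = pd.DataFrame(rows)
        _write_csv(df, outdir / "heritability.csv", cfg_hash)
        manifest["outputs"].append("heritability.csv")
        return df

    h2_table = _heritability()

    @stage("phenotypic_correlation")
    def _phenocorr():
        df = phenotypic_correlation(records, trait)
        _write_csv(df, outdir / "phenotypic_correlation.csv", cfg_hash)
        manifest["outputs"].append("phenotypic_correlation.csv")
        return df

    _phenocorr()

    @stage("bivariate")
    def _bivariate():
        rows = []
        for h in harvests:
            grp = records[records["harvest"] == h]
            vi = grp[~grp["is_yield"]]
            fy = grp[grp["is_yield"]]
            if fy.empty:
                continue
            last = vi[vi["gdd"] == vi["gdd"].max()]
            paired = last.merge(
                fy[["plot", trait]].rename(columns={trait: "yield"}), on="plot"
            )
            fit = fit_bivariate(paired, trait, "yield")
            log_fit("bivariate", harvest=str(h), converged=bool(fit.converged),
                    n_iter=fit.n_iter, loglik=fit.loglik)
            rows.append(
                {
                    "harvest": h,
                    "r_g": fit.r_g,
                    "r_e": fit.r_e,
                    "sigma2_g_vi": fit.G[0, 0],
                    "sigma2_g_fy": fit.G[1, 1],
                    "converged": fit.converged,
                }
            )
        df = pd.DataFrame(rows)
        _write_csv(df, outdir / "genetic_correlation_mt.csv", cfg_hash)
        manifest["outputs"].append("genetic_correlation_mt.csv")
        return df

    biv_table = _bivariate()

    @stage("random_regression")
    def _rr():
        fits = {}
        for h in harvests:
            grp = records[records["harvest"] == h]
            spec = RRSpec(
                data=grp,
                trait=trait,
                order=config.order,
                include_yield=config.include_yield and grp["is_yield"].any(),
                residual_structure=config.residual_structure,
            )
            fit = fit_rr(spec, tol=config.tol, max_iter=config.max_iter)
            log_fit("random_regression", harvest=str(h), converged=bool(fit.converged),
                    n_iter=fit.n_iter, loglik=fit.loglik)
            fits[h] = fit
            tag = str(h)
            _write_csv(pd.DataFrame(fit.K_g), outdir / f"rr_Kg_{tag}.csv", cfg_hash)
            _write_csv(pd.DataFrame(fit.K_p), outdir / f"rr_Kp_{tag}.csv", cfg_hash)
            if fit.terminal_gdd is not None:
                _write_csv(
                    genetic_correlation_curve(fit),
                    outdir / f"rr_corr_curve_{tag}.csv",
                    cfg_hash,
                )
            _write_csv(growth_curves(fit), outdir / f"rr_growth_curves_{tag}.csv", cfg_hash)
            _write_csv(heritability_curve(fit), outdir / f"rr_h2_curve_{tag}.csv", cfg_hash)
        manifest["outputs"] += [f"rr_Kg_{h}.csv" for h in fits]
        return fits

    rr_fits = _rr()

    @stage("rse")
    def _rse():
        if h2_table is None or biv_table is None:
            raise RuntimeError("needs heritability and bivariate stages")
        rows = []
        for h in harvests:
            sub = h2_table[h2_table["harvest"] == h]
            vi_rows = sub[sub["trait"] == trait]
            fy_rows = sub[sub["trait"] == "yield"]
            b = biv_table[biv_table["harvest"] == h]
            if vi_rows.empty or fy_rows.empty or b.empty:
                continue
            h2_vi = float(vi_rows.iloc[-1]["H2"])  # flight closest to harvest
            h2_fy = float(fy_rows.iloc[0]["H2"])
            r_g = float(b.iloc[0]["r_g"])
            rows.append(
                {"harvest": h, "h2_vi": h2_vi, "h2_fy": h2_fy, "r_g": r_g,
                 "rse": rse(h2_vi, h2_fy, np.clip(r_g, -1, 1))}
            )
        df = pd.DataFrame(rows)
        _write_csv(df, outdir / "rse.csv", cfg_hash)
        manifest["outputs"].append("rse.csv")
        return df

    _rse()

    @stage("stability")
    def _stability():
        fy = records[records["is_yield"]]
        if fy.empty or rr_fits is None or len(rr_fits) < 2:
            raise RuntimeError("needs yield rows and >= 2 RR fits")
        ge = fy.pivot_table(index="genotype", columns="harvest", values=trait, aggfunc="mean")
        biplot = gge_biplot(ge)
        scores = biplot.genotype_scores.join(biplot.aea_mean).join(biplot.aea_stability)
        _write_csv(scores, outdir / "gge_genotype_scores.csv", cfg_hash, index=True)
        _write_csv(
            biplot.environment_scores, outdir / "gge_environment_scores.csv", cfg_hash, index=True
        )
        yield_blups = {}
        for h in harvests:
            sub = fy[fy["harvest"] == h]
            if sub.empty:
                continue
            vc = fit_st_blup(sub, trait, tol=config.tol, max_iter=config.max_iter)
            yield_blups[h] = vc.blups
        profile = growth_stability(
            list(rr_fits.values()), yield_blups=yield_blups, n_points=config.stability_points
        )
        _write_csv(profile.growth_sd, outdir / "growth_stability.csv", cfg_hash, index=True)
        report = mean_vs_stability_report(biplot, profile)
        _write_csv(report, outdir / "mean_vs_stability.csv", cfg_hash, index=True)
        manifest["outputs"] += [
            "gge_genotype_scores.csv",
            "growth_stability.csv",
            "mean_vs_stability.csv",
        ]
        if config.make_plots:
            _plot_biplot(biplot, outdir / "gge_biplot.png")
            manifest["outputs"].append("gge_biplot.png")
        return report

    _stability()
    _finish(manifest, outdir, fitlog)
    return manifest


def _plot_biplot(biplot, path) -> None:  # pragma: no cover - optional artifact
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    g = biplot.genotype_scores
    e = biplot.environment_scores
    ax.scatter(g["PC1"], g["PC2"], s=12, color="tab:blue")
    for name, row in e.iterrows():
        ax.annotate(str(name), (row["PC1"], row["PC2"]), color="tab:green")
    aea = e.mean(axis=0).to_numpy()
    aea = aea / np.linalg.norm(aea) * max(np.abs(g.to_numpy()).max(), 1e-9)
    ax.annotate("", xy=aea, xytext=(0, 0), arrowprops={"color": "green", "arrowstyle": "->"})
    ax.axline((0, 0), aea, color="green", lw=0.5)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_title("GGE biplot: mean vs stability")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _finish(manifest, outdir, fitlog) -> None:
    fitlog.close()
    with open(Path(outdir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
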