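"""End-to-end orchestration of the two-pronged landscape analysis.

A run proceeds in the order of the underlying study: generate (or load)
the inputs, run surprisal analysis on the kinetic transcriptome, reduce
the flow-cytometry clouds to the 1-D reaction coordinate and estimate
densities, fit the diffusivity from the sorting-relaxation series, fit
the drift/growth landscape to the drug-treatment series, fit growth rates
from cell counts, and compare the two potential landscapes.  Every stage
writes its artifacts to the run directory so stages can be re-run and
inspected individually; a manifest records the configuration, its hash,
seeds and per-stage summaries.  Runs are deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, fp, inference, surprisal, synthetic, trajectory

__all__ = ["PipelineConfig", "run_full"]


@dataclass
class PipelineConfig:
    """Configuration of a full run; defaults reproduce the M397-like fixture."""

    scenario: str = "m397-like"  # named synthetic scenario (or "data" with paths)
    expression_path: str | None = None
    clouds_path: str | None = None
    sorting_path: str | None = None
    counts_path: str | None = None
    seed: int = 0
    n_genes: int = 10_000
    noise_sd: float = 0.1
    cells_per_timepoint: int = 10_000
    n_grid: int = 256
    min_mean: float = 0.5  # gene prefilter thresholds
    min_cv: float = 0.15
    n_constraints: int | str = "auto"
    curve_span: float = 0.15
    kde_bandwidth: float | None = None  # None = Silverman per timepoint
    sorting_gate: tuple = (3.1, 6.0)
    sorting_times: tuple = (0.0, 1.0, 2.0, 4.0, 7.0, 10.0)
    d_grid_min: float = 0.01
    d_grid_max: float = 3.0
    d_grid_size: int = 30
    n_knots: int = 20
    n_starts: int = 2
    max_iter: int = 400
    fit_grid: int = 128  # densities are resampled to this grid for the landscape fit
    growth_windows: tuple = ((0.0, 21.0), (21.0, 78.0))
    growth_noise_cv: float = 0.05
    make_figures: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_constraints"] = self.n_constraints
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("sorting_gate", "sorting_times", "growth_windows"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(tuple(v) if isinstance(v, (list, tuple)) else v
                                 for v in raw[key]) if key == "growth_windows" else tuple(raw[key])
        return cls(**raw)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        wrapped.__name__ = fn.__name__
        return wrapped
    return deco


@_stage("simulate")
def _simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    indir = outdir / "inputs"
    indir.mkdir(parents=True, exist_ok=True)
    tt = synthetic.m397_like_transcriptome_truth(
        n_genes=cfg.n_genes, noise_sd=cfg.noise_sd, seed=cfg.seed)
    X = synthetic.gen_transcriptome(tt)
    X.to_tsv(indir / "expression.tsv")
    tt.to_json(indir / "transcriptome_truth.json")

    st = synthetic.m397_like_simulation_truth(
        n_grid=cfg.n_grid, cells_per_timepoint=cfg.cells_per_timepoint, seed=cfg.seed)
    clouds = synthetic.gen_flow_clouds(st, synthetic.M397_TIMEPOINTS)
    clouds.to_csv(indir / "clouds.csv")
    st.to_json(indir / "simulation_truth.json")

    nt = synthetic.drug_naive_simulation_truth(
        n_grid=cfg.n_grid, cells_per_timepoint=cfg.cells_per_timepoint, seed=cfg.seed)
    sorting = synthetic.gen_sorting_relaxation(nt, cfg.sorting_gate, np.array(cfg.sorting_times))
    sorting.to_csv(indir / "sorting.csv")
    # unsorted drug-naive population: the measured steady state
    unsorted = synthetic.gen_sorting_relaxation(
        nt, (float(nt.grid[0]), float(nt.grid[-1])), np.array([0.0]))
    unsorted.to_csv(indir / "unsorted.csv")

    count_times = np.array([0.0, 7.0, 21.0, 30.0, 43.0, 66.0, 78.0])
    # doublings/day implied by the planted net growth over each phase
    counts_a = synthetic.gen_growth_counts(
        synthetic.M397_ALPHAS[1] / np.log(2), 1e5, count_times[count_times <= 21],
        cfg.growth_noise_cv, seed=cfg.seed + 7)
    counts_b = synthetic.gen_growth_counts(
        synthetic.M397_ALPHAS[2] / np.log(2),
        float(counts_a["count"].iloc[-1]), count_times[count_times > 21] - 21.0,
        cfg.growth_noise_cv, seed=cfg.seed + 8)
    counts_b["time_day"] += 21.0
    import pandas as pd

    counts = pd.concat([counts_a, counts_b], ignore_index=True)
    counts.to_csv(indir / "counts.csv", index=False)
    return {"transcriptome": X, "clouds": clouds, "sorting": sorting,
            "unsorted": unsorted, "counts": counts, "sim_truth": st,
            "naive_truth": nt}


@_stage("surprisal")
def _run_surprisal(cfg: PipelineConfig, X, outdir: Path):
    d = outdir / "surprisal"
    d.mkdir(exist_ok=True)
    Xf = surprisal.filter_genes(X, cfg.min_mean, cfg.min_cv)
    dec = surprisal.fit_surprisal(Xf, cfg.n_constraints)
    fes = surprisal.free_energy(dec, Xf)
    dec.amplitudes_frame().to_csv(d / "amplitudes.tsv", sep="\t")
    dec.loadings_frame().iloc[:, : dec.J + 1].to_csv(d / "loadings.tsv", sep="\t")
    import pandas as pd

    pd.DataFrame({"time_day": fes.timepoints, "F": fes.F}).to_csv(
        d / "free_energy.tsv", sep="\t", index=False)
    meta = {
        "n_genes_in": X.n_genes, "n_genes_filtered": Xf.n_genes,
        "J": dec.J, "pseudocount": dec.pseudocount,
        "lambda0_rel_range": float(np.ptp(dec.lambda0) / np.abs(dec.lambda0).mean()),
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=1))
    return dec, fes, meta


@_stage("trajectory")
def _run_trajectory(cfg: PipelineConfig, clouds, sorting, unsorted, outdir: Path):
    d = outdir / "trajectory"
    d.mkdir(exist_ok=True)
    curve = trajectory.fit_principal_curve(clouds, span=cfg.curve_span)
    curve.to_frame().to_csv(d / "curve.tsv", sep="\t", index=False)
    coords = trajectory.project(clouds, curve)
    grid = trajectory.default_grid(coords, n=cfg.n_grid)
    dens = trajectory.estimate_density(coords, clouds.times, grid, cfg.kde_bandwidth)
    dens.to_csv(d / "densities.csv")
    sort_coords = trajectory.project(sorting, curve)
    sort_dens = trajectory.estimate_density(sort_coords, sorting.times, grid, cfg.kde_bandwidth)
    sort_dens.to_csv(d / "sorting_densities.csv")
    steady = None
    if unsorted is not None:
        u_coords = trajectory.project(unsorted, curve)
        steady = trajectory.estimate_density(u_coords, unsorted.times, grid,
                                             cfg.kde_bandwidth).densities[0]
    return curve, dens, sort_dens, steady


@_stage("fit-d")
def _run_fit_d(cfg: PipelineConfig, sort_dens, naive_steady, outdir: Path):
    d = outdir / "fits"
    d.mkdir(exist_ok=True)
    D_grid = np.geomspace(cfg.d_grid_min, cfg.d_grid_max, cfg.d_grid_size)
    D, info = inference.fit_diffusivity(sort_dens, naive_steady, D_grid, return_details=True)
    (d / "diffusivity.json").write_text(json.dumps(
        {"D": D, "grid": info["grid"].tolist(), "losses": info["losses"].tolist(),
         "refined": info["refined"]}, indent=1))
    return D


def _resample(series: fp.DensitySeries, n: int) -> fp.DensitySeries:
    grid = np.linspace(series.grid[0], series.grid[-1], n)
    dens = np.vstack([np.interp(grid, series.grid, row) for row in series.densities])
    dens /= np.trapezoid(dens, grid, axis=1)[:, None]
    return fp.DensitySeries(grid=grid, densities=dens, times=series.times, normalized=True)


@_stage("fit-landscape")
def _run_fit_landscape(cfg: PipelineConfig, dens, D, outdir: Path):
    d = outdir / "fits"
    d.mkdir(exist_ok=True)
    small = _resample(dens, cfg.fit_grid)
    coexist = None
    for row in small.densities:  # earliest timepoint with three resolvable modes
        try:
            coexist = inference.cutoffs_from_minima(row, small.grid)
            break
        except ValueError:
            continue
    if coexist is None:
        raise ValueError("no timepoint shows three coexisting modes; supply cutoffs")
    fit = inference.fit_landscape(small, D, small.densities[0], coexist,
                                  n_knots=cfg.n_knots, n_starts=cfg.n_starts,
                                  max_iter=cfg.max_iter, seed=cfg.seed)
    plain = inference.fit_landscape(small, D, small.densities[0], coexist,
                                    n_knots=cfg.n_knots, n_starts=1,
                                    max_iter=cfg.max_iter // 2, seed=cfg.seed,
                                    fit_growth=False)
    out = fit.to_dict()
    out["cutoffs_detected"] = list(coexist)
    out["plain_fp_loss"] = plain.loss
    (d / "landscape.json").write_text(json.dumps(out, indent=1))
    return fit, plain, coexist


@_stage("growth")
def _run_growth(cfg: PipelineConfig, counts, outdir: Path):
    d = outdir / "fits"
    d.mkdir(exist_ok=True)
    fits = inference.fit_growth_rates(counts, cfg.growth_windows)
    (d / "growth.json").write_text(json.dumps(
        [dataclasses.asdict(g) for g in fits], indent=1))
    return fits


@_stage("compare")
def _run_compare(cfg: PipelineConfig, fit, fes, cutoffs, outdir: Path):
    d = outdir / "fits"
    grid = fit.model.grid
    c1, c2 = cutoffs
    states = [
        ("melanocytic", (grid[0], c1), [0.0, 3.0]),
        ("neural-crest", (c1, c2), [11.0, 17.0, 21.0]),
        ("mesenchymal", (c2, grid[-1]), [73.0]),
    ]
    report = inference.compare_landscapes(fit.model.potential(), grid, fes, states)
    (d / "comparison.json").write_text(json.dumps(report, indent=1))
    import pandas as pd

    pd.DataFrame({"state": report["states"],
                  "potential_fp": report["potential_fp"],
                  "potential_surprisal": report["potential_surprisal"]}).to_csv(
        d / "comparison.tsv", sep="\t", index=False)
    return report


def _figures(outdir: Path, dens, fit, fes) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)

    fig, axes = plt.subplots(1, dens.times.size, figsize=(2.2 * dens.times.size, 2.4),
                             sharey=True)
    pred = fp.normalize_population(fp.solve_fp_source(
        fit.model, dens.densities[0], dens.times[1:]))
    for k, ax in enumerate(np.atleast_1d(axes)):
        ax.plot(dens.grid, dens.densities[k], "b-", lw=1, label="measured")
        if k > 0:
            small = np.interp(dens.grid, pred.grid, pred.densities[k - 1])
            ax.plot(dens.grid, small, "r-", lw=1, label="model")
        ax.set_title(f"day {dens.times[k]:g}", fontsize=8)
    np.atleast_1d(axes)[0].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(figdir / "densities.png", dpi=120)
    plt.close(fig)

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(7, 2.6))
    ax1.plot(fit.model.grid, fit.model.potential())
    ax1.set_xlabel("reaction coordinate x (q)")
    ax1.set_ylabel("U(x)")
    ax2.plot(fes.timepoints, fes.F, "o-")
    ax2.set_xlabel("day")
    ax2.set_ylabel("F(t)")
    fig.tight_layout()
    fig.savefig(figdir / "landscapes.png", dpi=120)
    plt.close(fig)


def run_full(config: PipelineConfig, outdir) -> dict:
    """Run every stage and return the manifest (also written to the run dir)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.scenario == "m397-like":
        data = _simulate(config, outdir)
        X = data["transcriptome"]
        clouds, sorting, counts = data["clouds"], data["sorting"], data["counts"]
        unsorted = data["unsorted"]
    elif config.scenario == "data":
        X = surprisal.ExpressionMatrix.from_tsv(config.expression_path)
        clouds = synthetic.MarkerCloudSeries.from_csv(config.clouds_path)
        sorting = synthetic.MarkerCloudSeries.from_csv(config.sorting_path)
        import pandas as pd

        counts = pd.read_csv(config.counts_path)
        unsorted = None
    else:
        raise RuntimeError(f"pipeline stage 'config' failed: unknown scenario {config.scenario!r}")

    dec, fes, smeta = _run_surprisal(config, X, outdir)
    curve, dens, sort_dens, steady = _run_trajectory(config, clouds, sorting, unsorted, outdir)
    if steady is None:
        steady = sort_dens.densities[-1]  # last relaxation timepoint as steady proxy
    D = _run_fit_d(config, sort_dens, steady, outdir)
    fit, plain, cutoffs = _run_fit_landscape(config, dens, D, outdir)
    growth = _run_growth(config, counts, outdir)
    report = _run_compare(config, fit, fes, cutoffs, outdir)
    if config.make_figures:
        _figures(outdir, _resample(dens, config.fit_grid), fit, fes)

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "surprisal": smeta,
        "curve": {"length": curve.length, "n_iter": curve.n_iter},
        "diffusivity": D,
        "landscape": {"loss": fit.loss, "plain_fp_loss": plain.loss,
                      "alpha1": fit.alpha1, "alpha2": fit.alpha2,
                      "converged": fit.converged, "cutoffs": list(cutoffs)},
        "growth": [dataclasses.asdict(g) for g in growth],
        "comparison": report,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
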