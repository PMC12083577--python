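"""End-to-end orchestration: simulate -> preprocess -> curves -> fit -> evaluate.

Every stage writes its outputs under the configured output directory and the
run ends with a manifest recording the configuration echo, a config hash,
package/numpy versions, and a SHA-256 per output file.  Re-running with an
identical configuration reproduces identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .curves import METRICS, BinGrid, compute_curves, curve_matrix, write_curve_matrix
from .evaluate import (comparison_markdown, compute_biomarker, metric_comparison,
                       stratify_biomarker)
from .preprocess import preprocess_cohort, read_long_csv, write_wide_csv
from .sofr import (BSplineBasis, QuadratureSpec, build_design, export_beta_csv,
                   fit_sofr)
from .synthetic import (SimulationConfig, simulate_cohort, write_covariates_csv,
                        write_long_csv)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Single source of truth for a reproducible run (YAML-serializable)."""

    outdir: str = "movereserve_out"
    seed: int = 0
    # inputs: if both paths are None, a synthetic cohort is generated
    input_long_csv: str = None
    input_covariates_csv: str = None
    # synthetic stage
    n_subjects: int = 60
    n_days: int = 7
    reserve_effect: float = 0.7
    noise_sd: float = 1.2
    latent_metric: str = "q100"
    dst_mode: str = "none"
    nonwear_rate: float = 0.15
    nonwear_duration: int = 120
    edss_grid: bool = False
    # preprocess stage
    nonwear_min_run: int = 90
    wear_fraction: float = 0.9
    min_valid_days: int = 3
    nonwear_policy: str = "exclude"
    # curves stage
    bin_width: int = 10
    quantile_type: str = "lower"
    cv_threshold_c: float = 0.0
    scales: tuple = ("AC", "LAC")
    metrics: tuple = METRICS
    # SOFR stage
    n_basis: int = 15
    penalty_order: int = 2
    lambda_rule: str = "gcv"
    # evaluation stage
    folds: int = 5
    reps: int = 100
    edss_threshold: float = 4.0
    # reporting
    figures: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.scales = tuple(cfg.scales)
        cfg.metrics = tuple(cfg.metrics)
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class StageFailure(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; return a bundle of in-memory results and paths."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    timings, bundle = {}, {"config": config, "outdir": out}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:
                logger.error("stage %s failed: %s", name, exc)
                raise StageFailure(name, exc) from exc
            timings[name] = round(time.perf_counter() - t0, 3)
            logger.info("stage %s done in %.2fs", name, timings[name])
        return deco

    @stage("simulate")
    def _simulate():
        sim_dir = out / "simulate"
        sim_dir.mkdir(exist_ok=True)
        if config.input_long_csv:
            bundle["raw"] = read_long_csv(config.input_long_csv)
            bundle["covariates"] = pd.read_csv(config.input_covariates_csv,
                                               dtype={"subject_id": str})
            bundle["truth"] = None
            return
        sim = SimulationConfig(
            n_subjects=config.n_subjects, n_days=config.n_days,
            reserve_effect=config.reserve_effect, noise_sd=config.noise_sd,
            latent_metric=config.latent_metric, dst_mode=config.dst_mode,
            nonwear_rate=config.nonwear_rate,
            nonwear_duration=config.nonwear_duration,
            edss_grid=config.edss_grid, seed=config.seed)
        mats, cov, truth = simulate_cohort(sim)
        write_long_csv(mats, sim_dir / "cohort_long.csv")
        write_covariates_csv(cov, sim_dir / "covariates.csv")
        truth.to_json(sim_dir / "truth.json",
                      BinGrid(config.bin_width).midpoints_hours)
        bundle.update(raw=mats, covariates=cov, truth=truth)

    @stage("preprocess")
    def _preprocess():
        qc_dir = out / "qc"
        qc_dir.mkdir(exist_ok=True)
        clean, report = preprocess_cohort(
            bundle["raw"], min_valid_days=config.min_valid_days,
            wear_fraction=config.wear_fraction,
            min_run=config.nonwear_min_run,
            nonwear_policy=config.nonwear_policy)
        report.to_json(qc_dir / "qc_report.json")
        (qc_dir / "qc_report.txt").write_text(report.summary() + "\n")
        write_wide_csv(clean, qc_dir / "clean_wide.csv", qc_dir / "wear_mask.csv")
        bundle.update(clean=clean, qc=report)
        bundle["covariates"] = bundle["covariates"][
            bundle["covariates"]["subject_id"].isin(
                [m.subject_id for m in clean])].reset_index(drop=True)

    grid = BinGrid(config.bin_width)
    copts = {"quantile_type": config.quantile_type,
             "cv_threshold": config.cv_threshold_c}

    @stage("curves")
    def _curves():
        cdir = out / "curves"
        cdir.mkdir(exist_ok=True)
        cms = {}
        for scale in config.scales:
            for metric in config.metrics:
                cm, ids = curve_matrix(bundle["clean"], bundle["covariates"],
                                       grid, metric, scale=scale, **copts)
                cms[(metric, scale)] = (cm, ids)
                write_curve_matrix(
                    cm, ids, grid, cdir / f"curves_{metric}_{scale}.csv",
                    cdir / f"curves_{metric}_{scale}.json",
                    metric=metric, scale=scale,
                    quantile_type=config.quantile_type,
                    cv_threshold=config.cv_threshold_c)
        bundle["curve_matrices"] = cms

    @stage("fit")
    def _fit():
        fdir = out / "fit"
        fdir.mkdir(exist_ok=True)
        basis = BSplineBasis(K=config.n_basis)
        quad = QuadratureSpec.from_bingrid(grid)
        fits, biomarkers = {}, []
        for (metric, scale), (cm, ids) in bundle["curve_matrices"].items():
            cov = bundle["covariates"].set_index("subject_id").loc[ids].reset_index()
            y = cov["EDSS"].to_numpy(dtype=float)
            Z, F, P = build_design(cm, cov, basis, quad, config.penalty_order)
            fit = fit_sofr(y, Z, F, P, lambda_rule=config.lambda_rule,
                           basis=basis, quad=quad,
                           penalty_order=config.penalty_order)
            fit.to_json(fdir / f"sofr_{metric}_{scale}.json")
            export_beta_csv(fit, fdir / f"beta_{metric}_{scale}.csv")
            fits[(metric, scale)] = (fit, cm, ids)
            bm = compute_biomarker(fit, cm, ids, metric=f"{metric}_{scale}")
            biomarkers.append(bm)
        bundle["fits"] = fits
        bundle["biomarkers"] = pd.concat(biomarkers, ignore_index=True)

    @stage("evaluate")
    def _evaluate():
        edir = out / "evaluate"
        edir.mkdir(exist_ok=True)
        basis = BSplineBasis(K=config.n_basis)
        table, results = metric_comparison(
            bundle["clean"], bundle["covariates"], metrics=config.metrics,
            scales=config.scales, grid=grid, k=config.folds, reps=config.reps,
            seed=config.seed, basis=basis, lambda_rule=config.lambda_rule,
            curve_options=copts)
        table.to_csv(edir / "comparison.csv", index=False, float_format="%.10g")
        (edir / "comparison.md").write_text(comparison_markdown(table) + "\n")
        for (metric, scale), res in results.items():
            res.to_json(edir / f"cv_{metric}_{scale}.json")
        bundle["comparison"] = table
        bundle["cv_results"] = results
        bundle["biomarkers"].to_csv(edir / "biomarkers.csv", index=False,
                                    float_format="%.10g")
        edss = bundle["covariates"].set_index("subject_id")["EDSS"]
        strata = stratify_biomarker(bundle["biomarkers"], edss,
                                    threshold=config.edss_threshold)
        strata.to_csv(edir / "biomarker_strata.csv", index=False,
                      float_format="%.10g")
        bundle["strata"] = strata

    if config.figures:
        @stage("figures")
        def _figures():
            plot_outputs(bundle)

    @stage("manifest")
    def _manifest():
        files = sorted(p for p in out.rglob("*")
                       if p.is_file() and p.name != "manifest.json")
        manifest = {
            "package": "movereserve",
            "version": __version__,
            "numpy": np.__version__,
            "seed": config.seed,
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "timings_s": timings,
            "files": {str(p.relative_to(out)): _sha256(p) for p in files},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        bundle["manifest"] = manifest

    return bundle


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

def plot_outputs(bundle: dict) -> list:
    """Figure set: per-subject quantile profiles, distributional summaries,
    and beta-hat with 95% bands.  Missing stages are skipped with a log entry."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(bundle["outdir"]) / "figures"
    out.mkdir(exist_ok=True)
    config = bundle["config"]
    grid = BinGrid(config.bin_width)
    written = []

    clean = bundle.get("clean")
    cov = bundle.get("covariates")
    if clean and cov is not None and len(cov) >= 2:
        edss = cov.set_index("subject_id")["EDSS"]
        ids = [m.subject_id for m in clean if m.subject_id in edss.index]
        lo_id = min(ids, key=lambda s: edss[s])
        hi_id = max(ids, key=lambda s: edss[s])
        by_id = {m.subject_id: m for m in clean}
        qmetrics = [m for m in ("q50", "q90", "q95", "q99", "q100")
                    if m in config.metrics]
        dmetrics = [m for m in ("mean", "mode", "sd", "mad", "cv")
                    if m in config.metrics]
        for name, metrics_set in (("quantile_profiles", qmetrics),
                                  ("distributional_summaries", dmetrics)):
            if not metrics_set:
                continue
            fig, axes = plt.subplots(1, len(metrics_set),
                                     figsize=(3.2 * len(metrics_set), 3),
                                     sharex=True)
            axes = np.atleast_1d(axes)
            for ax, metric in zip(axes, metrics_set):
                for sid, color in ((lo_id, "tab:blue"), (hi_id, "tab:red")):
                    c = compute_curves(by_id[sid], grid, (metric,),
                                       quantile_type=config.quantile_type,
                                       cv_threshold=config.cv_threshold_c)[metric]
                    ax.plot(grid.midpoints_hours, c.values, color=color,
                            label=f"{sid} (EDSS {edss[sid]:.1f})")
                ax.set_title(metric)
                ax.set_xlabel("hour of day")
            axes[0].legend(fontsize=7)
            fig.tight_layout()
            path = out / f"{name}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)
    else:
        logger.warning("skipping subject profile figures: no cleaned cohort")

    fits = bundle.get("fits")
    if fits:
        from .sofr import beta_pointwise_band
        for (metric, scale), (fit, _, _) in fits.items():
            if metric != "q100":
                continue
            s = np.linspace(0, 24, 241)
            est, lob, hib = beta_pointwise_band(fit, s)
            fig, ax = plt.subplots(figsize=(5, 3))
            ax.plot(s, est, "k-", label=r"$\hat\beta(s)$")
            ax.plot(s, lob, "k:", lw=0.8)
            ax.plot(s, hib, "k:", lw=0.8)
            ax.axhline(0, color="grey", lw=0.5)
            ax.set_xlabel("hour of day")
            ax.set_title(f"coefficient function, {metric} ({scale})")
            fig.tight_layout()
            path = out / f"beta_{metric}_{scale}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)
    else:
        logger.warning("skipping beta figures: no fits in bundle")
    return written
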