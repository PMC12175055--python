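"""Config-driven end-to-end pipeline.

Stages (each can be toggled): simulate -> phenology -> pca -> fit ->
synchrony -> wavelet -> trends.  One global seed is expanded into
independent per-stage streams with ``numpy.random.SeedSequence(seed).spawn``
in a fixed stage order, so any stage can be rerun reproducibly on its own.
Every run writes a machine-readable manifest (stage seeds, settings,
convergence flags, artifact hashes).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import gompertz, io, phenology, synchrony, synthetic, trends, wavelets

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "phenology", "pca", "fit", "synchrony", "wavelet",
               "trends"]


@dataclass
class PipelineConfig:
    out_dir: str = "sealsync_out"
    seed: int = 0
    stages: list = field(default_factory=lambda: list(STAGE_ORDER))
    counts_file: str | None = None      # use instead of simulated counts
    sic_file: str | None = None         # netCDF or long CSV
    # simulate stage
    n_species: int = 3
    n_years: int = 48
    start_year: int = 1977
    missing_years: list = field(default_factory=lambda: [1996, 2021])
    sigma_delta2: float = 0.04
    sigma_eps2: float = 0.04
    r: float = 20.0
    alpha: float = 0.0
    nu_diag: float = -0.15
    gamma_shared: float = -0.103
    y0: float = 1000.0
    sim_seasons: int = 12
    sic_noise_sd: float = 5.0
    # fit stage
    n_pcs: int = 2
    selection: bool = False
    mcmc_profile: str = "reduced"       # "reduced" | "full"
    # synchrony stage
    n_perm: int = 999
    # wavelet stage
    highpass_years: float = 8.0
    # trends stage
    n_boot: int = 500

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return PipelineConfig(**data)


def _spawn_stage_seeds(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(STAGE_ORDER))
    return {st: int(c.generate_state(1)[0] % (2**31)) for st, c in
            zip(STAGE_ORDER, children)}


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage in dependency order; returns the manifest."""
    out = io.ensure_dir(config.out_dir)
    seeds = _spawn_stage_seeds(config.seed)
    manifest: dict = {"seed": config.seed, "stage_seeds": seeds,
                      "config": asdict(config), "stages": {}, "artifacts": {}}
    enabled = [s for s in STAGE_ORDER if s in config.stages]

    counts = None
    truth = None
    grid = None
    scores = None

    # ------------------------------------------------------------- simulate
    if "simulate" in enabled:
        sseed = seeds["simulate"]
        years = np.arange(config.start_year, config.start_year + config.n_years)
        missing_idx = frozenset(int(y) - config.start_year
                                for y in config.missing_years
                                if config.start_year <= y < config.start_year
                                + config.n_years)
        scenario = synthetic.SimScenario(
            n_species=config.n_species, n_years=config.n_years,
            alpha=config.alpha, nu=np.eye(config.n_species) * config.nu_diag,
            gamma=config.gamma_shared, sigma_delta2=config.sigma_delta2,
            sigma_eps2=config.sigma_eps2, r=config.r, y0=config.y0,
            missing_years=missing_idx, seed=sseed,
        )
        counts, truth = synthetic.gen_counts(scenario)
        counts.years = years
        io.write_counts(counts, out / "counts.csv")
        params = [synthetic.SeasonParams(label_year=config.start_year + i,
                                         advance_day=110 + 9 * (i % 4),
                                         retreat_day=270 + 11 * (i % 3),
                                         plateau=55.0 + 8.0 * (i % 5),
                                         ramp_days=30)
                  for i in range(config.sim_seasons)]
        grid, sic_truth = synthetic.gen_sic(params, noise_sd=config.sic_noise_sd,
                                            seed=sseed + 1,
                                            spatial_gradient=0.8)
        truth.advance = sic_truth.advance
        truth.retreat = sic_truth.retreat
        io.write_sic_netcdf(grid, out / "sic.nc")
        manifest["stages"]["simulate"] = {"seed": sseed,
                                          "n_years": config.n_years}
    if config.counts_file:
        counts = io.read_counts(config.counts_file)
    if config.sic_file:
        p = str(config.sic_file)
        grid = io.read_sic_csv(p) if p.endswith(".csv") else io.read_sic_netcdf(p)
    if counts is None and any(s in enabled for s in
                              ("fit", "synchrony", "wavelet", "trends")):
        raise RuntimeError("stage dependency missing: counts "
                           "(enable 'simulate' or set counts_file)")

    # ------------------------------------------------------------ phenology
    table = None
    if "phenology" in enabled:
        if grid is None:
            raise RuntimeError("stage dependency missing: SIC grid for 'phenology'")
        table = phenology.build_covariate_table(grid)
        io.write_covariates(table, out / "ice_covariates.csv")
        manifest["stages"]["phenology"] = {"n_seasons": int(len(table))}

    if "pca" in enabled:
        if table is None:
            raise RuntimeError("stage dependency missing: covariate table for 'pca'")
        keep = table.columns[table.std(ddof=1) > 0]
        if len(keep) < len(table.columns):
            logger.info("pca: dropping constant column(s) %s",
                        sorted(set(table.columns) - set(keep)))
        res = phenology.pca(table[keep])
        io.write_covariates(res.scores, out / "pc_scores.csv")
        io.write_covariates(res.loadings, out / "pc_loadings.csv")
        scores = res.scores
        manifest["stages"]["pca"] = {
            "var_explained": [float(v) for v in res.var_explained],
            "cum_var_6pc": float(res.var_explained[:6].sum()),
        }

    # ------------------------------------------------------------------ fit
    if "fit" in enabled:
        fseed = seeds["fit"]
        T = len(counts.years)
        if scores is not None:
            k = min(config.n_pcs, scores.shape[1])
            z = np.zeros((T, k))
            rows = min(len(scores), T)
            z[-rows:, :] = scores.iloc[-rows:, :k].to_numpy()
        else:
            rng = np.random.default_rng(fseed)
            z = rng.standard_normal((T, config.n_pcs))
        spec = gompertz.ModelSpec.build(
            n_species=len(counts.species), n_cov=z.shape[1],
            share_covariates=True, selection=config.selection)
        cfg = (gompertz.MCMCConfig(seed=fseed) if config.mcmc_profile == "full"
               else gompertz.MCMCConfig.reduced(seed=fseed))
        samples, summary = gompertz.run_mcmc(counts, z, spec, config=cfg)
        fit_json = {
            "icc_overall": summary.icc_overall,
            "icc_species": [float(v) for v in summary.icc_species],
            "icc_ci": summary.icc_ci,
            "waic": summary.waic,
            "bayes_pvalue": summary.bayes_pvalue,
            "max_rhat": summary.max_rhat,
            "rhat_ok": summary.rhat_ok,
            "geometric_lambda": summary.geometric_lambda,
            "gamma_mean": [float(v) for v in np.atleast_1d(summary.mean["gamma"])],
            "inclusion": summary.inclusion,
        }
        (out / "fit_summary.json").write_text(json.dumps(fit_json, indent=2))
        manifest["stages"]["fit"] = {"seed": fseed, "rhat_ok": summary.rhat_ok,
                                     "max_rhat": summary.max_rhat}

    # ------------------------------------------------------------ synchrony
    if "synchrony" in enabled:
        pseed = seeds["synchrony"]
        y = np.where(counts.observed, counts.y, np.nan).astype(float)
        rows = []
        for transform in ("none", "logdiff"):
            for stat in synchrony.STATISTICS:
                res = synchrony.permutation_pvalue(
                    y, stat, n_perm=config.n_perm, seed=pseed,
                    transform=transform)
                rows.append({"statistic": res.statistic,
                             "transform": res.transform,
                             "value": res.value, "p_value": res.p_value,
                             "n_permutations": res.n_permutations})
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "synchrony.csv", index=False)
        manifest["stages"]["synchrony"] = {"seed": pseed, "n_perm": config.n_perm}

    # -------------------------------------------------------------- wavelet
    if "wavelet" in enabled:
        y = np.where(counts.observed, counts.y, np.nan).astype(float)
        filtered = np.vstack([
            wavelets.gaussian_highpass(row, config.highpass_years)
            for row in y])
        coh = wavelets.wavelet_coherence(filtered[0], filtered[1])
        mv = wavelets.modulus_ratio(list(filtered))
        import pandas as pd

        recs = []
        for i, s in enumerate(coh.scales):
            for j, t in enumerate(coh.times):
                recs.append({"scale": s, "time": counts.years[j],
                             "coherence": coh.coherence[i, j],
                             "phase": coh.phase[i, j],
                             "modulus_ratio": mv.ratio[i, j],
                             "inside_coi": bool(s <= coh.coi[j])})
        pd.DataFrame(recs).to_csv(out / "wavelet.csv", index=False)
        manifest["stages"]["wavelet"] = {
            "mean_coherence_in_coi": float(coh.coherence[coh.inside_coi()].mean()),
            "mean_modulus_ratio_in_coi": float(mv.ratio[mv.inside_coi()].mean()),
        }

    # --------------------------------------------------------------- trends
    if "trends" in enabled:
        tseed = seeds["trends"]
        results = {}
        for i, sp in enumerate(counts.species):
            obs = counts.observed[i]
            yrs = counts.years[obs]
            logc = np.log(counts.y[i, obs] + 1.0)
            fit = trends.robust_mm_fit(yrs, logc, subsample_seed=tseed)
            fit = trends.bootstrap_ci(fit, yrs, logc, n_boot=config.n_boot,
                                      seed=tseed + i)
            span = float(counts.years[-1] - counts.years[0])
            results[sp] = {
                "slope": fit.slope,
                "slope_ci": fit.slope_ci,
                "longterm_decline_pct": trends.decline_percent(fit.slope, span),
                "longterm_pct_ci": fit.longterm_pct_ci,
                "annual_decline_pct": trends.decline_percent(fit.slope, 1.0),
                "annual_pct_ci": fit.annual_pct_ci,
            }
        (out / "trends.json").write_text(json.dumps(results, indent=2))
        manifest["stages"]["trends"] = {"seed": tseed, "n_boot": config.n_boot}

    for f in sorted(out.glob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["artifacts"][f.name] = _hash_file(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
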