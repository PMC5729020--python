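"""End-to-end orchestration: synth -> fit -> pool -> project-inputs -> attribute -> eCI.

One configuration object (optionally read from YAML) drives the whole
chain on synthetic data: generate a multi-location ensemble and pseudo-GCM
scenario series, fit the first-stage DLNMs, pool them by meta-regression,
derive BLUPs, recalibrate the modelled series, attribute decadal excess
mortality to heat and cold per location x GCM x RCP, aggregate to
GCM-ensemble fractions with net change versus the reference decade, and
attach Monte Carlo eCIs.  Runs are deterministic under a fixed master
seed.  With an output directory, each stage persists its artifacts and is
skipped on rerun when they already exist (deleting a stage's outputs
regenerates that stage and everything downstream).
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
from .attribution import (
    REFERENCE_DECADE,
    aggregate,
    attribution_by_decade,
    decadal_an_draws,
    find_mmt,
    results_to_frame,
)
from .climate import (
    ModelledSeries,
    baseline_mortality_profile,
    build_projection_inputs,
    calibrate,
)
from .dlnm import (
    CrossBasisSpec,
    ControlSpec,
    DailySeries,
    ReducedCurve,
    fit_location,
)
from .meta import (
    BlupCurve,
    MetaDesign,
    MetaFit,
    blup_joint_components,
    compute_blups,
    fit_meta_regression,
)
from .synth import (
    ENSEMBLE_VAR_BOUNDARY,
    ENSEMBLE_VAR_KNOTS,
    RCP_LABELS,
    ScenarioSpec,
    ensemble_truth_record,
    generate_modelled_climate,
    make_multilocation_ensemble,
)
from .uncertainty import empirical_ci, location_seed, sample_blup_ensemble

log = logging.getLogger("tempmort.pipeline")

#: default end-of-century warming (deg C, 2090-99 vs 2010-19) per pathway,
#: the magnitude order of published multi-region GCM-ensemble averages
DEFAULT_WARMING = {"RCP2.6": 0.6, "RCP4.5": 1.7, "RCP6.0": 2.3, "RCP8.5": 4.1}


@dataclass
class PipelineConfig:
    """Canonical configuration; defaults mirror the study design
    (21-day lag, 1990-2099 horizon, decadal reporting, 2010-19 reference,
    four RCPs, five GCMs)."""

    master_seed: int = 0
    n_locations: int = 6
    n_years: int = 10
    heterogeneity_sd: float = 0.02
    gdp_effect: float = 0.1
    base_rate: float = 30.0
    overdispersion: float = 1.3
    rcps: dict = field(default_factory=lambda: dict(DEFAULT_WARMING))
    n_gcms: int = 5
    gcm_bias_offset: float = 1.0
    gcm_bias_scale: float = 1.1
    horizon: tuple = ("1990-01-01", "2099-12-31")
    formula: tuple = ("gdp_pc",)
    grouping: str = "region"
    reference_decade: str = REFERENCE_DECADE
    mc_samples: int = 250
    max_lag: int = 21
    time_df_per_year: float = 8.0
    mmt_percentiles: tuple = (1.0, 99.0)

    def __post_init__(self) -> None:
        bad = set(self.rcps) - set(RCP_LABELS)
        if bad:
            raise ValueError(f"unknown RCP labels {sorted(bad)}; allowed: {RCP_LABELS}")
        self.formula = tuple(self.formula)
        self.horizon = tuple(self.horizon)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    truth: dict
    observed: list[DailySeries]
    metadata: pd.DataFrame
    curves: list[ReducedCurve]
    blups: list[BlupCurve]
    mmts: dict
    results: pd.DataFrame
    aggregates: pd.DataFrame
    manifest: dict


def _seed(cfg: PipelineConfig, *key: int) -> int:
    return int(
        np.random.SeedSequence([cfg.master_seed, *key]).generate_state(1)[0] % (2**31)
    )


def _stage_ready(paths: list[Path]) -> bool:
    return len(paths) > 0 and all(p.exists() for p in paths)


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path | None = None
) -> PipelineResult:
    """Run the full chain; see the module docstring for the stages."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    rcp_list = sorted(config.rcps)
    gcm_ids = [f"GCM{g + 1}" for g in range(config.n_gcms)]

    # ---- stage: synth ----------------------------------------------------
    synth_dir = out / "synth" if out else None
    obs_paths, mod_paths = [], {}
    if out:
        obs_paths = [synth_dir / f"observed_loc{i:03d}.csv" for i in range(config.n_locations)]
        for rcp in rcp_list:
            for i in range(config.n_locations):
                for g in gcm_ids:
                    mod_paths[(i, rcp, g)] = synth_dir / f"modelled_loc{i:03d}_{rcp}_{g}.csv"
        synth_files = obs_paths + list(mod_paths.values()) + [
            synth_dir / "metadata.csv", synth_dir / "truth.json"
        ]
    synth_fresh = out is None or not _stage_ready(synth_files)
    if synth_fresh:
        log.info("synth: generating %d locations, %d RCPs x %d GCMs",
                 config.n_locations, len(rcp_list), config.n_gcms)
        ensemble = make_multilocation_ensemble(
            config.n_locations,
            heterogeneity_sd=config.heterogeneity_sd,
            seed=_seed(config, 1),
            n_years=config.n_years,
            base_rate=config.base_rate,
            gdp_effect=config.gdp_effect,
            overdispersion=config.overdispersion,
        )
        observed = [m.series for m in ensemble]
        metadata = pd.DataFrame([m.metadata for m in ensemble])
        truth = ensemble_truth_record(ensemble)
        truth["scenarios"] = {}
        modelled: dict = {}
        for rcp in rcp_list:
            scen = ScenarioSpec(
                rcp_id=rcp,
                warming_by_2099=float(config.rcps[rcp]),
                gcm_bias_offset=config.gcm_bias_offset,
                gcm_bias_scale=config.gcm_bias_scale,
                n_gcms=config.n_gcms,
                seed=_seed(config, 2),
            )
            for i, m in enumerate(ensemble):
                temps = pd.Series(m.series.tmean, index=m.series.dates)
                series_list, scen_truth = generate_modelled_climate(
                    temps, scen, location_id=m.series.location_id,
                    horizon=config.horizon,
                )
                for ms in series_list:
                    modelled[(i, rcp, ms.gcm_id)] = ms
            truth["scenarios"][rcp] = scen_truth
        if out:
            synth_dir.mkdir(parents=True, exist_ok=True)
            for p, s in zip(obs_paths, observed):
                s.to_csv(p)
            metadata.to_csv(synth_dir / "metadata.csv", index=False)
            with open(synth_dir / "truth.json", "w") as fh:
                json.dump(truth, fh, indent=1)
            for key, ms in modelled.items():
                ms.to_csv(mod_paths[key])
    else:
        log.info("synth: outputs present, loading")
        observed = [
            DailySeries.from_csv(p, location_id=f"loc{i:03d}")
            for i, p in enumerate(obs_paths)
        ]
        metadata = pd.read_csv(synth_dir / "metadata.csv")
        with open(synth_dir / "truth.json") as fh:
            truth = json.load(fh)
        modelled = {
            key: ModelledSeries.from_csv(p, f"loc{key[0]:03d}", key[2], key[1])
            for key, p in mod_paths.items()
        }

    # ---- stage: fit ------------------------------------------------------
    fit_dir = out / "fit" if out else None
    curve_paths = (
        [fit_dir / f"curve_loc{i:03d}.json" for i in range(config.n_locations)]
        if out else []
    )
    fit_fresh = synth_fresh or out is None or not _stage_ready(curve_paths)
    if fit_fresh:
        log.info("fit: first-stage quasi-Poisson DLNM per location")
        spec_proto = dict(
            var_knots=np.asarray(ENSEMBLE_VAR_KNOTS),
            var_boundary=ENSEMBLE_VAR_BOUNDARY,
            max_lag=config.max_lag,
        )
        control = ControlSpec(time_df_per_year=config.time_df_per_year)
        curves = []
        for s in observed:
            spec = CrossBasisSpec(
                centering_value=float(np.median(s.tmean)), **spec_proto
            )
            curves.append(fit_location(s, spec=spec, control=control))
        if out:
            fit_dir.mkdir(parents=True, exist_ok=True)
            for p, c in zip(curve_paths, curves):
                c.to_json(p)
    else:
        log.info("fit: outputs present, loading")
        curves = [ReducedCurve.from_json(p) for p in curve_paths]

    # ---- stage: pool -----------------------------------------------------
    pool_dir = out / "pool" if out else None
    blup_paths = (
        [pool_dir / f"blup_loc{i:03d}.json" for i in range(config.n_locations)]
        if out else []
    )
    pool_fresh = fit_fresh or out is None or not _stage_ready(blup_paths)
    if pool_fresh:
        log.info("pool: multivariate meta-regression (formula=%s)", config.formula)
        metafit = fit_meta_regression(
            curves, predictors=metadata, formula=config.formula,
            seed=_seed(config, 3),
        )
        blups = compute_blups(metafit, curves)
        if out:
            pool_dir.mkdir(parents=True, exist_ok=True)
            for p, b in zip(blup_paths, blups):
                b.to_json(p)
            with open(pool_dir / "metafit.json", "w") as fh:
                json.dump(
                    {
                        "schema": "tempmort.metafit.v1",
                        "fixed_coefs": metafit.fixed_coefs.tolist(),
                        "psi": metafit.psi.tolist(),
                        "gamma_vcov": metafit.gamma_vcov.tolist(),
                        "design_X": metafit.design.X.tolist(),
                        "design_names": metafit.design.names,
                        "location_ids": metafit.location_ids,
                        "loglik_reml": metafit.loglik_reml,
                        "converged": metafit.converged,
                    },
                    fh, indent=1,
                )
    else:
        log.info("pool: outputs present, loading")
        loaded = [ReducedCurve.from_json(p) for p in blup_paths]
        blups = [
            BlupCurve(**{f: getattr(c, f) for f in (
                "location_id", "theta", "V", "var_knots", "var_boundary",
                "centering_value", "temp_percentiles")})
            for c in loaded
        ]
        with open(pool_dir / "metafit.json") as fh:
            mf = json.load(fh)
        X = np.asarray(mf["design_X"], float)
        metafit = MetaFit(
            fixed_coefs=np.asarray(mf["fixed_coefs"], float),
            psi=np.asarray(mf["psi"], float),
            gamma_vcov=np.asarray(mf["gamma_vcov"], float),
            loglik_reml=float(mf["loglik_reml"]),
            design=MetaDesign(
                X=X, names=list(mf["design_names"]),
                center=np.zeros(X.shape[1]), spread=np.ones(X.shape[1]),
            ),
            location_ids=list(mf["location_ids"]),
            converged=bool(mf["converged"]),
            n_locations=X.shape[0],
            k=np.asarray(mf["psi"]).shape[0],
        )

    # ---- stage: project-inputs + attribute -------------------------------
    log.info("attribute: recalibration, MMT search and decadal attribution")
    att_dir = out / "attribute" if out else None
    mmts = {}
    results = []
    inputs_cache = {}
    for i, (s, blup) in enumerate(zip(observed, blups)):
        mmts[s.location_id] = find_mmt(blup, search_percentiles=config.mmt_percentiles)
        profile = baseline_mortality_profile(s)
        for rcp in rcp_list:
            for g in gcm_ids:
                _, recal = calibrate(modelled[(i, rcp, g)], s)
                inputs = build_projection_inputs(recal, profile)
                inputs_cache[(i, rcp, g)] = inputs
                results.extend(
                    attribution_by_decade(
                        inputs, blup, mmts[s.location_id], max_lag=config.max_lag
                    )
                )
    results_df = results_to_frame(results)
    agg = aggregate(
        results_df,
        grouping=config.grouping,
        reference_decade=config.reference_decade,
        location_groups=metadata,
    )

    # ---- stage: eCI ------------------------------------------------------
    if config.mc_samples >= 2:
        log.info("eci: %d joint coefficient draws", config.mc_samples)
        agg = attach_ecis(
            agg, metafit, curves, blups, mmts, inputs_cache, metadata, config
        )

    if out:
        att_dir.mkdir(parents=True, exist_ok=True)
        results_df.to_csv(att_dir / "results.csv", index=False)
        agg.to_csv(att_dir / "aggregates.csv", index=False)

    manifest = {
        "tempmort_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "master_seed": config.master_seed,
        "config_digest": config.digest(),
        "n_locations": config.n_locations,
        "rcps": rcp_list,
        "n_gcms": config.n_gcms,
        "stages": ["synth", "fit", "pool", "project-inputs", "attribute", "eci"],
    }
    if out:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return PipelineResult(
        config=config,
        truth=truth,
        observed=observed,
        metadata=metadata,
        curves=curves,
        blups=blups,
        mmts=mmts,
        results=results_df,
        aggregates=agg,
        manifest=manifest,
    )


def attach_ecis(
    agg: pd.DataFrame,
    metafit: MetaFit,
    curves: list[ReducedCurve],
    blups: list[BlupCurve],
    mmts: dict,
    inputs_cache: dict,
    metadata: pd.DataFrame,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Pooled (draw x GCM) eCIs for every aggregate row, plus net change.

    Curve coefficients are drawn jointly across locations (the shared
    fixed-effects error is one draw per sample) and paired across decades,
    GCMs and locations within a draw index; the net-change interval comes
    from the per-draw decadal difference, not from differencing the
    endpoint intervals.
    """
    rcp_list = sorted({k[1] for k in inputs_cache})
    gcm_ids = sorted({k[2] for k in inputs_cache})
    groups = metadata.set_index("location_id")[config.grouping]
    sampled = sample_blup_ensemble(
        [b.theta for b in blups],
        blup_joint_components(metafit, curves),
        metafit.gamma_vcov,
        S=config.mc_samples,
        seed=location_seed(config.master_seed, 0),
    )
    samples = dict(enumerate(sampled))

    # an_draws[(group, rcp, decade)] -> (S, G) totals; denom fixed per cell
    an_cells: dict = {}
    hot_cells: dict = {}
    cold_cells: dict = {}
    denom_cells: dict = {}
    for (i, rcp, g), inputs in inputs_cache.items():
        gi = gcm_ids.index(g)
        blup = blups[i]
        grp = groups.loc[inputs.location_id]
        labels, tot, hot, cld = decadal_an_draws(
            inputs, blup, mmts[inputs.location_id], samples[i],
            max_lag=config.max_lag,
        )
        years = inputs.dates.year.to_numpy()
        decades = (years // 10) * 10
        for d, lab in enumerate(labels):
            key = (grp, rcp, lab)
            S = tot.shape[1]
            if key not in an_cells:
                G = len(gcm_ids)
                an_cells[key] = np.zeros((S, G))
                hot_cells[key] = np.zeros((S, G))
                cold_cells[key] = np.zeros((S, G))
                denom_cells[key] = np.zeros(G)
            an_cells[key][:, gi] += tot[d]
            hot_cells[key][:, gi] += hot[d]
            cold_cells[key][:, gi] += cld[d]
            sel = decades == (int(lab[:4]))
            denom_cells[key][gi] += inputs.expected_deaths[sel].sum()

    rows = []
    for _, row in agg.iterrows():
        key = (row["grouping"], row["rcp_id"], row["decade"])
        ref_key = (row["grouping"], row["rcp_id"], config.reference_decade)
        af_draws = an_cells[key] / denom_cells[key]
        ci = empirical_ci(af_draws, point=row["af_total"])
        af_ref = an_cells[ref_key] / denom_cells[ref_key]
        net = empirical_ci(af_draws - af_ref, point=row["net_change"])
        heat_ci = empirical_ci(hot_cells[key] / denom_cells[key], point=row["af_heat"])
        cold_ci = empirical_ci(cold_cells[key] / denom_cells[key], point=row["af_cold"])
        rows.append(
            {
                "eci_low": ci.lower,
                "eci_high": ci.upper,
                "heat_eci_low": heat_ci.lower,
                "heat_eci_high": heat_ci.upper,
                "cold_eci_low": cold_ci.lower,
                "cold_eci_high": cold_ci.upper,
                "net_eci_low": net.lower,
                "net_eci_high": net.upper,
            }
        )
    return pd.concat([agg.reset_index(drop=True), pd.DataFrame(rows)], axis=1)
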