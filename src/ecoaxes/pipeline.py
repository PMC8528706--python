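"""End-to-end orchestration: flux table -> EFPs -> axes -> attribution.

Every tunable constant of the analysis lives on :class:`RunConfig` with the
field-standard default (200 W m-2 daytime cutoff, 24-h rain look-back, 30%
growing-season fraction, 5-day windows, 90th/95th percentiles, 15 degC
reference temperature); nothing is hard-coded downstream. ``run_site``
executes the per-site chain, ``run_study`` the multi-site chain, and both
are deterministic for a fixed configuration.
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

from . import axes as _axes
from . import causal as _causal
from . import efp as _efp
from . import importance as _importance
from .flux_io import SiteMeta
from .synthetic import COVARIATE_NAMES

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds, window lengths, quantiles, seeds and alpha levels."""

    # situational filters
    sw_in_min: float = 200.0         # W m-2, daytime cutoff
    rain_lookback_h: float = 24.0    # hours without precipitation
    gs_fraction: float = 0.30        # growing-season amplitude fraction
    night_sw: float = 20.0           # W m-2, night threshold
    qc_max_flag: int = 1
    min_coverage: float = 0.2
    # window fits
    window_days: int = 5
    min_points_day: int = 20
    min_points_night: int = 10
    # quantile levels
    q_gppsat: float = 0.90
    q_nepmax: float = 0.90
    q_etmax: float = 0.95
    q_gsmax: float = 0.90
    q_rbmax: float = 0.95
    # physics
    t_ref: float = 15.0              # degC
    sw_to_ppfd: float = 2.3          # W m-2 -> umol m-2 s-1
    default_ca: float = 400.0        # umol mol-1
    cswi_capacity: float = 5.0       # mm
    # resampling / models
    n_boot_dimensionality: int = 499
    n_boot_loadings: int = 999
    rf_trees: int = 1000
    icp_trees: int = 100
    alpha: float = 0.05
    seed: int = 0
    output_dir: str = "ecoaxes_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class StudyResult:
    """Aggregated outputs of the multi-site chain."""

    efp: pd.DataFrame
    axes: _axes.AxesResult | None = None
    importance: dict = field(default_factory=dict)      # PC name -> ImportanceResult
    anova: dict = field(default_factory=dict)           # PC name -> AnovaResult
    invariance: dict = field(default_factory=dict)      # PC name -> InvarianceResult
    causal_importance: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)
    skipped: dict = field(default_factory=dict)


def run_site(config: RunConfig, table: pd.DataFrame,
             meta: SiteMeta | None = None) -> _efp.EFPVector:
    """flux_io -> efp chain for one site; failures isolate to the site."""
    from .flux_io import apply_qc

    table = apply_qc(table, config.qc_max_flag)
    vec = _efp.compute_efp_vector(table, meta, config)
    frac = vec.diagnostics.get("dry_daytime_fraction")
    if frac is not None:
        logger.info("dry-daytime retention: %.1f%%", 100 * frac)
    return vec


def site_climate_covariates(table: pd.DataFrame,
                            config: RunConfig | None = None) -> dict:
    """Mean-annual climate covariates for the attribution stages.

    T_air and SW_in are all-data means, VPD the growing-season mean, P the
    mean annual total, CSWI the mean of the bucket index.
    """
    from .flux_io import compute_cswi, growing_season_mask, le_to_et

    cfg = config or RunConfig()
    out = {
        "T_air": float(table["t_air"].mean()),
        "SW_in": float(table["sw_in"].mean()),
    }
    daily_gpp = table["gpp"].resample("D").mean()
    try:
        gs = growing_season_mask(daily_gpp, fraction=cfg.gs_fraction)
        in_season = gs.for_index(table.index)
        out["VPD"] = float(table["vpd"][in_season].mean())
    except ValueError:
        out["VPD"] = float(table["vpd"].mean())
    if "precip" in table.columns:
        annual = table["precip"].fillna(0.0).resample("YS").sum()
        out["P"] = float(annual.mean())
        et = pd.Series(le_to_et(table["le"], table["t_air"]),
                       index=table.index).clip(lower=0).fillna(0.0)
        cswi = compute_cswi(table["precip"].fillna(0.0), et,
                            capacity=cfg.cswi_capacity)
        out["CSWI"] = float(cswi.mean())
    else:
        out["P"] = np.nan
        out["CSWI"] = np.nan
    return out


def covariates_from_meta(metas: list[SiteMeta]) -> pd.DataFrame:
    """Structure covariates (LAI_max, AGB, H_c, N%) from site metadata."""
    rows = {}
    for m in metas:
        rows[m.site_id] = {"LAI_max": m.lai_max, "AGB": m.agb,
                           "H_c": m.h_c, "N_pct": m.n_pct}
    return pd.DataFrame(rows).T


def run_study(config: RunConfig, tables: list[pd.DataFrame],
              metas: list[SiteMeta],
              covariates: pd.DataFrame | None = None,
              min_sites: int = 10) -> StudyResult:
    """EFP table -> PCA axes -> predictive importance -> causal screening.

    ``covariates`` (sites x 9) may be supplied directly (e.g. from an
    ensemble's ground truth); otherwise structure comes from the metadata and
    climate from the flux tables. Stages whose inputs are unavailable are
    skipped with a recorded reason.
    """
    vectors = {}
    for table, meta in zip(tables, metas):
        try:
            vectors[meta.site_id] = run_site(config, table, meta)
        except Exception as err:  # site failures must not kill the study
            logger.warning("site %s failed: %s", meta.site_id, err)
    efp_df = _efp.efp_table(vectors)
    result = StudyResult(efp=efp_df)

    # complete-case on the EFPs that were computable for most sites
    usable = efp_df.loc[:, efp_df.notna().mean() > 0.5]
    z = _axes.ztransform(usable)
    if len(z) < min_sites:
        raise ValueError(f"only {len(z)} complete-case sites; need >= {min_sites}")
    ax = _axes.run_pca(z)
    ax.n_significant_components = _axes.test_dimensionality(
        z, n_boot=config.n_boot_dimensionality, seed=config.seed)
    ncomp = max(ax.n_significant_components, 1)
    ax.significant_loadings = _axes.bootstrap_loadings(
        z, n_boot=config.n_boot_loadings, seed=config.seed,
        alpha=config.alpha, n_components=ncomp)
    result.axes = ax

    if covariates is None:
        struct = covariates_from_meta(metas)
        climate = pd.DataFrame(
            {m.site_id: site_climate_covariates(t, config)
             for t, m in zip(tables, metas)}).T
        covariates = struct.join(climate)
    covariates = covariates.reindex(columns=list(COVARIATE_NAMES))
    cov = covariates.reindex(z.index)

    complete = cov.dropna()
    for k in range(ncomp):
        pc = f"PC{k + 1}"
        y = ax.scores[pc].reindex(complete.index)
        try:
            result.importance[pc] = _importance.fit_rf_importance(
                complete, y, n_trees=config.rf_trees, seed=config.seed)
        except ValueError as err:
            result.skipped[f"importance:{pc}"] = str(err)
        pfts = pd.Series({m.site_id: m.pft for m in metas}).reindex(z.index)
        try:
            result.anova[pc] = _importance.anova_tukey(
                ax.scores[pc], pfts, alpha=config.alpha)
        except ValueError as err:
            result.skipped[f"anova:{pc}"] = str(err)
        try:
            env = _causal.assign_environments(metas).labels.reindex(complete.index)
            result.invariance[pc] = _causal.icp_search(
                complete, y, env.to_numpy(), alpha=config.alpha,
                seed=config.seed, n_trees=config.icp_trees)
            imp = result.importance.get(pc)
            if imp is not None:
                result.causal_importance[pc] = _causal.causal_importance(
                    imp.model, complete,
                    list(complete.columns) + ["structure", "climate"],
                    seed=config.seed)
        except (ValueError, KeyError) as err:
            result.skipped[f"causal:{pc}"] = str(err)

    result.manifest = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_sites_in": len(tables),
        "n_sites_complete": int(len(z)),
        "n_significant_components": ax.n_significant_components,
        "config": asdict(config),
    }
    return result


def write_study(result: StudyResult, outdir) -> None:
    """Write the study artifacts as CSV/JSON under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.efp.to_csv(out / "efp.csv")
    if result.axes is not None:
        ax = result.axes
        pd.DataFrame({"eigenvalue": ax.eigenvalues,
                      "explained_fraction": ax.explained_fraction}).to_csv(
            out / "eigenvalues.csv", index_label="component")
        ax.loadings.to_csv(out / "loadings.csv")
        ax.scores.to_csv(out / "scores.csv")
        ax.contributions.to_csv(out / "contributions.csv")
        if ax.significant_loadings is not None:
            ax.significant_loadings.to_csv(out / "significant_loadings.csv")
    for pc, imp in result.importance.items():
        pd.DataFrame({"pct_inc_mse": imp.importance,
                      "group": imp.groups}).to_csv(out / f"importance_{pc}.csv")
    for pc, ci in result.causal_importance.items():
        ci.to_csv(out / f"causal_importance_{pc}.csv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
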