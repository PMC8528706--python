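"""Synthetic half-hourly flux data with known ground truth.

Every downstream stage of the pipeline is testable by parameter recovery
against data produced here. The generator composes the same process forms the
estimators invert:

* shortwave radiation from solar geometry (declination + hour angle) with an
  AR(1) daily cloudiness factor; air temperature and VPD co-vary with
  radiation with a lag; precipitation is a clustered event process;
* GPP from a rectangular-hyperbola light response whose plateau follows a
  raised-cosine annual cycle; ecosystem respiration from the Lloyd–Taylor
  form with a basal rate tied to recent productivity; NEE = Reco - GPP;
* surface conductance from the Medlyn optimal-stomatal model, latent heat by
  forward Penman–Monteith with the same aerodynamic-conductance formula the
  estimation side uses, and sensible heat as the energy-balance residual
  (H + LE = Rn - G exactly in noiseless mode);
* optional multiplicative flux noise, standard deviation a fixed fraction
  (default 5%) of the flux value, truncated at -0.95 to keep fluxes physical.

Multi-site ensembles (:func:`simulate_ensemble`) add covariate -> EFP
structure for testing the PCA, variable-importance and invariance stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import efp as _efp
from .flux_io import SiteMeta

#: ratio of friction velocity to horizontal wind speed in generated drivers
USTAR_OVER_WIND = 0.15
#: share of evapotranspiration that is transpiration in the generated product
TRANSPIRATION_FRACTION = 0.65
#: day of year of peak growing season (northern hemisphere)
PEAK_DOY_NORTH = 200


@dataclass
class SiteTruth:
    """Generative parameters of one synthetic site (the recovery target)."""

    alpha: float = 0.05        # initial light-response slope, umol CO2 / umol photons
    beta_peak: float = 30.0    # peak GPP at infinite light, umol m-2 s-1
    seasonal_amp: float = 0.6  # relative seasonal amplitude of beta, 0..1
    rb15: float = 2.0          # basal respiration at 15 degC, umol m-2 s-1
    e0: float = 150.0          # temperature sensitivity, K
    g1: float = 3.0            # Medlyn stomatal slope, kPa^0.5
    ca: float = 400.0          # ambient CO2, umol mol-1
    noise_sd_frac: float = 0.05
    lat: float = 45.0          # degrees
    seed: int = 0
    # ensemble-level ground truth (filled by simulate_ensemble)
    efp_true: np.ndarray | None = None   # true 12-EFP vector (scenario units)
    latent: np.ndarray | None = None     # latent site factors
    covariates: dict | None = None       # covariate name -> value
    env: str | None = None               # environment label (icp_scm)

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta_peak > 0 and self.rb15 > 0
                and self.g1 > 0):
            raise ValueError("alpha, beta_peak, rb15 and g1 must be positive")
        if not 50.0 <= self.e0 <= 400.0:
            raise ValueError("e0 must lie in [50, 400] K")
        if self.noise_sd_frac < 0:
            raise ValueError("noise_sd_frac must be nonnegative")
        if not 0.0 <= self.seasonal_amp <= 1.0:
            raise ValueError("seasonal_amp must lie in [0, 1]")


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd / np.sqrt(1 - phi**2))
    eps = rng.normal(0.0, sd, n)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i]
    return x


def seasonal_weight(doy: np.ndarray, lat: float) -> np.ndarray:
    """Raised-cosine annual cycle in [0, 1], peaking mid-growing-season."""
    peak = PEAK_DOY_NORTH if lat >= 0 else PEAK_DOY_NORTH - 182
    return 0.5 * (1.0 + np.cos(2.0 * np.pi * (doy - peak) / 365.25))


def simulate_drivers(days: int, truth: SiteTruth,
                     start: str = "2001-01-01") -> pd.DataFrame:
    """Generate a half-hourly meteorological driver series.

    Deterministic for a fixed ``truth.seed``. Shortwave radiation follows
    solar geometry for ``truth.lat`` scaled by an AR(1) daily cloud factor;
    temperature and VPD co-vary with radiation (VPD lags temperature);
    precipitation is a clustered marked point process; u* = 0.15 u.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = np.random.default_rng(truth.seed)
    n = days * 48
    index = pd.date_range(start, periods=n, freq="30min", name="timestamp")
    doy = index.dayofyear.to_numpy(dtype=float)
    hour = index.hour.to_numpy() + index.minute.to_numpy() / 60.0

    # solar geometry
    lat_r = np.deg2rad(truth.lat)
    decl = np.deg2rad(23.45) * np.sin(2.0 * np.pi * (284.0 + doy) / 365.25)
    hang = np.deg2rad(15.0 * (hour - 12.0))
    cosz = np.sin(lat_r) * np.sin(decl) + np.cos(lat_r) * np.cos(decl) * np.cos(hang)
    cosz = np.clip(cosz, 0.0, None)
    cloud_daily = np.clip(0.75 + 0.2 * _ar1(rng, days, 0.6, 1.0), 0.25, 1.0)
    sw_in = 1000.0 * cosz * np.repeat(cloud_daily, 48)

    # temperature: seasonal mean + diurnal cycle lagging solar noon + AR noise
    seas = seasonal_weight(doy, truth.lat)
    t_mean = -2.0 + 20.0 * seas
    diurnal = 5.0 * np.sin(2.0 * np.pi * (hour - 9.0) / 24.0)
    t_air = t_mean + diurnal + _ar1(rng, n, 0.95, 0.5)

    # precipitation: clustered events (geometric spell length, exp depths)
    precip = np.zeros(n)
    wet = rng.random(n) < 0.004
    starts = np.flatnonzero(wet)
    for s in starts:
        length = rng.geometric(1.0 / 6.0)
        depth = rng.exponential(0.8, size=length)
        precip[s:s + length] += depth[: max(0, n - s)]

    # relative humidity: higher at night/after rain; VPD from Tetens
    rh = 0.85 - 0.012 * (t_air - 5.0) + 0.05 * _ar1(rng, n, 0.9, 0.5)
    wet_recent = pd.Series(precip > 0).rolling(12, min_periods=1).max().to_numpy()
    rh = np.clip(np.where(wet_recent > 0, rh + 0.1, rh), 0.2, 1.0)
    vpd_hpa = np.maximum(_efp.esat_kpa(t_air) * (1.0 - rh) * 10.0, 0.0)

    wind = np.maximum(2.5 + _ar1(rng, n, 0.9, 0.35), 0.3)
    ustar = USTAR_OVER_WIND * wind

    return pd.DataFrame(
        {"sw_in": sw_in, "t_air": t_air, "vpd": vpd_hpa, "precip": precip,
         "wind": wind, "ustar": ustar, "pressure": 101.325},
        index=index,
    )


def _beta_daily(index: pd.DatetimeIndex, truth: SiteTruth) -> np.ndarray:
    doy = index.dayofyear.to_numpy(dtype=float)
    w = seasonal_weight(doy, truth.lat)
    return truth.beta_peak * (1.0 - truth.seasonal_amp * (1.0 - w))


def simulate_fluxes(drivers: pd.DataFrame, truth: SiteTruth,
                    with_noise: bool = True,
                    return_internals: bool = False):
    """Forward-model half-hourly fluxes from drivers and a :class:`SiteTruth`.

    Returns a canonical flux table (QC flags all 0). With
    ``return_internals=True`` also returns a dict of noiseless internal
    series (true GPP, Reco, Gs, the daily basal-respiration series, the daily
    light-response plateau) for recovery tests.
    """
    idx = drivers.index
    if len(idx) >= 2:
        step = idx[1] - idx[0]
        if step != pd.Timedelta(minutes=30) or not idx.is_monotonic_increasing:
            raise ValueError("drivers must be on a strict 30-min cadence")
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 7]))

    q = _efp.SW_TO_PPFD * drivers["sw_in"].to_numpy()
    beta_d = _beta_daily(idx, truth)
    gpp = np.where(q > 0,
                   truth.alpha * q * beta_d / (truth.alpha * q + beta_d), 0.0)

    # basal respiration tracks recent productivity (7-day trailing mean GPP)
    gpp_daily = pd.Series(gpp, index=idx).resample("D").mean()
    g7 = gpp_daily.rolling(7, min_periods=1).mean()
    gbar = max(float(g7.mean()), 1e-9)
    rb_daily = truth.rb15 * (0.4 + 0.6 * g7 / gbar)
    rb_hh = rb_daily.reindex(idx.normalize()).to_numpy()
    t_air = drivers["t_air"].to_numpy()
    reco = _efp.lloyd_taylor(t_air, rb_hh, truth.e0)
    nee = reco - gpp

    # Medlyn surface conductance (VPD floored only inside 1/sqrt) and
    # forward Penman-Monteith with the true VPD
    vpd_kpa = drivers["vpd"].to_numpy() / 10.0
    vpd_medlyn = np.maximum(vpd_kpa, 0.05)
    pressure = drivers["pressure"].to_numpy()
    gs_mol = 1.6 * (1.0 + truth.g1 / np.sqrt(vpd_medlyn)) * gpp / truth.ca
    gs_ms = gs_mol / _efp.molar_air_density(t_air, pressure)
    ga = _efp.aerodynamic_conductance(drivers["wind"].to_numpy(),
                                      drivers["ustar"].to_numpy())
    rn = 0.85 * drivers["sw_in"].to_numpy() - 35.0
    g_soil = 0.1 * rn
    le = _efp.penman_monteith_le(gs_ms, ga, rn, g_soil, 0.0, vpd_kpa,
                                 t_air, pressure)
    h = rn - g_soil - le
    # transpiration product (TEA-like input column): fixed share of ET
    et_mm = np.maximum(le, 0.0) * 1800.0 / _efp.latent_heat_vaporization(t_air)
    transp = TRANSPIRATION_FRACTION * et_mm

    table = pd.DataFrame(
        {"nee": nee, "gpp": gpp, "le": le, "h": h,
         "t_air": t_air, "vpd": drivers["vpd"].to_numpy(),
         "sw_in": drivers["sw_in"].to_numpy(), "rn": rn, "g": g_soil,
         "s_storage": 0.0, "ustar": drivers["ustar"].to_numpy(),
         "wind": drivers["wind"].to_numpy(),
         "precip": drivers["precip"].to_numpy(),
         "co2": truth.ca, "pressure": pressure, "transpiration": transp},
        index=idx,
    )
    if with_noise and truth.noise_sd_frac > 0:
        for col in ("nee", "gpp", "le", "h"):
            eps = np.maximum(rng.normal(0.0, truth.noise_sd_frac, len(table)),
                             -0.95)
            table[col] = table[col].to_numpy() * (1.0 + eps)
    for col in ("nee", "gpp", "le", "h", "t_air", "vpd", "sw_in", "co2"):
        table[col + "_qc"] = 0

    if not return_internals:
        return table
    internals = {
        "gpp": pd.Series(gpp, index=idx), "reco": pd.Series(reco, index=idx),
        "gs_ms": pd.Series(gs_ms, index=idx), "ga": pd.Series(ga, index=idx),
        "le": pd.Series(le, index=idx),
        "rb_daily": rb_daily, "beta_daily": pd.Series(beta_d, index=idx),
    }
    return table, internals


def implied_efp_truths(drivers: pd.DataFrame, truth: SiteTruth) -> dict:
    """Generator-implied values of the recoverable functional properties.

    GPP_sat is the 90th percentile over days of the light-response curve at
    Q = 2000 with the day's plateau; Rb is the mean of the generated daily
    basal-respiration series; E0, G1 and the noise-free uWUE and EF are
    evaluated from the noiseless forward run under the same dry-daytime
    filter the estimators use.
    """
    from .flux_io import dry_daytime_filter, le_to_et

    table, internals = simulate_fluxes(drivers, truth, with_noise=False,
                                       return_internals=True)
    beta_day = internals["beta_daily"].resample("D").first().to_numpy()
    v_day = (truth.alpha * _efp.Q_SAT * beta_day
             / (truth.alpha * _efp.Q_SAT + beta_day))
    mask = dry_daytime_filter(table)
    et = pd.Series(le_to_et(table["le"], table["t_air"]), index=table.index)
    uwue = _efp.efp_uwue(table["gpp"], table["vpd"], et, mask)
    ef, ef_ampl = _efp.efp_ef(table["h"], table["le"], mask)
    return {
        "gpp_sat": float(np.quantile(v_day, 0.90)),
        "rb": float(internals["rb_daily"].mean()),
        "e0": truth.e0,
        "g1": truth.g1,
        "uwue": uwue,
        "ef": ef,
        "ef_ampl": ef_ampl,
    }


# ---------------------------------------------------------------------------
# multi-site ensembles
# ---------------------------------------------------------------------------

SCENARIOS = ("latent3", "rf_drivers", "icp_scm")

#: names and order of the nine climate/structure covariates
COVARIATE_NAMES = ("LAI_max", "AGB", "H_c", "N_pct",
                   "T_air", "VPD", "SW_in", "P", "CSWI")
STRUCTURE_COVARIATES = ("LAI_max", "AGB", "H_c", "N_pct")
CLIMATE_COVARIATES = ("T_air", "VPD", "SW_in", "P", "CSWI")

#: 12 x 3 mixing matrix of the latent3 scenario: each latent site factor
#: drives one block of four EFPs (productivity / water / respiration-WUE).
LATENT3_MIXING = np.zeros((12, 3))
LATENT3_MIXING[0:4, 0] = 1.0
LATENT3_MIXING[4:8, 1] = 0.9
LATENT3_MIXING[8:12, 2] = 0.8
#: independent noise s.d. per EFP, standardized units
LATENT3_NOISE_SD = 0.5

#: per-EFP physical location/scale used to map standardized truths to the
#: units of :data:`ecoaxes.efp.EFP_NAMES`
EFP_PHYS_LOC = np.array([20.0, 12.0, 0.25, 0.55, 0.15, 0.012,
                         2.5, 4.0, 0.55, 10.0, 3.0, 3.0])
EFP_PHYS_SCALE = np.array([5.0, 3.0, 0.05, 0.1, 0.04, 0.003,
                           0.6, 1.0, 0.1, 2.0, 0.8, 0.7])

#: linear effects of the rf_drivers scenario (standardized covariates ->
#: latent factor 1); all other covariates have exactly zero effect on it
RF_DRIVERS_EFFECTS = {"LAI_max": 1.2, "AGB": 0.9}

#: direct causal parents of the response in the icp_scm scenario
ICP_PARENTS = ("LAI_max", "T_air")

_E1_PREFIXES = ("US", "DE", "FR", "CN", "JP", "CA")   # N. America / Europe / Asia
_E2_PREFIXES = ("AU", "BR", "ZA", "AR", "NZ", "BW")   # Oceania / S. America / Africa
_FOREST_PFTS = ("ENF", "DBF", "EBF", "MF")
_NONFOREST_PFTS = ("GRA", "SAV", "OSH", "WET")


def _draw_covariates(rng: np.random.Generator, n: int,
                     shift: np.ndarray | None = None) -> pd.DataFrame:
    """Plausible site covariates; optional per-covariate mean shift."""
    x = pd.DataFrame({
        "LAI_max": rng.uniform(0.5, 7.0, n),
        "AGB": rng.lognormal(np.log(80.0), 0.6, n),
        "H_c": np.nan,
        "N_pct": rng.normal(2.0, 0.45, n),
        "T_air": rng.normal(10.0, 7.0, n),
        "VPD": rng.gamma(4.0, 2.0, n),
        "SW_in": rng.normal(180.0, 35.0, n),
        "P": rng.gamma(3.0, 250.0, n),
        "CSWI": np.nan,
    })
    x["H_c"] = 0.05 * x["AGB"] + rng.normal(0.0, 5.0, n) + 4.0
    x["CSWI"] = np.clip(0.004 * x["P"] - 0.15 * x["VPD"]
                        + rng.normal(0.0, 0.8, n), -10.0, 5.0)
    if shift is not None:
        x = x + pd.Series(shift, index=COVARIATE_NAMES)
    return x


def _truth_from_efp(efp_phys: np.ndarray, seed: int, lat: float) -> SiteTruth:
    """Map a physical 12-EFP vector back to forward-model parameters."""
    v = float(np.clip(efp_phys[0], 2.0, 95.0))      # gpp_sat at Q=2000
    alpha = 0.05
    beta = alpha * _efp.Q_SAT * v / (alpha * _efp.Q_SAT - v)
    return SiteTruth(
        alpha=alpha, beta_peak=float(beta), seasonal_amp=0.6,
        rb15=float(np.clip(efp_phys[6], 0.3, 10.0)),
        e0=150.0, g1=float(np.clip(efp_phys[10], 0.5, 12.0)),
        lat=lat, seed=seed,
    )


def simulate_ensemble(n_sites: int, scenario: str, seed: int,
                      days: int = 365):
    """Generate a multi-site ensemble with known covariate -> EFP structure.

    Scenarios
    ---------
    ``latent3``
        True EFP vectors are linear mixtures of 3 independent latent site
        factors plus independent noise (PCA recovery).
    ``rf_drivers``
        Nine site covariates are drawn and the latent factors are functions
        of a stated covariate subset (variable-importance recovery); factor 1
        depends on LAI_max and AGB only (:data:`RF_DRIVERS_EFFECTS`).
    ``icp_scm``
        Sites carry an environment label that shifts the covariate
        distribution but not the response mechanism (invariance testing);
        true parents are :data:`ICP_PARENTS`.

    Returns ``(tables, metas, truths)``; ensemble-level ground truth rides on
    the :class:`SiteTruth` records (``efp_true``, ``latent``, ``covariates``,
    ``env``).
    """
    if n_sites < 4:
        raise ValueError("n_sites must be >= 4")
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; valid: {SCENARIOS}")
    rng = np.random.default_rng(seed)
    truths: list[SiteTruth] = []
    metas: list[SiteMeta] = []

    if scenario == "latent3":
        z = rng.standard_normal((n_sites, 3))
        efp_std = z @ LATENT3_MIXING.T + rng.normal(
            0.0, LATENT3_NOISE_SD, (n_sites, 12))
        covs = _draw_covariates(rng, n_sites)
        envs = [None] * n_sites
        latents = z
    elif scenario == "rf_drivers":
        covs = _draw_covariates(rng, n_sites)
        zc = (covs - covs.mean()) / covs.std(ddof=0)
        f1 = sum(w * zc[k] for k, w in RF_DRIVERS_EFFECTS.items()) \
            + rng.normal(0.0, 0.35, n_sites)
        f2 = 1.0 * zc["T_air"] - 0.7 * zc["VPD"] + rng.normal(0.0, 0.4, n_sites)
        f3 = 0.8 * zc["CSWI"] + rng.normal(0.0, 0.4, n_sites)
        latents = np.column_stack([f1, f2, f3])
        efp_std = latents @ LATENT3_MIXING.T + rng.normal(
            0.0, LATENT3_NOISE_SD, (n_sites, 12))
        envs = [None] * n_sites
    else:  # icp_scm
        env_flag = (np.arange(n_sites) % 2).astype(float)   # balanced E1/E2
        n = n_sites
        covs = _draw_covariates(rng, n)
        # environment shifts the covariate distribution ...
        covs["LAI_max"] = rng.normal(3.0 + 1.5 * env_flag, 1.0)
        covs["T_air"] = rng.normal(8.0 + 6.0 * env_flag, 3.0)
        covs["VPD"] = rng.normal(8.0 + 4.0 * env_flag, 2.0)   # env child, not a parent
        # ... but not the response mechanism
        y = (0.9 * covs["LAI_max"].to_numpy()
             + 0.35 * covs["T_air"].to_numpy()
             + rng.normal(0.0, 0.8, n))
        # AGB is a child of the response and of env: never invariant
        covs["AGB"] = 20.0 * y + rng.normal(0.0, 30.0, n) + 40.0 * env_flag + 50.0
        latents = np.column_stack(
            [y, rng.standard_normal(n), rng.standard_normal(n)])
        yz = (y - y.mean()) / y.std(ddof=0)
        lz = latents.copy()
        lz[:, 0] = yz
        efp_std = lz @ LATENT3_MIXING.T + rng.normal(
            0.0, LATENT3_NOISE_SD, (n, 12))
        envs = ["E1" if e == 0 else "E2" for e in env_flag]

    site_seeds = rng.integers(0, 2**31 - 1, n_sites)
    for i in range(n_sites):
        efp_phys = EFP_PHYS_LOC + EFP_PHYS_SCALE * efp_std[i]
        lat = 45.0 if envs[i] != "E2" else -30.0
        truth = _truth_from_efp(efp_phys, int(site_seeds[i]), lat)
        truth = replace(
            truth, efp_true=efp_phys, latent=np.asarray(latents[i]),
            covariates={k: float(covs[k].iloc[i]) for k in COVARIATE_NAMES},
            env=envs[i],
        )
        truths.append(truth)
        if envs[i] == "E1":
            prefix = _E1_PREFIXES[i % len(_E1_PREFIXES)]
            pft = _FOREST_PFTS[i % len(_FOREST_PFTS)]
        elif envs[i] == "E2":
            if i % 2:
                prefix = _E2_PREFIXES[i % len(_E2_PREFIXES)]
                pft = (_FOREST_PFTS + _NONFOREST_PFTS)[i % 8]
            else:
                prefix = _E1_PREFIXES[i % len(_E1_PREFIXES)]
                pft = _NONFOREST_PFTS[i % len(_NONFOREST_PFTS)]
        else:
            prefix = (_E1_PREFIXES + _E2_PREFIXES)[i % 12]
            pft = (_FOREST_PFTS + _NONFOREST_PFTS)[i % 8]
        metas.append(SiteMeta(
            site_id=f"{prefix}-S{i:03d}", pft=pft, lat=truth.lat, lon=0.0,
            n_pct=float(covs["N_pct"].iloc[i]),
            lai_max=float(covs["LAI_max"].iloc[i]),
            h_c=float(covs["H_c"].iloc[i]),
            agb=float(covs["AGB"].iloc[i]),
        ))

    tables = []
    for truth in truths:
        drivers = simulate_drivers(days, truth)
        tables.append(simulate_fluxes(drivers, truth, with_noise=True))
    return tables, metas, truths


def true_efp_matrix(truths: list[SiteTruth],
                    metas: list[SiteMeta] | None = None) -> pd.DataFrame:
    """Stack the per-site true EFP vectors (physical units) into a DataFrame."""
    idx = [m.site_id for m in metas] if metas else None
    return pd.DataFrame([t.efp_true for t in truths], columns=_efp.EFP_NAMES,
                        index=idx)


def covariate_matrix(truths: list[SiteTruth],
                     metas: list[SiteMeta] | None = None) -> pd.DataFrame:
    """Stack the per-site generated covariates into a DataFrame."""
    idx = [m.site_id for m in metas] if metas else None
    return pd.DataFrame([t.covariates for t in truths],
                        columns=list(COVARIATE_NAMES), index=idx)


def write_truths(truths: list[SiteTruth], path) -> None:
    """Serialize site truths as a key=value sidecar (one block per site)."""
    with open(path, "w") as fh:
        for i, t in enumerate(truths):
            fh.write(f"[site {i}]\n")
            for key in ("alpha", "beta_peak", "seasonal_amp", "rb15", "e0",
                        "g1", "ca", "noise_sd_frac", "lat", "seed", "env"):
                fh.write(f"{key}={getattr(t, key)}\n")
            fh.write("\n")
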