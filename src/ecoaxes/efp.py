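"""Ecosystem functional properties (EFPs) from a filtered half-hourly flux table.

Twelve site-level scalars summarise carbon-uptake capacity (GPP_sat, NEP_max),
respiration (Rb, Rb_max, aCUE), water exchange (ET_max, EF, EF_ampl, Gs_max)
and water-use efficiency (uWUE, G1, WUE_t). Core physics:

* rectangular-hyperbola light response  GPP = alpha Q beta / (alpha Q + beta),
  fitted in 5-day moving windows and evaluated at saturating light
  Q = 2000 umol m-2 s-1;
* Lloyd–Taylor respiration  R = Rb exp(E0 (1/(Tref - T0) - 1/(T - T0))) with
  Tref = 15 degC, T0 = -46.02 degC, E0 fitted once per site from night-time
  NEE and Rb re-fitted daily in 5-day windows;
* surface conductance by inversion of the Penman–Monteith equation, with the
  empirical aerodynamic conductance G_a = 1/(u/u*^2 + 6.2 u*^-0.67);
* the Medlyn optimal-stomatal model  g_s = 1.6 (1 + G1/sqrt(VPD)) GPP/Ca for
  the stomatal slope G1.

All operations are deterministic: no random numbers are used anywhere in this
module. Unit conventions: VPD enters Penman–Monteith and the Medlyn fit in
kPa, and uWUE in hPa (as reported in flux products); conductances are m s-1
except where noted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .flux_io import (
    GrowingSeasonMask,
    SiteMeta,
    data_coverage_check,
    dry_daytime_filter,
    growing_season_mask,
    latent_heat_vaporization,
    le_to_et,
)

logger = logging.getLogger(__name__)

# physical constants
CP_AIR = 1004.834        # specific heat of air, J kg-1 K-1
EPS_MW = 0.622           # molecular weight ratio water vapour / dry air
RD = 287.058             # gas constant of dry air, J kg-1 K-1
RGAS = 8.31446           # universal gas constant, J mol-1 K-1
KELVIN = 273.15
T_REF = 15.0             # Lloyd-Taylor reference temperature, degC
T0_LLOYD = -46.02        # Lloyd-Taylor zero, degC
Q_SAT = 2000.0           # saturating PPFD, umol m-2 s-1
SW_TO_PPFD = 2.3         # W m-2 -> umol photons m-2 s-1 (0.5 PAR x 4.6)
NIGHT_SW = 20.0          # night threshold on SW_in, W m-2
UMOL_TO_GC = 12.011e-6   # umol CO2 -> g C


# ---------------------------------------------------------------------------
# psychrometrics and Penman-Monteith
# ---------------------------------------------------------------------------

@dataclass
class PsychrometricState:
    """Moist-air state used by Penman-Monteith (all SI except kPa pressures)."""

    delta: np.ndarray      # slope of saturation vapour-pressure curve, kPa K-1
    gamma: np.ndarray      # psychrometric constant, kPa K-1
    rho: np.ndarray        # air density, kg m-3
    cp: float              # specific heat of air, J K-1 kg-1
    lam: np.ndarray        # latent heat of vaporization, J kg-1


def esat_kpa(t_air):
    """Saturation vapour pressure (kPa), Tetens over water."""
    t = np.asarray(t_air, dtype=float)
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def psychrometric_state(t_air, pressure_kpa=101.325) -> PsychrometricState:
    t = np.asarray(t_air, dtype=float)
    p = np.asarray(pressure_kpa, dtype=float)
    lam = latent_heat_vaporization(t)
    delta = 4098.0 * esat_kpa(t) / (t + 237.3) ** 2
    gamma = CP_AIR * p / (EPS_MW * lam)
    rho = p * 1000.0 / (RD * (t + KELVIN))
    return PsychrometricState(delta=delta, gamma=gamma, rho=rho, cp=CP_AIR, lam=lam)


def aerodynamic_conductance(wind, ustar):
    """Empirical bulk aerodynamic conductance G_a = 1/(u/u*^2 + 6.2 u*^-0.67), m s-1."""
    u = np.asarray(wind, dtype=float)
    us = np.asarray(ustar, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ga = 1.0 / (u / us**2 + 6.2 * us**-0.67)
    return np.where((u > 0) & (us > 0), ga, np.nan)


def penman_monteith_le(gs, ga, rn, g, s, vpd_kpa, t_air, pressure_kpa=101.325):
    """Forward Penman-Monteith latent heat flux (W m-2).

    LE = (Delta (Rn - G - S) + rho Cp Ga VPD) / (Delta + gamma (1 + Ga/Gs)).
    Gs = 0 gives LE = 0 (fully closed surface).
    """
    st = psychrometric_state(t_air, pressure_kpa)
    gs = np.asarray(gs, dtype=float)
    ga = np.asarray(ga, dtype=float)
    avail = np.asarray(rn, dtype=float) - np.asarray(g, dtype=float) - np.asarray(s, dtype=float)
    num = st.delta * avail + st.rho * st.cp * ga * np.asarray(vpd_kpa, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        den = st.delta + st.gamma * (1.0 + ga / gs)
        le = num / den
    return np.where(gs > 0, le, 0.0)


def surface_conductance(le, ga, rn, g, s, vpd_kpa, t_air, pressure_kpa=101.325):
    """Surface conductance (m s-1) by inverting the Penman-Monteith equation.

    Gs = LE Ga gamma / (Delta (Rn - G - S) + rho Cp Ga VPD - LE (Delta + gamma)).
    Nonpositive denominators (unphysical inversions) yield NaN.
    """
    st = psychrometric_state(t_air, pressure_kpa)
    le = np.asarray(le, dtype=float)
    ga = np.asarray(ga, dtype=float)
    avail = np.asarray(rn, dtype=float) - np.asarray(g, dtype=float) - np.asarray(s, dtype=float)
    den = st.delta * avail + st.rho * st.cp * ga * np.asarray(vpd_kpa, dtype=float) - le * (st.delta + st.gamma)
    with np.errstate(divide="ignore", invalid="ignore"):
        gs = le * ga * st.gamma / den
    return np.where(den > 0, gs, np.nan)


def molar_air_density(t_air, pressure_kpa=101.325):
    """Molar density of air, mol m-3 (ideal gas)."""
    t = np.asarray(t_air, dtype=float)
    return np.asarray(pressure_kpa, dtype=float) * 1000.0 / (RGAS * (t + KELVIN))


# ---------------------------------------------------------------------------
# window fits
# ---------------------------------------------------------------------------

@dataclass
class WindowFit:
    """One moving-window parameter fit assigned at the window centre."""

    centre: pd.Timestamp
    params: dict
    rmse: float
    n: int


def _hyperbola(q, alpha, beta):
    return alpha * q * beta / (alpha * q + beta)


def lloyd_taylor(t_air, rb, e0, t_ref: float = T_REF, t0: float = T0_LLOYD):
    """Lloyd-Taylor respiration at temperature t_air (degC)."""
    t = np.asarray(t_air, dtype=float)
    return rb * np.exp(e0 * (1.0 / (t_ref - t0) - 1.0 / (t - t0)))


def fit_light_response_windows(gpp: pd.Series, ppfd: pd.Series,
                               window_days: int = 5,
                               min_points: int = 20) -> list[WindowFit]:
    """Fit GPP = alpha Q beta/(alpha Q + beta) in 5-day windows (stride 1 day).

    Daytime points only (Q > 0). Windows with fewer than ``min_points`` valid
    points, degenerate light-GPP relationships (no positive correlation, i.e.
    no usable curvature) or failed fits are skipped. Each fit stores the curve
    value at Q = 2000 as the window's GPP_sat.
    """
    df = pd.DataFrame({"gpp": gpp, "q": ppfd}).dropna()
    df = df[df["q"] > 0]
    fits: list[WindowFit] = []
    if df.empty:
        logger.warning("no daytime points for light-response fits")
        return fits
    days = df.index.normalize()
    half = pd.Timedelta(days=window_days / 2.0)
    for centre in pd.date_range(days.min(), days.max(), freq="D"):
        centre_mid = centre + pd.Timedelta(hours=12)
        win = df[(df.index >= centre_mid - half) & (df.index < centre_mid + half)]
        if len(win) < min_points:
            continue
        q = win["q"].to_numpy()
        y = win["gpp"].to_numpy()
        if y.std() < 1e-9:
            continue
        r = np.corrcoef(q, y)[0, 1]
        if not np.isfinite(r) or r <= 0.0:
            continue  # no curvature / light dependence to fit
        beta0 = max(float(np.quantile(y, 0.9)), 0.5)
        try:
            popt, _ = curve_fit(
                _hyperbola, q, y, p0=[0.05, beta0],
                bounds=([1e-6, 1e-2], [5.0, 500.0]), maxfev=2000,
            )
        except RuntimeError:
            continue
        alpha, beta = popt
        resid = y - _hyperbola(q, alpha, beta)
        fits.append(WindowFit(
            centre=centre,
            params={"alpha": alpha, "beta": beta,
                    "gpp_sat": _hyperbola(Q_SAT, alpha, beta)},
            rmse=float(np.sqrt(np.mean(resid**2))),
            n=len(win),
        ))
    if not fits:
        logger.warning("no fittable light-response windows")
    return fits


def efp_gppsat(fits: list[WindowFit], q: float = 0.90,
               min_windows: int = 10) -> float:
    """90th percentile of the window GPP_sat estimates."""
    vals = np.array([f.params["gpp_sat"] for f in fits], dtype=float)
    if len(vals) < min_windows:
        return np.nan
    return float(np.quantile(vals, q))


def efp_nepmax(nee: pd.Series, gs_mask: GrowingSeasonMask, q: float = 0.90) -> float:
    """90th percentile of half-hourly NEP = -NEE in the growing season."""
    in_season = gs_mask.for_index(nee.index)
    nep = -nee.to_numpy(dtype=float)[in_season]
    nep = nep[np.isfinite(nep)]
    if nep.size == 0:
        return np.nan
    return float(np.quantile(nep, q))


def fit_e0(resp_night: pd.Series, t_air: pd.Series,
           min_points: int = 100, min_trange: float = 5.0,
           bounds: tuple = (50.0, 400.0),
           min_points_day: int = 4) -> float:
    """Site-level temperature sensitivity E0 (K) from night-time NEE.

    Nonlinear least squares of NEE_night = Rb exp(E0 (1/(Tref-T0) - 1/(T-T0)))
    in which the basal rate Rb is free to differ between days (it tracks
    productivity and phenology) while E0 is shared. The fit is separable:
    for fixed E0 each day's optimal Rb has a closed form, so E0 minimises
    the concentrated sum of squares

        SSE(E0) = sum_d [ sum y^2 - (sum y f)^2 / sum f^2 ],
        f = exp(E0 (1/(Tref - T0) - 1/(T - T0))),

    over days with at least ``min_points_day`` night half-hours. A single
    whole-series (Rb, E0) fit would alias the seasonal Rb cycle into a
    biased E0. E0 is clipped to [50, 400] K as in night-time partitioning.
    """
    from scipy.optimize import minimize_scalar

    df = pd.DataFrame({"nee": resp_night, "t": t_air}).dropna()
    if len(df) < min_points:
        raise ValueError(f"need >= {min_points} night points, got {len(df)}")
    t_all = df["t"].to_numpy()
    if t_all.max() - t_all.min() < min_trange:
        raise ValueError("temperature range too small: E0 unidentifiable")

    day = df.index.normalize()
    counts = day.value_counts()
    keep = day.isin(counts[counts >= min_points_day].index)
    df = df[keep]
    if len(df) < min_points:
        raise ValueError("too few night points after per-day grouping")
    codes = pd.factorize(df.index.normalize())[0]
    t = df["t"].to_numpy()
    y = df["nee"].to_numpy()
    arrhenius_x = 1.0 / (T_REF - T0_LLOYD) - 1.0 / (t - T0_LLOYD)
    sum_y2 = np.bincount(codes, weights=y * y)

    def sse(e0: float) -> float:
        f = np.exp(e0 * arrhenius_x)
        syf = np.bincount(codes, weights=y * f)
        sff = np.bincount(codes, weights=f * f)
        return float(np.sum(sum_y2 - syf**2 / np.maximum(sff, 1e-300)))

    lo, hi = bounds[0] - 20.0, bounds[1] + 100.0
    res = minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    return float(np.clip(res.x, *bounds))


def fit_rb_daily(resp_night: pd.Series, t_air: pd.Series, e0: float,
                 window_days: int = 5, min_points: int = 10) -> list[WindowFit]:
    """Daily basal respiration Rb_d (at 15 degC) in 5-day windows, E0 fixed.

    With E0 fixed the window problem is linear in Rb_d and solved exactly:
    Rb_d = sum(NEE f) / sum(f^2) with f = exp(E0 (1/(Tref-T0) - 1/(T-T0))).
    """
    df = pd.DataFrame({"nee": resp_night, "t": t_air}).dropna()
    fits: list[WindowFit] = []
    if df.empty:
        return fits
    half = pd.Timedelta(days=window_days / 2.0)
    days = df.index.normalize()
    for centre in pd.date_range(days.min(), days.max(), freq="D"):
        centre_mid = centre + pd.Timedelta(hours=12)
        win = df[(df.index >= centre_mid - half) & (df.index < centre_mid + half)]
        if len(win) < min_points:
            continue
        f = lloyd_taylor(win["t"].to_numpy(), 1.0, e0)
        y = win["nee"].to_numpy()
        denom = float(np.sum(f * f))
        if denom <= 0:
            continue
        rb = max(float(np.sum(y * f) / denom), 0.0)
        resid = y - rb * f
        fits.append(WindowFit(centre=centre, params={"rb_d": rb},
                              rmse=float(np.sqrt(np.mean(resid**2))), n=len(win)))
    return fits


def rb_daily_series(fits: list[WindowFit]) -> pd.Series:
    return pd.Series({f.centre: f.params["rb_d"] for f in fits}, name="rb_d")


def efp_rb_stats(rb_d: pd.Series, q_max: float = 0.95,
                 min_days: int = 10) -> tuple[float, float]:
    """(Rb, Rb_max) = mean and 95th percentile of the daily basal respiration."""
    vals = rb_d.dropna().to_numpy(dtype=float)
    if vals.size < min_days:
        return np.nan, np.nan
    return float(vals.mean()), float(np.quantile(vals, q_max))


def efp_acue(gpp_daily: pd.Series, rb_d: pd.Series, gs_mask: GrowingSeasonMask,
             gpp_floor: float = 0.5) -> float:
    """Apparent carbon-use efficiency: median over in-season days of 1 - Rb_d/GPP_d.

    Days with daily GPP below ``gpp_floor`` (umol m-2 s-1) are excluded to
    avoid division blow-ups.
    """
    df = pd.DataFrame({"gpp": gpp_daily, "rb": rb_d}).dropna()
    if df.empty:
        return np.nan
    in_season = gs_mask.mask.reindex(df.index).fillna(False).to_numpy(dtype=bool)
    df = df[in_season & (df["gpp"].to_numpy() > gpp_floor)]
    if df.empty:
        return np.nan
    acue_d = 1.0 - df["rb"] / df["gpp"]
    return float(acue_d.median())


def efp_gsmax(gs: pd.Series, mask: pd.Series, q: float = 0.90,
              min_points: int = 50) -> float:
    """90th percentile of dry-daytime surface conductance (m s-1)."""
    vals = gs[mask.reindex(gs.index).fillna(False)].dropna().to_numpy(dtype=float)
    if vals.size < min_points:
        return np.nan
    return float(np.quantile(vals, q))


def fit_g1(gs: pd.Series, gpp: pd.Series, vpd_kpa: pd.Series, ca: pd.Series,
           t_air: pd.Series, pressure_kpa, mask: pd.Series,
           min_points: int = 100) -> float:
    """Medlyn stomatal slope G1 (kPa^0.5) from surface conductance and GPP.

    Least squares of  Gs_mol = 1.6 (1 + G1/sqrt(VPD)) GPP/Ca  over the
    dry-daytime mask, Gs converted from m s-1 to mol m-2 s-1 with the molar
    air density. The model is linear in G1, so the stated nonlinear regression
    has the exact solution  G1 = sum(x (y - b)) / sum(x^2)  with
    b = 1.6 GPP/Ca and x = b/sqrt(VPD). Returns G1 >= 0; NaN when
    unidentifiable (e.g. GPP identically 0).
    """
    df = pd.DataFrame({"gs": gs, "gpp": gpp, "vpd": vpd_kpa, "ca": ca,
                       "t": t_air}).dropna()
    df["p"] = (pressure_kpa.reindex(df.index)
               if isinstance(pressure_kpa, pd.Series)
               else float(np.asarray(pressure_kpa, dtype=float).ravel()[0]))
    df = df[mask.reindex(df.index).fillna(False)]
    df = df[(df["vpd"] > 0.05) & (df["gpp"] > 0) & (df["ca"] > 0)]
    if len(df) < min_points:
        return np.nan
    rho_mol = molar_air_density(df["t"].to_numpy(), df["p"].to_numpy())
    y = df["gs"].to_numpy() * rho_mol                       # mol m-2 s-1
    b = 1.6 * df["gpp"].to_numpy() / df["ca"].to_numpy()
    x = b / np.sqrt(df["vpd"].to_numpy())
    sxx = float(np.sum(x * x))
    if sxx <= 0:
        return np.nan
    g1 = float(np.sum(x * (y - b)) / sxx)
    return max(g1, 0.0)


def efp_uwue(gpp: pd.Series, vpd_hpa: pd.Series, et: pd.Series,
             mask: pd.Series) -> float:
    """Underlying water-use efficiency: median of GPP sqrt(VPD)/ET (VPD in hPa)."""
    df = pd.DataFrame({"gpp": gpp, "vpd": vpd_hpa, "et": et}).dropna()
    df = df[mask.reindex(df.index).fillna(False)]
    df = df[df["et"] > 0]
    if df.empty:
        return np.nan
    uwue = df["gpp"] * np.sqrt(df["vpd"]) / df["et"]
    return float(uwue.median())


def efp_wuet(gpp: pd.Series, transpiration: pd.Series | None) -> float:
    """Transpiration-based WUE: mean annual GPP (gC m-2 d-1) / mean annual T (kg m-2 d-1)."""
    if transpiration is None:
        return np.nan
    gpp_gc_day = float(gpp.mean()) * UMOL_TO_GC * 86400.0
    t_day = float(transpiration.mean()) * 48.0   # mm/30min -> mm/day == kg m-2 d-1
    if not np.isfinite(t_day) or t_day <= 0:
        return np.nan
    return gpp_gc_day / t_day


def efp_etmax(et: pd.Series, mask: pd.Series, q: float = 0.95,
              min_points: int = 50) -> float:
    """95th percentile of dry-daytime growing-season ET (mm / 30 min)."""
    vals = et[mask.reindex(et.index).fillna(False)].dropna().to_numpy(dtype=float)
    if vals.size < min_points:
        return np.nan
    return float(np.quantile(vals, q))


def efp_ef(h: pd.Series, le: pd.Series, mask: pd.Series,
           min_points_per_day: int = 3) -> tuple[float, float]:
    """Evaporative fraction and its amplitude from daily mean daytime EF.

    Per retained day EF_d = mean(LE)/(mean(H) + mean(LE)); days with
    nonpositive available energy are dropped. Returns (mean of EF_d,
    interquartile range of EF_d).
    """
    df = pd.DataFrame({"h": h, "le": le}).dropna()
    df = df[mask.reindex(df.index).fillna(False)]
    if df.empty:
        return np.nan, np.nan
    daily = df.resample("D").agg(["mean", "count"])
    enough = daily[("h", "count")] >= min_points_per_day
    h_d = daily[("h", "mean")][enough]
    le_d = daily[("le", "mean")][enough]
    denom = h_d + le_d
    ok = denom > 0
    ef_d = (le_d[ok] / denom[ok]).dropna()
    if ef_d.empty:
        return np.nan, np.nan
    q25, q75 = np.quantile(ef_d.to_numpy(), [0.25, 0.75])
    return float(ef_d.mean()), float(q75 - q25)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

EFP_NAMES = ("gpp_sat", "nep_max", "et_max", "ef", "ef_ampl", "gs_max",
             "rb", "rb_max", "acue", "uwue", "g1", "wue_t")


@dataclass
class EFPVector:
    """The twelve per-site ecosystem functional properties (NaN = missing)."""

    gpp_sat: float = np.nan   # umol m-2 s-1
    nep_max: float = np.nan   # umol m-2 s-1
    et_max: float = np.nan    # mm / 30 min
    ef: float = np.nan        # --
    ef_ampl: float = np.nan   # --
    gs_max: float = np.nan    # m s-1
    rb: float = np.nan        # umol m-2 s-1
    rb_max: float = np.nan    # umol m-2 s-1
    acue: float = np.nan      # --
    uwue: float = np.nan      # (umol m-2 s-1) hPa^0.5 / (mm / 30 min)
    g1: float = np.nan        # kPa^0.5
    wue_t: float = np.nan     # gC / kg H2O
    reasons: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def to_series(self) -> pd.Series:
        return pd.Series({k: getattr(self, k) for k in EFP_NAMES})


def compute_efp_vector(table: pd.DataFrame, meta: SiteMeta | None = None,
                       config=None) -> EFPVector:
    """Compute the full 12-component EFP vector for one site.

    Orchestrates the light-response, respiration, conductance and efficiency
    estimators with the shared growing-season and dry-daytime masks. Any
    component may come back missing; ``reasons`` records why, and
    ``diagnostics`` records window counts and filter retention fractions.
    """
    from .pipeline import RunConfig
    cfg = config or RunConfig()
    out = EFPVector()
    if len(table) == 0:
        out.reasons = {k: "empty table" for k in EFP_NAMES}
        return out

    cov = data_coverage_check(table, cfg.min_coverage)
    out.diagnostics["coverage"] = cov.fractions
    if not cov.passed:
        out.reasons = {k: f"coverage check failed: {cov.flagged}" for k in EFP_NAMES}
        return out

    pressure = (table["pressure"] if "pressure" in table.columns
                else pd.Series(101.325, index=table.index))
    ppfd = table["sw_in"] * cfg.sw_to_ppfd
    daily_gpp = table["gpp"].resample("D").mean()
    try:
        gs_mask = growing_season_mask(daily_gpp, fraction=cfg.gs_fraction)
    except ValueError as err:
        out.reasons = {k: str(err) for k in EFP_NAMES}
        return out
    mask = dry_daytime_filter(table, sw_min=cfg.sw_in_min,
                              lookback_hours=cfg.rain_lookback_h, gs_mask=gs_mask)
    out.diagnostics["dry_daytime_fraction"] = float(mask.mean())
    out.diagnostics["growing_season_days"] = int(gs_mask.mask.sum())

    et = pd.Series(le_to_et(table["le"], table["t_air"]), index=table.index)

    # --- carbon uptake
    lr_fits = fit_light_response_windows(table["gpp"], ppfd,
                                         window_days=cfg.window_days,
                                         min_points=cfg.min_points_day)
    out.diagnostics["n_light_windows"] = len(lr_fits)
    out.gpp_sat = efp_gppsat(lr_fits, q=cfg.q_gppsat)
    if np.isnan(out.gpp_sat):
        out.reasons["gpp_sat"] = "too few light-response windows"
    out.nep_max = efp_nepmax(table["nee"], gs_mask, q=cfg.q_nepmax)

    # --- respiration
    # Night-time partitioning convention: GPP == 0 at night in the flux
    # product, so NEE + GPP is the respiration proxy robust to twilight
    # half-hours with residual light.
    night = table["sw_in"] < cfg.night_sw
    nee_night = (table["nee"] + table["gpp"].fillna(0.0))[night]
    t_night = table["t_air"][night]
    rb_d = pd.Series(dtype=float)
    try:
        e0 = fit_e0(nee_night, t_night)
        rb_fits = fit_rb_daily(nee_night, t_night, e0,
                               window_days=cfg.window_days,
                               min_points=cfg.min_points_night)
        rb_d = rb_daily_series(rb_fits)
        out.rb, out.rb_max = efp_rb_stats(rb_d, q_max=cfg.q_rbmax)
        out.diagnostics["e0"] = e0
        out.diagnostics["n_rb_windows"] = len(rb_fits)
    except ValueError as err:
        out.reasons["rb"] = out.reasons["rb_max"] = str(err)
    out.acue = efp_acue(daily_gpp, rb_d, gs_mask)
    if np.isnan(out.acue):
        out.reasons.setdefault("acue", "no eligible days")

    # --- conductances and water-use efficiency
    ga = pd.Series(aerodynamic_conductance(table["wind"], table["ustar"]),
                   index=table.index)
    rn = table["rn"] if "rn" in table.columns else pd.Series(np.nan, index=table.index)
    g_soil = table["g"] if "g" in table.columns else pd.Series(0.0, index=table.index)
    s_sto = (table["s_storage"] if "s_storage" in table.columns
             else pd.Series(0.0, index=table.index))
    vpd_kpa = table["vpd"] / 10.0
    gs = pd.Series(
        surface_conductance(table["le"], ga, rn, g_soil.fillna(0.0),
                            s_sto.fillna(0.0), vpd_kpa, table["t_air"], pressure),
        index=table.index,
    )
    n_day = int((table["sw_in"] > cfg.sw_in_min).sum())
    if n_day:
        out.diagnostics["gs_invalid_fraction"] = float(
            gs[table["sw_in"] > cfg.sw_in_min].isna().mean())
    out.gs_max = efp_gsmax(gs, mask, q=cfg.q_gsmax)
    if np.isnan(out.gs_max):
        out.reasons["gs_max"] = "too few valid dry-daytime Gs values"

    ca = (table["co2"] if "co2" in table.columns and table["co2"].notna().any()
          else pd.Series(cfg.default_ca, index=table.index))
    out.g1 = fit_g1(gs, table["gpp"], vpd_kpa, ca, table["t_air"],
                    pressure, mask)
    if np.isnan(out.g1):
        out.reasons["g1"] = "G1 fit not identifiable (too few points or GPP=0)"

    out.uwue = efp_uwue(table["gpp"], table["vpd"], et, mask)
    out.et_max = efp_etmax(et, mask, q=cfg.q_etmax)
    out.ef, out.ef_ampl = efp_ef(table["h"], table["le"], mask)
    out.wue_t = efp_wuet(
        table["gpp"],
        table["transpiration"] if "transpiration" in table.columns else None)
    if np.isnan(out.wue_t):
        out.reasons.setdefault("wue_t", "transpiration (TEA output) not provided")
    return out


def efp_table(vectors: dict) -> pd.DataFrame:
    """Stack per-site EFP vectors into a tidy sites x 12 DataFrame."""
    return pd.DataFrame({sid: v.to_series() for sid, v in vectors.items()}).T
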