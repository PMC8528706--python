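"""Reading FLUXNET-dialect flux tables and the shared situational filters.

Half-hourly eddy-covariance data are held in a plain :class:`pandas.DataFrame`
("flux table") with a strictly increasing 30-min :class:`~pandas.DatetimeIndex`
and canonical column names:

====================  ======================================  =============
column                meaning                                 units
====================  ======================================  =============
``nee``               net ecosystem exchange                  umol m-2 s-1
``gpp``               gross primary productivity              umol m-2 s-1
``le``                latent heat flux                        W m-2
``h``                 sensible heat flux                      W m-2
``t_air``             air temperature                         degC
``vpd``               vapour pressure deficit                 hPa
``sw_in``             incoming shortwave radiation            W m-2
``rn``                net radiation (optional)                W m-2
``g``                 ground heat flux (optional)             W m-2
``s_storage``         energy storage term (optional)          W m-2
``ustar``             friction velocity                       m s-1
``wind``              horizontal wind speed                   m s-1
``precip``            precipitation (optional)                mm / 30 min
``co2``               ambient CO2 (optional)                  umol mol-1
``pressure``          air pressure (optional)                 kPa
``transpiration``     transpiration estimate (optional)       mm / 30 min
``<var>_qc``          quality flag (0 measured .. 3 poor)     --
====================  ======================================  =============

Missing values are NaN internally; the FLUXNET sentinel -9999 is mapped on
read and restored on write.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -9999.0

#: canonical name -> FLUXNET2015 column
FLUXNET2015_MAP = {
    "nee": "NEE_VUT_50",
    "gpp": "GPP_NT_VUT_50",
    "le": "LE",
    "h": "H",
    "t_air": "TA_F",
    "vpd": "VPD_F",
    "sw_in": "SW_IN_F",
    "rn": "NETRAD",
    "g": "G_F",
    "ustar": "USTAR",
    "wind": "WS",
    "precip": "P",
    "co2": "CO2_F_MDS",
    "pressure": "PA",
}

#: canonical name -> LaThuile column (dialect reconstructed from common usage;
#: only NEE and GPP_f are documented for this release)
LATHUILE_MAP = {
    "nee": "NEE",
    "gpp": "GPP_f",
    "le": "LE",
    "h": "H",
    "t_air": "Ta_f",
    "vpd": "VPD_f",
    "sw_in": "Rg_f",
    "rn": "Rn_f",
    "g": "G_f",
    "ustar": "ustar",
    "wind": "WS",
    "precip": "Precip",
    "co2": "CO2",
}

DIALECTS = {"fluxnet2015": FLUXNET2015_MAP, "lathuile": LATHUILE_MAP}

MANDATORY = ("nee", "gpp", "le", "h", "t_air", "vpd", "sw_in")

#: variables that carry a quality flag in the FLUXNET product
QC_VARS = ("nee", "gpp", "le", "h", "t_air", "vpd", "sw_in", "co2")

FOREST_PFTS = frozenset({"CSH", "DBF", "DNF", "EBF", "ENF", "GRA", "MF",
                         "OSH", "SAV", "WET"})


@dataclass
class SiteMeta:
    """Static site attributes (vegetation structure and location)."""

    site_id: str
    pft: str
    koppen: str = ""
    lat: float = np.nan
    lon: float = np.nan
    n_pct: float | None = None       # foliar N, gN 100 g-1
    lai_max: float | None = None     # m2 m-2
    h_c: float | None = None         # canopy height, m
    agb: float | None = None         # above-ground biomass, t DM ha-1

    def __post_init__(self) -> None:
        if self.pft not in FOREST_PFTS:
            raise ValueError(
                f"unknown PFT {self.pft!r}; expected one of {sorted(FOREST_PFTS)}"
            )


@dataclass
class GrowingSeasonMask:
    """Per-day in-season flag from the smoothed-GPP amplitude rule."""

    mask: pd.Series                  # bool, indexed by date
    threshold: float                 # umol m-2 s-1
    amplitude: float                 # umol m-2 s-1

    def for_index(self, index: pd.DatetimeIndex) -> np.ndarray:
        """Expand the daily mask to a half-hourly boolean array."""
        days = pd.DatetimeIndex(index.normalize())
        mapped = self.mask.reindex(days.unique())
        return mapped.reindex(days).to_numpy(dtype=bool, na_value=False)


def read_fluxnet_csv(path, dialect: str = "fluxnet2015") -> pd.DataFrame:
    """Read one site's half-hourly CSV into the canonical flux table.

    ``-9999`` is mapped to NaN; dialect column names are mapped to canonical
    ones; timestamps (``TIMESTAMP_START`` as YYYYMMDDHHMM) become the index.
    No unit conversion is performed.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(DIALECTS)}")
    colmap = DIALECTS[dialect]
    raw = pd.read_csv(path, na_values=[MISSING, int(MISSING), str(int(MISSING))],
                      float_precision="round_trip")

    ts_col = "TIMESTAMP_START" if "TIMESTAMP_START" in raw.columns else "TIMESTAMP"
    if ts_col not in raw.columns:
        raise ValueError("missing column: TIMESTAMP_START")
    idx = pd.to_datetime(raw[ts_col].astype("int64").astype(str), format="%Y%m%d%H%M")
    if idx.duplicated().any():
        raise ValueError("duplicate timestamps in input")

    out = pd.DataFrame(index=pd.DatetimeIndex(idx, name="timestamp"))
    inverse = {v: k for k, v in colmap.items()}
    for src, canon in inverse.items():
        if src in raw.columns:
            out[canon] = raw[src].to_numpy(dtype=float)
        qc_src = src + "_QC"
        if qc_src in raw.columns:
            out[canon + "_qc"] = raw[qc_src].to_numpy(dtype=float)
    for canon in MANDATORY:
        if canon not in out.columns:
            raise ValueError(f"missing column: {colmap[canon]} (canonical {canon!r})")
    if not out.index.is_monotonic_increasing:
        out = out.sort_index()
    return out


def write_fluxnet_csv(table: pd.DataFrame, path, dialect: str = "fluxnet2015") -> None:
    """Write a canonical flux table as a FLUXNET-dialect CSV (NaN -> -9999)."""
    colmap = DIALECTS[dialect]
    out = pd.DataFrame()
    start = table.index
    out["TIMESTAMP_START"] = start.strftime("%Y%m%d%H%M")
    out["TIMESTAMP_END"] = (start + pd.Timedelta(minutes=30)).strftime("%Y%m%d%H%M")
    for canon, src in colmap.items():
        if canon in table.columns:
            out[src] = table[canon].to_numpy(dtype=float)
            qc = canon + "_qc"
            if qc in table.columns:
                out[src + "_QC"] = table[qc].to_numpy(dtype=float)
    out = out.fillna(MISSING)
    out.to_csv(path, index=False)


def apply_qc(table: pd.DataFrame, max_flag: int = 1) -> pd.DataFrame:
    """Mask values whose quality flag exceeds ``max_flag``.

    The FLUXNET convention keeps flag 0 (measured) and 1 (good-quality
    gap-filled). Variables without a flag column pass through unchanged.
    """
    out = table.copy()
    for var in QC_VARS:
        qc = var + "_qc"
        if var in out.columns and qc in out.columns:
            bad = out[qc].to_numpy() > max_flag
            if bad.any():
                col = out[var].to_numpy(dtype=float).copy()
                col[bad] = np.nan
                out[var] = col
        elif var in out.columns:
            logger.debug("no QC flag for %s; values pass through", var)
    return out


def latent_heat_vaporization(t_air):
    """Latent heat of vaporization lambda(T) in J kg-1 (linear in degC)."""
    return (2.501 - 0.00237 * np.asarray(t_air, dtype=float)) * 1e6


def le_to_et(le, t_air):
    """Convert latent heat flux (W m-2) to evapotranspiration (mm / 30 min)."""
    return np.asarray(le, dtype=float) * 1800.0 / latent_heat_vaporization(t_air)


def growing_season_mask(daily_gpp: pd.Series, fraction: float = 0.30,
                        smooth_days: int = 15,
                        min_amplitude: float = 0.1) -> GrowingSeasonMask:
    """Growing-season rule: smoothed daily GPP above 30% of its amplitude.

    The amplitude is q95 - q05 of the 15-day-smoothed daily GPP (robust to
    spikes). If the amplitude is below ``min_amplitude`` the seasonal cycle is
    considered flat and every day is in season.
    """
    daily_gpp = daily_gpp.dropna()
    if len(daily_gpp) < 30:
        raise ValueError("growing-season mask needs >= 30 valid days")
    smoothed = daily_gpp.rolling(smooth_days, center=True, min_periods=1).mean()
    q05, q95 = np.nanquantile(smoothed.to_numpy(), [0.05, 0.95])
    amplitude = q95 - q05
    if amplitude < min_amplitude:
        mask = pd.Series(True, index=daily_gpp.index)
        return GrowingSeasonMask(mask, threshold=q05, amplitude=amplitude)
    threshold = q05 + fraction * amplitude
    mask = smoothed > threshold
    return GrowingSeasonMask(mask, threshold=threshold, amplitude=amplitude)


def dry_daytime_filter(table: pd.DataFrame, sw_min: float = 200.0,
                       lookback_hours: float = 24.0,
                       gs_mask: GrowingSeasonMask | None = None) -> pd.Series:
    """Shared situational filter for G1, uWUE, Gs, ET_max and EF.

    A half-hour is retained iff SW_in > 200 W m-2, no precipitation fell in
    the trailing 24 h (including the current half-hour; filter disabled with a
    warning when no precipitation column exists), and its day is in the
    growing season.
    """
    if gs_mask is None:
        daily_gpp = table["gpp"].resample("D").mean()
        gs_mask = growing_season_mask(daily_gpp)
    keep = table["sw_in"].to_numpy(dtype=float) > sw_min

    if "precip" in table.columns:
        p = table["precip"].fillna(0.0).to_numpy(dtype=float)
        wet = p > 0
        nback = int(round(lookback_hours * 2))
        wet_recent = (
            pd.Series(wet, index=table.index)
            .rolling(nback, min_periods=1).max()
            .shift(1).fillna(0.0).to_numpy() > 0
        )
        keep &= ~wet & ~wet_recent
    else:
        warnings.warn("no precipitation column; rain filter disabled", stacklevel=2)

    keep &= gs_mask.for_index(table.index)
    return pd.Series(keep, index=table.index, name="dry_daytime")


def compute_cswi(precip: pd.Series, et: pd.Series, capacity: float = 5.0) -> pd.Series:
    """Cumulative soil water index: capped bucket CSWI_t = min(cap, CSWI_{t-1} + P - ET).

    A stand-in bucket recursion (water balance with an upper cap, initialised
    full); monotone non-increasing under zero precipitation.
    """
    if capacity < 0:
        raise ValueError("capacity must be nonnegative")
    p = np.nan_to_num(np.asarray(precip, dtype=float))
    e = np.nan_to_num(np.asarray(et, dtype=float))
    out = np.empty(len(p))
    state = capacity
    for i in range(len(p)):
        state = min(capacity, state + p[i] - e[i])
        out[i] = state
    return pd.Series(out, index=precip.index, name="cswi")


@dataclass
class CoverageReport:
    fractions: dict = field(default_factory=dict)
    flagged: list = field(default_factory=list)
    min_fraction: float = 0.2

    @property
    def passed(self) -> bool:
        return not self.flagged


def data_coverage_check(table: pd.DataFrame, min_fraction: float = 0.2) -> CoverageReport:
    """Fraction of good-quality (non-missing) half-hours per mandatory variable."""
    rep = CoverageReport(min_fraction=min_fraction)
    n = len(table)
    for var in MANDATORY:
        frac = 0.0 if n == 0 else float(table[var].notna().mean())
        rep.fractions[var] = frac
        if frac < min_fraction:
            rep.flagged.append(var)
    return rep
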