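"""Scalar and field metrics for model-model and model-data comparison.

Includes the RMSE misfit used against gridded fixation climatologies, the
upper-decile bloom-intensity statistic, the chlorophyll conversion and the
oligotrophic-area fraction, the exponential-decay fit, and the analytic
niche-closure timescale relating the excess-P inventory to the global
fixation rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import MOLAR_MASS_C, MOLAR_MASS_N, IntegrationResult
from .geometry import BoxGeometry
from .params import EcosystemParams
from .state import I_PD, I_PO


# ---------------------------------------------------------------------------
# gridded fields
# ---------------------------------------------------------------------------

@dataclass
class GriddedField:
    """Values on a (box) or (lat, lon) grid with units, mask and cell areas.

    ``mask`` is True on valid cells; metrics honour it.  Units strings are
    compared literally: combining two fields with different units raises.
    """

    values: np.ndarray
    units: str
    area: Optional[np.ndarray] = None     # m^2 per cell
    mask: Optional[np.ndarray] = None     # True = valid
    lat: Optional[np.ndarray] = None
    lon: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.units:
            raise ValueError("units attribute is mandatory")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values")
        if self.area is not None:
            self.area = np.asarray(self.area, dtype=float)
            if self.area.shape != self.values.shape:
                raise ValueError("area shape must match values")

    def to_dataarray(self):
        """Convert to an :class:`xarray.DataArray` with a units attribute."""
        import xarray as xr

        dims = ("lat", "lon") if self.values.ndim == 2 else ("cell",)
        coords = {}
        if self.lat is not None and self.values.ndim == 2:
            coords["lat"] = self.lat
        if self.lon is not None and self.values.ndim == 2:
            coords["lon"] = self.lon
        da = xr.DataArray(self.values, dims=dims, coords=coords,
                          attrs={"units": self.units})
        return da


def _joint_mask(model: GriddedField, obs: GriddedField) -> np.ndarray:
    if model.units != obs.units:
        raise ValueError(
            f"units mismatch: {model.units!r} vs {obs.units!r}; convert first"
        )
    if model.values.shape != obs.values.shape:
        raise ValueError("fields must be on congruent grids; regrid first")
    joint = model.mask & obs.mask
    if not joint.any():
        raise ValueError("joint validity mask is empty")
    return joint


def rmse_misfit(model: GriddedField, obs: GriddedField,
                area_weighted: bool = False) -> float:
    """Root-mean-square difference over jointly valid cells (obs units).

    Unweighted by default; ``area_weighted=True`` weights by cell area.
    """
    joint = _joint_mask(model, obs)
    diff2 = (model.values - obs.values)[joint] ** 2
    if area_weighted:
        if model.area is None:
            raise ValueError("area-weighted RMSE requires cell areas")
        w = model.area[joint]
        return float(np.sqrt((diff2 * w).sum() / w.sum()))
    return float(np.sqrt(diff2.mean()))


def bloom_intensity_p90(field: GriddedField, method: str = "percentile") -> float:
    """Bloom-intensity measure: the upper decile of positive valid values.

    ``method='percentile'`` (default) returns the 90th percentile with
    linear interpolation; ``method='top_decile_mean'`` the mean of the top
    10% of values.
    """
    vals = field.values[field.mask]
    vals = vals[vals > 0]
    if vals.size == 0:
        raise ValueError("field has no positive values")
    if method == "percentile":
        return float(np.percentile(vals, 90))
    if method == "top_decile_mean":
        cut = np.percentile(vals, 90)
        return float(vals[vals >= cut].mean())
    raise ValueError(f"unknown method {method!r}")


def chlorophyll_field(P_O, P_D, chl_per_N: float = 1.59, area=None,
                      mask=None) -> GriddedField:
    """Surface chlorophyll from phytoplankton nitrogen biomass.

    ``chl = chl_per_N * (P_O + P_D)`` with the default conversion of
    1.59 mg Chl a per mmol N.
    """
    P_O = np.asarray(P_O, dtype=float)
    P_D = np.asarray(P_D, dtype=float)
    if np.any(P_O < 0) or np.any(P_D < 0):
        raise ValueError("biomass must be non-negative")
    return GriddedField(values=chl_per_N * (P_O + P_D),
                        units="mg Chl a m-3", area=area, mask=mask)


def oligotrophic_area_fraction(chl: GriddedField, threshold: float = 0.07) -> float:
    """Area-weighted fraction of valid ocean with chl below ``threshold``.

    The default threshold, 0.07 mg Chl a m⁻³ at the surface, is the standard
    delimiter of the oligotrophic gyres.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if chl.area is None:
        raise ValueError("oligotrophic area fraction requires cell areas")
    m = chl.mask
    total = chl.area[m].sum()
    low = chl.area[m & (chl.values < threshold)].sum()
    return float(low / total)


# ---------------------------------------------------------------------------
# time-series fits and analytic timescales
# ---------------------------------------------------------------------------

@dataclass
class DecayFit:
    """Log-linear exponential-decay fit."""

    tau_years: float        # e-folding time (inf for a flat series)
    r_squared: float
    slope: float            # d ln(series) / dt, yr^-1

    @property
    def is_decay(self) -> bool:
        return self.slope < 0


def fit_exponential_decay_timescale(series, t) -> DecayFit:
    """Fit ``series ~ exp(-t/tau)`` by least squares on the logarithm.

    Requires at least 10 strictly positive points; a zero slope yields an
    infinite timescale.
    """
    series = np.asarray(series, dtype=float)
    t = np.asarray(t, dtype=float)
    if series.shape != t.shape or series.ndim != 1:
        raise ValueError("series and t must be 1-D arrays of equal length")
    if series.size < 10:
        raise ValueError("need at least 10 points")
    if np.any(series <= 0):
        raise ValueError("series must be strictly positive")
    logy = np.log(series)
    if np.ptp(logy) == 0.0:          # flat series: infinite timescale
        return DecayFit(tau_years=math.inf, r_squared=1.0, slope=0.0)
    slope, intercept = np.polyfit(t, logy, 1)
    pred = slope * t + intercept
    ss_res = ((logy - pred) ** 2).sum()
    ss_tot = ((logy - logy.mean()) ** 2).sum()
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    tau = math.inf if slope == 0 else -1.0 / slope
    return DecayFit(tau_years=float(tau), r_squared=float(r2), slope=float(slope))


def niche_closure_timescale(excess_inventory_Pmol_N: float,
                            fixation_TgN_per_yr: float) -> float:
    """Years needed for fixation to erase the excess-P nitrogen deficit.

    ``tau = inventory / rate`` with the inventory given in Pmol of nitrogen
    equivalents (converted at 14 g mol⁻¹ to Tg N) and the rate in Tg N yr⁻¹.
    """
    if excess_inventory_Pmol_N < 0:
        raise ValueError("excess inventory must be non-negative")
    if fixation_TgN_per_yr <= 0:
        raise ValueError("fixation rate must be strictly positive")
    inventory_TgN = excess_inventory_Pmol_N * 1.0e15 * MOLAR_MASS_N / 1.0e12
    return inventory_TgN / fixation_TgN_per_yr


# ---------------------------------------------------------------------------
# global diagnostic series from a run
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticsSeries:
    """Annual global diagnostics of an integration.

    Fixation and denitrification in Tg N yr⁻¹, diazotroph biomass (upper
    100 m) in Tg C, the biomass-to-fixation ratio in Tg C per (Tg N yr⁻¹)
    (NaN where fixation vanishes), and the oligotrophic area fraction.
    """

    year: np.ndarray
    fixation_TgN: np.ndarray
    biomass_TgC: np.ndarray
    oligotrophic_fraction: np.ndarray
    denit_TgN: np.ndarray
    denit_by_box: np.ndarray          # (nyears, n_col)
    fixation_by_box: np.ndarray       # (nyears, n_col), Tg N yr^-1
    biomass_by_box: np.ndarray        # (nyears, n_col), Tg C

    @property
    def ratio_TgC_per_TgN_yr(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.fixation_TgN > 0,
                            self.biomass_TgC / self.fixation_TgN, np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "year": self.year,
            "fixation_TgN_yr": self.fixation_TgN,
            "diazotroph_biomass_TgC": self.biomass_TgC,
            "biomass_to_fixation_ratio": self.ratio_TgC_per_TgN_yr,
            "oligotrophic_area_fraction": self.oligotrophic_fraction,
            "denitrification_TgN_yr": self.denit_TgN,
        })


def global_series(result: IntegrationResult, geometry: BoxGeometry,
                  params: EcosystemParams) -> DiagnosticsSeries:
    """Reduce an integration to annual global diagnostics."""
    area = geometry.area
    vs = area * geometry.h_surface       # surface volumes, m^3
    vd = area * geometry.h_deep
    # volumetric mmol m^-3 d^-1 -> Tg N yr^-1
    to_TgN = 1.0e-3 * 365.0 * MOLAR_MASS_N / 1.0e12
    fix_box = result.fixation * vs[None, :] * to_TgN
    den_box = result.denit * vd[None, :] * to_TgN
    pd_surf = result.traj[:, :, 0, I_PD]                  # mmol N m^-3
    biomass_box = (pd_surf * vs[None, :] * 1.0e-3
                   * params.r_CN * MOLAR_MASS_C / 1.0e12)  # Tg C
    chl = params.chl_per_N * (result.traj[:, :, 0, I_PO]
                              + result.traj[:, :, 0, I_PD])
    oligo = ((chl < 0.07) * area[None, :]).sum(axis=1) / area.sum()
    return DiagnosticsSeries(
        year=result.years,
        fixation_TgN=fix_box.sum(axis=1),
        biomass_TgC=biomass_box.sum(axis=1),
        oligotrophic_fraction=oligo,
        denit_TgN=den_box.sum(axis=1),
        denit_by_box=den_box,
        fixation_by_box=fix_box,
        biomass_by_box=biomass_box,
    )
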