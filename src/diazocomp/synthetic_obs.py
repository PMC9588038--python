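"""Synthetic observation-like fields with known ground truth.

Real climatologies of N2 fixation and depth-integrated diazotroph biomass
are patchy, positively skewed, strongly zero-inflated and confined to warm
waters, and the point observations behind them are sparse and anecdotal.
This module generates fields with exactly that character — a sum of Gaussian
hotspots under multiplicative lognormal noise, hard-zeroed outside a warm
latitude band and thinned by a random absence mask — so that every
diagnostic can be exercised against a known truth without external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .diagnostics import GriddedField

EARTH_RADIUS_M = 6.371e6


@dataclass
class ObsGenSpec:
    """Generator settings for one observation-like field."""

    nlat: int = 90                    # 2-degree grid by default
    nlon: int = 180
    n_hotspots: int = 25
    hotspot_scale_deg: float = 12.0   # Gaussian length scale
    hotspot_amplitude: float = 60.0   # median peak value, field units
    lognormal_sigma: float = 0.6      # multiplicative noise strength
    zero_fraction: float = 0.35       # random absences inside the warm band
    warm_band_lat: float = 40.0       # habitat edge (temperature constraint)
    n_samples: int = 200
    units: str = "mmol N m-2 yr-1"
    seed: int = 12345

    def __post_init__(self) -> None:
        if self.nlat <= 0 or self.nlon <= 0 or self.n_hotspots < 0:
            raise ValueError("grid sizes and hotspot count must be non-negative")
        if self.lognormal_sigma < 0 or self.hotspot_scale_deg <= 0:
            raise ValueError("sigma must be >= 0 and the length scale positive")
        if not 0.0 <= self.zero_fraction <= 1.0:
            raise ValueError("zero_fraction must lie in [0, 1]")
        if self.n_samples < 0:
            raise ValueError("n_samples must be non-negative")


def _grid(spec: ObsGenSpec) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    lat = -90.0 + (np.arange(spec.nlat) + 0.5) * 180.0 / spec.nlat
    lon = -180.0 + (np.arange(spec.nlon) + 0.5) * 360.0 / spec.nlon
    dlat = np.deg2rad(180.0 / spec.nlat)
    dlon = np.deg2rad(360.0 / spec.nlon)
    area = (EARTH_RADIUS_M ** 2 * dlat * dlon
            * np.cos(np.deg2rad(lat)))[:, None] * np.ones((1, spec.nlon))
    return lat, lon, area


def generate_obs_field(spec: ObsGenSpec,
                       seed: Optional[int] = None
                       ) -> Tuple[GriddedField, GriddedField]:
    """Generate ``(noisy, truth)`` fields, deterministic per seed.

    The truth is the hotspot sum with the warm-band and absence masks
    applied; the noisy field multiplies it by mean-one lognormal noise.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    lat, lon, area = _grid(spec)
    lat2, lon2 = np.meshgrid(lat, lon, indexing="ij")

    truth = np.zeros((spec.nlat, spec.nlon))
    centers_lat = rng.uniform(-spec.warm_band_lat, spec.warm_band_lat,
                              spec.n_hotspots)
    centers_lon = rng.uniform(-180.0, 180.0, spec.n_hotspots)
    amps = spec.hotspot_amplitude * rng.lognormal(0.0, 0.5, spec.n_hotspots)
    s2 = 2.0 * spec.hotspot_scale_deg ** 2
    for clat, clon, amp in zip(centers_lat, centers_lon, amps):
        dlon = np.abs(lon2 - clon)
        dlon = np.minimum(dlon, 360.0 - dlon)           # wrap in longitude
        truth += amp * np.exp(-((lat2 - clat) ** 2 + dlon ** 2) / s2)

    band = np.abs(lat2) <= spec.warm_band_lat
    truth = np.where(band, truth, 0.0)
    if spec.zero_fraction > 0:
        absent = band & (rng.random(truth.shape) < spec.zero_fraction)
        truth = np.where(absent, 0.0, truth)

    sigma = spec.lognormal_sigma
    if sigma > 0:
        noise = rng.lognormal(-0.5 * sigma ** 2, sigma, truth.shape)
        noisy = truth * noise
    else:
        noisy = truth.copy()

    mask = np.ones_like(truth, dtype=bool)
    kw = dict(units=spec.units, area=area, mask=mask, lat=lat, lon=lon)
    return (GriddedField(values=noisy, **kw), GriddedField(values=truth, **kw))


def sample_sparse_points(field: GriddedField, n: int,
                         seed: int = 0) -> pd.DataFrame:
    """Draw ``n`` cells uniformly without replacement from the valid mask.

    Returns a table of (lat, lon, value) mimicking anecdotal point sampling.
    """
    if field.lat is None or field.lon is None:
        raise ValueError("field must carry lat/lon coordinates")
    valid = np.argwhere(field.mask)
    if n > len(valid):
        raise ValueError(f"requested {n} samples but only {len(valid)} "
                         "valid cells exist")
    rng = np.random.default_rng(seed)
    picks = valid[rng.choice(len(valid), size=n, replace=False)]
    return pd.DataFrame({
        "lat": field.lat[picks[:, 0]],
        "lon": field.lon[picks[:, 1]],
        "value": field.values[picks[:, 0], picks[:, 1]],
    })


def regrid_to_model(points: pd.DataFrame, template: GriddedField,
                    ) -> GriddedField:
    """Bin point samples onto the template grid by cell-mean aggregation.

    Points outside the grid are dropped (their count is recorded in the
    returned field via the ``n_dropped`` attribute); empty cells are masked
    invalid.
    """
    if len(points) < 1:
        raise ValueError("need at least one point")
    if template.lat is None or template.lon is None:
        raise ValueError("template must carry lat/lon coordinates")
    lat, lon = template.lat, template.lon
    lat_edges = np.concatenate([[lat[0] - (lat[1] - lat[0]) / 2],
                                (lat[:-1] + lat[1:]) / 2,
                                [lat[-1] + (lat[-1] - lat[-2]) / 2]])
    lon_edges = np.concatenate([[lon[0] - (lon[1] - lon[0]) / 2],
                                (lon[:-1] + lon[1:]) / 2,
                                [lon[-1] + (lon[-1] - lon[-2]) / 2]])
    i = np.searchsorted(lat_edges, points["lat"].to_numpy(), side="right") - 1
    j = np.searchsorted(lon_edges, points["lon"].to_numpy(), side="right") - 1
    inside = (i >= 0) & (i < len(lat)) & (j >= 0) & (j < len(lon))
    n_dropped = int((~inside).sum())
    sums = np.zeros(template.values.shape)
    counts = np.zeros(template.values.shape)
    np.add.at(sums, (i[inside], j[inside]), points["value"].to_numpy()[inside])
    np.add.at(counts, (i[inside], j[inside]), 1.0)
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    out = GriddedField(values=values, units=template.units,
                       area=template.area, mask=counts > 0,
                       lat=lat, lon=lon)
    out.n_dropped = n_dropped
    return out
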