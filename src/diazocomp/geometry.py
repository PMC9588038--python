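"""Box layout: latitude bands x basins, two layers per column.

The default geometry covers the ice-free ocean with five latitude bands
(southern high latitudes to northern high latitudes) split into three basins
(Atlantic, Pacific, Indian).  Each column has a 100 m surface layer in which
biology operates and a deep layer holding the nutrient reservoirs.  The three
tropical columns are flagged as denitrifying (oxygen-minimum-zone upwelling
sources); the high-latitude southern band and, more weakly, the northern band
carry a static iron-limitation factor that scales maximum growth rates down.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

BAND_NAMES = (
    "southern-high", "southern-subtropical", "tropical",
    "northern-subtropical", "northern-high",
)
BASIN_NAMES = ("atlantic", "pacific", "indian")


@dataclass
class BoxGeometry:
    """Surface/deep box layout with physical forcing fields.

    Arrays are per column (length ``n_col``).  ``kv`` is the vertical
    exchange velocity between the two layers (m d⁻¹); ``kh_*`` relaxation
    rates live in :class:`~diazocomp.params.EcosystemParams`.
    """

    names: tuple                  # column labels
    band: np.ndarray              # band index per column
    area: np.ndarray              # m^2
    temp: np.ndarray              # surface temperature, degC
    J_IO: np.ndarray              # light-limited growth rate cap, 1/d
    kv: np.ndarray                # vertical exchange velocity, m/d
    fe_limit: np.ndarray          # iron-limitation factor in (0, 1]
    denit_box: np.ndarray         # bool, deep box denitrifies
    h_surface: float = 100.0      # m
    h_deep: float = 3600.0        # m

    def __post_init__(self) -> None:
        n = len(self.names)
        for name in ("band", "area", "temp", "J_IO", "kv", "fe_limit", "denit_box"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"geometry field {name!r} must have shape ({n},)")
            setattr(self, name, arr)
        if np.any(self.area <= 0) or self.h_surface <= 0 or self.h_deep <= 0:
            raise ValueError("areas and layer thicknesses must be positive")
        if np.any(self.kv < 0) or np.any(self.J_IO < 0):
            raise ValueError("kv and J_IO must be non-negative")
        if np.any((self.fe_limit <= 0) | (self.fe_limit > 1)):
            raise ValueError("fe_limit must lie in (0, 1]")
        self.denit_box = self.denit_box.astype(bool)

    @property
    def n_col(self) -> int:
        return len(self.names)

    @property
    def volumes(self) -> np.ndarray:
        """Box volumes, m^3, shape (n_col, 2)."""
        return np.stack(
            [self.area * self.h_surface, self.area * self.h_deep], axis=1
        )

    @property
    def fed_box(self) -> np.ndarray:
        """Columns whose surface receives water with a denitrification
        history (the upwelling columns above denitrifying deep boxes)."""
        return self.denit_box.copy()

    def replace(self, **kwargs) -> "BoxGeometry":
        return dataclasses.replace(self, **kwargs)

    def scale_kv(self, factor: float) -> "BoxGeometry":
        return self.replace(kv=self.kv * float(factor))


# per-band defaults (calibrated; see docs/methods.md)
_BAND_AREA = np.array([47.0, 73.0, 96.0, 61.0, 31.0]) * 1.0e12   # m^2
_BAND_TEMP = np.array([4.0, 19.0, 27.0, 20.0, 12.2])             # degC
_BAND_JIO = np.array([0.15, 0.30, 0.42, 0.30, 0.20])             # 1/d
_BAND_KV = np.array([0.08, 0.003, 0.011, 0.003, 0.08])           # m/d
_BAND_FE = np.array([0.35, 1.0, 1.0, 1.0, 0.55])
#: basin share of each band's area
_BASIN_FRACTION = {"atlantic": 0.3, "pacific": 0.5, "indian": 0.2}
#: basin asymmetry of subtropical stratification: the Atlantic gyre is the
#: ultra-oligotrophic end member, the Pacific gyre the best-ventilated one
_SUBTROPICAL_KV = {"atlantic": 0.0007, "pacific": 0.0045, "indian": 0.003}


def default_geometry() -> BoxGeometry:
    """The standard 15-column, two-layer global geometry."""
    names, band, area, temp, jio, kv, fe, denit = [], [], [], [], [], [], [], []
    for b, bname in enumerate(BAND_NAMES):
        for basin in BASIN_NAMES:
            names.append(f"{basin}:{bname}")
            band.append(b)
            area.append(_BAND_AREA[b] * _BASIN_FRACTION[basin])
            temp.append(_BAND_TEMP[b])
            jio.append(_BAND_JIO[b])
            if bname.endswith("subtropical"):
                kv.append(_SUBTROPICAL_KV[basin])
            else:
                kv.append(_BAND_KV[b])
            fe.append(_BAND_FE[b])
            denit.append(bname == "tropical")
    return BoxGeometry(
        names=tuple(names),
        band=np.array(band),
        area=np.array(area),
        temp=np.array(temp),
        J_IO=np.array(jio),
        kv=np.array(kv),
        fe_limit=np.array(fe),
        denit_box=np.array(denit),
    )
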