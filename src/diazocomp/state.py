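"""Tracer state containers.

The state holds six tracers per box and layer: NO3 (mmol N m⁻³), PO4
(mmol P m⁻³) and the nitrogen-currency pools of ordinary phytoplankton,
diazotrophs, zooplankton and detritus (all mmol N m⁻³).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import BoxGeometry

TRACERS = ("NO3", "PO4", "P_O", "P_D", "Z", "Det")
TRACER_UNITS = {
    "NO3": "mmol N m-3",
    "PO4": "mmol P m-3",
    "P_O": "mmol N m-3",
    "P_D": "mmol N m-3",
    "Z": "mmol N m-3",
    "Det": "mmol N m-3",
}
LAYERS = ("surface", "deep")

I_NO3, I_PO4, I_PO, I_PD, I_Z, I_DET = range(6)
#: tracer indices whose currency is nitrogen
N_TRACERS = (I_NO3, I_PO, I_PD, I_Z, I_DET)


@dataclass
class EcosystemState:
    """Tracer concentrations, array of shape ``(n_col, 2, 6)``."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or self.data.shape[1:] != (2, 6):
            raise ValueError("state array must have shape (n_col, 2, 6)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("state contains NaN or infinite values")
        if np.any(self.data < 0):
            raise ValueError("state contains negative tracer concentrations")

    @property
    def n_col(self) -> int:
        return self.data.shape[0]

    def tracer(self, name: str, layer: str = "surface") -> np.ndarray:
        """Concentration of one tracer in one layer, shape (n_col,)."""
        return self.data[:, LAYERS.index(layer), TRACERS.index(name)]

    def copy(self) -> "EcosystemState":
        return EcosystemState(self.data.copy())

    @classmethod
    def zeros(cls, n_col: int) -> "EcosystemState":
        return cls(np.zeros((n_col, 2, 6)))


@dataclass
class Tendency:
    """Time derivatives (mmol m⁻³ d⁻¹) plus diagnostic fluxes.

    ``fixation`` is the surface-volumetric N2-fixation rate and ``denit``
    the deep-volumetric denitrification rate per column; ``grazing`` holds
    the fluxes removed from ordinary phytoplankton, diazotrophs and
    detritus by zooplankton.
    """

    data: np.ndarray              # (n_col, 2, 6)
    fixation: np.ndarray          # (n_col,), mmol N m-3 d-1 (surface)
    denit: np.ndarray             # (n_col,), mmol N m-3 d-1 (deep)
    grazing: np.ndarray           # (n_col, 3) on (P_O, P_D, Det)

    def tracer(self, name: str, layer: str = "surface") -> np.ndarray:
        return self.data[:, LAYERS.index(layer), TRACERS.index(name)]


# deep NO3 deficits relative to Redfield balance, mmol N m^-3, per band:
# a strong oxygen-minimum-zone signal under the tropical columns and a weak
# deficit under the subtropical gyres (water with a diluted denitrification
# history); high-latitude deep water starts Redfield-balanced.
_BAND_DEEP_DEFICIT = np.array([0.0, 0.1, 16.0, 0.1, 0.0])
_DEEP_PO4 = 2.2  # mmol P m-3


def default_initial_state(geometry: BoxGeometry) -> EcosystemState:
    """Pre-industrial initial condition near the expected equilibrium.

    Deep PO4 is uniform; deep NO3 carries a nitrogen deficit relative to its
    Redfield equivalent only where water has a denitrification history.
    Surface nutrients start low, with small seed populations everywhere.
    """
    n = geometry.n_col
    data = np.zeros((n, 2, 6))
    deficit = _BAND_DEEP_DEFICIT[geometry.band]
    data[:, 1, I_PO4] = _DEEP_PO4
    data[:, 1, I_NO3] = _DEEP_PO4 * 16.0 - deficit
    data[:, 0, I_NO3] = 0.3
    data[:, 0, I_PO4] = 0.05
    data[:, 0, I_PO] = 0.05
    data[:, 0, I_PD] = 0.005
    data[:, 0, I_Z] = 0.05
    data[:, 0, I_DET] = 0.01
    return EcosystemState(data)
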