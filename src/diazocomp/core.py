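"""Dynamical core: growth, grazing and tracer tendencies.

Growth follows Liebig's law of the minimum over light and Monod-limited
nutrients; ordinary phytoplankton are limited by both NO3 and PO4 while
diazotrophs are insensitive to nitrate scarcity (they fix N2 to cover any
Redfield deficit) but pay a growth handicap ``C_d`` and stop growing below a
temperature cutoff.  Zooplankton graze ordinary phytoplankton, diazotrophs
and detritus with fixed preferences, linearly in prey; an optional
saturating (multiple-prey Holling II) denominator is available behind
``EcosystemParams.holling_saturation``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from ._kernel import integrate_kernel, rhs
from .geometry import BoxGeometry
from .params import EcosystemParams
from .state import EcosystemState, Tendency, I_NO3, I_PO4, N_TRACERS

MOLAR_MASS_N = 14.0   # g/mol
MOLAR_MASS_C = 12.0   # g/mol


# ---------------------------------------------------------------------------
# elementary rate laws
# ---------------------------------------------------------------------------

def monod(conc, k):
    """Monod limitation factor ``conc / (k + conc)`` in [0, 1].

    Parameters may be scalars or arrays; ``k`` must be strictly positive and
    ``conc`` non-negative.
    """
    conc = np.asarray(conc, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(k <= 0):
        raise ValueError("half-saturation k must be strictly positive")
    if np.any(conc < 0):
        raise ValueError("concentration must be non-negative")
    out = conc / (k + conc)
    return out.item() if out.ndim == 0 else out


def growth_rate_ordinary(J_IO, NO3, PO4, params: EcosystemParams):
    """Realized ordinary-phytoplankton growth rate (d⁻¹).

    The minimum of the light-limited rate and the NO3- and PO4-limited
    Monod rates.
    """
    J_IO, NO3, PO4 = (np.asarray(v, dtype=float) for v in (J_IO, NO3, PO4))
    if np.any(J_IO < 0) or np.any(NO3 < 0) or np.any(PO4 < 0):
        raise ValueError("J_IO, NO3 and PO4 must be non-negative")
    out = np.minimum(
        J_IO,
        np.minimum(
            params.J_O_max * monod(NO3, params.k_N),
            params.J_O_max * monod(PO4, params.k_P),
        ),
    )
    return out.item() if out.ndim == 0 else out


def growth_rate_diazotroph(J_IO, PO4, temperature, params: EcosystemParams):
    """Realized diazotroph growth rate (d⁻¹); independent of NO3.

    Zero below the temperature cutoff, else the minimum of the light-limited
    rate and the PO4-limited Monod rate with maximum ``C_d * J_O_max``.
    """
    J_IO, PO4 = (np.asarray(v, dtype=float) for v in (J_IO, PO4))
    temperature = np.asarray(temperature, dtype=float)
    if np.any(J_IO < 0) or np.any(PO4 < 0):
        raise ValueError("J_IO and PO4 must be non-negative")
    rate = np.minimum(J_IO, params.J_D_max * monod(PO4, params.k_P_d))
    out = np.where(temperature >= params.T_min_diaz, rate, 0.0)
    return out.item() if out.ndim == 0 else out


def grazing_rate(Z, prey, theta, params: EcosystemParams, total_weighted_prey=None):
    """Grazing flux ``mu_max * Z * theta * prey`` (mmol N m⁻³ d⁻¹).

    Linear in prey by default; if ``params.holling_saturation`` is set, the
    flux is divided by ``1 + total_weighted_prey / k_graze`` where
    ``total_weighted_prey`` is the preference-weighted sum over all prey.
    """
    Z, prey = (np.asarray(v, dtype=float) for v in (Z, prey))
    theta = float(theta)
    if np.any(Z < 0) or np.any(prey < 0):
        raise ValueError("Z and prey must be non-negative")
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    flux = params.mu_max * Z * theta * prey
    if params.holling_saturation:
        if total_weighted_prey is None:
            total_weighted_prey = theta * prey
        flux = flux / (1.0 + np.asarray(total_weighted_prey) / params.k_graze)
    return flux.item() if np.ndim(flux) == 0 else flux


# ---------------------------------------------------------------------------
# assembled tendencies and stepping
# ---------------------------------------------------------------------------

def seasonal_J_IO(geometry: BoxGeometry, t_days: float,
                  amplitude: float = 0.3) -> np.ndarray:
    """Sinusoidal seasonal modulation of the light-limited rate cap.

    Peaks at mid-year in the northern hemisphere and half a year later in
    the southern; tropical columns are left unmodulated.  Use with the
    ``J_IO`` override of :func:`tendencies` and the :func:`step` API (the
    compiled multi-year integrator uses the annual-mean light).
    """
    if not 0.0 <= amplitude < 1.0:
        raise ValueError("amplitude must lie in [0, 1)")
    phase = np.where(geometry.band > 2, 0.25, 0.75)   # hemisphere summer
    seasonal = 1.0 + amplitude * np.sin(
        2.0 * np.pi * (t_days / 365.0 - phase))
    seasonal = np.where(geometry.band == 2, 1.0, seasonal)
    return geometry.J_IO * seasonal


def tendencies(state: EcosystemState, geometry: BoxGeometry,
               params: EcosystemParams, denit_enabled: bool = True,
               temp: Optional[np.ndarray] = None,
               kv: Optional[np.ndarray] = None,
               J_IO: Optional[np.ndarray] = None) -> Tendency:
    """Full tendency of every tracer plus diagnostic fluxes.

    ``temp``, ``kv`` and ``J_IO`` override the geometry's surface
    temperature, vertical exchange velocity and light-limited rate cap
    (scenario or seasonal forcing).
    """
    if state.n_col != geometry.n_col:
        raise ValueError("state and geometry have different column counts")
    temp = geometry.temp if temp is None else np.asarray(temp, dtype=float)
    kv = geometry.kv if kv is None else np.asarray(kv, dtype=float)
    jio = geometry.J_IO if J_IO is None else np.asarray(J_IO, dtype=float)
    dy, fix, den, graz = rhs(
        state.data, params.pack(denit_enabled), geometry.area.astype(float),
        temp, jio.astype(float), kv,
        geometry.fe_limit.astype(float),
        geometry.denit_box.astype(np.float64),
        geometry.h_surface, geometry.h_deep,
    )
    return Tendency(data=dy, fixation=fix, denit=den, grazing=graz)


def step(state: EcosystemState, tendency_provider: Callable[[EcosystemState], Tendency],
         dt: float, clip_epsilon: float = 1.0e-6) -> EcosystemState:
    """Advance one explicit RK4 step of length ``dt`` days.

    Small negative excursions (above ``-clip_epsilon``) are clipped to zero;
    larger ones raise, advising a smaller time step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    y = state.data
    k1 = tendency_provider(EcosystemState(y)).data
    k2 = tendency_provider(EcosystemState(np.maximum(y + 0.5 * dt * k1, 0.0))).data
    k3 = tendency_provider(EcosystemState(np.maximum(y + 0.5 * dt * k2, 0.0))).data
    k4 = tendency_provider(EcosystemState(np.maximum(y + dt * k3, 0.0))).data
    out = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    if out.min() < -clip_epsilon:
        raise RuntimeError(
            "tracer went negative beyond the clipping tolerance; "
            "use a smaller dt"
        )
    return EcosystemState(np.maximum(out, 0.0))


@dataclass
class MassBudget:
    """Volume-integrated tracer totals."""

    mol_N: float            # total nitrogen over all N-currency tracers
    mol_P: float            # total phosphorus (PO4 + organic N / r_NP)
    Tg_N: float
    Tg_C: float             # organic carbon equivalent of the N pools
    excess_P_mol_N: float   # (16*PO4_total - NO3_total), mol N equivalents

    @property
    def excess_P_Pmol_N(self) -> float:
        return self.excess_P_mol_N / 1.0e15


def mass_budget(state: EcosystemState, geometry: BoxGeometry,
                params: EcosystemParams) -> MassBudget:
    """Global tracer inventories (mol and Tg).

    The excess-P inventory is the PO4 pool beyond the Redfield equivalent of
    the NO3 pool, expressed in nitrogen equivalents.
    """
    if state.n_col != geometry.n_col:
        raise ValueError("state and geometry have different column counts")
    vol = geometry.volumes  # (n_col, 2)
    mmol = (state.data * vol[:, :, None]).sum(axis=(0, 1))  # per tracer, mmol
    mol = mmol * 1.0e-3
    mol_N = sum(mol[i] for i in N_TRACERS)
    mol_P = mol[I_PO4] + (mol_N - mol[I_NO3]) / params.r_NP
    organic_N = mol_N - mol[I_NO3]
    return MassBudget(
        mol_N=mol_N,
        mol_P=mol_P,
        Tg_N=mol_N * MOLAR_MASS_N / 1.0e12,
        Tg_C=organic_N * params.r_CN * MOLAR_MASS_C / 1.0e12,
        excess_P_mol_N=params.r_NP * mol[I_PO4] - mol[I_NO3],
    )


@dataclass
class IntegrationResult:
    """Raw output of a multi-year integration."""

    state: EcosystemState          # final state
    traj: np.ndarray               # annual-mean states, (nyears, n_col, 2, 6)
    fixation: np.ndarray           # annual-mean volumetric fixation, (nyears, n_col)
    denit: np.ndarray              # annual-mean volumetric denitrification
    clipped_mmol: float            # total clipped negative mass
    years: np.ndarray              # year coordinates


def integrate(state: EcosystemState, geometry: BoxGeometry,
              params: EcosystemParams, years: int,
              steps_per_year: int = 365, denit_enabled: bool = True,
              dT: Optional[np.ndarray] = None,
              kv_scale: Optional[np.ndarray] = None,
              year0: float = 0.0) -> IntegrationResult:
    """Integrate the model forward with the compiled RK4 kernel.

    ``dT``/``kv_scale`` (shape ``(years, n_col)``) apply per-year surface
    warming offsets and vertical-exchange scalings.
    """
    if years <= 0 or steps_per_year <= 0:
        raise ValueError("years and steps_per_year must be positive")
    n = geometry.n_col
    if dT is None:
        dT = np.zeros((years, n))
    if kv_scale is None:
        kv_scale = np.ones((years, n))
    dT = np.asarray(dT, dtype=float)
    kv_scale = np.asarray(kv_scale, dtype=float)
    if dT.shape != (years, n) or kv_scale.shape != (years, n):
        raise ValueError("forcing arrays must have shape (years, n_col)")
    y, traj, fix, den, clipped, status = integrate_kernel(
        state.data.copy(), params.pack(denit_enabled),
        geometry.area.astype(float), geometry.temp.astype(float),
        geometry.J_IO.astype(float), geometry.kv.astype(float),
        geometry.fe_limit.astype(float), geometry.denit_box.astype(np.float64),
        geometry.h_surface, geometry.h_deep,
        years, steps_per_year, dT, kv_scale,
    )
    if status != 0:
        raise RuntimeError(
            "integration produced a negative tracer beyond the clipping "
            "tolerance; use more steps per year"
        )
    return IntegrationResult(
        state=EcosystemState(y), traj=traj, fixation=fix, denit=den,
        clipped_mmol=clipped, years=year0 + 0.5 + np.arange(years),
    )
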