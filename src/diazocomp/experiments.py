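"""Experiment definitions: the four paradigms, spin-up, the warming
scenario, the niche-closure decay experiment, and sensitivity scans.

CONTR gives diazotrophs no competitive advantage beyond N2 fixation itself;
GRAZ adds a grazing refuge (theta_d < theta_o); OLIGO adds high-affinity
phosphate uptake (k_P_d < k_P); DECAY is CONTR with denitrification nulled,
so that fixation gradually erases the global nitrogen deficit and the
diazotroph niche closes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import IntegrationResult, integrate, mass_budget
from .diagnostics import (DecayFit, DiagnosticsSeries,
                          fit_exponential_decay_timescale, global_series)
from .geometry import BoxGeometry, default_geometry
from .params import PARADIGMS, EcosystemParams, default_params
from .state import EcosystemState, I_NO3, I_PO4, default_initial_state

#: per-band scaling of the surface-warming amplitude (polar amplification)
BAND_WARMING_FACTOR = np.array([1.5, 1.0, 0.85, 1.0, 1.4])


@dataclass
class WarmingRamp:
    """Warming/stratification forcing for the 1800-2150 projection.

    The normalized ramp ``w(t) = ((t - year_start)/(year_end - year_start))
    ** exponent`` scales a surface-warming amplitude (amplified towards the
    poles) and a proportional reduction of the vertical exchange
    coefficient, the box-model proxy for increased stratification.
    """

    year_start: int = 1800
    year_end: int = 2150
    exponent: float = 2.0
    amplitude_degC: float = 3.0          # base surface warming at year_end
    mixing_reduction: float = 0.5        # fractional kv reduction at year_end

    def w(self, year) -> np.ndarray:
        year = np.asarray(year, dtype=float)
        x = np.clip((year - self.year_start)
                    / (self.year_end - self.year_start), 0.0, None)
        return x ** self.exponent


@dataclass
class ExperimentConfig:
    """Paradigm, scenario forcing, solver and spin-up settings."""

    paradigm: str = "CONTR"
    params: EcosystemParams = field(default_factory=default_params)
    denitrification_enabled: bool = True
    scenario: str = "preindustrial"          # or "warming"
    ramp: WarmingRamp = field(default_factory=WarmingRamp)
    steps_per_year: int = 365
    spinup_tol_per_century: float = 1.0e-3   # relative drift per century
    spinup_max_years: int = 3000
    spinup_check_years: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.paradigm not in PARADIGMS:
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if self.scenario not in ("preindustrial", "warming"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.paradigm == "DECAY" and self.denitrification_enabled:
            raise ValueError("DECAY requires denitrification_enabled=False")
        self.params.check_paradigm(self.paradigm)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = self.params.to_dict()
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def build_config(paradigm: str, overrides: Optional[dict] = None,
                 **config_kwargs) -> ExperimentConfig:
    """Config for a paradigm; ``overrides`` adjusts EcosystemParams fields.

    Overrides that violate the paradigm's defining parameter relations
    (e.g. OLIGO with ``k_P_d >= k_P``) are rejected.
    """
    params = default_params(paradigm, **(overrides or {}))
    if paradigm == "DECAY":
        config_kwargs.setdefault("denitrification_enabled", False)
    return ExperimentConfig(paradigm=paradigm, params=params, **config_kwargs)


@dataclass
class RunResult:
    """Trajectory, diagnostics and provenance of one integration."""

    config: ExperimentConfig
    geometry: BoxGeometry
    result: IntegrationResult
    diagnostics: DiagnosticsSeries
    converged: Optional[bool] = None
    drift_per_century: Optional[float] = None

    @property
    def final_state(self) -> EcosystemState:
        return self.result.state

    def summary(self) -> pd.DataFrame:
        """Mean global diagnostics over the final decade."""
        frame = self.diagnostics.to_frame().tail(10).mean(numeric_only=True)
        return frame.to_frame(name="final-decade mean")


def _run(config: ExperimentConfig, geometry: BoxGeometry,
         state: EcosystemState, years: int, year0: float = 0.0,
         dT=None, kv_scale=None) -> RunResult:
    res = integrate(state, geometry, config.params, years,
                    steps_per_year=config.steps_per_year,
                    denit_enabled=config.denitrification_enabled,
                    dT=dT, kv_scale=kv_scale, year0=year0)
    return RunResult(config=config, geometry=geometry, result=res,
                     diagnostics=global_series(res, geometry, config.params))


def spinup_to_equilibrium(config: ExperimentConfig,
                          geometry: Optional[BoxGeometry] = None,
                          initial_state: Optional[EcosystemState] = None,
                          max_years: Optional[int] = None) -> RunResult:
    """Integrate to quasi-equilibrium under pre-industrial forcing.

    Convergence is declared when the relative drifts per century of global
    fixation and of every tracer inventory fall below the configured
    tolerance; hitting the year cap instead sets ``converged=False``.
    """
    geometry = geometry or default_geometry()
    state = initial_state or default_initial_state(geometry)
    cap = max_years or config.spinup_max_years
    chunk = config.spinup_check_years
    vol = geometry.volumes
    elapsed = 0
    run = None
    prev_fix = None
    prev_inv = None
    converged = False
    drift = np.inf
    chunks = []
    while elapsed < cap:
        years = min(chunk, cap - elapsed)
        run = _run(config, geometry, state, years, year0=elapsed)
        chunks.append(run)
        state = run.final_state
        elapsed += years
        fix = run.diagnostics.fixation_TgN[-min(10, years):].mean()
        inv = (state.data * vol[:, :, None]).sum(axis=(0, 1))  # per tracer
        if prev_fix is not None:
            scale = 100.0 / years
            dfix = abs(fix - prev_fix) / max(abs(prev_fix), 1e-12) * scale
            dinv = np.abs(inv - prev_inv) / np.maximum(np.abs(prev_inv), 1e-9) * scale
            drift = max(dfix, dinv.max())
            if drift < config.spinup_tol_per_century:
                converged = True
                break
        prev_fix, prev_inv = fix, inv
    # stitch the chunks into one result for diagnostics/trajectory access
    full = IntegrationResult(
        state=state,
        traj=np.concatenate([c.result.traj for c in chunks]),
        fixation=np.concatenate([c.result.fixation for c in chunks]),
        denit=np.concatenate([c.result.denit for c in chunks]),
        clipped_mmol=sum(c.result.clipped_mmol for c in chunks),
        years=np.concatenate([c.result.years for c in chunks]),
    )
    out = RunResult(config=config, geometry=geometry, result=full,
                    diagnostics=global_series(full, geometry, config.params),
                    converged=converged, drift_per_century=float(drift))
    if not converged:
        import warnings
        warnings.warn(
            f"spin-up hit the {cap}-year cap with drift "
            f"{drift:.2e} per century (tolerance "
            f"{config.spinup_tol_per_century:.1e})", RuntimeWarning)
    return out


def scenario_forcing(config: ExperimentConfig, geometry: BoxGeometry,
                     years: np.ndarray):
    """Per-year (dT, kv_scale) arrays for the warming ramp."""
    w = config.ramp.w(years)[:, None]
    dT = w * config.ramp.amplitude_degC * BAND_WARMING_FACTOR[geometry.band][None, :]
    kv_scale = 1.0 - config.ramp.mixing_reduction * np.broadcast_to(
        w, (len(years), geometry.n_col)).copy()
    return dT, kv_scale


def run_scenario(config: ExperimentConfig, equilibrium: RunResult) -> RunResult:
    """Project 1800-2150 from a matching pre-industrial equilibrium.

    Applies the warming ramp (surface warming up, vertical exchange down)
    and returns annual diagnostics.
    """
    if equilibrium.config.paradigm != config.paradigm:
        raise ValueError(
            f"equilibrium paradigm {equilibrium.config.paradigm!r} does not "
            f"match scenario paradigm {config.paradigm!r}")
    geometry = equilibrium.geometry
    years = np.arange(config.ramp.year_start, config.ramp.year_end)
    if config.scenario == "warming":
        dT, kv_scale = scenario_forcing(config, geometry, years)
    else:
        dT = np.zeros((len(years), geometry.n_col))
        kv_scale = np.ones((len(years), geometry.n_col))
    return _run(config, geometry, equilibrium.final_state, len(years),
                year0=float(years[0]), dT=dT, kv_scale=kv_scale)


# ---------------------------------------------------------------------------
# niche-closure (DECAY) experiment
# ---------------------------------------------------------------------------

def rescale_excess_inventory(state: EcosystemState, geometry: BoxGeometry,
                             params: EcosystemParams,
                             target_Pmol_N: float) -> EcosystemState:
    """Scale every box's local N deficit so the global excess-P inventory
    (in nitrogen equivalents) hits ``target_Pmol_N``.

    PO4 is left untouched; NO3 is moved towards/away from its local
    Redfield equivalent by a single global factor, preserving the spatial
    pattern of the deficit.
    """
    current = mass_budget(state, geometry, params).excess_P_Pmol_N
    if current <= 0:
        raise ValueError("state has no positive excess-P inventory to scale")
    s = target_Pmol_N / current
    data = state.data.copy()
    deficit = params.r_NP * data[:, :, I_PO4] - data[:, :, I_NO3]
    data[:, :, I_NO3] = params.r_NP * data[:, :, I_PO4] - s * deficit
    data[:, :, I_NO3] = np.maximum(data[:, :, I_NO3], 0.0)
    return EcosystemState(data)


@dataclass
class DecayExperimentResult:
    """Output of the calibrated niche-closure experiment."""

    fit: DecayFit
    initial_fixation_TgN: float
    initial_excess_Pmol_N: float
    run: RunResult
    analytic_tau_years: float

    @property
    def tau_years(self) -> float:
        return self.fit.tau_years


def run_decay_experiment(target_excess_Pmol_N: float = 5.5,
                         target_fixation_TgN: float = 70.0,
                         years: int = 1600,
                         fit_window: tuple = (100, 1500),
                         spinup_years: int = 600,
                         steps_per_year: int = 365,
                         geometry: Optional[BoxGeometry] = None,
                         contr_equilibrium: Optional[RunResult] = None
                         ) -> DecayExperimentResult:
    """Spin up CONTR, calibrate to the canonical global nitrogen budget,
    null denitrification and watch the diazotroph niche close.

    The CONTR equilibrium is rescaled so the excess-P inventory equals
    ``target_excess_Pmol_N`` (in N equivalents) and the vertical exchange
    is tuned so the initial fixation is ``target_fixation_TgN``; the decline
    of global diazotroph biomass is then fitted log-linearly over
    ``fit_window`` (years after the switch).
    """
    geometry = geometry or default_geometry()
    contr = build_config("CONTR", steps_per_year=steps_per_year)
    if contr_equilibrium is None:
        contr_equilibrium = spinup_to_equilibrium(
            contr, geometry, max_years=spinup_years)
    geometry = contr_equilibrium.geometry
    decay = build_config("DECAY", steps_per_year=steps_per_year)
    state = rescale_excess_inventory(
        contr_equilibrium.final_state, geometry, decay.params,
        target_excess_Pmol_N)

    # tune the vertical exchange so the post-switch fixation starts at the
    # target rate (fixation responds linearly to kv at fixed inventories)
    relax_years = 20
    for _ in range(4):
        probe = _run(decay, geometry, state, relax_years)
        fix0 = probe.diagnostics.fixation_TgN[-5:].mean()
        if abs(fix0 - target_fixation_TgN) / target_fixation_TgN < 0.02:
            break
        geometry = geometry.scale_kv(target_fixation_TgN / fix0)

    run = _run(decay, geometry, state, years)
    # re-anchor the measured initial conditions after the short adjustment
    initial_fix = run.diagnostics.fixation_TgN[5:25].mean()
    initial_excess = mass_budget(state, geometry, decay.params).excess_P_Pmol_N
    lo, hi = fit_window
    hi = min(hi, years)
    sel = (run.diagnostics.year >= lo) & (run.diagnostics.year <= hi)
    fit = fit_exponential_decay_timescale(
        run.diagnostics.biomass_TgC[sel], run.diagnostics.year[sel])
    from .diagnostics import niche_closure_timescale
    return DecayExperimentResult(
        fit=fit, initial_fixation_TgN=float(initial_fix),
        initial_excess_Pmol_N=float(initial_excess), run=run,
        analytic_tau_years=niche_closure_timescale(
            initial_excess, initial_fix),
    )


# ---------------------------------------------------------------------------
# sensitivity scans and tipping-point detection
# ---------------------------------------------------------------------------

#: reference step sizes (20% of the covered parameter ranges)
SCAN_STEP = {"theta_d": 0.02, "k_P_d": 0.0088}


def sensitivity_scan(config: ExperimentConfig, param_name: str,
                     values: Sequence[float],
                     geometry: Optional[BoxGeometry] = None,
                     spinup_years: int = 600) -> pd.DataFrame:
    """Equilibrium fixation and biomass across a parameter grid.

    One spin-up per value; returns a table ordered by parameter value with
    global fixation (Tg N yr⁻¹), diazotroph biomass (Tg C), the biomass
    outside the denitrification-fed columns, and a convergence flag.  The
    frame's ``attrs`` carry the mean absolute response per reference step
    (0.02 for theta_d, 0.0088 for k_P_d) over converged members.
    """
    if param_name not in SCAN_STEP:
        raise ValueError("param_name must be 'theta_d' or 'k_P_d'")
    geometry = geometry or default_geometry()
    rows = []
    for v in sorted(float(v) for v in values):
        overrides = {param_name: v}
        cfg = build_config(config.paradigm, overrides,
                           steps_per_year=config.steps_per_year,
                           spinup_tol_per_century=config.spinup_tol_per_century)
        eq = spinup_to_equilibrium(cfg, geometry, max_years=spinup_years)
        d = eq.diagnostics
        outside = ~geometry.fed_box
        rows.append({
            param_name: v,
            "fixation_TgN_yr": d.fixation_TgN[-10:].mean(),
            "biomass_TgC": d.biomass_TgC[-10:].mean(),
            "biomass_outside_fed_TgC": d.biomass_by_box[-10:, outside].sum(axis=1).mean(),
            "converged": bool(eq.converged),
        })
    table = pd.DataFrame(rows)
    ok = table[table["converged"]]
    step = SCAN_STEP[param_name]
    for col in ("fixation_TgN_yr", "biomass_TgC"):
        if len(ok) >= 2:
            dv = np.diff(ok[param_name].to_numpy())
            dy = np.abs(np.diff(ok[col].to_numpy()))
            resp = float(np.mean(dy / dv * step))
        else:
            resp = float("nan")
        table.attrs[f"response_{col}_per_{step}"] = resp
    table.attrs["param_name"] = param_name
    table.attrs["reference_step"] = step
    return table


def detect_tipping_point(scan_table: pd.DataFrame,
                         fraction: float = 0.01) -> Optional[float]:
    """Parameter value at which diazotrophs collapse outside the
    denitrification-fed columns.

    Scans the table (ordered by parameter value) for the first value whose
    outside-biomass drops below ``fraction`` of the maximum across the scan,
    adjacent to an above-threshold member; returns None for a flat scan.
    """
    if len(scan_table) < 5:
        raise ValueError("tipping-point detection needs a scan over >= 5 values")
    param = scan_table.attrs.get("param_name")
    if param is None:
        candidates = [c for c in scan_table.columns
                      if c not in ("fixation_TgN_yr", "biomass_TgC",
                                   "biomass_outside_fed_TgC", "converged")]
        param = candidates[0]
    table = scan_table.sort_values(param).reset_index(drop=True)
    outside = table["biomass_outside_fed_TgC"].to_numpy()
    vmax = outside.max()
    if vmax <= 0:
        return None
    below = outside < fraction * vmax
    if not below.any() or below.all():
        return None
    for i in range(len(below)):
        if below[i]:
            left_above = i > 0 and not below[i - 1]
            right_above = i + 1 < len(below) and not below[i + 1]
            if left_above or right_above:
                return float(table[param].iloc[i])
    return None
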