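import numpy as np
import pytest

import diazocomp as dz
from diazocomp.core import MassBudget
from diazocomp.geometry import BoxGeometry
from diazocomp.state import EcosystemState, I_NO3, I_PO4, N_TRACERS
from diazocomp.params import EcosystemParams, default_params

from conftest import random_state


@pytest.fixture(scope="module")
def params():
    return default_params("CONTR")


# ---------------------------------------------------------------------------
# elementary rate laws
# ---------------------------------------------------------------------------

class TestMonod:
    @pytest.mark.parametrize("conc,k,expected", [
        (0.0, 0.5, 0.0),          # zero concentration
        (0.5, 0.5, 0.5),          # half-saturation identity
        (1.5, 0.5, 0.75),         # 3k -> 3/4
    ])
    def test_values(self, conc, k, expected):
        assert dz.monod(conc, k) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            dz.monod(-0.1, 0.5)
        with pytest.raises(ValueError):
            dz.monod(0.1, 0.0)

    def test_monotonic_and_bounded(self):
        c = np.linspace(0, 50, 200)
        f = dz.monod(c, 0.7)
        assert np.all(np.diff(f) > 0)
        assert np.all((f >= 0) & (f < 1))


class TestGrowthRates:
    def test_liebig_zero_nutrient(self, params):
        assert dz.growth_rate_ordinary(1.0, 0.0, 5.0, params) == 0.0

    def test_half_saturation_identity(self, params):
        rate = dz.growth_rate_ordinary(10.0, 1e6, params.k_P, params)
        assert rate == pytest.approx(params.J_O_max / 2)

    def test_light_limited_branch(self, params):
        assert dz.growth_rate_ordinary(0.1, 1e6, 1e6, params) == pytest.approx(0.1)

    def test_never_exceeds_any_argument(self, params):
        rate = dz.growth_rate_ordinary(0.3, 0.5, 0.02, params)
        assert rate <= 0.3
        assert rate <= params.J_O_max * dz.monod(0.5, params.k_N)
        assert rate <= params.J_O_max * dz.monod(0.02, params.k_P)

    def test_diazotroph_temperature_cutoff(self, params):
        assert dz.growth_rate_diazotroph(10.0, 1e6, 10.0, params) == 0.0
        assert dz.growth_rate_diazotroph(10.0, 1e6, 25.0, params) > 0.0

    def test_diazotroph_half_saturation(self, params):
        rate = dz.growth_rate_diazotroph(10.0, params.k_P_d, 25.0, params)
        assert rate == pytest.approx(params.J_D_max / 2)

    def test_diazotroph_independent_of_NO3(self, params):
        # identical output whatever the ambient nitrate (not an argument)
        r = dz.growth_rate_diazotroph(0.3, 0.1, 25.0, params)
        assert r == pytest.approx(
            min(0.3, params.J_D_max * 0.1 / (params.k_P_d + 0.1)))


class TestGrazing:
    def test_zero_prey(self, params):
        assert dz.grazing_rate(1.0, 0.0, 0.3, params) == 0.0

    def test_printed_parameter_arithmetic(self, params):
        # mu_max=0.4, theta_o=0.3, Z=1, prey=2 -> 0.24
        assert dz.grazing_rate(1.0, 2.0, params.theta_o, params) == pytest.approx(0.24)

    def test_preference_ratio_at_equal_biomass(self):
        graz = default_params("GRAZ")
        fo = dz.grazing_rate(1.0, 1.0, graz.theta_o, graz)
        fd = dz.grazing_rate(1.0, 1.0, graz.theta_d, graz)
        assert fd / fo == pytest.approx(graz.theta_d / graz.theta_o)
        assert fd / fo == pytest.approx(1.0 / 3.0)

    def test_domain_errors(self, params):
        with pytest.raises(ValueError):
            dz.grazing_rate(-1.0, 1.0, 0.3, params)
        with pytest.raises(ValueError):
            dz.grazing_rate(1.0, 1.0, 1.5, params)

    def test_optional_saturation_reduces_flux(self, params):
        sat = params.replace(holling_saturation=True)
        lin = dz.grazing_rate(1.0, 2.0, 0.3, params)
        hol = dz.grazing_rate(1.0, 2.0, 0.3, sat, total_weighted_prey=0.6)
        assert hol < lin
        assert hol == pytest.approx(lin / (1 + 0.6 / params.k_graze))


# ---------------------------------------------------------------------------
# assembled tendencies
# ---------------------------------------------------------------------------

class TestTendencies:
    def test_zero_biology_zero_tendency(self, geometry):
        """All rates zero and no gradients -> identically zero tendencies."""
        n = geometry.n_col
        quiet = geometry.replace(kv=np.zeros(n))
        data = np.zeros((n, 2, 6))
        data[:, :, I_NO3] = 10.0
        data[:, :, I_PO4] = 1.0
        params = default_params("CONTR")
        ten = dz.tendencies(EcosystemState(data), quiet, params)
        assert np.allclose(ten.data, 0.0, atol=1e-15)
        assert np.allclose(ten.fixation, 0.0)

    def test_nitrogen_budget_closes_pointwise(self, geometry):
        """Sum of N tendencies equals fixation - denitrification."""
        rng = np.random.default_rng(42)
        params = default_params("CONTR")
        vol = geometry.volumes
        for _ in range(5):
            state = random_state(rng, geometry.n_col)
            ten = dz.tendencies(state, geometry, params)
            dN = sum(ten.data[:, :, k] * vol for k in N_TRACERS).sum()
            source = (ten.fixation * vol[:, 0] - ten.denit * vol[:, 1]).sum()
            assert dN == pytest.approx(source, rel=1e-12, abs=1e-6)

    def test_phosphorus_tendency_closes_pointwise(self, geometry):
        rng = np.random.default_rng(7)
        params = default_params("CONTR")
        vol = geometry.volumes
        state = random_state(rng, geometry.n_col)
        ten = dz.tendencies(state, geometry, params)
        organic = sum(ten.data[:, :, k] for k in N_TRACERS if k != I_NO3)
        dP = ((ten.data[:, :, I_PO4] + organic / params.r_NP) * vol).sum()
        scale = np.abs(ten.data).max() * vol.max()
        assert abs(dP) < 1e-12 * scale

    def test_decay_config_has_zero_denitrification(self, geometry):
        rng = np.random.default_rng(3)
        state = random_state(rng, geometry.n_col)
        params = default_params("DECAY")
        ten = dz.tendencies(state, geometry, params, denit_enabled=False)
        assert np.all(ten.denit == 0.0)
        on = dz.tendencies(state, geometry, params, denit_enabled=True)
        assert on.denit[geometry.denit_box].max() > 0.0

    def test_rejects_invalid_states(self, geometry):
        bad = np.zeros((geometry.n_col, 2, 6))
        bad[0, 0, 0] = -1.0
        with pytest.raises(ValueError):
            EcosystemState(bad)
        nan = np.zeros((geometry.n_col, 2, 6))
        nan[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            EcosystemState(nan)


# ---------------------------------------------------------------------------
# time stepping
# ---------------------------------------------------------------------------

class TestStep:
    def test_zero_tendency_identity(self, geometry):
        state = dz.default_initial_state(geometry)
        zero = lambda s: dz.Tendency(
            data=np.zeros_like(s.data), fixation=np.zeros(s.n_col),
            denit=np.zeros(s.n_col), grazing=np.zeros((s.n_col, 3)))
        out = dz.step(state, zero, dt=1.0)
        assert np.array_equal(out.data, state.data)

    def test_dt_requirements(self, geometry):
        state = dz.default_initial_state(geometry)
        with pytest.raises(ValueError):
            dz.step(state, lambda s: None, dt=0.0)

    def test_halving_dt_converged_trajectory(self, geometry):
        """One year at daily steps matches half-daily steps to <1e-6."""
        params = default_params("CONTR")
        state = dz.default_initial_state(geometry)
        coarse = dz.integrate(state, geometry, params, 1, steps_per_year=365)
        fine = dz.integrate(state, geometry, params, 1, steps_per_year=730)
        scale = np.abs(fine.state.data).max()
        assert np.abs(coarse.state.data - fine.state.data).max() < 1e-6 * scale

    def test_phosphorus_conserved_over_run(self, geometry):
        params = default_params("CONTR")
        state = dz.default_initial_state(geometry)
        res = dz.integrate(state, geometry, params, 50)
        before = dz.mass_budget(state, geometry, params).mol_P
        after = dz.mass_budget(res.state, geometry, params).mol_P
        assert abs(after - before) / before < 1e-10


# ---------------------------------------------------------------------------
# mass budgets
# ---------------------------------------------------------------------------

def _unit_geometry():
    return BoxGeometry(
        names=("a", "b"), band=np.array([2, 2]),
        area=np.array([1.0, 1.0]), temp=np.array([25.0, 25.0]),
        J_IO=np.array([1.0, 1.0]), kv=np.array([0.0, 0.0]),
        fe_limit=np.array([1.0, 1.0]),
        denit_box=np.array([False, False]),
        h_surface=1.0, h_deep=1.0,
    )


class TestMassBudget:
    def test_empty_state_is_zero(self):
        geom = _unit_geometry()
        b = dz.mass_budget(EcosystemState.zeros(2), geom, default_params())
        assert b.mol_N == 0 and b.mol_P == 0 and b.Tg_N == 0

    def test_unit_conversion(self):
        """1 mmol N in 1 m^3 is 14 mg of nitrogen."""
        geom = _unit_geometry()
        data = np.zeros((2, 2, 6))
        data[0, 0, I_NO3] = 1.0
        b = dz.mass_budget(EcosystemState(data), geom, default_params())
        assert b.mol_N == pytest.approx(1.0e-3)
        assert b.mol_N * 14.0 == pytest.approx(14.0e-3)   # grams

    def test_excess_P_matches_hand_computation(self):
        """Two-box toy: E = r_NP*PO4_total - NO3_total in moles."""
        geom = _unit_geometry()
        params = default_params()
        data = np.zeros((2, 2, 6))
        data[:, :, I_PO4] = [[2.0, 1.0], [0.5, 0.25]]
        data[:, :, I_NO3] = [[16.0, 8.0], [4.0, 2.0]]
        b = dz.mass_budget(EcosystemState(data), geom, params)
        po4 = (2.0 + 1.0 + 0.5 + 0.25) * 1e-3
        no3 = (16.0 + 8.0 + 4.0 + 2.0) * 1e-3
        assert b.excess_P_mol_N == pytest.approx(16 * po4 - no3)

    def test_geometry_mismatch_rejected(self, geometry):
        with pytest.raises(ValueError):
            dz.mass_budget(EcosystemState.zeros(2), geometry, default_params())


class TestSeasonalLight:
    def test_annual_mean_preserved_and_hemispheres_opposed(self, geometry):
        days = np.arange(365.0)
        series = np.stack([dz.seasonal_J_IO(geometry, t, 0.3) for t in days])
        assert np.allclose(series.mean(axis=0), geometry.J_IO, rtol=1e-3)
        north = np.where(geometry.band == 4)[0][0]
        south = np.where(geometry.band == 0)[0][0]
        trop = np.where(geometry.band == 2)[0][0]
        # tropical light is unmodulated; summer peaks half a year apart
        assert np.allclose(series[:, trop], geometry.J_IO[trop])
        assert abs(np.argmax(series[:, north]) - np.argmax(series[:, south])
                   ) == pytest.approx(365 / 2, abs=2)

    def test_tendencies_accept_light_override(self, geometry):
        params = default_params("CONTR")
        state = dz.default_initial_state(geometry)
        # nutrient-replete surface so the light cap is the binding limit
        state.data[:, 0, I_NO3] = 20.0
        state.data[:, 0, I_PO4] = 2.0
        jio = dz.seasonal_J_IO(geometry, 180.0, 0.3)
        ten = dz.tendencies(state, geometry, params, J_IO=jio)
        base = dz.tendencies(state, geometry, params)
        assert not np.array_equal(ten.data, base.data)

    def test_amplitude_validated(self, geometry):
        with pytest.raises(ValueError):
            dz.seasonal_J_IO(geometry, 0.0, 1.5)
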