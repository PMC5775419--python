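"""Actuator physics: vapor pressure, thermal RC response, design arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from sweatwatch.actuator import (
    DEFAULT_POWER_TRAIN,
    PF5060,
    ExpansionFluid,
    PowerTrain,
    ThermalCircuit,
    VolumeDesign,
    average_power,
    battery_life,
    circuit_from_geometry,
    conductive_resistance,
    convective_resistance,
    fluid_heat_capacity,
    fluid_temperature,
    heater_power,
    parallel_resistance,
    select_fluid_volume,
    time_to_temperature,
    vapor_pressure,
)
from sweatwatch.errors import DomainError, InfeasibleDesignError, UnreachableTargetError

from conftest import random_circuit


class TestVaporPressure:
    def test_equals_reference_pressure_at_boiling(self, volatile_fluid):
        assert vapor_pressure(volatile_fluid, 56.0) == volatile_fluid.pressure_at_boiling

    def test_zero_enthalpy_is_constant(self):
        fluid = ExpansionFluid("flat", 56.0, 1.68, 1.05, 101325.0, 0.0)
        assert vapor_pressure(fluid, 10.0) == 101325.0
        assert vapor_pressure(fluid, 90.0) == 101325.0

    def test_frozen_clausius_clapeyron_value(self, volatile_fluid):
        # independent high-precision evaluation of the exponential form,
        # 20 K below boiling (329.15 K -> 309.15 K)
        assert vapor_pressure(volatile_fluid, 36.0) == pytest.approx(
            49854.952205, rel=1e-9
        )

    @given(st.floats(min_value=-40.0, max_value=120.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_temperature(self, t):
        fluid = ExpansionFluid("m", 56.0, 1.68, 1.05, 101325.0, 30000.0)
        assert vapor_pressure(fluid, t + 1.0) > vapor_pressure(fluid, t)

    def test_nonpositive_kelvin_rejected(self, volatile_fluid):
        with pytest.raises(DomainError):
            vapor_pressure(volatile_fluid, -300.0)

    def test_missing_constants_rejected(self):
        with pytest.raises(DomainError):
            vapor_pressure(PF5060, 30.0)  # no enthalpy in the preset


class TestCircuitElements:
    def test_documented_convective_resistance(self):
        # still air on the 5.31 cm2 membrane
        assert convective_resistance(20.0, 5.31e-4) == pytest.approx(94.2, abs=0.05)

    def test_documented_conductive_resistance(self):
        # 9 mm PMMA wall; direct evaluation gives 84.75 K/W
        assert conductive_resistance(0.2, 0.009, 5.31e-4) == pytest.approx(84.75, abs=0.005)

    def test_zero_thickness_wall(self):
        assert conductive_resistance(0.2, 0.0, 1e-3) == 0.0

    @pytest.mark.parametrize("fn,args", [
        (convective_resistance, (0.0, 1.0)),
        (convective_resistance, (1.0, -1.0)),
        (conductive_resistance, (0.0, 1.0, 1.0)),
        (conductive_resistance, (1.0, 1.0, 0.0)),
        (parallel_resistance, (0.0, 1.0)),
        (heater_power, (6.0, 0.0)),
    ])
    def test_domain_errors(self, fn, args):
        with pytest.raises(DomainError):
            fn(*args)

    @given(st.floats(min_value=1e-3, max_value=1e4))
    @settings(max_examples=50, deadline=None)
    def test_parallel_symmetry_and_bound(self, r):
        assert parallel_resistance(r, r) == pytest.approx(r / 2)
        assert parallel_resistance(r, 3 * r) < r

    def test_parallel_of_documented_pair(self):
        assert parallel_resistance(94.2, 84.8) == pytest.approx(44.63, abs=0.005)

    @pytest.mark.parametrize("v,r,expected", [(6, 20, 1.8), (0, 20, 0.0), (6, 50, 0.72)])
    def test_heater_power(self, v, r, expected):
        assert heater_power(v, r) == pytest.approx(expected)

    @pytest.mark.parametrize("vol,expected", [(0.0, 0.0), (0.4, 0.7056), (1.0, 1.764)])
    def test_fluid_heat_capacity(self, vol, expected):
        assert fluid_heat_capacity(vol, PF5060) == pytest.approx(expected)

    def test_negative_volume_rejected(self):
        with pytest.raises(DomainError):
            fluid_heat_capacity(-0.1, PF5060)


class TestTemperatureResponse:
    def test_initial_condition_is_ambient(self, default_circuit):
        assert fluid_temperature(0.0, default_circuit) == default_circuit.ambient_temp_c

    def test_steady_state(self, default_circuit):
        t_inf = fluid_temperature(100 * default_circuit.time_constant, default_circuit)
        assert t_inf == pytest.approx(default_circuit.steady_state_temp_c, abs=1e-9)

    def test_one_time_constant(self, default_circuit):
        c = default_circuit
        expected = c.ambient_temp_c + c.heat_rate * c.combined_resistance * (1 - math.e**-1)
        assert fluid_temperature(c.time_constant, c) == pytest.approx(expected)

    def test_monotone_over_random_circuits(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            c = random_circuit(rng)
            ts = np.sort(rng.uniform(0, 10 * c.time_constant, 20))
            temps = [fluid_temperature(t, c) for t in ts]
            assert np.all(np.diff(temps) >= 0)
            assert temps[0] >= c.ambient_temp_c

    def test_matches_ode_integration(self):
        """Closed form equals numeric integration of C1 dT/dt = Q - (T-Ts)/R2."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            c = random_circuit(rng)

            def rhs(t, temp):
                return (c.heat_rate - (temp[0] - c.ambient_temp_c) / c.combined_resistance) / c.fluid_heat_capacity

            t_end = 10 * c.time_constant
            sol = solve_ivp(rhs, (0, t_end), [c.ambient_temp_c], rtol=1e-10, atol=1e-10,
                            t_eval=np.linspace(0, t_end, 25))
            closed = [fluid_temperature(t, c) for t in sol.t]
            assert np.max(np.abs(sol.y[0] - closed)) < 1e-3


class TestTimeToTemperature:
    def test_ambient_target_is_zero(self, default_circuit):
        assert time_to_temperature(default_circuit, default_circuit.ambient_temp_c) == 0.0

    def test_asymptote_unreachable(self, default_circuit):
        with pytest.raises(UnreachableTargetError):
            time_to_temperature(default_circuit, default_circuit.steady_state_temp_c)

    def test_below_ambient_rejected(self, default_circuit):
        with pytest.raises(DomainError):
            time_to_temperature(default_circuit, default_circuit.ambient_temp_c - 1)

    def test_design_point_time_to_boiling(self, default_circuit):
        # 1.8 W, 0.4 ml charge: boiling is reached in about 15.4 s
        assert time_to_temperature(default_circuit, 56.0) == pytest.approx(15.36, abs=0.05)

    def test_roundtrip_identity_with_response(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            c = random_circuit(rng)
            target = c.ambient_temp_c + rng.uniform(0.05, 0.95) * (
                c.steady_state_temp_c - c.ambient_temp_c
            )
            t = time_to_temperature(c, target)
            assert fluid_temperature(t, c) == pytest.approx(target, abs=1e-6)

    def test_agrees_with_bisection_oracle(self, default_circuit):
        c = default_circuit
        t_closed = time_to_temperature(c, 56.0)
        t_bisect = brentq(lambda t: fluid_temperature(t, c) - 56.0, 0, 1e4, xtol=1e-10)
        assert t_closed == pytest.approx(t_bisect, abs=1e-8)


class TestVolumeSelection:
    def test_documented_design_point(self):
        """The 13 mm membrane / 3 mm stroke / 16 s deadline picks 0.4 ml."""
        design = select_fluid_volume(
            VolumeDesign(candidate_volumes_ml=[0.2, 0.4, 0.6, 1.0])
        )
        assert design.selected_volume_ml == 0.4
        # 0.2 ml is excluded by displacement (needs ~0.398 ml), not by time
        assert design.required_displacement_ml == pytest.approx(0.398, abs=0.001)
        assert design.time_to_boiling_s[0.2] < design.deadline_s

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            candidates = sorted(rng.uniform(0.05, 1.5, 5).round(3))
            deadline = rng.uniform(5, 60)
            stroke = rng.uniform(1, 5)
            diameter = rng.uniform(8, 20)
            spec = VolumeDesign(
                candidate_volumes_ml=list(candidates),
                deadline_s=deadline,
                required_stroke_mm=stroke,
                membrane_diameter_mm=diameter,
            )
            needed = spec.required_displacement_ml
            feasible = []
            for v in candidates:
                c = circuit_from_geometry(fluid_volume_ml=v)
                try:
                    t = time_to_temperature(c, PF5060.boiling_temp_c)
                except UnreachableTargetError:
                    continue
                if t <= deadline and v >= needed:
                    feasible.append(v)
            if feasible:
                assert select_fluid_volume(spec).selected_volume_ml == min(feasible)
            else:
                with pytest.raises(InfeasibleDesignError):
                    select_fluid_volume(spec)

    def test_single_feasible_candidate(self):
        design = select_fluid_volume(VolumeDesign(candidate_volumes_ml=[0.4]))
        assert design.selected_volume_ml == 0.4

    def test_impossible_deadline(self):
        with pytest.raises(InfeasibleDesignError):
            select_fluid_volume(
                VolumeDesign(candidate_volumes_ml=[0.4, 0.6], deadline_s=0.001)
            )


class TestPowerBudget:
    def test_documented_duty_cycle(self):
        assert average_power(DEFAULT_POWER_TRAIN) == pytest.approx(0.4)

    def test_always_on(self):
        assert average_power(PowerTrain(1.6, 30.0, 0.0)) == 1.6

    def test_zero_power(self):
        assert average_power(PowerTrain(0.0, 30.0, 90.0)) == 0.0

    @pytest.mark.parametrize("off,expected", [(90.0, 3.6), (150.0, 5.4)])
    def test_battery_life_hand_arithmetic(self, off, expected):
        life = battery_life(240.0, 6.0, PowerTrain(1.6, 30.0, off))
        assert life == pytest.approx(expected)

    def test_idle_device_never_drains(self):
        assert battery_life(240.0, 6.0, PowerTrain(0.0, 30.0, 90.0)) == math.inf
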