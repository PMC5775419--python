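"""Thermo-pneumatic actuator physics and design arithmetic.

The actuator heats a small cavity of volatile expansion fluid; the
temperature-dependent vapor pressure deflects a membrane that lifts the
humidity chamber off the skin. Two pieces of physics drive the design:

* the Clausius–Clapeyron relation between fluid temperature and vapor
  pressure, and
* a lumped thermal RC circuit (heater power ``Q`` charging the fluid heat
  capacity ``C1`` through loss resistances ``R21`` parallel ``R22``) whose
  first-order step response gives the fluid temperature versus time.

From the step response we obtain the time to reach the fluid's boiling
point for any candidate fluid volume, and hence the smallest volume that
both actuates fast enough and displaces enough vapor to produce the
required membrane stroke. Duty-cycled power and battery-life estimates for
the periodic heater drive live here as well.

Interface temperatures are in degrees Celsius; only the vapor-pressure
formula converts to kelvin internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import DomainError, InfeasibleDesignError, UnreachableTargetError

GAS_CONSTANT = 8.314  # J/(mol K)
CELSIUS_OFFSET = 273.15

#: Heater resistance presets (Ω). The device documentation quotes three
#: values in different contexts; ``design_20ohm`` reproduces the nominal
#: 1.8 W drive at 6 V and is the default.
HEATER_PRESETS = {
    "design_20ohm": 20.0,
    "characterization_23ohm": 23.0,
    "methods_50ohm": 50.0,
}


@dataclass(frozen=True)
class ExpansionFluid:
    """Thermophysical constants of the actuator working fluid.

    The packaged default is PF-5060 (perfluorohexane), chosen for its low
    boiling point of 56 °C. Vapor-pressure fields are optional because the
    thermal design needs only density, specific heat and the boiling point;
    ``vapor_pressure`` requires them.

    Parameters
    ----------
    boiling_temp_c : float
        Boiling temperature at ambient pressure, °C.
    density : float
        g/ml.
    specific_heat : float
        J/(g K).
    pressure_at_boiling : float, optional
        Vapor pressure at the boiling point, Pa. At the standard boiling
        point this equals atmospheric pressure by definition.
    vaporization_enthalpy : float, optional
        Molar enthalpy of vaporization, J/mol.
    """

    name: str
    boiling_temp_c: float
    density: float
    specific_heat: float
    pressure_at_boiling: float | None = None
    vaporization_enthalpy: float | None = None

    def __post_init__(self) -> None:
        if self.boiling_temp_c + CELSIUS_OFFSET <= 0:
            raise DomainError("boiling temperature must be above 0 K")
        if self.density <= 0 or self.specific_heat <= 0:
            raise DomainError("density and specific heat must be positive")
        if self.pressure_at_boiling is not None and self.pressure_at_boiling <= 0:
            raise DomainError("pressure at boiling must be positive")


#: PF-5060 with the documented constants.
PF5060 = ExpansionFluid(
    name="PF-5060",
    boiling_temp_c=56.0,
    density=1.68,
    specific_heat=1.05,
    pressure_at_boiling=101325.0,
)


def vapor_pressure(fluid: ExpansionFluid, temperature_c: float) -> float:
    """Clausius–Clapeyron vapor pressure of the fluid at ``temperature_c``.

    P = P_boil · exp(ΔH_vap/R · (1/T_boil − 1/T)), temperatures in kelvin.
    Strictly increasing in temperature for positive ΔH_vap.

    Returns pressure in Pa.
    """
    t_kelvin = temperature_c + CELSIUS_OFFSET
    if t_kelvin <= 0:
        raise DomainError("temperature must be above 0 K")
    if fluid.pressure_at_boiling is None:
        raise DomainError(f"{fluid.name}: pressure_at_boiling is not set")
    if fluid.vaporization_enthalpy is None:
        raise DomainError(f"{fluid.name}: vaporization_enthalpy is not set")
    t_boil = fluid.boiling_temp_c + CELSIUS_OFFSET
    exponent = fluid.vaporization_enthalpy / GAS_CONSTANT * (1.0 / t_boil - 1.0 / t_kelvin)
    return fluid.pressure_at_boiling * math.exp(exponent)


def convective_resistance(h: float, area: float) -> float:
    """Thermal resistance 1/(h·A) of a convective interface, K/W."""
    if h <= 0 or area <= 0:
        raise DomainError("h and area must be positive")
    return 1.0 / (h * area)


def conductive_resistance(k: float, thickness: float, area: float) -> float:
    """Thermal resistance L/(k·A) of a conductive wall, K/W."""
    if k <= 0 or area <= 0:
        raise DomainError("k and area must be positive")
    if thickness < 0:
        raise DomainError("thickness must be non-negative")
    return thickness / (k * area)


def parallel_resistance(r_a: float, r_b: float) -> float:
    """Two thermal resistances in parallel: r_a·r_b/(r_a + r_b)."""
    if r_a <= 0 or r_b <= 0:
        raise DomainError("resistances must be positive")
    return r_a * r_b / (r_a + r_b)


def heater_power(voltage: float, resistance: float) -> float:
    """Joule heating V²/R of the resistive heater, W."""
    if resistance <= 0:
        raise DomainError("resistance must be positive")
    return voltage * voltage / resistance


def fluid_heat_capacity(volume_ml: float, fluid: ExpansionFluid) -> float:
    """Lumped heat capacity C1 = v·d·c of the fluid charge, J/K."""
    if volume_ml < 0:
        raise DomainError("volume must be non-negative")
    return volume_ml * fluid.density * fluid.specific_heat


@dataclass(frozen=True)
class ThermalCircuit:
    """Lumped thermal RC model of the heated fluid cavity.

    The heater delivers ``heat_rate`` W into a fluid lump of heat capacity
    ``fluid_heat_capacity`` J/K; heat leaks to the surroundings through the
    convective air path (``conv_resistance_air``) in parallel with the
    conductive cavity wall (``cond_resistance_wall``). The heater-to-fluid
    resistance is stored for completeness but drops out of the solved
    first-order response, which depends only on Q, R2 and C1.
    """

    heater_voltage: float
    heater_resistance: float
    conv_resistance_fluid: float  # R1, K/W; informational
    conv_resistance_air: float  # R21, K/W
    cond_resistance_wall: float  # R22, K/W
    fluid_heat_capacity: float  # C1, J/K
    ambient_temp_c: float = 25.0
    heater_temp_c: float | None = None  # T0, informational

    def __post_init__(self) -> None:
        for r in (
            self.heater_resistance,
            self.conv_resistance_fluid,
            self.conv_resistance_air,
            self.cond_resistance_wall,
        ):
            if r <= 0:
                raise DomainError("all resistances must be positive")
        if self.fluid_heat_capacity <= 0:
            raise DomainError("fluid heat capacity must be positive")

    @property
    def heat_rate(self) -> float:
        """Q = V²/R, W."""
        return heater_power(self.heater_voltage, self.heater_resistance)

    @property
    def combined_resistance(self) -> float:
        """R2 = R21·R22/(R21 + R22), K/W."""
        return parallel_resistance(self.conv_resistance_air, self.cond_resistance_wall)

    @property
    def time_constant(self) -> float:
        """τ = R2·C1, s."""
        return self.combined_resistance * self.fluid_heat_capacity

    @property
    def steady_state_temp_c(self) -> float:
        """Asymptotic fluid temperature T_surr + Q·R2, °C."""
        return self.ambient_temp_c + self.heat_rate * self.combined_resistance


def circuit_from_geometry(
    *,
    heater_voltage: float = 6.0,
    heater_resistance: float = HEATER_PRESETS["design_20ohm"],
    fluid_volume_ml: float = 0.4,
    fluid: ExpansionFluid = PF5060,
    air_h: float = 20.0,
    wall_k: float = 0.2,
    wall_thickness: float = 0.009,
    membrane_area: float = 5.31e-4,
    heater_area: float = 5.31e-4,
    fluid_h: float = 500.0,
    ambient_temp_c: float = 25.0,
) -> ThermalCircuit:
    """Assemble a :class:`ThermalCircuit` from geometry and material inputs.

    Defaults reproduce the documented watch-type device: 6 V across a 20 Ω
    heater (1.8 W), a 5.31 cm² membrane losing heat to still air at
    h = 20 W/(m² K) in parallel with a 9 mm PMMA wall of conductivity
    0.2 W/(m K). The heater-to-fluid film coefficient ``fluid_h`` only sets
    the informational R1.
    """
    return ThermalCircuit(
        heater_voltage=heater_voltage,
        heater_resistance=heater_resistance,
        conv_resistance_fluid=convective_resistance(fluid_h, heater_area),
        conv_resistance_air=convective_resistance(air_h, membrane_area),
        cond_resistance_wall=conductive_resistance(wall_k, wall_thickness, membrane_area),
        fluid_heat_capacity=fluid_heat_capacity(fluid_volume_ml, fluid),
        ambient_temp_c=ambient_temp_c,
    )


def fluid_temperature(t: float, circuit: ThermalCircuit) -> float:
    """Fluid temperature (°C) after ``t`` seconds of constant heater drive.

    First-order step response T(t) = T_surr + Q·R2·(1 − exp(−t/(R2·C1))).
    """
    if t < 0:
        raise DomainError("time must be non-negative")
    q_r2 = circuit.heat_rate * circuit.combined_resistance
    return circuit.ambient_temp_c + q_r2 * (1.0 - math.exp(-t / circuit.time_constant))


def time_to_temperature(circuit: ThermalCircuit, target_c: float) -> float:
    """Seconds of heating needed for the fluid to reach ``target_c``.

    Closed-form inversion of the step response:
    t = −R2·C1·ln(1 − (T − T_surr)/(Q·R2)).

    Raises
    ------
    DomainError
        If the target lies below ambient.
    UnreachableTargetError
        If the target is at or above the steady-state asymptote.
    """
    if target_c < circuit.ambient_temp_c:
        raise DomainError("target below ambient temperature")
    q_r2 = circuit.heat_rate * circuit.combined_resistance
    rise = target_c - circuit.ambient_temp_c
    if rise >= q_r2:
        raise UnreachableTargetError(
            f"target {target_c} °C at or above steady state "
            f"{circuit.ambient_temp_c + q_r2:.2f} °C"
        )
    return -circuit.time_constant * math.log(1.0 - rise / q_r2)


@dataclass(frozen=True)
class PowerTrain:
    """Periodic on/off heater drive: ``on_power`` W for ``on_duration`` s,
    then 0 W for ``off_duration`` s."""

    on_power: float
    on_duration: float
    off_duration: float

    def __post_init__(self) -> None:
        if self.on_power < 0:
            raise DomainError("on_power must be non-negative")
        if self.on_duration <= 0 or self.off_duration < 0:
            raise DomainError("on_duration must be positive, off_duration non-negative")


#: Documented drive: 1.6 W for 30 s then 0 W for 90 s (2 min period, 0.4 W mean).
DEFAULT_POWER_TRAIN = PowerTrain(on_power=1.6, on_duration=30.0, off_duration=90.0)


def average_power(train: PowerTrain) -> float:
    """Duty-cycled mean power of the periodic drive, W."""
    period = train.on_duration + train.off_duration
    if period <= 0:
        raise DomainError("total period must be positive")
    return train.on_power * train.on_duration / period


def battery_life(capacity_mah: float, supply_voltage: float, train: PowerTrain) -> float:
    """Idealized constant-voltage battery life in hours.

    capacity [mAh] / mean current [mA], with mean current = 1000·P̄/V.
    Ignores voltage sag and conversion losses, so it is an upper-bound
    estimate. Zero average power returns ``math.inf`` (a sentinel, not an
    error: an idle device never drains the battery in this model).
    """
    if capacity_mah <= 0 or supply_voltage <= 0:
        raise DomainError("capacity and supply voltage must be positive")
    p_avg = average_power(train)
    if p_avg == 0:
        return math.inf
    return capacity_mah / (1000.0 * p_avg / supply_voltage)


@dataclass
class VolumeDesign:
    """Fluid-volume selection problem and (once solved) its outcome.

    The selected volume must reach the fluid boiling point within
    ``deadline_s`` and be at least the vapor volume swept by the membrane
    stroke, approximated as a cylinder π·(membrane_diameter/2)²·stroke.
    """

    candidate_volumes_ml: list[float]
    deadline_s: float = 16.0
    required_stroke_mm: float = 3.0
    membrane_diameter_mm: float = 13.0
    selected_volume_ml: float | None = None
    time_to_boiling_s: dict[float, float] = field(default_factory=dict)

    @property
    def required_displacement_ml(self) -> float:
        radius_mm = self.membrane_diameter_mm / 2.0
        return math.pi * radius_mm**2 * self.required_stroke_mm / 1000.0


def select_fluid_volume(
    design: VolumeDesign,
    fluid: ExpansionFluid = PF5060,
    **circuit_kwargs,
) -> VolumeDesign:
    """Pick the smallest candidate volume meeting deadline and stroke.

    For each candidate the fluid heat capacity, hence the RC time constant,
    scales with volume; the time to the fluid's boiling temperature is
    computed from the closed-form response. A candidate is feasible when
    that time is within ``design.deadline_s`` and the volume covers the
    membrane displacement requirement. Extra keyword arguments are passed
    to :func:`circuit_from_geometry` (heater preset, ambient, geometry).

    Returns the same ``design`` with ``selected_volume_ml`` and the
    per-volume boiling times filled in.

    Raises
    ------
    InfeasibleDesignError
        If no candidate satisfies both constraints.
    """
    if not design.candidate_volumes_ml:
        raise DomainError("candidate volume list is empty")
    if any(v <= 0 for v in design.candidate_volumes_ml):
        raise DomainError("candidate volumes must be positive")
    if design.deadline_s <= 0:
        raise DomainError("deadline must be positive")

    times: dict[float, float] = {}
    for volume in sorted(design.candidate_volumes_ml):
        circuit = circuit_from_geometry(
            fluid_volume_ml=volume, fluid=fluid, **circuit_kwargs
        )
        try:
            times[volume] = time_to_temperature(circuit, fluid.boiling_temp_c)
        except UnreachableTargetError:
            times[volume] = math.inf
    design.time_to_boiling_s = times

    needed = design.required_displacement_ml
    for volume in sorted(times):
        if times[volume] <= design.deadline_s and volume >= needed:
            design.selected_volume_ml = volume
            return design
    raise InfeasibleDesignError(
        f"no candidate in {sorted(times)} reaches {fluid.boiling_temp_c} °C "
        f"within {design.deadline_s} s while displacing ≥ {needed:.3f} ml"
    )
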