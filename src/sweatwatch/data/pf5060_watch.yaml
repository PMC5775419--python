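# Watch-type closed-chamber sweat-rate sensor: documented device constants.
# Units are embedded in the key names.
fluid:
  name: PF-5060                    # perfluorohexane expansion fluid
  boiling_temp_c: 56.0             # low boiling point chosen for low-power actuation
  density_g_per_ml: 1.68
  specific_heat_j_per_gk: 1.05
  pressure_at_boiling_pa: 101325.0 # vapor pressure equals 1 atm at the boiling point
  # vaporization enthalpy is not part of the device documentation; set it
  # explicitly before using the vapor-pressure model.

heater:
  voltage_v: 6.0                   # two CR2032 coin cells in series
  preset: design_20ohm             # 20 ohm: the nominal 1.8 W design drive
  presets:                         # alternative documented resistances
    design_20ohm: 20.0
    characterization_23ohm: 23.0
    methods_50ohm: 50.0

thermal:
  air_h_w_per_m2k: 20.0            # free-convection film coefficient, still air
  wall_k_w_per_mk: 0.2             # PMMA cavity wall conductivity
  wall_thickness_m: 0.009
  membrane_area_m2: 5.31e-4
  ambient_temp_c: 25.0

design:
  fluid_volume_ml: 0.4             # selected expansion-fluid charge
  candidate_volumes_ml: [0.2, 0.4, 0.6, 1.0]
  deadline_s: 16.0                 # time budget to reach boiling
  membrane_diameter_mm: 13.0
  stroke_mm: 3.0                   # required chamber travel

power_train:
  on_power_w: 1.6
  on_duration_s: 30.0
  off_duration_s: 90.0             # 2 min measurement period, 0.4 W average

battery:
  capacity_mah: 240.0              # CR2032
  supply_voltage_v: 6.0

sensor:
  humidity_sensitivity_pf_per_rh: 0.6
  temp_coefficient_pf_per_c: 0.16
  chamber_temp_low_c: 23.4         # chamber temperature before heating
  chamber_temp_high_c: 26.8        # peak chamber temperature in a cycle
  sampling_rate_hz: 8.0
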