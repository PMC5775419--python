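"""Synthetic generators for the closed-chamber measurement pipeline.

Everything the analysis consumes can be generated here with known ground
truth: cycle-structured capacitance traces, wet-cup calibration sweeps, and
multi-subject thermal-status study datasets.

A measurement cycle mimics the actuated chamber: during the 15 s skin
contact the chamber is sealed and humidity — hence the capacitance of the
polyimide humidity sensor — rises linearly at a rate proportional to the
sweat rate; when the actuator lifts the chamber, the accumulated humidity
ventilates and the capacitance relaxes exponentially back toward the
ambient baseline. The first 2 s of contact are mechanical stabilization;
only the following 13 s detection window carries the sweat-rate signal.

The generator separates the humidity component from a thermally induced
offset: the heater warms the chamber during the approach phase and the
temperature holds during contact, so the offset is constant inside the
detection window and does not bias the fitted slope — the behaviour the
physical sensor is designed to have.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DomainError

#: Artificial-skin sweep range, g/m²h (12 wet-cup reference points).
CALIBRATION_RANGE = (3.76, 137.68)
CALIBRATION_POINTS = 12


@dataclass(frozen=True)
class CycleTiming:
    """Schedule of one measurement cycle.

    A cycle lasts ``period_s`` (default 2 min). The chamber travels down
    during ``[0, contact_start_s)``, sits on the skin for
    ``contact_duration_s`` = stabilization + detection, then lifts and
    ventilates for the rest of the period. Sampling is uniform at
    ``sampling_rate_hz``.
    """

    period_s: float = 120.0
    contact_start_s: float = 15.0
    contact_duration_s: float = 15.0
    stabilization_s: float = 2.0
    detection_s: float = 13.0
    sampling_rate_hz: float = 8.0

    def __post_init__(self) -> None:
        if abs(self.stabilization_s + self.detection_s - self.contact_duration_s) > 1e-9:
            raise DomainError("stabilization + detection must equal contact duration")
        if self.contact_start_s + self.contact_duration_s > self.period_s:
            raise DomainError("contact phase must fit inside the period")
        if self.sampling_rate_hz <= 0:
            raise DomainError("sampling rate must be positive")

    @property
    def samples_per_cycle(self) -> int:
        return int(round(self.period_s * self.sampling_rate_hz))

    @property
    def detection_start_s(self) -> float:
        """Cycle-relative start of the detection window."""
        return self.contact_start_s + self.stabilization_s

    @property
    def contact_end_s(self) -> float:
        return self.contact_start_s + self.contact_duration_s


DEFAULT_TIMING = CycleTiming()


@dataclass(frozen=True)
class SensorTruth:
    """Ground-truth sensor parameters used by the generator.

    ``sensitivity`` is the capacitance rising rate per unit sweat rate,
    (pF/s)/(g/m²h); ``wind_factor`` multiplies it to emulate wind-dependent
    sensitivity bins. ``baseline_capacitance`` defaults to the humidity
    sensitivity (0.6 pF/%RH) times a 50 %RH ambient; saturation sits at the
    100 %RH level. ``recovery_tau`` is the ventilation time constant.
    """

    sensitivity: float = 0.0050  # (pF/s)/(g/m²h)
    humidity_sensitivity: float = 0.6  # pF/%RH
    ambient_rh: float = 50.0  # %RH
    baseline_offset: float = 0.0  # pF added to the RH baseline
    temp_coefficient: float = 0.16  # pF/°C
    temp_rise_c: float = 3.4  # chamber warm-up amplitude, 23.4 → 26.8 °C
    noise_sd: float = 0.05  # pF
    recovery_tau: float = 42.2  # s; 85% recovery in 80 s
    wind_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.sensitivity <= 0:
            raise DomainError("sensitivity must be positive")
        if self.noise_sd < 0:
            raise DomainError("noise sd must be non-negative")
        if self.recovery_tau <= 0:
            raise DomainError("recovery tau must be positive")
        if self.saturation_capacitance <= self.baseline_capacitance:
            raise DomainError("saturation must exceed baseline")

    @property
    def baseline_capacitance(self) -> float:
        return self.humidity_sensitivity * self.ambient_rh + self.baseline_offset

    @property
    def saturation_capacitance(self) -> float:
        """Capacitance at 100 %RH inside the sealed chamber."""
        return self.baseline_capacitance + self.humidity_sensitivity * (100.0 - self.ambient_rh)

    @property
    def effective_sensitivity(self) -> float:
        return self.wind_factor * self.sensitivity


DEFAULT_TRUTH = SensorTruth()


@dataclass
class CapacitanceTrace:
    """Uniformly sampled capacitance time series with provenance metadata."""

    times_s: np.ndarray
    capacitances_pf: np.ndarray
    sampling_rate_hz: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.capacitances_pf = np.asarray(self.capacitances_pf, dtype=float)
        if self.times_s.shape != self.capacitances_pf.shape:
            raise DomainError("times and capacitances must have equal length")

    def __len__(self) -> int:
        return self.times_s.size


@dataclass(frozen=True)
class WetCupSpec:
    """A wet-cup reference measurement: water mass loss through a
    semipermeable membrane over a known dish area and time."""

    water_mass_loss_g: float
    dish_area_m2: float
    elapsed_h: float

    def __post_init__(self) -> None:
        if self.dish_area_m2 <= 0 or self.elapsed_h <= 0:
            raise DomainError("dish area and elapsed time must be positive")
        if self.water_mass_loss_g < 0:
            raise DomainError("mass loss must be non-negative")


def wet_cup_sweat_rate(spec: WetCupSpec) -> float:
    """Reference sweat rate SR = W/(A·T) in g/m²h."""
    return spec.water_mass_loss_g / (spec.dish_area_m2 * spec.elapsed_h)


def _temperature_offset(t_rel: np.ndarray, timing: CycleTiming, truth: SensorTruth) -> np.ndarray:
    """Thermal capacitance offset within one cycle (cycle-relative times).

    The chamber warms linearly while the actuator drives it down, holds the
    peak temperature through the contact phase, then cools exponentially
    after release. Constant within the detection window by construction.
    """
    amplitude = truth.temp_coefficient * truth.temp_rise_c
    offset = np.empty_like(t_rel)
    approach = t_rel < timing.contact_start_s
    contact = (t_rel >= timing.contact_start_s) & (t_rel < timing.contact_end_s)
    release = t_rel >= timing.contact_end_s
    offset[approach] = amplitude * t_rel[approach] / timing.contact_start_s
    offset[contact] = amplitude
    offset[release] = amplitude * np.exp(
        -(t_rel[release] - timing.contact_end_s) / truth.recovery_tau
    )
    return offset


def simulate_trace(
    sweat_rate: float,
    truth: SensorTruth = DEFAULT_TRUTH,
    timing: CycleTiming = DEFAULT_TIMING,
    n_cycles: int = 3,
    seed: int | np.random.SeedSequence = 0,
) -> CapacitanceTrace:
    """Generate a cycle-structured capacitance trace with known truth.

    Within each contact window the humidity component rises linearly at
    ``wind_factor · sensitivity · sweat_rate`` pF/s from the level it had
    when the chamber sealed, clipped at the saturation capacitance; during
    release it relaxes exponentially toward the baseline with
    ``recovery_tau``. i.i.d. Gaussian noise of sd ``noise_sd`` is added per
    sample. Identical (parameters, seed) give an identical trace.
    """
    if sweat_rate < 0:
        raise DomainError("sweat rate must be non-negative")
    if n_cycles < 1:
        raise DomainError("n_cycles must be at least 1")
    rng = np.random.default_rng(seed)

    fs = timing.sampling_rate_hz
    n_per = timing.samples_per_cycle
    slope = truth.effective_sensitivity * sweat_rate
    t_rel = np.arange(n_per) / fs

    approach = t_rel < timing.contact_start_s
    contact = (t_rel >= timing.contact_start_s) & (t_rel < timing.contact_end_s)
    release = t_rel >= timing.contact_end_s

    base = truth.baseline_capacitance
    level = base  # humidity component at the start of the current cycle
    chunks = []
    for _ in range(n_cycles):
        humid = np.empty(n_per)
        humid[approach] = base + (level - base) * np.exp(-t_rel[approach] / truth.recovery_tau)
        seal_level = base + (level - base) * np.exp(-timing.contact_start_s / truth.recovery_tau)
        humid[contact] = np.minimum(
            seal_level + slope * (t_rel[contact] - timing.contact_start_s),
            truth.saturation_capacitance,
        )
        release_level = min(
            seal_level + slope * timing.contact_duration_s, truth.saturation_capacitance
        )
        humid[release] = base + (release_level - base) * np.exp(
            -(t_rel[release] - timing.contact_end_s) / truth.recovery_tau
        )
        level = base + (release_level - base) * np.exp(
            -(timing.period_s - timing.contact_end_s) / truth.recovery_tau
        )
        chunks.append(humid + _temperature_offset(t_rel, timing, truth))

    capacitance = np.concatenate(chunks)
    if truth.noise_sd > 0:
        capacitance = capacitance + rng.normal(0.0, truth.noise_sd, capacitance.size)
    times = np.arange(n_cycles * n_per) / fs
    seed_repr = seed if isinstance(seed, int) else None
    return CapacitanceTrace(
        times_s=times,
        capacitances_pf=capacitance,
        sampling_rate_hz=fs,
        metadata={
            "true_sweat_rate_gm2h": sweat_rate,
            "seed": seed_repr,
            "n_cycles": n_cycles,
            "wind_factor": truth.wind_factor,
            "timing": {
                "period_s": timing.period_s,
                "contact_start_s": timing.contact_start_s,
                "stabilization_s": timing.stabilization_s,
                "detection_s": timing.detection_s,
                "sampling_rate_hz": fs,
            },
        },
    )


def default_calibration_grid() -> np.ndarray:
    """12 log-spaced sweat rates spanning the artificial-skin range."""
    return np.geomspace(*CALIBRATION_RANGE, CALIBRATION_POINTS)


def simulate_calibration_set(
    sweat_rates: np.ndarray | list[float] | None = None,
    truth: SensorTruth = DEFAULT_TRUTH,
    timing: CycleTiming = DEFAULT_TIMING,
    replicates: int = 1,
    n_cycles: int = 1,
    seed: int = 0,
) -> list[tuple[float, CapacitanceTrace]]:
    """Simulate an artificial-skin calibration sweep.

    One trace per (sweat rate, replicate); replicates share the truth but
    draw independent noise. The default grid is 12 log-spaced points over
    3.76–137.68 g/m²h.
    """
    if sweat_rates is None:
        sweat_rates = default_calibration_grid()
    sweat_rates = np.asarray(sweat_rates, dtype=float)
    if sweat_rates.size == 0:
        raise DomainError("sweat rate list is empty")
    if np.any(sweat_rates <= 0):
        raise DomainError("sweat rates must be positive")
    children = np.random.SeedSequence(seed).spawn(sweat_rates.size * replicates)
    out = []
    for i, rate in enumerate(sweat_rates):
        for j in range(replicates):
            child = children[i * replicates + j]
            out.append((float(rate), simulate_trace(rate, truth, timing, n_cycles, child)))
    return out


#: Nine-point thermal sensation scale codes and labels.
THERMAL_LABELS = {
    -4: "very cold",
    -3: "cold",
    -2: "cool",
    -1: "slightly cool",
    0: "comfortable",
    1: "slightly warm",
    2: "warm",
    3: "hot",
    4: "very hot",
}

#: Documented mean sweat rates (g/m²h) for statuses 0..+3 in the seated
#: warm-up protocol; used as the default study design means.
STATUS_MEAN_SWEAT_RATES = {0: 13.40, 1: 26.04, 2: 50.95, 3: 109.57}


@dataclass(frozen=True)
class StudyDesign:
    """Design of a multi-subject thermal-status study.

    Subject-level mean sweat rates per status are drawn log-normally around
    ``status_means`` with the given between-subject coefficient of
    variation; each reading then scatters log-normally around the subject
    mean with ``within_subject_cv``. Sweat rates are positive, which is why
    the log-normal family is used.
    """

    n_subjects: int = 3
    status_means: dict[int, float] = field(
        default_factory=lambda: dict(STATUS_MEAN_SWEAT_RATES)
    )
    between_subject_cv: float = 0.323
    within_subject_cv: float = 0.10
    readings_per_status: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not set(self.status_means) <= set(THERMAL_LABELS):
            raise DomainError("status codes must lie in -4..+4")
        if self.readings_per_status < 3:
            raise DomainError("at least three readings per status are required")
        if self.between_subject_cv < 0 or self.within_subject_cv < 0:
            raise DomainError("coefficients of variation must be non-negative")
        if self.n_subjects < 1:
            raise DomainError("need at least one subject")


def _lognormal_around(rng: np.random.Generator, mean: float, cv: float, size=None):
    """Log-normal draw with the requested arithmetic mean and CV."""
    if cv == 0:
        return np.full(size, mean) if size is not None else mean
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def simulate_study(design: StudyDesign) -> list["SubjectSession"]:
    """Simulate per-subject sweat-rate readings across thermal statuses.

    Returns one :class:`~sweatwatch.comfort.SubjectSession` per subject,
    fully determined by the design (including its seed).
    """
    from .comfort import SubjectSession, ThermalStatus

    rng = np.random.default_rng(design.seed)
    sessions = []
    for s in range(design.n_subjects):
        records = []
        for code in sorted(design.status_means):
            subj_mean = _lognormal_around(
                rng, design.status_means[code], design.between_subject_cv
            )
            readings = _lognormal_around(
                rng, subj_mean, design.within_subject_cv, size=design.readings_per_status
            )
            records.append((ThermalStatus(code), [float(r) for r in readings]))
        sessions.append(SubjectSession(subject_id=f"S{s + 1}", records=records))
    return sessions


def truth_for_wind_bin(truth: SensorTruth, factor: float) -> SensorTruth:
    """Copy of ``truth`` with its sensitivity scaled by a wind-bin factor."""
    return replace(truth, wind_factor=factor)
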