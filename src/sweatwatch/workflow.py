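"""Run configuration and the end-to-end pipeline.

A single :class:`RunConfig` (YAML-loadable, strictly validated) drives the
full chain simulate → extract → calibrate → analyze. All randomness flows
from one seed through named per-stage substreams, so any stage can be
re-run independently and the whole run is reproducible bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .actuator import (
    DEFAULT_POWER_TRAIN,
    HEATER_PRESETS,
    PF5060,
    VolumeDesign,
    average_power,
    battery_life,
    select_fluid_volume,
)
from .calibration import (
    CalibrationPoint,
    fit_calibration,
    temperature_offset,
    wind_robustness,
)
from .comfort import mean_cv, pooled_differences, status_statistics, summaries_from_moments
from .errors import FormatError
from . import io as swio
from .pipeline import extract_rates
from .synth import (
    CycleTiming,
    SensorTruth,
    StudyDesign,
    simulate_calibration_set,
    simulate_study,
    truth_for_wind_bin,
)

#: Named per-stage substreams of the run seed.
_STAGES = {"simulate": 1, "study": 2, "windbins": 3}

#: Device reference figures the end-to-end report compares against:
#: duty-cycled mean power, within-cycle capacitance offset and its %RH
#: equivalent, the wind-bin sensitivity spread, and the three-subject
#: study's pooled adjacent-status difference and mean inter-subject CV.
REFERENCE_VALUES = {
    "average_power_w": 0.4,
    "temp_offset_pf": 0.5,
    "temp_offset_rh_pct": 0.8,
    "wind_sensitivity_diff_pct": 8.2,
    "pooled_diff_mean_gm2h": 32.06,
    "pooled_diff_sd_gm2h": 27.19,
    "mean_intersubject_cv_pct": 32.3,
}

#: Documented wind-bin sensitivities, (pF/s)/(g/m²h), for the three air
#: velocity ranges 0–0.5, 0.5–1.0 and 1.0–1.5 m/s.
WIND_BIN_SENSITIVITIES = {"0-0.5 m/s": 0.0049, "0.5-1.0 m/s": 0.0050, "1.0-1.5 m/s": 0.0053}


def stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Deterministic named substream of the run seed."""
    return np.random.SeedSequence([seed, _STAGES[stage]])


def stage_seed_int(seed: int, stage: str) -> int:
    """31-bit integer form of a stage substream, for APIs taking ints."""
    return int(stage_seed(seed, stage).generate_state(1)[0] % (2**31))


class TruthConfig(BaseModel):
    """Overrides for the synthetic sensor ground truth."""

    model_config = ConfigDict(extra="forbid")
    sensitivity: float = 0.0050
    humidity_sensitivity: float = 0.6
    ambient_rh: float = 50.0
    baseline_offset: float = 0.0
    temp_coefficient: float = 0.16
    temp_rise_c: float = 3.4
    noise_sd: float = 0.05
    recovery_tau: float = 42.2
    wind_factor: float = 1.0

    def build(self) -> SensorTruth:
        return SensorTruth(**self.model_dump())


class TimingConfig(BaseModel):
    """Overrides for the measurement-cycle schedule."""

    model_config = ConfigDict(extra="forbid")
    period_s: float = 120.0
    contact_start_s: float = 15.0
    contact_duration_s: float = 15.0
    stabilization_s: float = 2.0
    detection_s: float = 13.0
    sampling_rate_hz: float = 8.0

    def build(self) -> CycleTiming:
        return CycleTiming(**self.model_dump())


class StudyConfig(BaseModel):
    """Overrides for the synthetic thermal-status study."""

    model_config = ConfigDict(extra="forbid")
    n_subjects: int = Field(default=3, ge=1)
    between_subject_cv: float = Field(default=0.323, ge=0)
    within_subject_cv: float = Field(default=0.10, ge=0)
    readings_per_status: int = Field(default=3, ge=3)

    def build(self, seed: int) -> StudyDesign:
        return StudyDesign(seed=seed, **self.model_dump())


class RunConfig(BaseModel):
    """Top-level configuration of an end-to-end run.

    Unknown keys are rejected so that typos surface as validation errors
    naming the offending key.
    """

    model_config = ConfigDict(extra="forbid")
    heater_preset: str = "design_20ohm"
    seed: int = Field(default=0, ge=0)
    out_dir: Path = Path("runs")
    calibration_replicates: int = Field(default=1, ge=1)
    truth: TruthConfig = TruthConfig()
    timing: TimingConfig = TimingConfig()
    study: StudyConfig = StudyConfig()

    @field_validator("heater_preset")
    @classmethod
    def _known_preset(cls, v: str) -> str:
        if v not in HEATER_PRESETS:
            raise ValueError(f"unknown heater preset {v!r}; choose from {sorted(HEATER_PRESETS)}")
        return v

    @property
    def heater_resistance(self) -> float:
        return HEATER_PRESETS[self.heater_preset]

    def config_hash(self) -> str:
        payload = self.model_dump_json().encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML/JSON run configuration; an empty file means all defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise FormatError(f"{path}: cannot parse configuration: {exc}") from exc
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: configuration must be a mapping")
    return RunConfig.model_validate(raw)


def design_report(config: RunConfig) -> dict:
    """Actuator design summary: volume selection, power and battery budget."""
    design = select_fluid_volume(
        VolumeDesign(candidate_volumes_ml=[0.2, 0.4, 0.6, 1.0]),
        fluid=PF5060,
        heater_resistance=config.heater_resistance,
    )
    return {
        "selected_volume_ml": design.selected_volume_ml,
        "time_to_boiling_s": {f"{v:g}": t for v, t in design.time_to_boiling_s.items()},
        "required_displacement_ml": design.required_displacement_ml,
        "average_power_w": average_power(DEFAULT_POWER_TRAIN),
        "battery_life_h": battery_life(240.0, 6.0, DEFAULT_POWER_TRAIN),
    }


def _close(a: float, b: float, tol: float = 0.05) -> bool:
    return abs(a - b) <= tol


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate → extract → calibrate → analyze and write a report.

    Every stage's inputs and outputs are persisted under ``config.out_dir``;
    the returned report includes recovery checks (does the fitted
    calibration recover the generator truth?) and comparisons of the
    fixture-derived statistics against the device reference figures.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = config.truth.build()
    timing = config.timing.build()

    # simulate + extract + calibrate
    sweep = simulate_calibration_set(
        truth=truth,
        timing=timing,
        replicates=config.calibration_replicates,
        seed=stage_seed_int(config.seed, "simulate"),
    )
    points = []
    for i, (rate, trace) in enumerate(sweep):
        swio.write_trace_csv(trace, out / f"trace_{i:02d}.csv")
        for result in extract_rates(trace, timing):
            if not result.saturated:
                points.append(CalibrationPoint(rate, result.slope_pf_per_s))
    swio.write_points_csv(points, out / "calibration_points.csv")
    curve = fit_calibration(points)
    swio.write_calibration_json(curve, out / "calibration.json")

    # wind robustness from the documented per-bin sensitivities
    bin_curves = []
    wind_seed = stage_seed(config.seed, "windbins")
    for (label, sens), child in zip(
        WIND_BIN_SENSITIVITIES.items(), wind_seed.spawn(len(WIND_BIN_SENSITIVITIES))
    ):
        bin_truth = truth_for_wind_bin(truth, sens / truth.sensitivity)
        bin_sweep = simulate_calibration_set(
            truth=bin_truth, timing=timing, seed=int(child.generate_state(1)[0] % 2**31)
        )
        bin_points = [
            CalibrationPoint(rate, r.slope_pf_per_s)
            for rate, tr in bin_sweep
            for r in extract_rates(tr, timing)
            if not r.saturated
        ]
        bin_curves.append((label, fit_calibration(bin_points)))
    sens_diff_pct, lin_diff_pct = wind_robustness(bin_curves)

    # synthetic study + analysis
    sessions = simulate_study(config.study.build(stage_seed_int(config.seed, "study")))
    swio.write_study_csv(sessions, out / "study.csv")
    summaries, study_cv = status_statistics(sessions)
    pooled_mean, pooled_sd, n_diffs = pooled_differences(sessions)

    # fixture statistics against the device reference figures
    fixture_diffs, fixture_moments = swio.load_human_fixture()
    from .comfort import difference_stats

    all_diffs = [d for diffs in fixture_diffs.values() for d in diffs]
    fix_mean, fix_sd = difference_stats(all_diffs)
    fix_cv = mean_cv(summaries_from_moments(fixture_moments))
    offset_pf, offset_rh = temperature_offset(truth.temp_coefficient, 23.4, 26.8,
                                              truth.humidity_sensitivity)

    ref = REFERENCE_VALUES
    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "design": design_report(config),
        "calibration": {
            "sensitivity": curve.sensitivity,
            "linearity_pct": curve.linearity_pct,
            "uncertainty_gm2h": curve.uncertainty_gm2h,
            "lod_gm2h": curve.lod_gm2h,
            "n_points": curve.n_points,
            "truth_sensitivity": truth.effective_sensitivity,
            "recovered": _close(
                curve.sensitivity / truth.effective_sensitivity, 1.0, 0.05
            ),
        },
        "wind": {
            "sensitivity_diff_pct": sens_diff_pct,
            "linearity_diff_pct": lin_diff_pct,
            "matches_reference": _close(sens_diff_pct, ref["wind_sensitivity_diff_pct"], 0.5),
        },
        "temperature_offset": {
            "offset_pf": offset_pf,
            "rh_equivalent_pct": offset_rh,
            "matches_reference": offset_pf == ref["temp_offset_pf"]
            and offset_rh == ref["temp_offset_rh_pct"],
        },
        "study": {
            "summaries": [
                {
                    "status": s.status.code,
                    "label": s.status.label,
                    "mean_gm2h": s.mean_gm2h,
                    "sd_gm2h": s.sd_gm2h,
                    "cv_pct": s.cv_pct,
                    "n_subjects": s.n_subjects,
                }
                for s in summaries
            ],
            "mean_cv_pct": study_cv,
            "pooled_diff_mean_gm2h": pooled_mean,
            "pooled_diff_sd_gm2h": pooled_sd,
            "n_differences": n_diffs,
        },
        "fixture": {
            "pooled_diff_mean_gm2h": fix_mean,
            "pooled_diff_sd_gm2h": fix_sd,
            "mean_cv_pct": fix_cv,
            "matches_reference": _close(fix_mean, ref["pooled_diff_mean_gm2h"], 0.005)
            and _close(fix_sd, ref["pooled_diff_sd_gm2h"], 0.005)
            and _close(fix_cv, ref["mean_intersubject_cv_pct"], 0.05),
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
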