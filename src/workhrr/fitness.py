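"""Submaximal cycle-ergometer estimation of maximal oxygen uptake.

The Åstrand–Ryhming method extrapolates the linear heart-rate–oxygen-uptake
relation measured at one submaximal steady state to the sex-specific
reference maximal heart rate.  With the oxygen cost of cycling taken as
VO2 = 0.002 L/min per kpm/min + 0.3 L/min of resting metabolism, the
estimate is

    VO2max = VO2(workload) * (HRref - HR0) / (HRss - HR0)

with (HR0, HRref) = (61, 195) beats/min for men and (72, 198) for women,
multiplied by the published age-correction factor (reference age 25).
Steady-state heart rates are only accepted inside the nomogram's tabulated
band of 120-170 beats/min; no extrapolation outside it.

Protocol rules: a test is steady once the heart rate changes by less than
5 beats/min between minutes 5 and 6 (later consecutive minutes are checked
the same way up to the 10-min cap); a first-minute heart rate below
110 beats/min triggers a power increase targeting at least 60% of the
age-predicted maximum or 120 beats/min, whichever is higher.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .hrr import hr_max_tanaka

KPM_PER_WATT = 6.12
VO2_L_PER_KPM = 0.002
VO2_REST_L = 0.3

#: (extrapolation intercept HR0, reference maximal HR) per sex.
HR_ANCHORS = {"male": (61.0, 195.0), "female": (72.0, 198.0)}

#: Tabulated steady-state heart-rate band of the nomogram.
HR_TABLE_RANGE = (120.0, 170.0)

#: Age-correction factors (reference age 25 -> factor 1.0), linearly
#: interpolated between tabulated ages and clamped at the table ends.
AGE_CORRECTION_TABLE = (
    (15.0, 1.10),
    (25.0, 1.00),
    (35.0, 0.87),
    (40.0, 0.83),
    (45.0, 0.78),
    (50.0, 0.75),
    (55.0, 0.71),
    (60.0, 0.68),
    (65.0, 0.65),
)

STEADY_STATE_TOL_BPM = 5.0
MAX_TEST_MINUTES = 10
ADJUSTMENT_HR_BPM = 110.0


class HrOutOfRange(ValueError):
    """Steady-state heart rate outside the tabulated nomogram band."""


@dataclass
class ErgometerTest:
    """One submaximal test: final power, per-minute HR readings, subject data."""

    power_w: float
    hr_readings: list[float]
    sex: str
    age: float
    body_mass: float
    cadence: float = 60.0
    power_adjusted: bool = False

    def __post_init__(self) -> None:
        if self.power_w <= 0:
            raise ValueError("power must be positive")
        if self.sex not in HR_ANCHORS:
            raise ValueError(f"unknown sex {self.sex!r}")
        if len(self.hr_readings) > MAX_TEST_MINUTES:
            raise ValueError("a test lasts at most 10 minutes")
        for hr in self.hr_readings:
            if not 30.0 < hr < 220.0:
                raise ValueError(f"implausible HR reading {hr}")


@dataclass
class FitnessResult:
    vo2max_abs: Optional[float]
    vo2max_rel: Optional[float]
    steady_state: bool
    power_adjusted: bool
    termination_minute: Optional[int]
    reason: str = ""


def steady_state_reached(hr_min5: Optional[float], hr_min6: Optional[float]) -> bool:
    """Change of strictly less than 5 beats/min between two consecutive minutes."""
    if hr_min5 is None or hr_min6 is None:
        return False
    return abs(hr_min6 - hr_min5) < STEADY_STATE_TOL_BPM


def power_adjustment_needed(hr_min1: float, est_hr_max: float) -> Optional[float]:
    """Target HR when the first-minute reading is below 110 beats/min, else None."""
    if hr_min1 >= ADJUSTMENT_HR_BPM:
        return None
    return max(0.6 * est_hr_max, 120.0)


def watts_to_kpm(power_w: float) -> float:
    return power_w * KPM_PER_WATT


def vo2_at_workload(kpm_per_min: float) -> float:
    """Submaximal oxygen uptake (L/min) at a cycling workload."""
    return VO2_L_PER_KPM * kpm_per_min + VO2_REST_L


def age_correction(age: float) -> float:
    ages, factors = zip(*AGE_CORRECTION_TABLE)
    return float(np.interp(age, ages, factors))


def nomogram_vo2max(power_w: float, hr_ss: float, sex: str) -> float:
    """Uncorrected maximal oxygen uptake (L/min) from power and steady-state HR."""
    if not HR_TABLE_RANGE[0] <= hr_ss <= HR_TABLE_RANGE[1]:
        raise HrOutOfRange(
            f"steady-state HR {hr_ss:.0f} outside tabulated range {HR_TABLE_RANGE}"
        )
    hr0, hr_ref = HR_ANCHORS[sex]
    vo2_sub = vo2_at_workload(watts_to_kpm(power_w))
    return vo2_sub * (hr_ref - hr0) / (hr_ss - hr0)


def estimate_vo2max(test: ErgometerTest) -> FitnessResult:
    """Full estimate from a test record: steady-state check, nomogram, age correction.

    The steady-state heart rate is the mean of the two consecutive readings
    that satisfied the termination rule (earliest pair from minutes 5-6 on).
    """
    readings = test.hr_readings
    term = None
    for m in range(6, len(readings) + 1):  # minute index, 1-based
        if steady_state_reached(readings[m - 2], readings[m - 1]):
            term = m
            break
    if term is None:
        return FitnessResult(None, None, False, test.power_adjusted, None,
                             reason="no steady state within 10 min")
    hr_ss = 0.5 * (readings[term - 2] + readings[term - 1])
    try:
        vo2_abs = nomogram_vo2max(test.power_w, hr_ss, test.sex) * age_correction(test.age)
    except HrOutOfRange as exc:
        return FitnessResult(None, None, True, test.power_adjusted, term, reason=str(exc))
    return FitnessResult(
        vo2max_abs=vo2_abs,
        vo2max_rel=1000.0 * vo2_abs / test.body_mass,
        steady_state=True,
        power_adjusted=test.power_adjusted,
        termination_minute=term,
    )


def eligible_for_fitness_test(
    systolic: Optional[float] = None,
    diastolic: Optional[float] = None,
    angina: bool = False,
    heart_lung_medication: bool = False,
    disc_herniation: bool = False,
    low_back_pain: bool = False,
    fever: bool = False,
    pregnancy: bool = False,
) -> bool:
    """Screening rule for the ergometer test (clinical fields supplied separately)."""
    if systolic is not None and systolic >= 160:
        return False
    if diastolic is not None and diastolic >= 100:
        return False
    return not (angina or heart_lung_medication or disc_herniation or low_back_pain
                or fever or pregnancy)


@dataclass
class ProtocolConfig:
    """Simulated session settings: starting power, HR kinetics, reading noise."""

    initial_power_w: float = 70.0
    power_step_w: float = 5.0
    tau_min: float = 1.2
    hr_rest: float = 70.0
    target_margin_bpm: float = 8.0
    noise_sd: float = 0.0


def _steady_hr_for(power_w: float, sex: str, age: float, vo2max_abs: float) -> float:
    """Physiological steady-state HR implied by a worker's true capacity.

    Inverts the full estimator (including the age correction), so a noiseless
    session round-trips to the true value.
    """
    hr0, hr_ref = HR_ANCHORS[sex]
    uncorrected = vo2max_abs / age_correction(age)
    return hr0 + vo2_at_workload(watts_to_kpm(power_w)) * (hr_ref - hr0) / uncorrected


def simulate_test_session(
    worker: pd.Series,
    protocol: Optional[ProtocolConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[ErgometerTest, FitnessResult]:
    """Run a simulated ergometer session for one worker and estimate fitness.

    Per-minute readings approach the steady state exponentially; the power
    adjustment rule is applied after minute 1 and the test terminates at the
    first steady pair from minute 6 on (10-min cap).
    """
    protocol = protocol or ProtocolConfig()
    sex = str(worker["sex"])
    age = float(worker["age"])
    mass = float(worker["body_mass"])
    true_abs = float(worker["vo2max_rel"]) * mass / 1000.0

    power = protocol.initial_power_w
    hr_ss = _steady_hr_for(power, sex, age, true_abs)
    adjusted = False

    readings: list[float] = []
    hr = protocol.hr_rest
    for minute in range(1, MAX_TEST_MINUTES + 1):
        hr = hr_ss - (hr_ss - hr) * math.exp(-1.0 / protocol.tau_min)
        reading = hr
        if protocol.noise_sd > 0 and rng is not None:
            reading += rng.normal(0.0, protocol.noise_sd)
        readings.append(float(np.clip(reading, 35.0, 215.0)))
        if minute == 1:
            target = power_adjustment_needed(readings[0], hr_max_tanaka(age))
            if target is not None:
                # smallest power step reaching the target with a safety margin
                hr0, hr_ref = HR_ANCHORS[sex]
                uncorrected = true_abs / age_correction(age)
                need_vo2 = (target + protocol.target_margin_bpm - hr0) * uncorrected / (hr_ref - hr0)
                need_w = (max(need_vo2 - VO2_REST_L, 0.05) / VO2_L_PER_KPM) / KPM_PER_WATT
                new_power = math.ceil(need_w / protocol.power_step_w) * protocol.power_step_w
                if new_power > power:
                    power = new_power
                    hr_ss = _steady_hr_for(power, sex, age, true_abs)
                    adjusted = True
        if minute >= 6 and steady_state_reached(readings[-2], readings[-1]):
            break

    test = ErgometerTest(
        power_w=power, hr_readings=readings, sex=sex, age=age, body_mass=mass,
        power_adjusted=adjusted,
    )
    return test, estimate_vo2max(test)
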