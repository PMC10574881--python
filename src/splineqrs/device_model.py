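"""Closed-form device arithmetic and the real-time alarm engine.

Covers the monitor's full-scale/resolution relations, the battery-life
projection, the electrode lead-off status decoding and the visual/acoustic
alarm logic.  The analog lead-off excitation itself (a small DC current
injected through the right-leg electrode) lives in the front-end chip; only
the resulting per-electrode status bits are modeled here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .record_format import DeviceSpec

__all__ = [
    "PowerBudget",
    "AlarmInputs",
    "AlarmState",
    "ELECTRODES",
    "full_scale_range",
    "battery_life_h",
    "update_alarms",
    "leadoff_from_status",
    "HR_ALARM_RANGE_BPM",
    "HR_ALARM_DEBOUNCE_BEATS",
]

#: Electrode order of the status word, least-significant bit first.
ELECTRODES = ("RL", "LL", "LA", "RA", "V2")

#: Heart rates outside this closed range raise the HR alarm.
HR_ALARM_RANGE_BPM = (60.0, 100.0)

#: Consecutive out-of-range beats required before the HR alarm raises
#: (suppresses single ectopic beats).
HR_ALARM_DEBOUNCE_BEATS = 3


@dataclass(frozen=True)
class PowerBudget:
    """Supply and battery figures for the battery-life projection.

    Defaults are the monitor's worst-case numbers: constant 50 mA draw from
    a 3.3 V supply, fed by a 3000 mAh / 3.7 V Li-ion cell of which ~70% is
    usable before the low-voltage protection cuts out.
    """

    supply_current_ma: float = 50.0
    supply_voltage_v: float = 3.3
    battery_capacity_mah: float = 3000.0
    battery_voltage_v: float = 3.7
    usable_fraction: float = 0.70

    def __post_init__(self) -> None:
        vals = (
            self.supply_current_ma,
            self.supply_voltage_v,
            self.battery_capacity_mah,
            self.battery_voltage_v,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all power-budget figures must be positive")
        if not (0 < self.usable_fraction <= 1):
            raise ValueError("usable_fraction must be in (0, 1]")


@dataclass(frozen=True)
class AlarmInputs:
    """Sensor snapshot fed to the alarm engine."""

    electrode_status_word: int = 0
    sd_connected: bool = True
    sd_full: bool = False
    acquiring: bool = True
    hr_bpm: float | None = None
    battery_low: bool = False


@dataclass(frozen=True)
class AlarmState:
    """Visual and acoustic alarm outputs.

    The buzzer sounds iff an electrode fault, an SD disconnect during
    acquisition, a full SD card, or an out-of-range heart rate is active;
    a low battery raises only the visual alarm.
    """

    electrode_fault: tuple[bool, ...] = (False,) * len(ELECTRODES)
    sd_disconnected: bool = False
    sd_full: bool = False
    hr_out_of_range: bool = False
    low_battery: bool = False
    buzzer_on: bool = False
    hr_oor_count: int = 0  # debounce counter, part of the engine's only state


def full_scale_range(spec: DeviceSpec = DeviceSpec()) -> float:
    """Total differential input range ``2 v_ref / gain`` (i.e. ±v_ref/gain)."""
    return 2.0 * spec.v_ref / spec.gain


def battery_life_h(budget: PowerBudget = PowerBudget()) -> tuple[float, float]:
    """Theoretical and usable battery life in hours.

    ``theoretical = (capacity x battery_voltage) / (current x supply_voltage)``
    — 11,100 mWh / 165 mW = 67.27 h with the defaults — and the usable figure
    scales it by ``usable_fraction`` (47.09 h at 70%).
    """
    p_draw_mw = budget.supply_current_ma * budget.supply_voltage_v
    p_bank_mwh = budget.battery_capacity_mah * budget.battery_voltage_v
    theoretical = p_bank_mwh / p_draw_mw
    return theoretical, budget.usable_fraction * theoretical


def leadoff_from_status(status_word: int) -> dict[str, bool]:
    """Per-electrode fault booleans from the status bit field (bit set = fault)."""
    if status_word < 0 or status_word >= 2 ** len(ELECTRODES):
        raise ValueError(f"status word must fit in {len(ELECTRODES)} bits")
    return {name: bool(status_word >> i & 1) for i, name in enumerate(ELECTRODES)}


def update_alarms(state: AlarmState, inputs: AlarmInputs) -> AlarmState:
    """Advance the alarm engine by one input snapshot.

    Pure except for the HR debounce counter carried in ``state``: the HR
    alarm raises only after :data:`HR_ALARM_DEBOUNCE_BEATS` consecutive
    out-of-range values and clears on the first in-range one.
    """
    if inputs.hr_bpm is not None and inputs.hr_bpm < 0:
        raise ValueError("hr_bpm must be non-negative")
    faults = tuple(leadoff_from_status(inputs.electrode_status_word).values())

    lo, hi = HR_ALARM_RANGE_BPM
    if inputs.hr_bpm is not None and not (lo <= inputs.hr_bpm <= hi):
        count = state.hr_oor_count + 1
    else:
        count = 0
    hr_alarm = count >= HR_ALARM_DEBOUNCE_BEATS

    sd_disc = (not inputs.sd_connected) and inputs.acquiring
    buzzer = any(faults) or sd_disc or inputs.sd_full or hr_alarm
    return AlarmState(
        electrode_fault=faults,
        sd_disconnected=sd_disc,
        sd_full=inputs.sd_full,
        hr_out_of_range=hr_alarm,
        low_battery=inputs.battery_low,
        buzzer_on=buzzer,
        hr_oor_count=count,
    )
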