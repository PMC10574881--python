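"""Synthetic 3-lead ECG with exact beat ground truth.

Each beat is a sum of five Gaussian waves (P, Q, R, S, T) placed at RR
intervals drawn from a truncated normal distribution — the classic
Gaussian-template construction, chosen over dynamical-system generators
because every R-peak location is known analytically.  Per-lead amplitude
scaling approximates the DI / aVF / V2 projections of a normal axis; on top
of the clean templates the generator can add white noise (directly or via a
target SNR), sinusoidal baseline wander, 50/60 Hz powerline interference,
global QRS polarity inversion, and electrode lead-off episodes that
saturate the affected leads at the positive input rail.

Everything is reproducible from ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import DEFAULT_LEADS, EcgRecord

__all__ = [
    "Wave",
    "NoiseConfig",
    "SimConfig",
    "GroundTruth",
    "ELECTRODE_LEADS",
    "default_wave_params",
    "generate_ecg",
    "generate_hr_trace",
]

#: Which leads an electrode fault corrupts (DI = LA-RA, aVF uses LL,
#: RL is the reference for every lead).
ELECTRODE_LEADS = {
    "RA": ("DI", "aVF"),
    "LA": ("DI",),
    "LL": ("aVF",),
    "V2": ("V2",),
    "RL": ("DI", "aVF", "V2"),
}

#: Positive ADC rail in millivolts (full scale at unity gain), used for
#: lead-off saturation.
RAIL_MV = 2400.0

#: Shortest RR the generator will place (physiological floor, 200 bpm).
RR_FLOOR_MS = 300.0


@dataclass(frozen=True)
class Wave:
    """One Gaussian component of the beat template."""

    amplitude_mv: float
    offset_s: float  # center relative to the R peak
    width_s: float  # Gaussian sigma

    def __post_init__(self) -> None:
        if self.width_s <= 0:
            raise ValueError("wave width must be positive")


def default_wave_params() -> dict[str, dict[str, Wave]]:
    """Textbook lead-II-like morphology with per-lead amplitude scaling."""
    base = {
        "P": Wave(0.12, -0.180, 0.022),
        "Q": Wave(-0.15, -0.026, 0.010),
        "R": Wave(1.20, 0.000, 0.011),
        "S": Wave(-0.25, 0.026, 0.010),
        "T": Wave(0.35, 0.280, 0.045),
    }
    lead_scale = {"DI": 0.8, "aVF": 1.0, "V2": 1.4}
    return {
        lead: {
            name: Wave(w.amplitude_mv * s, w.offset_s, w.width_s)
            for name, w in base.items()
        }
        for lead, s in lead_scale.items()
    }


@dataclass(frozen=True)
class NoiseConfig:
    """Additive disturbances, all in millivolts."""

    white_sd_mv: float = 0.0
    baseline_amp_mv: float = 0.0
    baseline_freq_hz: float = 0.3
    powerline_amp_mv: float = 0.0
    powerline_freq_hz: float = 50.0


@dataclass
class SimConfig:
    """Generator settings; defaults give one clean minute at 70 bpm."""

    sampling_rate_hz: float = 1000.0
    duration_s: float = 60.0
    mean_hr_bpm: float = 70.0
    hr_sd_bpm: float = 0.0
    wave_params: dict[str, dict[str, Wave]] | None = None
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    snr_db: float | None = None  # overrides white_sd_mv when set
    invert_qrs: bool = False
    leadoff_episodes: list[tuple[str, float, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_hr_bpm <= 0 or self.duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("rate, duration and mean heart rate must be positive")
        if self.hr_sd_bpm < 0:
            raise ValueError("hr_sd_bpm must be non-negative")
        for electrode, start, end in self.leadoff_episodes:
            if electrode not in ELECTRODE_LEADS:
                raise ValueError(f"unknown electrode {electrode!r}")
            if not 0 <= start < end:
                raise ValueError("lead-off episode must have 0 <= start < end")


@dataclass
class GroundTruth:
    """Known beat and artifact locations of a generated record."""

    r_peak_indices: np.ndarray  # shared by all leads (beats are synchronous)
    rr_ms: np.ndarray
    leadoff_mask: dict[str, np.ndarray]

    def rr_series(self) -> np.ndarray:
        return self.rr_ms


def _beat_times(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """RR intervals: max(300 ms, Normal(60000/HR, jitter)) until the end."""
    rr_mean_ms = 60000.0 / config.mean_hr_bpm
    # beat-to-beat bpm jitter mapped to RR jitter at the operating point
    rr_sd_ms = 60000.0 * config.hr_sd_bpm / config.mean_hr_bpm**2
    times, t = [], 0.4  # first beat clear of the record edge
    margin = 0.4
    while t < config.duration_s - margin:
        times.append(t)
        rr = max(RR_FLOOR_MS, rng.normal(rr_mean_ms, rr_sd_ms)) if rr_sd_ms else rr_mean_ms
        t += rr / 1000.0
    return np.asarray(times)


def generate_ecg(config: SimConfig) -> tuple[EcgRecord, GroundTruth]:
    """Generate a 3-lead record and its ground truth.

    Returns the record with samples in volts and the per-beat/per-electrode
    truth.  With ``snr_db`` set, the white-noise level is computed per lead
    from the clean template power so that the record has exactly the
    requested signal-to-noise ratio (wander and powerline terms are extra).
    """
    fs = config.sampling_rate_hz
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(config.seed)
    waves = config.wave_params or default_wave_params()

    # beat centers quantized to the sample grid so R-peak truth is exact
    r_idx = np.round(_beat_times(config, rng) * fs).astype(int)
    beat_times = r_idx / fs

    signal_mv = np.zeros((n, len(DEFAULT_LEADS)))
    for col, lead in enumerate(DEFAULT_LEADS):
        x = signal_mv[:, col]
        for name, w in waves[lead].items():
            amp = w.amplitude_mv
            if config.invert_qrs and name in ("Q", "R", "S"):
                amp = -amp
            half = 6.0 * w.width_s  # truncation at 6 sigma, error < 2e-8
            for tc in beat_times:
                c = tc + w.offset_s
                i0 = max(0, int((c - half) * fs))
                i1 = min(n, int((c + half) * fs) + 1)
                x[i0:i1] += amp * np.exp(-((t[i0:i1] - c) ** 2) / (2.0 * w.width_s**2))

    clean_rms = np.sqrt(np.mean(signal_mv**2, axis=0))

    for col in range(signal_mv.shape[1]):
        if config.snr_db is not None:
            sd = clean_rms[col] / 10.0 ** (config.snr_db / 20.0)
        else:
            sd = config.noise.white_sd_mv
        if sd > 0:
            signal_mv[:, col] += rng.normal(0.0, sd, size=n)
    if config.noise.baseline_amp_mv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        wander = config.noise.baseline_amp_mv * np.sin(
            2 * np.pi * config.noise.baseline_freq_hz * t + phase
        )
        signal_mv += wander[:, None]
    if config.noise.powerline_amp_mv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        hum = config.noise.powerline_amp_mv * np.sin(
            2 * np.pi * config.noise.powerline_freq_hz * t + phase
        )
        signal_mv += hum[:, None]

    leadoff_mask = {e: np.zeros(n, dtype=bool) for e in ELECTRODE_LEADS}
    for electrode, start, end in config.leadoff_episodes:
        i0, i1 = int(start * fs), min(n, int(end * fs))
        leadoff_mask[electrode][i0:i1] = True
        for lead in ELECTRODE_LEADS[electrode]:
            signal_mv[i0:i1, DEFAULT_LEADS.index(lead)] = RAIL_MV

    record = EcgRecord(
        samples=signal_mv / 1000.0, sampling_rate_hz=fs, leads=DEFAULT_LEADS
    )
    truth = GroundTruth(
        r_peak_indices=r_idx,
        rr_ms=np.diff(r_idx) * 1000.0 / fs,
        leadoff_mask=leadoff_mask,
    )
    return record, truth


def generate_hr_trace(
    base_bpm: float = 75.0,
    n_beats: int = 60,
    excursions: list[tuple[int, int, float]] | None = None,
) -> np.ndarray:
    """Piecewise-constant beat-to-beat HR series for alarm-engine tests.

    ``excursions`` are ``(start_beat, end_beat, bpm)`` half-open spans that
    override the base rate, e.g. a scripted run above 100 bpm.
    """
    trace = np.full(n_beats, float(base_bpm))
    for start, end, bpm in excursions or []:
        trace[start:end] = bpm
    return trace
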