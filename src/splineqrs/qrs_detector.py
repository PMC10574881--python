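"""Streaming QRS detector on spline-CWT coefficients.

Each QRS complex maps, through the antisymmetric wavelet, to a modulus
pair — a positive maximum (Pmax) and a negative minimum (Pmin) — with a
zero crossing (P1) in between that marks the R/S peak.  The detector keeps
two adaptive threshold memories at 75% of the recent modulus amplitudes,
arms a candidate when the CWT exceeds either memory, and declares a beat
when moduli of opposite sign pair up within a short window.  The pairing is
order-agnostic: morphology changes (or a global polarity inversion) swap
which modulus comes first without affecting the P1 location.

Beat-to-beat timing is the P1-to-P1 distance (the RR interval); the
instantaneous heart rate is ``60000 / RR_ms``.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .containers import EcgRecord
from .spline_cwt import CWTConfig, build_spline_wavelet, cwt_filter

__all__ = [
    "DetectorState",
    "BeatEvent",
    "init_detector",
    "process_sample",
    "rr_to_hr",
    "detect_record",
]

#: Physiological blanking after a detected beat (also suppresses T waves).
REFRACTORY_MS = 200.0
#: Maximum Pmax-to-Pmin spacing accepted as one QRS (a QRS-width bound).
PAIRING_WINDOW_MS = 120.0
#: Fraction of the modulus amplitude the threshold memories hold.
THRESHOLD_FACTOR = 0.75
#: Exponential smoothing weight of the threshold update (adapts over ~4 beats).
THRESHOLD_ALPHA = 0.25
#: Threshold floor as a fraction of the learning-phase maximum modulus.
FLOOR_FRACTION = 0.01
#: With no beat for this multiple of the running mean RR, halve the memories.
MISSED_BEAT_FACTOR = 1.5


@dataclass(frozen=True)
class BeatEvent:
    """One detected beat.

    ``p1_index`` is the zero crossing between the modulus pair, in samples on
    the coefficient stream (compensated to the ECG time base by
    :func:`detect_record`).  ``rr_ms`` is absent for the first beat.
    ``pair_order`` records which modulus came first (``"max-first"`` or
    ``"min-first"``).
    """

    p1_index: int
    rr_ms: float | None
    hr_bpm: float | None
    pair_order: str


@dataclass
class DetectorState:
    """Mutable running state of one lead's streaming detector."""

    sampling_rate_hz: float
    learning_end_index: int
    blank_until: int
    refractory_samples: int
    pairing_window_samples: int
    abs_floor: float
    # threshold memories (valid after the learning phase)
    memory_pmax: float = 0.0
    memory_pmin: float = 0.0
    floor: float = 0.0
    learning: bool = True
    learn_max: float = 0.0
    learn_min: float = 0.0
    # candidate tracking
    pending_modulus: tuple[int, float, int] | None = None  # (sign, amplitude, index)
    excursion: tuple[int, float, int] | None = None  # (sign, peak value, peak index)
    last_p1_index: int | None = None
    refractory_until: int = -1
    next_decay_index: int | None = None
    rr_history_ms: deque = field(default_factory=lambda: deque(maxlen=8), repr=False)
    last_index: int = -1
    # ring buffer of recent coefficients for the zero-crossing search
    _buf: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self._buf is None:
            self._buf = np.zeros(max(int(self.sampling_rate_hz), 64))

    @property
    def mean_rr_samples(self) -> float:
        """Running mean RR in samples (defaults to 1 s before any beat)."""
        if self.rr_history_ms:
            rr_ms = sum(self.rr_history_ms) / len(self.rr_history_ms)
            return rr_ms * self.sampling_rate_hz / 1000.0
        return self.sampling_rate_hz


def init_detector(config: CWTConfig, learning_duration_s: float = 2.0) -> DetectorState:
    """Create detector state in its learning phase.

    During the first ``learning_duration_s`` seconds the extreme positive and
    negative CWT values seed the 75% threshold memories; no beats are emitted.
    The first ``delay_samples`` coefficients (zero-padded filter history) are
    blanked out of the learning statistics.
    """
    if learning_duration_s < 1:
        raise ValueError("learning_duration_s must be >= 1 s")
    fs = config.sampling_rate_hz
    kernel = build_spline_wavelet(config.resolved_scale)
    return DetectorState(
        sampling_rate_hz=fs,
        learning_end_index=int(round(learning_duration_s * fs)),
        blank_until=kernel.delay_samples,
        refractory_samples=int(round(REFRACTORY_MS * fs / 1000.0)),
        pairing_window_samples=int(round(PAIRING_WINDOW_MS * fs / 1000.0)),
        abs_floor=1e-12,
    )


def rr_to_hr(rr_ms: float) -> float:
    """Convert an RR interval in milliseconds to beats per minute."""
    if rr_ms <= 0:
        raise ValueError(f"rr_ms must be positive, got {rr_ms}")
    return 60000.0 / rr_ms


def _finish_learning(state: DetectorState) -> None:
    peak = max(state.learn_max, -state.learn_min, 0.0)
    state.floor = max(FLOOR_FRACTION * peak, state.abs_floor)
    state.memory_pmax = max(THRESHOLD_FACTOR * state.learn_max, state.floor)
    state.memory_pmin = min(THRESHOLD_FACTOR * state.learn_min, -state.floor)
    state.learning = False


def _find_p1(state: DetectorState, sign: int, i_from: int, i_to: int) -> int:
    """First zero crossing of the buffered CWT after the first modulus."""
    n = len(state._buf)
    for j in range(i_from + 1, i_to + 1):
        if sign * state._buf[j % n] <= 0.0:
            return j
    return (i_from + i_to) // 2  # no strict crossing buffered; use the midpoint


def _declare_beat(state: DetectorState, first, second) -> BeatEvent | None:
    sign1, amp1, i1 = first
    sign2, amp2, i2 = second
    p1 = _find_p1(state, sign1, i1, i2)
    if p1 < state.refractory_until:
        return None
    amp_pos = amp1 if sign1 > 0 else amp2
    amp_neg = amp1 if sign1 < 0 else amp2
    a = THRESHOLD_ALPHA
    state.memory_pmax = max(
        (1 - a) * state.memory_pmax + a * THRESHOLD_FACTOR * amp_pos, state.floor
    )
    state.memory_pmin = min(
        (1 - a) * state.memory_pmin + a * THRESHOLD_FACTOR * amp_neg, -state.floor
    )
    rr_ms = hr = None
    if state.last_p1_index is not None:
        rr_ms = (p1 - state.last_p1_index) * 1000.0 / state.sampling_rate_hz
        if rr_ms <= 0:
            return None
        hr = rr_to_hr(rr_ms)
        state.rr_history_ms.append(rr_ms)
    state.last_p1_index = p1
    state.refractory_until = p1 + state.refractory_samples
    period = int(round(MISSED_BEAT_FACTOR * state.mean_rr_samples))
    state.next_decay_index = p1 + max(period, 1)
    return BeatEvent(
        p1_index=p1,
        rr_ms=rr_ms,
        hr_bpm=hr,
        pair_order="max-first" if sign1 > 0 else "min-first",
    )


def process_sample(state: DetectorState, coeff: float, index: int) -> BeatEvent | None:
    """Advance the detector by one CWT coefficient.

    ``index`` must be strictly increasing across calls.  Returns a
    :class:`BeatEvent` when the second modulus of a pair is finalized,
    otherwise ``None``.
    """
    if index <= state.last_index:
        raise ValueError(f"sample index must be strictly increasing, got {index}")
    state.last_index = index
    state._buf[index % len(state._buf)] = coeff

    if state.learning:
        if index >= state.learning_end_index:
            _finish_learning(state)
        else:
            if index >= state.blank_until:
                if coeff > state.learn_max:
                    state.learn_max = coeff
                elif coeff < state.learn_min:
                    state.learn_min = coeff
            return None

    event = None

    if state.excursion is not None:
        sign, peak, ipeak = state.excursion
        beyond = coeff > state.memory_pmax if sign > 0 else coeff < state.memory_pmin
        if beyond:
            if sign * coeff > sign * peak:
                state.excursion = (sign, coeff, index)
        else:
            # modulus finalized: try to pair it with the previous one
            state.excursion = None
            modulus = (sign, peak, ipeak)
            pend = state.pending_modulus
            if (
                pend is not None
                and pend[0] != sign
                and ipeak - pend[2] <= state.pairing_window_samples
            ):
                event = _declare_beat(state, pend, modulus)
                state.pending_modulus = None
            else:
                state.pending_modulus = modulus

    if state.excursion is None:
        if coeff > state.memory_pmax:
            state.excursion = (1, coeff, index)
        elif coeff < state.memory_pmin:
            state.excursion = (-1, coeff, index)

    # stale candidates and dropout recovery
    pend = state.pending_modulus
    if pend is not None and index - pend[2] > state.pairing_window_samples:
        state.pending_modulus = None
    if state.next_decay_index is not None and index >= state.next_decay_index:
        state.memory_pmax = max(0.5 * state.memory_pmax, state.floor)
        state.memory_pmin = min(0.5 * state.memory_pmin, -state.floor)
        state.next_decay_index = index + max(
            int(round(MISSED_BEAT_FACTOR * state.mean_rr_samples)), 1
        )

    return event


def detect_record(
    record: EcgRecord, config: CWTConfig, learning_duration_s: float = 2.0
) -> list[list[BeatEvent]]:
    """Run the full chain — kernel, CWT, streaming detector — on every lead.

    Heart rate is computed independently for each lead.  Beat indices are
    compensated by the kernel group delay so that ``p1_index`` aligns with
    the R/S peak on the ECG time base.
    """
    kernel = build_spline_wavelet(config.resolved_scale)
    results: list[list[BeatEvent]] = []
    for col in range(record.n_leads):
        coeffs = cwt_filter(record.samples[:, col], kernel)
        state = init_detector(config, learning_duration_s)
        events: list[BeatEvent] = []
        step = process_sample
        for i in range(coeffs.shape[0]):
            ev = step(state, coeffs[i], i)
            if ev is not None:
                events.append(
                    BeatEvent(
                        p1_index=ev.p1_index - kernel.delay_samples,
                        rr_ms=ev.rr_ms,
                        hr_bpm=ev.hr_bpm,
                        pair_order=ev.pair_order,
                    )
                )
        results.append(events)
    return results
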