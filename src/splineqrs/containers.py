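"""Shared in-memory containers for multi-lead ECG."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Lead order used throughout: the three quasi-orthogonal leads recorded
#: by the monitor (frontal horizontal, frontal vertical, precordial).
DEFAULT_LEADS = ("DI", "aVF", "V2")


@dataclass
class EcgRecord:
    """A multi-lead ECG sample matrix.

    Attributes
    ----------
    samples
        Array of shape ``(n_samples, n_leads)`` in volts.
    sampling_rate_hz
        Sampling rate of every lead (all leads are sampled synchronously).
    leads
        Lead labels, one per column of ``samples``.
    adc_codes
        Optional integer ADC codes of shape ``(n_samples, n_leads)``.  When a
        record is read from (or destined for) the monitor's binary format the
        raw 24-bit codes are kept here so that write/read round-trips are
        bit-exact; ``samples`` then holds their voltage interpretation.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    leads: tuple[str, ...] = DEFAULT_LEADS
    adc_codes: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[1] != len(self.leads):
            raise ValueError(
                f"samples has {self.samples.shape[1]} columns "
                f"but {len(self.leads)} lead labels were given"
            )
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_leads(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def lead(self, name: str) -> np.ndarray:
        """Return one lead's sample vector by label."""
        return self.samples[:, self.leads.index(name)]
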