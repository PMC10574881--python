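"""Spline-wavelet CWT evaluated as a streaming FIR filter.

At a fixed integer scale ``a`` the continuous wavelet transform acts as a
bandpass filter.  The analysing wavelet here is the first derivative of a
fourth-order B-spline smoothing kernel, an antisymmetric single-cycle
wavelet: its response to a peaked deflection (a QRS complex) is a
positive/negative modulus pair with a zero crossing at the peak.  By the
B-spline derivative identity the prototype is evaluated as a half-sample
finite difference of cubic B-splines,

    psi(t) = d/dt B4(t) = B3(t + 1/2) - B3(t - 1/2),

supported on |t| <= 2.5.  The scale-``a`` kernel samples psi(t/a)/a at the
integers, so the passband scales as Fm/a: with the monitor's rate/scale
pairings (250 Hz, 2), (500 Hz, 4), (1000 Hz, 8) the -3 dB band stays at
~14.7-48.6 Hz, below the 50/60 Hz powerline components.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.interpolate import BSpline
from scipy.signal import freqz, lfilter

__all__ = [
    "CWTConfig",
    "WaveletKernel",
    "FrequencyBand",
    "build_spline_wavelet",
    "select_scale",
    "cwt_filter",
    "estimate_band",
    "TARGET_BAND_HZ",
]

#: Passband the monitor maintains across sampling rates (Hz): chosen so the
#: filter keeps QRS energy while rejecting 50/60 Hz interference.
TARGET_BAND_HZ = (14.4, 48.6)

#: Rate -> scale pairings used by the device.
_DEVICE_SCALES = {250.0: 2, 500.0: 4, 1000.0: 8}

# Centered cubic B-spline, support [-2, 2].
_B3 = BSpline.basis_element(np.arange(5.0) - 2.0, extrapolate=False)


def _b3(x: np.ndarray) -> np.ndarray:
    return np.nan_to_num(_B3(np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class WaveletKernel:
    """Sampled spline wavelet at one integer scale, used as an FIR kernel.

    ``taps`` are zero-mean and antisymmetric about the kernel center;
    ``delay_samples`` is the center index, i.e. the group delay between an
    ECG feature and the corresponding zero crossing of the filter output.
    """

    scale: int
    taps: np.ndarray
    delay_samples: int

    def __len__(self) -> int:
        return len(self.taps)


@dataclass(frozen=True)
class FrequencyBand:
    """A -3 dB passband in hertz."""

    fc_min_hz: float
    fc_max_hz: float

    @property
    def midpoint_hz(self) -> float:
        """Geometric band center."""
        return float(np.sqrt(self.fc_min_hz * self.fc_max_hz))


@dataclass
class CWTConfig:
    """Detector front-end configuration.

    ``scale`` may be an explicit positive integer or ``"auto"``, in which
    case it is chosen from the sampling rate via :func:`select_scale`.
    """

    sampling_rate_hz: float
    scale: int | str = "auto"
    _resolved: int = field(init=False, repr=False, default=0)

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.scale == "auto":
            self._resolved = select_scale(self.sampling_rate_hz)
        else:
            s = self.scale
            if not (isinstance(s, (int, np.integer)) and s >= 1):
                raise ValueError(f"scale must be 'auto' or a positive integer, got {s!r}")
            self._resolved = int(s)

    @property
    def resolved_scale(self) -> int:
        return self._resolved

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CWTConfig":
        """Load ``sampling_rate_hz`` and ``scale`` from a YAML file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            sampling_rate_hz=float(raw["sampling_rate_hz"]),
            scale=raw.get("scale", "auto"),
        )


@functools.lru_cache(maxsize=64)
def _cached_kernel(scale: int) -> WaveletKernel:
    n = np.arange(-int(np.ceil(2.5 * scale)), int(np.ceil(2.5 * scale)) + 1)
    taps = (_b3(n / scale + 0.5) - _b3(n / scale - 0.5)) / scale
    # trim exact-zero end taps so delay_samples is the true support center
    nz = np.nonzero(taps)[0]
    taps = taps[nz[0] : nz[-1] + 1]
    taps = taps - taps.mean()  # enforce zero mean against roundoff
    taps.setflags(write=False)
    return WaveletKernel(scale=scale, taps=taps, delay_samples=(len(taps) - 1) // 2)


def build_spline_wavelet(scale: int) -> WaveletKernel:
    """Sample the derivative-spline wavelet at an integer dilation.

    The returned taps are the time samples of ``psi(t/a)/a`` (L1-style ``1/a``
    normalisation, so modulus amplitudes stay comparable across scales).

    Parameters
    ----------
    scale
        Positive integer dilation ``a``; the kernel length grows linearly
        with it (support ``±2.5 a`` samples).
    """
    if not (isinstance(scale, (int, np.integer)) and not isinstance(scale, bool)):
        raise ValueError(f"scale must be a positive integer, got {scale!r}")
    if scale < 1:
        raise ValueError(f"scale must be >= 1, got {scale}")
    return _cached_kernel(int(scale))


def select_scale(sampling_rate_hz: float) -> int:
    """Choose the CWT scale whose passband best matches the target band.

    The device pairings 250/500/1000 Hz -> 2/4/8 are returned exactly; any
    other positive rate picks the integer scale whose band midpoint is
    closest to the 14.4-48.6 Hz target in log frequency.
    """
    if sampling_rate_hz <= 0:
        raise ValueError("sampling_rate_hz must be positive")
    if float(sampling_rate_hz) in _DEVICE_SCALES:
        return _DEVICE_SCALES[float(sampling_rate_hz)]
    target_mid = np.sqrt(TARGET_BAND_HZ[0] * TARGET_BAND_HZ[1])
    best, best_dist = 1, np.inf
    for scale in range(1, 129):
        band = estimate_band(build_spline_wavelet(scale), sampling_rate_hz)
        dist = abs(np.log(band.midpoint_hz) - np.log(target_mid))
        if dist < best_dist:
            best, best_dist = scale, dist
    return best


def cwt_filter(samples: np.ndarray, kernel: WaveletKernel) -> np.ndarray:
    """Run the CWT as a causal streaming filter.

    Each output sample depends only on the current and past inputs; the
    wavelet response trails the input feature by ``kernel.delay_samples``.
    A unit impulse reproduces the taps themselves, and any constant input
    maps to (numerically) zero because the kernel is zero-mean.  The first
    ``delay_samples`` outputs are computed against zero-padded history and
    should be ignored by downstream consumers (startup blanking).
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        return np.empty(0)
    return lfilter(kernel.taps, [1.0], x)


def estimate_band(
    kernel: WaveletKernel, sampling_rate_hz: float, n_grid: int = 8192
) -> FrequencyBand:
    """Measure the kernel's -3 dB cutoffs on a dense frequency grid.

    The magnitude response is evaluated at ``n_grid`` points up to Nyquist
    and the two half-power crossings around the peak are located by linear
    interpolation.
    """
    w, h = freqz(kernel.taps, worN=max(int(n_grid), 4096))
    mag = np.abs(h)
    ip = int(mag.argmax())
    thr = mag[ip] / np.sqrt(2.0)

    below = np.nonzero(mag[:ip] < thr)[0]
    i0 = int(below[-1]) if below.size else 0
    w_lo = np.interp(thr, [mag[i0], mag[i0 + 1]], [w[i0], w[i0 + 1]])

    above = np.nonzero(mag[ip:] < thr)[0]
    if above.size:
        i1 = ip + int(above[0])
        w_hi = np.interp(thr, [mag[i1], mag[i1 - 1]], [w[i1], w[i1 - 1]])
    else:  # band extends to Nyquist
        w_hi = w[-1]

    to_hz = sampling_rate_hz / (2.0 * np.pi)
    return FrequencyBand(fc_min_hz=float(w_lo * to_hz), fc_max_hz=float(w_hi * to_hz))
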