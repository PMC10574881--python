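"""Beat-detection scoring and device-agreement statistics.

Detections are matched one-to-one to reference annotations within a
tolerance window, giving sensitivity Se = TP/(TP+FN), positive
predictivity P+ = TP/(TP+FP) and the detection error
100·(FP+FN)/(TP+FN).  Paired RR series are compared with Bland–Altman
limits of agreement, and simultaneously digitized waveforms with a
lag-aligned Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MatchResult",
    "AgreementResult",
    "match_detections",
    "bland_altman",
    "align_and_correlate",
    "DEFAULT_MATCH_TOL_MS",
]

#: Beat-matching window (common convention for beat-by-beat comparison).
DEFAULT_MATCH_TOL_MS = 75.0


@dataclass(frozen=True)
class MatchResult:
    """TP/FP/FN counts with the derived detection statistics (percent)."""

    tp: int
    fp: int
    fn: int

    @property
    def se_pct(self) -> float:
        """Sensitivity 100·TP/(TP+FN)."""
        denom = self.tp + self.fn
        return 100.0 * self.tp / denom if denom else float("nan")

    @property
    def ppv_pct(self) -> float:
        """Positive predictivity 100·TP/(TP+FP)."""
        denom = self.tp + self.fp
        return 100.0 * self.tp / denom if denom else float("nan")

    @property
    def error_pct(self) -> float:
        """Detection error 100·(FP+FN)/(TP+FN)."""
        denom = self.tp + self.fn
        return 100.0 * (self.fp + self.fn) / denom if denom else float("nan")


@dataclass(frozen=True)
class AgreementResult:
    """Bland–Altman agreement of paired measurements (milliseconds)."""

    bias_ms: float
    loa_ms: float  # ±2·SD limits of agreement half-width
    r_pct: float | None = None
    lag_samples: int | None = None


def match_detections(
    truth_idx,
    detected_idx,
    sampling_rate_hz: float,
    tol_ms: float = DEFAULT_MATCH_TOL_MS,
) -> MatchResult:
    """Greedy one-to-one nearest matching of detections to annotations.

    Both index lists must be sorted.  Every unmatched annotation counts as a
    false negative and every unmatched detection as a false positive.
    """
    truth = np.asarray(truth_idx, dtype=float)
    det = np.asarray(detected_idx, dtype=float)
    for name, arr in (("truth_idx", truth), ("detected_idx", det)):
        if np.any(np.diff(arr) < 0):
            raise ValueError(f"{name} must be sorted")
    tol = tol_ms * sampling_rate_hz / 1000.0

    # candidate pairs sorted by |distance|, matched greedily one-to-one
    pairs = []
    j0 = 0
    for i, tv in enumerate(truth):
        j = np.searchsorted(det, tv - tol, side="left")
        while j < len(det) and det[j] <= tv + tol:
            pairs.append((abs(det[j] - tv), i, j))
            j += 1
    pairs.sort()
    used_t: set[int] = set()
    used_d: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i not in used_t and j not in used_d:
            used_t.add(i)
            used_d.add(j)
            tp += 1
    return MatchResult(tp=tp, fp=len(det) - tp, fn=len(truth) - tp)


def bland_altman(rr_a, rr_b) -> AgreementResult:
    """Bland–Altman agreement of two paired RR series.

    Bias is ``mean(a - b)``; the limits of agreement are ``±2·SD`` of the
    paired differences (sample SD, n−1 denominator).
    """
    a = np.asarray(rr_a, dtype=float)
    b = np.asarray(rr_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 paired values")
    d = a - b
    return AgreementResult(bias_ms=float(d.mean()), loa_ms=float(2.0 * d.std(ddof=1)))


def align_and_correlate(x, y, max_lag: int) -> tuple[int, float]:
    """Best alignment lag and Pearson correlation of two waveforms.

    Searches lags in ``[-max_lag, max_lag]`` for the maximum (absolute)
    cross-correlation of the mean-removed signals, then reports
    ``(lag_samples, 100 x Pearson r)`` over the overlapping span at that
    lag.  A positive lag means ``y`` trails ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    max_lag = int(max_lag)
    xc = x - x.mean()
    yc = y - y.mean()
    full = np.correlate(xc, yc, mode="full")  # index len(y)-1 is lag 0
    center = len(y) - 1
    lo = max(0, center - max_lag)
    hi = min(len(full), center + max_lag + 1)
    window = full[lo:hi]
    # shift d such that y[m] ~ x[m + d]; y trails x when d < 0
    d = int(np.argmax(np.abs(window)) + lo - center)
    lag = -d

    if d >= 0:
        xs, ys = x[d:], y
    else:
        xs, ys = x, y[-d:]
    m = min(len(xs), len(ys))
    xs, ys = xs[:m], ys[:m]
    if len(xs) < 2:
        raise ValueError("overlap at best lag is shorter than 2 samples")
    r = float(np.corrcoef(xs, ys)[0, 1])
    return lag, 100.0 * r
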