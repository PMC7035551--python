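"""ECG/PPG filtering, beat delineation and windowed PAT averaging.

The pulse arrival time (PAT) of a beat is the interval from the ECG R-peak
to the point of maximum first derivative on the rising edge of the same
beat's PPG pulse.  The stages here follow the standard wearable-BP
processing chain:

1. zero-phase band-pass filtering (ECG 1-40 Hz, PPG 0.5-20 Hz, 4th-order
   Butterworth sections applied forward-backward);
2. R-peak detection by thresholded local maxima with a 250 ms refractory
   period;
3. per-cycle search for the PPG maximum-slope point, restricted to the
   pulse rising edge (foot to peak) to avoid dicrotic-notch artefacts;
4. beat-wise PAT and 30-s window means (windows with fewer than eight
   cardiac cycles are discarded, since shorter averages are dominated by
   respiratory PAT modulation).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "PATSeries",
    "PATWindow",
    "filter_ecg",
    "filter_ppg",
    "detect_r_peaks",
    "detect_max_slope_points",
    "compute_pat_series",
    "average_pat_windows",
    "extract_pat_series",
]

logger = logging.getLogger(__name__)

#: Minimum cardiac cycles per window admitted to analysis.
MIN_BEATS_PER_WINDOW = 8

_REFRACTORY_S = 0.25


@dataclass(frozen=True)
class PATSeries:
    """Beat-wise PAT anchored at R-peak times."""

    beat_times: np.ndarray  # s
    pat: np.ndarray  # s

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_times, float)
        p = np.asarray(self.pat, float)
        if bt.shape != p.shape:
            raise ValueError("beat_times and pat must align")
        object.__setattr__(self, "beat_times", bt)
        object.__setattr__(self, "pat", p)


@dataclass(frozen=True)
class PATWindow:
    """Mean PAT over one analysis window (matched to a cuff measurement)."""

    t_start: float
    t_end: float
    pat_bar: float
    n_beats: int


def _bandpass(raw: np.ndarray, fs: float, low: float, high: float) -> np.ndarray:
    if fs <= 2 * high:
        raise ValueError(f"sampling rate {fs} Hz too low for {high} Hz low-pass")
    raw = np.asarray(raw, float)
    if raw.size == 0:
        return raw.copy()
    sos_hp = sps.butter(4, low, btype="highpass", fs=fs, output="sos")
    sos_lp = sps.butter(4, high, btype="lowpass", fs=fs, output="sos")
    out = sps.sosfiltfilt(sos_hp, raw)
    return sps.sosfiltfilt(sos_lp, out)


def filter_ecg(raw: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 1-40 Hz band-pass for the ECG channel."""
    if fs <= 80:
        raise ValueError("fs must exceed 80 Hz for ECG filtering")
    return _bandpass(raw, fs, 1.0, 40.0)


def filter_ppg(raw: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 0.5-20 Hz band-pass for the PPG channel."""
    return _bandpass(raw, fs, 0.5, 20.0)


def detect_r_peaks(ecg: np.ndarray, fs: float, t0: float = 0.0) -> np.ndarray:
    """Detect R-peaks as thresholded local maxima.

    The threshold adapts to the record: half of the 99th-percentile
    amplitude.  Peaks closer than the 250 ms refractory period are pruned,
    keeping the larger.  Returns peak times in seconds; warns (rather than
    silently returning nothing) when a nonempty record yields no peaks.
    """
    ecg = np.asarray(ecg, float)
    if ecg.size == 0:
        return np.array([])
    height = 0.5 * np.percentile(ecg, 99)
    if height <= 0 or np.ptp(ecg) == 0:
        warnings.warn("no R-peaks detected: flat or non-positive ECG record")
        return np.array([])
    idx, _ = sps.find_peaks(ecg, height=height,
                            distance=max(1, int(_REFRACTORY_S * fs)))
    if idx.size == 0:
        warnings.warn("no R-peaks detected above the adaptive threshold")
    return t0 + (idx + _parabolic_offset(ecg, idx)) / fs


def _parabolic_offset(y: np.ndarray, idx: np.ndarray | int) -> np.ndarray | float:
    """Sub-sample vertex offset of a 3-point parabola through y[idx-1:idx+2].

    Refines a discrete extremum to sub-sample precision; returns 0 at the
    array edges or where the curvature vanishes.  Offsets are clipped to
    [-1, 1] so a noisy neighbourhood cannot move the estimate past the
    adjacent samples.
    """
    idx_arr = np.atleast_1d(np.asarray(idx, int))
    off = np.zeros(idx_arr.size)
    interior = (idx_arr > 0) & (idx_arr < y.size - 1)
    i = idx_arr[interior]
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    safe = denom != 0
    vals = np.zeros(i.size)
    vals[safe] = 0.5 * (y[i - 1] - y[i + 1])[safe] / denom[safe]
    off[interior] = np.clip(vals, -1.0, 1.0)
    return off if np.ndim(idx) else float(off[0])


def detect_max_slope_points(ppg: np.ndarray, fs: float, r_times: np.ndarray,
                            t0: float = 0.0) -> np.ndarray:
    """Locate the PPG maximum-slope point in each cardiac cycle.

    For cycle ``[r_i, r_{i+1})`` (the last cycle extends to the record
    end), the search runs over the pulse rising edge: from the PPG minimum
    within the cycle to the subsequent maximum.  Returns one time per
    R-peak; cycles without an admissible point are NaN.
    """
    ppg = np.asarray(ppg, float)
    r_times = np.asarray(r_times, float)
    if r_times.size == 0:
        raise ValueError("r_times must be nonempty")
    n = ppg.size
    out = np.full(r_times.size, np.nan)
    diff = np.diff(ppg)
    for i, r in enumerate(r_times):
        a = int(round((r - t0) * fs))
        b = int(round((r_times[i + 1] - t0) * fs)) if i + 1 < r_times.size else n
        a, b = max(a, 0), min(b, n)
        if b - a < 3:
            continue
        seg = ppg[a:b]
        if np.ptp(seg) == 0:
            continue  # flat cycle: no pulse
        # pulse peak first, then the foot (pre-rise minimum) before it;
        # searching the minimum over the whole cycle instead can land on
        # the slow drift toward the next beat's trough at the cycle edge
        peak = a + int(np.argmax(seg))
        if peak - a < 1:
            continue
        foot = a + int(np.argmin(ppg[a:peak + 1]))
        if peak - foot < 1:
            continue
        k = foot + int(np.argmax(diff[foot:peak]))
        # first-difference index k sits between samples k and k+1; the
        # midpoint plus a parabolic sub-sample refinement of the diff peak
        out[i] = t0 + (k + 0.5 + _parabolic_offset(diff, k)) / fs
    return out


def compute_pat_series(r_times: np.ndarray, slope_times: np.ndarray) -> PATSeries:
    """Beat-wise PAT = PPG max-slope time minus R-peak time.

    Missing (NaN) slope points are dropped; beats with non-positive PAT are
    rejected with a warning.
    """
    r_times = np.asarray(r_times, float)
    slope_times = np.asarray(slope_times, float)
    if r_times.shape != slope_times.shape:
        raise ValueError("r_times and slope_times must align per cycle")
    pat = slope_times - r_times
    keep = ~np.isnan(pat)
    bad = keep & (pat <= 0)
    if np.any(bad):
        warnings.warn(f"rejected {int(np.sum(bad))} beats with non-positive PAT")
        keep &= pat > 0
    return PATSeries(beat_times=r_times[keep], pat=pat[keep])


def average_pat_windows(series: PATSeries,
                        windows: list[tuple[float, float]],
                        min_beats: int = MIN_BEATS_PER_WINDOW) -> list[PATWindow]:
    """Mean PAT per window, discarding windows with too few cycles.

    A beat belongs to a window when its R-time lies in ``[t_start, t_end)``.
    Windows with fewer than ``min_beats`` beats are excluded (and counted
    in the log).
    """
    out: list[PATWindow] = []
    excluded = 0
    for t_start, t_end in windows:
        mask = (series.beat_times >= t_start) & (series.beat_times < t_end)
        n = int(np.sum(mask))
        if n < min_beats:
            excluded += 1
            continue
        out.append(PATWindow(t_start=float(t_start), t_end=float(t_end),
                             pat_bar=float(np.mean(series.pat[mask])), n_beats=n))
    if excluded:
        logger.info("excluded %d windows with fewer than %d beats",
                    excluded, min_beats)
    return out


def extract_pat_series(ecg: np.ndarray, ppg: np.ndarray, fs: float,
                       t0: float = 0.0, prefiltered: bool = False) -> PATSeries:
    """Full chain: filter both channels, delineate beats, compute PAT."""
    if not prefiltered:
        ecg = filter_ecg(ecg, fs)
        ppg = filter_ppg(ppg, fs)
    r_times = detect_r_peaks(ecg, fs, t0=t0)
    if r_times.size == 0:
        return PATSeries(beat_times=np.array([]), pat=np.array([]))
    slope_times = detect_max_slope_points(ppg, fs, r_times, t0=t0)
    return compute_pat_series(r_times, slope_times)
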