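"""Bipolar electrogram annotation and abnormality classification.

Each trace is annotated with a local activation time (time of maximum
absolute slope), peak-to-peak voltage, above-noise-floor duration and a
prominence-filtered deflection count.  A signal is abnormal when its
peak-to-peak amplitude is below 0.5 mV, or when it is both long
(> 70 ms) and multicomponent (> 3 deflections); all inequalities are
strict.  Fractionation alone means > 3 deflections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .egm import EgmTrace
from .sampling import MappingPointSet

VOLTAGE_CUTOFF_MV = 0.5
DURATION_CUTOFF_MS = 70.0
DEFLECTION_CUTOFF = 3
DEFAULT_NOISE_FLOOR_MV = 0.05
DEFAULT_PROMINENCE_MV = 0.05


class NoActivationError(ValueError):
    """Raised when a trace carries no signal above the noise floor."""


def _smooth(v: np.ndarray) -> np.ndarray:
    """Light low-pass (Savitzky-Golay, ~5 ms) to suppress sample noise
    without blunting deflections, which are several ms wide."""
    if len(v) < 7:
        return v
    return savgol_filter(v, 7, 2)


@dataclass
class EgmFeatures:
    lat: float
    peak_to_peak: float
    duration: float
    deflection_count: int
    abnormal: bool
    fractionated: bool


def detect_lat(
    trace: EgmTrace,
    noise_floor: float = DEFAULT_NOISE_FLOOR_MV,
    method: str = "max_slope",
) -> float:
    """Local activation time: time of maximum |dV/dt| (central difference).

    Only samples whose amplitude exceeds the noise floor are eligible, so
    baseline noise cannot win.  ``method='peak'`` instead returns the time
    of the largest absolute voltage.
    """
    v, t = trace.v, trace.t
    hot = np.flatnonzero(np.abs(v) > noise_floor)
    if len(hot) == 0:
        raise NoActivationError("no samples above the noise floor")
    if method == "peak":
        return float(t[hot[np.argmax(np.abs(v[hot]))]])
    # slope search runs over the contiguous envelope run holding the
    # dominant deflection, so steep flanks that dip under the floor remain
    # eligible while remote baseline noise cannot win
    sm = _smooth(v)
    if np.abs(sm).max() < 4 * noise_floor and len(v) >= 15:
        # near-floor signals: heavier smoothing before the slope search,
        # or sample noise outcompetes the true flank
        sm = savgol_filter(v, 15, 2)
    env = np.abs(sm)
    run = env > min(noise_floor, 0.5 * env.max())
    peak_i = int(np.argmax(env))
    lo = peak_i
    while lo > 0 and run[lo - 1]:
        lo -= 1
    hi = peak_i
    while hi < len(v) - 1 and run[hi + 1]:
        hi += 1
    lo, hi = max(lo - 3, 0), min(hi + 4, len(v))
    slope = np.abs(np.gradient(sm, t))
    slope[:lo] = 0.0
    slope[hi:] = 0.0
    return float(t[int(np.argmax(slope))])


def peak_to_peak(trace: EgmTrace) -> float:
    """Peak-to-peak voltage, max(v) - min(v), in mV."""
    return float(trace.v.max() - trace.v.min())


def egm_duration(trace: EgmTrace, noise_floor: float = DEFAULT_NOISE_FLOOR_MV) -> float:
    """Time between the first and last samples above the noise floor (ms)."""
    if noise_floor <= 0:
        raise ValueError("noise_floor must be positive")
    hot = np.flatnonzero(np.abs(trace.v) > noise_floor)
    if len(hot) == 0:
        return 0.0
    return float(trace.t[hot[-1]] - trace.t[hot[0]])


def count_deflections(
    trace: EgmTrace, prominence: float = DEFAULT_PROMINENCE_MV
) -> int:
    """Number of prominence-filtered local extrema (both polarities)."""
    if prominence <= 0:
        raise ValueError("prominence must be positive")
    v = _smooth(trace.v)
    n_pos = len(find_peaks(v, prominence=prominence)[0])
    n_neg = len(find_peaks(-v, prominence=prominence)[0])
    return int(n_pos + n_neg)


def classify_abnormal(
    peak_to_peak_mv: float,
    duration_ms: float,
    deflection_count: int,
    voltage_cutoff: float = VOLTAGE_CUTOFF_MV,
    duration_cutoff: float = DURATION_CUTOFF_MS,
    deflection_cutoff: int = DEFLECTION_CUTOFF,
) -> tuple[bool, bool]:
    """(abnormal, fractionated) per the low-voltage / long-fractionated rule.

    abnormal = p2p < 0.5 mV, OR (duration > 70 ms AND deflections > 3);
    fractionated = deflections > 3.  Strict inequalities: values exactly at
    a cutoff are normal.
    """
    fractionated = deflection_count > deflection_cutoff
    abnormal = (peak_to_peak_mv < voltage_cutoff) or (
        duration_ms > duration_cutoff and fractionated
    )
    return abnormal, fractionated


def extract_features(
    trace: EgmTrace,
    noise_floor: float = DEFAULT_NOISE_FLOOR_MV,
    prominence: float = DEFAULT_PROMINENCE_MV,
    lat_method: str = "max_slope",
) -> EgmFeatures:
    p2p = peak_to_peak(trace)
    dur = egm_duration(trace, noise_floor)
    ndef = count_deflections(trace, prominence)
    abnormal, fractionated = classify_abnormal(p2p, dur, ndef)
    try:
        lat = detect_lat(trace, noise_floor, lat_method)
    except NoActivationError:
        # tiny signals (diseased tissue) can sit under the global floor;
        # annotate them against their own amplitude scale instead
        lat = detect_lat(trace, 0.5 * float(np.abs(trace.v).max()), lat_method)
    return EgmFeatures(
        lat=lat,
        peak_to_peak=p2p,
        duration=dur,
        deflection_count=ndef,
        abnormal=abnormal,
        fractionated=fractionated,
    )


def annotate_points(
    points: MappingPointSet,
    noise_floor: float = DEFAULT_NOISE_FLOOR_MV,
    prominence: float = DEFAULT_PROMINENCE_MV,
    lat_method: str = "max_slope",
) -> pd.DataFrame:
    """Feature table for every point: point_id, lat_ms, p2p_mv, duration_ms,
    deflections, abnormal, fractionated (plus point coordinates)."""
    rows = []
    for pid, trace in zip(points.table["point_id"], points.traces):
        f = extract_features(trace, noise_floor, prominence, lat_method)
        rows.append(
            (pid, f.lat, f.peak_to_peak, f.duration, f.deflection_count, f.abnormal, f.fractionated)
        )
    feat = pd.DataFrame(
        rows,
        columns=["point_id", "lat_ms", "p2p_mv", "duration_ms", "deflections", "abnormal", "fractionated"],
    )
    return points.table[["point_id", "x_mm", "y_mm", "z_mm"]].merge(feat, on="point_id")
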