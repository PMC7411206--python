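"""Synthetic bipolar electrogram traces.

A trace is a train of ``n_deflections`` alternating-polarity Gaussian
lobes whose amplitudes taper geometrically, so the first (dominant)
deflection carries the activation wavefront; lobe width and spacing are
sized in closed form so the above-noise-floor signal width matches the
requested duration.  The train is time-aligned so its steepest slope
falls at the prescribed local activation time and scaled so the
peak-to-peak voltage equals the requested amplitude, then Gaussian noise
is added.  Healthy tissue yields one or two sharp deflections; diseased
tissue yields long multicomponent (fractionated) signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter


class WindowError(ValueError):
    """Raised when a requested signal does not fit the trace window."""


#: geometric amplitude decay between successive deflections
LOBE_TAPER = 0.7
#: minimum lobe spacing in units of lobe sigma (keeps extrema distinct)
MIN_SPACING_SIGMA = 2.2


@dataclass
class EgmTrace:
    """Uniformly sampled bipolar electrogram: ``t`` (ms), ``v`` (mV)."""

    t: np.ndarray
    v: np.ndarray
    true_lat: float = np.nan
    true_deflection_count: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.v.shape:
            raise ValueError("t and v must be matching 1-D arrays")
        dt = np.diff(self.t)
        if len(dt) and (dt <= 0).any():
            raise ValueError("time axis must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


def _lobe_train(t: np.ndarray, centers: np.ndarray, sigma: float) -> np.ndarray:
    # each lobe rises faster than it decays (sharp depolarisation upstroke,
    # slower recovery), so the steepest slope sits unambiguously on the rise
    n = len(centers)
    signs = (-1.0) ** np.arange(n)
    amps = LOBE_TAPER ** np.arange(n)
    v = np.zeros_like(t)
    for c, s, a in zip(centers, signs, amps):
        w = np.where(t < c, 0.75 * sigma, 1.25 * sigma)
        v += s * a * np.exp(-0.5 * ((t - c) / w) ** 2)
    return v


def synthesize_egm(
    true_lat: float,
    amplitude: float,
    n_deflections: int,
    duration: float,
    noise_sd: float = 0.01,
    seed: int = 0,
    window: tuple[float, float] = (0.0, 500.0),
    sample_interval: float = 1.0,
    noise_floor: float = 0.05,
) -> EgmTrace:
    """Synthesize one bipolar electrogram trace.

    ``duration`` is the target above-noise-floor signal width (ms) of the
    noiseless trace; ``amplitude`` the exact noiseless peak-to-peak (mV).
    """
    if n_deflections < 1:
        raise ValueError("n_deflections must be >= 1")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    t0, t1 = window
    if true_lat - duration / 2 < t0 or true_lat + duration / 2 > t1:
        raise WindowError(
            f"signal [{true_lat - duration / 2:.0f}, {true_lat + duration / 2:.0f}] ms "
            f"exceeds the trace window [{t0:.0f}, {t1:.0f}] ms"
        )
    t = np.arange(t0, t1 + 0.5 * sample_interval, sample_interval)
    n = int(n_deflections)

    # closed-form sizing: duration = (n-1)*spacing + 2*sigma*k_tail, where
    # k_tail is how many sigmas the dominant lobe needs to decay to the floor
    peak = amplitude if n == 1 else amplitude / (1.0 + LOBE_TAPER)
    k_tail = np.sqrt(2.0 * np.log(max(peak / noise_floor, 1.2)))
    sigma = duration / ((n - 1) * MIN_SPACING_SIGMA + 2.0 * k_tail)
    sigma = max(sigma, 0.75 * sample_interval)
    spacing = MIN_SPACING_SIGMA * sigma
    centers = true_lat + np.arange(n) * spacing - (n - 1) * spacing / 2.0

    # align the steepest slope (the activation marker) with true_lat, using
    # the same lightly smoothed slope estimate the feature extractor applies
    proto = _lobe_train(t, centers, sigma)
    if len(proto) >= 7:
        proto = savgol_filter(proto, 7, 2)
    shift = t[int(np.argmax(np.abs(np.gradient(proto, t))))] - true_lat
    v = _lobe_train(t, centers - shift, sigma)
    v *= amplitude / (v.max() - v.min())

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=len(t))
    return EgmTrace(t, v, true_lat=float(true_lat), true_deflection_count=n)
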