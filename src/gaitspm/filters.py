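"""Zero-phase Butterworth filtering helpers.

All pipeline filters are designed as single-pass Butterworth filters of the
stated order and applied forward-backward (``sosfiltfilt``), so they add no
group delay; burst timing and gait-event timing are therefore comparable
across conditions. The bidirectional pass squares the magnitude response.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .config import FilterSpec, ConfigError


def butter_sos(spec: FilterSpec, rate: float) -> np.ndarray:
    """Second-order-section design for ``spec`` at sampling rate ``rate``."""
    spec.validate_for_rate(rate)
    btype = {"low-pass": "lowpass", "high-pass": "highpass"}[spec.kind]
    return signal.butter(spec.order, spec.cutoff, btype=btype, fs=rate, output="sos")


def apply_filter(x: np.ndarray, spec: FilterSpec, rate: float) -> np.ndarray:
    """Filter ``x`` along its first axis per ``spec``.

    Zero-phase (forward-backward) when ``spec.zero_phase``; single forward
    pass otherwise.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 15:
        raise ValueError("series too short to filter stably")
    sos = butter_sos(spec, rate)
    if spec.zero_phase:
        return signal.sosfiltfilt(sos, x, axis=0)
    return signal.sosfilt(sos, x, axis=0)


def lowpass(x: np.ndarray, cutoff: float, rate: float, order: int = 4) -> np.ndarray:
    return apply_filter(x, FilterSpec("low-pass", order=order, cutoff=cutoff), rate)


def highpass(x: np.ndarray, cutoff: float, rate: float, order: int = 4) -> np.ndarray:
    return apply_filter(x, FilterSpec("high-pass", order=order, cutoff=cutoff), rate)


def bandpass_noise(
    rng: np.random.Generator,
    n: int,
    rate: float,
    low: float,
    high: float,
    order: int = 4,
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [low, high] Hz.

    Used as the stochastic sEMG carrier. The band is clipped to the Nyquist
    interval; RMS is normalised empirically after filtering.
    """
    if not 0 < low < high:
        raise ConfigError("need 0 < low < high for band-limited noise")
    high = min(high, 0.499 * rate)
    x = rng.standard_normal(n)
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rate, output="sos")
    y = signal.sosfiltfilt(sos, x)
    rms = float(np.sqrt(np.mean(y**2)))
    return y / rms if rms > 0 else y
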