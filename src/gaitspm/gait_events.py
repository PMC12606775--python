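"""Right-hind impact detection from sacral vertical acceleration.

Impacts are defined as vertical-displacement minima of the tubera-sacrale
point. The displacement is obtained by double trapezoidal integration of
the vertical acceleration with mean removal after each integration step,
an adaptive zero-phase high-pass (4th-order Butterworth, cut-off a fixed
fraction — default 0.5 — of the estimated stride frequency) and a 30 Hz
zero-phase low-pass. Displacement minima alternate between the two hind
limbs; the deeper class is taken as the right hind (the side is
user-selectable for real data, where a single sacral sensor cannot encode
side on a perfectly symmetric signal).
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, signal

from .config import DISPLACEMENT_LOWPASS, FilterSpec
from .filters import apply_filter
from .types import GaitEventSeries

PHYSIOLOGICAL_BAND_HZ = (0.3, 1.5)   # stride frequencies considered


class GaitEventError(ValueError):
    pass


def accel_to_displacement(accel: np.ndarray, rate: float,
                          stride_frequency_estimate: float,
                          hp_fraction: float = 0.5,
                          lowpass: FilterSpec = DISPLACEMENT_LOWPASS,
                          ) -> np.ndarray:
    """Vertical displacement (mm) from vertical acceleration (m/s^2).

    Cumulative trapezoidal integration, mean removal, second integration,
    mean removal, then the adaptive high-pass and the 30 Hz low-pass, both
    zero-phase. Output is zero-mean by construction of the high-pass.
    """
    accel = np.asarray(accel, dtype=float)
    if stride_frequency_estimate <= 0:
        raise GaitEventError("stride_frequency_estimate must be > 0")
    if len(accel) < 4 * rate / stride_frequency_estimate:
        raise GaitEventError("series shorter than 4 stride periods")
    cutoff = hp_fraction * stride_frequency_estimate
    if cutoff >= rate / 2:
        raise GaitEventError("adaptive high-pass cutoff at or above Nyquist")

    vel = integrate.cumulative_trapezoid(accel, dx=1.0 / rate, initial=0.0)
    vel -= vel.mean()
    disp = integrate.cumulative_trapezoid(vel, dx=1.0 / rate, initial=0.0)
    disp -= disp.mean()
    disp = apply_filter(disp, FilterSpec("high-pass", order=4, cutoff=cutoff),
                        rate)
    disp = apply_filter(disp, lowpass, rate)
    return disp * 1000.0  # m -> mm


def estimate_stride_frequency(series: np.ndarray, rate: float,
                              band_hz: tuple[float, float] = PHYSIOLOGICAL_BAND_HZ,
                              min_peak: float = 0.25) -> float:
    """Dominant stride rate (Hz) from the autocorrelation peak in ``band_hz``.

    The candidate lag range excludes the step rate (twice the stride rate at
    walk), so the fundamental found here is the stride, not the step. Raises
    when no sufficiently strong peak exists (e.g. white noise), advising a
    manual override.
    """
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    lo, hi = band_hz
    max_lag = int(rate / lo)
    if len(x) < 2 * max_lag:
        raise GaitEventError("series shorter than 2 maximum stride periods")
    # biased autocorrelation via FFT, normalised to r(0) = 1
    n = len(x)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    r = np.fft.irfft(spec * np.conj(spec))[:max_lag + 1]
    if r[0] <= 0:
        raise GaitEventError("zero-variance series")
    r = r / r[0]
    lag_min = int(np.ceil(rate / hi))
    seg = r[lag_min:max_lag + 1]
    peaks, _ = signal.find_peaks(seg)
    if len(peaks) == 0 or seg[peaks].max() < min_peak:
        raise GaitEventError(
            "no periodicity found in the physiological stride band "
            f"{band_hz} Hz; pass a manual stride-frequency override")
    best = peaks[np.argmax(seg[peaks])]
    return rate / float(lag_min + best)


def detect_impacts(displacement: np.ndarray, rate: float,
                   stride_frequency: float, side: str = "auto",
                   min_separation_fraction: float = 0.35,
                   trial_id: str = "") -> GaitEventSeries:
    """Right-hind impacts from the displacement minima.

    All local minima separated by at least ``min_separation_fraction`` of
    the stride period are found after trimming one stride period of filter
    transient at each end; alternate minima are classed by mean depth and
    the deeper class is returned as the right hind (``side="auto"``); pass
    ``side="first"``/``side="second"`` to force a class. The first and last
    minima are dropped as partial-stride boundaries.
    """
    disp = np.asarray(displacement, dtype=float)
    if stride_frequency <= 0:
        raise GaitEventError("stride_frequency must be > 0")
    period_samples = rate / stride_frequency
    trim = int(period_samples)
    core = disp[trim:len(disp) - trim]
    if len(core) < 3:
        raise GaitEventError("series too short after transient trimming")
    distance = max(1, int(min_separation_fraction * period_samples))
    minima, props = signal.find_peaks(-core, distance=distance,
                                      plateau_size=1)
    # plateau minima resolve to the plateau midpoint sample
    mids = ((props["left_edges"] + props["right_edges"]) // 2)
    minima = np.asarray(mids, dtype=int)
    if len(minima) < 3:
        raise GaitEventError(f"fewer than 3 minima detected "
                             f"({len(minima)} found)")
    flags: list[str] = []
    depths_a = disp[trim + minima[0::2]]
    depths_b = disp[trim + minima[1::2]]
    diff = float(np.mean(depths_a) - np.mean(depths_b))
    scale = float(np.std(disp[trim:len(disp) - trim])) or 1.0
    if side == "first":
        chosen = minima[0::2]
    elif side == "second":
        chosen = minima[1::2]
    else:
        if abs(diff) < 0.05 * scale:
            flags.append("ambiguous side assignment (minima depth difference "
                         "below resolution); defaulting to first class")
            chosen = minima[0::2]
        else:
            chosen = minima[0::2] if diff < 0 else minima[1::2]
    times = (trim + chosen) / rate
    if len(times) >= 3:
        times = times[1:-1]  # drop partial strides at the ends
    ev = GaitEventSeries(impact_times=times, provenance=trial_id
                         or "detect_impacts", side="right")
    ev.flags.extend(flags)
    return ev


def events_to_strides(events: GaitEventSeries, n_samples: int, rate: float,
                      start_time: float = 0.0,
                      ) -> tuple[list[tuple[int, int]], list[str]]:
    """Half-open per-stride sample windows [i0, i1) at the target rate.

    Each impact time maps to its nearest sample; strides falling (even
    partially) outside the series span are dropped with a log entry.
    Windows tile the inter-impact span: every sample between the first and
    last retained impact belongs to exactly one stride.
    """
    log: list[str] = []
    idx = np.rint((events.impact_times - start_time) * rate).astype(int)
    windows: list[tuple[int, int]] = []
    for k in range(len(idx) - 1):
        i0, i1 = int(idx[k]), int(idx[k + 1])
        if i0 < 0 or i1 > n_samples:
            log.append(f"stride {k} [{i0}, {i1}) outside series span "
                       f"[0, {n_samples}); dropped")
            continue
        windows.append((i0, i1))
    return windows, log
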