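"""sEMG conditioning: linear envelopes, stride peak amplitudes, robust
outlier-stride removal, and RVC amplitude normalisation.

Processing chain (all filters Butterworth 4th-order, zero-phase):
DC-offset removal -> 40 Hz high-pass -> full-wave rectification -> 10 Hz
low-pass. The per-stride peak amplitude (PA) of the envelope drives both
outlier-stride detection (median +- k scaled-MAD per muscle within a trial,
k = 3 by default) and normalisation to the reference voluntary contraction
(RVC): the maximum PA across retained reference-condition (overground)
strides for each muscle, with envelopes then expressed in %RVC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import EMG_HIGHPASS, EMG_ENVELOPE_LOWPASS, FilterSpec
from .filters import apply_filter


class EMGError(ValueError):
    pass


@dataclass
class EnvelopeSignal:
    """Envelope and per-stride metrics for one muscle in one trial."""

    muscle: str
    condition: str
    envelope: np.ndarray                 # (n,) >= 0, volts (or %RVC)
    rate: float
    peak_amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))
    outlier_flags: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    rvc: float | None = None
    clipped_fraction: float = 0.0
    flags: list[str] = field(default_factory=list)


def envelope(raw: np.ndarray, rate: float,
             high: FilterSpec = EMG_HIGHPASS,
             low: FilterSpec = EMG_ENVELOPE_LOWPASS,
             ) -> tuple[np.ndarray, float]:
    """Linear envelope of a raw sEMG series; returns (envelope, clipped).

    ``clipped`` is the fraction of samples where small negative ringing from
    the final low-pass was clipped to zero (logged by callers; typically
    well under 1%).
    """
    if rate <= 2 * high.cutoff:
        raise EMGError(f"sampling rate {rate} Hz must exceed twice the "
                       f"high-pass cutoff {high.cutoff} Hz")
    x = np.asarray(raw, dtype=float)
    x = x - x.mean()
    x = apply_filter(x, high, rate)
    x = np.abs(x)
    x = apply_filter(x, low, rate)
    clipped = float(np.mean(x < 0))
    return np.maximum(x, 0.0), clipped


def stride_peak_amplitudes(env: np.ndarray,
                           windows: list[tuple[int, int]]) -> np.ndarray:
    """PA_i = max of the envelope within stride i's half-open window."""
    env = np.asarray(env, dtype=float)
    out = np.empty(len(windows))
    for i, (i0, i1) in enumerate(windows):
        if i1 <= i0:
            raise EMGError(f"empty stride window [{i0}, {i1})")
        out[i] = env[i0:i1].max()
    return out


def outlier_flags_one_muscle(pas: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Strides whose PA lies outside median +- k scaled-MAD for one muscle."""
    pas = np.asarray(pas, dtype=float)
    med = np.median(pas)
    smad = stats.median_abs_deviation(pas, scale="normal")
    if smad == 0:
        # degenerate spread: anything off the median is an outlier
        return pas != med
    return np.abs(pas - med) > k * smad


def remove_outlier_strides(pas_per_muscle: dict[str, np.ndarray],
                           k: float = 3.0,
                           min_strides: int = 5,
                           ) -> tuple[np.ndarray, list[str]]:
    """Global outlier flags across muscles for one trial.

    A stride flagged by any muscle is removed globally, keeping the sEMG and
    kinematic stride sets aligned for the equal-count requirement. With
    fewer than ``min_strides`` strides no removal is attempted (warned).
    """
    counts = {len(v) for v in pas_per_muscle.values()}
    if len(counts) != 1:
        raise EMGError("muscles disagree on stride count")
    n = counts.pop()
    log: list[str] = []
    if n < min_strides:
        log.append(f"only {n} strides (< {min_strides}): outlier removal "
                   "skipped")
        return np.zeros(n, dtype=bool), log
    flags = np.zeros(n, dtype=bool)
    for muscle, pas in pas_per_muscle.items():
        f = outlier_flags_one_muscle(np.asarray(pas, dtype=float), k=k)
        if f.any():
            log.append(f"{muscle}: strides {np.flatnonzero(f).tolist()} "
                       "flagged as PA outliers")
        flags |= f
    return flags, log


def compute_rvc(reference_pas: np.ndarray,
                outlier_flags: np.ndarray | None = None) -> float:
    """RVC = maximum PA across retained reference-condition strides."""
    pas = np.asarray(reference_pas, dtype=float)
    if outlier_flags is not None:
        pas = pas[~np.asarray(outlier_flags, dtype=bool)]
    if len(pas) == 0:
        raise EMGError("no retained reference strides to define the RVC")
    rvc = float(pas.max())
    if rvc <= 0:
        raise EMGError("RVC is not positive")
    return rvc


def rvc_normalise(env: np.ndarray, rvc: float, muscle: str = "") -> np.ndarray:
    """Express an envelope in % of the muscle's RVC."""
    if rvc is None or rvc <= 0:
        raise EMGError(f"RVC missing or non-positive for muscle "
                       f"{muscle or '<unnamed>'}")
    return 100.0 * np.asarray(env, dtype=float) / rvc
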