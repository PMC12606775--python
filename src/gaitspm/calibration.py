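"""Monte-Carlo calibration harnesses for the SPM inference.

These drive the package's own generator and pipeline to measure (a) the
family-wise error of the random-field-theory threshold on smooth Gaussian
null fields, (b) its agreement with the sign-flip permutation oracle,
(c) the end-to-end false-positive rate of the full pipeline on null
condition pairs, and (d) the power to recover an injected mid-stance
envelope increase. They are used by the test suite and the acceptance
script; all randomness is derived from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SessionConfig
from .pipeline import run_study
from .spm import (
    estimate_fwhm,
    paired_t_field,
    permutation_oracle,
    rft_threshold,
    smooth_gaussian_fields,
)
from .synthetic import (
    Burst,
    ConditionEffect,
    NoiseSpec,
    generate_session,
    null_pair,
    study_replication_effects,
)


def smooth_field_fwe(n_reps: int = 2000, seed: int = 0, n: int = 32,
                     node_count: int = 101, fwhm: float = 15.0,
                     alpha: float = 0.05) -> float:
    """Empirical P(any |t| > t*) on smooth Gaussian null fields.

    Each replicate draws ``n`` unit-variance fields of known smoothness,
    forms the one-sample (paired-difference) t-field, estimates the FWHM
    from the residuals and applies the RFT threshold — the same inferential
    path the pipeline uses.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    zeros = np.zeros((n, node_count))
    for _ in range(n_reps):
        f = smooth_gaussian_fields(rng, n, node_count, fwhm)
        t, dof, residuals, _ = paired_t_field(f, zeros)
        est, _ = estimate_fwhm(residuals)
        t_star = rft_threshold(dof, est, node_count, alpha)
        hits += bool(np.any(np.abs(t) > t_star))
    return hits / n_reps


def rft_vs_permutation(seed: int = 0, n: int = 32, node_count: int = 101,
                       fwhm: float = 15.0, n_perm: int = 1000,
                       alpha: float = 0.05) -> tuple[float, float]:
    """(RFT t*, permutation empirical t*) on one smooth null dataset."""
    rng = np.random.default_rng(seed)
    f = smooth_gaussian_fields(rng, n, node_count, fwhm)
    zeros = np.zeros_like(f)
    _, dof, residuals, _ = paired_t_field(f, zeros)
    est, _ = estimate_fwhm(residuals)
    t_star = rft_threshold(dof, est, node_count, alpha)
    perm = permutation_oracle(f, zeros, n_perm=n_perm, seed=seed, alpha=alpha)
    return t_star, perm.t_star


def _harness_config(seed: int = 0) -> SessionConfig:
    """Single-muscle two-condition configuration for pipeline calibration.

    60 s trials (the study's acquisition length) give ~54 strides at a
    1.1 s stride, leaving headroom above the 32-per-condition equalisation
    target after transient trimming and outlier removal.
    """
    return SessionConfig(muscles=("BF",), trial_duration=60.0, seed=seed)


def _pair_significant(config: SessionConfig, effect_a: ConditionEffect,
                      effect_b: ConditionEffect, seed: int,
                      noise: NoiseSpec):
    """Run the full pipeline on a generated A/B pair; returns the single
    SPM comparison result."""
    cfg, _, _, _ = null_pair(config, effect_a, seed=seed, noise=noise)
    trials, static, _ = generate_session(
        cfg, effects={"A": effect_a, "B": effect_b}, seed=seed, noise=noise)
    report = run_study(cfg, session=(trials, static))
    assert len(report.comparisons) == 1
    return report.comparisons[0]


def null_pipeline_fwe(n_reps: int = 1000, seed: int = 0,
                      noise: NoiseSpec = NoiseSpec()) -> float:
    """Fraction of null condition pairs (identical generator parameters,
    independent noise) yielding at least one significant cluster."""
    base = study_replication_effects(("BF",))["OG"]
    config = _harness_config(seed)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_reps) % (2**31 - 1)
    hits = 0
    for s in child_seeds:
        result = _pair_significant(config, base, base, int(s), noise)
        hits += result.significant
    return hits / n_reps


@dataclass
class RecoveryOutcome:
    rate: float               # fraction of reps with an overlapping cluster
    effect_to_sd: float       # realised mean shift / stride SD in the window
    n_reps: int


def effect_recovery(n_reps: int = 200, seed: int = 0,
                    burst_amplitude: float = 0.2,
                    window_pct: tuple[int, int] = (10, 40),
                    noise: NoiseSpec = NoiseSpec()) -> RecoveryOutcome:
    """Power to detect an injected mid-stance envelope increase.

    Condition B adds one Gaussian burst (centre 25% stride, SD 7% stride)
    of the given amplitude to the reference muscle profile, spanning the
    10-40% window. A replicate counts as recovered when a significant
    cluster overlaps that window. The realised effect size (mean %RVC shift
    over the window median stride-to-stride SD) is measured on the first
    replicate and reported.
    """
    base = study_replication_effects(("BF",))["OG"]
    boosted = ConditionEffect(
        bursts={"BF": base.bursts["BF"] + (Burst(25.0, 7.0, burst_amplitude),)},
        angles=base.angles,
        stride_duration=base.stride_duration,
        stride_duration_cv=base.stride_duration_cv)
    config = _harness_config(seed)
    lo, hi = window_pct
    ss = np.random.SeedSequence(seed + 1)
    child_seeds = ss.generate_state(n_reps) % (2**31 - 1)
    hits = 0
    effect_to_sd = np.nan
    for i, s in enumerate(child_seeds):
        result = _pair_significant(config, base, boosted, int(s), noise)
        overlap = any(c.start_node <= hi and c.end_node >= lo
                      for c in result.clusters)
        hits += overlap
        if i == 0:
            effect_to_sd = _measure_effect_size(config, base, boosted,
                                                int(s), noise, (lo, hi))
    return RecoveryOutcome(rate=hits / n_reps, effect_to_sd=effect_to_sd,
                           n_reps=n_reps)


def _measure_effect_size(config, effect_a, effect_b, seed, noise, window):
    from .assembly import normalise_strides
    from .emg import compute_rvc, rvc_normalise
    from .pipeline import process_trial
    cfg, _, _, _ = null_pair(config, effect_a, seed=seed, noise=noise)
    trials, static, _ = generate_session(
        cfg, effects={"A": effect_a, "B": effect_b}, seed=seed, noise=noise)
    r_a = process_trial(trials[0], cfg, static)
    r_b = process_trial(trials[1], cfg, static)
    muscle = cfg.muscles[0]
    rvc = compute_rvc(r_a.peak_amplitudes[muscle][r_a.retained])
    m_a = normalise_strides(rvc_normalise(r_a.envelopes[muscle], rvc),
                            [r_a.emg_windows[i] for i in r_a.retained],
                            cfg.node_count)
    m_b = normalise_strides(rvc_normalise(r_b.envelopes[muscle], rvc),
                            [r_b.emg_windows[i] for i in r_b.retained],
                            cfg.node_count)
    lo, hi = window
    shift = m_b.mean(axis=0)[lo:hi + 1] - m_a.mean(axis=0)[lo:hi + 1]
    sd = np.median(m_b.std(axis=0, ddof=1)[lo:hi + 1])
    return float(shift.max() / sd)
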