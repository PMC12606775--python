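"""The 1D SPM statistics: t-fields, smoothness, RFT thresholds, clusters,
and the sign-flip permutation oracle."""

import numpy as np
import pytest
from scipy import stats

from gaitspm.spm import (
    SPMError,
    cluster_inference,
    cluster_p_value,
    ec_density_1d,
    estimate_fwhm,
    paired_t_field,
    permutation_oracle,
    rft_threshold,
    smooth_gaussian_fields,
    spm_paired_test,
    two_sample_t_field,
)
from gaitspm.types import StrideMatrix


def test_identical_matrices_give_zero_t(rng):
    a = rng.normal(size=(8, 101))
    t, dof, res, flags = paired_t_field(a, a.copy())
    assert np.all(t == 0) and dof == 7


def test_zero_mean_differences_give_zero_t():
    a = np.zeros((4, 5))
    b = -np.array([[1.0, 1, 1, 1, 1], [-1, -1, -1, -1, -1],
                   [1, 1, 1, 1, 1], [-1, -1, -1, -1, -1]])
    t, *_ = paired_t_field(a, b)
    np.testing.assert_allclose(t, 0.0)


def test_t_field_matches_per_node_textbook_t(rng):
    a = rng.normal(size=(32, 101))
    b = rng.normal(size=(32, 101))
    t, dof, _, _ = paired_t_field(a, b)
    ref = np.array([stats.ttest_rel(a[:, q], b[:, q]).statistic
                    for q in range(101)])
    np.testing.assert_allclose(t, ref, atol=1e-10)
    assert dof == 31


def test_t_field_antisymmetry_and_shift_invariance(rng):
    a = rng.normal(size=(12, 101))
    b = rng.normal(size=(12, 101))
    t_ab, *_ = paired_t_field(a, b)
    t_ba, *_ = paired_t_field(b, a)
    np.testing.assert_allclose(t_ab, -t_ba, atol=1e-12)
    curve = np.sin(np.linspace(0, 3, 101))
    t_shift, *_ = paired_t_field(a + curve, b + curve)
    np.testing.assert_allclose(t_shift, t_ab, atol=1e-9)


def test_unequal_shapes_and_tiny_n_rejected(rng):
    with pytest.raises(SPMError):
        paired_t_field(rng.normal(size=(5, 101)), rng.normal(size=(6, 101)))
    with pytest.raises(SPMError):
        paired_t_field(rng.normal(size=(2, 101)), rng.normal(size=(2, 101)))


def test_white_noise_residuals_estimate_small_fwhm(rng):
    ests = [estimate_fwhm(rng.standard_normal((32, 101)))[0]
            for _ in range(500)]
    assert np.mean(ests) < 3.0


def test_known_smoothness_recovered_within_20pct(rng):
    ests = []
    for _ in range(500):
        f = smooth_gaussian_fields(rng, 32, 101, 15.0)
        ests.append(estimate_fwhm(f - f.mean(axis=0))[0])
    assert abs(np.mean(ests) - 15.0) / 15.0 < 0.2


def test_constant_residual_rows_clamp_fwhm():
    res = np.tile(np.array([[1.0], [-1.0], [0.5]]), (1, 101))
    fwhm, flags = estimate_fwhm(res)
    assert fwhm == pytest.approx(3 * 101)
    assert flags


def test_zero_resel_limit_is_ordinary_critical_t():
    t_star = rft_threshold(31, fwhm=1e12, node_count=101, alpha=0.05)
    assert t_star == pytest.approx(stats.t.ppf(0.975, 31), abs=1e-6)


def test_threshold_monotone_in_alpha_and_smoothness():
    t1 = rft_threshold(31, 15.0, 101, 0.05)
    t2 = rft_threshold(31, 15.0, 101, 0.01)
    t3 = rft_threshold(31, 5.0, 101, 0.05)
    assert t2 > t1          # stricter alpha -> higher threshold
    assert t3 > t1          # rougher field -> higher threshold


def test_ec_density_decreases_in_u():
    u = np.linspace(1, 6, 50)
    d = ec_density_1d(u, 31)
    assert np.all(np.diff(d) < 0)


def test_subthreshold_field_yields_no_clusters():
    t = 0.5 * np.sin(np.linspace(0, 6, 101))
    assert cluster_inference(t, 3.0, 15.0, 31) == []


def test_single_run_cluster_bounds():
    t = np.zeros(101)
    t[40:61] = 5.0
    clusters = cluster_inference(t, 3.0, 15.0, 31)
    assert len(clusters) == 1
    c = clusters[0]
    assert (c.start_node, c.end_node, c.extent_nodes) == (40, 60, 21)
    assert c.max_abs_t == 5.0
    assert 0 < c.p <= 0.05


def test_cluster_p_decreases_with_extent():
    ps = [cluster_p_value(k, 3.2, 15.0, 31, 101) for k in (2, 8, 20, 40)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))
    assert ps[-1] < ps[0]


def test_p_value_report_floor():
    from gaitspm.types import Cluster
    c = Cluster(10, 20, 5.0, 11, 0.0004)
    assert c.formatted_p() == "< 0.001"
    c2 = Cluster(10, 20, 4.0, 11, 0.012)
    assert c2.formatted_p() == "0.012"


def test_permutation_exhaustive_for_three_pairs(rng):
    a = rng.normal(size=(3, 31))
    b = rng.normal(size=(3, 31))
    out = permutation_oracle(a, b, n_perm=100, seed=0)
    assert out.exhaustive and out.n_perm == 8


def test_permutation_deterministic_under_seed(rng):
    a = rng.normal(size=(10, 101))
    b = rng.normal(size=(10, 101))
    o1 = permutation_oracle(a, b, n_perm=200, seed=42)
    o2 = permutation_oracle(a, b, n_perm=200, seed=42)
    np.testing.assert_array_equal(o1.max_t_distribution,
                                  o2.max_t_distribution)


def test_rft_agrees_with_permutation_on_smooth_null(rng):
    f = smooth_gaussian_fields(rng, 32, 101, 15.0)
    zeros = np.zeros_like(f)
    _, dof, res, _ = paired_t_field(f, zeros)
    fwhm, _ = estimate_fwhm(res)
    t_star = rft_threshold(dof, fwhm, 101, 0.05)
    perm = permutation_oracle(f, zeros, n_perm=1000, seed=7)
    assert abs(t_star - perm.t_star) / perm.t_star < 0.05


def test_rft_cluster_p_within_factor_two_of_permutation(rng):
    # marginal boxcar mean shift on smooth noise: compare the RFT
    # expected-extent cluster p with the sign-flip oracle's empirical p,
    # keeping only clusters the 1000-flip oracle can actually resolve
    ratios = []
    for k in range(60):
        f = smooth_gaussian_fields(rng, 32, 101, 15.0)
        f[:, 40:61] += 0.55
        zeros = np.zeros_like(f)
        t, dof, res, _ = paired_t_field(f, zeros)
        fwhm, _ = estimate_fwhm(res)
        t_star = rft_threshold(dof, fwhm, 101, 0.05)
        clusters = [c for c in cluster_inference(t, t_star, fwhm, dof)
                    if c.start_node <= 60 and c.end_node >= 40]
        if not clusters:
            continue
        perm = permutation_oracle(f, zeros, n_perm=1000, seed=k)
        p_perm = perm.cluster_p(clusters[0].extent_nodes)
        if p_perm < 5.0 / perm.n_perm:     # below oracle resolution
            continue
        ratios.append(clusters[0].p / p_perm)
    assert len(ratios) >= 10, "too few resolvable clusters in simulation"
    med = float(np.median(ratios))
    assert 0.5 <= med <= 2.0, med


def test_spm_paired_test_end_to_end(rng):
    a = StrideMatrix("BF", "OG", smooth_gaussian_fields(rng, 32, 101, 12.0),
                     [("OG-1", i) for i in range(32)])
    shifted = smooth_gaussian_fields(rng, 32, 101, 12.0)
    shifted[:, 20:41] += 2.5
    b = StrideMatrix("BF", "WT80", shifted, [("WT80-1", i) for i in range(32)])
    res = spm_paired_test(a, b)
    assert res.significant
    assert any(c.start_node <= 40 and c.end_node >= 20 for c in res.clusters)
    assert res.t_star > 0 and res.dof == 31


def test_two_sample_variant_close_to_paired_for_independent_data(rng):
    a = rng.normal(size=(32, 101))
    b = rng.normal(size=(32, 101)) + 1.0
    t2, dof2, _, _ = two_sample_t_field(a, b)
    ref = np.array([stats.ttest_ind(a[:, q], b[:, q]).statistic
                    for q in range(101)])
    np.testing.assert_allclose(t2, ref, atol=1e-10)
    assert dof2 == 62
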