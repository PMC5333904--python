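import numpy as np
import pytest
from scipy import stats

import mristand as ms
from mristand.histogram import CumulativeDistribution

# (Z, r) cells of the published histogram-comparison and intensity-difference
# tables (standardised T1-weighted rows plus the quantitative-T1 rows).
TABLE_Z_R_CELLS = [
    # WM average / WM max errors, whole brain and ROI
    (3.73, 0.59), (2.46, 0.39), (3.81, 0.60), (1.64, 0.26),
    (3.36, 0.53), (2.80, 0.44), (3.77, 0.60), (2.35, 0.37),
    (3.92, 0.62), (1.57, 0.25), (3.92, 0.62), (-0.16, -0.03),
    (0.82, 0.13), (3.14, 0.50), (2.50, 0.40), (3.14, 0.50),
    (3.88, 0.61), (3.10, 0.49), (3.88, 0.61), (2.95, 0.47),
    (3.10, 0.49), (3.62, 0.57), (1.75, 0.28), (0.60, 0.09),
    # GM average / GM max errors
    (-3.21, -0.51), (-2.58, -0.41), (-3.55, -0.56), (-2.50, -0.40),
    (-3.62, -0.57), (-2.69, -0.43), (-3.66, -0.58), (-2.43, -0.38),
    (3.66, 0.58), (0.97, 0.15), (3.58, 0.57), (0.49, 0.08),
    (0.47, 0.07), (3.81, 0.60), (-1.74, -0.27), (3.73, 0.59),
    (3.78, 0.60), (3.06, 0.48), (3.81, 0.60), (3.19, 0.50),
    (0.11, 0.02), (0.37, 0.06), (1.01, 0.16), (-0.82, -0.13),
    # voxelwise intensity differences
    (3.88, 0.61), (3.92, 0.62), (-2.02, -0.32), (-1.05, -0.17),
    (3.85, 0.61), (3.92, 0.62), (-2.17, -0.34), (-0.34, -0.05),
    (3.92, 0.62), (3.14, 0.50), (0.07, 0.01), (0.60, 0.09),
    (3.85, 0.61), (3.92, 0.62), (3.66, 0.58), (3.92, 0.62),
    (3.73, 0.59), (3.10, 0.49), (3.47, 0.55), (3.66, 0.58),
]


def uniform_cdf(hi, top=4095):
    levels = np.arange(top + 1, dtype=float)
    P = np.clip((levels + 1) / (hi + 1), 0, 1)
    return CumulativeDistribution(levels, P, 100000)


class TestCDFError:
    def test_identical_cdfs_have_zero_error(self, phantom_histogram):
        c = ms.cumulative_distribution(phantom_histogram)
        res = ms.cdf_abs_error(c, c)
        assert res.average_abs_error == 0.0
        assert res.maximum_abs_error == 0.0

    def test_disjoint_supports_are_an_error(self):
        a = CumulativeDistribution(np.arange(4096.0),
                                   (np.arange(4096) >= 1000).astype(float), 10)
        b = CumulativeDistribution(np.arange(4096.0),
                                   (np.arange(4096) >= 3000).astype(float), 10)
        with pytest.raises(ValueError, match="overlap"):
            ms.cdf_abs_error(a, b)

    def test_uniform_closed_form_max_error(self):
        """U(0,2047) vs U(0,4095): max |P_T - P_R| = 0.5 at level 2047."""
        res = ms.cdf_abs_error(uniform_cdf(2047), uniform_cdf(4095))
        assert res.maximum_abs_error == pytest.approx(0.5, abs=1e-3)
        assert res.shared_range == (0.0, 2047.0)

    def test_symmetry(self, default_phantom):
        _, vol, labels = default_phantom
        vol2, labels2 = ms.generate_phantom(ms.PhantomSpec(seed=9))
        a = ms.cumulative_distribution(
            ms.compute_histogram(vol, labels=labels, tissue="GM"))
        b = ms.cumulative_distribution(
            ms.compute_histogram(vol2, labels=labels2, tissue="GM"))
        r1 = ms.cdf_abs_error(a, b)
        r2 = ms.cdf_abs_error(b, a)
        assert r1.average_abs_error == r2.average_abs_error
        assert r1.maximum_abs_error == r2.maximum_abs_error


class TestVoxelwiseDifference:
    def test_equal_volumes_give_zero(self, default_phantom):
        _, vol, labels = default_phantom
        assert ms.voxelwise_intensity_difference(
            vol, vol, labels, labels, "WM") == 0.0

    def test_constant_offset_gives_the_offset(self, default_phantom):
        _, vol, labels = default_phantom
        shifted = vol.copy_with(vol.data + 100.0)
        assert ms.voxelwise_intensity_difference(
            vol, shifted, labels, labels, "GM") == pytest.approx(100.0)

    def test_matches_a_brute_force_voxel_loop(self, noiseless_phantom):
        _, vol, labels = noiseless_phantom
        m, n = 1.07, -45.0
        dist = ms.apply_distortion(
            vol, ms.DistortionSpec("linear", {"slope": m, "offset": n}))
        got = ms.voxelwise_intensity_difference(vol, dist, labels, labels, "WM")
        acc, cnt = 0.0, 0
        L = labels.labels
        for idx in zip(*np.nonzero(L == 3)):
            acc += abs(vol.data[idx] - dist.data[idx])
            cnt += 1
        assert got == pytest.approx(acc / cnt, rel=1e-12)

    def test_empty_intersection_is_an_error(self, default_phantom):
        _, vol, labels = default_phantom
        other = ms.TissueLabelMap(
            np.where(labels.labels == 3, 2, labels.labels).astype(np.int16))
        with pytest.raises(ValueError, match="no voxel"):
            ms.voxelwise_intensity_difference(vol, vol, labels, other, "WM")


class TestColourCoding:
    def test_published_anchor_colours(self):
        """Red at the bottom of the range, blue at the top (T1w preset)."""
        cm = ms.t1w_colour_map()
        vol = ms.IntensityVolume(np.array([[[0.0, 4000.0]]]))
        rgb = ms.colorize(vol, cm)
        assert tuple(rgb[0, 0, 0]) == (255, 0, 0)
        assert tuple(rgb[0, 0, 1]) == (0, 0, 255)

    def test_white_point_is_exact_at_the_mid_anchor(self):
        cm = ms.t1w_colour_map(0.60)
        x = cm.lo + 0.60 * (cm.hi - cm.lo)
        rgb = ms.colorize(ms.IntensityVolume(np.full((1, 1, 1), x)), cm)
        assert tuple(rgb[0, 0, 0]) == (255, 255, 255)

    def test_t1map_preset_orientation(self):
        cm = ms.t1map_colour_map()
        assert (cm.lo, cm.hi) == (950.0, 3700.0)
        assert cm.mid_fraction == 0.40
        vol = ms.IntensityVolume(np.array([[[950.0, 3700.0]]]))
        rgb = ms.colorize(vol, cm)
        assert tuple(rgb[0, 0, 0]) == (0, 0, 255)
        assert tuple(rgb[0, 0, 1]) == (255, 0, 0)

    def test_out_of_range_intensities_clamp(self):
        cm = ms.t1w_colour_map()
        vol = ms.IntensityVolume(np.array([[[-50.0, 4090.0]]]))
        rgb = ms.colorize(vol, cm)
        assert tuple(rgb[0, 0, 0]) == (255, 0, 0)
        assert tuple(rgb[0, 0, 1]) == (0, 0, 255)

    def test_white_fraction_conversions(self):
        cm = ms.t1w_colour_map(0.60)
        assert ms.white_fraction_to_intensity(cm) == pytest.approx(2400.0)
        cm2 = ms.ColourMap(0, 100, (255, 0, 0), (255, 255, 255), (0, 0, 255), 0.5)
        assert ms.white_fraction_to_intensity(cm2, 0.5) == 50.0
        f = 0.37
        x = ms.white_fraction_to_intensity(cm, f)
        assert ms.intensity_to_white_fraction(cm, x) == pytest.approx(f)
        with pytest.raises(ValueError):
            ms.white_fraction_to_intensity(cm, 1.5)


class TestBoundaryIntensity:
    def test_two_voxel_interface(self):
        data = np.array([[[1907.0, 3246.0]]])
        labels = ms.TissueLabelMap(np.array([[[2, 3]]], dtype=np.int16))
        assert ms.interface_boundary_intensity(
            ms.IntensityVolume(data), labels) == pytest.approx(2576.5)

    def test_boundary_lies_between_tissue_means(self, noiseless_phantom):
        _, vol, labels = noiseless_phantom
        b = ms.interface_boundary_intensity(vol, labels)
        assert 1907.0 <= b <= 3246.0

    def test_no_interface_is_an_error(self):
        labels = ms.TissueLabelMap(np.full((4, 4, 4), 1, dtype=np.int16))
        with pytest.raises(ValueError, match="interface"):
            ms.interface_boundary_intensity(
                ms.IntensityVolume(np.ones((4, 4, 4))), labels)


class TestWilcoxon:
    def test_saturated_statistic_at_n20(self):
        """20 one-signed, tie-free differences give |Z| = 3.92."""
        x = np.arange(1.0, 21.0)
        res = ms.wilcoxon_signed_rank(x, np.zeros(20))
        assert abs(res.statistic) == pytest.approx(3.92, abs=0.005)
        assert res.p_two_tailed == pytest.approx(8.9e-5, rel=0.01)

    def test_effect_size_convention(self):
        """r = Z / sqrt(N) with N = 2 * n_pairs: 3.73 -> 0.59 at n = 20."""
        assert round(3.73 / np.sqrt(40), 2) == 0.59

    @pytest.mark.parametrize("z,r", TABLE_Z_R_CELLS)
    def test_published_effect_sizes_reconstruct_from_z(self, z, r):
        """Every published (Z, r) cell satisfies r = Z/sqrt(40) up to the
        print precision of both numbers."""
        assert abs(z / np.sqrt(40) - r) < 0.006

    def test_agrees_with_scipy_normal_approximation(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.normal(0, 1, 20)
            y = rng.normal(0.3, 1, 20)
            res = ms.wilcoxon_signed_rank(x, y)
            ref = stats.wilcoxon(x, y, zero_method="wilcox",
                                 correction=False, method="approx")
            assert abs(res.statistic) == pytest.approx(
                abs(ref.zstatistic), abs=1e-10)
            assert res.p_two_tailed == pytest.approx(ref.pvalue, rel=1e-9)

    def test_sign_convention_positive_when_x_exceeds_y(self):
        res = ms.wilcoxon_signed_rank(np.arange(1.0, 21.0), np.zeros(20))
        assert res.statistic > 0

    def test_all_zero_differences_is_an_error(self):
        x = np.ones(10)
        with pytest.raises(ValueError, match="zero"):
            ms.wilcoxon_signed_rank(x, x)

    def test_too_few_nonzero_pairs_is_an_error(self):
        x = np.ones(10)
        y = x.copy()
        y[0] += 1.0
        with pytest.raises(ValueError, match="at least 5"):
            ms.wilcoxon_signed_rank(x, y)


class TestPitmanMorgan:
    def test_equal_variances_give_t_zero(self):
        x = np.random.default_rng(0).normal(0, 2, 20)
        res = ms.pitman_morgan(x, x + 5.0)  # shift does not change the SD
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_df_is_n_minus_2(self):
        rng = np.random.default_rng(1)
        res = ms.pitman_morgan(rng.normal(0, 5.3, 20), rng.normal(0, 2.5, 20))
        assert res.df == 18

    def test_invariant_to_common_shift(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 3, 25), rng.normal(0, 1, 25)
        a = ms.pitman_morgan(x, y)
        b = ms.pitman_morgan(x + 123.4, y + 123.4)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-10)

    def test_p_value_matches_a_permutation_oracle(self):
        """Swapping members within pairs is the exchangeable null."""
        rng = np.random.default_rng(7)
        base = rng.normal(0, 1, 20)
        x = base + rng.normal(0, 0.8, 20)
        y = 0.6 * base + rng.normal(0, 0.9, 20)
        res = ms.pitman_morgan(x, y)
        n_perm, hits = 4000, 0
        obs = abs(res.statistic)
        for _ in range(n_perm):
            swap = rng.random(20) < 0.5
            xs = np.where(swap, y, x)
            ys = np.where(swap, x, y)
            r_sd = np.corrcoef(xs + ys, xs - ys)[0, 1]
            t = r_sd * np.sqrt(18) / np.sqrt(1 - r_sd ** 2)
            hits += abs(t) >= obs - 1e-12
        p_perm = hits / n_perm
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm) + 1e-3
        assert abs(res.p_two_tailed - p_perm) < 5 * se + 0.02

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError, match="variance"):
            ms.pitman_morgan(np.ones(10), np.arange(10.0))


class TestSteiger:
    def test_equal_correlations_give_zero(self):
        res = ms.steiger_dependent_correlations(0.5, 0.5, 0.3, 20)
        assert res.statistic == 0.0
        assert res.effect_size == 0.0

    def test_cohens_q_fisher_arithmetic(self):
        q = ms.cohens_q(0.66, 0.20)
        assert q == pytest.approx(0.590, abs=0.001)
        assert ms.grade_q(q) == "large"
        assert ms.grade_q(0.11) == "small"
        assert ms.grade_q(0.35) == "medium"

    def test_extreme_correlations_rejected(self):
        with pytest.raises(ValueError):
            ms.steiger_dependent_correlations(1.0, 0.5, 0.3, 20)

    def test_type_one_error_rate_matches_alpha(self):
        """Monte-Carlo oracle: under H0 (exchangeable correlations) the test
        rejects at ~5%."""
        rng = np.random.default_rng(11)
        rho, r12 = 0.4, 0.5
        cov = np.array([[1, rho, rho], [rho, 1, r12], [rho, r12, 1]])
        L = np.linalg.cholesky(cov)
        n, reps, rejects = 60, 1500, 0
        for _ in range(reps):
            z = rng.standard_normal((n, 3)) @ L.T
            c = np.corrcoef(z.T)
            try:
                res = ms.steiger_dependent_correlations(
                    c[0, 1], c[0, 2], c[1, 2], n)
            except ValueError:
                continue
            rejects += res.p_two_tailed < 0.05
        rate = rejects / reps
        assert abs(rate - 0.05) < 0.025

    def test_detects_a_true_difference(self):
        res = ms.steiger_dependent_correlations(0.8, 0.1, 0.2, 30)
        assert res.p_two_tailed < 0.01
        assert ms.grade_q(res.effect_size) == "large"


class TestICC:
    def test_identical_runs_give_one(self):
        run = np.array([3.0, 5.0, 9.0, 2.0, 7.0])
        assert ms.icc_test_retest(run, run) == pytest.approx(1.0)

    def test_constant_offset_keeps_consistency_at_one(self):
        run = np.array([3.0, 5.0, 9.0, 2.0, 7.0])
        assert ms.icc_test_retest(run, run + 4.0) == pytest.approx(1.0)

    def test_independent_runs_average_near_zero(self):
        rng = np.random.default_rng(13)
        vals = [ms.icc_test_retest(rng.normal(size=50), rng.normal(size=50))
                for _ in range(60)]
        assert abs(np.mean(vals)) < 0.06

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError, match="variance"):
            ms.icc_test_retest(np.ones(5), np.ones(5))


class TestCorrelationMaintenance:
    def test_unchanged_volumes_are_not_flagged(self):
        rng = np.random.default_rng(0)
        age = rng.uniform(20, 70, 20)
        vol = 800000 - 3000 * age + rng.normal(0, 5000, 20)
        res = ms.correlation_maintenance(vol, vol.copy(), age)
        assert res.test.statistic == 0.0
        assert not res.changed

    def test_destroyed_correlation_is_flagged(self):
        rng = np.random.default_rng(1)
        age = rng.uniform(20, 70, 20)
        before = 800000 - 3000 * age + rng.normal(0, 5000, 20)
        after = np.full(20, before.mean()) + rng.normal(0, 2000, 20)
        res = ms.correlation_maintenance(before, after, age)
        assert abs(res.r_age_after) < abs(res.r_age_before)
        assert res.changed
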