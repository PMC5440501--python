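"""The statistical core: local histograms, KS statistics, null, p-values."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cascade_wmh import (
    CumulativeHistogram,
    EmpiricalNull,
    KSResult,
    RunConfig,
    SequenceVolume,
    Study,
    VoxelMask,
    build_empirical_null,
    combine_pvalues,
    confidence_map,
    directional_statistic,
    expected_normal_histogram,
    ks_statistic,
    local_cumulative_histogram,
    normalize_intensities,
    p_value,
    threshold_confidence,
)
from cascade_wmh.detect import _cumulative_count_maps
from cascade_wmh.errors import DegenerateVolumeError, InputError
from cascade_wmh.normal import evident_normal_mask

from conftest import small_config


def _vol(data, spacing=(1, 1, 1), kind="FLAIR"):
    aff = np.diag(list(spacing) + [1.0])
    return SequenceVolume(affine=aff, data=np.asarray(data, float), kind=kind)


def _mask(data, spacing=(1, 1, 1)):
    aff = np.diag(list(spacing) + [1.0])
    return VoxelMask(affine=aff, data=data)


def _hist(F, edges=None):
    F = np.asarray(F, float)
    if edges is None:
        edges = np.linspace(0, 1, len(F) + 1)
    return CumulativeHistogram(bin_edges=edges, F=F, support_count=100)


def _random_cdf(rng, n_bins):
    p = rng.dirichlet(np.ones(n_bins))
    return np.cumsum(p) / p.sum()


# ---------------------------------------------------------------------------
# local cumulative histograms
# ---------------------------------------------------------------------------

class TestLocalHistogram:
    def test_constant_neighborhood_is_point_mass(self):
        data = np.full((9, 9, 9), 0.37)
        brain = np.ones(data.shape, bool)
        cfg = RunConfig(histogram_bins=16, neighborhood_radius_mm=2.0)
        h = local_cumulative_histogram(_vol(data), _mask(brain), (4, 4, 4), cfg)
        jump_bin = int(0.37 * 16)
        assert np.all(h.F[:jump_bin] == 0)
        assert np.all(h.F[jump_bin:] == 1)

    def test_two_value_neighborhood_hand_counted(self):
        # 10 in-brain voxels: 5 at 0.1 and 5 at 0.9, 4 bins -> F = (.5,.5,.5,1)
        data = np.zeros((9, 9, 9))
        brain = np.zeros(data.shape, bool)
        spots = [(4, 4, 4), (4, 4, 5), (4, 5, 4), (4, 5, 5), (5, 4, 4),
                 (5, 4, 5), (5, 5, 4), (5, 5, 5), (4, 4, 3), (4, 3, 4)]
        for i, s in enumerate(spots):
            brain[s] = True
            data[s] = 0.1 if i < 5 else 0.9
        cfg = RunConfig(histogram_bins=4, neighborhood_radius_mm=3.0)
        h = local_cumulative_histogram(_vol(data), _mask(brain), (4, 4, 4), cfg)
        assert h.support_count == 10
        np.testing.assert_allclose(h.F, [0.5, 0.5, 0.5, 1.0])

    def test_brain_edge_truncates_support(self):
        data = np.random.default_rng(0).random((9, 9, 9))
        brain = np.zeros(data.shape, bool)
        brain[:, :, :5] = True
        cfg = RunConfig(neighborhood_radius_mm=3.0)
        interior = local_cumulative_histogram(_vol(data), _mask(brain), (4, 4, 2), cfg)
        edge = local_cumulative_histogram(_vol(data), _mask(brain), (4, 4, 4), cfg)
        assert edge.support_count < interior.support_count

    def test_center_outside_brain_rejected(self):
        brain = np.zeros((5, 5, 5), bool)
        brain[2, 2, 2] = True
        cfg = RunConfig()
        with pytest.raises(InputError):
            local_cumulative_histogram(_vol(np.zeros((5, 5, 5))), _mask(brain),
                                       (0, 0, 0), cfg)

    def test_vectorized_maps_match_per_center(self, rng):
        """The all-voxel count maps agree exactly with the scalar operation."""
        data = rng.random((12, 11, 9))
        brain = rng.random(data.shape) < 0.8
        cfg = RunConfig(histogram_bins=16, neighborhood_radius_mm=2.5)
        vol = _vol(data, spacing=(1, 1, 2))
        bm = _mask(brain, spacing=(1, 1, 2))
        C, n = _cumulative_count_maps(vol, bm, cfg)
        centers = np.argwhere(brain)[rng.choice(brain.sum(), 25, replace=False)]
        for c in centers:
            h = local_cumulative_histogram(vol, bm, c, cfg)
            assert n[tuple(c)] == h.support_count
            np.testing.assert_allclose(C[:, c[0], c[1], c[2]] / n[tuple(c)], h.F,
                                       atol=1e-6)


# ---------------------------------------------------------------------------
# expected normal histogram
# ---------------------------------------------------------------------------

class TestExpectedNormalHistogram:
    def test_constant_image_equals_any_local_cdf(self):
        data = np.full((12, 12, 12), 0.5)
        brain = np.ones(data.shape, bool)
        normal = brain.copy()
        cfg = small_config(min_normal_voxels=10, histogram_bins=8)
        F2 = expected_normal_histogram(_vol(data), _mask(normal), _mask(brain), cfg)
        h = local_cumulative_histogram(_vol(data), _mask(brain), (6, 6, 6), cfg)
        np.testing.assert_allclose(F2.F, h.F, atol=1e-12)

    def test_binwise_average_of_two_centers(self):
        # two isolated 5-voxel neighborhoods with local CDFs (0.2, 1) and
        # (0.6, 1) on 2 bins -> F2 = (0.4, 1)
        data = np.zeros((20, 9, 9))
        brain = np.zeros(data.shape, bool)

        def put(x0, n_low):
            spots = [(x0, 4, 4), (x0, 4, 5), (x0, 5, 4), (x0, 3, 4), (x0, 4, 3)]
            for i, s in enumerate(spots):
                brain[s] = True
                data[s] = 0.25 if i < n_low else 0.75

        put(3, 1)
        put(14, 3)
        normal = np.zeros(data.shape, bool)
        normal[3, 4, 4] = normal[14, 4, 4] = True
        cfg = small_config(min_normal_voxels=1, histogram_bins=2,
                           neighborhood_radius_mm=2.0)
        F2 = expected_normal_histogram(_vol(data), _mask(normal), _mask(brain), cfg)
        np.testing.assert_allclose(F2.F, [0.4, 1.0])

    def test_mean_preserves_cdf_properties(self, rng):
        data = rng.random((16, 16, 12))
        brain = np.ones(data.shape, bool)
        normal = rng.random(data.shape) < 0.5
        cfg = small_config(min_normal_voxels=10)
        F2 = expected_normal_histogram(_vol(data), _mask(normal), _mask(brain), cfg)
        assert np.all(np.diff(F2.F) >= -1e-12)
        assert 0 <= F2.F[0] <= 1
        assert F2.F[-1] == pytest.approx(1.0)

    def test_too_small_normal_mask_rejected(self):
        data = np.random.default_rng(0).random((8, 8, 8))
        brain = np.ones(data.shape, bool)
        normal = np.zeros(data.shape, bool)
        normal[4, 4, 4] = True
        with pytest.raises(DegenerateVolumeError):
            expected_normal_histogram(_vol(data), _mask(normal), _mask(brain),
                                      small_config(min_normal_voxels=100))


# ---------------------------------------------------------------------------
# KS statistics
# ---------------------------------------------------------------------------

class TestKSStatistic:
    def test_identical_cdfs_zero(self):
        F = _hist([0.2, 0.5, 0.8, 1.0])
        ks = ks_statistic(F, F)
        assert ks.d_plus == 0.0 and ks.d_minus == 0.0

    def test_hand_computed_pair(self):
        ks = ks_statistic(_hist([0.10, 0.40, 0.80, 1.00]),
                          _hist([0.30, 0.60, 0.90, 1.00]))
        assert ks.d_plus == pytest.approx(0.0, abs=1e-15)
        assert ks.d_minus == pytest.approx(0.20, abs=1e-12)

    def test_extreme_right_shift(self):
        ks = ks_statistic(_hist([0, 0, 0, 1.0]), _hist([1.0, 1.0, 1.0, 1.0]))
        assert ks.d_minus == pytest.approx(1.0)
        assert ks.d_plus == 0.0

    def test_brute_force_oracle_thousand_pairs(self, rng):
        """Matches an explicit per-bin loop to 1e-12 on random CDF pairs."""
        for _ in range(1000):
            n_bins = int(rng.integers(2, 33))
            f1, f2 = _random_cdf(rng, n_bins), _random_cdf(rng, n_bins)
            ks = ks_statistic(_hist(f1), _hist(f2))
            bp = max(max(a - b for a, b in zip(f1, f2)), 0.0)
            bm = max(max(b - a for a, b in zip(f1, f2)), 0.0)
            assert abs(ks.d_plus - bp) < 1e-12
            assert abs(ks.d_minus - bm) < 1e-12

    def test_bin_mismatch_rejected(self):
        with pytest.raises(InputError):
            ks_statistic(_hist([0.5, 1.0]), _hist([0.2, 0.6, 1.0]))

    def test_directional_mapping_and_swap_symmetry(self):
        ks = KSResult(d_plus=0.1, d_minus=0.2)
        assert directional_statistic(ks, "hyper") == 0.2
        assert directional_statistic(ks, "hypo") == 0.1
        f1, f2 = _hist([0.1, 0.5, 1.0]), _hist([0.4, 0.7, 1.0])
        fwd, rev = ks_statistic(f1, f2), ks_statistic(f2, f1)
        assert fwd.d_minus == rev.d_plus and fwd.d_plus == rev.d_minus


# ---------------------------------------------------------------------------
# empirical null and p-values
# ---------------------------------------------------------------------------

class TestNullAndPValues:
    def test_constant_image_null_is_all_zero(self):
        data = np.full((14, 14, 10), 0.4)
        brain = np.ones(data.shape, bool)
        cfg = small_config(min_normal_voxels=10, null_sample_size=500)
        F2 = expected_normal_histogram(_vol(data), _mask(brain), _mask(brain), cfg)
        null = build_empirical_null(_vol(data), _mask(brain), F2, cfg,
                                    brain=_mask(brain))
        assert np.all(null.statistics == 0)

    def test_null_deterministic_for_seed(self, rng):
        data = rng.random((14, 14, 10))
        brain = np.ones(data.shape, bool)
        cfg = small_config(min_normal_voxels=10, null_sample_size=400)
        F2 = expected_normal_histogram(_vol(data), _mask(brain), _mask(brain), cfg)
        a = build_empirical_null(_vol(data), _mask(brain), F2, cfg, brain=_mask(brain))
        b = build_empirical_null(_vol(data), _mask(brain), F2, cfg, brain=_mask(brain))
        np.testing.assert_array_equal(a.statistics, b.statistics)
        assert a.statistics.min() >= 0 and a.statistics.max() <= 1

    def test_p_value_micro_example(self):
        null = EmpiricalNull(statistics=np.array([0.1, 0.2, 0.3, 0.4, 0.5]))
        # #{>= 0.35} = 2, n = 5 -> (1+2)/6
        assert p_value(0.35, null) == pytest.approx(0.5)

    def test_p_value_floor_and_ceiling(self):
        null = EmpiricalNull(statistics=np.linspace(0, 0.5, 200))
        assert p_value(0.0, null) == pytest.approx(1.0)
        assert p_value(0.99, null) == pytest.approx(1 / 201)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=10))
    @settings(max_examples=30, deadline=None)
    def test_p_value_monotone_nonincreasing(self, ds):
        null = EmpiricalNull(statistics=np.random.default_rng(5).random(300))
        ps = [p_value(d, null) for d in sorted(ds)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


class TestCombine:
    def test_fisher_closed_form_pair(self):
        # X = -2*(ln .5 + ln .5) = 2.7726, df=4: p = e^{-X/2} (1 + X/2)
        assert combine_pvalues([0.5, 0.5], "fisher") == pytest.approx(0.5966, abs=2e-4)

    def test_identity_on_single_p(self):
        for method in ("fisher", "max_p", "min_p"):
            assert combine_pvalues([0.03], method) == pytest.approx(0.03, abs=1e-12)

    def test_max_and_min(self):
        assert combine_pvalues([0.2, 0.6], "max_p") == 0.6
        assert combine_pvalues([0.2, 0.6], "min_p") == 0.2

    def test_fisher_against_scipy(self, rng):
        from scipy import stats

        for _ in range(20):
            ps = rng.uniform(0.01, 1.0, size=int(rng.integers(2, 5)))
            ours = combine_pvalues(ps, "fisher")
            theirs = stats.combine_pvalues(ps, method="fisher").pvalue
            assert ours == pytest.approx(theirs, rel=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            combine_pvalues([], "fisher")


# ---------------------------------------------------------------------------
# confidence map and thresholding on the phantom
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def phantom_confidence(small_phantom, small_cfg):
    study, truth = small_phantom
    brain = study.tissue.brain_mask()
    sub = study.subset(["FLAIR", "T1"])
    normalized = Study(
        volumes={k: normalize_intensities(v, brain) for k, v in sub.volumes.items()},
        tissue=study.tissue,
    )
    normal = evident_normal_mask(normalized, small_cfg)
    cm = confidence_map(normalized, normal, small_cfg)
    return cm, normal, truth


class TestConfidenceMap:
    def test_zero_inside_normal_mask_and_outside_region(self, phantom_confidence):
        cm, normal, _ = phantom_confidence
        assert np.all(cm.values[normal.data] == 0)
        assert np.all(cm.values[~cm.tested] == 0)

    def test_lesion_cores_highly_confident(self, phantom_confidence):
        from scipy import ndimage

        cm, _, truth = phantom_confidence
        core = ndimage.binary_erosion(truth.data) & cm.tested
        assert core.sum() > 50
        assert np.median(cm.values[core]) > 0.95

    def test_threshold_monotone_in_alpha(self, phantom_confidence):
        cm, _, _ = phantom_confidence
        m1 = threshold_confidence(cm, 0.01)
        m2 = threshold_confidence(cm, 0.05)
        m3 = threshold_confidence(cm, 0.2)
        assert np.all(m2.data[m1.data]) and np.all(m3.data[m2.data])

    def test_threshold_matches_confidence_rule(self, phantom_confidence):
        cm, _, _ = phantom_confidence
        mask = threshold_confidence(cm, 0.05)
        expected = cm.tested & (cm.values >= 0.95)
        np.testing.assert_array_equal(mask.data, expected)

    def test_per_sequence_pvalues_retained(self, phantom_confidence):
        cm, _, _ = phantom_confidence
        assert set(cm.p_per_sequence) == {"FLAIR", "T1"}
        for p in cm.p_per_sequence.values():
            assert p.min() > 0 and p.max() <= 1


class TestShiftDetection:
    def test_added_brightness_increases_d_minus_until_saturation(self, rng):
        """A hyperintense local perturbation strictly raises the statistic."""
        data = rng.normal(0.4, 0.05, size=(16, 16, 12)).clip(0, 1)
        brain = np.ones(data.shape, bool)
        cfg = small_config(min_normal_voxels=10, histogram_bins=32,
                           neighborhood_radius_mm=2.5)
        vol = _vol(data)
        F2 = expected_normal_histogram(vol, _mask(brain), _mask(brain), cfg)
        center = (8, 8, 6)
        prev = -1.0
        values = []
        for shift in (0.0, 0.1, 0.2, 0.4, 0.6):
            shifted = data.copy()
            sel = tuple(slice(c - 2, c + 3) for c in center)
            shifted[sel] = np.clip(shifted[sel] + shift, 0, 1)
            h = local_cumulative_histogram(_vol(shifted), _mask(brain), center, cfg)
            d = ks_statistic(h, F2).d_minus
            assert d >= prev - 1e-12
            prev = d
            values.append(d)
        assert values[-1] > values[0]
        assert values[-1] > 0.9  # saturates near 1 once fully displaced
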