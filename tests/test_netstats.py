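import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fnoverlap import netstats
from fnoverlap.formats import BrainMask
from tests.conftest import bh_oracle


class TestGroupTMap:
    def test_hand_computed_t_value(self):
        tm = netstats.group_t_map(np.array([[1.0], [2.0], [3.0]]))
        # mean 2, sd 1, n 3: t = 2 / (1/sqrt(3)) = 3.4641
        assert tm.t[0] == pytest.approx(2.0 * np.sqrt(3.0))
        assert tm.df == 2

    def test_zero_variance_voxel_flagged(self):
        tm = netstats.group_t_map(np.full((4, 2), 3.0))
        assert tm.zero_variance.all()
        assert (tm.t == 0).all() and (tm.p == 1).all()

    def test_symmetric_values_give_t_zero(self):
        tm = netstats.group_t_map(np.array([[2.0], [-2.0], [2.0], [-2.0]]))
        assert tm.t[0] == pytest.approx(0.0)
        assert tm.p[0] == pytest.approx(1.0)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            netstats.group_t_map(np.ones((1, 5)))


class TestFdrThreshold:
    KNOWN_PS = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205,
               0.212, 0.216, 0.222, 0.251, 0.269, 0.275, 0.34, 0.341,
               0.384, 0.569, 0.594, 0.696]

    def test_all_p_one_gives_empty_masks(self):
        tm = netstats.TMap(t=np.ones(5), p=np.ones(5), df=4,
                           zero_variance=np.zeros(5, dtype=bool))
        pos, neg = netstats.fdr_threshold(tm, level=0.05)
        assert pos.n_voxels == 0 and neg.n_voxels == 0

    def test_known_p_vector_matches_brute_force_oracle(self):
        p = np.array(self.KNOWN_PS)
        t = np.ones_like(p)
        tm = netstats.TMap(t=t, p=p, df=9, zero_variance=np.zeros(20, bool))
        pos, _ = netstats.fdr_threshold(tm, level=0.05)
        np.testing.assert_array_equal(pos.values, bh_oracle(p, 0.05))

    def test_single_p_reduces_to_plain_level(self):
        tm = netstats.TMap(t=np.array([2.0]), p=np.array([0.025]), df=5,
                           zero_variance=np.zeros(1, bool))
        pos, _ = netstats.fdr_threshold(tm, level=0.05)
        assert pos.n_voxels == 1

    def test_sign_split_disjoint(self):
        rng = np.random.default_rng(0)
        t = rng.standard_normal(200) * 5
        from scipy import stats as sps
        p = 2 * sps.t.sf(np.abs(t), 7)
        tm = netstats.TMap(t=t, p=p, df=7, zero_variance=np.zeros(200, bool))
        pos, neg = netstats.fdr_threshold(tm, level=0.01)
        assert not (pos.values & neg.values).any()

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(1, 300), st.integers(0, 2**31 - 1),
           st.floats(0.001, 0.2))
    def test_bh_matches_oracle_on_random_vectors(self, m, seed, level):
        p = np.random.default_rng(seed).uniform(size=m)
        np.testing.assert_array_equal(
            netstats.bh_reject(p, level), bh_oracle(p, level))

    def test_zero_variance_voxels_excluded_from_pool(self):
        p = np.array([0.01, 1.0, 1.0, 1.0])
        t = np.array([3.0, 0.0, 0.0, 0.0])
        zero = np.array([False, True, True, True])
        tm = netstats.TMap(t=t, p=p, df=7, zero_variance=zero)
        pos, _ = netstats.fdr_threshold(tm, level=0.04)
        # with the three dead voxels excluded, m=1 and p=.01 <= .04 rejects
        assert pos.values[0]


class TestOverlapMap:
    def test_two_identical_single_voxel_masks_sum_to_two(self):
        v = np.zeros(10, dtype=bool)
        v[3] = True
        masks = [netstats.SubNetworkMask(0, "positive", v),
                 netstats.SubNetworkMask(1, "positive", v)]
        om = netstats.overlap_map(masks)
        assert om.counts[3] == 2 and om.max_overlap == 2

    def test_disjoint_masks_max_one(self):
        a = np.zeros(10, dtype=bool); a[1] = True
        b = np.zeros(10, dtype=bool); b[7] = True
        om = netstats.overlap_map([
            netstats.SubNetworkMask(0, "positive", a),
            netstats.SubNetworkMask(0, "negative", b)])
        assert om.max_overlap == 1

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(1, 8), st.integers(0, 2**31 - 1))
    def test_counts_conserve_integer_mask_sum(self, k, seed):
        rng = np.random.default_rng(seed)
        masks = [netstats.SubNetworkMask(i, "positive", rng.random(40) < 0.3)
                 for i in range(k)]
        om = netstats.overlap_map(masks)
        expect = np.sum([m.values for m in masks], axis=0)
        np.testing.assert_array_equal(om.counts, expect)
        assert om.counts.max() <= k

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grids"):
            netstats.overlap_map([
                netstats.SubNetworkMask(0, "positive", np.zeros(5, bool) | True),
                netstats.SubNetworkMask(1, "positive", np.ones(6, bool))])


class TestVolumeSummary:
    def _brain(self, n=100):
        side = np.ones((n, 1, 1), dtype=np.uint8)
        return BrainMask(side)

    def _mask(self, idx, n=100, ic=0, pol="positive"):
        v = np.zeros(n, dtype=bool)
        v[list(idx)] = True
        return netstats.SubNetworkMask(ic, pol, v)

    def test_ten_voxels_of_hundred_is_ten_percent(self):
        rows = netstats.volume_summary(
            {"positive": [self._mask(range(10))]}, self._brain())
        row = next(r for r in rows if r["region"] == "union_positive")
        assert row["n_voxels"] == 10
        assert row["pct_whole_brain"] == pytest.approx(10.0)

    def test_identical_unions_intersect_fully(self):
        m = self._mask(range(20))
        m2 = self._mask(range(20), ic=1, pol="negative")
        rows = netstats.volume_summary(
            {"positive": [m], "negative": [m2]}, self._brain())
        inter = next(r for r in rows
                     if r["region"] == "intersection_negative_positive")
        assert inter["n_voxels"] == 20

    def test_three_disjoint_singletons_union_three(self):
        rows = netstats.volume_summary(
            {"positive": [self._mask([0])], "negative": [self._mask([1])],
             "neutral": [self._mask([2])]}, self._brain())
        allu = next(r for r in rows if r["region"] == "union_all_classes")
        assert allu["n_voxels"] == 3

    def test_union_monotone_as_masks_added(self):
        base = [self._mask(range(5))]
        more = base + [self._mask(range(4, 12), ic=1)]
        r1 = netstats.volume_summary({"positive": base}, self._brain())
        r2 = netstats.volume_summary({"positive": more}, self._brain())
        n1 = next(r for r in r1 if r["region"] == "union_positive")["n_voxels"]
        n2 = next(r for r in r2 if r["region"] == "union_positive")["n_voxels"]
        assert n2 >= n1


class TestArtifactFlags:
    def _result_with_timecourse(self, tc):
        class R:
            n_ics = 1
            subject_timecourses = [tc[:, None]]
        return R()

    def test_slow_sinusoid_not_flagged(self):
        t = np.arange(200) * 1.5
        tc = np.sin(2 * np.pi * 0.05 * t)
        rows = netstats.flag_artifact_components(
            self._result_with_timecourse(tc), tr=1.5)
        assert rows[0]["power_ratio"] > 10
        assert not rows[0]["artifact_flag"]

    def test_fast_sinusoid_flagged(self):
        t = np.arange(200) * 1.5
        tc = np.sin(2 * np.pi * 0.20 * t)
        rows = netstats.flag_artifact_components(
            self._result_with_timecourse(tc), tr=1.5)
        assert rows[0]["power_ratio"] < 1
        assert rows[0]["artifact_flag"]

    def test_peak_in_csf_flagged_regardless_of_spectrum(self):
        t = np.arange(200) * 1.5
        tc = np.sin(2 * np.pi * 0.05 * t)  # BOLD-like spectrum
        tmap = netstats.TMap(t=np.array([1.0, 9.0]), p=np.array([0.5, 1e-6]),
                             df=7, zero_variance=np.zeros(2, bool))
        rows = netstats.flag_artifact_components(
            self._result_with_timecourse(tc), tr=1.5,
            tissue_masks={"csf": np.array([False, True])},
            group_tmaps=[tmap])
        assert rows[0]["peak_in_tissue"] == "csf"
        assert rows[0]["artifact_flag"]

    def test_long_tr_truncates_band_with_warning(self, caplog):
        import logging
        tc = np.sin(np.arange(100))
        with caplog.at_level(logging.WARNING, logger="fnoverlap.netstats"):
            netstats.power_ratio(tc, tr=3.0)  # Nyquist 0.167 < 0.25
        assert any("truncated" in r.message for r in caplog.records)
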