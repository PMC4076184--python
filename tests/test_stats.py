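"""Group-level inference: one-sided t, linear contrast, BH-FDR, baselines."""

import itertools

import numpy as np
import pytest
import scipy.stats

from boldcaps.stats import (
    DEFAULT_CONTRAST_WEIGHTS,
    condition_significance,
    fdr_bh,
    linear_consciousness_contrast,
    one_sample_t_one_sided,
    peak_table,
    seed_correlation_map,
    sliding_window_maps,
    subject_cap_maps,
)

from conftest import make_session, series_session


def bh_step_up_oracle(p, q):
    """Literal step-up enumeration: reject all p <= p_(k*),
    k* = max{k : p_(k) <= k q / m}."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ps = p[order]
    k_star = 0
    for k in range(1, m + 1):
        if ps[k - 1] <= k * q / m:
            k_star = k
    reject = np.zeros(m, bool)
    if k_star:
        reject[p <= ps[k_star - 1]] = True
    return reject


class TestOneSampleT:
    def test_all_zero_maps_give_t0_p_half(self):
        t, p = one_sample_t_one_sided(np.zeros((5, 7)))
        assert (t == 0).all() and (p == 0.5).all()

    def test_zero_variance_positive_mean_sentinel(self):
        t, p = one_sample_t_one_sided(np.ones((4, 1)))
        assert np.isposinf(t[0]) and p[0] == 0.0
        t, p = one_sample_t_one_sided(-np.ones((4, 1)))
        assert np.isneginf(t[0]) and p[0] == 1.0

    def test_matches_textbook_formula(self):
        vals = np.array([2.1, 1.9, 2.0, 2.2, 1.8])
        t, p = one_sample_t_one_sided(vals[:, None])
        expected_t = vals.mean() / (vals.std(ddof=1) / np.sqrt(5))
        assert t[0] == pytest.approx(expected_t, abs=1e-10)
        assert p[0] == pytest.approx(scipy.stats.t.sf(expected_t, df=4), abs=1e-12)

    def test_insufficient_subjects_rejected(self):
        with pytest.raises(ValueError, match="3 subjects"):
            one_sample_t_one_sided(np.zeros((2, 4)))


class TestLinearContrast:
    def test_default_weights_sum_to_zero(self):
        assert sum(DEFAULT_CONTRAST_WEIGHTS) == 0.0

    def test_condition_constant_data_gives_zero_contrast(self):
        rng = np.random.default_rng(0)
        per_subject = rng.normal(size=(6, 1, 10))
        maps = np.repeat(per_subject, 4, axis=1)  # identical across conditions
        res = linear_consciousness_contrast(maps)
        assert (res.t_map == 0).all()
        assert (res.p_map == 0.5).all()
        assert res.n_significant == 0

    def test_nonzero_sum_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 0"):
            linear_consciousness_contrast(np.zeros((4, 4, 3)), weights=[1, 0, 0, 0])

    def test_subject_with_missing_condition_excluded(self):
        rng = np.random.default_rng(1)
        maps = rng.normal(size=(5, 4, 6))
        maps[2, 1] = np.nan
        res = linear_consciousness_contrast(maps)
        assert res.n_subjects == 4

    def test_planted_monotone_gain_detected_preferentially(self):
        """Voxels following the consciousness profile dominate sig_mask."""
        rng = np.random.default_rng(2)
        n_sub, n_vox = 18, 300
        planted = np.zeros(n_vox, bool)
        planted[:30] = True
        profile = np.array([1.0, 0.6, 0.2, 0.9])  # W, S, U, R
        maps = rng.normal(size=(n_sub, 4, n_vox))
        maps[:, :, planted] += profile[None, :, None] * 1.5
        res = linear_consciousness_contrast(maps)
        sens = res.sig_mask[planted].mean()
        fpr = res.sig_mask[~planted].mean()
        assert sens > 0.5
        assert sens > 5 * max(fpr, 1e-3)


class TestFdr:
    def test_textbook_example_all_rejected(self):
        mask = fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]), q=0.05)
        assert mask.all()

    def test_large_p_none_rejected(self):
        assert not fdr_bh(np.array([0.5, 0.6]), q=0.05).any()

    def test_all_zero_p_all_rejected(self):
        assert fdr_bh(np.zeros(5), q=0.05).all()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError, match="p-values"):
            fdr_bh(np.array([0.1, 1.2]))

    def test_agrees_with_step_up_oracle_exhaustively(self):
        """All p-vectors of length <= 5 over a fixed grid match the oracle
        (the acceptance suite extends this to length 6)."""
        grid = [0.0, 0.011, 0.024, 0.05, 0.2, 1.0]
        for length in range(1, 6):
            for p in itertools.product(grid, repeat=length):
                p = np.array(p)
                np.testing.assert_array_equal(
                    fdr_bh(p, q=0.05), bh_step_up_oracle(p, 0.05), err_msg=str(p)
                )


class TestConditionSignificance:
    def test_strong_uniform_coactivation_survives_fdr(self):
        rng = np.random.default_rng(3)
        maps = 1.0 + 0.1 * rng.normal(size=(10, 50))
        res = condition_significance(maps)
        assert res.sig_mask.all()

    def test_null_maps_rarely_significant(self):
        rng = np.random.default_rng(4)
        res = condition_significance(rng.normal(size=(10, 200)))
        assert res.sig_mask.mean() <= 0.05


class TestSubjectCapMaps:
    def test_assembly_and_empty_cells(self):
        frames = np.arange(12, dtype=float).reshape(4, 3)
        records = [
            {"subject_id": "s1", "condition_label": "a", "frames": frames,
             "labels": np.array([0, 0, 1, 1])},
            {"subject_id": "s1", "condition_label": "b", "frames": frames[:2],
             "labels": np.array([0, 0])},
        ]
        maps, counts = subject_cap_maps(records, k=2, subjects=["s1"], conditions=["a", "b"])
        np.testing.assert_allclose(maps[0, 0, 0], frames[:2].mean(axis=0))
        assert np.isnan(maps[0, 1, 1]).all()  # no cap-1 frames in condition b
        row = counts[(counts.condition_label == "b") & (counts.cap_index == 1)]
        assert row["n_frames_contributing"].item() == 0


class TestBaselines:
    def test_seed_correlates_perfectly_with_itself(self):
        rng = np.random.default_rng(5)
        sess = series_session(rng.normal(size=(60, 4)))
        cmap = seed_correlation_map(sess, np.array([2]))
        assert cmap[2] == pytest.approx(1.0, abs=1e-10)

    def test_negated_seed_voxel_gives_minus_one(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=60)
        sess = series_session(np.column_stack([x, -x]))
        cmap = seed_correlation_map(sess, np.array([0]))
        assert cmap[1] == pytest.approx(-1.0, abs=1e-10)

    def test_full_window_equals_static_map(self):
        rng = np.random.default_rng(7)
        sess = series_session(rng.normal(size=(60, 5)))
        maps = sliding_window_maps(sess, np.array([0]), window_frames=60, step=10)
        assert maps.shape[0] == 1
        # the window map uses the raw seed mean; same ordering as the static map
        static = seed_correlation_map(sess, np.array([0]))
        np.testing.assert_allclose(maps[0], static, atol=1e-10)

    def test_window_count_formula(self):
        rng = np.random.default_rng(8)
        sess = series_session(rng.normal(size=(60, 3)))
        maps = sliding_window_maps(sess, np.array([0]), window_frames=10, step=7)
        assert maps.shape[0] == (60 - 10) // 7 + 1

    def test_window_bounds_validated(self):
        sess = series_session(np.random.default_rng(9).normal(size=(20, 2)))
        with pytest.raises(ValueError, match=">= 3"):
            sliding_window_maps(sess, np.array([0]), window_frames=2)
        with pytest.raises(ValueError, match="exceeds"):
            sliding_window_maps(sess, np.array([0]), window_frames=25)

    def test_peak_table_reports_mm_coordinates(self):
        rng = np.random.default_rng(10)
        maps = rng.normal(size=(8, 27))
        maps[:, 13] += 3.0
        res = condition_significance(maps)
        mask = np.ones((3, 3, 3), bool)
        tbl = peak_table(res, mask, np.diag([3.0, 3.0, 3.0, 1.0]), top=5)
        if len(tbl):
            assert {"x_mm", "y_mm", "z_mm", "t", "p"} <= set(tbl.columns)
            assert tbl["t"].is_monotonic_decreasing
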