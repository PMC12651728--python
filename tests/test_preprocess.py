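"""Preprocessing operations: clipping, imputation, derived features,
scaling, censoring, and the frozen fit/transform contract."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agfn.pipeline import _subset, censor_map, label_matrix
from agfn.preprocess import (censor_at_onset, derive_delta, derive_slope,
                             fit, impute_decay, robust_scale, transform,
                             winsorize)


class TestWinsorize:
    def test_values_inside_bounds_unchanged(self):
        out = winsorize([5.0, 7.5], (1.0, 10.0))
        np.testing.assert_array_equal(out, [5.0, 7.5])

    def test_linear_interpolation_quantiles_on_1_to_1000(self):
        vals = np.arange(1, 1001, dtype=float)
        q_lo, q_hi = np.quantile(vals, [0.005, 0.995])  # linear interpolation
        assert q_lo == pytest.approx(5.995)
        assert q_hi == pytest.approx(995.005)
        assert winsorize([1000.0], (q_lo, q_hi))[0] == pytest.approx(995.005)

    def test_constant_vector_unchanged(self):
        out = winsorize([4.0, 4.0, 4.0], (4.0, 4.0))
        np.testing.assert_array_equal(out, [4.0, 4.0, 4.0])

    def test_unfitted_bounds_and_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            winsorize([1.0], None)
        with pytest.raises(ValueError, match="index 1"):
            winsorize([1.0, np.nan], (0.0, 2.0))


class TestImputeDecay:
    def test_observed_values_pass_through(self):
        out = impute_decay([3.0, 9.0], [1, 1], alpha=0.5, xbar=0.0)
        np.testing.assert_array_equal(out, [3.0, 9.0])

    def test_alpha_one_is_pure_carry_forward(self):
        out = impute_decay([20.0, 0.0, 0.0], [1, 0, 0], alpha=1.0, xbar=10.0)
        np.testing.assert_array_equal(out, [20.0, 20.0, 20.0])

    def test_hand_evaluated_blend(self):
        # previous imputed 20, baseline 10, alpha .5 -> 15
        out = impute_decay([20.0, 0.0], [1, 0], alpha=0.5, xbar=10.0)
        assert out[1] == pytest.approx(15.0)

    def test_empty_series_and_bad_alpha(self):
        assert len(impute_decay([], [], 0.5, 0.0)) == 0
        with pytest.raises(ValueError):
            impute_decay([1.0], [1], alpha=1.5, xbar=0.0)

    @given(st.floats(0.05, 0.95), st.floats(-50, 50), st.floats(-50, 50),
           st.integers(2, 40))
    @settings(deadline=None, max_examples=50)
    def test_gap_imputations_decay_geometrically_to_baseline(
            self, alpha, x0, xbar, gap):
        series = [x0] + [0.0] * gap
        mask = [1] + [0] * gap
        out = impute_decay(series, mask, alpha, xbar)
        for t in range(1, gap + 1):
            assert abs(out[t] - xbar) <= alpha ** t * abs(x0 - xbar) + 1e-9


class TestDerivedFeatures:
    def test_constant_series_has_zero_slope(self):
        s, ok = derive_slope((0.0, 5.0), (10.0, 5.0))
        assert s == 0.0 and ok

    def test_slope_hand_case(self):
        s, ok = derive_slope((0.0, 100.0), (10.0, 130.0))
        assert s == pytest.approx(3.0) and ok

    def test_degenerate_window_yields_flagged_sentinel(self):
        s, ok = derive_slope((4.0, 100.0), (4.0, 100.0))
        assert s == 0.0 and not ok

    def test_delta_hand_case_and_length_contract(self):
        np.testing.assert_array_equal(derive_delta([3.0, 5.0, 4.0]), [2, -1])
        np.testing.assert_array_equal(derive_delta([2.0, 2.0, 2.0]), [0, 0])
        assert len(derive_delta([7.0])) == 0


class TestRobustScale:
    def test_median_maps_to_zero(self):
        assert robust_scale([3.0], median=3.0, iqr=2.0)[0] == 0.0

    def test_hand_case_with_linear_interpolation_quartiles(self):
        x = np.array([1.0, 2, 3, 4, 100])
        q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
        assert (q1, med, q3) == (2.0, 3.0, 4.0)
        z = robust_scale(x, med, q3 - q1)
        assert z[-1] == pytest.approx(48.5)

    def test_zero_iqr_warns_and_returns_zeros(self):
        with pytest.warns(UserWarning, match="IQR"):
            z = robust_scale([5.0, 5.0], median=5.0, iqr=0.0)
        np.testing.assert_array_equal(z, [0.0, 0.0])

    def test_unfitted_statistics_rejected(self):
        with pytest.raises(ValueError):
            robust_scale([1.0], None, None)


@pytest.fixture(scope="module")
def fitted_and_tensors(small_cohort):
    pids, _ = label_matrix(small_cohort)
    train_ids, val_ids = pids[:80], pids[80:]
    pre = fit(_subset(small_cohort, train_ids))
    tensors = transform(_subset(small_cohort, train_ids), pre)
    return pre, tensors, train_ids, val_ids


class TestCensoring:
    def test_onset_absent_leaves_tensor_unchanged(self, fitted_and_tensors):
        _, tensors, *_ = fitted_and_tensors
        pt = next(iter(tensors.values()))
        assert censor_at_onset(pt, None) is pt

    def test_onset_masks_all_later_bins(self, fitted_and_tensors):
        _, tensors, *_ = fitted_and_tensors
        pt = next(iter(tensors.values()))
        cens = censor_at_onset(pt, 48.0)
        assert cens.M[48:].sum() == 0
        np.testing.assert_array_equal(cens.M[:48], pt.M[:48])
        # slope must come from the pre-onset window only
        for d in range(cens.X.shape[1]):
            obs = np.nonzero(cens.M[:, d])[0]
            if len(obs) and cens.slope_defined[d]:
                expected = ((cens.X[obs[-1], d] - cens.X[obs[0], d])
                            / (obs[-1] - obs[0]))
                assert cens.slope[d] == pytest.approx(expected)

    def test_onset_zero_leaves_only_statics(self, fitted_and_tensors):
        _, tensors, *_ = fitted_and_tensors
        pt = next(iter(tensors.values()))
        cens = censor_at_onset(pt, 0.0)
        assert cens.M.sum() == 0
        np.testing.assert_array_equal(cens.statics, pt.statics)

    def test_no_post_onset_feature_contributes(self, small_cohort):
        """Censoring soundness audited through the masks of every pair."""
        pids, _ = label_matrix(small_cohort)
        pre = fit(small_cohort)
        cmap = censor_map(small_cohort)
        tensors = transform(small_cohort, pre, cmap)
        for pid, onset in cmap.items():
            assert tensors[pid].M[int(np.ceil(onset)):].sum() == 0


class TestFitTransform:
    def test_transform_never_refits(self, fitted_and_tensors, small_cohort):
        pre, _, _, val_ids = fitted_and_tensors
        h0 = pre.content_hash()
        transform(_subset(small_cohort, val_ids), pre)
        assert pre.content_hash() == h0

    def test_unseen_variable_dropped_with_warning(self, fitted_and_tensors,
                                                  small_cohort):
        import pandas as pd

        pre, _, _, val_ids = fitted_and_tensors
        sub = _subset(small_cohort, val_ids)
        extra = pd.DataFrame({"patient_id": [val_ids[0]],
                              "variable": ["novel_marker"],
                              "t_hours": [1.0], "value": [1.0]})
        sub.timeseries = pd.concat([sub.timeseries, extra], ignore_index=True)
        with pytest.warns(UserWarning, match="novel_marker"):
            transform(sub, pre)

    def test_training_values_bounded_by_winsor_quantiles(
            self, fitted_and_tensors):
        pre, tensors, *_ = fitted_and_tensors
        for pt in tensors.values():
            raw = pt.raw
            for d in range(raw.shape[1]):
                col = raw[:, d][~np.isnan(raw[:, d])]
                if len(col):
                    assert col.min() >= pre.winsor_lo[d] - 1e-12
                    assert col.max() <= pre.winsor_hi[d] + 1e-12

    def test_different_training_partitions_fit_differently(self, small_cohort):
        pids, _ = label_matrix(small_cohort)
        pre_a = fit(_subset(small_cohort, pids[:60]))
        pre_b = fit(_subset(small_cohort, pids[60:]))
        assert pre_a.content_hash() != pre_b.content_hash()

    def test_transform_before_fit_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            transform(small_cohort, None)
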