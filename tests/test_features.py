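import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ltest.exceptions import ValidationError
from ltest.features import (
    FEATURE_COLUMNS,
    N_FEATURES,
    STAT_NAMES,
    anova_f_scores,
    build_feature_matrix,
    reverse_dataset,
    select_top_k,
    window_statistics,
)
from ltest.io_model import SIGNAL_COLUMNS


def brute_force_stats(window_values: np.ndarray) -> dict:
    """Independent per-window oracle built on scipy population moments."""
    w = np.asarray(window_values, dtype=float)
    out = {
        "mean": np.mean(w),
        "std": np.std(w, ddof=1),
        "variation": np.var(w, ddof=1),
        "max": np.max(w),
        "min": np.min(w),
        "range": np.max(w) - np.min(w),
    }
    if np.all(w == w[0]):
        out["skewness"] = 0.0
        out["kurtosis"] = 0.0
    else:
        out["skewness"] = stats.skew(w, bias=True)
        out["kurtosis"] = stats.kurtosis(w, fisher=True, bias=True)
    return out


class TestWindowStatistics:
    def test_constant_window_degenerates_to_zero(self):
        out = window_statistics(np.full(40, 2.5), window=24)
        np.testing.assert_array_equal(out["mean"], np.full(40, 2.5))
        for stat in ("std", "variation", "range", "kurtosis", "skewness"):
            np.testing.assert_array_equal(out[stat], np.zeros(40))

    def test_ramp_window_moments(self):
        x = np.arange(1.0, 25.0)  # the window 1..24
        out = window_statistics(x, window=24)
        oracle = brute_force_stats(x)
        assert out["mean"][-1] == pytest.approx(12.5)
        assert out["min"][-1] == 1.0 and out["max"][-1] == 24.0
        assert out["range"][-1] == 23.0
        assert out["skewness"][-1] == pytest.approx(0.0, abs=1e-12)
        assert out["kurtosis"][-1] == pytest.approx(oracle["kurtosis"], abs=1e-12)

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=300)
        window = 24
        out = window_statistics(x, window)
        for i in range(window - 1, len(x), 17):
            oracle = brute_force_stats(x[i - window + 1 : i + 1])
            for stat in STAT_NAMES:
                assert out[stat][i] == pytest.approx(oracle[stat], abs=1e-9), stat

    def test_start_padding_repeats_first_full_window(self):
        x = np.arange(30.0)
        out = window_statistics(x, window=24)
        np.testing.assert_array_equal(out["mean"][:23], np.full(23, out["mean"][23]))

    def test_short_series_rejected(self):
        with pytest.raises(ValidationError):
            window_statistics(np.zeros(10), window=24)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(derandomize=True, max_examples=20)
    def test_brute_force_agreement_property(self, seed):
        rng = np.random.default_rng(seed)
        window = int(rng.integers(2, 12))
        x = rng.normal(scale=rng.uniform(0.1, 10), size=window + 20)
        out = window_statistics(x, window)
        i = len(x) - 1
        oracle = brute_force_stats(x[i - window + 1 :])
        for stat in STAT_NAMES:
            assert out[stat][i] == pytest.approx(oracle[stat], abs=1e-9)


class TestReverseDataset:
    def test_involution(self, clean_datasets):
        ds = clean_datasets["turn180_1"]
        back = reverse_dataset(reverse_dataset(ds))
        np.testing.assert_array_equal(back.label, ds.label)
        np.testing.assert_allclose(back.times, ds.times, atol=1e-9)
        for name in SIGNAL_COLUMNS:
            np.testing.assert_array_equal(back.signals[name], ds.signals[name])
        assert back.direction == ds.direction

    def test_times_stay_increasing(self, clean_datasets):
        rev = reverse_dataset(clean_datasets["stand_up"])
        assert np.all(np.diff(rev.times) > 0)
        assert rev.direction == "reversed"

    def test_mirror_symmetry_of_windowed_mean(self, clean_datasets):
        ds = clean_datasets["turn90_1"]
        window = 24
        fwd = window_statistics(ds.signals["azimuth"], window)
        rev = window_statistics(ds.signals["azimuth"][::-1], window)
        # mean over the last window of the reversed series equals the mean
        # over the first full window of the forward series
        assert rev["mean"][-1] == pytest.approx(fwd["mean"][window - 1], abs=1e-9)


class TestFeatureMatrix:
    def test_exactly_82_columns(self, clean_datasets):
        fm = build_feature_matrix(clean_datasets["stand_up"])
        assert fm.X.shape[1] == N_FEATURES == 82
        assert len(fm.X) == clean_datasets["stand_up"].n_samples

    def test_schema(self):
        expected = {f"{s}_{st_}" for s in SIGNAL_COLUMNS for st_ in STAT_NAMES}
        expected |= set(SIGNAL_COLUMNS) | {"system_time"}
        assert set(FEATURE_COLUMNS) == expected
        assert len(FEATURE_COLUMNS) == 82

    def test_no_missing_values(self, clean_datasets):
        for ds in clean_datasets.values():
            for direction in ("forward", "reversed"):
                fm = build_feature_matrix(ds, direction)
                assert not fm.X.isna().any().any()

    def test_reversed_rows_mirror_forward_labels(self, clean_datasets):
        ds = clean_datasets["sit_down"]
        fwd = build_feature_matrix(ds, "forward")
        rev = build_feature_matrix(ds, "reversed")
        np.testing.assert_array_equal(rev.y, fwd.y[::-1])


class TestAnovaF:
    def test_hand_computed_f54(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 7.0, 8.0, 9.0]})
        y = np.array([0, 0, 0, 1, 1, 1])
        ranking = anova_f_scores(X, y)
        assert ranking.scores[0] == pytest.approx(54.0)

    def test_identical_distributions_score_zero(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        y = np.array([0, 0, 0, 1, 1, 1])
        assert anova_f_scores(X, y).scores[0] == pytest.approx(0.0)

    def test_constant_feature_scores_zero_with_warning(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 7, 8, 9], "c": np.ones(6)})
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.warns(UserWarning, match="constant"):
            ranking = anova_f_scores(X, y)
        assert ranking.names[-1] == "c"
        assert ranking.scores[-1] == 0.0

    def test_matches_scipy_f_oneway_on_random_draws(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            n = int(rng.integers(10, 60))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            x = rng.normal(size=n) + y * rng.uniform(0, 2)
            ranking = anova_f_scores(pd.DataFrame({"x": x}), y)
            expected = stats.f_oneway(x[y == 0], x[y == 1]).statistic
            assert ranking.scores[0] == pytest.approx(expected, rel=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            anova_f_scores(pd.DataFrame({"a": [1.0, 2.0]}), np.array([1, 1]))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(40, 6)), columns=list("abcdef"))
        y = rng.integers(0, 2, size=40)
        base = anova_f_scores(X, y)
        perm = anova_f_scores(X[["d", "a", "f", "b", "e", "c"]], y)
        assert dict(zip(base.names, base.scores)) == pytest.approx(
            dict(zip(perm.names, perm.scores))
        )


class TestSelectTopK:
    def test_full_set_in_ranked_order(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        y = rng.integers(0, 2, size=30)
        ranking = anova_f_scores(X, y)
        assert select_top_k(ranking, 5) == ranking.names

    def test_top_one_is_planted_feature(self):
        X = pd.DataFrame(
            {
                "signal": [1.0, 2, 3, 7, 8, 9],
                "flat1": np.ones(6),
                "flat2": np.full(6, 3.3),
            }
        )
        y = np.array([0, 0, 0, 1, 1, 1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ranking = anova_f_scores(X, y)
        assert select_top_k(ranking, 1) == ["signal"]

    def test_ties_keep_schema_order(self):
        X = pd.DataFrame(
            {"later": [1.0, 2, 7, 8], "earlier": [1.0, 2, 7, 8]}
        )
        X = X[["later", "earlier"]]
        y = np.array([0, 0, 1, 1])
        ranking = anova_f_scores(X, y)
        assert ranking.names == ["later", "earlier"]  # stable tie-break

    def test_out_of_range_k_rejected(self):
        ranking = anova_f_scores(
            pd.DataFrame({"a": [1.0, 2, 7, 8]}), np.array([0, 0, 1, 1])
        )
        with pytest.raises(ValidationError):
            select_top_k(ranking, 0)
        with pytest.raises(ValidationError):
            select_top_k(ranking, 2)
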