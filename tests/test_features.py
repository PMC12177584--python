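import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats as sps

from flimdose import (
    BASE_FEATURES,
    build_feature_table,
    select_tail,
    standardize,
    summary_stats,
    tail_fit,
)
from flimdose.features import (
    FeatureTable,
    TailTooShortError,
    fit_record_tail,
    interaction_names,
)
from tests.test_dataset import make_record


class TestSummaryStats:
    def test_constant_signal_guard(self):
        s = summary_stats(make_record(counts=[5.0] * 4))
        assert s["counts_avg"] == 5 and s["counts_std"] == 0
        assert s["counts_skew"] == 0 and s["counts_max"] == 5
        assert s["counts_tix"] == 0.0  # first occurrence of the max

    def test_worked_single_spike(self):
        # counts [0,1,0] on grid [0, 0.008, 0.016]: m2 = 2/9, m3 = 2/27.
        s = summary_stats(make_record(counts=[0.0, 1.0, 0.0]))
        assert s["counts_avg"] == pytest.approx(1 / 3)
        assert s["counts_std"] == pytest.approx(np.sqrt(2 / 9))
        assert s["counts_skew"] == pytest.approx(1 / np.sqrt(2))
        assert s["counts_max"] == 1.0
        assert s["counts_tix"] == pytest.approx(0.008)

    def test_symmetric_pulse_has_zero_skew(self):
        tri = np.concatenate([np.arange(10), np.arange(10)[::-1]]).astype(float)
        s = summary_stats(make_record(counts=tri))
        assert abs(s["counts_skew"]) < 1e-12

    @given(
        hnp.arrays(np.float64, st.integers(3, 60),
                   elements=st.floats(0, 1e5, allow_nan=False))
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_two_pass_moments(self, counts):
        s = summary_stats(make_record(counts=counts, n=len(counts)))
        mean = sum(counts) / len(counts)
        if np.ptp(counts) == 0:  # constant input: guard path, oracle would
            assert s["counts_std"] == 0  # otherwise divide rounding noise
            assert s["counts_skew"] == 0
            return
        m2 = sum((x - mean) ** 2 for x in counts) / len(counts)
        m3 = sum((x - mean) ** 3 for x in counts) / len(counts)
        assert s["counts_avg"] == pytest.approx(mean, abs=1e-10, rel=1e-10)
        assert s["counts_std"] == pytest.approx(np.sqrt(m2), abs=1e-10, rel=1e-10)
        expected_skew = 0.0 if m2**1.5 == 0 else m3 / m2**1.5
        assert s["counts_skew"] == pytest.approx(expected_skew, abs=1e-8, rel=1e-8)

    def test_agrees_with_scipy_conventions(self, rng):
        c = rng.poisson(100, size=500).astype(float)
        s = summary_stats(make_record(counts=c, n=500))
        assert s["counts_std"] == pytest.approx(np.std(c), rel=1e-12)
        assert s["counts_skew"] == pytest.approx(sps.skew(c, bias=True), rel=1e-10)


class TestSelectTail:
    def test_by_hand_threshold_walk(self):
        rec = make_record(counts=[0, 10, 9.6, 9.4, 5, 1] + [0.5] * 10)
        sl = select_tail(rec, threshold_fraction=0.95)
        assert sl.start == 3  # first sample after the peak below 9.5

    def test_max_at_origin(self):
        c = 100 * np.exp(-0.5 * np.arange(50))
        rec = make_record(counts=c, n=50)
        sl = select_tail(rec)
        assert sl.start == 1 + int(np.argmax(c[1:] < 0.95 * c[0]))

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            select_tail(make_record(counts=[0.0] * 20))

    def test_short_tail_error(self):
        rec = make_record(counts=[0, 10, 1, 1, 1])
        with pytest.raises(TailTooShortError):
            select_tail(rec)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_suffix_and_threshold_monotonicity(self, seed):
        r = np.random.default_rng(seed)
        n = 80
        c = 1000 * np.exp(-0.2 * np.arange(n)) + r.integers(0, 5, n)
        rec = make_record(counts=c, n=n)
        hi = select_tail(rec, 0.95)
        assert hi.stop == n  # always a suffix
        lo = select_tail(rec, 0.5)
        assert lo.start >= hi.start  # lower threshold never lengthens the tail


class TestTailFit:
    def test_noiseless_recovery(self):
        t = np.arange(0, 8, 0.008)
        y = 100 * np.exp(-0.5 * t) + 10
        fit = tail_fit(t, y)
        assert fit.converged
        assert fit.a == pytest.approx(100, rel=1e-6)
        assert fit.b == pytest.approx(0.5, rel=1e-6)
        assert fit.c == pytest.approx(10, rel=1e-6)
        assert fit.rss < 1e-12 * len(t)

    def test_refit_own_model_is_stable(self):
        t = np.arange(0, 5, 0.008)
        first = tail_fit(t, 2e4 * np.exp(-1.7 * t) + 40)
        resampled = first.a * np.exp(-first.b * t) + first.c
        second = tail_fit(t, resampled)
        assert second.a == pytest.approx(first.a, rel=1e-8)
        assert second.b == pytest.approx(first.b, rel=1e-8)
        assert second.c == pytest.approx(first.c, rel=1e-8)

    def test_constant_counts_flagged(self):
        t = np.arange(0, 1, 0.008)
        fit = tail_fit(t, np.full_like(t, 7.0))
        assert not fit.converged

    def test_poisson_noise_recovery_within_5_percent(self):
        t = np.arange(0, 8, 0.008)
        expected = 2e4 * np.exp(-0.8 * t) + 30
        rng = np.random.default_rng(1)
        errs = []
        for _ in range(100):
            fit = tail_fit(t, rng.poisson(expected).astype(float))
            errs.append(abs(fit.b - 0.8) / 0.8)
        assert np.mean(errs) < 0.05

    def test_too_few_points(self):
        with pytest.raises(TailTooShortError):
            tail_fit(np.arange(5) * 0.1, np.ones(5))


class TestFeatureTable:
    def test_column_counts(self, default_ds):
        ds, _ = default_ds
        base = build_feature_table(ds, include_interactions=False)
        full = build_feature_table(ds, include_interactions=True)
        assert list(base.column_names) == list(BASE_FEATURES)
        assert len(base.column_names) == 7
        assert len(full.column_names) == 28

    def test_two_feature_interaction_combinatorics(self):
        assert len(interaction_names(["u", "v"])) == 1
        assert interaction_names(["u", "v"]) == ["u*v"]
        assert len(interaction_names(list("abcde"))) == 10

    def test_interactions_are_exact_products(self, default_table):
        t = default_table
        cols = {n: t.values[:, i] for i, n in enumerate(t.column_names)}
        for name in t.column_names[7:]:
            x, y = name.split("*")
            np.testing.assert_array_equal(cols[name], cols[x] * cols[y])

    def test_noiseless_fit_rate_matches_generator_lifetime(self):
        from flimdose import GeneratorConfig, conform_lengths, generate_dataset

        cfg = GeneratorConfig(cells_per_condition=1, poisson_noise=False,
                              cell_cv=0.0, length_jitter=False, seed=0)
        ds, truth = generate_dataset(cfg)
        table = build_feature_table(conform_lengths(ds), include_interactions=False)
        fit_rate = table.values[:, list(table.column_names).index("fit_rate")]
        # 2% bound: the pulse-smeared region just after the peak and the
        # rounding of the noise-free expectation bias the rate slightly.
        np.testing.assert_allclose(fit_rate, 1.0 / truth["tau_ns"], rtol=0.02)

    def test_targets_align_with_labels(self, small_ds):
        ds, _ = small_ds
        t = build_feature_table(ds, target_name="exposure", include_interactions=False)
        assert set(np.unique(t.target)) <= {0.0, 24.0, 48.0, 72.0, 96.0}

    def test_csv_round_trip(self, small_table, tmp_path):
        path = tmp_path / "feat.csv"
        small_table.to_csv(path)
        back = FeatureTable.from_csv(path, target_name="dosage")
        assert back.column_names == small_table.column_names
        np.testing.assert_allclose(back.values, small_table.values, rtol=1e-12)
        np.testing.assert_allclose(back.target, small_table.target, rtol=1e-12)


class TestStandardize:
    def test_closed_form_z_scores(self):
        t = FeatureTable(["x"], np.array([[1.0], [2.0], [3.0]]))
        out, _ = standardize(t)
        np.testing.assert_allclose(out.values.ravel(),
                                   [-1.22474487, 0.0, 1.22474487], atol=1e-8)

    def test_idempotent_on_fit_rows(self):
        t = FeatureTable(["x", "y"], np.random.default_rng(0).normal(size=(40, 2)))
        once, _ = standardize(t)
        twice, _ = standardize(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-10)

    def test_fit_rows_statistics_apply_to_all_rows(self, small_table):
        rows = np.arange(0, small_table.n_rows, 2)
        out, std = standardize(small_table, rows)
        sub = out.values[rows]
        assert np.abs(sub.mean(axis=0)).max() < 1e-10
        assert np.abs(sub.std(axis=0) - 1).max() < 1e-10
        np.testing.assert_allclose(std.inverse_transform(out.values),
                                   small_table.values, rtol=1e-10)

    def test_constant_column_errors_with_name(self):
        t = FeatureTable(["ok", "flat"], np.column_stack([np.arange(5.0), np.ones(5)]))
        with pytest.raises(ValueError, match="flat"):
            standardize(t)


def test_record_tail_fit_end_to_end(small_ds):
    ds, truth = small_ds
    fit = fit_record_tail(ds[0])
    assert fit.converged
    tau = truth["tau_ns"].iloc[0]
    assert fit.b == pytest.approx(1.0 / tau, rel=0.1)  # Poisson noise present
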