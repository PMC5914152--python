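import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fbcsp import (FeatureTable, Standardizer, assemble_features,
                   log_bandpower, mi_rank, select_top)


def make_table(values, labels=None):
    values = np.atleast_2d(values)
    if labels is None:
        labels = np.array(["a", "b"] * (len(values) // 2) + ["a"] * (len(values) % 2))
    prov = [("band", i) for i in range(values.shape[1])]
    return FeatureTable(values=values, provenance=prov, labels=labels)


class TestLogBandpower:
    def test_unit_variance_is_zero(self, rng):
        x = rng.standard_normal(100_000)
        x = (x - x.mean()) / x.std()
        assert abs(log_bandpower(x)) < 1e-9

    @settings(deadline=None, max_examples=30)
    @given(st.floats(0.01, 100.0))
    def test_scaling_adds_two_log_c(self, c):
        # tolerance dominated by the epsilon guard at the smallest scales
        x = np.sin(np.linspace(0, 20, 500))
        assert log_bandpower(c * x) - log_bandpower(x) == pytest.approx(
            2 * np.log(c), abs=1e-6)

    def test_matches_two_pass_variance_oracle(self, rng):
        x = rng.normal(3.0, 2.5, 1000)
        mean = sum(x) / len(x)
        var = sum((v - mean) ** 2 for v in x) / len(x)
        assert log_bandpower(x) == pytest.approx(np.log(var), abs=1e-12)

    def test_constant_signal_guarded(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            out = log_bandpower(np.full(100, 7.0))
        assert np.isfinite(out)


class TestAssembleFeatures:
    def test_k_is_bands_times_components(self, rng):
        labels = np.array(["a", "b"] * 5)
        projected = {f"band{i}": rng.standard_normal((10, 14, 192))
                     for i in range(10)}
        table = assemble_features(projected, labels)
        assert table.n_features == 140
        assert len(table.provenance) == 140

    def test_pairs_configuration_gives_sixty(self, rng):
        labels = np.array(["a", "b"] * 5)
        projected = {f"band{i}": rng.standard_normal((10, 6, 192))
                     for i in range(10)}
        assert assemble_features(projected, labels).n_features == 60

    def test_provenance_roundtrips_through_csv(self, rng, tmp_path):
        table = make_table(rng.standard_normal((6, 4)))
        path = tmp_path / "features.csv"
        table.to_csv(path)
        back = FeatureTable.from_csv(path)
        assert back.provenance == table.provenance
        np.testing.assert_allclose(back.values, table.values)
        assert list(back.labels) == list(table.labels)

    def test_inconsistent_trial_counts_rejected(self, rng):
        projected = {"a": rng.standard_normal((10, 2, 50)),
                     "b": rng.standard_normal((9, 2, 50))}
        with pytest.raises(ValueError, match="trial counts"):
            assemble_features(projected, np.array(["a"] * 10))


class TestStandardizer:
    def test_training_columns_become_standard(self, rng):
        table = make_table(rng.normal(5, 3, (40, 6)))
        out = Standardizer().fit_transform(table)
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.values.var(axis=0), 1.0, atol=1e-10)

    def test_test_rows_use_training_statistics(self, rng):
        train = make_table(rng.normal(0, 2, (30, 3)))
        scaler = Standardizer().fit(train)
        shifted = make_table(train.values[:1] + 4.0, labels=np.array(["a"]))
        base = scaler.transform(make_table(train.values[:1], np.array(["a"])))
        out = scaler.transform(shifted)
        np.testing.assert_allclose(out.values[0] - base.values[0],
                                   4.0 / scaler.scale_, atol=1e-12)

    def test_fit_never_reads_test_rows(self, rng):
        """Leakage probe: garbage test rows leave the fitted statistics unchanged."""
        train = make_table(rng.normal(0, 1, (20, 4)))
        s1 = Standardizer().fit(train)
        _ = s1.transform(make_table(np.full((2, 4), 1e9),
                                    labels=np.array(["a", "b"])))
        s2 = Standardizer().fit(train)
        np.testing.assert_array_equal(s1.mean_, s2.mean_)
        np.testing.assert_array_equal(s1.scale_, s2.scale_)

    def test_zero_variance_column_centered_only(self):
        vals = np.column_stack([np.arange(10.0), np.full(10, 3.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            out = Standardizer().fit_transform(make_table(vals))
        np.testing.assert_allclose(out.values[:, 1], 0.0)


class TestMIRanking:
    def test_independent_feature_inside_permutation_null(self, rng):
        n = 120
        y = np.array(["a", "b"] * (n // 2))
        x = rng.standard_normal((n, 1))
        table = make_table(x, labels=y)
        observed = mi_rank(table, k=3, seed=0).mi[0]
        null = []
        for _ in range(200):
            perm = make_table(x, labels=rng.permutation(y))
            null.append(mi_rank(perm, k=3, seed=0).mi[0])
        assert observed <= np.quantile(null, 0.995)

    def test_separated_feature_approaches_label_entropy(self, rng):
        n = 200
        y = np.array(["a", "b"] * (n // 2))
        x = np.where(y == "a", 0.0, 100.0) + rng.normal(0, 0.1, n)
        table = make_table(x.reshape(-1, 1), labels=y)
        assert mi_rank(table, k=3, seed=0).mi[0] == pytest.approx(np.log(2),
                                                                  abs=0.05)

    def test_ranking_invariant_under_monotone_transform(self, rng):
        n = 150
        y = np.array(["a", "b"] * (n // 2))
        vals = rng.standard_normal((n, 5))
        vals[:, 2] += (y == "b") * 1.5
        vals[:, 4] += (y == "b") * 0.5
        transformed = vals.copy()
        transformed[:, 1] = np.exp(vals[:, 1])
        transformed[:, 2] = vals[:, 2] ** 3
        r1 = mi_rank(make_table(vals, labels=y), seed=0)
        r2 = mi_rank(make_table(transformed, labels=y), seed=0)
        np.testing.assert_array_equal(r1.order, r2.order)

    def test_estimates_nonnegative_and_ranking_is_permutation(self, rng):
        table = make_table(rng.standard_normal((40, 8)))
        r = mi_rank(table, seed=0)
        assert np.all(r.mi >= 0)
        assert sorted(r.order) == list(range(8))

    def test_k_reduced_for_tiny_classes(self, rng):
        y = np.array(["a", "a", "a", "b", "b", "b"])
        table = make_table(rng.standard_normal((6, 2)), labels=y)
        with pytest.warns(UserWarning, match="reduced"):
            r = mi_rank(table, k=5, seed=0)
        assert r.k == 2

    def test_ranking_stable_across_halves_of_stationary_data(self, rng):
        n = 400
        y = np.array(["a", "b"] * (n // 2))
        vals = rng.standard_normal((n, 10))
        vals[:, 0] += (y == "b") * 2.0
        vals[:, 3] += (y == "b") * 1.0
        vals[:, 7] += (y == "b") * 0.5
        r1 = mi_rank(make_table(vals[: n // 2], labels=y[: n // 2]), seed=0)
        r2 = mi_rank(make_table(vals[n // 2:], labels=y[n // 2:]), seed=0)
        from scipy import stats
        rho, _ = stats.spearmanr(np.argsort(r1.order), np.argsort(r2.order))
        assert rho > 0.5


class TestSelectTop:
    def test_full_selection_is_identity(self, rng):
        table = make_table(rng.standard_normal((20, 6)))
        r = mi_rank(table, seed=0)
        out = select_top(r, table, 6)
        assert out.n_features == 6
        np.testing.assert_allclose(np.sort(out.values.ravel()),
                                   np.sort(table.values.ravel()))

    def test_selection_is_a_prefix_of_the_ranking(self, rng):
        table = make_table(rng.standard_normal((30, 12)))
        r = mi_rank(table, seed=0)
        out = select_top(r, table, 9)
        expected = [table.provenance[i] for i in r.order[:9]]
        assert out.provenance == expected

    @pytest.mark.parametrize("n_sel", [0, 13])
    def test_out_of_range_rejected(self, rng, n_sel):
        table = make_table(rng.standard_normal((10, 12)))
        r = mi_rank(table, seed=0)
        with pytest.raises(ValueError):
            select_top(r, table, n_sel)
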