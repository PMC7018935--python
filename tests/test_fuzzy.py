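"""Subordinate function μ, contribution-rate weights, D score, classes, ranks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coldeval import (
    ColdToleranceEvaluator,
    classify,
    d_score,
    fit_pca,
    membership,
    rank,
    weights,
)
from coldeval.fuzzy import MinMaxMembership, TOLERANCE_CLASSES


class TestMembership:
    def test_worked_example_matches_printed_values(self, worked_example):
        """All 18 published μ values agree to the printed precision (the CI
        inputs are printed at 3 dp, so agreement is to one last-digit unit)."""
        mu = membership(worked_example["ci_scores"])
        np.testing.assert_allclose(
            mu.to_numpy(), worked_example["printed_membership"].to_numpy(), atol=1e-3
        )

    def test_extreme_varieties_hit_exact_bounds(self, worked_example):
        mu = membership(worked_example["ci_scores"])
        assert mu.loc["WR164", "CI(1)"] == 1.0  # column max
        assert mu.loc["WR155", "CI(1)"] == 0.0  # column min
        assert (mu.min() == 0.0).all() and (mu.max() == 1.0).all()

    def test_degenerate_constant_column_rejected(self):
        df = pd.DataFrame({"CI(1)": [1.0, 2.0, 3.0], "CI(2)": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="CI\\(2\\)"):
            membership(df)

    @given(a=st.floats(0.1, 10.0), b=st.floats(-5.0, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_invariance_under_increasing_affine_maps(self, a, b):
        col = np.array([0.3, -1.2, 2.0, 0.9, -0.4])
        mu0 = membership(pd.DataFrame({"c": col}))
        mu1 = membership(pd.DataFrame({"c": a * col + b}))
        np.testing.assert_allclose(mu0.to_numpy(), mu1.to_numpy(), atol=1e-9)
        mu_neg = membership(pd.DataFrame({"c": -a * col + b}))
        np.testing.assert_allclose(mu_neg.to_numpy(), 1.0 - mu0.to_numpy(), atol=1e-9)

    def test_transform_on_new_data_uses_fitted_extremes(self):
        scaler = MinMaxMembership().fit(pd.DataFrame({"c": [0.0, 2.0]}))
        out = scaler.transform(pd.DataFrame({"c": [1.0, 3.0]}))
        np.testing.assert_allclose(out["c"], [0.5, 1.5])


class TestWeights:
    def test_physiological_rates_reproduce_printed_weights(self):
        w = weights((46.789, 28.146, 18.904))
        np.testing.assert_allclose(w, (0.499, 0.300, 0.201), atol=1e-3)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_morphological_rates_reproduce_printed_weights(self):
        w = weights((54.545, 32.01))
        np.testing.assert_allclose(w, (0.630, 0.369), atol=1e-3)

    def test_single_component_gets_unit_weight(self):
        np.testing.assert_allclose(weights((77.7,)), [1.0])

    @pytest.mark.parametrize("bad", [(), (0.0, 50.0), (-1.0, 2.0), (np.nan, 1.0)])
    def test_invalid_rates_rejected(self, bad):
        with pytest.raises(ValueError):
            weights(bad)


class TestDScore:
    def test_unit_membership_gives_unit_d(self):
        mu = pd.DataFrame({"a": [1.0], "b": [1.0], "c": [1.0]})
        assert d_score(mu, weights((50.0, 30.0, 20.0)))[0] == pytest.approx(1.0)

    def test_weighted_sum_oracle_values(self):
        """Hand-computed Σ μ·w for two varieties of the worked example."""
        w = np.array([0.499, 0.300, 0.201])
        mu = pd.DataFrame(
            [[0.000, 0.205, 0.231], [0.440, 1.000, 1.000]], index=["WR155", "WR16"]
        )
        d = d_score(mu, w)
        assert d["WR155"] == pytest.approx(0.1080, abs=1e-4)
        assert d["WR16"] == pytest.approx(0.7206, abs=1e-4)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            d_score(pd.DataFrame({"a": [0.5], "b": [0.5]}), [1.0])

    def test_d_bounded_by_membership_range(self, worked_example):
        mu = membership(worked_example["ci_scores"])
        d = d_score(mu, weights(worked_example["contribution_rates"]))
        assert (d >= 0.0).all() and (d <= 1.0).all()


class TestClassify:
    @pytest.mark.parametrize(
        "d,cls",
        [
            (0.8328, "very_strong"),
            (0.35, "moderate"),
            (0.0, "weak"),
            (1.0, "very_strong"),
            # boundaries go to the higher class
            (0.2, "moderate"),
            (0.5, "strong"),
            (0.8, "very_strong"),
            (0.19999, "weak"),
        ],
    )
    def test_threshold_rule(self, d, cls):
        assert classify(d) == cls

    def test_every_d_gets_exactly_one_class(self):
        out = classify(pd.Series(np.linspace(0, 1, 1001)))
        assert set(out.unique()) <= set(TOLERANCE_CLASSES)
        assert out.notna().all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify(1.2)


class TestRank:
    def test_published_top_three_order(self):
        d = pd.Series({"WR29": 0.8328, "WR157": 0.8219, "Kongyu131": 0.8181})
        assert rank(d).tolist() == [1, 2, 3]

    def test_competition_ranking_for_ties(self):
        assert rank(pd.Series([0.7, 0.7, 0.5])).tolist() == [1, 1, 3]

    def test_single_variety(self):
        assert rank(pd.Series([0.4])).tolist() == [1]

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            rank(pd.Series([], dtype=float))


class TestColdToleranceEvaluator:
    def test_end_to_end_invariant_to_positive_rescaling(self, random_index_matrix):
        """Correlation PCA + min–max membership make D unit-free."""
        ev1 = ColdToleranceEvaluator().fit(random_index_matrix)
        scaled = random_index_matrix.data * np.array([3.0, 0.2, 10.0, 7.5, 0.01])
        from coldeval import IndexMatrix

        ev2 = ColdToleranceEvaluator().fit(
            IndexMatrix(scaled, random_index_matrix.polarity)
        )
        np.testing.assert_allclose(ev1.d_.to_numpy(), ev2.d_.to_numpy(), atol=1e-10)

    def test_variety_maximal_in_every_component_gets_d_one(self):
        ci = pd.DataFrame(
            {"CI(1)": [2.0, 1.0, -1.0], "CI(2)": [1.5, 0.0, -0.5]},
            index=["top", "mid", "low"],
        )
        ev = ColdToleranceEvaluator(
            precomputed_ci=True, contribution_rates=[60.0, 40.0]
        ).fit(ci)
        assert ev.d_["top"] == pytest.approx(1.0)
        assert ev.d_["low"] == pytest.approx(0.0)
        assert ev.ranks_["top"] == 1

    def test_results_table_is_consistent(self, random_index_matrix):
        ev = ColdToleranceEvaluator().fit(random_index_matrix)
        assert ev.weights_.sum() == pytest.approx(1.0, abs=1e-12)
        assert list(ev.results_.columns[-3:]) == ["D", "tolerance_class", "rank"]
        assert (ev.d_ >= 0).all() and (ev.d_ <= 1).all()
        reclass = classify(ev.d_)
        assert (reclass == ev.classes_).all()

    def test_precomputed_ci_requires_rates(self, worked_example):
        with pytest.raises(ValueError, match="contribution_rates"):
            ColdToleranceEvaluator(precomputed_ci=True).fit(worked_example["ci_scores"])

    def test_transform_scores_new_varieties(self, random_index_matrix):
        ev = ColdToleranceEvaluator().fit(random_index_matrix)
        d_new = ev.transform(random_index_matrix.data.iloc[:3])
        np.testing.assert_allclose(d_new.to_numpy(), ev.d_.iloc[:3].to_numpy(), atol=1e-10)

    def test_sklearn_params_round_trip(self):
        ev = ColdToleranceEvaluator(cumulative_threshold=90.0)
        params = ev.get_params()
        assert params["cumulative_threshold"] == 90.0
        ev.set_params(cumulative_threshold=80.0)
        assert ev.cumulative_threshold == 80.0
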