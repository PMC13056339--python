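"""Grid-search likelihood fitting, baselines, and model comparison."""

import math

import numpy as np
import pandas as pd
import pytest

from pluralcause import (
    FitConfig,
    build_predictor,
    compare_models,
    constant_baseline_fit,
    grid_fit,
    linear_combination_baseline,
    question_means,
    scale_prediction,
)
from pluralcause.fitting import rescale_means


class TestScalePrediction:
    @pytest.mark.parametrize(
        "raw, gamma, expected",
        [
            (1.0, 0.26, 1.0),
            (1.0, 2.93, 1.0),
            (0.25, 0.5, 0.5),
            (-0.2, 0.26, 0.0),  # negative scores clip before exponentiation
            (0.0, 1.7, 0.0),
        ],
    )
    def test_values(self, raw, gamma, expected):
        assert scale_prediction(raw, gamma) == pytest.approx(expected)

    def test_gamma_must_be_positive(self):
        with pytest.raises(ValueError):
            scale_prediction(0.5, 0.0)


def synthetic_predict(s, w=0.0):
    """A smooth toy prediction function over five questions."""
    base = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
    return np.clip(base * (0.5 + s) + 0.2 * w * (1 - base), 0.0, 1.0)


class TestGridFit:
    def test_recovers_noise_free_truth(self):
        config = FitConfig(
            s_grid=np.arange(0.0, 1.01, 0.1),
            gamma_grid=np.array([0.5, 1.0, 2.0]),
        )
        truth = scale_prediction(synthetic_predict(0.5), 1.0)
        means = 1.0 + 8.0 * truth
        fit = grid_fit(synthetic_predict, means, config)
        assert fit.s == pytest.approx(0.5)
        assert fit.gamma == pytest.approx(1.0)

    def test_recovers_w_and_gamma(self):
        config = FitConfig(
            s_grid=np.arange(0.0, 1.01, 0.25),
            w_grid=np.arange(0.0, 1.01, 0.25),
            gamma_grid=np.array([0.5, 1.0, 2.0]),
        )
        truth = scale_prediction(synthetic_predict(0.25, 0.75), 2.0)
        means = 1.0 + 8.0 * truth
        fit = grid_fit(synthetic_predict, means, config)
        assert (fit.s, fit.w, fit.gamma) == (0.25, 0.75, 2.0)
        assert fit.n_params == 4

    def test_selected_loglik_is_grid_maximum(self):
        rng = np.random.default_rng(5)
        means = 1.0 + 8.0 * np.clip(
            scale_prediction(synthetic_predict(0.3), 1.0)
            + rng.normal(0, 0.05, 5),
            0, 1,
        )
        config = FitConfig(
            s_grid=np.arange(0.0, 1.01, 0.2),
            gamma_grid=np.array([0.5, 1.0, 1.5]),
        )
        fit = grid_fit(synthetic_predict, means, config)
        y = rescale_means(means)
        for s in config.s_grid:
            for gamma in config.gamma_grid:
                preds = scale_prediction(synthetic_predict(s), gamma)
                rss = float(np.sum((y - preds) ** 2))
                sigma = max(math.sqrt(rss / y.size), 1e-9)
                ll = (
                    -0.5 * y.size * math.log(2 * math.pi * sigma**2)
                    - rss / (2 * sigma**2)
                )
                assert fit.loglik >= ll - 1e-9

    def test_likelihood_invariant_to_question_order(self):
        rng = np.random.default_rng(11)
        means = 1.0 + 8.0 * np.clip(
            synthetic_predict(0.4) + rng.normal(0, 0.03, 5), 0, 1
        )
        config = FitConfig(
            s_grid=np.arange(0.0, 1.01, 0.1),
            gamma_grid=np.array([1.0]),
        )
        perm = np.array([3, 0, 4, 1, 2])
        fit = grid_fit(synthetic_predict, means, config)
        fit_perm = grid_fit(
            lambda s, w=0.0: synthetic_predict(s, w)[perm], means[perm], config
        )
        assert fit.loglik == pytest.approx(fit_perm.loglik)
        assert fit.s == fit_perm.s

    def test_generating_model_beats_constant_baseline(self):
        rng = np.random.default_rng(3)
        means = 1.0 + 8.0 * np.clip(
            scale_prediction(synthetic_predict(0.5), 1.0)
            + rng.normal(0, 0.02, 5),
            0, 1,
        )
        config = FitConfig(
            s_grid=np.arange(0.0, 1.01, 0.1),
            gamma_grid=np.arange(0.25, 2.01, 0.25),
        )
        fit = grid_fit(synthetic_predict, means, config)
        baseline = constant_baseline_fit(means, config.gamma_grid)
        assert fit.loglik > baseline.loglik
        assert fit.bic < baseline.bic

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            grid_fit(synthetic_predict, [], FitConfig())


class TestConstantBaseline:
    def test_flat_means_fit_perfectly_at_gamma_one(self):
        fit = constant_baseline_fit([5.0] * 6, np.array([0.5, 1.0, 2.0]))
        assert fit.gamma == pytest.approx(1.0)  # 0.5**1 == (5-1)/8
        assert fit.sigma == pytest.approx(1e-9)
        assert fit.correlation == 0.0
        assert fit.n_params == 2

    def test_information_criterion_identities(self):
        fit = constant_baseline_fit([3.0, 4.0, 6.0, 7.0])
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.loglik)
        assert fit.bic == pytest.approx(2 * math.log(4) - 2 * fit.loglik)


class TestLinearCombinationBaseline:
    def test_pair_prediction_is_average(self):
        preds = linear_combination_baseline(
            {"a": 4.0, "b": 6.0}, [("a", "b")]
        )
        assert preds == [5.0]

    def test_idempotent_on_equal_singulars(self):
        assert linear_combination_baseline({"a": 7.0, "b": 7.0}, [("a", "b")]) == [7.0]

    def test_permutation_equivariance(self):
        singles = {"a": 2.0, "b": 5.0, "c": 8.0}
        pairs = [("a", "b"), ("a", "c"), ("b", "c")]
        preds = dict(zip(pairs, linear_combination_baseline(singles, pairs)))
        flipped = dict(
            zip(
                [(b, a) for a, b in pairs],
                linear_combination_baseline(
                    singles, [(b, a) for a, b in pairs]
                ),
            )
        )
        for (a, b), value in preds.items():
            assert flipped[(b, a)] == value

    def test_missing_singular_rejected(self):
        with pytest.raises(KeyError):
            linear_combination_baseline({"a": 4.0}, [("a", "b")])


class TestCompareModels:
    def test_equal_k_lower_loglik_means_higher_bic(self):
        means = [3.0, 5.0, 7.0, 6.0, 4.0]
        good = grid_fit(
            synthetic_predict,
            means,
            FitConfig(
                s_grid=np.arange(0, 1.01, 0.1),
                gamma_grid=np.arange(0.25, 2.01, 0.25),
            ),
            model="free",
        )
        worse = grid_fit(
            synthetic_predict,
            means,
            FitConfig(s_grid=np.array([0.0]), gamma_grid=np.array([3.0])),
            model="pinned",
        )
        table = compare_models([good, worse])
        assert set(table.model) == {"free", "pinned"}
        row_good = table[table.model == "free"].iloc[0]
        row_worse = table[table.model == "pinned"].iloc[0]
        assert row_worse.loglik <= row_good.loglik
        assert row_worse.bic >= row_good.bic

    def test_single_fit_identities(self):
        fit = constant_baseline_fit([4.0, 5.0, 6.0])
        table = compare_models([fit])
        row = table.iloc[0]
        assert row.aic == pytest.approx(2 * row.n_params - 2 * row.loglik)
        assert row.bic == pytest.approx(
            row.n_params * math.log(row.n_questions) - 2 * row.loglik
        )

    def test_mismatched_question_counts_rejected(self):
        a = constant_baseline_fit([4.0, 5.0])
        b = constant_baseline_fit([4.0, 5.0, 6.0])
        with pytest.raises(ValueError, match="different question sets"):
            compare_models([a, b])


def test_question_means_aggregates_by_round_and_cause():
    ratings = pd.DataFrame(
        {
            "round": ["r1", "r1", "r1", "r1"],
            "cause": ["A", "A", "A&B", "A&B"],
            "rating": [4, 6, 9, 7],
        }
    )
    means = question_means(ratings).set_index(["round", "cause"])
    assert means.loc[("r1", "A"), "mean"] == 5.0
    assert means.loc[("r1", "A&B"), "n"] == 2


def test_nested_w_fit_wins_on_w_generated_data(exp2):
    """Free-w fit beats the w=0 restriction on data generated with w > 0."""
    questions, predict = build_predictor(
        exp2, "cesm", rounds=["overdetermined_negative"]
    )
    truth = scale_prediction(predict(0.2, 0.8), 1.0)
    means = 1.0 + 8.0 * truth
    grids = dict(
        s_grid=np.arange(0.0, 1.01, 0.2),
        gamma_grid=np.array([1.0]),
    )
    free = grid_fit(
        predict, means, FitConfig(w_grid=np.arange(0.0, 1.01, 0.2), **grids)
    )
    restricted = grid_fit(
        predict, means, FitConfig(w_grid=np.array([0.0, 1e-9]), **grids)
    )
    assert free.w == pytest.approx(0.8)
    assert free.loglik > restricted.loglik
    assert free.bic < restricted.bic
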