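import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import statsmodels.api as sm
from scipy.special import expit

from wearmiss import (
    ConfusionMatrix,
    GeneratorConfig,
    auc,
    cluster_bootstrap,
    confusion_metrics,
    fit_gee,
    fit_rf,
    forward_select,
    generate,
    select_corstr,
)
from wearmiss.data_model import SLEEP_STAGES, make_dataset
from conftest import tiny_dataset


def brute_force_auc(scores, labels):
    """Pairwise-comparison probability: P(score_pos > score_neg) + 0.5 ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfectly_ordered(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_tie_matches_pair_enumeration(self):
        scores, labels = [0.2, 0.5, 0.5, 0.9], [0, 0, 1, 1]
        assert auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels)
        )

    def test_one_class_errors(self):
        with pytest.raises(ValueError, match="one class"):
            auc([0.1, 0.2], [1, 1])

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(1000)
        labels = rng.binomial(1, 0.3, 1000)
        n1, n0 = labels.sum(), (1 - labels).sum()
        se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(auc(scores, labels) - 0.5) < 3 * se

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_matches_bruteforce_on_small_instances(self, data):
        n = data.draw(st.integers(4, 12))
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda L: 0 < sum(L) < len(L)
            )
        )
        scores = data.draw(
            st.lists(
                st.floats(0, 1, allow_nan=False, width=32), min_size=n, max_size=n
            )
        )
        assert auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )


class TestConfusionMetrics:
    def test_diagonal_all_ones(self):
        m = confusion_metrics(ConfusionMatrix(tn=7, fp=0, fn=0, tp=3))
        assert (m["accuracy"], m["sensitivity"], m["specificity"]) == (1.0, 1.0, 1.0)

    def test_empty_positive_class_flagged(self):
        m = confusion_metrics(ConfusionMatrix(tn=5, fp=1, fn=0, tp=0))
        assert np.isnan(m["sensitivity"])
        assert m["specificity"] == pytest.approx(5 / 6, abs=0.005)

    @given(
        st.tuples(*[st.integers(0, 50)] * 4).filter(lambda t: sum(t) > 0)
    )
    @settings(max_examples=50, deadline=None)
    def test_rates_in_unit_interval(self, counts):
        tn, fp, fn, tp = counts
        m = confusion_metrics(ConfusionMatrix(tn=tn, fp=fp, fn=fn, tp=tp))
        for k in ("accuracy_raw", "sensitivity_raw", "specificity_raw"):
            assert np.isnan(m[k]) or 0.0 <= m[k] <= 1.0


class TestClusterBootstrap:
    def test_single_participant_resample_is_itself(self):
        ds = tiny_dataset([(0, 0, 1, 0, 0)])
        bs = cluster_bootstrap(ds, seed=0)
        assert bs.n_participants == 1
        assert bs.n_total_nights == 5
        assert bs.n_missing_nights == 1

    def test_resample_always_whole_clusters(self, small_mar_dataset):
        for seed in range(5):
            bs = cluster_bootstrap(small_mar_dataset, seed=seed)
            sizes = bs.nights.groupby("participant_id").size()
            assert (sizes == 5).all()
            assert bs.n_total_nights == small_mar_dataset.n_total_nights

    def test_distinct_fraction_matches_closed_form(self):
        # E[fraction of distinct participants] = 1 - (1 - 1/m)^m
        ds = tiny_dataset([(0, 0, 0, 0, 0)] * 12)
        m = ds.n_participants
        fracs = []
        for seed in range(300):
            bs = cluster_bootstrap(ds, seed=seed)
            src = {pid.split("#")[0] for pid in bs.participants}
            fracs.append(len(src) / m)
        expected = 1 - (1 - 1 / m) ** m
        assert np.mean(fracs) == pytest.approx(expected, abs=0.02)


class TestRandomForest:
    def test_separable_outcome_gives_auc_one(self):
        # missingness a deterministic function of night index
        ds = tiny_dataset([(0, 0, 0, 1, 1)] * 12)
        fit = fit_rf(ds, n_trees=50, seed=0)
        assert fit.auc == 1.0
        assert fit.oob_auc == 1.0

    def test_single_class_outcome_errors(self):
        ds = tiny_dataset([(0, 0, 0, 0, 0)] * 6)
        with pytest.raises(ValueError, match="single class"):
            fit_rf(ds, n_trees=10, seed=0)

    def test_importances_cover_all_predictors(self, small_mar_dataset):
        fit = fit_rf(small_mar_dataset, n_trees=30, seed=1)
        assert len(fit.variable_importances) == 6
        assert fit.variable_importances.sum() == pytest.approx(1.0, abs=1e-8)

    def test_seed_reproducible(self, small_mar_dataset):
        a = fit_rf(small_mar_dataset, n_trees=30, seed=5)
        b = fit_rf(small_mar_dataset, n_trees=30, seed=5)
        assert a.auc == b.auc and a.oob_auc == b.oob_auc

    def test_predictions_aligned_with_nights(self, small_mar_dataset):
        fit = fit_rf(small_mar_dataset, n_trees=30, seed=2)
        assert len(fit.predictions) == small_mar_dataset.n_total_nights
        assert (fit.predictions["true"] == small_mar_dataset.nights["missing"]).all()


class TestGEE:
    def test_single_observation_clusters_match_glm(self):
        ds = generate(GeneratorConfig(mechanism="MAR", n_nights=1, seed=7))
        fit = fit_gee(ds, terms=["employed", "household_size"],
                      corstr="independence")
        m = ds.merged()
        X = sm.add_constant(m[["employed", "household_size"]].astype(float))
        glm = sm.GLM(m["missing"], X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(
            fit.coefficients["estimate"].to_numpy(), glm.params.to_numpy(),
            atol=1e-6,
        )

    def test_sandwich_matches_handrolled_oracle(self):
        # single-observation clusters: GEE robust covariance equals the
        # B^-1 M B^-1 logistic sandwich computed from scratch
        ds = generate(GeneratorConfig(mechanism="MAR", n_nights=1, seed=17))
        fit = fit_gee(ds, terms=["employed", "household_size"],
                      corstr="independence")
        m = ds.merged()
        X = sm.add_constant(m[["employed", "household_size"]].astype(float)).to_numpy()
        y = m["missing"].to_numpy()
        beta = fit.coefficients["estimate"].to_numpy()
        p = expit(X @ beta)
        bread = np.linalg.inv(X.T @ (X * (p * (1 - p))[:, None]))
        meat = (X * ((y - p) ** 2)[:, None]).T @ X
        se = np.sqrt(np.diag(bread @ meat @ bread))
        np.testing.assert_allclose(
            fit.coefficients["robust_se"].to_numpy(), se, atol=1e-6
        )

    def test_exchangeable_alpha_in_valid_range(self, mar_dataset):
        fit = fit_gee(mar_dataset, terms=["night_index", "employed"])
        assert -1 / 4 < fit.alpha < 1

    def test_singular_design_names_terms(self, small_mar_dataset):
        ds = small_mar_dataset
        merged = ds.nights.copy()
        merged["employed_copy"] = ds.covariates["employed"].reindex(
            merged["participant_id"]
        ).to_numpy()
        ds.nights["employed_copy"] = merged["employed_copy"]
        try:
            with pytest.raises(ValueError, match="employed"):
                fit_gee(ds, terms=["employed", "employed_copy"])
        finally:
            ds.nights.drop(columns="employed_copy", inplace=True)

    def test_intercept_only_model(self, small_mar_dataset):
        fit = fit_gee(small_mar_dataset, terms=[])
        assert list(fit.coefficients.index) == ["const"]
        marg = small_mar_dataset.nights["missing"].mean()
        assert expit(fit.coefficients.loc["const", "estimate"]) == pytest.approx(
            marg, abs=0.02
        )


class TestCorstrSelection:
    def test_single_candidate_returned(self, small_mar_dataset):
        best, table = select_corstr(
            small_mar_dataset, terms=["night_index"], candidates=["ar1"]
        )
        assert best == "ar1"
        assert len(table) == 1

    def test_winner_is_argmin_of_table(self, small_mar_dataset):
        best, table = select_corstr(small_mar_dataset, terms=["night_index"])
        valid = table.dropna(subset=["qic"])
        assert best == valid.loc[valid["qic"].idxmin(), "corstr"]

    def test_independent_data_qic_spread_small(self):
        # with no within-cluster dependence the structures are equivalent
        small = 0
        for s in range(10):
            ds = generate(
                GeneratorConfig(mechanism="MCAR", n_participants=100, seed=4000 + s)
            )
            _, table = select_corstr(ds, terms=["employed"])
            small += (table["qic"].max() - table["qic"].min()) < 2
        assert small >= 8


class TestForwardSelection:
    def test_noise_predictors_pruned(self):
        # MCAR: every predictor is noise; final model intercept-only most runs
        empty = 0
        for s in range(10):
            ds = generate(
                GeneratorConfig(mechanism="MCAR", n_participants=150, seed=8000 + s)
            )
            fit = forward_select(ds, alpha=0.05)
            empty += len(fit.selected_terms) == 0
        assert empty >= 6

    def test_recovers_night_and_employment_signal(self):
        hits = 0
        for s in range(10):
            ds = generate(GeneratorConfig(mechanism="MAR", seed=300 + s))
            fit = forward_select(ds, alpha=0.05)
            hits += set(fit.selected_terms) == {"night_index", "employed"}
        assert hits >= 6

    def test_single_significant_candidate(self, mar_dataset):
        fit = forward_select(mar_dataset, candidate_terms=["night_index"])
        assert fit.selected_terms == ["night_index"]

    def test_step_trace_records_every_step(self, small_mar_dataset):
        fit = forward_select(small_mar_dataset)
        steps = [t["step"] for t in fit.step_trace]
        assert steps == [1, 2, 3, 4, 5, 6, "final"]

    def test_empty_candidate_list_rejected(self, small_mar_dataset):
        with pytest.raises(ValueError, match="empty"):
            forward_select(small_mar_dataset, candidate_terms=[])
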