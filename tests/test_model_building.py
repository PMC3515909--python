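"""Importance ranking, the 10x10 CV harness and forward model building."""

import numpy as np
import pytest

from metavote import (
    ConfigurationError,
    InputError,
    MethodSpec,
    cv10x10,
    forward_select,
    importance_rank,
)
from metavote.model_building import REDUCED_GRIDS, _resolve_mtry

from conftest import make_study, signal_study

LSVM = MethodSpec("L-SVM", {"C": (1.0,)})


class TestGrids:
    def test_mtry_tokens_resolve_clipped_to_feature_count(self):
        # p=25: {1, round(0.5*5), 5, 10, 25}
        assert [_resolve_mtry(t, 25) for t in ("1", "0.5sqrt", "sqrt", "2sqrt", "all")] == [
            1, 2, 5, 10, 25,
        ]
        # p=2: everything collapses into [1, 2]
        assert {_resolve_mtry(t, 2) for t in ("1", "0.5sqrt", "sqrt", "2sqrt", "all")} == {1, 2}

    def test_grid_points_deduplicate_resolved_mtry(self):
        spec = MethodSpec("RF", {"ntree": (50,), "mtry": ("sqrt", "2sqrt", "all")})
        points = spec.grid_points(n_features=1)
        assert points == [{"mtry": 1, "ntree": 50}]

    def test_illegal_grid_axis_rejected(self):
        with pytest.raises(ConfigurationError):
            MethodSpec("LR", {"C": (1.0,)})
        with pytest.raises(ConfigurationError):
            MethodSpec("XGB", {})


class TestImportanceRank:
    def test_planted_gene_ranked_first_across_seeds(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 100
            y = np.array([1] * 25 + [0] * 75)
            X = rng.normal(size=(51, n))
            X[0, y == 1] += 3.0  # one strongly informative gene among 50 nulls
            study = make_study(X, y, study_id=f"imp{seed}")
            ranked = importance_rank(study, study.gene_ids, seed=seed, n_trees=100, n_repeats=3)
            hits += ranked[0] == "g000"
        assert hits == 10

    def test_singleton_pool_is_returned_as_is(self):
        study, _ = signal_study(0)
        assert importance_rank(study, ["g000"], seed=0) == ["g000"]

    def test_empty_pool_rejected(self):
        study, _ = signal_study(0)
        with pytest.raises(InputError):
            importance_rank(study, [], seed=0)


class TestCV10x10:
    def test_every_sample_gets_exactly_ten_votes(self):
        study, genes = signal_study(1)
        votes, perf = cv10x10(study, LSVM, genes, {"C": 1.0}, seed=0)
        assert votes.shape == (study.n_samples, 10)
        assert set(np.unique(votes.to_numpy())) <= {0, 1}
        # performance pools all out-of-fold predictions: 10 per sample
        assert perf.n_samples == 10 * study.n_samples

    def test_deterministic_given_seed(self):
        study, genes = signal_study(2)
        v1, p1 = cv10x10(study, LSVM, genes, {"C": 1.0}, seed=3)
        v2, p2 = cv10x10(study, LSVM, genes, {"C": 1.0}, seed=3)
        assert (v1 == v2).all().all()
        assert p1 == p2

    def test_separable_data_classified_almost_perfectly(self):
        rng = np.random.default_rng(4)
        n = 40
        y = np.array([1] * 10 + [0] * 30)
        X = rng.normal(size=(2, n)) * 0.1
        X[:, y == 1] += 5.0
        study = make_study(X, y, study_id="sep")
        _, perf = cv10x10(study, LSVM, study.gene_ids, {"C": 1.0}, seed=0)
        assert perf.bacc >= 0.95

    def test_too_few_samples_rejected(self):
        study = make_study(np.random.default_rng(0).normal(size=(3, 12)), [1] * 4 + [0] * 8)
        with pytest.raises(InputError):
            cv10x10(study, LSVM, study.gene_ids, {"C": 1.0}, seed=0)


class TestForwardSelect:
    def test_max_features_one_yields_single_feature(self):
        study, genes = signal_study(5)
        model = forward_select(study, LSVM, study.gene_ids[:6], seed=0, max_features=1)
        assert len(model.features) == 1
        assert model.features[0] == study.gene_ids[0]

    def test_selected_bacc_dominates_first_candidate(self):
        study, _ = signal_study(6)
        spec = MethodSpec("L-SVM", {"C": (0.1, 1.0)})
        ranked = study.gene_ids[:5]
        model = forward_select(study, spec, ranked, seed=1, max_features=4)
        _, base = cv10x10(study, spec, ranked[:1], spec.grid_points(1)[0], seed=1)
        assert model.cv_performance.bacc >= base.bacc
        # features are a prefix of the supplied ranking
        assert model.features == ranked[: len(model.features)]

    def test_informative_pair_recovered_with_small_models(self):
        """Two informative genes among 20 are found and models stay small."""
        included, small = 0, 0
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            n = 200
            y = np.array([1] * 50 + [0] * 150)
            X = rng.normal(size=(20, n))
            X[0, y == 1] += 1.5
            X[1, y == 1] -= 1.5
            study = make_study(X, y, study_id=f"pair{seed}")
            ranked = importance_rank(
                study, study.gene_ids, seed=seed, n_trees=100, n_repeats=3
            )
            model = forward_select(study, LSVM, ranked, seed=seed, max_features=8)
            included += {"g000", "g001"} <= set(model.features)
            small += len(model.features) <= 8
        assert included >= 9
        assert small == 10

    def test_resubstitution_bacc_at_least_cv_bacc(self):
        from metavote import performance

        study, genes = signal_study(7, n_informative=2, effect=1.2)
        spec = MethodSpec("RF", dict(REDUCED_GRIDS["RF"]))
        model = forward_select(study, spec, study.gene_ids[:5], seed=2, max_features=2)
        resub = performance(study.outcome, model.predict(study))
        assert resub.bacc >= model.cv_performance.bacc

    def test_predictions_deterministic_and_missing_feature_named(self):
        study, genes = signal_study(8)
        model = forward_select(study, LSVM, study.gene_ids[:4], seed=0, max_features=2)
        copy = study.with_expression(study.expression.copy())
        assert (model.predict(study) == model.predict(copy)).all()
        dropped = study.with_expression(study.expression.drop(index=model.features[0]))
        with pytest.raises(InputError, match=model.features[0]):
            model.predict(dropped)

    def test_empty_ranking_rejected(self):
        study, _ = signal_study(9)
        with pytest.raises(InputError):
            forward_select(study, LSVM, [], seed=0)


def test_paper_mode_estimate_inflated_versus_clean_mode():
    """Whole-set importance ranking before CV leaks information: its CV
    bAcc should on average beat fold-internal ranking on signal data."""
    diffs = []
    for seed in range(10):
        rng = np.random.default_rng(500 + seed)
        n = 30
        y = np.array([1] * 8 + [0] * 22)
        X = rng.normal(size=(6, n))
        X[0, y == 1] += 1.0  # weak signal: leakage matters most here
        study = make_study(X, y, study_id=f"leak{seed}")
        ranked = importance_rank(study, study.gene_ids, seed=seed, n_trees=30, n_repeats=2)
        paper = forward_select(
            study, LSVM, ranked, seed=seed, max_features=2, mode="paper"
        )
        clean = forward_select(
            study, LSVM, ranked, seed=seed, max_features=2, mode="clean",
            rank_trees=30, rank_repeats=2,
        )
        diffs.append(paper.cv_performance.bacc - clean.cv_performance.bacc)
    assert np.mean(diffs) > 0
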