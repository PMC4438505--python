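import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from methdet.classify import (
    auc_score,
    cross_validate_models,
    default_model_specs,
    evaluate_panel,
    evaluate_single_genes,
    metrics_from_scores,
    rank_and_select_panel,
    vip_scores,
    youden_threshold,
)
from methdet.differential import apply_cutoffs, differential_table
from methdet.tables import PANEL_GENES
from tests.conftest import cohort_matrix, make_matrix


def brute_force_auc(y, scores):
    """All-pairs concordance count: ties contribute 1/2."""
    pos = [s for s, yy in zip(scores, y) if yy == 1]
    neg = [s for s, yy in zip(scores, y) if yy == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_worked_example(self):
        y = np.array([1, 1, 1, 0, 0])
        s = np.array([0.9, 0.8, 0.7, 0.75, 0.6])
        assert auc_score(y, s) == pytest.approx(5 / 6)

    @given(st.data())
    @settings(derandomize=True, max_examples=100)
    def test_rank_construction_equals_pair_counting(self, data):
        n = data.draw(st.integers(4, 40))
        n_pos = data.draw(st.integers(1, n - 1))
        y = np.array([1] * n_pos + [0] * (n - n_pos))
        # discrete score levels force ties
        scores = np.array(
            data.draw(st.lists(st.integers(0, 5), min_size=n, max_size=n))
        )
        assert auc_score(y, scores) == pytest.approx(brute_force_auc(y, scores))

    def test_label_swap_maps_auc_to_complement(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        s = rng.normal(size=50)
        assert auc_score(y, s) + auc_score(1 - y, s) == pytest.approx(1.0)


class TestMetrics:
    def test_confusion_arithmetic(self):
        """tp=14, fn=1, tn=19, fp=0 at a threshold separating the scores."""
        y = np.array([1] * 15 + [0] * 19)
        scores = np.array([1.0] * 14 + [-1.0] + [-1.0] * 19)
        m = metrics_from_scores(y, scores, threshold=0.0, scope="panel",
                                evaluation="resubstitution")
        assert (m.tp, m.fp, m.tn, m.fn) == (14, 0, 19, 1)
        assert m.sensitivity == pytest.approx(14 / 15)
        assert m.specificity == 1.0
        assert m.ppv == 1.0
        assert m.npv == pytest.approx(19 / 20)

    def test_undefined_ratio_is_nan_not_zero(self):
        y = np.array([1, 1, 0, 0])
        scores = np.array([-1.0, -1.0, -2.0, -2.0])
        m = metrics_from_scores(y, scores, threshold=5.0, scope="panel",
                                evaluation="resubstitution")
        assert m.tp + m.fp == 0
        assert math.isnan(m.ppv)
        assert m.sensitivity == 0.0

    def test_label_swap_symmetry(self):
        """Swapping classes (and mirroring scores/threshold) exchanges
        sensitivity with specificity and PPV with NPV."""
        rng = np.random.default_rng(1)
        y = np.array([1] * 10 + [0] * 15)
        scores = rng.normal(y, 1.0)
        thr = 0.3
        a = metrics_from_scores(y, scores, thr, "panel", "resubstitution")
        b = metrics_from_scores(1 - y, -scores, -thr + 1e-9, "panel",
                                "resubstitution")
        assert a.sensitivity == pytest.approx(b.specificity)
        assert a.specificity == pytest.approx(b.sensitivity)
        assert a.ppv == pytest.approx(b.npv)
        assert a.npv == pytest.approx(b.ppv)
        # mirroring both labels and scores preserves AUC; swapping labels
        # alone complements it (covered in TestAUC)
        assert a.auc == pytest.approx(b.auc)

    def test_youden_threshold_separates_perfectly_separable_scores(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        scores = np.array([3.0, 2.5, 2.0, 1.0, 0.5, 0.0])
        thr = youden_threshold(y, scores)
        assert 1.0 < thr <= 2.0


class TestCrossValidation:
    def test_separable_cohort_all_models_perfect(self):
        rng = np.random.default_rng(2)
        X = np.hstack([rng.normal(4, 0.1, (3, 10)), rng.normal(-4, 0.1, (3, 10))])
        matrix, labels = make_matrix(X, n_relapse=10)
        results, best = cross_validate_models(matrix, labels, k=5, runs=3, seed=0)
        for r in results:
            assert r.auc_mean == pytest.approx(1.0)
        assert best.family == "pls"  # tie broken by fixed listing order

    def test_run_structure_and_determinism(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (4, 24))
        matrix, labels = make_matrix(X, n_relapse=12)
        results, _ = cross_validate_models(matrix, labels, k=5, runs=10, seed=5)
        assert all(len(r.auc_per_run) == 10 for r in results)
        again, _ = cross_validate_models(matrix, labels, k=5, runs=10, seed=5)
        for a, b in zip(results, again):
            assert a.auc_per_run == b.auc_per_run

    def test_permuted_labels_score_near_chance(self):
        """With labels randomized, every family's mean AUC sits in the
        Monte-Carlo null band around 0.5."""
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (8, 200))
        matrix, labels = make_matrix(X, n_relapse=100)
        perm = pd.Series(
            rng.permutation(labels.to_numpy()), index=labels.index
        )
        results, _ = cross_validate_models(matrix, perm, k=5, runs=3, seed=6)
        for r in results:
            assert abs(r.auc_mean - 0.5) < 0.12, r.model.family

    def test_single_class_is_an_error(self):
        X = np.zeros((2, 6))
        matrix, labels = make_matrix(X, n_relapse=0)
        with pytest.raises(ValueError, match="both classes"):
            cross_validate_models(matrix, labels)


class TestVIPSelection:
    def test_vip_squared_scores_average_to_one(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 12))
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        v = vip_scores(X, y, n_components=2)
        assert (v**2).mean() == pytest.approx(1.0)

    def test_single_informative_gene_tops_ranking(self):
        """One strongly shifted gene among nulls receives the top VIP and is
        selected in nearly every replicate."""
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            X = rng.normal(0, 1, (10, 30))
            X[0, :15] += 3.0
            matrix, labels = make_matrix(X, n_relapse=15)
            ranking, selected = rank_and_select_panel(
                matrix, labels, cv_runs=2, seed=seed
            )
            hits += ranking.scores.index[0] == "g0" and "g0" in selected
        assert hits >= 38  # >= 95 %

    def test_exchangeable_nulls_select_no_stable_gene(self):
        """Under label permutation no gene is selected in a majority of
        replicates."""
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (12, 40))
        counts = {f"g{i}": 0 for i in range(12)}
        n_rep = 30
        for seed in range(n_rep):
            matrix, labels = make_matrix(X, n_relapse=20)
            perm = pd.Series(
                np.random.default_rng(seed).permutation(labels.to_numpy()),
                index=labels.index,
            )
            _, selected = rank_and_select_panel(matrix, perm, cv_runs=2, seed=seed)
            for g in selected:
                counts[g] += 1
        assert max(counts.values()) < n_rep / 2

    def test_planted_panel_recovered_exactly(self, planted_panel_cohort):
        """With the seven prognostic genes planted at their published fold
        changes among 49 null probes, the screen + VIP > 1 rule returns
        exactly those seven genes."""
        cohort = planted_panel_cohort
        matrix = cohort_matrix(cohort)
        candidates = apply_cutoffs(differential_table(matrix, cohort.labels))
        _, selected = rank_and_select_panel(
            matrix, cohort.labels, candidate_genes=candidates.genes, seed=3
        )
        assert set(selected) == set(PANEL_GENES)

    def test_too_few_candidates_is_an_error(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (5, 10))
        matrix, labels = make_matrix(X, n_relapse=5)
        with pytest.raises(ValueError, match="candidate"):
            rank_and_select_panel(matrix, labels, candidate_genes=["g0"])


class TestEvaluate:
    def test_perfect_classifier_metrics(self):
        X = np.array([[1.0] * 8 + [0.0] * 8, [1.0] * 8 + [0.0] * 8])
        matrix, labels = make_matrix(X, n_relapse=8)
        m, roc = evaluate_panel(matrix, labels, ["g0", "g1"])
        assert m.sensitivity == m.specificity == m.ppv == m.npv == m.auc == 1.0
        assert {"threshold", "fpr", "tpr"} == set(roc.columns)

    def test_single_gene_rows_one_per_gene(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (3, 20))
        X[0, :10] += 2
        matrix, labels = make_matrix(X, n_relapse=10)
        rows = evaluate_single_genes(matrix, labels, ["g0", "g1", "g2"])
        assert [m.scope for m in rows] == [
            "single_gene:g0",
            "single_gene:g1",
            "single_gene:g2",
        ]

    def test_single_gene_auc_matches_gaussian_closed_form(self):
        """For a standardized separation d the expected AUC is Phi(d/sqrt 2);
        at d = 2 that is about 0.921."""
        rng = np.random.default_rng(9)
        n = 2000
        X = np.concatenate([rng.normal(2, 1, n), rng.normal(0, 1, n)])[None, :]
        matrix, labels = make_matrix(X, n_relapse=n)
        (m,) = evaluate_single_genes(matrix, labels, ["g0"])
        assert m.auc == pytest.approx(norm.cdf(2 / math.sqrt(2)), abs=0.015)

    def test_resubstitution_optimism_on_average(self):
        """Whole-data fits score higher than cross-validated fits on average
        over seeds (the published whole-model-fit numbers are optimistic)."""
        diffs = []
        for seed in range(25):
            rng = np.random.default_rng(seed)
            X = rng.normal(0, 1, (7, 38))
            X[:, :19] += rng.normal(0.8, 0.3, (7, 1))
            matrix, labels = make_matrix(X, n_relapse=19)
            resub, _ = evaluate_panel(matrix, labels, list(matrix.genes))
            cv, _ = evaluate_panel(
                matrix, labels, list(matrix.genes), mode="cross_validated", seed=seed
            )
            diffs.append(resub.auc - cv.auc)
        assert np.mean(diffs) > 0

    def test_empty_panel_is_an_error(self):
        rng = np.random.default_rng(10)
        matrix, labels = make_matrix(rng.normal(0, 1, (2, 8)), n_relapse=4)
        with pytest.raises(ValueError, match="non-empty"):
            evaluate_panel(matrix, labels, [])


def test_default_specs_cover_the_six_families():
    assert [s.family for s in default_model_specs()] == [
        "pls",
        "knn",
        "logistic",
        "discriminant",
        "tree",
        "glm_forward",
    ]
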