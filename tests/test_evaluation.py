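import dataclasses

import numpy as np
import pytest

from mdapred.evaluation import (
    CVConfig,
    CVResult,
    ablation_attention,
    auc,
    cross_validate,
    degree_baseline_logits,
    hyperparameter_sweep,
    kfold_split,
    run_fold,
)
from mdapred.pipeline import PipelineConfig, compute_scores
from mdapred.rwr import RWRConfig
from mdapred.sae_attention import SAEConfig
from mdapred.similarity import cosine_similarity, gaussian_kernel_similarity

FAST_SAE = SAEConfig(hidden_sizes=(16, 8), heads=2, epochs=30, pretrain_epochs=5, seed=0)


def brute_force_auc(scores, labels):
    """O(n^2) pairwise comparison with half-credit for ties (oracle)."""
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_and_inverted_rankings(self):
        assert auc([0.9, 0.8, 0.3, 0.1], [1, 1, 0, 0]) == 1.0
        assert auc([0.9, 0.1], [0, 1]) == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            auc([0.4, 0.5], [1, 1])

    @pytest.mark.parametrize("n,tie_fraction", [(50, 0.0), (200, 0.5), (500, 0.9)])
    def test_matches_pairwise_oracle_including_ties(self, n, tie_fraction, rng):
        scores = rng.random(n)
        tie_mask = rng.random(n) < tie_fraction
        scores[tie_mask] = np.round(scores[tie_mask], 1)  # force ties
        labels = (rng.random(n) < 0.4).astype(int)
        labels[:2] = [0, 1]
        assert auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )


class TestKFoldSplit:
    def test_partition_properties(self, small_dataset):
        dataset, _ = small_dataset
        folds = kfold_split(dataset, CVConfig(k=5, seed=3))
        all_test = np.vstack([test for _, test in folds])
        positives = dataset.positive_pairs()
        # folds partition the positive set
        assert len(all_test) == len(positives)
        assert {tuple(p) for p in all_test} == {tuple(p) for p in positives}
        sizes = [len(test) for _, test in folds]
        assert max(sizes) - min(sizes) <= 1
        for train, test in folds:
            assert {tuple(p) for p in train} | {tuple(p) for p in test} == {
                tuple(p) for p in positives
            }
            assert not ({tuple(p) for p in train} & {tuple(p) for p in test})

    def test_ten_positives_five_folds_of_two(self, tmp_path):
        from mdapred.data_io import AssociationDataset

        S = np.zeros((5, 4))
        S[[0, 0, 1, 1, 2, 2, 3, 3, 4, 4], [0, 1, 0, 2, 1, 3, 2, 3, 0, 3]] = 1.0
        ds = AssociationDataset([f"d{i}" for i in range(5)], [f"m{j}" for j in range(4)], S)
        folds = kfold_split(ds, CVConfig(k=5, seed=0))
        assert [len(test) for _, test in folds] == [2, 2, 2, 2, 2]

    def test_same_seed_reproduces_folds(self, small_dataset):
        dataset, _ = small_dataset
        a = kfold_split(dataset, CVConfig(k=4, seed=9))
        b = kfold_split(dataset, CVConfig(k=4, seed=9))
        for (_, ta), (_, tb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            CVConfig(k=1)


class TestRunFold:
    def test_shuffled_labels_near_half(self, small_dataset, rng):
        """Random labels against any fixed ranking give AUC ~ 0.5."""
        dataset, _ = small_dataset
        scores = rng.random(2000)
        aucs = [
            auc(scores, np.random.default_rng(s).permutation(
                np.r_[np.ones(1000), np.zeros(1000)]))
            for s in range(20)
        ]
        assert 0.45 < float(np.mean(aucs)) < 0.55

    def test_perfect_oracle_scores_give_auc_one(self, small_dataset):
        dataset, _ = small_dataset
        folds = kfold_split(dataset, CVConfig(k=3, seed=1))
        _, test = folds[0]
        oracle = np.zeros_like(dataset.S)
        oracle[test[:, 0], test[:, 1]] = 1.0  # test positives outrank everything
        neg = np.argwhere(dataset.S == 0.0)
        scores = np.concatenate([oracle[test[:, 0], test[:, 1]], oracle[neg[:, 0], neg[:, 1]]])
        labels = np.concatenate([np.ones(len(test)), np.zeros(len(neg))])
        assert auc(scores, labels) == 1.0

    def test_fold_auc_beats_degree_baseline(self, small_dataset, small_similarities):
        dataset, _ = small_dataset
        sr, fm = small_similarities
        pc = PipelineConfig(sae=FAST_SAE, drug_structural=sr, microbe_functional=fm)
        cv_cfg = CVConfig(k=3, seed=2)
        folds = kfold_split(dataset, cv_cfg)
        a = run_fold(dataset, folds[0], pc, cv_cfg, seed=5)
        train, test = folds[0]
        S_train = dataset.S.copy()
        S_train[test[:, 0], test[:, 1]] = 0.0
        logits = degree_baseline_logits(S_train)
        neg = np.argwhere(dataset.S == 0.0)
        scores = np.concatenate([logits[test[:, 0], test[:, 1]], logits[neg[:, 0], neg[:, 1]]])
        labels = np.concatenate([np.ones(len(test)), np.zeros(len(neg))])
        assert a > auc(scores, labels)

    def test_leakage_guard_masked_similarities_ignore_test_positives(self, small_dataset):
        """Per-fold similarity inputs depend only on the masked adjacency."""
        dataset, _ = small_dataset
        folds = kfold_split(dataset, CVConfig(k=3, seed=4))
        _, test = folds[0]
        S_train = dataset.S.copy()
        S_train[test[:, 0], test[:, 1]] = 0.0
        base = {
            "Gr": gaussian_kernel_similarity(S_train, "rows").values,
            "Cm": cosine_similarity(S_train, "columns").values,
        }
        # flipping the held-out entries in the FULL matrix must not matter
        S_flipped = dataset.S.copy()
        S_flipped[test[:, 0], test[:, 1]] = 0.0
        np.testing.assert_array_equal(
            gaussian_kernel_similarity(S_flipped, "rows").values, base["Gr"]
        )
        np.testing.assert_array_equal(
            cosine_similarity(S_flipped, "columns").values, base["Cm"]
        )

    def test_empty_fold_skipped_with_warning(self, small_dataset):
        dataset, _ = small_dataset
        fold = (dataset.positive_pairs(), np.empty((0, 2), dtype=int))
        with pytest.warns(RuntimeWarning, match="zero test positives"):
            assert run_fold(dataset, fold) is None

    def test_sampled_negative_policy_runs(self, small_dataset, small_similarities):
        dataset, _ = small_dataset
        sr, fm = small_similarities
        pc = PipelineConfig(sae=FAST_SAE, drug_structural=sr, microbe_functional=fm)
        cv_cfg = CVConfig(k=3, seed=2, negative_policy="sampled_1to1")
        folds = kfold_split(dataset, cv_cfg)
        a = run_fold(dataset, folds[1], pc, cv_cfg, seed=5)
        assert 0.0 <= a <= 1.0


class TestCVResult:
    def test_mean_std_recomputable_and_summary_format(self):
        res = CVResult.from_aucs([0.9, 0.95, 0.92])
        assert res.mean_auc == pytest.approx(np.mean(res.per_fold_auc))
        assert res.std_auc == pytest.approx(np.std(res.per_fold_auc))
        assert res.summary() == f"{res.mean_auc:.4f} ± {res.std_auc:.4f}"


class TestAblation:
    def test_attention_off_twice_gives_zero_delta(self, small_dataset, small_similarities):
        dataset, _ = small_dataset
        sr, fm = small_similarities
        pc = PipelineConfig(
            sae=dataclasses.replace(FAST_SAE, use_attention=False),
            drug_structural=sr, microbe_functional=fm,
        )
        cv_cfg = CVConfig(k=3, seed=6)
        a = cross_validate(dataset, pc, cv_cfg)
        b = cross_validate(dataset, pc, cv_cfg)
        np.testing.assert_array_equal(a.per_fold_auc, b.per_fold_auc)

    def test_paired_deltas_reported(self, small_dataset, small_similarities):
        dataset, _ = small_dataset
        sr, fm = small_similarities
        pc = PipelineConfig(sae=FAST_SAE, drug_structural=sr, microbe_functional=fm)
        res = ablation_attention(dataset, pc, CVConfig(k=3, seed=6))
        assert len(res.per_fold_delta) == 3
        assert res.mean_delta == pytest.approx(np.mean(res.per_fold_delta))
        # identical folds: arm configs differ only in use_attention
        assert res.with_attention.config["sae"]["use_attention"] is True
        assert res.without_attention.config["sae"]["use_attention"] is False
        assert res.with_attention.config["cv"] == res.without_attention.config["cv"]


class TestSweep:
    def test_single_point_table_and_resume(self, small_dataset, small_similarities, tmp_path):
        dataset, _ = small_dataset
        sr, fm = small_similarities
        pc = PipelineConfig(sae=FAST_SAE, drug_structural=sr, microbe_functional=fm)
        out = tmp_path / "sweep.tsv"
        table = hyperparameter_sweep(
            dataset, lr_grid=[0.01], heads_grid=[2], pipe_cfg=pc,
            cv_cfg=CVConfig(k=3, seed=1), out_path=out,
        )
        assert len(table) == 1
        assert {"lr", "heads", "mean_auc", "std_auc"} <= set(table.columns)
        # rerun: the completed point is skipped, table unchanged
        table2 = hyperparameter_sweep(
            dataset, lr_grid=[0.01], heads_grid=[2], pipe_cfg=pc,
            cv_cfg=CVConfig(k=3, seed=1), out_path=out,
        )
        # the resumed row round-trips through TSV text, so compare to its precision
        assert len(table2) == 1
        assert table2.loc[0, "mean_auc"] == pytest.approx(table.loc[0, "mean_auc"], abs=1e-12)


class TestGlobalSimilarityMode:
    def test_global_mode_uses_full_matrix_for_similarities(self, small_dataset, small_similarities):
        dataset, _ = small_dataset
        sr, fm = small_similarities
        pc = PipelineConfig(sae=FAST_SAE, drug_structural=sr, microbe_functional=fm)
        folds = kfold_split(dataset, CVConfig(k=3, seed=8))
        a_masked = run_fold(dataset, folds[0], pc, CVConfig(k=3, seed=8), seed=1)
        a_global = run_fold(
            dataset, folds[0], pc,
            CVConfig(k=3, seed=8, mask_mode="global_similarity"), seed=1,
        )
        assert a_masked != a_global  # different similarity inputs
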