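"""Cross-validation, AUC, attention ablation and hyperparameter sweeps.

The evaluation protocol folds the KNOWN POSITIVE pairs: the positive set is
randomly partitioned into k near-equal subsets; each subset in turn is hidden
(zeroed in the adjacency matrix), the full pipeline is re-run on the masked
matrix, and the held-out positives are ranked against pairs that are unknown
in the complete dataset. Similarities are recomputed from the masked matrix
by default so no test association can leak into the features.

AUC is rank-based (Mann-Whitney, midranks for ties) and computed on the raw
logits; the logistic transform is strictly monotone so this equals AUC on
the scores while avoiding saturation ties at float precision.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from mdapred.data_io import AssociationDataset
from mdapred.pipeline import PipelineConfig, compute_scores

logger = logging.getLogger(__name__)

MaskMode = Literal["per_fold_similarity", "global_similarity"]
NegativePolicy = Literal["all_unknown", "sampled_1to1"]


@dataclass
class CVConfig:
    """Cross-validation protocol parameters."""

    k: int = 5
    seed: int = 0
    n_repeats: int = 1
    mask_mode: MaskMode = "per_fold_similarity"
    negative_policy: NegativePolicy = "all_unknown"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class CVResult:
    """Per-fold AUCs with their mean and standard deviation."""

    per_fold_auc: list[float]
    mean_auc: float
    std_auc: float
    config: dict = field(default_factory=dict)

    @classmethod
    def from_aucs(cls, aucs: Sequence[float], config: dict | None = None) -> "CVResult":
        a = np.asarray(aucs, dtype=float)
        return cls(
            per_fold_auc=[float(x) for x in a],
            mean_auc=float(a.mean()),
            std_auc=float(a.std()),
            config=config or {},
        )

    def summary(self) -> str:
        """Report-style "mean ± std" string."""
        return f"{self.mean_auc:.4f} ± {self.std_auc:.4f}"


@dataclass
class AblationResult:
    """Paired with/without-attention cross-validation on identical folds."""

    with_attention: CVResult
    without_attention: CVResult

    @property
    def per_fold_delta(self) -> list[float]:
        return [
            a - b
            for a, b in zip(self.with_attention.per_fold_auc, self.without_attention.per_fold_auc)
        ]

    @property
    def mean_delta(self) -> float:
        return float(np.mean(self.per_fold_delta))


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC (Mann-Whitney with midranks for ties)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def kfold_split(
    dataset: AssociationDataset, cfg: CVConfig
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded random partition of the positive pairs into k near-equal folds.

    Returns ``[(train_pairs, test_pairs), ...]`` with pairs as (row, col)
    index arrays; folds are disjoint, their union is the positive set, and
    fold sizes differ by at most one.
    """
    positives = dataset.positive_pairs()
    if len(positives) < cfg.k:
        raise ValueError(f"need at least k={cfg.k} positive pairs, have {len(positives)}")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(positives))
    folds = np.array_split(order, cfg.k)
    out = []
    for f in folds:
        test = positives[f]
        train = positives[np.setdiff1d(order, f, assume_unique=True)]
        out.append((train, test))
    return out


def _fold_labels_and_scores(
    dataset: AssociationDataset,
    test_pairs: np.ndarray,
    logits: np.ndarray,
    policy: NegativePolicy,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Held-out positives vs pairs unknown in the full dataset."""
    neg_idx = np.argwhere(dataset.S == 0.0)
    if policy == "sampled_1to1":
        pick = rng.choice(len(neg_idx), size=min(len(test_pairs), len(neg_idx)), replace=False)
        neg_idx = neg_idx[pick]
    pos_scores = logits[test_pairs[:, 0], test_pairs[:, 1]]
    neg_scores = logits[neg_idx[:, 0], neg_idx[:, 1]]
    scores = np.concatenate([pos_scores, neg_scores])
    labels = np.concatenate([np.ones(len(pos_scores)), np.zeros(len(neg_scores))])
    return scores, labels


def run_fold(
    dataset: AssociationDataset,
    fold: tuple[np.ndarray, np.ndarray],
    pipe_cfg: PipelineConfig | None = None,
    cv_cfg: CVConfig | None = None,
    seed: int = 0,
) -> float | None:
    """Score one fold: mask its test positives, re-run the pipeline, compute AUC.

    Returns None (with a warning) for a fold without test positives.
    """
    pipe_cfg = pipe_cfg or PipelineConfig()
    cv_cfg = cv_cfg or CVConfig()
    _, test_pairs = fold
    if len(test_pairs) == 0:
        warnings.warn("fold with zero test positives skipped", RuntimeWarning, stacklevel=2)
        return None
    S_train = dataset.S.copy()
    S_train[test_pairs[:, 0], test_pairs[:, 1]] = 0.0
    S_sim = dataset.S if cv_cfg.mask_mode == "global_similarity" else None
    sm, _ = compute_scores(S_train, pipe_cfg, seed=seed, S_sim=S_sim)
    rng = np.random.default_rng(seed)
    scores, labels = _fold_labels_and_scores(
        dataset, test_pairs, sm.raw_logits, cv_cfg.negative_policy, rng
    )
    return auc(scores, labels)


def cross_validate(
    dataset: AssociationDataset,
    pipe_cfg: PipelineConfig | None = None,
    cv_cfg: CVConfig | None = None,
) -> CVResult:
    """k-fold cross-validation, optionally repeated with shifted seeds."""
    pipe_cfg = pipe_cfg or PipelineConfig()
    cv_cfg = cv_cfg or CVConfig()
    aucs: list[float] = []
    for rep in range(cv_cfg.n_repeats):
        rep_seed = (cv_cfg.seed + rep) % (2**31 - 1)
        folds = kfold_split(dataset, replace(cv_cfg, seed=rep_seed))
        for i, fold in enumerate(folds):
            a = run_fold(dataset, fold, pipe_cfg, cv_cfg, seed=rep_seed * 131 % (2**31 - 1) + i)
            if a is not None:
                aucs.append(a)
            logger.info("repeat %d fold %d: AUC=%s", rep, i, f"{a:.4f}" if a is not None else "skipped")
    snapshot = {"cv": asdict(cv_cfg), "rwr": asdict(pipe_cfg.rwr), "sae": asdict(pipe_cfg.sae)}
    return CVResult.from_aucs(aucs, config=snapshot)


def ablation_attention(
    dataset: AssociationDataset,
    pipe_cfg: PipelineConfig | None = None,
    cv_cfg: CVConfig | None = None,
) -> AblationResult:
    """Paired CV runs differing only in the attention block (identical folds/seeds)."""
    pipe_cfg = pipe_cfg or PipelineConfig()
    cv_cfg = cv_cfg or CVConfig()
    with_cfg = replace(pipe_cfg, sae=replace(pipe_cfg.sae, use_attention=True))
    without_cfg = replace(pipe_cfg, sae=replace(pipe_cfg.sae, use_attention=False))
    return AblationResult(
        with_attention=cross_validate(dataset, with_cfg, cv_cfg),
        without_attention=cross_validate(dataset, without_cfg, cv_cfg),
    )


def hyperparameter_sweep(
    dataset: AssociationDataset,
    lr_grid: Sequence[float] = (1e-4, 5e-4, 1e-3, 1e-2, 1e-1),
    heads_grid: Sequence[int] = (2, 4, 8, 16),
    pipe_cfg: PipelineConfig | None = None,
    cv_cfg: CVConfig | None = None,
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Mean CV AUC over a (learning rate x attention heads) grid.

    When ``out_path`` is given the table is written as TSV after every grid
    point and completed (lr, heads) points found there are skipped on rerun.
    """
    pipe_cfg = pipe_cfg or PipelineConfig()
    cv_cfg = cv_cfg or CVConfig()
    done: pd.DataFrame | None = None
    if out_path is not None and Path(out_path).exists():
        done = pd.read_csv(out_path, sep="\t")
    rows = [] if done is None else done.to_dict("records")
    for lr in lr_grid:
        for h in heads_grid:
            if done is not None and (
                (np.isclose(done["lr"], lr)) & (done["heads"] == h)
            ).any():
                logger.info("sweep point lr=%g h=%d already done; skipping", lr, h)
                continue
            cfg = replace(pipe_cfg, sae=replace(pipe_cfg.sae, learning_rate=lr, heads=h))
            res = cross_validate(dataset, cfg, cv_cfg)
            rows.append(
                {"lr": lr, "heads": h, "mean_auc": res.mean_auc, "std_auc": res.std_auc}
            )
            if out_path is not None:
                pd.DataFrame(rows).to_csv(out_path, sep="\t", index=False)
    return pd.DataFrame(rows)


def degree_baseline_logits(S_train: np.ndarray) -> np.ndarray:
    """Popularity baseline: score(i, j) = train degree of drug i x microbe j."""
    S_train = np.asarray(S_train, dtype=np.float64)
    return np.outer(S_train.sum(axis=1), S_train.sum(axis=0))
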