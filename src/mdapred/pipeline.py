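"""End-to-end orchestration: adjacency -> similarities -> RWR + SAE -> scores.

One call of :func:`compute_scores` runs the whole method on a (possibly
training-masked) adjacency matrix:

1. Gaussian interaction-profile kernel similarities for drugs and microbes
   feed the restart random walk, giving diffusion profile matrices DR and MR.
2. Cosine similarities plus the externally supplied structural (drugs) and
   functional (microbes) similarities each train an independent stacked
   autoencoder, giving the four attribute feature matrices. When an external
   matrix is absent, the corresponding cosine matrix substitutes for it and
   the run is tagged as a fallback.
3. The features are block-concatenated with adjacency copies and every
   drug-microbe pair is scored by the logistic of the feature inner product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from mdapred.data_io import SimilarityMatrix
from mdapred.fusion_scoring import IntegratedFeatures, ScoreMatrix, integrate_features, score
from mdapred.rwr import RWRConfig, rwr_profile, transition_matrix
from mdapred.sae_attention import SAEConfig, train_sae
from mdapred.similarity import cosine_similarity, gaussian_kernel_similarity

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one full scoring run."""

    rwr: RWRConfig = field(default_factory=RWRConfig)
    sae: SAEConfig = field(default_factory=SAEConfig)
    drug_structural: SimilarityMatrix | None = None
    microbe_functional: SimilarityMatrix | None = None
    standardize_features: bool = False


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds below 2**31."""
    return [int(s) for s in np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)]


def compute_scores(
    S_adj: np.ndarray,
    cfg: PipelineConfig | None = None,
    seed: int = 0,
    S_sim: np.ndarray | None = None,
) -> tuple[ScoreMatrix, dict[str, Any]]:
    """Run the full pipeline on an adjacency matrix.

    Parameters
    ----------
    S_adj : binary adjacency used for the adjacency blocks of the integrated
        features (inside cross-validation this is the training-masked matrix).
    cfg : pipeline configuration; defaults throughout when omitted.
    seed : run seed; the four autoencoders get distinct child seeds from it.
    S_sim : adjacency from which similarities are computed; defaults to
        ``S_adj``. Passing the full matrix here reproduces a protocol where
        similarities are not re-masked per fold (test-association leakage).

    Returns the score matrix and an info dict (fallback tags, RWR iteration
    counts, final SAE losses, the integrated features).
    """
    cfg = cfg or PipelineConfig()
    S_adj = np.asarray(S_adj, dtype=np.float64)
    S_sim = S_adj if S_sim is None else np.asarray(S_sim, dtype=np.float64)
    info: dict[str, Any] = {"fallback": []}

    Gr = gaussian_kernel_similarity(S_sim, "rows")
    Gm = gaussian_kernel_similarity(S_sim, "columns")
    Cr = cosine_similarity(S_sim, "rows")
    Cm = cosine_similarity(S_sim, "columns")
    Sr = cfg.drug_structural
    if Sr is None:
        Sr = Cr
        info["fallback"].append("drug_structural<-cosine")
        logger.warning("no drug structural similarity supplied; falling back to cosine")
    Fm = cfg.microbe_functional
    if Fm is None:
        Fm = Cm
        info["fallback"].append("microbe_functional<-cosine")
        logger.warning("no microbe functional similarity supplied; falling back to cosine")

    DR = rwr_profile(transition_matrix(Gr, cfg.rwr.normalization), cfg.rwr, entity="drug")
    MR = rwr_profile(transition_matrix(Gm, cfg.rwr.normalization), cfg.rwr, entity="microbe")
    info["rwr_iterations"] = {"drug": DR.n_iter, "microbe": MR.n_iter}

    seeds = _spawn_seeds(seed, 4)
    sae_inputs = [
        ("drug", "cosine", Cr, seeds[0]),
        ("drug", Sr.measure, Sr, seeds[1]),
        ("microbe", "cosine", Cm, seeds[2]),
        ("microbe", Fm.measure, Fm, seeds[3]),
    ]
    feats = []
    losses = {}
    for entity, measure, sim, s in sae_inputs:
        f = train_sae(sim.values, replace(cfg.sae, seed=s), entity=entity, source_measure=measure)
        feats.append(f)
        losses[f"{entity}/{measure}"] = f.final_loss
    SAEr1, SAEr2, SAEm1, SAEm2 = feats
    info["sae_final_losses"] = losses

    IF = integrate_features(DR, MR, SAEr1, SAEr2, SAEm1, SAEm2, S_adj)
    if cfg.standardize_features:
        IF = IntegratedFeatures(
            IFMr=_zscore_columns(IF.IFMr),
            IFMm=_zscore_columns(IF.IFMm),
            block_layout=IF.block_layout,
        )
    sm = score(IF)
    info["features"] = IF
    return sm, info


def _zscore_columns(A: np.ndarray) -> np.ndarray:
    mu = A.mean(axis=0, keepdims=True)
    sd = A.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (A - mu) / sd
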