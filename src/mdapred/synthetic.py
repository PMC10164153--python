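"""Synthetic bipartite association data with planted block structure.

Generates sparse binary drug x microbe adjacency matrices in which drugs and
microbes are partitioned into co-clusters: a pair inside a co-cluster is
associated with probability ``within_block_prob``, any other pair with
``background_prob``, and every label is then flipped independently with
``noise_flip_prob``. A block model is used because the pipeline's features
are association-profile based, so co-clusters give a controllable,
interpretable planted signal the full method should recover.

Stand-ins for externally computed similarity matrices (drug structural,
microbe functional) are block indicators mixed with symmetric noise at a
chosen reliability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mdapred.data_io import AssociationDataset, Entity, SimilarityMatrix


@dataclass
class SyntheticSpec:
    """Parameters of the planted block model."""

    n_drugs: int = 200
    n_microbes: int = 60
    n_blocks: int = 4
    within_block_prob: float = 0.3
    background_prob: float = 0.01
    noise_flip_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drugs < 1 or self.n_microbes < 1 or self.n_blocks < 1:
            raise ValueError("n_drugs, n_microbes and n_blocks must be positive")
        if not (0.0 < self.within_block_prob <= 1.0):
            raise ValueError("within_block_prob must be in (0, 1]")
        if not (0.0 <= self.background_prob < 1.0):
            raise ValueError("background_prob must be in [0, 1)")
        if not self.within_block_prob > self.background_prob:
            raise ValueError("within_block_prob must exceed background_prob (planted signal)")
        if not (0.0 <= self.noise_flip_prob < 1.0):
            raise ValueError("noise_flip_prob must be in [0, 1)")


@dataclass
class BlockLabels:
    """Ground-truth co-cluster assignments from :func:`generate`."""

    drug_blocks: np.ndarray
    microbe_blocks: np.ndarray


def generate(spec: SyntheticSpec) -> tuple[AssociationDataset, BlockLabels]:
    """Draw a seeded planted-block association dataset.

    Identifiers are zero-padded (``drug_0042``) so that lexicographic entity
    order matches index order.
    """
    rng = np.random.default_rng(spec.seed)
    drug_blocks = _balanced_blocks(rng, spec.n_drugs, spec.n_blocks)
    microbe_blocks = _balanced_blocks(rng, spec.n_microbes, spec.n_blocks)
    same = drug_blocks[:, None] == microbe_blocks[None, :]
    p = np.where(same, spec.within_block_prob, spec.background_prob)
    S = (rng.random((spec.n_drugs, spec.n_microbes)) < p).astype(np.float64)
    if spec.noise_flip_prob > 0:
        flips = rng.random(S.shape) < spec.noise_flip_prob
        S = np.where(flips, 1.0 - S, S)
    expected = (p * (1 - spec.noise_flip_prob) + (1 - p) * spec.noise_flip_prob).sum()
    if expected < 1.0:
        raise ValueError("expected positive count below 1; increase sizes or probabilities")
    dwidth = len(str(spec.n_drugs - 1))
    mwidth = len(str(spec.n_microbes - 1))
    dataset = AssociationDataset(
        drug_ids=[f"drug_{i:0{dwidth}d}" for i in range(spec.n_drugs)],
        microbe_ids=[f"microbe_{j:0{mwidth}d}" for j in range(spec.n_microbes)],
        S=S,
    )
    return dataset, BlockLabels(drug_blocks=drug_blocks, microbe_blocks=microbe_blocks)


def make_external_similarities(
    labels: BlockLabels,
    reliability: float = 0.8,
    seed: int = 0,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Synthetic stand-ins for externally computed similarity matrices.

    Each matrix is ``reliability * block_indicator + (1 - reliability) * noise``
    with symmetric uniform noise, diagonal forced to 1. Returns the
    (drug structural, microbe functional) pair.
    """
    if not (0.0 <= reliability <= 1.0):
        raise ValueError("reliability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    drug = _noisy_block_similarity(labels.drug_blocks, reliability, rng, "drug", "structural")
    microbe = _noisy_block_similarity(labels.microbe_blocks, reliability, rng, "microbe", "functional")
    return drug, microbe


def _balanced_blocks(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    blocks = np.arange(n) % k
    return blocks[rng.permutation(n)]


def _noisy_block_similarity(
    blocks: np.ndarray, reliability: float, rng: np.random.Generator,
    entity: Entity, measure: str,
) -> SimilarityMatrix:
    n = len(blocks)
    indicator = (blocks[:, None] == blocks[None, :]).astype(np.float64)
    noise = rng.random((n, n))
    noise = (noise + noise.T) / 2.0
    values = reliability * indicator + (1.0 - reliability) * noise
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(entity=entity, measure=measure, values=np.clip(values, 0.0, 1.0))
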