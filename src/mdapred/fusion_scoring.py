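"""Feature integration and pair scoring.

The integrated drug feature matrix interleaves the diffusion profiles and the
two attribute feature matrices with copies of the adjacency matrix:

    IFMr = [DR | S | SAEr1 | S | SAEr2 | S]          (Nr x 3(Nr+Nm))
    IFMm = [S^T | MR | S^T | SAEm1 | S^T | SAEm2]    (Nm x 3(Nr+Nm))

The adjacency copies both carry raw association information and make the two
column layouts line up block by block, so the inner product decomposes as

    IFMr . IFMm^T = DR.S + S.MR^T + SAEr1.S + S.SAEm1^T + SAEr2.S + S.SAEm2^T

Scores are the elementwise logistic of that inner product. With thousands of
nonnegative feature columns the logits are large and the logistic saturates
at float precision, so ranking uses the raw logits (the logistic is strictly
monotone, so orderings -- and hence AUC -- are identical).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from mdapred.rwr import ProbabilityProfile
from mdapred.sae_attention import AttributeFeatures

_BLOCK_NAMES_R = ("DR", "S", "SAEr1", "S", "SAEr2", "S")
_BLOCK_NAMES_M = ("S_T", "MR", "S_T", "SAEm1", "S_T", "SAEm2")


@dataclass
class IntegratedFeatures:
    """Block-concatenated feature matrices for drugs and microbes."""

    IFMr: np.ndarray = field(repr=False)
    IFMm: np.ndarray = field(repr=False)
    block_layout: tuple[tuple[str, int], ...] = ()

    @property
    def n_drugs(self) -> int:
        return self.IFMr.shape[0]

    @property
    def n_microbes(self) -> int:
        return self.IFMm.shape[0]

    def block_slice(self, k: int) -> slice:
        """Column slice of the k-th block (shared layout for both matrices)."""
        start = sum(w for _, w in self.block_layout[:k])
        return slice(start, start + self.block_layout[k][1])


@dataclass
class ScoreMatrix:
    """Predicted association scores (logistic of inner products) plus raw logits."""

    values: np.ndarray = field(repr=False)
    raw_logits: np.ndarray = field(repr=False)


def _check_block(name: str, arr: np.ndarray, expected: tuple[int, int]) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float64)
    if arr.shape != expected:
        raise ValueError(f"block {name}: expected shape {expected}, got {arr.shape}")
    return arr


def integrate_features(
    DR: ProbabilityProfile | np.ndarray,
    MR: ProbabilityProfile | np.ndarray,
    SAEr1: AttributeFeatures | np.ndarray,
    SAEr2: AttributeFeatures | np.ndarray,
    SAEm1: AttributeFeatures | np.ndarray,
    SAEm2: AttributeFeatures | np.ndarray,
    S: np.ndarray,
) -> IntegratedFeatures:
    """Assemble IFMr and IFMm by horizontal concatenation in the fixed block order."""
    unwrap = lambda x: x.values if hasattr(x, "values") else np.asarray(x, dtype=np.float64)
    S = np.asarray(S, dtype=np.float64)
    nr, nm = S.shape
    DR = _check_block("DR", unwrap(DR), (nr, nr))
    MR = _check_block("MR", unwrap(MR), (nm, nm))
    SAEr1 = _check_block("SAEr1", unwrap(SAEr1), (nr, nr))
    SAEr2 = _check_block("SAEr2", unwrap(SAEr2), (nr, nr))
    SAEm1 = _check_block("SAEm1", unwrap(SAEm1), (nm, nm))
    SAEm2 = _check_block("SAEm2", unwrap(SAEm2), (nm, nm))
    IFMr = np.hstack([DR, S, SAEr1, S, SAEr2, S])
    IFMm = np.hstack([S.T, MR, S.T, SAEm1, S.T, SAEm2])
    widths = (nr, nm, nr, nm, nr, nm)
    layout = tuple(zip(_BLOCK_NAMES_R, widths))
    return IntegratedFeatures(IFMr=IFMr, IFMm=IFMm, block_layout=layout)


def score(IF: IntegratedFeatures) -> ScoreMatrix:
    """Score every drug-microbe pair: logits = IFMr . IFMm^T, values = logistic."""
    if IF.IFMr.shape[1] != IF.IFMm.shape[1]:
        raise ValueError(
            f"feature column mismatch: IFMr has {IF.IFMr.shape[1]}, IFMm has {IF.IFMm.shape[1]}"
        )
    logits = IF.IFMr @ IF.IFMm.T
    if not np.isfinite(logits).all():
        raise FloatingPointError(
            f"non-finite logits; max finite magnitude "
            f"{np.nanmax(np.abs(logits[np.isfinite(logits)])) if np.isfinite(logits).any() else 'n/a'}"
        )
    return ScoreMatrix(values=expit(logits), raw_logits=logits)


def block_decomposition(
    IF: IntegratedFeatures,
) -> dict[str, np.ndarray]:
    """Per-block contributions to the logits (diagnostic).

    Returns one Nr x Nm matrix per block pairing; their sum equals
    ``raw_logits`` up to floating-point roundoff.
    """
    out: dict[str, np.ndarray] = {}
    for k, ((rname, _), mname) in enumerate(zip(IF.block_layout, _BLOCK_NAMES_M)):
        sl = IF.block_slice(k)
        out[f"{rname}.{mname}^T"] = IF.IFMr[:, sl] @ IF.IFMm[:, sl].T
    return out
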