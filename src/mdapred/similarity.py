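"""Interaction-profile similarity matrices computed from the adjacency matrix.

Two measures per entity type, both derived solely from the binary adjacency
matrix ``S``:

* Gaussian interaction-profile (GIP) kernel:
  ``G(i, j) = exp(-mu * ||p_i - p_j||^2)`` where ``p_i`` is the association
  profile of node i (row of S for drugs, column for microbes) and the
  bandwidth ``mu`` is the reciprocal of the mean squared profile norm.
* Cosine similarity of the same profiles.

Profiles of unobserved entities (all-zero rows/columns) have no direction, so
their cosine similarity to anything -- including themselves -- is defined as 0.
"""

from __future__ import annotations

from typing import Literal

import numpy as np

from mdapred.data_io import Entity, SimilarityMatrix

Axis = Literal["rows", "columns"]

_AXIS_ENTITY: dict[Axis, Entity] = {"rows": "drug", "columns": "microbe"}


def _profiles(S: np.ndarray, axis: Axis) -> np.ndarray:
    S = np.asarray(S, dtype=np.float64)
    if S.ndim != 2 or S.size == 0:
        raise ValueError("S must be a nonempty 2-D matrix")
    if axis == "rows":
        return S
    if axis == "columns":
        return S.T
    raise ValueError(f"axis must be 'rows' or 'columns', got {axis!r}")


def kernel_bandwidth(S: np.ndarray, axis: Axis) -> float:
    """GIP bandwidth: 1 / mean squared profile norm over the chosen axis."""
    P = _profiles(S, axis)
    mean_sq = float((P**2).sum()) / P.shape[0]
    if mean_sq == 0.0:
        raise ValueError("bandwidth undefined: adjacency matrix has no associations")
    return 1.0 / mean_sq


def gaussian_kernel_similarity(S: np.ndarray, axis: Axis) -> SimilarityMatrix:
    """GIP kernel similarity between association profiles.

    ``axis='rows'`` compares drugs (rows of S), ``axis='columns'`` microbes.
    The result is symmetric with unit diagonal; entries lie in (0, 1].
    """
    P = _profiles(S, axis)
    mu = kernel_bandwidth(S, axis)
    sq_norms = (P**2).sum(axis=1)
    # ||p_i - p_j||^2 = ||p_i||^2 + ||p_j||^2 - 2 p_i . p_j
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * (P @ P.T)
    np.maximum(d2, 0.0, out=d2)
    G = np.exp(-mu * d2)
    G = (G + G.T) / 2.0
    np.fill_diagonal(G, 1.0)
    return SimilarityMatrix(entity=_AXIS_ENTITY[axis], measure="gaussian", values=G)


def cosine_similarity(S: np.ndarray, axis: Axis) -> SimilarityMatrix:
    """Cosine similarity between association profiles.

    Any pair involving an all-zero profile gets similarity 0, including the
    diagonal entry of the zero profile itself.
    """
    P = _profiles(S, axis)
    norms = np.linalg.norm(P, axis=1)
    safe = np.where(norms == 0.0, 1.0, norms)
    C = (P @ P.T) / (safe[:, None] * safe[None, :])
    zero = norms == 0.0
    C[zero, :] = 0.0
    C[:, zero] = 0.0
    C = np.clip((C + C.T) / 2.0, 0.0, 1.0)
    nz = ~zero
    C[nz, nz] = 1.0
    return SimilarityMatrix(entity=_AXIS_ENTITY[axis], measure="cosine", values=C)
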