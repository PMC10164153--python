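"""Loading, validation and serialization of association lists and similarity matrices.

The central object is the binary adjacency matrix ``S`` (drugs on rows,
microbes on columns): ``S[i, j] = 1`` iff drug ``i`` has a known association
with microbe ``j``. Entity order is lexicographic by identifier so that every
run of the pipeline sees the same row/column layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Entity = Literal["drug", "microbe"]
Measure = Literal["gaussian", "cosine", "structural", "functional"]

_SYMMETRY_TOL = 1e-10
_SYMMETRIZE_TOL = 1e-8


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class AssociationDataset:
    """Named bipartite association data with its binary adjacency matrix.

    Attributes
    ----------
    drug_ids : list of str
        Unique drug identifiers; row order of ``S``.
    microbe_ids : list of str
        Unique microbe identifiers; column order of ``S``.
    S : ndarray of shape (n_drugs, n_microbes)
        Binary adjacency; dtype float64 with values in {0, 1}.
    """

    drug_ids: list[str]
    microbe_ids: list[str]
    S: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=np.float64)
        if self.S.shape != (len(self.drug_ids), len(self.microbe_ids)):
            raise DataError(
                f"adjacency shape {self.S.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.microbe_ids)} microbes"
            )
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise DataError("duplicate drug identifiers")
        if len(set(self.microbe_ids)) != len(self.microbe_ids):
            raise DataError("duplicate microbe identifiers")
        if not np.isin(self.S, (0.0, 1.0)).all():
            raise DataError("adjacency matrix must contain only 0/1 values")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_microbes(self) -> int:
        return len(self.microbe_ids)

    @property
    def n_associations(self) -> int:
        return int(self.S.sum())

    def positive_pairs(self) -> np.ndarray:
        """Known association pairs as an (n_associations, 2) array of (row, col)."""
        return np.argwhere(self.S == 1.0)


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity over one entity type, values in [0, 1]."""

    entity: Entity
    measure: Measure
    values: np.ndarray = field(repr=False)
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DataError(f"similarity matrix must be square, got {v.shape}")
        if not np.all(np.abs(v - v.T) <= _SYMMETRY_TOL):
            raise DataError("similarity matrix is not symmetric within 1e-10")
        if v.size and (v.min() < -_SYMMETRY_TOL or v.max() > 1 + _SYMMETRY_TOL):
            raise DataError("similarity values outside [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def load_associations(
    path: str | Path,
    format: Literal["tsv", "csv"] | None = None,
    header: bool = False,
) -> AssociationDataset:
    """Load a two-column (drug_id, microbe_id) pair list into an :class:`AssociationDataset`.

    Duplicate pairs are collapsed (count logged). Entity order is lexicographic.

    Parameters
    ----------
    path : path to a TSV/CSV file with two identifier columns.
    format : "tsv" or "csv"; inferred from the suffix when omitted.
    header : whether the first row is a header and should be skipped.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"association file not found: {path}")
    sep = _infer_sep(path, format)
    try:
        df = pd.read_csv(
            path,
            sep=sep,
            header=0 if header else None,
            dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        raise DataError(f"empty association file: {path}") from None
    if df.shape[1] < 2:
        raise DataError(f"{path}: expected 2 identifier columns, found {df.shape[1]}")
    df = df.iloc[:, :2]
    df.columns = ["drug_id", "microbe_id"]
    offset = 2 if header else 1  # 1-based line numbers in error messages
    bad = df.index[df.isna().any(axis=1) | (df.apply(lambda c: c.str.strip()) == "").any(axis=1)]
    if len(bad):
        raise DataError(f"{path}: malformed row at line {int(bad[0]) + offset} (missing identifier)")
    pairs = list(zip(df["drug_id"].str.strip(), df["microbe_id"].str.strip()))
    if not pairs:
        raise DataError(f"empty association file: {path}")
    unique_pairs = sorted(set(pairs))
    n_dup = len(pairs) - len(unique_pairs)
    if n_dup:
        logger.info("collapsed %d duplicate association pairs", n_dup)
    drug_ids = sorted({d for d, _ in unique_pairs})
    microbe_ids = sorted({m for _, m in unique_pairs})
    drug_index = {d: i for i, d in enumerate(drug_ids)}
    microbe_index = {m: j for j, m in enumerate(microbe_ids)}
    S = np.zeros((len(drug_ids), len(microbe_ids)))
    for d, m in unique_pairs:
        S[drug_index[d], microbe_index[m]] = 1.0
    logger.info(
        "loaded %d drugs, %d microbes, %d associations from %s",
        len(drug_ids), len(microbe_ids), len(unique_pairs), path,
    )
    return AssociationDataset(drug_ids=drug_ids, microbe_ids=microbe_ids, S=S)


def write_associations(dataset: AssociationDataset, path: str | Path) -> None:
    """Write the positive pair list as a two-column TSV (drug_id, microbe_id)."""
    path = Path(path)
    rows = [
        (dataset.drug_ids[i], dataset.microbe_ids[j])
        for i, j in dataset.positive_pairs()
    ]
    pd.DataFrame(rows, columns=["drug_id", "microbe_id"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def write_adjacency(dataset: AssociationDataset, dense_path: str | Path | None = None,
                    coo_path: str | Path | None = None) -> None:
    """Export the adjacency matrix as labeled dense CSV and/or coordinate-list TSV."""
    if dense_path is not None:
        pd.DataFrame(dataset.S, index=dataset.drug_ids, columns=dataset.microbe_ids).to_csv(dense_path)
    if coo_path is not None:
        rows = [
            (dataset.drug_ids[i], dataset.microbe_ids[j], 1)
            for i, j in dataset.positive_pairs()
        ]
        pd.DataFrame(rows, columns=["drug_id", "microbe_id", "value"]).to_csv(
            coo_path, sep="\t", index=False
        )


def load_similarity(
    path: str | Path,
    entity: Entity,
    measure: Measure,
    ids: Sequence[str],
) -> SimilarityMatrix:
    """Load a precomputed labeled square similarity CSV, aligned to ``ids`` order.

    The file's first row and first column are identifiers. The matrix is
    reordered to ``ids``; symmetrized as ``(A + A.T)/2`` when asymmetric beyond
    1e-8 (logged); values outside [0, 1] are clipped with a logged count.
    Typical use: drug structural similarity or microbe functional similarity
    computed by external tools.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"similarity file not found: {path}")
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    ids = [str(i) for i in ids]
    missing = sorted(set(ids) - set(df.index)) + sorted(set(ids) - set(df.columns))
    if missing:
        raise DataError(f"{path}: missing identifiers {sorted(set(missing))}")
    sub = df.loc[ids, ids]
    try:
        values = sub.to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise DataError(f"{path}: non-numeric cell ({exc})") from None
    if np.isnan(values).any():
        raise DataError(f"{path}: non-numeric or missing cell after alignment")
    asym = np.abs(values - values.T).max() if values.size else 0.0
    if asym > _SYMMETRIZE_TOL:
        logger.warning("%s: asymmetry %.3g beyond 1e-8; symmetrizing as (A+A.T)/2", path, asym)
        values = (values + values.T) / 2.0
    n_clip = int(((values < 0) | (values > 1)).sum())
    if n_clip:
        logger.info("%s: clipped %d entries to [0, 1]", path, n_clip)
        values = np.clip(values, 0.0, 1.0)
    # exact symmetry after the (A+A.T)/2 average, guard rounding
    values = (values + values.T) / 2.0
    return SimilarityMatrix(entity=entity, measure=measure, values=values, ids=list(ids))


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    """Write a similarity matrix as labeled square CSV."""
    ids = sim.ids if sim.ids is not None else [str(i) for i in range(sim.n)]
    pd.DataFrame(sim.values, index=ids, columns=ids).to_csv(path)


def _infer_sep(path: Path, format: str | None) -> str:
    if format == "tsv":
        return "\t"
    if format == "csv":
        return ","
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
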