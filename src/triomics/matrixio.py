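"""Expression-matrix container and the TSV dialect used across the pipeline.

The on-disk format is a plain tab-separated table: first column holds the
feature identifiers, the header row holds the sample identifiers, values are
decimal-point floats, UTF-8 encoded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "MatrixFormatError",
    "read_matrix",
    "write_matrix",
    "read_gene_map",
    "write_gene_map",
]

VALID_LEVELS = ("", "miRNA", "mRNA", "protein", "score", "zscore")


class MatrixFormatError(ValueError):
    """Raised when an expression matrix (in memory or on disk) is malformed."""


@dataclass
class ExpressionMatrix:
    """A features x samples matrix for one molecular level.

    Parameters
    ----------
    values : ndarray of shape (n_features, n_samples)
        Real-valued expression. NaN marks a missing measurement.
    feature_ids, sample_ids : list of str
        Unique, ordered identifiers for rows and columns.
    level : str
        Free-text molecular level tag (e.g. ``"miRNA"``).
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    level: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise MatrixFormatError(
                f"values must be 2-D, got shape {self.values.shape}"
            )
        n_feat, n_samp = self.values.shape
        if n_feat == 0:
            raise MatrixFormatError("matrix has zero features")
        if n_samp == 0:
            raise MatrixFormatError("matrix has zero samples")
        if len(self.feature_ids) != n_feat:
            raise MatrixFormatError(
                f"{len(self.feature_ids)} feature ids for {n_feat} rows"
            )
        if len(self.sample_ids) != n_samp:
            raise MatrixFormatError(
                f"{len(self.sample_ids)} sample ids for {n_samp} columns"
            )
        for name, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise MatrixFormatError(f"duplicated {name} ids: {dupes[:5]}")

    # -- basic accessors -------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature {feature_id!r}") from None

    def row(self, feature_id: str) -> np.ndarray:
        return self.values[self.feature_index(feature_id)]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), list(self.feature_ids), list(self.sample_ids), self.level
        )

    def subset_features(self, keep: list[str]) -> "ExpressionMatrix":
        idx = [self.feature_index(f) for f in keep]
        return ExpressionMatrix(
            self.values[idx], list(keep), list(self.sample_ids), self.level
        )

    def subset_samples(self, keep: list[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in keep if s not in pos]
        if missing:
            raise KeyError(f"unknown samples: {missing[:5]}")
        idx = [pos[s] for s in keep]
        return ExpressionMatrix(
            self.values[:, idx], list(self.feature_ids), list(keep), self.level
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, level: str = "") -> "ExpressionMatrix":
        return cls(
            frame.to_numpy(dtype=float),
            [str(i) for i in frame.index],
            [str(c) for c in frame.columns],
            level,
        )


def read_matrix(path, level: str = "") -> ExpressionMatrix:
    """Read a TSV expression matrix (feature rows, sample columns)."""
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n")
    cols = header.split("\t")[1:]
    if len(set(cols)) != len(cols):
        raise MatrixFormatError(f"{path}: duplicated sample ids in header")
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise MatrixFormatError(f"{path}: cannot parse TSV matrix: {exc}") from exc
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise MatrixFormatError(f"{path}: empty matrix")
    if frame.isna().any(axis=None) and frame.shape[1] != len(cols):
        raise MatrixFormatError(f"{path}: ragged rows")
    idx = [str(i) for i in frame.index]
    if len(set(idx)) != len(idx):
        raise MatrixFormatError(f"{path}: duplicated feature ids")
    try:
        values = frame.to_numpy(dtype=object)
        values = np.where(pd.isna(values) | (values == ""), "nan", values)
        values = values.astype(float)
    except ValueError:
        # slow path only to locate the offending cell for the error message
        raw = frame.to_numpy(dtype=object)
        for i in range(frame.shape[0]):
            for j in range(frame.shape[1]):
                cell = raw[i, j]
                if pd.isna(cell) or cell == "":
                    continue
                try:
                    float(cell)
                except ValueError:
                    raise MatrixFormatError(
                        f"{path}: non-numeric value {cell!r} at feature "
                        f"{idx[i]!r}, sample {cols[j]!r}"
                    ) from None
        raise MatrixFormatError(f"{path}: non-numeric content") from None
    return ExpressionMatrix(values, idx, cols, level)


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write the TSV dialect; lossless for float64 via repr round-trip."""
    frame = matrix.to_frame()
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t", float_format="%.17g")


def read_gene_map(path) -> dict[str, str]:
    """Read a two-column TSV pairing each protein with its in-cis mRNA."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise MatrixFormatError(f"{path}: gene map needs two columns (protein, mrna)")
    pairs = {}
    for _, row in frame.iterrows():
        prot, gene = str(row.iloc[0]).strip(), str(row.iloc[1]).strip()
        if prot in pairs:
            raise MatrixFormatError(f"{path}: protein {prot!r} mapped twice")
        pairs[prot] = gene
    return pairs


def write_gene_map(gene_map: dict[str, str], path) -> None:
    frame = pd.DataFrame(
        {"protein": list(gene_map.keys()), "mrna": list(gene_map.values())}
    )
    frame.to_csv(path, sep="\t", index=False)
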