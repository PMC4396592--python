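"""Range standardization and log transformation applied before model fitting.

Every feature is independently mapped to the interval ``[delta0, 1 + delta0]``
with ``X* = (X - min) / (max - min) + delta0`` so that all molecular levels
share a common positive range and can be log-transformed without guards.
The natural logarithm is used internally; the fitted exponents are invariant
to the log base, only the intercept changes units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrixio import ExpressionMatrix

__all__ = [
    "StandardizationParams",
    "standardize",
    "log_transform",
    "DEFAULT_DELTA0",
]

DEFAULT_DELTA0 = 0.1


@dataclass
class StandardizationParams:
    """Per-feature min/max on the input scale plus the positivity offset."""

    delta0: float
    feature_ids: list[str]
    mins: np.ndarray
    maxs: np.ndarray
    dropped: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature_id": self.feature_ids, "min": self.mins, "max": self.maxs}
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def standardize(
    matrix: ExpressionMatrix, delta0: float = DEFAULT_DELTA0
) -> tuple[ExpressionMatrix, StandardizationParams]:
    """Map each feature to ``[delta0, 1 + delta0]`` across samples.

    Zero-variance features (max == min) are dropped with a warning: the map
    is undefined for them and they carry no association signal. Missing
    values propagate as NaN; min/max are computed over observed values.
    """
    if not delta0 > 0:
        raise ValueError(f"delta0 must be > 0, got {delta0}")
    values = matrix.values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        mins = np.nanmin(values, axis=1)
        maxs = np.nanmax(values, axis=1)
    span = maxs - mins
    keep = np.isfinite(span) & (span > 0)
    dropped = [f for f, k in zip(matrix.feature_ids, keep) if not k]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} zero-variance feature(s): {dropped[:5]}",
            UserWarning,
            stacklevel=2,
        )
    if not keep.any():
        raise ValueError("all features have zero variance; nothing to standardize")
    out = (values[keep] - mins[keep, None]) / span[keep, None] + delta0
    kept_ids = [f for f, k in zip(matrix.feature_ids, keep) if k]
    result = ExpressionMatrix(out, kept_ids, list(matrix.sample_ids), matrix.level)
    params = StandardizationParams(
        delta0=float(delta0),
        feature_ids=kept_ids,
        mins=mins[keep],
        maxs=maxs[keep],
        dropped=dropped,
    )
    return result, params


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise natural logarithm; rejects nonpositive values by feature."""
    values = matrix.values
    with np.errstate(invalid="ignore"):
        bad = values <= 0
    bad &= ~np.isnan(values)
    if bad.any():
        offenders = [
            matrix.feature_ids[i] for i in sorted(set(np.nonzero(bad)[0]))
        ]
        raise ValueError(
            f"nonpositive values in feature(s) {offenders[:5]}; "
            "standardize with delta0 > 0 first"
        )
    return ExpressionMatrix(
        np.log(values), list(matrix.feature_ids), list(matrix.sample_ids), matrix.level
    )
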