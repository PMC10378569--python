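"""Equal-width discretization and arity statistics.

Continuous features are cut into ``bins`` intervals of equal span over the
observed range of each feature (5 bins for generic benchmark tables, 3 for
expression data, mirroring the high/normal/low reading of protein levels).
The fitted :class:`BinningModel` can be applied to held-out data, in which
case out-of-range values clip to the extreme bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatable import FeatureTable

__all__ = [
    "BinningModel",
    "DiscreteTable",
    "fit_equal_width",
    "apply_binning",
    "discretize_table",
    "arity_stats",
]


@dataclass
class BinningModel:
    """Per-feature equal-width bin edges fitted on a complete table."""

    feature_names: list[str]
    lower: np.ndarray
    upper: np.ndarray
    bin_count: int

    def edges(self, feature: str) -> np.ndarray:
        """Edge list of length ``bin_count + 1`` for one feature."""
        j = self.feature_names.index(feature)
        return np.linspace(self.lower[j], self.upper[j], self.bin_count + 1)


@dataclass
class DiscreteTable:
    """Integer-coded feature matrix with a coded class vector.

    ``codes`` is ``(n_samples, m_features)`` of nonnegative integers;
    ``class_codes`` holds ``c >= 1`` distinct values coded by first
    appearance.  No missing entries are representable.
    """

    codes: np.ndarray
    feature_names: list[str]
    class_codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        self.class_codes = np.asarray(self.class_codes, dtype=np.int64)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D")
        if self.codes.shape[0] != self.class_codes.shape[0]:
            raise ValueError("class_codes length must match sample count")
        if len(self.feature_names) != self.codes.shape[1]:
            raise ValueError("feature_names must match column count")
        if self.codes.size and self.codes.min() < 0:
            raise ValueError("codes must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_features(self) -> int:
        return self.codes.shape[1]

    @property
    def n_classes(self) -> int:
        return len(np.unique(self.class_codes))

    def column(self, feature: str) -> np.ndarray:
        return self.codes[:, self.feature_names.index(feature)]

    def arities(self) -> np.ndarray:
        """Count of distinct observed codes per feature."""
        return np.array(
            [len(np.unique(self.codes[:, j])) for j in range(self.n_features)]
        )


def _encode_labels(labels: np.ndarray) -> np.ndarray:
    """Integer-code labels by first appearance order (deterministic)."""
    seen: dict = {}
    out = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        if lab not in seen:
            seen[lab] = len(seen)
        out[i] = seen[lab]
    return out


def fit_equal_width(table: FeatureTable, bins: int) -> BinningModel:
    """Fit per-feature equal-width edges spanning the observed min..max."""
    if bins < 1:
        raise ValueError("bins must be a positive integer")
    if np.isnan(table.values).any():
        raise ValueError("table has missing cells; impute before binning")
    lower = table.values.min(axis=0)
    upper = table.values.max(axis=0)
    return BinningModel(list(table.feature_names), lower, upper, bins)


def apply_binning(table: FeatureTable, model: BinningModel) -> DiscreteTable:
    """Code each value into its bin; class labels coded by first appearance.

    Value ``v`` maps to code ``k`` with ``e_k <= v < e_{k+1}``; the maximum
    edge is inclusive in the last bin.  Values outside the fitted range
    (possible when the model came from a training split) clip to the nearest
    extreme bin.  A degenerate feature (``upper == lower``) codes to 0.
    """
    missing = [n for n in table.feature_names if n not in model.feature_names]
    if missing:
        raise ValueError(f"features absent from binning model: {missing}")
    if np.isnan(table.values).any():
        raise ValueError("table has missing cells; impute before binning")
    B = model.bin_count
    codes = np.empty(table.values.shape, dtype=np.int64)
    for j, name in enumerate(table.feature_names):
        i = model.feature_names.index(name)
        lo, hi = model.lower[i], model.upper[i]
        v = table.values[:, j]
        if hi <= lo:
            codes[:, j] = 0
            continue
        width = (hi - lo) / B
        k = np.floor((v - lo) / width).astype(np.int64)
        codes[:, j] = np.clip(k, 0, B - 1)
    return DiscreteTable(codes, list(table.feature_names),
                         _encode_labels(table.class_labels))


def discretize_table(table: FeatureTable, bins: int) -> DiscreteTable:
    """Fit equal-width edges on ``table`` and apply them to the same table."""
    return apply_binning(table, fit_equal_width(table, bins))


def arity_stats(discrete: DiscreteTable) -> tuple[np.ndarray, float]:
    """Per-feature arities and their median (mean of middle two when even)."""
    arities = discrete.arities()
    return arities, float(np.median(arities))
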