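"""Delimited feature tables and missing-value preprocessing.

A :class:`FeatureTable` holds a samples × features matrix of real values
(``numpy.nan`` marks a missing cell) together with a categorical class label
per sample.  Preprocessing follows the usual proteomics convention: drop
features that are missing in more than a given fraction of samples, then
replace the remaining missing cells by the per-feature mean of the observed
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "read_table",
    "write_table",
    "filter_missing",
    "impute_mean",
]


@dataclass
class FeatureTable:
    """Raw named feature matrix plus class labels; may contain missing cells.

    Parameters
    ----------
    values
        ``(n_samples, n_features)`` float array; ``nan`` encodes missing.
    feature_names
        Unique column names, one per feature.
    class_labels
        Length ``n_samples`` array of opaque categorical labels.
    sample_ids
        Optional row identifiers.
    """

    values: np.ndarray
    feature_names: list[str]
    class_labels: np.ndarray
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples × features array")
        self.feature_names = list(self.feature_names)
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.feature_names)} feature names for "
                f"{self.values.shape[1]} columns"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            dupes = sorted(
                {n for n in self.feature_names if self.feature_names.count(n) > 1}
            )
            raise ValueError(f"duplicate feature names: {dupes}")
        self.class_labels = np.asarray(self.class_labels, dtype=object)
        if self.class_labels.shape[0] != self.values.shape[0]:
            raise ValueError("class_labels must have one entry per sample")
        if any(lab is None or (isinstance(lab, float) and np.isnan(lab))
               for lab in self.class_labels):
            raise ValueError("missing class label encountered")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def missing_fraction(self) -> np.ndarray:
        """Per-feature fraction of missing cells, in column order."""
        return np.isnan(self.values).mean(axis=0)

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.values.copy(),
            list(self.feature_names),
            self.class_labels.copy(),
            None if self.sample_ids is None else list(self.sample_ids),
        )


def read_table(
    path,
    target_column: str,
    delimiter: str = ",",
    na_token: str = "NA",
) -> FeatureTable:
    """Read a delimited text file into a :class:`FeatureTable`.

    The file must have a header row; ``target_column`` names the class
    column, which is removed from the feature matrix.  Cells equal to
    ``na_token`` become missing; every other cell must parse as a number.
    """
    df = pd.read_csv(
        path, sep=delimiter, na_values=[na_token], keep_default_na=False,
        dtype=str,
    )
    if target_column not in df.columns:
        raise ValueError(
            f"target column {target_column!r} not found; "
            f"columns are {list(df.columns)}"
        )
    labels = df[target_column]
    if labels.isna().any():
        row = int(labels.isna().idxmax())
        raise ValueError(f"missing class label at row {row}")
    feats = df.drop(columns=[target_column])
    numeric = feats.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & feats.notna()
    if bad.any().any():
        col = bad.any().idxmax()
        row = int(bad[col].idxmax())
        raise ValueError(
            f"non-numeric value {feats.loc[row, col]!r} at row {row}, "
            f"column {col!r}"
        )
    return FeatureTable(
        numeric.to_numpy(dtype=float),
        list(feats.columns),
        labels.to_numpy(dtype=object),
    )


def write_table(
    table: FeatureTable,
    path,
    target_column: str = "class",
    delimiter: str = ",",
    na_token: str = "NA",
) -> None:
    """Write a table in the same dialect ``read_table`` accepts."""
    df = pd.DataFrame(table.values, columns=table.feature_names)
    df[target_column] = table.class_labels
    df.to_csv(path, sep=delimiter, index=False, na_rep=na_token)


def filter_missing(
    table: FeatureTable, max_missing_fraction: float = 0.5
) -> tuple[FeatureTable, list[str]]:
    """Drop features whose missing fraction strictly exceeds the threshold.

    A feature missing in *over* ``max_missing_fraction`` of the samples is
    removed; a fraction exactly at the threshold is kept.  Returns the
    filtered table and the list of dropped feature names in column order.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must lie in [0, 1]")
    frac = table.missing_fraction()
    keep = frac <= max_missing_fraction
    dropped = [n for n, k in zip(table.feature_names, keep) if not k]
    out = FeatureTable(
        table.values[:, keep],
        [n for n, k in zip(table.feature_names, keep) if k],
        table.class_labels.copy(),
        None if table.sample_ids is None else list(table.sample_ids),
    )
    return out, dropped


def impute_mean(table: FeatureTable) -> FeatureTable:
    """Replace each missing cell by the mean of its feature's observed values."""
    values = table.values.copy()
    for j, name in enumerate(table.feature_names):
        col = values[:, j]
        mask = np.isnan(col)
        if mask.all():
            raise ValueError(f"feature {name!r} has no observed values")
        if mask.any():
            col[mask] = col[~mask].mean()
    return FeatureTable(
        values,
        list(table.feature_names),
        table.class_labels.copy(),
        None if table.sample_ids is None else list(table.sample_ids),
    )
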