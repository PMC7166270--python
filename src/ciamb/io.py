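"""CSV ingestion for feature tables.

Input files are comma-separated UTF-8 with a mandatory header row and period
decimal separators — the shape that HPLC/MS intensity exports and the common
public regression tables share: one named column per feature plus one named
continuous target column. Empty cells are treated as missing and either
replaced by the column mean (``impute="mean"``) or rejected
(``impute="none"``).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FeatureTable

__all__ = ["read_feature_table"]


def read_feature_table(path, target_column: str, impute: str = "mean") -> FeatureTable:
    """Read a CSV feature table, separating out the target column.

    Parameters
    ----------
    path : str or Path
        CSV file with a header row; all data cells numeric or empty.
    target_column : str
        Name of the continuous response column (removed from the features).
    impute : {"mean", "none"}, default "mean"
        How to treat missing feature cells: replace by the column mean of the
        observed values, or raise.

    Row and column order are preserved; nothing is silently dropped.
    """
    if impute not in ("mean", "none"):
        raise ValueError(f"impute must be 'mean' or 'none', got {impute!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such feature table: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    if target_column not in df.columns:
        raise ValueError(
            f"target column {target_column!r} not found; available columns: "
            + ", ".join(map(str, df.columns))
        )
    if len(df) < 4:
        raise ValueError(f"feature table needs at least 4 rows, got {len(df)}")
    try:
        df = df.astype(np.float64)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    target = df[target_column].to_numpy()
    if np.isnan(target).any():
        raise ValueError("target column contains missing values")
    features = df.drop(columns=[target_column])
    if features.isna().any().any():
        if impute == "none":
            bad = [c for c in features.columns if features[c].isna().any()]
            raise ValueError(
                "missing values with impute='none' in columns: " + ", ".join(bad)
            )
        means = features.mean(skipna=True)
        if means.isna().any():
            empty = [c for c in features.columns if np.isnan(means[c])]
            raise ValueError("entirely empty feature columns: " + ", ".join(empty))
        features = features.fillna(means)
    return FeatureTable(
        values=features.to_numpy(),
        feature_names=[str(c) for c in features.columns],
        target=target,
        target_name=str(target_column),
    )
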