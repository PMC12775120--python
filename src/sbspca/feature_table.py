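"""Feature-table container for non-target screening intensity data.

A feature table is the samples x features intensity matrix exported by an
LC-HRMS peak-picking tool, together with per-feature (m/z, retention time)
and per-sample (time index) metadata.  The on-disk dialect is a plain CSV
with one row per feature: ``feature_id, mz, rt`` followed by one intensity
column per time-ordered sample named ``t001 .. tNNN``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "read_feature_table", "write_feature_table"]


@dataclass
class FeatureTable:
    """Samples x features intensity matrix with metadata.

    Parameters
    ----------
    X : ndarray of shape (n_samples, n_features)
        Non-negative intensities; zeros encode non-detects.
    feature_meta : DataFrame
        One row per feature with at least ``feature_id`` (unique str),
        ``mz`` (Da) and ``rt`` (min).  Extra columns (e.g. an
        internal-standard flag) are carried along in memory.
    sample_meta : DataFrame
        One row per sample with at least ``time_index`` (strictly
        increasing) and ``label``.
    """

    X: np.ndarray
    feature_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        n, p = self.X.shape
        if len(self.sample_meta) != n:
            raise ValueError(
                f"sample_meta has {len(self.sample_meta)} rows but X has {n} samples"
            )
        if len(self.feature_meta) != p:
            raise ValueError(
                f"feature_meta has {len(self.feature_meta)} rows but X has {p} features"
            )
        for col in ("feature_id", "mz", "rt"):
            if col not in self.feature_meta.columns:
                raise ValueError(f"feature_meta lacks required column {col!r}")
        if "time_index" not in self.sample_meta.columns:
            raise ValueError("sample_meta lacks required column 'time_index'")
        if np.nanmin(self.X, initial=0.0) < 0:
            raise ValueError("negative intensities are not allowed")
        t = np.asarray(self.sample_meta["time_index"])
        if n > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("sample time_index must be strictly increasing")
        ids = self.feature_meta["feature_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate feature_id {dup!r}")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.feature_meta["feature_id"])

    def feature_index(self, feature_id: str) -> int:
        idx = self.feature_meta.index[self.feature_meta["feature_id"] == feature_id]
        if len(idx) == 0:
            raise KeyError(f"feature {feature_id!r} not in table")
        return int(self.feature_meta.index.get_loc(idx[0]))

    def column(self, feature_id: str) -> np.ndarray:
        """Intensity series of one feature across all samples."""
        return self.X[:, self.feature_index(feature_id)]

    def select_features(self, keep: np.ndarray | list) -> "FeatureTable":
        """Subset to features given by boolean mask or integer positions."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return FeatureTable(
            X=self.X[:, keep].copy(),
            feature_meta=self.feature_meta.iloc[keep].reset_index(drop=True),
            sample_meta=self.sample_meta.copy(),
        )

    def with_X(self, X: np.ndarray) -> "FeatureTable":
        """Same metadata, new intensity matrix."""
        return FeatureTable(
            X=np.asarray(X, dtype=float),
            feature_meta=self.feature_meta.copy(),
            sample_meta=self.sample_meta.copy(),
        )

    def copy(self) -> "FeatureTable":
        return self.with_X(self.X.copy())

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long-for-features frame in the on-disk dialect (features as rows)."""
        cols = [f"t{i + 1:03d}" for i in range(self.n_samples)]
        out = self.feature_meta[["feature_id", "mz", "rt"]].copy()
        out[cols] = self.X.T
        return out


def write_feature_table(table: FeatureTable, path) -> None:
    """Write the CSV dialect: feature_id, mz, rt, t001..tNNN (one row/feature)."""
    table.to_frame().to_csv(path, index=False)


def read_feature_table(path) -> FeatureTable:
    """Read a feature-table CSV written by :func:`write_feature_table`."""
    df = pd.read_csv(path)
    for col in ("feature_id", "mz", "rt"):
        if col not in df.columns:
            raise ValueError(f"feature table CSV lacks column {col!r}")
    sample_cols = [c for c in df.columns if c.startswith("t") and c[1:].isdigit()]
    if not sample_cols:
        raise ValueError("feature table CSV has no sample columns (t001..)")
    sample_cols.sort(key=lambda c: int(c[1:]))
    X = df[sample_cols].to_numpy(dtype=float).T
    feature_meta = df[["feature_id", "mz", "rt"]].copy()
    feature_meta["feature_id"] = feature_meta["feature_id"].astype(str)
    sample_meta = pd.DataFrame(
        {"time_index": [int(c[1:]) for c in sample_cols], "label": sample_cols}
    )
    return FeatureTable(X=X, feature_meta=feature_meta, sample_meta=sample_meta)
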