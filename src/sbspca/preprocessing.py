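"""Feature-table preprocessing chain for multivariate trend modeling.

The chain is fixed in order: internal-standard normalization ->
near-zero-variance filtering -> row-wise total-abundance normalization
with log transform -> autoscaling.  Each stage returns a new object; the
filter additionally reports which features it removed and why.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_table import FeatureTable

__all__ = [
    "PreprocessParams",
    "ScalingState",
    "is_normalize",
    "nzv_filter",
    "nzv_flags",
    "log_total_normalize",
    "autoscale",
    "preprocess",
]

log = logging.getLogger(__name__)


@dataclass
class PreprocessParams:
    """Parameters of the preprocessing chain.

    freq_cut is the ratio of the most common value's frequency over the
    second most common one's above which a feature counts as near-zero
    variance (default 95/5 = 19); unique_cut the percent-distinct
    threshold at or below which it does (default 8).  pseudocount is
    added before the log10 transform.  is_ids lists internal-standard
    feature ids; when empty, IS normalization is skipped.
    """

    freq_cut: float = 95.0 / 5.0
    unique_cut: float = 8.0
    pseudocount: float = 1.0
    is_ids: list = field(default_factory=list)

    def __post_init__(self):
        if self.freq_cut <= 1:
            raise ValueError("freq_cut must be > 1")
        if not (0 < self.unique_cut < 100):
            raise ValueError("unique_cut must be in (0, 100)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


def is_normalize(table: FeatureTable, is_ids: list) -> FeatureTable:
    """Divide each sample by its internal-standard response factor.

    The per-sample factor is the geometric mean over the IS channels of
    that sample's IS intensity divided by the IS's own across-time
    geometric mean, so factors are centred at 1 and encode relative
    sensitivity.  IS columns are retained (and flagged) so downstream
    stages can exclude them from modeling.
    """
    if not is_ids:
        raise ValueError("is_ids must name at least one internal standard")
    idx = [table.feature_index(f) for f in is_ids]
    IS = table.X[:, idx]  # (n, n_is)
    if np.any(IS <= 0):
        s, f = np.argwhere(IS <= 0)[0]
        raise ValueError(
            f"internal standard {is_ids[int(f)]!r} has a non-positive intensity "
            f"at time point {int(table.sample_meta['time_index'].iloc[int(s)])}"
        )
    logIS = np.log(IS)
    rel = logIS - logIS.mean(axis=0, keepdims=True)  # centre each IS over time
    factors = np.exp(rel.mean(axis=1))  # per-sample geometric mean
    out = table.with_X(table.X / factors[:, None])
    out.feature_meta["is_internal_standard"] = out.feature_meta["feature_id"].isin(
        set(is_ids)
    ) | out.feature_meta.get(
        "is_internal_standard", pd.Series(False, index=out.feature_meta.index)
    ).astype(bool)
    return out


def _nzv_stats(col: np.ndarray) -> tuple[float, float]:
    """(frequency ratio, percent unique) of one feature column."""
    n = col.size
    _, counts = np.unique(col, return_counts=True)
    n_unique = counts.size
    percent_unique = 100.0 * n_unique / n
    if n_unique == 1:
        freq_ratio = np.inf
    else:
        top2 = np.sort(counts)[::-1][:2]
        freq_ratio = top2[0] / top2[1]
    return float(freq_ratio), float(percent_unique)


def nzv_flags(
    X: np.ndarray, freq_cut: float = 19.0, unique_cut: float = 8.0
) -> pd.DataFrame:
    """Per-feature near-zero-variance diagnostics.

    A feature is flagged iff its frequency ratio exceeds ``freq_cut``
    (strict) AND its percent of distinct values is at most ``unique_cut``;
    constant features are always flagged.
    """
    rows = []
    for j in range(X.shape[1]):
        fr, pu = _nzv_stats(X[:, j])
        constant = not np.isfinite(fr)
        remove = constant or (fr > freq_cut and pu <= unique_cut)
        reason = (
            "constant"
            if constant
            else ("near_zero_variance" if remove else "")
        )
        rows.append((fr, pu, remove, reason))
    return pd.DataFrame(
        rows, columns=["freq_ratio", "percent_unique", "remove", "reason"]
    )


def nzv_filter(
    table: FeatureTable, freq_cut: float = 19.0, unique_cut: float = 8.0
) -> tuple[FeatureTable, pd.DataFrame]:
    """Drop near-zero-variance (spiky/uninformative) features.

    Returns the filtered table and a report of the removed features
    (feature_id, reason, freq_ratio, percent_unique).
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples to assess variance")
    flags = nzv_flags(table.X, freq_cut=freq_cut, unique_cut=unique_cut)
    removed = flags["remove"].to_numpy()
    report = pd.concat(
        [table.feature_meta[["feature_id"]].reset_index(drop=True), flags], axis=1
    )
    report = report.loc[removed, ["feature_id", "reason", "freq_ratio", "percent_unique"]]
    report = report.reset_index(drop=True)
    if removed.all():
        warnings.warn("near-zero-variance filter removed every feature")
    return table.select_features(~removed), report


def log_total_normalize(table: FeatureTable, pseudocount: float = 1.0) -> FeatureTable:
    """Row-wise total-abundance normalization followed by log10.

    Each sample row is rescaled to the median total intensity, then
    transformed as log10(value + pseudocount).  Rows no longer share a
    common sum afterwards (logging follows normalization).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    totals = table.X.sum(axis=1)
    if np.any(totals <= 0):
        bad = int(np.argwhere(totals <= 0)[0][0])
        t = int(table.sample_meta["time_index"].iloc[bad])
        raise ValueError(f"sample at time point {t} has zero total intensity")
    target = np.median(totals)
    X = table.X * (target / totals)[:, None]
    return table.with_X(np.log10(X + pseudocount))


@dataclass
class ScalingState:
    """Per-feature mean/sd of an autoscaling, for inverse mapping."""

    mean: np.ndarray
    sd: np.ndarray

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return Z * self.sd + self.mean


def autoscale(X) -> tuple[np.ndarray, ScalingState]:
    """Centre each feature to mean 0 and scale to unit sample sd (ddof=1).

    Accepts a FeatureTable or a bare (samples x features) array and
    returns the scaled matrix plus the state needed to invert it.
    Zero-variance features are rejected by name/index.
    """
    feature_ids = None
    if isinstance(X, FeatureTable):
        feature_ids = X.feature_ids
        X = X.X
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd <= 0)
    if bad.size:
        name = feature_ids[bad[0]] if feature_ids else f"column {bad[0]}"
        raise ValueError(f"zero-variance feature {name} cannot be autoscaled")
    return (X - mean) / sd, ScalingState(mean=mean, sd=sd)


def preprocess(
    table: FeatureTable, params: PreprocessParams
) -> tuple[np.ndarray, FeatureTable, pd.DataFrame, ScalingState]:
    """Run the full chain and return the modeling matrix.

    Order: IS normalization (skipped with a log message when no IS ids
    are given) -> drop IS columns from modeling -> near-zero-variance
    filter -> row-wise total normalization + log10 -> autoscale.

    Returns ``(Z, filtered_table, removed_report, scaling_state)`` where
    ``Z`` is the autoscaled matrix whose columns follow
    ``filtered_table.feature_meta``.
    """
    if params.is_ids:
        table = is_normalize(table, params.is_ids)
        flag = table.feature_meta["is_internal_standard"].to_numpy(dtype=bool)
        table = table.select_features(~flag)
    else:
        log.info("no internal-standard ids given; IS normalization skipped")
        if "is_internal_standard" in table.feature_meta.columns:
            flag = table.feature_meta["is_internal_standard"].to_numpy(dtype=bool)
            if flag.any():
                table = table.select_features(~flag)
    filtered, report = nzv_filter(
        table, freq_cut=params.freq_cut, unique_cut=params.unique_cut
    )
    normed = log_total_normalize(filtered, pseudocount=params.pseudocount)
    Z, state = autoscale(normed)
    return Z, filtered, report, state
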