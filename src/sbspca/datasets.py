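"""Synthetic feature-table generator for time-trend screening studies.

Emulates the statistical structure of influent-wastewater LC-HRMS
non-target screening data: a fluctuating log-normal background with
temporal autocorrelation and slow sensitivity drift, internal-standard
channels, zero-inflated non-detects, spiky single-point artifacts, and
spiked target compounds following reference temporal profiles (monotone
trends, stable and fluctuating levels, and several spill shapes).

Two stock study designs are provided:

* dataset I  -- 53 replicate injections of a pooled matrix, 8 spiked
  targets covering trend/stability profile kinds;
* dataset II -- 52 consecutive daily samples, 9 spiked targets covering
  spill profile kinds (left-sided, wide, short-lived, right-sided,
  episodic).

``emulate_tool_variants`` derives several distorted copies of one table,
standing in for the output of different peak-picking tools (feature
dropout, duplicate and satellite features, intensity rescaling, missed
detections), with a provenance map back to the parent features.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from .feature_table import FeatureTable

__all__ = [
    "PROFILE_KINDS",
    "TargetProfile",
    "SpikeEntry",
    "SpikeRegistry",
    "GeneratorConfig",
    "ToolVariant",
    "generate_profile",
    "generate_dataset",
    "emulate_tool_variants",
    "dataset_i_registry_spec",
    "dataset_ii_registry_spec",
    "write_registry_json",
    "read_registry_json",
]

PROFILE_KINDS = (
    "increasing",
    "decreasing",
    "fluctuating",
    "stable",
    "spill_left",
    "spill_wide",
    "spill_short",
    "spill_right",
    "episodic",
)

#: kinds whose support spans every time point
FULL_SUPPORT_KINDS = ("increasing", "decreasing", "fluctuating", "stable")

#: kinds whose support is a block (or blocks) of time points
SPILL_KINDS = ("spill_left", "spill_wide", "spill_short", "spill_right", "episodic")

#: persistent spill shapes -- long contiguous exposure windows
PERSISTENT_SPILL_KINDS = ("spill_left", "spill_wide", "spill_right")

#: transient spill shapes -- brief or fragmented exposure
TRANSIENT_SPILL_KINDS = ("spill_short", "episodic")


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class TargetProfile:
    """Reference temporal intensity profile of one spiked target.

    ``values`` holds the noise-free expected spike contribution per time
    point (arbitrary intensity units, max equal to ``amplitude``);
    ``support`` is the tuple of time indices with a non-zero value and
    ``exposure`` the exact fraction ``len(support) / n_times``.
    """

    kind: str
    n_times: int
    support: tuple
    amplitude: float
    values: tuple

    def __post_init__(self):
        if self.kind not in PROFILE_KINDS:
            raise ValueError(
                f"unknown profile kind {self.kind!r}; expected one of {PROFILE_KINDS}"
            )
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (self.n_times,):
            raise ValueError("values must have length n_times")
        if np.any(vals < 0):
            raise ValueError("profile values must be >= 0")
        nz = tuple(int(i) for i in np.flatnonzero(vals > 0))
        if nz != tuple(self.support):
            raise ValueError("support must equal the indices of non-zero values")

    @property
    def exposure(self) -> float:
        return len(self.support) / self.n_times

    @property
    def exposure_percent(self) -> int:
        """Exposure rounded to whole percent, as reported in study tables."""
        return _round_half_away(100.0 * self.exposure)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def _blocks_of(support: tuple) -> list[tuple[int, int]]:
    """Maximal runs of consecutive indices as (start, stop_exclusive)."""
    if not support:
        return []
    blocks = []
    start = prev = support[0]
    for i in support[1:]:
        if i == prev + 1:
            prev = i
            continue
        blocks.append((start, prev + 1))
        start = prev = i
    blocks.append((start, prev + 1))
    return blocks


def generate_profile(
    kind: str,
    n_times: int,
    exposure: float = 1.0,
    amplitude: float = 1.0,
    anchor: int | None = None,
    seed: int = 0,
) -> TargetProfile:
    """Build a reference target profile of the given shape.

    Parameters
    ----------
    kind : str
        One of :data:`PROFILE_KINDS`.
    n_times : int
        Number of time points (>= 10).
    exposure : float
        Targeted fraction of time points with non-zero spike amplitude;
        the realized support size is ``round(exposure * n_times)`` (ties
        away from zero).  Full-support kinds require exposure 1.
    amplitude : float
        Peak expected spike intensity (arbitrary units, > 0).
    anchor : int, optional
        Start index overriding the default placement of a contiguous
        spill block (ignored for full-support and episodic kinds).
    seed : int
        Seeds the placement of short/episodic blocks and the fluctuating
        waveform; all other kinds are fully deterministic.
    """
    if kind not in PROFILE_KINDS:
        raise ValueError(
            f"unknown profile kind {kind!r}; expected one of {PROFILE_KINDS}"
        )
    if n_times < 10:
        raise ValueError("n_times must be >= 10")
    if not (0 < exposure <= 1):
        raise ValueError("exposure must be in (0, 1]")
    if amplitude <= 0:
        raise ValueError("amplitude must be > 0")
    m = _round_half_away(exposure * n_times)
    if m == 0:
        raise ValueError(
            f"exposure {exposure} rounds to an empty support on {n_times} time points"
        )
    m = min(m, n_times)
    rng = np.random.default_rng(seed)
    values = np.zeros(n_times)

    if kind in FULL_SUPPORT_KINDS:
        if m != n_times:
            raise ValueError(f"kind {kind!r} requires full support (exposure 1)")
        if kind == "increasing":
            values = np.linspace(amplitude / n_times, amplitude, n_times)
        elif kind == "decreasing":
            values = np.linspace(amplitude, amplitude / n_times, n_times)
        elif kind == "stable":
            values = np.full(n_times, amplitude)
        else:  # fluctuating: smooth positive waveform, seeded phase/period
            t = np.arange(n_times)
            n_cycles = rng.integers(2, 5)
            phase = rng.uniform(0, 2 * np.pi)
            wave = np.sin(2 * np.pi * n_cycles * t / n_times + phase)
            values = amplitude * (0.55 + 0.45 * wave)
    elif kind == "episodic":
        if m < 2:
            raise ValueError("episodic profiles need a support of >= 2 points")
        # split support into >= 2 disjoint short blocks (each <= 5 long)
        n_blocks = max(2, int(math.ceil(m / 5)))
        sizes = np.full(n_blocks, m // n_blocks)
        sizes[: m % n_blocks] += 1
        # place blocks left-to-right with seeded gaps (>= 1 to keep disjoint)
        slack = n_times - int(sizes.sum()) - (n_blocks - 1)
        if slack < 0:
            raise ValueError("episodic support does not fit with disjoint blocks")
        cuts = np.sort(rng.integers(0, slack + 1, size=n_blocks))
        extras = np.diff(np.concatenate(([0], cuts)))  # slack before each block
        pos = 0
        for size, extra in zip(sizes, extras):
            pos += extra
            values[pos : pos + size] = amplitude
            pos += size + 1  # mandatory gap
    else:  # contiguous spill block
        if kind == "spill_short" and m > 5:
            raise ValueError(
                f"spill_short support must be <= 5 points, got {m} "
                f"(exposure {exposure} on {n_times})"
            )
        if kind == "spill_left":
            start = 0
        elif kind == "spill_right":
            start = n_times - m
        elif kind == "spill_wide":
            start = (n_times - m) // 2
        else:  # spill_short: seeded interior placement
            start = int(rng.integers(1, max(2, n_times - m)))
        if anchor is not None:
            start = int(anchor)
        if not (0 <= start <= n_times - m):
            raise ValueError(f"anchor {start} leaves no room for a {m}-point block")
        values[start : start + m] = amplitude

    support = tuple(int(i) for i in np.flatnonzero(values > 0))
    return TargetProfile(
        kind=kind,
        n_times=n_times,
        support=support,
        amplitude=float(amplitude),
        values=tuple(float(v) for v in values),
    )


# ----------------------------------------------------------------------
# dataset generation
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class SpikeEntry:
    feature_id: str
    profile: TargetProfile
    concentration: tuple  # expected spike series, relative units


@dataclass
class SpikeRegistry:
    """Ground truth of spiked targets for recovery scoring."""

    entries: list
    dataset_label: str

    @property
    def feature_ids(self) -> list[str]:
        return [e.feature_id for e in self.entries]

    def entry(self, feature_id: str) -> SpikeEntry:
        for e in self.entries:
            if e.feature_id == feature_id:
                return e
        raise KeyError(feature_id)

    def ids_of_kinds(self, kinds) -> list[str]:
        return [e.feature_id for e in self.entries if e.profile.kind in kinds]


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic background matrix.

    noise_cv is the multiplicative coefficient of variation of the
    log-normal background intensity noise (matrix variability);
    spike_noise_cv the smaller analytical noise on the spiked-standard
    term, whose concentrations follow predefined profiles;
    ar_coefficient the lag-1 autocorrelation of background
    log-intensities; drift_magnitude scales a smooth, seeded
    multiplicative sensitivity drift shared by all channels (internal
    standards included), emulating drifts that IS normalization is
    meant to correct.
    """

    n_times: int = 52
    n_background_features: int = 200
    n_is_channels: int = 5
    noise_cv: float = 0.35
    spike_noise_cv: float = 0.15
    ar_coefficient: float = 0.6
    zero_rate: float = 0.05
    n_artifact_features: int = 10
    drift_magnitude: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_times < 10:
            raise ValueError("n_times must be >= 10")
        if self.noise_cv <= 0:
            raise ValueError("noise_cv must be > 0")
        if self.spike_noise_cv < 0:
            raise ValueError("spike_noise_cv must be >= 0")
        if not (0 <= self.ar_coefficient < 1):
            raise ValueError("ar_coefficient must be in [0, 1)")
        for name in ("zero_rate",):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.drift_magnitude < 0:
            raise ValueError("drift_magnitude must be >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


#: amplitude unit: expected spike maxima are quoted on the same linear
#: intensity scale as the background (background medians ~1e4-4e5).
_DEFAULT_AMPLITUDE = 1.5e5


def dataset_ii_registry_spec(amplitude: float = _DEFAULT_AMPLITUDE) -> list[dict]:
    """Nine spill-type targets of the daily time-series design.

    Exposures follow the study design: two left-sided spills (38% and
    33%), two wide spills (52%, 54%), three short-lived spills, one
    right-sided spill (25%) and one episodic pattern (13%).
    """
    return [
        {"kind": "spill_left", "exposure": 0.38, "amplitude": amplitude},
        {"kind": "spill_left", "exposure": 0.33, "amplitude": amplitude},
        {"kind": "spill_wide", "exposure": 0.52, "amplitude": amplitude},
        {"kind": "spill_wide", "exposure": 0.54, "amplitude": amplitude},
        {"kind": "spill_short", "exposure": 0.06, "amplitude": amplitude},
        {"kind": "spill_short", "exposure": 0.08, "amplitude": amplitude},
        {"kind": "spill_short", "exposure": 0.09, "amplitude": amplitude},
        {"kind": "spill_right", "exposure": 0.25, "amplitude": amplitude},
        {"kind": "episodic", "exposure": 0.13, "amplitude": amplitude},
    ]


def dataset_i_registry_spec(amplitude: float = _DEFAULT_AMPLITUDE) -> list[dict]:
    """Eight targets of the replicate-injection design (trend/stability kinds)."""
    return [
        {"kind": "increasing", "exposure": 1.0, "amplitude": amplitude},
        {"kind": "decreasing", "exposure": 1.0, "amplitude": amplitude},
        {"kind": "fluctuating", "exposure": 1.0, "amplitude": amplitude},
        {"kind": "stable", "exposure": 1.0, "amplitude": amplitude},
        {"kind": "spill_left", "exposure": 0.30, "amplitude": amplitude},
        {"kind": "spill_wide", "exposure": 0.50, "amplitude": amplitude},
        {"kind": "spill_short", "exposure": 0.08, "amplitude": amplitude},
        {"kind": "spill_right", "exposure": 0.25, "amplitude": amplitude},
    ]


def _resolve_registry_spec(spec, n_times: int) -> tuple[list[dict], str]:
    if isinstance(spec, str):
        label = spec.upper()
        if label == "II":
            return dataset_ii_registry_spec(), "II"
        if label == "I":
            return dataset_i_registry_spec(), "I"
        raise ValueError(f"unknown stock registry spec {spec!r} (use 'I' or 'II')")
    return list(spec), "custom"


def _smooth_drift(rng: np.random.Generator, n: int, magnitude: float) -> np.ndarray:
    """Seeded slow multiplicative sensitivity drift, centred at 1."""
    if magnitude == 0:
        return np.ones(n)
    walk = np.cumsum(rng.standard_normal(n + 6))
    kernel = np.ones(7) / 7.0
    smooth = np.convolve(walk, kernel, mode="valid")
    smooth = (smooth - smooth.mean()) / max(smooth.std(), 1e-12)
    return np.exp(magnitude * smooth)


def _ar1(rng: np.random.Generator, n: int, rho: float, sigma: float) -> np.ndarray:
    """Stationary AR(1) log-noise with marginal sd sigma."""
    e = np.empty(n)
    e[0] = rng.normal(0.0, sigma)
    innov_sd = sigma * math.sqrt(max(1.0 - rho * rho, 0.0))
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for t in range(1, n):
        e[t] = rho * e[t - 1] + eps[t - 1]
    return e


def generate_dataset(
    config: GeneratorConfig,
    registry_spec="II",
) -> tuple[FeatureTable, SpikeRegistry]:
    """Generate one seeded feature table plus its spike ground truth.

    The table columns are, in order: background features (``B####``),
    internal standards (``IS##``), spiked targets (``T##_<kind>``) and
    artifact features (``A##``).  Spiked rows are background-level
    baseline plus ``profile x multiplicative log-normal noise``; the
    sensitivity drift multiplies every channel; zeros are injected at
    ``zero_rate`` on background features only.
    """
    spec, label = _resolve_registry_spec(registry_spec, config.n_times)
    if len(spec) > config.n_background_features:
        raise ValueError(
            f"registry of {len(spec)} targets exceeds table capacity "
            f"({config.n_background_features} background features)"
        )
    rng = np.random.default_rng(config.seed)
    n = config.n_times
    sigma_log = math.sqrt(math.log1p(config.noise_cv**2))
    drift = _smooth_drift(rng, n, config.drift_magnitude)

    cols: list[np.ndarray] = []
    meta_rows: list[tuple[str, float, float]] = []

    def _mzrt():
        return float(rng.uniform(100.0, 900.0)), float(rng.uniform(0.5, 15.0))

    # background matrix: log-normal AR(1) around a per-feature base level
    for i in range(config.n_background_features):
        mu = rng.uniform(math.log(1e4), math.log(4e5))
        series = np.exp(mu + _ar1(rng, n, config.ar_coefficient, sigma_log)) * drift
        if config.zero_rate > 0:
            series = np.where(rng.random(n) < config.zero_rate, 0.0, series)
        mz, rt = _mzrt()
        cols.append(series)
        meta_rows.append((f"B{i + 1:04d}", mz, rt))

    # internal standards: constant true level, drift + small analytical noise
    for i in range(config.n_is_channels):
        level = rng.uniform(5e4, 2e5)
        series = level * drift * np.exp(rng.normal(0.0, 0.02, size=n))
        mz, rt = _mzrt()
        cols.append(series)
        meta_rows.append((f"IS{i + 1:02d}", mz, rt))

    # spiked targets
    entries: list[SpikeEntry] = []
    for i, item in enumerate(spec):
        profile = generate_profile(
            kind=item["kind"],
            n_times=n,
            exposure=item.get("exposure", 1.0),
            amplitude=item.get("amplitude", _DEFAULT_AMPLITUDE),
            anchor=item.get("anchor"),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        mu = rng.uniform(math.log(1e4), math.log(8e4))
        baseline = np.exp(mu + _ar1(rng, n, config.ar_coefficient, sigma_log))
        spike_sigma = math.sqrt(math.log1p(config.spike_noise_cv**2))
        spike_noise = np.exp(rng.normal(0.0, spike_sigma, size=n))
        series = (baseline + profile.as_array() * spike_noise) * drift
        fid = f"T{i + 1:02d}_{profile.kind}"
        mz, rt = _mzrt()
        cols.append(series)
        meta_rows.append((fid, mz, rt))
        entries.append(
            SpikeEntry(
                feature_id=fid,
                profile=profile,
                concentration=tuple(float(v) for v in profile.as_array()),
            )
        )

    # spiky single-point artifacts: zeros except 1-2 huge detections
    for i in range(config.n_artifact_features):
        series = np.zeros(n)
        n_hits = int(rng.integers(1, 3))
        hits = rng.choice(n, size=n_hits, replace=False)
        series[hits] = rng.uniform(1e6, 1e7, size=n_hits)
        mz, rt = _mzrt()
        cols.append(series)
        meta_rows.append((f"A{i + 1:02d}", mz, rt))

    X = np.column_stack(cols)
    feature_meta = pd.DataFrame(meta_rows, columns=["feature_id", "mz", "rt"])
    is_ids = set(f"IS{i + 1:02d}" for i in range(config.n_is_channels))
    feature_meta["is_internal_standard"] = feature_meta["feature_id"].isin(is_ids)
    sample_meta = pd.DataFrame(
        {"time_index": np.arange(1, n + 1), "label": [f"t{i + 1:03d}" for i in range(n)]}
    )
    table = FeatureTable(X=X, feature_meta=feature_meta, sample_meta=sample_meta)
    registry = SpikeRegistry(entries=entries, dataset_label=label)
    return table, registry


# ----------------------------------------------------------------------
# multi-tool variant emulation
# ----------------------------------------------------------------------


@dataclass
class ToolVariant:
    """One emulated peak-picking-tool output derived from a parent table."""

    tool_id: str
    table: FeatureTable
    #: variant feature_id -> parent feature_id (duplicates/satellites map
    #: to the feature they were derived from; dropped features are absent)
    provenance: dict


_DEFAULT_VARIANT = dict(
    dropout_rate=0.1,
    duplicate_rate=0.05,
    satellite_rate=0.05,
    rescale_sd=0.2,
    missed_rate=0.02,
    mz_jitter_ppm=1.5,
    rt_jitter=0.02,
)


def emulate_tool_variants(
    table: FeatureTable,
    registry: SpikeRegistry,
    variant_params: list[dict],
    seed: int = 0,
) -> list[ToolVariant]:
    """Derive >= 2 tool-like variants of a parent table.

    Each variant applies, with its own parameters: seeded feature
    dropout, duplicate-feature insertion (same profile, m/z and RT
    perturbed within matching tolerance), correlated satellite features
    (isotope/adduct-like, +1.00335 Da), per-feature intensity
    rescaling, and sporadic per-time-point missed detections (set to 0,
    optionally boosted per feature via ``missed_rate_overrides``).
    Registry (ground-truth) features are never fully dropped.
    """
    if len(variant_params) < 2:
        raise ValueError("at least 2 tool variants must be requested")
    rng = np.random.default_rng(seed)
    registry_ids = set(registry.feature_ids)
    variants: list[ToolVariant] = []

    for v_idx, user_params in enumerate(variant_params):
        params = {**_DEFAULT_VARIANT, **user_params}
        if params["dropout_rate"] >= 1.0:
            raise ValueError(
                "dropout rate 1.0 would remove all ground-truth features; "
                "every registry feature must survive in the variant"
            )
        vrng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        n, p = table.X.shape
        keep = vrng.random(p) >= params["dropout_rate"]
        # internal standards are spiked high and always detected
        if "is_internal_standard" in table.feature_meta.columns:
            keep |= table.feature_meta["is_internal_standard"].to_numpy(dtype=bool)
        # guarantee ground truth survives total wipeout per variant
        fids = table.feature_ids
        overrides = params.get("missed_rate_overrides", {}) or {}

        is_flags = (
            table.feature_meta["is_internal_standard"].to_numpy(dtype=bool)
            if "is_internal_standard" in table.feature_meta.columns
            else np.zeros(p, dtype=bool)
        )
        new_cols, new_meta, provenance = [], [], {}
        for j in np.flatnonzero(keep):
            fid = fids[j]
            scale = float(np.exp(vrng.normal(0.0, params["rescale_sd"])))
            series = table.X[:, j] * scale
            rate = 0.0 if is_flags[j] else overrides.get(fid, params["missed_rate"])
            if rate > 0:
                series = np.where(vrng.random(n) < rate, 0.0, series)
            mz = float(
                table.feature_meta["mz"].iloc[j]
                * (1.0 + vrng.normal(0.0, params["mz_jitter_ppm"] / 3.0) * 1e-6)
            )
            rt = float(
                table.feature_meta["rt"].iloc[j]
                + vrng.normal(0.0, params["rt_jitter"] / 3.0)
            )
            new_cols.append(series)
            new_meta.append((fid, mz, rt))
            provenance[fid] = fid

            if vrng.random() < params["duplicate_rate"]:
                dup_id = f"{fid}_dup"
                dmz = mz * (1.0 + vrng.normal(0.0, params["mz_jitter_ppm"] / 3.0) * 1e-6)
                drt = rt + vrng.normal(0.0, params["rt_jitter"] / 3.0)
                dscale = float(np.exp(vrng.normal(0.0, params["rescale_sd"])))
                new_cols.append(series * dscale)
                new_meta.append((dup_id, dmz, drt))
                provenance[dup_id] = fid
            if vrng.random() < params["satellite_rate"]:
                sat_id = f"{fid}_sat"
                frac = vrng.uniform(0.05, 0.35)  # isotope/adduct abundance
                sat = series * frac * np.exp(vrng.normal(0.0, 0.05, size=n))
                new_cols.append(sat)
                new_meta.append((sat_id, mz + 1.00335, rt))
                provenance[sat_id] = fid

        meta = pd.DataFrame(new_meta, columns=["feature_id", "mz", "rt"])
        meta["is_internal_standard"] = meta["feature_id"].isin(
            set(table.feature_meta.loc[
                table.feature_meta.get(
                    "is_internal_standard",
                    pd.Series(False, index=table.feature_meta.index),
                ).astype(bool),
                "feature_id",
            ])
        )
        variant_table = FeatureTable(
            X=np.column_stack(new_cols) if new_cols else np.zeros((n, 0)),
            feature_meta=meta,
            sample_meta=table.sample_meta.copy(),
        )
        surviving = registry_ids & set(variant_table.feature_ids)
        if not surviving:
            raise ValueError(
                f"variant {v_idx} dropped every ground-truth feature; "
                "lower the dropout rate"
            )
        variants.append(
            ToolVariant(tool_id=f"tool{v_idx + 1}", table=variant_table, provenance=provenance)
        )
    return variants


# ----------------------------------------------------------------------
# registry serialization
# ----------------------------------------------------------------------


def write_registry_json(registry: SpikeRegistry, path) -> None:
    payload = {
        "dataset_label": registry.dataset_label,
        "entries": [
            {
                "feature_id": e.feature_id,
                "kind": e.profile.kind,
                "n_times": e.profile.n_times,
                "support": list(e.profile.support),
                "amplitude": e.profile.amplitude,
                "exposure": e.profile.exposure,
                "values": list(e.profile.values),
                "concentration": list(e.concentration),
            }
            for e in registry.entries
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_registry_json(path) -> SpikeRegistry:
    with open(path) as fh:
        payload = json.load(fh)
    entries = [
        SpikeEntry(
            feature_id=item["feature_id"],
            profile=TargetProfile(
                kind=item["kind"],
                n_times=item["n_times"],
                support=tuple(item["support"]),
                amplitude=item["amplitude"],
                values=tuple(item["values"]),
            ),
            concentration=tuple(item["concentration"]),
        )
        for item in payload["entries"]
    ]
    return SpikeRegistry(entries=entries, dataset_label=payload["dataset_label"])
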