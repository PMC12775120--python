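"""Stability selection for sparse PCA via stratified bootstrap (SBS-SPCA).

Rows (time points) are resampled with replacement inside consecutive
temporal strata (default five time points), so each bootstrap replicate
preserves the local temporal structure that spill patterns live on.  For
every penalty configuration on an L1 x L2 grid, sparse PCA is fitted to
each re-autoscaled replicate, replicate components are aligned to a
full-data reference model by greedy maximal-|cosine| matching, and the
per-feature, per-component selection frequency is the fraction of
replicates in which the feature carries a non-zero aligned loading.
Empirical significance comes from a permutation test that destroys
temporal structure by permuting each feature independently across time;
robust markers combine high selection frequency with small permutation
p-values.  A consensus penalty choice and the final fixed-penalty model
round off the workflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .spca import (
    PenaltyConfig,
    SPCAModel,
    fit_spca,
    control_limits,
    outside_limits,
    rank_loadings,
)

__all__ = [
    "DEFAULT_GRID",
    "BootstrapPlan",
    "StabilityResult",
    "build_strata",
    "stratified_resample",
    "run_sbs_grid",
    "permutation_pvalues",
    "select_robust_markers",
    "choose_consensus_penalties",
    "final_model",
]

#: default penalty grid: 4 sparsity levels x 4 ridge values = 16 configs
DEFAULT_GRID = tuple(
    (s, r) for s in (0.6, 0.7, 0.8, 0.9) for r in (0.1, 1.0, 10.0, 100.0)
)


@dataclass
class BootstrapPlan:
    """Settings of one SBS run.

    ``spca_max_iter``/``spca_tol`` govern the per-replicate fits (looser
    than a one-off fit, since thousands of fits are performed); the
    final fixed model is refit at full precision by :func:`final_model`.
    """

    n_reps: int = 500
    stratum_size: int = 5
    n_components: int = 10
    grid: tuple = DEFAULT_GRID
    seed: int = 0
    alignment: str = "aligned"  # 'aligned' (cosine matching) or 'positional'
    max_failure_rate: float = 0.2
    spca_max_iter: int = 75
    spca_tol: float = 1e-3

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.stratum_size < 2:
            raise ValueError("stratum_size must be >= 2")
        if len(self.grid) == 0:
            raise ValueError("grid must be non-empty")
        if self.alignment not in ("aligned", "positional"):
            raise ValueError("alignment must be 'aligned' or 'positional'")

    def config(self, sparsity: float, ridge: float, **overrides) -> PenaltyConfig:
        return PenaltyConfig(
            n_components=self.n_components,
            sparsity=sparsity,
            ridge=ridge,
            max_iter=overrides.get("max_iter", self.spca_max_iter),
            tol=overrides.get("tol", self.spca_tol),
        )


@dataclass
class StabilityResult:
    """Selection frequencies (and optional p-values/flags) over the grid.

    Arrays are indexed ``[config, component, feature]`` with components
    0-based internally (component 1 of the report = index 0).
    """

    configs: list
    freq: np.ndarray
    #: fraction of replicates with a non-zero aligned loading in ANY of
    #: the first (component) reference components -- the "subspace"
    #: selection frequency (index [config, depth-1, feature])
    freq_subspace: np.ndarray
    n_reps: int
    n_reps_effective: np.ndarray
    reference_models: list
    invalid: np.ndarray
    feature_ids: list | None = None
    pvals: np.ndarray | None = None
    robust: np.ndarray | None = None
    alignment: str = "aligned"
    permutation_scheme: str | None = None
    seed: int | None = None

    @property
    def n_components(self) -> int:
        return self.freq.shape[1]

    @property
    def n_features(self) -> int:
        return self.freq.shape[2]

    def config_index(self, config) -> int:
        s, r = config
        for i, (cs, cr) in enumerate(self.configs):
            if np.isclose(cs, s) and np.isclose(cr, r):
                return i
        raise KeyError(f"config {config} not in grid {self.configs}")

    def to_long_frame(self) -> pd.DataFrame:
        """Long-form (feature_id, component, sparsity, ridge, freq[, pval, robust])."""
        n_c, A, p = self.freq.shape
        ids = self.feature_ids or [f"f{i}" for i in range(p)]
        recs = []
        for c, (s, r) in enumerate(self.configs):
            for a in range(A):
                for i in range(p):
                    rec = {
                        "feature_id": ids[i],
                        "component": a + 1,
                        "sparsity": s,
                        "ridge": r,
                        "freq": self.freq[c, a, i],
                    }
                    if self.pvals is not None:
                        rec["pval"] = self.pvals[c, a, i]
                    if self.robust is not None:
                        rec["robust"] = bool(self.robust[c, a, i])
                    recs.append(rec)
        return pd.DataFrame.from_records(recs)

    def to_heatmap_frame(self, config) -> pd.DataFrame:
        """Heatmap-ready pivot for one configuration: features x components."""
        c = self.config_index(config)
        ids = self.feature_ids or [f"f{i}" for i in range(self.n_features)]
        return pd.DataFrame(
            self.freq[c].T,
            index=pd.Index(ids, name="feature_id"),
            columns=[f"PC{a + 1}" for a in range(self.n_components)],
        )

    def metadata(self) -> dict:
        return {
            "n_reps": int(self.n_reps),
            "n_reps_effective": [int(v) for v in self.n_reps_effective],
            "configs": [[float(s), float(r)] for s, r in self.configs],
            "alignment": self.alignment,
            "permutation_scheme": self.permutation_scheme,
            "seed": self.seed,
            "invalid": [bool(v) for v in self.invalid],
        }


# ----------------------------------------------------------------------
# strata and resampling
# ----------------------------------------------------------------------


def build_strata(n_times: int, stratum_size: int = 5) -> list[np.ndarray]:
    """Partition 1..n into consecutive blocks of ``stratum_size``.

    A trailing remainder of >= 2 time points forms its own stratum; a
    remainder of 1 is merged into the last full stratum (a single-point
    stratum would be degenerate for resampling).
    """
    if stratum_size < 2:
        raise ValueError("stratum_size must be >= 2")
    if n_times < stratum_size:
        raise ValueError(f"n_times={n_times} is smaller than stratum_size={stratum_size}")
    edges = list(range(0, n_times + 1, stratum_size))
    if edges[-1] != n_times:
        remainder = n_times - edges[-1]
        if remainder == 1:
            edges[-1] = n_times  # merge the lone point into the last block
        else:
            edges.append(n_times)
    return [np.arange(a, b) for a, b in zip(edges[:-1], edges[1:])]


def stratified_resample(X: np.ndarray, strata: list, seed) -> np.ndarray:
    """Bootstrap rows within each stratum, preserving stratum order."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = _resample_indices(strata, rng)
    return np.asarray(X)[idx]


def _resample_indices(strata: list, rng: np.random.Generator) -> np.ndarray:
    parts = []
    for stratum in strata:
        m = len(stratum)
        if m == 1:
            parts.append(stratum)
        else:
            parts.append(stratum[rng.integers(0, m, size=m)])
    return np.concatenate(parts)


def _autoscale_resample(X: np.ndarray) -> np.ndarray:
    """Autoscale a bootstrap replicate; near-constant columns become 0."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    safe = np.where(sd > 1e-12, sd, 1.0)
    Z = (X - mean) / safe
    Z[:, sd <= 1e-12] = 0.0
    return Z


# ----------------------------------------------------------------------
# alignment
# ----------------------------------------------------------------------


def _greedy_match(ref_B: np.ndarray, rep_B: np.ndarray) -> np.ndarray:
    """Match replicate components to reference components.

    Greedy on |cosine| of unit-norm loading columns; returns ``perm``
    with ``perm[a]`` the replicate column matched to reference
    component ``a``.  The result is a permutation (each replicate
    component used once).
    """
    C = np.abs(ref_B.T @ rep_B)
    A = C.shape[0]
    perm = np.full(A, -1)
    used_ref = np.zeros(A, dtype=bool)
    used_rep = np.zeros(A, dtype=bool)
    order = np.argsort(-C, axis=None)
    for flat in order:
        a, b = divmod(int(flat), A)
        if used_ref[a] or used_rep[b]:
            continue
        perm[a] = b
        used_ref[a] = True
        used_rep[b] = True
        if used_ref.all():
            break
    # any leftovers (all-zero similarity rows): assign arbitrarily
    if (perm < 0).any():
        free = list(np.flatnonzero(~used_rep))
        for a in np.flatnonzero(perm < 0):
            perm[a] = free.pop()
    return perm


# ----------------------------------------------------------------------
# the SBS engine
# ----------------------------------------------------------------------


def _run_sbs(X, plan: BootstrapPlan, configs, rng: np.random.Generator, feature_ids=None):
    """Shared engine: one pass of resampling, fits for every config.

    Resample index draws are shared across configs so every penalty
    setting sees the same bootstrap replicates.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    strata = build_strata(n, plan.stratum_size)
    n_cfg = len(configs)
    A = plan.n_components

    references = []
    for s, r in configs:
        cfg = plan.config(s, r, max_iter=max(plan.spca_max_iter, 200), tol=plan.spca_tol)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            references.append(fit_spca(X, cfg, feature_ids=feature_ids))

    counts = np.zeros((n_cfg, A, p))
    counts_sub = np.zeros((n_cfg, A, p))
    n_eff = np.zeros(n_cfg, dtype=int)
    for _ in range(plan.n_reps):
        idx = _resample_indices(strata, rng)
        Z = _autoscale_resample(X[idx])
        for c, (s, r) in enumerate(configs):
            cfg = plan.config(s, r)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_spca(Z, cfg)
            if not model.converged:
                continue
            n_eff[c] += 1
            if plan.alignment == "aligned":
                perm = _greedy_match(references[c].loadings, model.loadings)
            else:
                perm = np.arange(A)
            member = model.loadings[:, perm] != 0.0  # (p, A), ref order
            counts[c] += member.T
            counts_sub[c] += np.logical_or.accumulate(member, axis=1).T
    freq = np.zeros_like(counts)
    freq_sub = np.zeros_like(counts_sub)
    ok = n_eff > 0
    freq[ok] = counts[ok] / n_eff[ok, None, None]
    freq_sub[ok] = counts_sub[ok] / n_eff[ok, None, None]
    return freq, freq_sub, n_eff, references


def run_sbs_grid(X: np.ndarray, plan: BootstrapPlan, feature_ids=None) -> StabilityResult:
    """Selection frequencies over the full penalty grid.

    For each grid configuration a full-data reference model is fitted;
    each stratified bootstrap replicate is re-autoscaled, fitted, and
    its components aligned to the reference before non-zero membership
    is recorded.  Non-converged replicate fits are dropped
    (``n_reps_effective``); a configuration losing more than
    ``plan.max_failure_rate`` of its replicates is flagged invalid.
    """
    rng = np.random.default_rng(plan.seed)
    freq, freq_sub, n_eff, refs = _run_sbs(
        X, plan, list(plan.grid), rng, feature_ids=feature_ids
    )
    invalid = n_eff < (1.0 - plan.max_failure_rate) * plan.n_reps
    if invalid.any():
        warnings.warn(
            f"{int(invalid.sum())} configuration(s) exceeded the replicate "
            f"failure budget and are flagged invalid"
        )
    return StabilityResult(
        configs=list(plan.grid),
        freq=freq,
        freq_subspace=freq_sub,
        n_reps=plan.n_reps,
        n_reps_effective=n_eff,
        reference_models=refs,
        invalid=invalid,
        feature_ids=list(feature_ids) if feature_ids is not None else None,
        alignment=plan.alignment,
        seed=plan.seed,
    )


def permutation_pvalues(
    X: np.ndarray,
    plan: BootstrapPlan,
    config,
    observed,
    n_perm: int,
    seed: int,
    null_reps: int | None = None,
    statistic: str = "per_component",
) -> np.ndarray:
    """Empirical p-values of observed selection frequencies.

    Null datasets are built by independently permuting every feature's
    values across time (temporal/spill structure destroyed, marginals
    preserved); the SBS selection frequency is recomputed on each and
    the null frequencies are pooled across features and permutations
    into one null distribution per component.  Then

        p(feature, component) = (1 + #{null >= observed}) / (1 + N_null).

    ``observed`` is a StabilityResult (frequencies for ``config`` are
    extracted) or a (components x features) frequency array;
    ``null_reps`` optionally reduces the per-permutation bootstrap
    count (recorded by the caller via run metadata).  ``statistic``
    selects the per-component frequency (default) or the cumulative
    "subspace" frequency (selected in any of the first a components);
    the null uses the matching statistic.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19 to resolve p <= 0.05")
    if statistic not in ("per_component", "subspace"):
        raise ValueError("statistic must be 'per_component' or 'subspace'")
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if isinstance(observed, StabilityResult):
        c = observed.config_index(config)
        obs = (observed.freq if statistic == "per_component" else observed.freq_subspace)[c]
    else:
        obs = np.asarray(observed, dtype=float)
    A = obs.shape[0]
    null_plan = replace(
        plan,
        n_reps=int(null_reps) if null_reps is not None else plan.n_reps,
        n_components=A,
    )
    rng = np.random.default_rng(seed)
    null_pool = np.empty((A, n_perm * p))
    for b in range(n_perm):
        Xp = np.empty_like(X)
        for j in range(p):
            Xp[:, j] = X[rng.permutation(n), j]
        # permuted columns of an autoscaled matrix stay autoscaled
        f, f_sub, _, _ = _run_sbs(Xp, null_plan, [tuple(config)], rng)
        null_pool[:, b * p : (b + 1) * p] = (f if statistic == "per_component" else f_sub)[0]
    N = null_pool.shape[1]
    pvals = np.empty_like(obs)
    for a in range(A):
        srt = np.sort(null_pool[a])
        # #{null >= obs} via searchsorted on the sorted null
        ge = N - np.searchsorted(srt, obs[a], side="left")
        pvals[a] = (1.0 + ge) / (1.0 + N)
    return pvals


def select_robust_markers(
    stability: StabilityResult,
    freq_threshold: float = 0.70,
    p_threshold: float = 0.05,
) -> np.ndarray:
    """Flag robust markers: frequency strictly above threshold AND p below.

    The 0.70 default is the strict reading; 0.50 (or a 0.40-0.60 band
    for narrow/abrupt spills) is supported by passing a different
    threshold.  Stores and returns the [config, component, feature]
    boolean array.
    """
    if stability.pvals is None:
        raise ValueError("stability has no p-values; run permutation_pvalues first")
    robust = (stability.freq > freq_threshold) & (stability.pvals < p_threshold)
    stability.robust = robust
    return robust


def choose_consensus_penalties(
    stability: StabilityResult,
    variance_floor: float = 0.0,
    freq_threshold: float = 0.70,
) -> list:
    """Grid configurations that maximize stable selection.

    Each configuration is scored by the number of (feature, component)
    cells whose selection frequency exceeds ``freq_threshold``, subject
    to its reference model retaining at least ``variance_floor`` percent
    adjusted total variance.  All configurations within 95% of the best
    score are returned, ordered by score (desc), then lower sparsity,
    then ridge nearest 1.
    """
    scores = (stability.freq > freq_threshold).sum(axis=(1, 2))
    var = np.array([m.total_adj_var for m in stability.reference_models])
    eligible = (var >= variance_floor) & ~stability.invalid
    if not eligible.any():
        lines = ", ".join(
            f"(s={s}, r={r}): var={v:.2f}%" for (s, r), v in zip(stability.configs, var)
        )
        raise ValueError(
            f"no configuration retains >= {variance_floor}% adjusted variance; {lines}"
        )
    best = scores[eligible].max()
    cut = 0.95 * best
    chosen = [
        (c, scores[c])
        for c in np.flatnonzero(eligible)
        if scores[c] >= cut
    ]
    chosen.sort(
        key=lambda cs: (
            -cs[1],
            stability.configs[cs[0]][0],
            abs(np.log10(max(stability.configs[cs[0]][1], 1e-12))),
        )
    )
    return [stability.configs[c] for c, _ in chosen]


def final_model(
    X: np.ndarray,
    plan: BootstrapPlan,
    chosen_config,
    feature_ids=None,
    top_k: int = 10,
    alpha: float = 0.01,
) -> tuple[SPCAModel, dict]:
    """Deterministic full-data fit at a chosen grid configuration.

    Refits at full precision (max_iter 500, tol 1e-6), ranks features
    by absolute loading per component, and attaches normal-theory score
    control limits with the flagged time points.
    """
    s, r = chosen_config
    if not any(np.isclose(cs, s) and np.isclose(cr, r) for cs, cr in plan.grid):
        raise ValueError(f"config {chosen_config} is not on the plan grid")
    cfg = plan.config(s, r, max_iter=500, tol=1e-6)
    model = fit_spca(np.asarray(X, dtype=float), cfg, feature_ids=feature_ids)
    report = {"rankings": {}, "control_limits": {}, "flagged_time_points": {}}
    for a in range(1, model.n_components + 1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report["rankings"][a] = rank_loadings(model, a, top_k=top_k)
            limits = control_limits(model.scores[:, a - 1], alpha=alpha)
        report["control_limits"][a] = limits
        flagged = np.flatnonzero(outside_limits(model.scores[:, a - 1], limits)) + 1
        report["flagged_time_points"][a] = [int(t) for t in flagged]
    return model, report
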