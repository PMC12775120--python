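"""Elastic-net sparse PCA in the regression (alternating) formulation.

Sparse components are obtained by alternating two steps: for a fixed
orthonormal helper matrix ``A_orth`` each loading column solves an
elastic-net regression of the projected data onto the data with ridge
penalty ``ridge`` and the L1 level chosen (by bisection on the penalty,
with a truncation fallback) so the column has exactly ``k`` non-zero
entries; for fixed loadings ``B`` the helper is refreshed from the
singular value decomposition of ``(X'X) B``.  Sparsity is specified as
the targeted fraction of zero loadings per component, mapped to the
per-component cardinality ``k = max(1, round((1 - sparsity) * p))``.

Also provides classical PCA, the QR-based adjusted explained variance
(which discounts variance shared among correlated sparse components),
normal-theory score control limits, and loading-magnitude feature
ranking.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "PenaltyConfig",
    "SPCAModel",
    "fit_pca",
    "fit_spca",
    "adjusted_variance",
    "control_limits",
    "outside_limits",
    "rank_loadings",
    "save_model",
]


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class PenaltyConfig:
    """Penalty/iteration settings of one sparse PCA fit.

    sparsity is the targeted fraction of zero loadings per component
    (0 fits dense components); ridge the quadratic penalty stabilizing
    correlated features.
    """

    n_components: int = 10
    sparsity: float = 0.0
    ridge: float = 0.0
    max_iter: int = 500
    tol: float = 1e-6

    def __post_init__(self):
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if not (0 <= self.sparsity < 1):
            raise ValueError("sparsity must be in [0, 1)")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")

    def cardinality(self, p: int) -> int:
        """Non-zero loadings targeted per component for p features."""
        k = max(1, _round_half_away((1.0 - self.sparsity) * p))
        return min(k, p)


@dataclass
class SPCAModel:
    """Fitted (sparse) PCA model.

    loadings: (p, A) unit-norm columns with at most k non-zeros each;
    scores: X @ loadings; adj_var: per-component adjusted explained
    variance in percent of total variance.
    """

    loadings: np.ndarray
    scores: np.ndarray
    A_orth: np.ndarray
    adj_var: np.ndarray
    config: PenaltyConfig
    converged: bool
    n_iter: int
    degenerate: np.ndarray  # per-component all-zero flag
    feature_ids: list | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def nonzero_mask(self) -> np.ndarray:
        """(p, A) boolean mask of non-zero loadings."""
        return self.loadings != 0.0

    @property
    def total_adj_var(self) -> float:
        return float(self.adj_var.sum())


# ----------------------------------------------------------------------
# numba elastic-net kernel (Gram formulation)
# ----------------------------------------------------------------------


@njit(cache=True)
def _cd_enet(G, gy, lam, lam1, b, max_sweeps, tol):
    """Coordinate descent for 0.5 b'Gb - gy'b + 0.5 lam |b|^2 + lam1 |b|_1.

    (Equivalently the elastic-net regression of X a onto X with Gram
    G = X'X and gy = X'X a.)  Updates b in place; returns sweeps used.
    """
    p = gy.shape[0]
    q = np.dot(G, b)
    for sweep in range(max_sweeps):
        delta_max = 0.0
        for i in range(p):
            gii = G[i, i]
            if gii <= 0.0:
                b[i] = 0.0
                continue
            bi = b[i]
            r = gy[i] - (q[i] - gii * bi)
            if r > lam1:
                nb = (r - lam1) / (gii + lam)
            elif r < -lam1:
                nb = (r + lam1) / (gii + lam)
            else:
                nb = 0.0
            d = nb - bi
            if d != 0.0:
                b[i] = nb
                for t in range(p):
                    q[t] += d * G[t, i]
                ad = abs(d)
                if ad > delta_max:
                    delta_max = ad
        if delta_max < tol:
            return sweep + 1
    return max_sweeps


def _ridge_on_support(G, gy, lam, support):
    Gs = G[np.ix_(support, support)] + lam * np.eye(len(support))
    try:
        bs = np.linalg.solve(Gs, gy[support])
    except np.linalg.LinAlgError:
        bs = np.linalg.lstsq(Gs, gy[support], rcond=None)[0]
    b = np.zeros(G.shape[0])
    b[support] = bs
    return b


def _enet_cardinality(
    G, gy, lam, k, b_warm=None, lam1_hint=None, n_bisect=60, max_sweeps=60
):
    """Loading column with exactly k non-zeros via the elastic net.

    The support is found by bisecting the L1 penalty of the elastic-net
    subproblem until its solution has cardinality k (if the count jumps
    past k because of ties on the path, the sparsest solution with
    >= k non-zeros is truncated to its top-k magnitudes).  The returned
    coefficients are the ridge solution restricted to that support, so
    the column is a deterministic function of the support and the
    alternating iteration has a well-defined fixed point.

    Returns ``(b, lam1, b_en)`` where lam1 is the penalty that produced
    the support (a warm hint for the next call) and b_en the shrunk
    elastic-net iterate (warm start for the next call's CD solves).
    """
    p = gy.shape[0]
    if k >= p:
        return _ridge_on_support(G, gy, lam, np.arange(p)), None, None
    hi0 = float(np.max(np.abs(gy)))
    if hi0 == 0.0:
        return np.zeros(p), None, None
    scale = hi0 / max(np.max(np.diag(G)), 1e-300)
    cd_tol = 1e-8 * max(scale, 1e-30)
    b = np.zeros(p) if b_warm is None else b_warm.astype(float).copy()

    lo, hi = 0.0, hi0
    exact = None  # (support, lam1)
    best_over = None  # sparsest solution seen with count > k
    best_over_count = p + 1

    def _probe(lam1, vec):
        _cd_enet(G, gy, lam, lam1, vec, max_sweeps, cd_tol)
        return int(np.count_nonzero(vec))

    if lam1_hint is not None and 0.0 < lam1_hint < hi0:
        c = _probe(float(lam1_hint), b)
        if c == k:
            exact = (np.flatnonzero(b), float(lam1_hint))
        elif c > k:
            lo = float(lam1_hint)
            best_over, best_over_count = b.copy(), c
        else:
            hi = float(lam1_hint)
    if exact is None:
        for _ in range(n_bisect):
            mid = 0.5 * (lo + hi)
            c = _probe(mid, b)
            if c == k:
                exact = (np.flatnonzero(b), mid)
                break
            if c > k:
                lo = mid
                if c < best_over_count:
                    best_over, best_over_count = b.copy(), c
            else:
                hi = mid
                if best_over is not None:
                    b = best_over.copy()  # re-warm from the denser side
        else:
            if best_over is None:
                # even lam1 -> 0 is sparser than k (ridge zeros): pad support
                _probe(0.0, b)
                exact = (np.sort(np.argsort(-np.abs(b))[:k]), 0.0)
            else:
                exact = (
                    np.sort(np.argsort(-np.abs(best_over))[:k]),
                    lo,
                )
    support, lam1 = exact
    return _ridge_on_support(G, gy, lam, np.sort(support)), lam1, b


# ----------------------------------------------------------------------
# model fitting
# ----------------------------------------------------------------------


def _fix_signs(B: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    B = B.copy()
    for j in range(B.shape[1]):
        col = B[:, j]
        if np.any(col != 0):
            i = int(np.argmax(np.abs(col)))
            if col[i] < 0:
                B[:, j] = -col
    return B


def _check_shape(X: np.ndarray, A: int) -> None:
    n, p = X.shape
    if A > min(n - 1, p):
        raise ValueError(
            f"n_components={A} exceeds min(n-1, p) = {min(n - 1, p)} for a {n}x{p} matrix"
        )


def fit_pca(X: np.ndarray, n_components: int, feature_ids=None) -> SPCAModel:
    """Classical PCA via SVD, packaged like a sparse model.

    Loadings are the top right singular vectors (sign fixed so the
    largest-magnitude entry of each column is positive); adj_var equals
    the classical explained-variance percentages.
    """
    X = np.asarray(X, dtype=float)
    _check_shape(X, n_components)
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    B = _fix_signs(Vt[:n_components].T)
    total = float(np.sum(s**2))
    adj = 100.0 * s[:n_components] ** 2 / total if total > 0 else np.zeros(n_components)
    cfg = PenaltyConfig(n_components=n_components, sparsity=0.0, ridge=0.0)
    return SPCAModel(
        loadings=B,
        scores=X @ B,
        A_orth=B.copy(),
        adj_var=adj,
        config=cfg,
        converged=True,
        n_iter=1,
        degenerate=np.zeros(n_components, dtype=bool),
        feature_ids=list(feature_ids) if feature_ids is not None else None,
    )


def fit_spca(X: np.ndarray, config: PenaltyConfig, feature_ids=None) -> SPCAModel:
    """Fit elastic-net sparse PCA with per-component cardinality control.

    X is expected autoscaled (each feature mean 0, unit sd).  Returns a
    model with unit-norm loading columns of at most ``k`` non-zeros; a
    model that fails to converge within ``config.max_iter`` is returned
    with ``converged=False`` and a warning.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    A = config.n_components
    _check_shape(X, A)
    k = config.cardinality(p)
    lam = float(config.ridge)

    G = X.T @ X
    # initialize the orthonormal helper with PCA loadings
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    A_orth = Vt[:A].T.copy()
    total = float(np.sum(s**2))

    B = A_orth.copy()
    B_prev = None
    lam1_hints = [None] * A
    en_warm = [None] * A  # shrunk elastic-net iterates, one per component
    converged = False
    n_iter = 0
    # near-tied features can make the k-support cycle indefinitely; past
    # this point each component's support is frozen at its current set
    # and the fixed-support ridge iteration is run to convergence
    freeze_at = max(10, int(0.4 * config.max_iter))
    frozen_supports = None
    for it in range(1, config.max_iter + 1):
        n_iter = it
        if frozen_supports is None and it > freeze_at:
            frozen_supports = [np.flatnonzero(B[:, j]) for j in range(A)]
        GY = G @ A_orth  # (p, A): per-component regression targets
        for j in range(A):
            if frozen_supports is not None:
                supp = frozen_supports[j]
                B[:, j] = (
                    _ridge_on_support(G, GY[:, j], lam, supp)
                    if supp.size
                    else 0.0
                )
                continue
            B[:, j], lam1_hints[j], en_warm[j] = _enet_cardinality(
                G,
                GY[:, j],
                lam,
                k,
                b_warm=en_warm[j] if en_warm[j] is not None else B[:, j],
                lam1_hint=lam1_hints[j],
            )
        # normalize for the convergence check (scale is arbitrary)
        Bn = B.copy()
        norms = np.linalg.norm(Bn, axis=0)
        nz = norms > 0
        Bn[:, nz] /= norms[nz]
        if B_prev is not None:
            # align signs before differencing: sign is not identified
            flip = np.sign(np.sum(Bn * B_prev, axis=0))
            flip[flip == 0] = 1.0
            if np.max(np.abs(Bn * flip - B_prev)) < config.tol:
                B_prev = Bn
                converged = True
                break
        B_prev = Bn
        # helper update: orthogonal polar factor of (X'X) B
        M = G @ Bn
        U, _, Vt2 = np.linalg.svd(M, full_matrices=False)
        A_orth = U @ Vt2

    if not converged:
        warnings.warn(
            f"sparse PCA did not converge in {config.max_iter} iterations "
            f"(tol={config.tol})"
        )
    B = _fix_signs(B_prev if B_prev is not None else B)
    degenerate = ~np.any(B != 0, axis=0)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} all-zero (degenerate) component(s)")
    adj = adjusted_variance(X, B, total_ss=total)
    return SPCAModel(
        loadings=B,
        scores=X @ B,
        A_orth=A_orth,
        adj_var=adj,
        config=config,
        converged=converged,
        n_iter=n_iter,
        degenerate=degenerate,
        feature_ids=list(feature_ids) if feature_ids is not None else None,
    )


def adjusted_variance(X: np.ndarray, B: np.ndarray, total_ss: float | None = None) -> np.ndarray:
    """Adjusted explained variance (percent) of components B on X.

    QR-factorizes the scores ``T = X B`` and credits component ``a``
    with ``R[a, a]^2 / trace(X'X) * 100``, so variance shared among
    correlated sparse components is counted once (for orthogonal PCA
    loadings this reduces to the classical percentages).  Components
    made redundant by earlier ones receive 0 with a warning.
    """
    X = np.asarray(X, dtype=float)
    B = np.asarray(B, dtype=float)
    T = X @ B
    if total_ss is None:
        total_ss = float(np.sum(X * X))
    if total_ss <= 0:
        raise ValueError("X has zero total variance")
    R = np.linalg.qr(T, mode="r")
    d = np.abs(np.diag(R))
    adj = 100.0 * d**2 / total_ss
    tiny = d**2 < 1e-12 * total_ss
    if tiny.any() and not np.all(B[:, tiny] == 0):
        warnings.warn(
            "rank-deficient score matrix: redundant component(s) credited 0 variance"
        )
        adj[tiny] = 0.0
    return adj


def control_limits(scores_column: np.ndarray, alpha: float = 0.01) -> tuple[float, float]:
    """Normal-theory control limits (mean +/- z_{1-alpha/2} sd) of a score series."""
    from scipy.stats import norm

    s = np.asarray(scores_column, dtype=float)
    if s.size < 10:
        raise ValueError("need >= 10 score values for control limits")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    sd = s.std(ddof=1)
    if sd == 0:
        warnings.warn("zero-variance scores: control limits collapse to the mean")
    z = norm.ppf(1.0 - alpha / 2.0)
    mu = s.mean()
    return float(mu - z * sd), float(mu + z * sd)


def outside_limits(scores_column: np.ndarray, limits: tuple[float, float]) -> np.ndarray:
    """Boolean mask of time points outside (lower, upper)."""
    s = np.asarray(scores_column, dtype=float)
    lo, hi = limits
    return (s < lo) | (s > hi)


def rank_loadings(model: SPCAModel, component: int, top_k: int = 10) -> pd.DataFrame:
    """Top features of one component by absolute loading.

    ``component`` is 1-based (PC1 = 1).  Only non-zero loadings are
    ranked; ties in |loading| break by feature id ascending.  Returns a
    frame with columns feature_id, loading, rank.
    """
    if not (1 <= component <= model.n_components):
        raise ValueError(
            f"component must be in 1..{model.n_components}, got {component}"
        )
    col = model.loadings[:, component - 1]
    nz = np.flatnonzero(col != 0)
    if nz.size == 0:
        warnings.warn(f"component {component} has no non-zero loadings")
        return pd.DataFrame(columns=["feature_id", "loading", "rank"])
    ids = (
        [model.feature_ids[i] for i in nz]
        if model.feature_ids is not None
        else [f"f{i}" for i in nz]
    )
    df = pd.DataFrame(
        {"feature_id": ids, "loading": col[nz], "_absload": np.abs(col[nz])}
    )
    df = df.sort_values(["_absload", "feature_id"], ascending=[False, True])
    df = df.drop(columns="_absload").head(top_k).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def save_model(model: SPCAModel, out_dir, stem: str = "spca") -> None:
    """Serialize a model: long-form loadings CSV, scores CSV, JSON sidecar."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p, A = model.loadings.shape
    ids = model.feature_ids if model.feature_ids is not None else [f"f{i}" for i in range(p)]
    rows = [
        (ids[i], a + 1, model.loadings[i, a])
        for a in range(A)
        for i in range(p)
        if model.loadings[i, a] != 0.0
    ]
    pd.DataFrame(rows, columns=["feature_id", "component", "loading"]).to_csv(
        out / f"{stem}_loadings.csv", index=False
    )
    n = model.scores.shape[0]
    srows = [(t + 1, a + 1, model.scores[t, a]) for a in range(A) for t in range(n)]
    pd.DataFrame(srows, columns=["sample", "component", "score"]).to_csv(
        out / f"{stem}_scores.csv", index=False
    )
    sidecar = {
        "config": {
            "n_components": model.config.n_components,
            "sparsity": model.config.sparsity,
            "ridge": model.config.ridge,
            "max_iter": model.config.max_iter,
            "tol": model.config.tol,
        },
        "adj_var_percent": [float(v) for v in model.adj_var],
        "converged": bool(model.converged),
        "n_iter": int(model.n_iter),
        "degenerate": [bool(v) for v in model.degenerate],
    }
    with open(out / f"{stem}_model.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
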