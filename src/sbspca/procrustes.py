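"""Procrustes superimposition of matched feature-table matrices.

Quantifies the concordance of one table-derived matrix with a reference
(e.g., the same matched targets exported by two peak-picking tools) by
the optimal translation + rotation/reflection + scaling of the
comparison onto the reference.  The dissimilarity

    d = ||ref_c - s * cmp_c * R||^2_F / ||ref_c||^2_F

(residual over total sum of squares of the column-centred reference) is
0 for an exact similarity transform and bounded by 1 when scaling is
enabled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["ProcrustesResult", "procrustes_align"]


@dataclass
class ProcrustesResult:
    """Optimal similarity transform and normalized dissimilarity."""

    d: float
    rotation: np.ndarray  # orthogonal (reflection permitted)
    scale: float
    translation: np.ndarray  # row vector added to the scaled/rotated comparison
    aligned: np.ndarray  # transformed comparison, same frame as the reference

    def to_json(self) -> str:
        return json.dumps(
            {
                "d": self.d,
                "scale": self.scale,
                "rotation": self.rotation.tolist(),
                "translation": self.translation.tolist(),
            },
            indent=1,
        )


def procrustes_align(
    reference: np.ndarray,
    comparison: np.ndarray,
    scaling: bool = True,
    center: bool = True,
) -> ProcrustesResult:
    """Align ``comparison`` onto ``reference`` by Procrustes superimposition.

    Both matrices must share shape (samples x matched targets); columns
    must be matched beforehand (see
    :func:`sbspca.prioritize.match_features_across_tools`).  The optimal
    rotation comes from the SVD of the cross-product of the centred
    matrices; reflection is permitted.
    """
    X = np.asarray(reference, dtype=float)
    Y = np.asarray(comparison, dtype=float)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: reference {X.shape} vs comparison {Y.shape}")
    mu_x = X.mean(axis=0) if center else np.zeros(X.shape[1])
    mu_y = Y.mean(axis=0) if center else np.zeros(Y.shape[1])
    Xc = X - mu_x
    Yc = Y - mu_y
    ssx = float(np.sum(Xc * Xc))
    ssy = float(np.sum(Yc * Yc))
    if ssx <= 0:
        raise ValueError("reference matrix has rank 0 after centring")
    if ssy <= 0:
        raise ValueError("comparison matrix has rank 0 after centring")
    U, sv, Vt = np.linalg.svd(Yc.T @ Xc)
    R = U @ Vt  # maps comparison frame onto reference frame
    trace = float(np.sum(sv))
    scale = trace / ssy if scaling else 1.0
    aligned = scale * (Yc @ R) + mu_x
    resid = float(np.sum((Xc - scale * (Yc @ R)) ** 2))
    d = resid / ssx
    return ProcrustesResult(
        d=d,
        rotation=R,
        scale=float(scale),
        translation=mu_x - scale * (mu_y @ R),
        aligned=aligned,
    )
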