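"""Clustering of length-normalized paths into movement phenotypes.

Paths are resampled to a fixed number of points equally spaced in cumulative
arc length (dropping time), concatenated into coordinate vectors, and
clustered by agglomerative (Ward) clustering.  The number of clusters comes
from the largest relative jump in dendrogram merge heights, floored at two.
Cluster labels are deterministically ordered so that label 1 is the cluster
with the smallest mean absolute maximum deviation — the "more direct path"
type — which fixes the sign convention of the downstream logistic models.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .dynamics import signed_deviations


def length_normalize(samples: np.ndarray, P: int = 100) -> np.ndarray:
    """Resample a path to P points equally spaced in arc length.

    ``samples`` is (n, >=3) with columns (t, x, y) or a bare (n, 2) xy
    array; returns a (P, 2) xy array.  Timing is discarded.
    """
    xy = samples[:, 1:3] if samples.shape[1] >= 3 else samples
    if len(xy) < 2:
        raise ValueError("need at least 2 samples")
    step = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(step)])
    total = arc[-1]
    if total == 0:
        raise ValueError("zero-length path")
    # drop duplicate arc positions for interpolation
    keep = np.concatenate([[True], np.diff(arc) > 0])
    arc_u, xy_u = arc[keep], xy[keep]
    s = np.linspace(0.0, total, P)
    out = np.column_stack(
        [np.interp(s, arc_u, xy_u[:, 0]), np.interp(s, arc_u, xy_u[:, 1])]
    )
    return out


def cluster_paths(
    normalized: np.ndarray, k_min: int = 2, k_max: int = 10, seed: int = 0
) -> tuple[np.ndarray, int, dict]:
    """Ward clustering of an (n_paths, P, 2) or (n_paths, 2P) array.

    Returns (labels, k, diagnostics).  Labels are 1-based; label 1 is the
    most direct cluster (smallest mean |MAD|).  Deterministic given inputs;
    ``seed`` is accepted for interface stability only.
    """
    X = np.asarray(normalized, float)
    if X.ndim == 3:
        flat = X.reshape(len(X), -1)
    else:
        flat = X
        X = flat.reshape(len(flat), -1, 2)
    n = len(flat)
    if n < k_min:
        raise ValueError(f"need at least k_min={k_min} paths, got {n}")
    Z = linkage(flat, method="ward")
    heights = Z[:, 2]
    degenerate = bool(np.all(heights <= 1e-12))
    if degenerate:
        warnings.warn("all paths identical: degenerate split at k_min", RuntimeWarning)
        return np.ones(n, dtype=int), k_min, {"degenerate": True, "heights": heights}
    k_hi = min(k_max, n - 1)
    best_k, best_gap = k_min, -np.inf
    gaps = {}
    for k in range(k_min, k_hi + 1):
        denom = heights[n - k - 1] if n - k - 1 >= 0 else np.nan
        if not np.isfinite(denom) or denom <= 0:
            continue
        gap = heights[n - k] / denom
        gaps[k] = float(gap)
        if gap > best_gap:
            best_k, best_gap = k, gap
    labels = fcluster(Z, t=best_k, criterion="maxclust")
    labels = _order_by_directness(labels, X)
    diag = {"degenerate": False, "relative_gaps": gaps, "chosen_k": best_k}
    return labels, best_k, diag


def _order_by_directness(labels: np.ndarray, paths: np.ndarray) -> np.ndarray:
    """Relabel clusters so label 1 has the smallest mean |MAD|."""
    mads = np.array(
        [
            np.max(np.abs(signed_deviations(np.column_stack([np.arange(len(p)), p]))))
            for p in paths
        ]
    )
    uniq = np.unique(labels)
    means = {c: mads[labels == c].mean() for c in uniq}
    order = sorted(uniq, key=lambda c: means[c])
    remap = {old: new + 1 for new, old in enumerate(order)}
    return np.array([remap[c] for c in labels])


def cluster_aligned_paths(
    aligned: pd.DataFrame, phase: str, P: int = 100, k_min: int = 2, seed: int = 0
) -> tuple[pd.DataFrame, int, dict]:
    """Normalize and cluster one phase's aligned paths from the long table.

    Returns a labels table (participant, trial, phase, cluster), the chosen
    k and linkage diagnostics.
    """
    keys, mats = [], []
    for (participant, trial), g in aligned[aligned["phase"] == phase].groupby(
        ["participant", "trial"], sort=True
    ):
        g = g.sort_values("t_ms")
        samples = g[["t_ms", "x", "y"]].to_numpy(float)
        if len(samples) < 2:
            continue
        mats.append(length_normalize(samples, P))
        keys.append((participant, trial))
    stack = np.stack(mats)
    labels, k, diag = cluster_paths(stack, k_min=k_min, seed=seed)
    out = pd.DataFrame(keys, columns=["participant", "trial"])
    out["phase"] = phase
    out["cluster"] = labels
    return out, k, diag
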