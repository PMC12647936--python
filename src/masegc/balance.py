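"""Hybrid resampling: SMOTE oversampling of the minority class followed by
Tomek-link removal.

SMOTE interpolates new minority points on segments between a minority sample
and one of its k nearest minority neighbours; Tomek links (mutual nearest
neighbours of opposite class) mark ambiguous boundary samples that are then
removed. Applied inside training folds by default — balancing before the
train/test split leaks synthetic copies of test-adjacent samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .errors import ResamplingError

__all__ = ["ResampledDataset", "smote_oversample", "find_tomek_links", "smote_tomek"]


@dataclass
class ResampledDataset:
    """Resampling output with per-sample provenance.

    ``provenance`` is ``"original"`` or ``"synthetic"`` per retained row;
    ``removed`` lists (index-into-augmented-set, reason) pairs.
    """

    X: np.ndarray
    y: np.ndarray
    provenance: list[str]
    removed: list[tuple[int, str]] = field(default_factory=list)
    #: index of each retained row in the SMOTE-augmented set (originals first)
    kept_indices: np.ndarray | None = None

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.y, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def _minority_majority(y: np.ndarray) -> tuple[int, int]:
    vals, counts = np.unique(y, return_counts=True)
    if len(vals) != 2:
        raise ResamplingError("resampling requires exactly two classes")
    order = np.argsort(counts, kind="stable")
    return int(vals[order[0]]), int(vals[order[1]])


def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    target_ratio: float = 1.0,
    seed: int = 0,
) -> ResampledDataset:
    """Add interpolated minority samples until minority/majority = target_ratio.

    Each synthetic point is ``x + u * (x_nn - x)`` for a minority sample x, a
    uniformly chosen one of its k nearest minority neighbours x_nn, and
    u ~ Uniform(0,1). Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ResamplingError("X must be (n_samples, n_features) matching y")
    minority, majority = _minority_majority(y)
    n_min = int((y == minority).sum())
    n_maj = int((y == majority).sum())
    if n_min < 2:
        raise ResamplingError("minority class needs at least 2 samples")
    if k >= n_min:
        raise ResamplingError(f"k={k} must be smaller than the minority class size {n_min}")

    n_target = int(round(target_ratio * n_maj))
    n_new = n_target - n_min
    provenance = ["original"] * len(y)
    if n_new <= 0:
        import warnings

        warnings.warn("target ratio already met; no synthetic samples added", stacklevel=2)
        return ResampledDataset(X.copy(), y.copy(), provenance)

    rng = np.random.default_rng(seed)
    X_min = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    # column 0 is the point itself (distance 0 ties resolved by index in sklearn)
    neigh = nn.kneighbors(X_min, return_distance=False)[:, 1:]

    base_idx = rng.integers(0, n_min, size=n_new)
    neigh_choice = rng.integers(0, k, size=n_new)
    u = rng.random(size=n_new)
    x = X_min[base_idx]
    x_nn = X_min[neigh[base_idx, neigh_choice]]
    synthetic = x + u[:, None] * (x_nn - x)

    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=int)])
    provenance += ["synthetic"] * n_new
    return ResampledDataset(X_out, y_out, provenance)


def find_tomek_links(X: np.ndarray, y: np.ndarray) -> list[tuple[int, int]]:
    """Return all pairs (a, b), a < b, of opposite class that are mutual
    single nearest neighbours (Euclidean).

    Distance ties are broken by the lowest sample index, so duplicated
    coordinates never raise.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) != 2:
        raise ResamplingError("Tomek links require both classes present")
    n = X.shape[0]
    # pairwise distances; argmin with index tie-break over the masked diagonal
    from scipy.spatial.distance import cdist

    d2 = cdist(X, X, metric="sqeuclidean")
    np.fill_diagonal(d2, np.inf)
    nn = d2.argmin(axis=1)  # argmin returns the lowest index on ties
    links = []
    for a in range(n):
        b = int(nn[a])
        if a < b and nn[b] == a and y[a] != y[b]:
            links.append((a, b))
    return links


def smote_tomek(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    target_ratio: float = 1.0,
    seed: int = 0,
    removal_policy: Literal["both", "majority_only"] = "both",
) -> ResampledDataset:
    """SMOTE, then remove Tomek links from the augmented set.

    With ``removal_policy="both"`` each link's two members are removed
    (boundary cleaning); ``"majority_only"`` removes only the majority-class
    member. Removal is iterated until no link remains, so re-running
    :func:`find_tomek_links` on the output always returns an empty list.
    """
    if removal_policy not in ("both", "majority_only"):
        raise ResamplingError(f"unknown removal_policy {removal_policy!r}")
    res = smote_oversample(X, y, k=k, target_ratio=target_ratio, seed=seed)
    _, majority = _minority_majority(y)

    keep = np.ones(len(res.y), dtype=bool)
    removed: list[tuple[int, str]] = []
    while True:
        idx = np.flatnonzero(keep)
        links = find_tomek_links(res.X[idx], res.y[idx])
        if not links:
            break
        for a, b in links:
            for local in (a, b):
                gidx = int(idx[local])
                if removal_policy == "majority_only" and res.y[gidx] != majority:
                    continue
                if keep[gidx]:
                    keep[gidx] = False
                    removed.append((gidx, "tomek"))
        if removal_policy == "majority_only":
            # a minority member may keep its link partner alive; removing the
            # majority member always breaks the mutual-NN pair, so we re-check
            pass
        if keep.sum() < 2 or len(np.unique(res.y[keep])) < 2:
            break
    return ResampledDataset(
        res.X[keep],
        res.y[keep],
        [p for p, k_ in zip(res.provenance, keep) if k_],
        removed,
        np.flatnonzero(keep),
    )
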