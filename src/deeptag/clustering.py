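"""Expression-pattern clustering over the four experimental groups.

Normalized expression is averaged per group, each gene's 4-point profile is
standardized to mean 0 / variance 1, and the profiles are partitioned by
k-means with correlation distance (1 - Pearson r), centroids being
re-standardized after every update so the distance stays well defined.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from deeptag.containers import GROUP_ORDER, group_labels

logger = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    """Gene -> cluster label (1..k), with re-standardized centroids.

    Labels are renumbered in decreasing cluster size for stable reporting.
    """

    labels: pd.Series
    centroids: pd.DataFrame  # k x 4, standardized
    total_within: float
    k: int
    seed: int | None


def _standardize_rows(x: np.ndarray, ddof: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale rows to unit variance; returns (rows, sd)."""
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (x - mean) / sd
    return out, sd[:, 0]


def standardize_patterns(
    normalized_expr: pd.DataFrame, samples: pd.DataFrame, genes: list[str] | None = None
) -> pd.DataFrame:
    """Standardized per-group mean profiles (columns in canonical group order).

    ``normalized_expr`` holds normalized (log-CPM) expression, genes x
    samples.  Genes whose four group means are constant cannot be
    standardized and are dropped with a warning.
    """
    groups = group_labels(samples)
    missing_groups = set(GROUP_ORDER) - set(groups)
    if missing_groups:
        raise ValueError(f"sample sheet lacks groups: {sorted(missing_groups)}")
    expr = normalized_expr if genes is None else normalized_expr.loc[genes]
    means = pd.DataFrame(
        {g: expr.loc[:, groups.index[groups == g]].mean(axis=1) for g in GROUP_ORDER}
    )
    std, sd = _standardize_rows(means.to_numpy(dtype=float))
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} gene(s) with constant group means dropped", stacklevel=2
        )
    return pd.DataFrame(std[~constant], index=means.index[~constant], columns=GROUP_ORDER)


def correlation_distance(x: np.ndarray, c: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between every row of x and every row of c."""
    xs, xsd = _standardize_rows(x, ddof=0)
    cs, csd = _standardize_rows(c, ddof=0)
    m = x.shape[1]
    r = (xs @ cs.T) / m
    return 1.0 - r


def _plusplus_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ style seeding under correlation distance."""
    n = x.shape[0]
    centers = [int(rng.integers(n))]
    d = correlation_distance(x, x[centers])[:, 0]
    for _ in range(1, k):
        weights = np.maximum(d, 0.0) ** 2
        total = weights.sum()
        if total <= 0:
            idx = int(rng.integers(n))
        else:
            idx = int(rng.choice(n, p=weights / total))
        centers.append(idx)
        d = np.minimum(d, correlation_distance(x, x[[idx]])[:, 0])
    return x[centers].copy()


def _lloyd(
    x: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, float]:
    centroids, _ = _standardize_rows(_plusplus_init(x, k, rng))
    labels = np.full(x.shape[0], -1)
    for _ in range(max_iter):
        d = correlation_distance(x, centroids)
        new_labels = d.argmin(axis=1)
        if (new_labels == labels).all():
            break
        labels = new_labels
        for j in range(k):
            members = x[labels == j]
            if len(members) == 0:
                # re-seed an empty cluster from the point farthest from its centroid
                far = int(d[np.arange(len(labels)), labels].argmax())
                centroids[j] = x[far]
                labels[far] = j
                continue
            centroids[j] = members.mean(axis=0)
        centroids, sd = _standardize_rows(centroids)
        for j in np.flatnonzero(sd == 0):  # degenerate centroid: re-seed
            far = int(correlation_distance(x, centroids[[0]]).argmax())
            centroids[j] = x[far]
    d = correlation_distance(x, centroids)
    labels = d.argmin(axis=1)
    total = float(d[np.arange(len(labels)), labels].sum())
    return labels, centroids, total


def kmeans_patterns(
    patterns: pd.DataFrame,
    k: int = 4,
    distance: str = "correlation",
    restarts: int = 50,
    seed: int | None = 0,
) -> ClusterAssignment:
    """Correlation-distance k-means over standardized pattern profiles.

    The best of ``restarts`` k-means++ initializations (by total
    within-cluster distance) is kept; results are deterministic given
    ``seed``.  Output labels are 1..k in decreasing cluster size.
    """
    if distance != "correlation":
        raise ValueError("only correlation distance is supported")
    x = patterns.to_numpy(dtype=float)
    if len(x) < k:
        raise ValueError(f"cannot form {k} clusters from {len(x)} genes")
    root = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for child in root.spawn(restarts):
        labels, centroids, total = _lloyd(x, k, child)
        if best is None or total < best[2]:
            best = (labels, centroids, total)
    labels, centroids, total = best
    # relabel in decreasing cluster size (stable on ties)
    sizes = np.bincount(labels, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    remap = {int(old): new + 1 for new, old in enumerate(order)}
    final = pd.Series([remap[int(l)] for l in labels], index=patterns.index, name="cluster")
    centroid_df = pd.DataFrame(
        centroids[order], index=pd.RangeIndex(1, k + 1, name="cluster"), columns=patterns.columns
    )
    return ClusterAssignment(final, centroid_df, total, k, seed)
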