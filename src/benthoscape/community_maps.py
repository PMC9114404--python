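"""Community-level maps from the stacked probability surfaces.

Richness at a cell is the number of morphotypes whose predicted
probability of occurrence exceeds 0.5 (strictly).  Assemblage maps are
k-means partitions of cells by their probability vectors alone; habitat
maps additionally concatenate (z-scored) environmental variables, in the
sense of a biotope.  The number of clusters is chosen by a k-means
cascade scored with the Calinski-Harabasz criterion, the ratio of
between- to within-cluster dispersion normalised by degrees of freedom:

    CH(k) = [B / (k - 1)] / [W / (n - k)]

with B the between-group and W the within-group sum of squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .grids import Grid, GridStack, mask_by_depth, resample
from .sdm import ProbabilityStack
from .stratify import LabelMap


def richness_map(stack: ProbabilityStack | GridStack, threshold: float = 0.5) -> Grid:
    """Per-cell count of morphotypes with probability strictly above threshold."""
    grids = stack.grids if isinstance(stack, ProbabilityStack) else stack
    if len(grids) == 0:
        raise ValueError("probability stack is empty")
    mask = grids.joint_valid_mask
    count = np.zeros(grids.reference.values.shape)
    for name in grids.names:
        count += (grids[name].values > threshold)
    count[~mask] = np.nan
    ref = grids.reference
    return Grid(count, ref.cell_size_m, ref.origin_x, ref.origin_y,
                name="richness", units="morphotypes")


def calinski_harabasz(data: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz score; +inf when within-group dispersion is zero."""
    data = np.asarray(data, float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    n, k = len(data), len(groups)
    if k < 2 or k > n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    grand = data.mean(axis=0)
    B = 0.0
    W = 0.0
    for g in groups:
        members = data[labels == g]
        if len(members) == 0:
            raise ValueError(f"empty cluster {g}")
        centroid = members.mean(axis=0)
        B += len(members) * float(((centroid - grand) ** 2).sum())
        W += float(((members - centroid) ** 2).sum())
    if W == 0.0:  # all-singleton or perfectly tight clusters
        return np.inf
    return (B / (k - 1)) / (W / (n - k))


@dataclass
class ClusterCascade:
    """Best-of-n_start k-means across a range of k, scored by CH."""

    k_range: list
    labels: dict = field(default_factory=dict)   # k -> label vector (0-based)
    scores: dict = field(default_factory=dict)   # k -> CH score
    best_k: int = 0
    seed: int = 0
    n_start: int = 25


def kmeans_cascade(data: np.ndarray, k_range=range(2, 11), n_start: int = 25,
                   seed: int = 0) -> ClusterCascade:
    """Run k-means (Lloyd, Euclidean, best of n_start inits) for each k.

    best_k maximises the CH score; +inf scores (degenerate zero
    within-group dispersion) are excluded from the argmax unless every
    score is infinite, in which case the smallest such k wins.
    """
    data = np.asarray(data, float)
    n = len(data)
    ks = [int(k) for k in k_range]
    if min(ks) < 2 or max(ks) > n - 1:
        raise ValueError(f"k range {ks} outside [2, n-1] for n={n}")
    cascade = ClusterCascade(k_range=ks, seed=seed, n_start=n_start)
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_start, algorithm="lloyd",
                    random_state=seed)
        labels = km.fit_predict(data)
        cascade.labels[k] = labels
        cascade.scores[k] = calinski_harabasz(data, labels)
    finite = {k: s for k, s in cascade.scores.items() if np.isfinite(s)}
    pool = finite or cascade.scores
    best = max(pool.values())
    cascade.best_k = min(k for k, s in pool.items() if s == best)
    return cascade


def _canonicalize(labels: np.ndarray, k: int) -> np.ndarray:
    """Relabel clusters 1..k by descending size so runs are comparable."""
    vals, counts = np.unique(labels, return_counts=True)
    order = vals[np.argsort(-counts, kind="stable")]
    mapping = {old: new + 1 for new, old in enumerate(order)}
    return np.vectorize(mapping.get)(labels).astype(float)


def _labels_to_map(labels: np.ndarray, mask: np.ndarray, ref: Grid, k: int,
                   provenance: str) -> LabelMap:
    values = np.full(ref.values.shape, np.nan)
    values[mask] = _canonicalize(labels, k)
    grid = Grid(values, ref.cell_size_m, ref.origin_x, ref.origin_y,
                name="labels", units="label")
    return LabelMap(grid, k, provenance)


def assemblage_map(stack: ProbabilityStack | GridStack, k_range=range(2, 11),
                   n_start: int = 25, seed: int = 0):
    """Cluster cells by their morphotype probability vectors alone.

    Probabilities are clustered raw (all in [0, 1], commensurate).
    Returns (LabelMap, ClusterCascade); labels are 1..best_k by
    descending cluster size.
    """
    grids = stack.grids if isinstance(stack, ProbabilityStack) else stack
    mask = grids.joint_valid_mask
    X = np.column_stack([grids[n].values[mask] for n in grids.names])
    if X.std(axis=0).max() == 0:
        raise ValueError("identical probability layers: clustering degenerate")
    cascade = kmeans_cascade(X, k_range, n_start, seed)
    label_map = _labels_to_map(cascade.labels[cascade.best_k], mask,
                               grids.reference, cascade.best_k,
                               f"assemblage k-means, seed={seed}")
    return label_map, cascade


def habitat_map(stack: ProbabilityStack | GridStack, env: GridStack,
                k: int | None = None, k_range=range(2, 11),
                standardize: bool = True, depth_mask_m: float | None = None,
                target_resolution_m: float | None = None,
                depth_layer: str = "depth", n_start: int = 25, seed: int = 0):
    """Biotope map from probabilities plus environmental variables.

    Environmental layers are z-scored (units differ) before being
    concatenated with the raw probabilities.  Optional steps, applied
    before clustering: resample everything to ``target_resolution_m``
    (block mean) and mask cells shallower than ``depth_mask_m``.  ``k``
    fixes the cluster count (e.g. 4 for a point-to-point comparison with
    another map); otherwise the CH criterion selects it over ``k_range``.
    """
    grids = stack.grids if isinstance(stack, ProbabilityStack) else stack
    combined = GridStack()
    for n in grids.names:
        combined.add(f"p_{n}", grids[n].copy())
    for n in env.names:
        combined.add(f"env_{n}", env[n].copy())
    env_names = [f"env_{n}" for n in env.names]

    if target_resolution_m is not None:
        res = GridStack()
        for n in combined.names:
            res.add(n, resample(combined[n], target_resolution_m, "block_mean"))
        combined = res
    if depth_mask_m is not None:
        combined, _ = mask_by_depth(combined, f"env_{depth_layer}", depth_mask_m)

    mask = combined.joint_valid_mask
    cols = []
    for n in combined.names:
        v = combined[n].values[mask]
        if standardize and n in env_names:
            sd = v.std()
            v = (v - v.mean()) / (sd if sd > 0 else 1.0)
        cols.append(v)
    X = np.column_stack(cols)

    if k is not None:
        cascade = kmeans_cascade(X, [k], n_start, seed)
        best_k = k
    else:
        cascade = kmeans_cascade(X, k_range, n_start, seed)
        best_k = cascade.best_k
    label_map = _labels_to_map(cascade.labels[best_k], mask,
                               combined.reference, best_k,
                               f"habitat k-means, k={best_k}, seed={seed}")
    return label_map, cascade
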