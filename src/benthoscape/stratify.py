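"""Bathymetric stratification and area-proportional image subsampling.

The terrain stack is clustered into k strata (k-means, or k-medoids via
the CLARA scheme: repeated PAM on random subsets, keeping the medoid set
with least total dissimilarity over all cells).  Images are then
subsampled within strata proportionally to each stratum's areal coverage,
anchored on the stratum with the fewest images relative to its coverage
so no stratum is over-asked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .grids import Grid, GridStack


@dataclass
class LabelMap:
    """Integer cluster-assignment grid with labels exactly 1..k."""

    grid: Grid
    k: int
    provenance: str = ""

    @property
    def labels(self) -> np.ndarray:
        return self.grid.values

    def counts(self) -> dict:
        valid = self.grid.valid_mask
        vals, counts = np.unique(self.grid.values[valid].astype(int),
                                 return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


@dataclass
class AllocationPlan:
    strata: list          # stratum labels in order
    coverage: dict        # label -> areal fraction
    available: dict       # label -> images available
    allocated: dict       # label -> images to draw
    anchor: int           # label of the anchoring stratum


# ---------------------------------------------------------------------------
# Clustering


def _pam(data: np.ndarray, k: int, rng: np.random.Generator,
         max_iter: int = 100) -> np.ndarray:
    """Partitioning Around Medoids on a small data matrix; returns medoid rows."""
    n = len(data)
    d = np.linalg.norm(data[:, None, :] - data[None, :, :], axis=2)
    # BUILD: greedy medoid initialisation
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        current = d[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - d, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = np.array(medoids)
    # SWAP
    best_cost = d[:, medoids].min(axis=1).sum()
    for _ in range(max_iter):
        improved = False
        for mi in range(k):
            others = np.delete(medoids, mi)
            rest = d[:, others].min(axis=1) if len(others) else np.full(n, np.inf)
            cand_costs = np.minimum(rest[None, :], d).sum(axis=1)
            cand_costs[medoids] = np.inf
            j = int(np.argmin(cand_costs))
            if cand_costs[j] < best_cost - 1e-12:
                medoids[mi] = j
                best_cost = cand_costs[j]
                improved = True
        if not improved:
            break
    return data[medoids]


def _clara(data: np.ndarray, k: int, seed: int, n_samples: int = 5,
           sample_size: int | None = None) -> np.ndarray:
    """CLARA: PAM on random subsets, keep medoids best over all data."""
    rng = np.random.default_rng(seed)
    n = len(data)
    size = min(n, sample_size or (40 + 2 * k))
    best_labels, best_cost = None, np.inf
    for _ in range(n_samples):
        idx = rng.choice(n, size=size, replace=False)
        medoids = _pam(data[idx], k, rng)
        d_all = np.linalg.norm(data[:, None, :] - medoids[None, :, :], axis=2)
        cost = d_all.min(axis=1).sum()
        if cost < best_cost:
            best_cost = cost
            best_labels = d_all.argmin(axis=1)
    return best_labels


def cluster_strata(terrain: GridStack, k: int, algorithm: str = "k_means",
                   standardize: bool = True, seed: int = 0) -> LabelMap:
    """Cluster the terrain stack's jointly valid cells into k strata.

    Variables are z-scored by default (depth, backscatter, slope and BPI
    have incommensurate units).  Labels are the integers 1..k; constant
    layers make the problem degenerate and raise.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    mask = terrain.joint_valid_mask
    n_valid = int(mask.sum())
    if n_valid < k:
        raise ValueError(f"only {n_valid} valid cells for k={k}")
    X = np.column_stack([terrain[n].values[mask] for n in terrain.names])
    sds = X.std(axis=0)
    if np.all(sds == 0):
        raise ValueError("all layers constant: clustering is degenerate")
    if standardize:
        X = (X - X.mean(axis=0)) / np.where(sds > 0, sds, 1.0)
    if algorithm == "k_means":
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels0 = km.fit_predict(X)
    elif algorithm == "k_medoids":
        labels0 = _clara(X, k, seed)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    ref = terrain.reference
    values = np.full(ref.values.shape, np.nan)
    values[mask] = labels0 + 1.0
    grid = Grid(values, ref.cell_size_m, ref.origin_x, ref.origin_y,
                name="strata", units="label")
    prov = (f"{algorithm} on {terrain.names}, k={k}, "
            f"standardize={standardize}, seed={seed}")
    return LabelMap(grid, k, prov)


# ---------------------------------------------------------------------------
# Allocation


def coverage_fractions(strata: LabelMap) -> dict:
    """Areal fraction of each stratum over valid cells; sums to 1."""
    counts = strata.counts()
    total = sum(counts.values())
    return {lab: c / total for lab, c in counts.items()}


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def allocate_subsample(available: dict, coverage: dict) -> AllocationPlan:
    """Area-proportional allocation anchored on the scarcest stratum.

    The anchor is the stratum minimising available/coverage; it
    contributes its full availability and every other stratum is
    allocated round(available_anchor * coverage_c / coverage_anchor),
    capped at its own availability.
    """
    if set(available) != set(coverage):
        raise ValueError("available and coverage must cover the same strata")
    total_cov = sum(coverage.values())
    if not np.isclose(total_cov, 1.0, atol=0.01):
        coverage = {lab: c / total_cov for lab, c in coverage.items()}
    for lab, avail in available.items():
        if avail == 0 and coverage[lab] > 0:
            raise ValueError(f"stratum {lab} has positive coverage but no images")
    anchor = min(available, key=lambda lab: available[lab] / coverage[lab])
    allocated = {}
    for lab in available:
        target = available[anchor] * coverage[lab] / coverage[anchor]
        allocated[lab] = min(available[lab], _round_half_up(target))
    allocated[anchor] = available[anchor]
    return AllocationPlan(sorted(available), dict(coverage), dict(available),
                          allocated, anchor)


def assign_strata(table: pd.DataFrame, strata: LabelMap) -> pd.Series:
    """Stratum label of each image from its coordinates; raises off-grid."""
    labels = strata.grid.sample(table["x"].to_numpy(), table["y"].to_numpy())
    bad = ~np.isfinite(labels)
    if bad.any():
        offenders = table.loc[bad, "image_id"].tolist()
        raise ValueError(f"images outside the stratified domain: {offenders[:10]}"
                         f"{'...' if len(offenders) > 10 else ''}")
    return pd.Series(labels.astype(int), index=table.index, name="stratum")


def draw_subsample(table: pd.DataFrame, strata: LabelMap, plan: AllocationPlan,
                   seed: int = 0) -> pd.DataFrame:
    """Uniform within-stratum random subsample of the allocated sizes."""
    rng = np.random.default_rng(seed)
    stratum = assign_strata(table, strata)
    pieces = []
    for lab in plan.strata:
        members = table.index[stratum == lab].to_numpy()
        want = plan.allocated.get(lab, 0)
        if want > len(members):
            raise ValueError(f"stratum {lab}: plan wants {want}, "
                             f"only {len(members)} images available")
        chosen = rng.choice(members, size=want, replace=False)
        pieces.append(table.loc[np.sort(chosen)])
    return pd.concat(pieces).reset_index(drop=True)
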