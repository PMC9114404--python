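"""Permutation statistics and map comparison for the cluster solutions.

PERMANOVA (one-way permutational multivariate ANOVA, Anderson's
formulation) tests whether two groups of multivariate observations —
here, cells' predicted probability vectors — differ in location.  From
the pairwise distance matrix d:

    SS_total   = (1/N) * sum_{i<j} d_ij^2
    SS_within  = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    SS_between = SS_total - SS_within
    pseudo-F   = [SS_between / (k-1)] / [SS_within / (N-k)]

and the p-value is (1 + #{permuted F >= observed F}) / (n_perm + 1)
under random reassignment of group labels.  Pairwise tests over k groups
are Bonferroni-adjusted with m = C(k, 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations as iter_permutations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform

from .grids import Grid
from .stratify import LabelMap
from .survey import PresenceAbsenceMatrix, morphotype_columns


@dataclass
class PermanovaResult:
    pair: tuple
    pseudo_f: float
    p_raw: float
    p_adjusted: float
    n_permutations: int
    seed: int


def _distance_matrix(data: np.ndarray, distance: str) -> np.ndarray:
    if distance == "euclidean":
        return squareform(pdist(data, metric="euclidean"))
    if distance == "bray_curtis":
        return squareform(pdist(data, metric="braycurtis"))
    raise ValueError(f"unknown distance {distance!r}")


def _pseudo_f_from_d2(d2: np.ndarray, groups: np.ndarray, group_ids) -> float:
    n = len(d2)
    k = len(group_ids)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in group_ids:
        idx = np.nonzero(groups == g)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    if ss_within == 0.0:
        if ss_between == 0.0:
            raise ValueError("degenerate: zero within- and between-group dispersion")
        return np.inf
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def permanova(data: np.ndarray, labels, distance: str = "euclidean",
              n_permutations: int = 999, seed: int = 0) -> PermanovaResult:
    """Two-group PERMANOVA with a Monte-Carlo permutation p-value."""
    data = np.asarray(data, float)
    labels = np.asarray(labels)
    group_ids = np.unique(labels)
    if len(group_ids) != 2:
        raise ValueError("permanova compares exactly two groups")
    for g in group_ids:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g} has fewer than 2 observations")
    d2 = _distance_matrix(data, distance) ** 2
    f_obs = _pseudo_f_from_d2(d2, labels, group_ids)
    rng = np.random.default_rng(seed)
    n_ge = 0
    perm = labels.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        if _pseudo_f_from_d2(d2, perm, group_ids) >= f_obs:
            n_ge += 1
    p_raw = (1 + n_ge) / (n_permutations + 1)
    return PermanovaResult(tuple(group_ids.tolist()), float(f_obs), p_raw,
                           p_raw, n_permutations, seed)


def permanova_exact(data: np.ndarray, labels,
                    distance: str = "euclidean") -> float:
    """Exact permutation p-value by full enumeration (tiny N only)."""
    data = np.asarray(data, float)
    labels = np.asarray(labels)
    if len(labels) > 10:
        raise ValueError("exact enumeration is for N <= 10")
    group_ids = np.unique(labels)
    d2 = _distance_matrix(data, distance) ** 2
    f_obs = _pseudo_f_from_d2(d2, labels, group_ids)
    n_ge = 0
    total = 0
    for perm in set(iter_permutations(labels.tolist())):
        total += 1
        if _pseudo_f_from_d2(d2, np.array(perm), group_ids) >= f_obs - 1e-12:
            n_ge += 1
    return n_ge / total


def pairwise_permanova(data: np.ndarray, labels, distance: str = "euclidean",
                       n_permutations: int = 999, adjust: str = "bonferroni",
                       seed: int = 0) -> list:
    """One two-group test per unordered pair of labels, Bonferroni-adjusted."""
    if adjust != "bonferroni":
        raise ValueError(f"unknown adjustment {adjust!r}")
    data = np.asarray(data, float)
    labels = np.asarray(labels)
    group_ids = np.unique(labels)
    if len(group_ids) < 2:
        raise ValueError("need at least two groups")
    pairs = list(combinations(group_ids.tolist(), 2))
    m = len(pairs)
    results = []
    for i, (a, b) in enumerate(pairs):
        sel = (labels == a) | (labels == b)
        res = permanova(data[sel], labels[sel], distance, n_permutations,
                        seed=seed + i)
        res.pair = (a, b)
        res.p_adjusted = min(1.0, m * res.p_raw)
        results.append(res)
    return results


def permanova_table(results) -> pd.DataFrame:
    return pd.DataFrame([{
        "group_a": r.pair[0], "group_b": r.pair[1], "pseudo_F": r.pseudo_f,
        "p_raw": r.p_raw, "p_adjusted": r.p_adjusted,
        "n_permutations": r.n_permutations, "seed": r.seed,
    } for r in results])


# ---------------------------------------------------------------------------
# Composition and per-assemblage summaries


def composition_fractions(matrix: PresenceAbsenceMatrix,
                          image_assemblage) -> pd.DataFrame:
    """Occurrence fraction of each morphotype per assemblage.

    Rows: morphotypes with at least one occurrence (zero-occurrence
    morphotypes are excluded with a note column absent); columns: one
    count and one fraction per assemblage label; fractions sum to 1 per
    row and are the ternary coordinates when there are three assemblages.
    """
    assemblage = pd.Series(np.asarray(image_assemblage),
                           index=matrix.values.index)
    if assemblage.isna().any():
        raise ValueError("every image must carry an assemblage label")
    groups = sorted(assemblage.unique().tolist())
    counts = pd.DataFrame(
        {g: matrix.values[assemblage == g].sum(axis=0) for g in groups})
    total = counts.sum(axis=1)
    nonzero = counts[total > 0]
    fractions = nonzero.div(nonzero.sum(axis=1), axis=0)
    out = pd.concat({"count": nonzero, "fraction": fractions}, axis=1)
    out.index.name = "morphotype_id"
    return out


def assemblage_summary(assemblages: LabelMap, table: pd.DataFrame,
                       matrix: PresenceAbsenceMatrix) -> pd.DataFrame:
    """Per-assemblage image count, specimens, richness and depth statistics.

    Total richness counts the distinct morphotypes observed on an
    assemblage's images regardless of any prevalence filtering; depth
    mean/sd are over member images.  Assemblages with no images yield a
    zero row.
    """
    labels = assemblages.grid.sample(table["x"].to_numpy(),
                                     table["y"].to_numpy())
    mcols = morphotype_columns(table)
    rows = []
    for g in range(1, assemblages.k + 1):
        sel = labels == g
        sub = table.loc[sel]
        counts = sub[mcols].to_numpy() if len(sub) else np.zeros((0, len(mcols)))
        rows.append({
            "assemblage": g,
            "n_images": int(sel.sum()),
            "n_specimens": int(counts.sum()),
            "total_richness": int((counts.sum(axis=0) > 0).sum()),
            "depth_mean_m": float(sub["depth_m"].mean()) if len(sub) else 0.0,
            "depth_sd_m": float(sub["depth_m"].std(ddof=0)) if len(sub) else 0.0,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Habitat-map agreement


@dataclass
class AgreementReport:
    confusion: pd.DataFrame     # rows: map_a labels, cols: map_b labels
    matching: dict              # map_a label -> matched map_b label
    agreement: float            # proportion agreeing under the matching
    difference_map: Grid        # 1 = matched agreement, 2 = disagreement


def habitat_agreement(map_a: LabelMap, map_b: LabelMap) -> AgreementReport:
    """Compare two label maps cell-by-cell with optimal label matching.

    The confusion matrix is built over jointly valid cells; a one-to-one
    matching of labels maximising total agreement is found by solving the
    assignment problem on it.  The difference map marks matched-agreeing
    cells 1 and disagreeing cells 2.
    """
    if not map_a.grid.same_geometry(map_b.grid):
        raise ValueError("label maps must share one geometry; resample first")
    a = map_a.grid.values
    b = map_b.grid.values
    mask = np.isfinite(a) & np.isfinite(b)
    av = a[mask].astype(int)
    bv = b[mask].astype(int)
    labs_a = list(range(1, map_a.k + 1))
    labs_b = list(range(1, map_b.k + 1))
    conf = np.zeros((len(labs_a), len(labs_b)), dtype=int)
    for i, la in enumerate(labs_a):
        for j, lb in enumerate(labs_b):
            conf[i, j] = int(((av == la) & (bv == lb)).sum())
    row_ind, col_ind = linear_sum_assignment(conf, maximize=True)
    matching = {labs_a[i]: labs_b[j] for i, j in zip(row_ind, col_ind)}
    agree_cells = conf[row_ind, col_ind].sum()
    agreement = agree_cells / mask.sum() if mask.sum() else 0.0

    diff = np.full(a.shape, np.nan)
    matched_b = np.vectorize(lambda la: matching.get(la, -1))(av)
    diff_vals = np.where(matched_b == bv, 1.0, 2.0)
    diff[mask] = diff_vals
    ref = map_a.grid
    diff_grid = Grid(diff, ref.cell_size_m, ref.origin_x, ref.origin_y,
                     name="difference", units="label")
    confusion = pd.DataFrame(conf, index=pd.Index(labs_a, name="map_a"),
                             columns=pd.Index(labs_b, name="map_b"))
    return AgreementReport(confusion, matching, float(agreement), diff_grid)
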