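"""Annotation-table cleaning, presence-absence conversion, prevalence filter.

The annotation table is a pandas DataFrame with one row per image: the
metadata columns ``image_id, x, y, area_m2, depth_m, cruise`` followed by
one non-negative integer count column per morphotype (prefixed ``mtp_``
by the simulator, but any non-metadata column is treated as a
morphotype).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

META_COLUMNS = ["image_id", "x", "y", "area_m2", "depth_m", "cruise"]


def morphotype_columns(table: pd.DataFrame) -> list:
    return [c for c in table.columns if c not in META_COLUMNS]


def validate_annotations(table: pd.DataFrame) -> None:
    if table["image_id"].duplicated().any():
        raise ValueError("image_id values must be unique")
    if (table["area_m2"] <= 0).any():
        raise ValueError("image areas must be positive")
    counts = table[morphotype_columns(table)]
    if (counts.to_numpy() < 0).any():
        raise ValueError("morphotype counts must be non-negative")


@dataclass
class PresenceAbsenceMatrix:
    """Binary images x morphotypes matrix with identifier registries."""

    values: pd.DataFrame  # index image_id, columns morphotype ids, entries 0/1

    @property
    def image_ids(self) -> list:
        return list(self.values.index)

    @property
    def morphotype_ids(self) -> list:
        return list(self.values.columns)

    @property
    def occurrence_counts(self) -> pd.Series:
        """Number of images each morphotype occurs in (column sums)."""
        return self.values.sum(axis=0)

    @property
    def n_images(self) -> int:
        return len(self.values)


@dataclass
class OverlapLog:
    dropped_ids: list = field(default_factory=list)
    pairs: list = field(default_factory=list)  # (retained_id, dropped_id)


def remove_overlaps(table: pd.DataFrame, footprint: str = "square_from_area",
                    min_separation_factor: float = 1.0):
    """Greedy removal of overlapping frames to avoid double-counted fauna.

    Images are processed in acquisition (row) order; an image is dropped
    when its centre lies within ``min_separation_factor * (side_i +
    side_j) / 2`` of an already retained image's centre, with side =
    sqrt(area) (square footprint).  Returns (retained table, OverlapLog).
    """
    if footprint != "square_from_area":
        raise ValueError(f"unknown footprint model {footprint!r}")
    validate_annotations(table)
    xs = table["x"].to_numpy(float)
    ys = table["y"].to_numpy(float)
    sides = np.sqrt(table["area_m2"].to_numpy(float))
    ids = table["image_id"].to_numpy()

    kept_idx: list = []
    log = OverlapLog()
    kx = np.empty(len(table))
    ky = np.empty(len(table))
    ks = np.empty(len(table))
    nk = 0
    for i in range(len(table)):
        if nk:
            d = np.hypot(kx[:nk] - xs[i], ky[:nk] - ys[i])
            thresh = min_separation_factor * (ks[:nk] + sides[i]) / 2.0
            clash = np.nonzero(d < thresh)[0]
            if clash.size:
                log.dropped_ids.append(ids[i])
                log.pairs.append((ids[kept_idx[clash[0]]], ids[i]))
                continue
        kept_idx.append(i)
        kx[nk], ky[nk], ks[nk] = xs[i], ys[i], sides[i]
        nk += 1
    return table.iloc[kept_idx].reset_index(drop=True), log


def to_presence_absence(table: pd.DataFrame) -> PresenceAbsenceMatrix:
    """Convert per-image counts to a binary presence-absence matrix."""
    if table.empty:
        raise ValueError("annotation table is empty")
    cols = morphotype_columns(table)
    binary = (table[cols].to_numpy() > 0).astype(int)
    values = pd.DataFrame(binary, index=pd.Index(table["image_id"], name="image_id"),
                          columns=cols)
    return PresenceAbsenceMatrix(values)


@dataclass
class PrevalenceReport:
    min_images: int
    inclusive: bool
    n_retained: int
    n_excluded: int
    retained_ids: list
    excluded_ids: list
    retained_specimens: int | None = None


def prevalence_filter(matrix: PresenceAbsenceMatrix, min_images: int = 10,
                      inclusive: bool = True,
                      source_table: pd.DataFrame | None = None):
    """Drop morphotypes observed in too few images to support a model.

    The retention rule is occurrences >= min_images (inclusive, default)
    or strictly > (exclusive); both conventions appear in field usage and
    the boundary case is configurable.  Returns (filtered matrix,
    PrevalenceReport); an empty result is allowed, downstream stages must
    handle zero morphotypes.
    """
    if min_images < 1:
        raise ValueError("min_images must be >= 1")
    occ = matrix.occurrence_counts
    keep = occ >= min_images if inclusive else occ > min_images
    retained = [c for c in matrix.morphotype_ids if keep[c]]
    excluded = [c for c in matrix.morphotype_ids if not keep[c]]
    specimens = None
    if source_table is not None:
        cols = [c for c in retained if c in source_table.columns]
        specimens = int(source_table[cols].to_numpy().sum())
    report = PrevalenceReport(min_images, inclusive, len(retained),
                              len(excluded), retained, excluded, specimens)
    return PresenceAbsenceMatrix(matrix.values[retained].copy()), report


@dataclass
class SurveySummary:
    n_images: int
    n_specimens: int
    total_area_m2: float
    density_per_m2: float
    morphotype_richness: int
    n_singletons: int

    @property
    def density_one_decimal(self) -> float:
        return round(self.density_per_m2, 1)


def survey_summary(table: pd.DataFrame) -> SurveySummary:
    """Specimen, area, density, richness and singleton totals.

    Singletons are morphotypes with exactly one specimen across the whole
    survey.  An empty table yields zeros.
    """
    if table.empty:
        return SurveySummary(0, 0, 0.0, 0.0, 0, 0)
    cols = morphotype_columns(table)
    counts = table[cols].to_numpy()
    totals = counts.sum(axis=0)
    n_specimens = int(totals.sum())
    area = float(table["area_m2"].sum())
    density = n_specimens / area if area > 0 else 0.0
    richness = int((totals > 0).sum())
    singletons = int((totals == 1).sum())
    return SurveySummary(len(table), n_specimens, area, density, richness,
                         singletons)
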