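"""Synthetic abyssal nodule-province seascape and photo-transect survey.

Emulates the statistical structure the analysis pipeline assumes: abyssal
plains at ~4100-4400 m deepening westward, Gaussian seamounts rising to
<1500 m depth, N-S trending ridge/trough texture, nodule fields
concentrated on the eastern plains and depleted near seamounts and
troughs, and a niche-structured megafauna community observed through a
towed-camera image survey at a mean density of about 0.6 individuals per
square metre.  Every generator output is a pure function of its spec,
including the seed, so downstream stages are testable without any survey
download.

Niche responses are logistic in covariates z-scored over the seascape's
valid cells, so coefficients read as log-odds per standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .grids import Grid, GridStack
from .terrain import bpi, slope

DEPTH_ENVELOPE_M = (1400.0, 4600.0)

META_COLUMNS = ["image_id", "x", "y", "area_m2", "depth_m", "cruise"]


# ---------------------------------------------------------------------------
# Specs


@dataclass
class SeascapeSpec:
    """Geometry and relief of the synthetic study area."""

    nrows: int = 150
    ncols: int = 250
    cell_size_m: float = 715.0
    plain_depth_range_m: tuple = (4100.0, 4350.0)
    west_east_gradient_m: float = 250.0  # depth decrease from west to east
    seamounts: tuple = (
        # (centre_col_frac, centre_row_frac, peak_rise_m, radius_m)
        (0.22, 0.30, 2600.0, 9000.0),
        (0.40, 0.22, 2200.0, 8000.0),
        (0.62, 0.70, 2500.0, 9000.0),
    )
    ridge_amplitude_m: float = 60.0
    ridge_wavelength_m: float = 14000.0
    noise_sd_m: float = 15.0
    # nodule facies contrast: kg m-2 step from the western low-nodule plain
    # to the eastern contiguous fields (0 switches the gradient off)
    nodule_east_contrast_kg_m2: float = 18.0
    seed: int = 0


@dataclass
class NicheSpec:
    """Logistic occurrence response of one morphotype to the environment."""

    morphotype_id: str
    archetype: str  # seamount | nodule_plain | trough | generalist | rare
    intercept: float
    coefficients: dict  # covariate name -> log-odds per SD
    max_probability: float = 1.0


@dataclass
class SurveyDesign:
    """Layout of the photo-transect image survey."""

    n_transects: int = 25
    images_per_transect: int = 200
    image_area_mean_m2: float = 8.0
    image_area_sd_m2: float = 1.5
    image_spacing_factor: float = 3.0  # spacing = factor * sqrt(mean area)
    overlap_fraction: float = 0.0
    n_cruises: int = 5
    seed: int = 0


@dataclass
class SurveyTruth:
    """Ground truth recorded alongside a simulated survey."""

    niche_table: pd.DataFrame
    overlap_pairs: list
    zone_map: Grid | None = None
    p_true: GridStack | None = None


# ---------------------------------------------------------------------------
# Bathymetry and environmental layers


def generate_bathymetry(spec: SeascapeSpec) -> Grid:
    """Plain + westward-deepening trend - seamount bumps + ridge field + noise."""
    rng = np.random.default_rng(spec.seed)
    nrows, ncols, cell = spec.nrows, spec.ncols, spec.cell_size_m
    xs = (np.arange(ncols) + 0.5) * cell
    ys = (np.arange(nrows) + 0.5) * cell
    xx, yy = np.meshgrid(xs, ys)
    width = ncols * cell

    base = spec.plain_depth_range_m[1]
    depth = base - spec.west_east_gradient_m * (xx / width)

    for cx_frac, cy_frac, rise, radius in spec.seamounts:
        if radius < 2 * cell:
            raise ValueError("seamount radius must span at least 2 cells")
        cx, cy = cx_frac * width, cy_frac * nrows * cell
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        depth -= rise * np.exp(-r2 / (2 * radius ** 2))

    if spec.ridge_amplitude_m > 0:
        depth += spec.ridge_amplitude_m * np.sin(2 * np.pi * xx / spec.ridge_wavelength_m)

    if spec.noise_sd_m > 0:
        white = rng.standard_normal((nrows, ncols))
        smooth = ndimage.gaussian_filter(white, sigma=2.0, mode="reflect")
        sd = smooth.std()
        if sd > 0:
            depth += spec.noise_sd_m * smooth / sd

    depth = np.clip(depth, *DEPTH_ENVELOPE_M)
    origin_y = nrows * cell  # origin at the NW outer corner
    return Grid(depth, cell, 0.0, origin_y, name="depth", units="m")


def generate_env_layers(depth: Grid, spec: SeascapeSpec) -> GridStack:
    """Environmental covariates consistent with the relief.

    Layers: depth, bpi_1000, bpi_17000, nodule_kg_m2 (eastward-increasing,
    suppressed on steep relief and above 3800 m), backscatter (dB,
    correlated with nodule abundance), mud_fraction (anticorrelated with
    slope).  All share the bathymetry geometry.
    """
    rng = np.random.default_rng(spec.seed + 1)
    stack = GridStack()
    stack.add("depth", depth.copy())
    bpi_small = bpi(depth, max(1000.0, depth.cell_size_m))
    bpi_large = bpi(depth, 17000.0)
    stack.add("bpi_1000", bpi_small)
    stack.add("bpi_17000", bpi_large)

    ncols = depth.ncols
    east = np.broadcast_to((np.arange(ncols) + 0.5) / ncols, depth.values.shape)
    relief = np.abs(np.nan_to_num(
        bpi(depth, max(5000.0, depth.cell_size_m)).values, nan=0.0))
    relief_scale = max(np.percentile(relief, 95), 1.0)
    # saturating depletion at the few-km scale: gentle ridge/trough
    # texture keeps most of the field, strong local relief (flanks,
    # trough walls) is swept bare, shallow seamount terrain carries none
    suppression = 1.0 / (1.0 + np.exp(20.0 * (relief / relief_scale - 0.35)))
    suppression /= 1.0 / (1.0 + np.exp(20.0 * (0.0 - 0.35)))
    suppression = np.where(depth.values < 3800.0, 0.0, suppression)
    # eastward increase as a facies transition: western plains hold sparse
    # nodules, eastern plains contiguous high-abundance fields
    facies = 1.0 / (1.0 + np.exp(-50.0 * (east - 0.45)))
    nodule = (2.5 + spec.nodule_east_contrast_kg_m2 * facies) * suppression
    nodule += 0.8 * ndimage.gaussian_filter(
        rng.standard_normal(depth.values.shape), sigma=2.0)
    nodule = np.clip(nodule, 0.0, None)
    nodule[~depth.valid_mask] = np.nan
    stack.add("nodule_kg_m2", Grid(nodule, depth.cell_size_m, depth.origin_x,
                                   depth.origin_y, units="kg m-2"))

    backscatter = -32.0 + 0.45 * nodule + 1.2 * ndimage.gaussian_filter(
        rng.standard_normal(depth.values.shape), sigma=1.5)
    backscatter[~depth.valid_mask] = np.nan
    stack.add("backscatter", Grid(backscatter, depth.cell_size_m, depth.origin_x,
                                  depth.origin_y, units="dB"))

    sl = slope(depth).values
    mud = np.clip(0.9 - 0.04 * sl, 0.0, 1.0)
    mud += 0.03 * ndimage.gaussian_filter(rng.standard_normal(depth.values.shape),
                                          sigma=1.5)
    mud = np.clip(mud, 0.0, 1.0)
    mud[~depth.valid_mask] = np.nan
    stack.add("mud_fraction", Grid(mud, depth.cell_size_m, depth.origin_x,
                                   depth.origin_y, units="fraction"))
    return stack


def _zscore_layers(env: GridStack, names) -> dict:
    """Per-layer (mean, sd) over jointly valid cells; sd floored at tiny."""
    mask = env.joint_valid_mask
    out = {}
    for n in names:
        v = env[n].values[mask]
        out[n] = (float(v.mean()), float(max(v.std(), 1e-12)))
    return out


def true_occurrence_probability(env: GridStack, niche: NicheSpec) -> Grid:
    """Planted per-image occurrence probability surface for one morphotype.

    p = max_probability * logistic(intercept + sum_c beta_c * z_c), with
    each referenced covariate z-scored over the stack's jointly valid
    cells.  This is the ground truth the distribution models must recover.
    """
    for cov in niche.coefficients:
        if cov not in env:
            raise KeyError(f"niche covariate {cov!r} missing from stack")
    zparams = _zscore_layers(env, niche.coefficients.keys())
    ref = env.reference
    lp = np.full(ref.values.shape, float(niche.intercept))
    for cov, beta in niche.coefficients.items():
        mu, sd = zparams[cov]
        lp = lp + beta * (env[cov].values - mu) / sd
    p = niche.max_probability / (1.0 + np.exp(-lp))
    p[~env.joint_valid_mask] = np.nan
    return Grid(p, ref.cell_size_m, ref.origin_x, ref.origin_y,
                name=niche.morphotype_id, units="probability")


# ---------------------------------------------------------------------------
# Communities

_ARCHETYPE_CODES = {"seamount": "SMT", "nodule_plain": "NOD", "trough": "TRG",
                    "generalist": "GEN", "rare": "RAR"}

# log-odds per SD templates; jittered per morphotype
_ARCHETYPE_TEMPLATES = {
    "seamount": {"intercept": -3.0, "max_p": 0.9,
                 "coefficients": {"depth": -3.0, "bpi_17000": 2.0}},
    "nodule_plain": {"intercept": 0.0, "max_p": 0.85,
                     "coefficients": {"nodule_kg_m2": 4.0, "depth": 0.5}},
    "trough": {"intercept": -2.0, "max_p": 0.8,
               "coefficients": {"nodule_kg_m2": -3.0, "bpi_17000": -2.0,
                                "depth": 2.0}},
    "generalist": {"intercept": -1.0, "max_p": 0.7,
                   "coefficients": {"depth": 0.3, "backscatter": 0.3}},
    "rare": {"intercept": -1.0, "max_p": 0.01,
             "coefficients": {"nodule_kg_m2": 0.5}},
}

DEFAULT_COMMUNITY_SIZES = {"seamount": 12, "nodule_plain": 20, "trough": 10,
                           "generalist": 18, "rare": 20}


def make_community(sizes: dict | None = None, seed: int = 0,
                   jitter: float = 0.25) -> list:
    """Morphotype niches drawn around the archetype templates.

    Default sizes give 80 morphotypes of which roughly 60-70 survive a
    10-image prevalence filter at the default survey effort (the rare
    archetype sits near that boundary by design).
    """
    sizes = dict(DEFAULT_COMMUNITY_SIZES if sizes is None else sizes)
    rng = np.random.default_rng(seed)
    niches = []
    for archetype, n in sizes.items():
        tmpl = _ARCHETYPE_TEMPLATES[archetype]
        code = _ARCHETYPE_CODES[archetype]
        for i in range(n):
            coeffs = {c: b * (1.0 + jitter * rng.standard_normal())
                      for c, b in tmpl["coefficients"].items()}
            niches.append(NicheSpec(
                morphotype_id=f"{code}_{i + 1:03d}",
                archetype=archetype,
                intercept=tmpl["intercept"] + 0.3 * rng.standard_normal(),
                coefficients=coeffs,
                max_probability=tmpl["max_p"],
            ))
    return niches


def three_zone_community(env: GridStack, n_per_zone: int = 13,
                         seed: int = 0, steepness: float = 20.0) -> list:
    """Strong-signal community of three archetype groups, one per zone.

    Used for the planted-structure recovery surface: each group's
    logistic response is steep (default 20 log-odds per SD) and its 0.5
    crossing is anchored on the same thresholds that define the planted
    zone map (the 3800-m seamount contour and the spatial-mean nodule
    abundance), so each group is nearly an indicator of its zone —
    seamount, eastern nodule plain, or the remaining low-nodule
    plain/trough — and the stacked models followed by assemblage
    clustering must find exactly three assemblages.
    """
    rng = np.random.default_rng(seed)
    zp = _zscore_layers(env, ["depth", "nodule_kg_m2"])
    mu_d, sd_d = zp["depth"]
    z3800 = (3800.0 - mu_d) / sd_d

    s = steepness
    templates = {
        # ON below the 3800-m contour (shallower = more probable)
        "seamount": {"max_p": 0.7, "intercept": s * z3800,
                     "coefficients": {"depth": -s}},
        # ON where nodule abundance exceeds its spatial mean
        "nodule_plain": {"max_p": 0.65, "intercept": 0.0,
                         "coefficients": {"nodule_kg_m2": s}},
        # ON on low-nodule seabeds: troughs, the western plain, and the
        # nodule-suppressed seamount terrain (so each zone carries a
        # distinct joint on/off profile of the three groups)
        "trough": {"max_p": 0.6, "intercept": 0.0,
                   "coefficients": {"nodule_kg_m2": -s}},
    }
    # Individual morphotypes turn on at staggered positions around the
    # zone threshold (community turnover, not a knife edge), top out at
    # moderate probabilities, and carry weak idiosyncratic responses to
    # other covariates.  The secondary responses point in a different
    # direction for every member, so within a zone the community varies
    # in many directions at once while the shared threshold response
    # still separates the zones.
    secondary_pool = ["bpi_1000", "bpi_1000", "bpi_17000", "backscatter",
                      "mud_fraction"]
    niches = []
    for archetype, tmpl in templates.items():
        code = _ARCHETYPE_CODES[archetype]
        for i in range(n_per_zone):
            jit = 1.0 + 0.1 * rng.standard_normal()
            stagger = 0.15 * s * rng.standard_normal()
            coeffs = {c: b * jit for c, b in tmpl["coefficients"].items()}
            for cov in rng.choice(secondary_pool, size=2, replace=False):
                coeffs[cov] = coeffs.get(cov, 0.0) + 3.5 * rng.standard_normal()
            niches.append(NicheSpec(
                morphotype_id=f"{code}_{i + 1:03d}", archetype=archetype,
                intercept=tmpl["intercept"] * jit + stagger,
                coefficients=coeffs,
                max_probability=min(1.0, tmpl["max_p"]
                                    * (1.0 + 0.15 * rng.standard_normal()))))
    return niches


def probability_stack(env: GridStack, niches) -> GridStack:
    stack = GridStack()
    for niche in niches:
        stack.add(niche.morphotype_id, true_occurrence_probability(env, niche))
    return stack


def planted_zone_map(env: GridStack) -> Grid:
    """Three-zone ground-truth map implied by the covariate thresholds.

    Zone 1: seamount (shallower than 3800 m, where nodules are also
    suppressed).  Zone 2: nodule-rich plain (nodule abundance above its
    spatial mean).  Zone 3: remaining low-nodule plains and troughs.
    These are the thresholds the three-zone community's responses are
    anchored on.
    """
    mask = env.joint_valid_mask
    depth = env["depth"].values
    nod = env["nodule_kg_m2"].values
    mu_n = np.nanmean(nod[mask])
    zones = np.full(depth.shape, np.nan)
    zones[mask] = 3.0
    zone2 = mask & (nod > mu_n)
    zones[zone2] = 2.0
    zone1 = mask & (depth < 3800.0)
    zones[zone1] = 1.0
    ref = env.reference
    return Grid(zones, ref.cell_size_m, ref.origin_x, ref.origin_y,
                name="planted_zone", units="label")


def calibrate_density(env: GridStack, niches, target_density_per_m2: float = 0.6,
                      image_area_m2: float = 8.0,
                      count_lambda: float = 0.3) -> list:
    """Scale niche max-probabilities so expected density hits the target.

    Expected specimens per image = sum_m mean_cell(p_m) * E[count|present]
    with zero-truncated-Poisson counts; one common factor multiplies every
    max_probability (capped at 1) so the generative model's expected
    density equals ``target_density_per_m2``.
    """
    mask = env.joint_valid_mask
    mean_p_total = sum(
        float(np.nanmean(true_occurrence_probability(env, n).values[mask]))
        for n in niches)
    ztp_mean = count_lambda / (1.0 - np.exp(-count_lambda))
    target_p_total = target_density_per_m2 * image_area_m2 / ztp_mean
    factor = target_p_total / mean_p_total
    out = []
    for n in niches:
        out.append(NicheSpec(n.morphotype_id, n.archetype, n.intercept,
                             dict(n.coefficients),
                             min(1.0, n.max_probability * factor)))
    return out


# ---------------------------------------------------------------------------
# Survey simulation


def _zero_truncated_poisson(rng: np.random.Generator, lam: float, size: int):
    if size == 0:
        return np.zeros(0, dtype=int)
    u = rng.uniform(stats.poisson.cdf(0, lam), 1.0, size=size)
    return stats.poisson.ppf(u, lam).astype(int)


def simulate_survey(env: GridStack, niches, design: SurveyDesign,
                    count_lambda: float = 0.3):
    """Simulate a photo-transect survey over the seascape.

    Straight transects with random start and heading; per-image presence
    of each morphotype is Bernoulli at the planted probability of the
    image's cell, and counts given presence are zero-truncated Poisson.
    A fraction of images is duplicated in place to plant known overlapping
    frames.  Returns (annotation table, SurveyTruth).
    """
    rng = np.random.default_rng(design.seed)
    ref = env.reference
    width = ref.ncols * ref.cell_size_m
    height = ref.nrows * ref.cell_size_m
    x0, y_top = ref.origin_x, ref.origin_y
    y_bot = y_top - height

    spacing = design.image_spacing_factor * np.sqrt(design.image_area_mean_m2)
    xs, ys, transect_ids = [], [], []
    for t in range(design.n_transects):
        x = x0 + rng.uniform(0.05, 0.95) * width
        y = y_bot + rng.uniform(0.05, 0.95) * height
        heading = rng.uniform(0, 2 * np.pi)
        dx, dy = np.cos(heading), np.sin(heading)
        for _ in range(design.images_per_transect):
            xs.append(x)
            ys.append(y)
            transect_ids.append(t)
            step = spacing * rng.uniform(0.8, 1.2)
            x += dx * step
            y += dy * step
            # bounce off the extent so transects never leave the grid
            if not (x0 < x < x0 + width):
                dx = -dx
                x = np.clip(x, x0 + 1.0, x0 + width - 1.0)
            if not (y_bot < y < y_top):
                dy = -dy
                y = np.clip(y, y_bot + 1.0, y_top - 1.0)
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    n = len(xs)
    if n and not np.all(env.reference.contains(xs, ys)):
        raise ValueError("survey design places images outside the grid extent")

    areas = np.clip(rng.normal(design.image_area_mean_m2,
                               design.image_area_sd_m2, n), 0.5, None)
    depths = env["depth"].sample(xs, ys) if n else np.zeros(0)
    cruises = [f"C{(t % design.n_cruises) + 1}" for t in transect_ids]

    table = pd.DataFrame({
        "image_id": [f"IMG_{i + 1:06d}" for i in range(n)],
        "x": xs, "y": ys, "area_m2": areas, "depth_m": depths,
        "cruise": cruises,
    })

    p_true = probability_stack(env, niches)
    for niche in niches:
        p = p_true[niche.morphotype_id].sample(xs, ys) if n else np.zeros(0)
        p = np.nan_to_num(p, nan=0.0)
        present = rng.uniform(size=n) < p
        counts = np.zeros(n, dtype=int)
        counts[present] = _zero_truncated_poisson(rng, count_lambda,
                                                  int(present.sum()))
        table[f"mtp_{niche.morphotype_id}"] = counts

    # plant duplicate frames (same position, same fauna) after the originals
    overlap_pairs = []
    n_overlap = int(np.floor(design.overlap_fraction * n))
    if n_overlap > 0:
        chosen = rng.choice(n, size=n_overlap, replace=False)
        dups = table.iloc[chosen].copy()
        dup_ids = [f"IMG_{n + j + 1:06d}" for j in range(n_overlap)]
        overlap_pairs = list(zip(table.iloc[chosen]["image_id"], dup_ids))
        dups["image_id"] = dup_ids
        table = pd.concat([table, dups], ignore_index=True)

    niche_table = pd.DataFrame({
        "morphotype_id": [nch.morphotype_id for nch in niches],
        "archetype": [nch.archetype for nch in niches],
        "max_probability": [nch.max_probability for nch in niches],
    })
    truth = SurveyTruth(niche_table=niche_table, overlap_pairs=overlap_pairs,
                        zone_map=planted_zone_map(env), p_true=p_true)
    return table, truth
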