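"""Monte Carlo randomization colocalization between two channels' clusters.

The colocalization of two molecular species in a rendered SMLM nucleus is
scored as the ratio of the observed overlap between their segmented clusters
to the overlap expected by chance in that same nucleus. The chance level is
estimated by rigidly relocating each cluster of one channel (the protein
channel) to a uniformly random position inside the nucleus ROI — keeping the
other channel's "real" distribution — and averaging the overlap over 20 such
randomizations. A coefficient of 1 means the observed overlap is exactly the
random expectation; 2 means twice random, and so on. The randomization
normalizes for nucleus area and for cell-to-cell differences in cluster
density, so coefficients are comparable across cells, timepoints, and
conditions.

Overlap can be measured as a count (number of fixed-channel clusters touching
at least one partner cluster) or as an area (nm^2 of the pixelwise mask
intersection). Count mode suits low-abundance factors (MRE11, BRCA1, CtIP,
BLM); area mode suits factors that accumulate into extended structures
(gammaH2AX, RPA, RAD51, RAD52, BRCA2).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import PlacementError, spawn_rng
from .render import Cluster, ClusterSet, GridSpec, NucleusROI

log = logging.getLogger(__name__)

DEFAULT_N_SIMS = 20

#: Default overlap mode per protein. Count of overlaps for transient,
#: low-copy factors; overlap area for accumulating ones.
PROTEIN_OVERLAP_MODE: dict[str, str] = {
    "MRE11": "number",
    "BRCA1": "number",
    "CtIP": "number",
    "BLM": "number",
    "gH2AX": "area",
    "γH2AX": "area",
    "RPA": "area",
    "RAD51": "area",
    "RAD52": "area",
    "BRCA2": "area",
}


def overlap_mode_for(protein: str) -> str:
    return PROTEIN_OVERLAP_MODE.get(protein, "area")


def count_overlaps(set_a: ClusterSet, set_b: ClusterSet) -> tuple[int, float]:
    """Overlap statistics between two cluster sets on the same grid.

    Returns ``(n_overlaps, overlap_area_nm2)``: the number of ``set_a``
    clusters whose mask intersects at least one ``set_b`` cluster
    (asymmetric; by convention ``set_a`` is the fixed / naDNA channel), and
    the total area of the pixelwise mask intersection (symmetric).
    """
    if set_a.grid != set_b.grid:
        raise ValueError("cluster sets are on different grids")
    mask_b = set_b.binary_mask()
    area = float(np.logical_and(set_a.binary_mask(), mask_b).sum()) * set_a.grid.pixel_area_nm2
    n = sum(1 for c in set_a.clusters if mask_b[c.rows, c.cols].any())
    return n, area


def randomize_clusters(
    cluster_set: ClusterSet,
    roi: NucleusROI,
    rng: np.random.Generator | int,
    max_tries: int = 10_000,
) -> ClusterSet:
    """Rigidly relocate every cluster to a uniform random in-ROI position.

    Each cluster's pixel mask is translated (no rotation or reflection) so
    that it lies fully inside the ROI; the anchor is drawn uniformly over the
    feasible translations by rejection sampling from the ROI pixels. Shapes
    and areas are preserved exactly; relocated clusters may overlap one
    another. Raises :class:`~nanofoci._util.PlacementError` if a cluster
    cannot be placed (it fits nowhere in the ROI).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    grid = cluster_set.grid
    roi_mask = roi.mask(grid)
    roi_rows, roi_cols = np.nonzero(roi_mask)
    if roi_rows.size == 0:
        raise PlacementError("ROI contains no pixels on this grid")
    n_rows, n_cols = grid.shape
    labels = np.zeros_like(cluster_set.label_image)
    new_clusters: list[Cluster] = []
    for c in cluster_set.clusters:
        placed = False
        for _ in range(max_tries):
            k = rng.integers(0, roi_rows.size)
            dr = int(roi_rows[k]) - int(c.rows[0])
            dc = int(roi_cols[k]) - int(c.cols[0])
            rr = c.rows + dr
            cc = c.cols + dc
            if rr.min() < 0 or rr.max() >= n_rows or cc.min() < 0 or cc.max() >= n_cols:
                continue
            if roi_mask[rr, cc].all():
                placed = True
                break
        if not placed:
            raise PlacementError(f"cluster {c.id} ({c.n_pixels} px) cannot be placed inside the ROI")
        labels[rr, cc] = c.id
        new_clusters.append(
            Cluster(
                id=c.id,
                channel=c.channel,
                rows=rr,
                cols=cc,
                intensities=c.intensities,
                area_nm2=c.area_nm2,
                com_nm=(c.com_nm[0] + dc * grid.pixel_nm, c.com_nm[1] + dr * grid.pixel_nm),
            )
        )
    return ClusterSet(
        channel=cluster_set.channel,
        grid=grid,
        clusters=new_clusters,
        label_image=labels,
        threshold=cluster_set.threshold,
        roi=roi,
    )


@dataclass
class ColocalizationResult:
    """Observed and randomized overlaps for one nucleus and channel pair."""

    nucleus_id: str
    fixed_channel: str
    randomized_channel: str
    n_real: int
    area_real_nm2: float
    sim_counts: np.ndarray
    sim_areas_nm2: np.ndarray
    seed: int
    #: True when the simulated overlaps averaged zero, leaving the
    #: coefficient undefined; such nuclei are excluded from population means.
    insufficient_randomization_overlap: bool = False

    @property
    def n_sims(self) -> int:
        return len(self.sim_counts)

    @property
    def coefficient_number(self) -> float:
        m = float(np.mean(self.sim_counts))
        return float(self.n_real) / m if m > 0 else float("nan")

    @property
    def coefficient_area(self) -> float:
        m = float(np.mean(self.sim_areas_nm2))
        return self.area_real_nm2 / m if m > 0 else float("nan")

    def coefficient(self, mode: str = "area") -> float:
        if mode == "area":
            return self.coefficient_area
        if mode == "number":
            return self.coefficient_number
        raise ValueError(f"unknown overlap mode {mode!r}")

    def to_dict(self) -> dict:
        return {
            "nucleus_id": self.nucleus_id,
            "fixed_channel": self.fixed_channel,
            "randomized_channel": self.randomized_channel,
            "n_real": self.n_real,
            "area_real_nm2": self.area_real_nm2,
            "sim_counts": np.asarray(self.sim_counts).tolist(),
            "sim_areas_nm2": np.asarray(self.sim_areas_nm2).tolist(),
            "n_sims": self.n_sims,
            "coefficient_number": None if np.isnan(self.coefficient_number) else self.coefficient_number,
            "coefficient_area": None if np.isnan(self.coefficient_area) else self.coefficient_area,
            "seed": self.seed,
            "insufficient_randomization_overlap": self.insufficient_randomization_overlap,
        }


def normalize_overlap(observed: float, simulated: Sequence[float]) -> float:
    """The colocalization coefficient: observed overlap over the simulation mean.

    Exactly 1 when the observation equals the mean of the randomizations;
    2 when the observed overlap doubles the random expectation.
    """
    m = float(np.mean(simulated))
    if m <= 0:
        return float("nan")
    return float(observed) / m


def colocalization_coefficient(
    set_fixed: ClusterSet,
    set_random: ClusterSet,
    roi: NucleusROI,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int = 0,
    nucleus_id: str = "0",
) -> ColocalizationResult:
    """Compute the randomization colocalization coefficient for one nucleus.

    The protein channel (``set_random``) is relocated ``n_sims`` times with
    deterministic sub-seeds derived from ``seed``; the real overlap count and
    area are ratioed to the simulation means. Both the count-based and the
    area-based coefficient are recorded, along with every simulated value.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    n_real, area_real = count_overlaps(set_fixed, set_random)
    sim_counts = np.empty(n_sims, int)
    sim_areas = np.empty(n_sims, float)
    for i in range(n_sims):
        shuffled = randomize_clusters(set_random, roi, spawn_rng(seed, i))
        sim_counts[i], sim_areas[i] = count_overlaps(set_fixed, shuffled)
    flagged = bool(np.mean(sim_counts) == 0 or np.mean(sim_areas) == 0)
    if flagged:
        log.warning("nucleus %s: zero mean simulated overlap; coefficient undefined", nucleus_id)
    return ColocalizationResult(
        nucleus_id=nucleus_id,
        fixed_channel=set_fixed.channel,
        randomized_channel=set_random.channel,
        n_real=n_real,
        area_real_nm2=area_real,
        sim_counts=sim_counts,
        sim_areas_nm2=sim_areas,
        seed=seed,
        insufficient_randomization_overlap=flagged,
    )


def csr_null_experiment(
    n_nuclei: int = 100,
    n_clusters_per_channel: int = 50,
    radius_range_nm: tuple[float, float] = (40.0, 100.0),
    roi_diameter_nm: float = 10_000.0,
    pixel_nm: float = 20.0,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int = 0,
    mode: str = "area",
) -> np.ndarray:
    """Calibration of the coefficient under complete spatial randomness (CSR).

    For each synthetic nucleus (circular ROI), both channels' disc-shaped
    clusters are placed uniformly at random within the ROI — i.e. drawn from
    the same distribution the randomizer uses — and the coefficient is
    computed with ``n_sims`` randomizations. Returns the per-nucleus
    coefficients; their mean estimates the null expectation of 1. Nuclei
    with undefined coefficients (zero mean simulated overlap) return NaN.
    """
    from .render import GridSpec, NucleusROI, disc_cluster_set

    r = roi_diameter_nm / 2.0
    roi = NucleusROI.from_ellipse((0.0, 0.0), (r, r))
    grid = roi.default_grid(pixel_nm)
    roi_mask = roi.mask(grid)
    coefs = np.empty(n_nuclei)
    for k in range(n_nuclei):
        rng = spawn_rng(seed, 7, k)
        sets = {}
        for ch in ("A", "B"):
            centers = _uniform_contained_discs(rng, roi, roi_mask, grid, n_clusters_per_channel, radius_range_nm)
            sets[ch] = disc_cluster_set(centers[0], centers[1], grid, ch, roi)
        res = colocalization_coefficient(sets["A"], sets["B"], roi, n_sims=n_sims, seed=int(rng.integers(2**31 - 1)), nucleus_id=str(k))
        coefs[k] = res.coefficient(mode)
    return coefs


def _uniform_contained_discs(
    rng: np.random.Generator,
    roi: NucleusROI,
    roi_mask: np.ndarray,
    grid,
    n: int,
    radius_range_nm: tuple[float, float],
    max_tries: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Disc centers/radii drawn uniformly over placements fully inside the ROI."""
    from skimage.draw import disk

    x_min, y_min, x_max, y_max = roi.bounds()
    px = grid.pixel_nm
    x0, y0 = grid.origin_nm
    centers = np.empty((n, 2))
    radii = rng.uniform(*radius_range_nm, size=n)
    for i in range(n):
        for _ in range(max_tries):
            cx = rng.uniform(x_min, x_max)
            cy = rng.uniform(y_min, y_max)
            rr, cc = disk(((cy - y0) / px - 0.5, (cx - x0) / px - 0.5), radii[i] / px, shape=grid.shape)
            if rr.size and roi_mask[rr, cc].all():
                centers[i] = (cx, cy)
                break
        else:
            raise PlacementError(f"disc {i} (r = {radii[i]:.0f} nm) does not fit in the ROI")
    return centers, radii


@dataclass
class PopulationSummary:
    condition: str
    timepoint_h: float
    coefficients: np.ndarray
    mean: float
    sem: float | None
    n_cells: int
    p_value: float | None = None
    t_statistic: float | None = None
    significance: str = ""
    flagged: bool = False  # n < 2: no s.e.m. / test


def significance_stars(p: float | None) -> str:
    """The conventional star tiers at 0.05 / 0.01 / 0.001 / 0.0001."""
    if p is None or np.isnan(p):
        return ""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p < cut:
            return stars
    return "ns"


_EPS_VAR = 1e-12


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float, bool]:
    """Welch two-sample t test with an epsilon-variance guard for degenerate groups."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    degenerate = va == 0.0 and vb == 0.0
    if degenerate:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0, True
        se = np.sqrt(_EPS_VAR / len(a) + _EPS_VAR / len(b))
        t = (np.mean(a) - np.mean(b)) / se
        df = len(a) + len(b) - 2
        p = 2.0 * stats.t.sf(abs(t), df)
        return float(t), float(p), True
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), False


def summarize_population(
    results: Mapping[tuple[str, float], Sequence[float]],
    reference_condition: str | None = None,
) -> list[PopulationSummary]:
    """Per-(condition, timepoint) mean, s.e.m., and Welch t test vs a reference.

    ``results`` maps (condition, timepoint_h) to per-cell coefficients;
    NaN coefficients (flagged nuclei) are excluded. The reference group is
    the ``reference_condition`` at the same timepoint if it exists, else the
    pooled reference condition.
    """
    groups = {k: np.asarray([v for v in vals if not np.isnan(v)], float) for k, vals in results.items()}
    ref_pool = None
    if reference_condition is not None:
        ref_all = [g for (cond, _), g in groups.items() if cond == reference_condition]
        if ref_all:
            ref_pool = np.concatenate(ref_all)
    out = []
    for (cond, tp), vals in groups.items():
        n = len(vals)
        mean = float(np.mean(vals)) if n else float("nan")
        sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n >= 2 else None
        t_stat = p = None
        if reference_condition is not None and cond != reference_condition and ref_pool is not None:
            ref = groups.get((reference_condition, tp), ref_pool)
            if n >= 2 and len(ref) >= 2:
                t_stat, p, degenerate = _welch(vals, ref)
                if degenerate:
                    log.warning("group (%s, %s): zero-variance t test, epsilon guard applied", cond, tp)
        out.append(
            PopulationSummary(
                condition=cond,
                timepoint_h=tp,
                coefficients=vals,
                mean=mean,
                sem=sem,
                n_cells=n,
                p_value=p,
                t_statistic=t_stat,
                significance=significance_stars(p),
                flagged=n < 2,
            )
        )
    return out


def build_timecourse_heatmap(summaries: Iterable[PopulationSummary], proteins: Sequence[str] | None = None) -> pd.DataFrame:
    """Protein x timepoint matrix of mean coefficients (conditions are proteins here).

    Missing (protein, timepoint) cells are left NaN; duplicate entries raise.
    """
    summaries = list(summaries)
    if not summaries:
        log.warning("build_timecourse_heatmap: empty input")
        return pd.DataFrame()
    seen = set()
    for s in summaries:
        key = (s.condition, s.timepoint_h)
        if key in seen:
            raise ValueError(f"duplicate (protein, timepoint) entry {key}")
        seen.add(key)
    df = pd.DataFrame([(s.condition, s.timepoint_h, s.mean) for s in summaries], columns=["protein", "timepoint_h", "mean"])
    mat = df.pivot(index="protein", columns="timepoint_h", values="mean")
    if proteins is not None:
        mat = mat.reindex(proteins)
    return mat
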