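"""Multi-channel repair-focus identification and intrafoci spatial statistics.

A repair focus is a nascent-DNA (naDNA) cluster together with the protein
clusters associated with it. Foci are classified by which proteins are
present (e.g. RPA-only / RAD51-only / both), yielding population fractions
over a nucleus or cohort, and — when two proteins co-occupy a focus — by the
distance between their clusters' centers of mass. The histogram of these
intrafoci distances is fitted with one or two Gaussians. A reference model
derived from double-labeled RAD51 (two labels on the same protein species,
i.e. maximal physical association) places closely associated proteins at a
center-of-mass separation of 135 nm with a 75 nm FWHM; a fitted single
Gaussian whose center falls within 135 +/- 37.5 nm is therefore classified
*proximal*, one centered beyond 180 nm *distal*, and histograms needing a
second free Gaussian on top of the fixed 135/75 component are *mixed*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial import cKDTree

from ._util import fwhm_to_sd, sd_to_fwhm
from .render import ClusterSet

log = logging.getLogger(__name__)

DEFAULT_ASSOCIATION_RADIUS_NM = 250.0

#: Reference ("proximal") component: center and FWHM of the intrafoci
#: distance Gaussian measured on double-labeled RAD51.
REFERENCE_CENTER_NM = 135.0
REFERENCE_FWHM_NM = 75.0
#: Single-Gaussian classification bands.
PROXIMAL_BAND_NM = (REFERENCE_CENTER_NM - 37.5, REFERENCE_CENTER_NM + 37.5)  # [97.5, 172.5]
DISTAL_MIN_NM = 180.0


class FittingError(RuntimeError):
    """Distance-histogram fit failed to converge."""


@dataclass
class FocusRecord:
    """One identified focus: a naDNA cluster plus associated protein clusters.

    Only naDNA clusters with at least one associated protein become records;
    protein-negative naDNA clusters are counted but not recorded.
    """

    nucleus_id: str
    nadna_cluster_id: int
    nadna_com_nm: tuple[float, float]
    presence: dict[str, bool]
    associated: dict[str, list[int]]  # protein -> associated cluster ids
    #: Intensity-weighted center of mass of the protein's signal at this
    #: focus, combined over all its associated clusters (robust to a single
    #: physical structure segmenting into several fragments).
    protein_com_nm: dict[str, tuple[float, float]]

    def pair_distance_nm(self, protein_a: str, protein_b: str) -> float | None:
        """Euclidean distance between the two proteins' centers of mass at
        this focus, when both are present."""
        if not (self.presence.get(protein_a) and self.presence.get(protein_b)):
            return None
        ax, ay = self.protein_com_nm[protein_a]
        bx, by = self.protein_com_nm[protein_b]
        return float(np.hypot(ax - bx, ay - by))


def identify_foci(
    nadna: ClusterSet,
    proteins: Mapping[str, ClusterSet],
    association_radius_nm: float = DEFAULT_ASSOCIATION_RADIUS_NM,
    nucleus_id: str = "0",
) -> tuple[list[FocusRecord], int]:
    """Associate protein clusters with naDNA clusters to build focus records.

    A protein is *present* at a naDNA cluster if any of its clusters either
    intersects the naDNA pixel mask or has its center of mass within
    ``association_radius_nm`` of the naDNA center of mass. Returns the focus
    records (naDNA clusters with >= 1 protein present) and the count of
    protein-negative naDNA clusters.
    """
    for name, cs in proteins.items():
        if cs.grid != nadna.grid:
            raise ValueError(f"protein {name!r} cluster set is on a different grid than naDNA")
    trees = {}
    for name, cs in proteins.items():
        coms = cs.centers_of_mass()
        trees[name] = cKDTree(coms) if len(coms) else None
    records: list[FocusRecord] = []
    n_negative = 0
    for c in nadna.clusters:
        presence: dict[str, bool] = {}
        associated: dict[str, list[int]] = {}
        nearest_com: dict[str, tuple[float, float]] = {}
        for name, cs in proteins.items():
            ids: set[int] = set()
            # pixel intersection: overlap implies presence regardless of distance
            hit_labels = np.unique(cs.label_image[c.rows, c.cols])
            ids.update(int(l) for l in hit_labels if l > 0)
            # center-of-mass proximity
            if trees[name] is not None:
                near = trees[name].query_ball_point(c.com_nm, association_radius_nm)
                ids.update(cs.clusters[i].id for i in near)
            presence[name] = bool(ids)
            associated[name] = sorted(ids)
            if ids:
                by_id = {cl.id: cl for cl in cs.clusters}
                weights = np.array([by_id[i].intensities.sum() for i in associated[name]])
                coms = np.array([by_id[i].com_nm for i in associated[name]])
                wsum = weights.sum()
                nearest_com[name] = tuple((coms * weights[:, None]).sum(axis=0) / wsum)
        if any(presence.values()):
            records.append(
                FocusRecord(
                    nucleus_id=nucleus_id,
                    nadna_cluster_id=c.id,
                    nadna_com_nm=c.com_nm,
                    presence=presence,
                    associated=associated,
                    protein_com_nm=nearest_com,
                )
            )
        else:
            n_negative += 1
    return records, n_negative


@dataclass
class PopulationFractions:
    """Per-class focus fractions for a protein pair, plus interdependency
    descriptors (prevalence, directional dependence, exclusion flag)."""

    protein_a: str
    protein_b: str
    fractions: dict[str, float]  # {"<A>-only", "<B>-only", "both"}
    n_foci: int
    prevalence: float  # fraction of foci positive for both
    dependence_a_on_b: float  # fraction of B-positive foci also A-positive
    dependence_b_on_a: float
    #: True when P(both) falls below the independence product P(A) * P(B):
    #: the two proteins co-occur less often than chance, suggesting exclusion.
    exclusion: bool


def classify_population(records: Sequence[FocusRecord], protein_a: str, protein_b: str) -> PopulationFractions:
    """Fractions of A-only / B-only / both foci among foci positive for either.

    Foci positive for neither protein of the pair (possible in three-color
    data) are ignored. Fractions sum to 1.
    """
    if not records:
        raise ValueError("empty focus list")
    n_a_only = n_b_only = n_both = 0
    for r in records:
        a = bool(r.presence.get(protein_a))
        b = bool(r.presence.get(protein_b))
        if a and b:
            n_both += 1
        elif a:
            n_a_only += 1
        elif b:
            n_b_only += 1
    n = n_a_only + n_b_only + n_both
    if n == 0:
        raise ValueError(f"no focus is positive for {protein_a!r} or {protein_b!r}")
    p_a = (n_a_only + n_both) / n
    p_b = (n_b_only + n_both) / n
    p_both = n_both / n
    return PopulationFractions(
        protein_a=protein_a,
        protein_b=protein_b,
        fractions={f"{protein_a}-only": n_a_only / n, f"{protein_b}-only": n_b_only / n, "both": p_both},
        n_foci=n,
        prevalence=p_both,
        dependence_a_on_b=n_both / (n_b_only + n_both) if (n_b_only + n_both) else float("nan"),
        dependence_b_on_a=n_both / (n_a_only + n_both) if (n_a_only + n_both) else float("nan"),
        exclusion=bool(p_both < p_a * p_b),
    )


def intrafoci_distances(records: Sequence[FocusRecord], protein_a: str, protein_b: str) -> np.ndarray:
    """Center-of-mass distances (nm) at foci where both proteins are present."""
    d = [r.pair_distance_nm(protein_a, protein_b) for r in records]
    out = np.array([x for x in d if x is not None], float)
    if out.size == 0:
        log.warning("intrafoci_distances: no focus carries both %s and %s", protein_a, protein_b)
    return out


@dataclass
class GaussianComponent:
    center_nm: float
    fwhm_nm: float
    amplitude: float
    fixed: bool = False

    @property
    def sd_nm(self) -> float:
        return fwhm_to_sd(self.fwhm_nm)


@dataclass
class DistanceFit:
    """Single- or double-Gaussian fit of an intrafoci distance histogram."""

    model: str  # "single" | "double"
    components: list[GaussianComponent]
    classification: str  # proximal | distal | mixed | indeterminate
    rss: float
    r_squared: float
    n_distances: int
    bin_width_nm: float
    bin_centers_nm: np.ndarray = field(default_factory=lambda: np.empty(0))
    counts: np.ndarray = field(default_factory=lambda: np.empty(0))

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        out = np.zeros_like(x)
        for c in self.components:
            out += c.amplitude * np.exp(-((x - c.center_nm) ** 2) / (2.0 * c.sd_nm**2))
        return out

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "components": [
                {"center_nm": c.center_nm, "fwhm_nm": c.fwhm_nm, "amplitude": c.amplitude, "fixed": c.fixed}
                for c in self.components
            ],
            "classification": self.classification,
            "rss": self.rss,
            "r_squared": self.r_squared,
            "n_distances": self.n_distances,
            "bin_width_nm": self.bin_width_nm,
        }


def classify_single_center(center_nm: float) -> str:
    """Classify a fitted single-Gaussian center.

    proximal for centers within the reference band [97.5, 172.5] nm
    (inclusive); distal beyond 180 nm; indeterminate in the unassigned gap
    (172.5, 180] and below 97.5 nm.
    """
    lo, hi = PROXIMAL_BAND_NM
    if lo <= center_nm <= hi:
        return "proximal"
    if center_nm > DISTAL_MIN_NM:
        return "distal"
    return "indeterminate"


def _gauss(x, a, c, s):
    return a * np.exp(-((x - c) ** 2) / (2.0 * s**2))


def _fit(x: np.ndarray, y: np.ndarray, model_fn, p0, bounds) -> tuple[np.ndarray, float]:
    # Poisson counting weights, taken from the model expectation rather than
    # the observed counts (weighting by observed counts biases the fitted
    # width low: downward-fluctuating bins get overweighted). One unweighted
    # pass seeds the expectation, then a reweighted pass refines it.
    try:
        popt, _ = optimize.curve_fit(model_fn, x, y, p0=p0, bounds=bounds, maxfev=20_000)
        sigma = np.sqrt(np.maximum(model_fn(x, *popt), 1.0))
        popt, _ = optimize.curve_fit(model_fn, x, y, p0=popt, sigma=sigma, bounds=bounds, maxfev=20_000)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FittingError(f"Gaussian fit did not converge: {exc}") from exc
    rss = float(np.sum((y - model_fn(x, *popt)) ** 2))
    return popt, rss


def fit_distance_distribution(
    distances: np.ndarray,
    bin_width_nm: float = 10.0,
    model: str = "auto",
) -> DistanceFit:
    """Fit an intrafoci distance histogram with one or two Gaussians.

    Distances are binned at ``bin_width_nm``; fits are least squares on the
    bin centers with Poisson counting weights. In double mode, component 1 is
    fixed at the 135 nm / 75 nm FWHM reference with a free amplitude while
    component 2 (center, FWHM, amplitude) is fully free. ``model="auto"``
    fits the single model first and adopts the double model only when it
    reduces the residual sum of squares by more than 50% and an F test at
    alpha = 0.05 favors it. Classification follows the fitted single center
    (:func:`classify_single_center`); accepted double fits are "mixed".
    """
    distances = np.asarray(distances, float)
    distances = distances[np.isfinite(distances)]
    if distances.size < 50:
        log.warning("fit_distance_distribution: only %d distances; fit may be unstable", distances.size)
    if distances.size < 5:
        raise FittingError(f"need at least 5 distances, got {distances.size}")
    hi = max(distances.max() + bin_width_nm, 3 * bin_width_nm)
    edges = np.arange(0.0, hi + bin_width_nm, bin_width_nm)
    counts, _ = np.histogram(distances, bins=edges)
    centers = edges[:-1] + bin_width_nm / 2.0

    ref_sd = fwhm_to_sd(REFERENCE_FWHM_NM)
    # single: amplitude, center, sd
    p0_single = [counts.max(), float(np.average(centers, weights=np.maximum(counts, 1e-9))), max(np.std(distances), bin_width_nm)]
    popt_s, rss_s = _fit(
        centers, counts, _gauss, p0_single, bounds=([0.0, 0.0, bin_width_nm / 10.0], [np.inf, np.inf, np.inf])
    )

    def _double(x, a1, a2, c2, s2):
        return _gauss(x, a1, REFERENCE_CENTER_NM, ref_sd) + _gauss(x, a2, c2, s2)

    result_model = "single"
    if model not in ("single", "double", "auto"):
        raise ValueError(f"unknown model {model!r}")
    popt_d = rss_d = None
    if model in ("double", "auto"):
        far = distances[distances > PROXIMAL_BAND_NM[1]]
        c2_guess = float(np.mean(far)) if far.size else REFERENCE_CENTER_NM + 150.0
        p0_double = [counts.max() / 2.0, counts.max() / 2.0, c2_guess, max(np.std(distances) / 2.0, bin_width_nm)]
        try:
            popt_d, rss_d = _fit(
                centers,
                counts,
                _double,
                p0_double,
                bounds=([0.0, 0.0, 0.0, bin_width_nm / 10.0], [np.inf, np.inf, np.inf, np.inf]),
            )
        except FittingError:
            if model == "double":
                raise
            popt_d = None
    if model == "double":
        result_model = "double"
    elif model == "auto" and popt_d is not None and rss_s > 0:
        n_bins = len(centers)
        df2 = n_bins - 4
        if rss_d < 0.5 * rss_s and df2 > 0 and rss_d > 0:
            f_stat = ((rss_s - rss_d) / 1.0) / (rss_d / df2)
            p_f = stats.f.sf(f_stat, 1, df2)
            if p_f < 0.05:
                result_model = "double"

    if result_model == "single":
        a, c, s = popt_s
        components = [GaussianComponent(center_nm=float(c), fwhm_nm=sd_to_fwhm(s), amplitude=float(a))]
        rss = rss_s
        classification = classify_single_center(float(c))
    else:
        a1, a2, c2, s2 = popt_d
        components = [
            GaussianComponent(center_nm=REFERENCE_CENTER_NM, fwhm_nm=REFERENCE_FWHM_NM, amplitude=float(a1), fixed=True),
            GaussianComponent(center_nm=float(c2), fwhm_nm=sd_to_fwhm(s2), amplitude=float(a2)),
        ]
        rss = rss_d
        classification = "mixed"
    tss = float(np.sum((counts - counts.mean()) ** 2))
    return DistanceFit(
        model=result_model,
        components=components,
        classification=classification,
        rss=float(rss),
        r_squared=1.0 - rss / tss if tss > 0 else float("nan"),
        n_distances=int(distances.size),
        bin_width_nm=bin_width_nm,
        bin_centers_nm=centers,
        counts=counts,
    )


def likelihood_map_2d(fit: DistanceFit, pixel_nm: float = 5.0, pad_sd: float = 3.0) -> np.ndarray:
    """Expand a distance fit into a radially symmetric 2D likelihood map.

    Each fitted component becomes a circular ridge at radius equal to its
    center, with a Gaussian cross-section of the component's FWHM and height
    proportional to its fitted amplitude; the map is normalized to a maximum
    of 1. This is a presentation aid for where a partner protein is likely
    to sit relative to a focus, not a statistical estimator.
    """
    half = max(c.center_nm + pad_sd * max(c.sd_nm, 1e-6) for c in fit.components)
    n = int(np.ceil(2.0 * half / pixel_nm)) | 1  # odd size so the origin is a pixel center
    ax = (np.arange(n) - n // 2) * pixel_nm
    rr = np.hypot(ax[:, None], ax[None, :])
    img = np.zeros_like(rr)
    for c in fit.components:
        s = max(c.sd_nm, 1e-6)
        img += c.amplitude * np.exp(-((rr - c.center_nm) ** 2) / (2.0 * s**2))
    m = img.max()
    return img / m if m > 0 else img


def fractions_table(fractions: PopulationFractions) -> pd.DataFrame:
    """Cumulative-bar-graph-ready table of the class fractions (percent)."""
    rows = [{"class": k, "fraction": v, "percent": 100.0 * v, "n_foci": fractions.n_foci} for k, v in fractions.fractions.items()]
    return pd.DataFrame(rows)
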