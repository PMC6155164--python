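"""Seeded synthetic SMLM scenes with known ground truth.

No public localization data exist for the repair-focus experiments this
package analyzes, so validation runs on synthetic scenes that emulate their
statistical structure: a nucleus ROI containing nascent-DNA (naDNA)
replication/repair foci, protein clusters per color channel with a
configurable colocalized fraction and per-focus class mixture (e.g.
RPA-only / mixed / RAD51-only), a Gaussian model for the displacement of a
colocalized protein cluster from its focus center (reference: 135 nm center,
75 nm FWHM), uniform background localizations, per-localization precision
noise, polynomially warped fiducial bead fields, and optionally raw camera
frames for the localization stage. Every generator records its ground truth
so that downstream estimates can be scored against it.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import ConfigurationError, PlacementError, fwhm_to_sd, spawn_rng
from .chromatic import evaluate_polynomial, identity_coefficients
from .render import NucleusROI

log = logging.getLogger(__name__)

#: Default per-channel localization precision (nm s.d.), from typical fitting
#: uncertainties of the three imaging channels (red / blue / green).
CHANNEL_PRECISION_NM: dict[str, float] = {"red": 9.5, "blue": 9.3, "green": 17.7}
DEFAULT_PRECISION_NM = 10.0

NADNA_CHANNEL = "naDNA"

#: RPA/RAD51 focus-class mixtures observed at repair foci during early
#: nucleofilament formation (2 h after damage) and later homology search
#: (8 h): the early population is dominated by RPA-only filaments (71.4%)
#: with a mixed subpopulation (22.1%); by 8 h RAD51-only filaments dominate
#: (48.7%) with mixed filaments persisting (42.1%).
RPA_RAD51_MIXTURE_2H: dict[str, float] = {"RPA-only": 0.714, "both": 0.221, "RAD51-only": 0.065}
RPA_RAD51_MIXTURE_8H: dict[str, float] = {"RPA-only": 0.092, "both": 0.421, "RAD51-only": 0.487}

MAX_PLACEMENT_TRIES = 10_000

LOC_COLUMNS = ["x_nm", "y_nm", "frame", "channel", "intensity", "precision_nm"]


@dataclass(frozen=True)
class DisplacementModel:
    """Scalar distance model for a colocalized protein cluster's offset
    from its focus center: Gaussian in distance, uniform in direction."""

    center_nm: float = 135.0
    fwhm_nm: float = 75.0

    @property
    def sd_nm(self) -> float:
        return fwhm_to_sd(self.fwhm_nm)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        # Distances are magnitudes; the Gaussian mass below zero is
        # negligible for the reference model (135/32 s.d. from zero) but is
        # folded back to keep samples non-negative in general.
        return np.abs(rng.normal(self.center_nm, self.sd_nm, size=n))


def resolve_class_channels(name: str, channels: Sequence[str]) -> tuple[str, ...]:
    """Map a focus-class name to the protein channels present in that class.

    Recognized forms: ``"X-only"`` (channel X alone), ``"X+Y"`` (both),
    ``"both"`` / ``"mixed"`` / ``"all"`` (every protein channel), or a bare
    channel name. Unknown names raise :class:`ConfigurationError`.
    """
    if name in ("both", "mixed", "all"):
        return tuple(channels)
    if name.endswith("-only"):
        base = name[: -len("-only")]
        if base in channels:
            return (base,)
        raise ConfigurationError(f"class {name!r}: channel {base!r} not among {list(channels)}")
    if "+" in name:
        parts = tuple(p.strip() for p in name.split("+"))
        missing = [p for p in parts if p not in channels]
        if missing:
            raise ConfigurationError(f"class {name!r}: unknown channels {missing}")
        return parts
    if name in channels:
        return (name,)
    raise ConfigurationError(f"unknown focus class {name!r} for channels {list(channels)}")


def _validate_mixture(mixture: Mapping[str, float], channels: Sequence[str]) -> None:
    total = float(sum(mixture.values()))
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"class mixture sums to {total!r}, not 1")
    if any(p < 0 or p > 1 for p in mixture.values()):
        raise ConfigurationError("class probabilities must lie in [0, 1]")
    for name in mixture:
        resolve_class_channels(name, channels)


@dataclass
class SceneConfig:
    """Parameters of one synthetic nucleus scene.

    Defaults describe a mid-sized nucleus (10 um circle) with 50 replication
    foci and two protein channels whose clusters are 40-100 nm in radius.
    """

    nucleus_axes_nm: tuple[float, float] = (5000.0, 5000.0)  # semi-axes of an elliptical nucleus
    nucleus_polygon: Sequence[tuple[float, float]] | None = None  # overrides the ellipse if given
    n_nadna_foci: int = 50
    n_protein_clusters: dict[str, int] = field(default_factory=lambda: {"RPA": 50, "RAD51": 50})
    cluster_radius_range_nm: tuple[float, float] = (40.0, 100.0)
    colocalized_fraction: dict[str, float] | float = 0.5
    class_mixture: dict[str, float] | None = None
    displacement: DisplacementModel = field(default_factory=DisplacementModel)
    background_density_um2: float = 1.0
    #: Mean localizations per cluster. Fluorophores re-blink over the frame
    #: sequence, so one protein cluster accumulates on the order of 10^2
    #: localizations.
    locs_per_cluster: float = 150.0
    locs_per_focus: float | None = None  # naDNA clusters; defaults to locs_per_cluster
    localization_precision_nm: dict[str, float] | float | None = None
    nadna_channel: str = NADNA_CHANNEL
    n_frames: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.cluster_radius_range_nm
        if not (0 < lo <= hi):
            raise ConfigurationError("cluster radii must be strictly positive and ordered")
        if self.background_density_um2 < 0:
            raise ConfigurationError("background density must be >= 0")
        fracs = self.fraction_for
        for ch in self.protein_channels:
            f = fracs(ch)
            if not (0.0 <= f <= 1.0):
                raise ConfigurationError(f"colocalized fraction for {ch!r} must be in [0, 1]")
        if self.class_mixture is not None:
            _validate_mixture(self.class_mixture, self.protein_channels)
        prec = self.localization_precision_nm
        if isinstance(prec, (int, float)) and prec <= 0:
            raise ConfigurationError("localization precision must be strictly positive")

    @property
    def protein_channels(self) -> tuple[str, ...]:
        return tuple(self.n_protein_clusters)

    def fraction_for(self, channel: str) -> float:
        f = self.colocalized_fraction
        return float(f) if isinstance(f, (int, float)) else float(f.get(channel, 0.0))

    def precision_for(self, channel: str) -> float:
        p = self.localization_precision_nm
        if isinstance(p, (int, float)):
            return float(p)
        if isinstance(p, Mapping) and channel in p:
            return float(p[channel])
        return CHANNEL_PRECISION_NM.get(channel, DEFAULT_PRECISION_NM)

    def roi(self) -> NucleusROI:
        if self.nucleus_polygon is not None:
            return NucleusROI(polygon=self.nucleus_polygon)
        return NucleusROI.from_ellipse((0.0, 0.0), self.nucleus_axes_nm)


@dataclass
class GroundTruth:
    """Everything the generator decided: focus positions and classes, every
    cluster's channel/center/size and focus link, and any bead-field warp."""

    focus_centers_nm: np.ndarray  # (n_foci, 2)
    focus_classes: list[str]
    clusters: pd.DataFrame  # cluster_id, channel, x_nm, y_nm, radius_nm, n_locs, focus_id (-1 = free)
    warp_coefficients: dict | None = None

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.focus_classes:
            out[c] = out.get(c, 0) + 1
        return out

    def to_json(self, path) -> None:
        payload = {
            "focus_centers_nm": self.focus_centers_nm.tolist(),
            "focus_classes": self.focus_classes,
            "clusters": self.clusters.to_dict(orient="list"),
            "warp_coefficients": self.warp_coefficients,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass
class SceneResult:
    locs: pd.DataFrame
    roi: NucleusROI
    truth: GroundTruth


def _sample_in_roi(roi: NucleusROI, rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform points inside the ROI polygon via rejection from the bounding box."""
    if n == 0:
        return np.empty((0, 2))
    x_min, y_min, x_max, y_max = roi.bounds()
    out = np.empty((n, 2))
    got = 0
    for _ in range(MAX_PLACEMENT_TRIES):
        need = n - got
        cand = np.column_stack(
            [rng.uniform(x_min, x_max, size=2 * need + 16), rng.uniform(y_min, y_max, size=2 * need + 16)]
        )
        inside = roi.contains(cand[:, 0], cand[:, 1])
        take = cand[inside][:need]
        out[got : got + len(take)] = take
        got += len(take)
        if got == n:
            return out
    raise PlacementError(f"could not place {n} points in ROI after {MAX_PLACEMENT_TRIES} rounds")


def _cluster_locs(
    rng: np.random.Generator,
    center: np.ndarray,
    radius_nm: float,
    n_locs: int,
    precision_nm: float,
    channel: str,
    n_frames: int,
) -> pd.DataFrame:
    """Member localizations of one cluster: isotropic Gaussian of
    s.d. = radius/2 around the center, plus isotropic precision noise."""
    pos = center + rng.normal(0.0, radius_nm / 2.0, size=(n_locs, 2))
    pos += rng.normal(0.0, precision_nm, size=(n_locs, 2))
    return pd.DataFrame(
        {
            "x_nm": pos[:, 0],
            "y_nm": pos[:, 1],
            "frame": rng.integers(0, n_frames, size=n_locs),
            "channel": channel,
            "intensity": rng.lognormal(math.log(1000.0), 0.3, size=n_locs),
            "precision_nm": precision_nm,
        }
    )


def _draw_n_locs(rng: np.random.Generator, mean: float, n: int) -> np.ndarray:
    """Per-cluster localization counts: log-normal (shape sigma=0.4) with the
    requested mean, floored at 3 so every cluster is renderable."""
    sigma = 0.4
    mu = math.log(mean) - sigma**2 / 2.0
    return np.maximum(3, np.round(rng.lognormal(mu, sigma, size=n))).astype(int)


def _background(rng: np.random.Generator, roi: NucleusROI, density_um2: float, channel: str, precision_nm: float, n_frames: int) -> pd.DataFrame:
    n = int(rng.poisson(density_um2 * roi.area_um2))
    pos = _sample_in_roi(roi, rng, n)
    return pd.DataFrame(
        {
            "x_nm": pos[:, 0],
            "y_nm": pos[:, 1],
            "frame": rng.integers(0, n_frames, size=n),
            "channel": channel,
            "intensity": rng.lognormal(math.log(1000.0), 0.3, size=n),
            "precision_nm": precision_nm,
        }
    )


def generate_nucleus_scene(config: SceneConfig) -> SceneResult:
    """Generate one synthetic nucleus: naDNA foci, protein clusters, background.

    Each naDNA focus is a cluster in the naDNA channel; a per-focus class
    sampled from ``class_mixture`` (default: all protein channels present)
    decides which protein channels may attach colocalized clusters to it.
    For protein channel ``c`` with ``n`` requested clusters, ``round(f*n)``
    clusters (f = colocalized fraction) are attached to a uniformly chosen
    class-eligible focus and displaced from its center by a distance drawn
    from the displacement model in a uniform random direction; the rest are
    placed uniformly in the ROI (centers inside; tails may cross the
    boundary, as real foci touch the nuclear envelope). Output is
    bit-identical for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    roi = config.roi()
    channels = config.protein_channels
    n_foci = int(config.n_nadna_foci)
    focus_centers = _sample_in_roi(roi, rng, n_foci)

    if config.class_mixture is not None:
        names = list(config.class_mixture)
        probs = np.array([config.class_mixture[k] for k in names], float)
        focus_classes = [names[i] for i in rng.choice(len(names), size=n_foci, p=probs / probs.sum())]
    else:
        focus_classes = ["all"] * n_foci
    class_members = {name: resolve_class_channels(name, channels) for name in set(focus_classes)} if channels else {}

    frames = []
    truth_rows = []
    cluster_id = 0
    lo, hi = config.cluster_radius_range_nm
    locs_per_focus = config.locs_per_focus if config.locs_per_focus is not None else config.locs_per_cluster

    # naDNA foci
    radii = rng.uniform(lo, hi, size=n_foci)
    counts = _draw_n_locs(rng, locs_per_focus, n_foci)
    prec_na = config.precision_for(config.nadna_channel)
    for k in range(n_foci):
        frames.append(_cluster_locs(rng, focus_centers[k], radii[k], counts[k], prec_na, config.nadna_channel, config.n_frames))
        truth_rows.append((cluster_id, config.nadna_channel, *focus_centers[k], radii[k], counts[k], k))
        cluster_id += 1

    # protein clusters
    for ch in channels:
        n_total = int(config.n_protein_clusters[ch])
        if n_total == 0:
            continue
        f = config.fraction_for(ch)
        n_col = int(round(f * n_total))
        prec = config.precision_for(ch)
        eligible = [k for k in range(n_foci) if ch in class_members[focus_classes[k]]]
        if n_col > 0 and not eligible:
            raise PlacementError(f"channel {ch!r}: colocalized clusters requested but no focus class contains it")
        radii = rng.uniform(lo, hi, size=n_total)
        counts = _draw_n_locs(rng, config.locs_per_cluster, n_total)
        if n_col:
            hosts = rng.choice(eligible, size=n_col)
            dist = config.displacement.sample(rng, n_col)
            theta = rng.uniform(0.0, 2.0 * np.pi, size=n_col)
            centers_col = focus_centers[hosts] + np.column_stack([dist * np.cos(theta), dist * np.sin(theta)])
        else:
            hosts = np.empty(0, int)
            centers_col = np.empty((0, 2))
        centers_free = _sample_in_roi(roi, rng, n_total - n_col)
        centers = np.vstack([centers_col, centers_free])
        focus_ids = np.concatenate([hosts, np.full(n_total - n_col, -1, int)])
        for k in range(n_total):
            frames.append(_cluster_locs(rng, centers[k], radii[k], counts[k], prec, ch, config.n_frames))
            truth_rows.append((cluster_id, ch, *centers[k], radii[k], counts[k], int(focus_ids[k])))
            cluster_id += 1

    # uniform background in every channel
    for ch in (config.nadna_channel, *channels):
        frames.append(_background(rng, roi, config.background_density_um2, ch, config.precision_for(ch), config.n_frames))

    locs = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=LOC_COLUMNS)
    truth = GroundTruth(
        focus_centers_nm=focus_centers,
        focus_classes=focus_classes,
        clusters=pd.DataFrame(truth_rows, columns=["cluster_id", "channel", "x_nm", "y_nm", "radius_nm", "n_locs", "focus_id"]),
    )
    return SceneResult(locs=locs, roi=roi, truth=truth)


@dataclass
class FocusPopulation:
    """A population of well-separated synthetic foci laid out on a grid."""

    classes: list[str]  # ground-truth class per focus
    focus_centers_nm: np.ndarray
    locs: pd.DataFrame
    roi: NucleusROI
    truth: GroundTruth


def generate_focus_population(
    n_foci: int,
    class_mixture: Mapping[str, float],
    displacement: DisplacementModel | None = None,
    seed: int = 0,
    channels: Sequence[str] = ("RPA", "RAD51"),
    spacing_nm: float = 1500.0,
    cluster_radius_range_nm: tuple[float, float] = (40.0, 100.0),
    locs_per_cluster: float = 150.0,
    background_density_um2: float = 0.5,
    n_frames: int = 2000,
) -> FocusPopulation:
    """Generate ``n_foci`` isolated foci whose classes follow ``class_mixture``.

    Foci are laid out on a square grid with ``spacing_nm`` pitch (plus a small
    jitter) inside a rectangular ROI, so each focus can be identified and
    classified independently. Each focus carries a naDNA cluster at its
    center plus one cluster per protein channel in its sampled class. A
    single protein is displaced from the focus center by the displacement
    model (uniform direction). A colocalized pair is placed symmetrically
    about the focus center, separated by a distance drawn from the model:
    the pair's center-of-mass separation then follows the displacement
    distribution exactly, while each partner stays within ~half that
    distance of the naDNA center (both remain associated with the focus).
    """
    if n_foci < 1:
        raise ConfigurationError("n_foci must be >= 1")
    _validate_mixture(class_mixture, channels)
    displacement = displacement or DisplacementModel()
    rng = np.random.default_rng(seed)

    n_cols = int(math.ceil(math.sqrt(n_foci)))
    n_rows = int(math.ceil(n_foci / n_cols))
    margin = spacing_nm
    width = n_cols * spacing_nm + 2 * margin
    height = n_rows * spacing_nm + 2 * margin
    roi = NucleusROI(polygon=[(0.0, 0.0), (width, 0.0), (width, height), (0.0, height)])

    idx = np.arange(n_foci)
    gx = margin + (idx % n_cols + 0.5) * spacing_nm
    gy = margin + (idx // n_cols + 0.5) * spacing_nm
    jitter = rng.uniform(-0.1, 0.1, size=(n_foci, 2)) * spacing_nm
    centers = np.column_stack([gx, gy]) + jitter

    names = list(class_mixture)
    probs = np.array([class_mixture[k] for k in names], float)
    classes = [names[i] for i in rng.choice(len(names), size=n_foci, p=probs / probs.sum())]
    members = {name: resolve_class_channels(name, channels) for name in names}

    lo, hi = cluster_radius_range_nm
    frames = []
    truth_rows = []
    cluster_id = 0
    prec_na = CHANNEL_PRECISION_NM.get(NADNA_CHANNEL, DEFAULT_PRECISION_NM)
    for k in range(n_foci):
        r = rng.uniform(lo, hi)
        n = _draw_n_locs(rng, locs_per_cluster, 1)[0]
        frames.append(_cluster_locs(rng, centers[k], r, n, prec_na, NADNA_CHANNEL, n_frames))
        truth_rows.append((cluster_id, NADNA_CHANNEL, *centers[k], r, n, k))
        cluster_id += 1
        chans = members[classes[k]]
        if len(chans) >= 2:
            d = displacement.sample(rng, 1)[0]
            theta = rng.uniform(0.0, 2.0 * np.pi)
            u = np.array([np.cos(theta), np.sin(theta)])
            offsets = [centers[k] + 0.5 * d * u, centers[k] - 0.5 * d * u]
            # any further channels fall back to center displacement
            for _ in chans[2:]:
                dd = displacement.sample(rng, 1)[0]
                th = rng.uniform(0.0, 2.0 * np.pi)
                offsets.append(centers[k] + dd * np.array([np.cos(th), np.sin(th)]))
        else:
            offsets = []
            for _ in chans:
                dd = displacement.sample(rng, 1)[0]
                th = rng.uniform(0.0, 2.0 * np.pi)
                offsets.append(centers[k] + dd * np.array([np.cos(th), np.sin(th)]))
        for ch, c in zip(chans, offsets):
            r = rng.uniform(lo, hi)
            n = _draw_n_locs(rng, locs_per_cluster, 1)[0]
            prec = CHANNEL_PRECISION_NM.get(ch, DEFAULT_PRECISION_NM)
            frames.append(_cluster_locs(rng, c, r, n, prec, ch, n_frames))
            truth_rows.append((cluster_id, ch, *c, r, n, k))
            cluster_id += 1
    for ch in (NADNA_CHANNEL, *channels):
        frames.append(_background(rng, roi, background_density_um2, ch, CHANNEL_PRECISION_NM.get(ch, DEFAULT_PRECISION_NM), n_frames))

    locs = pd.concat(frames, ignore_index=True)
    truth = GroundTruth(
        focus_centers_nm=centers,
        focus_classes=classes,
        clusters=pd.DataFrame(truth_rows, columns=["cluster_id", "channel", "x_nm", "y_nm", "radius_nm", "n_locs", "focus_id"]),
    )
    return FocusPopulation(classes=classes, focus_centers_nm=centers, locs=locs, roi=roi, truth=truth)


@dataclass
class BeadField:
    """Matched multi-channel fiducial bead localizations with a known warp."""

    tables: dict[str, pd.DataFrame]
    truth: GroundTruth
    reference_channel: str


def generate_bead_field(
    n_beads: int,
    field_size_nm: float = 40_000.0,
    warp_coefficients: tuple[np.ndarray, np.ndarray] | None = None,
    noise_sd_nm: float = 0.0,
    seed: int = 0,
    min_spacing_nm: float = 2000.0,
    reference_channel: str = "red",
    warped_channel: str = "blue",
    degree: int = 3,
) -> BeadField:
    """Simulate a two-channel fiducial bead field for chromatic-map fitting.

    Reference-channel beads are uniform in a square field with a minimum
    pairwise spacing (default 2 um) so cross-channel matching is
    unambiguous. The second channel is the reference warped by a bivariate
    polynomial (degree <= 3; identity if None) plus isotropic Gaussian
    localization noise of ``noise_sd_nm`` per coordinate.
    """
    if degree > 3:
        raise ConfigurationError("bead-field warp degree must be <= 3")
    rng = np.random.default_rng(seed)
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n_beads:
        cand = rng.uniform(0.0, field_size_nm, size=2)
        if all(np.hypot(*(cand - p)) >= min_spacing_nm for p in pts):
            pts.append(cand)
        tries += 1
        if tries > MAX_PLACEMENT_TRIES:
            raise PlacementError(
                f"placed only {len(pts)}/{n_beads} beads at {min_spacing_nm} nm spacing in a {field_size_nm} nm field"
            )
    ref = np.array(pts)
    if warp_coefficients is None:
        cx, cy = identity_coefficients(degree)
    else:
        cx, cy = (np.asarray(c, float) for c in warp_coefficients)
    wx, wy = evaluate_polynomial(cx, cy, ref[:, 0], ref[:, 1], degree)
    warped = np.column_stack([wx, wy])
    if noise_sd_nm > 0:
        warped = warped + rng.normal(0.0, noise_sd_nm, size=warped.shape)

    def _table(pos: np.ndarray, channel: str) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_nm": pos[:, 0],
                "y_nm": pos[:, 1],
                "frame": np.zeros(len(pos), int),
                "channel": channel,
                "intensity": np.full(len(pos), 1000.0),
                "precision_nm": np.full(len(pos), max(noise_sd_nm, 1.0)),
            }
        )

    truth = GroundTruth(
        focus_centers_nm=ref,
        focus_classes=[],
        clusters=pd.DataFrame(columns=["cluster_id", "channel", "x_nm", "y_nm", "radius_nm", "n_locs", "focus_id"]),
        warp_coefficients={"degree": degree, "coeff_x": cx.tolist(), "coeff_y": cy.tolist()},
    )
    return BeadField(
        tables={reference_channel: _table(ref, reference_channel), warped_channel: _table(warped, warped_channel)},
        truth=truth,
        reference_channel=reference_channel,
    )


@dataclass(frozen=True)
class FrameGeometry:
    shape: tuple[int, int]  # (rows, cols) pixels
    pixel_nm: float = 100.0
    n_frames: int | None = None  # default: max frame index in the table + 1


def generate_frames(
    locs: pd.DataFrame,
    geometry: FrameGeometry,
    psf_fwhm_nm: float = 300.0,
    photons_per_molecule: float = 1000.0,
    background_level: float = 10.0,
    seed: int = 0,
) -> np.ndarray:
    """Render localizations into a raw camera-frame stack (uint16).

    Each molecule appears in its assigned frame as a 2D Gaussian point-spread
    function of the stated FWHM carrying ``photons_per_molecule`` expected
    photons; Poisson shot noise is applied over a constant expected
    background. Molecules outside the frame are silently clipped (logged).
    """
    if psf_fwhm_nm <= 0:
        raise ConfigurationError("psf_fwhm_nm must be > 0")
    rng = np.random.default_rng(seed)
    n_rows, n_cols = geometry.shape
    n_frames = geometry.n_frames
    if n_frames is None:
        n_frames = int(locs["frame"].max()) + 1 if len(locs) else 1
    expected = np.full((n_frames, n_rows, n_cols), float(background_level))
    s_px = fwhm_to_sd(psf_fwhm_nm) / geometry.pixel_nm
    half = max(2, int(np.ceil(4 * s_px)))
    n_clipped = 0
    for x, y, f in zip(locs["x_nm"].to_numpy(float), locs["y_nm"].to_numpy(float), locs["frame"].to_numpy(int)):
        if not (0 <= f < n_frames):
            n_clipped += 1
            continue
        cx = x / geometry.pixel_nm
        cy = y / geometry.pixel_nm
        if not (0 <= cx < n_cols and 0 <= cy < n_rows):
            n_clipped += 1
            continue
        c_lo, c_hi = max(0, int(cx) - half), min(n_cols, int(cx) + half + 1)
        r_lo, r_hi = max(0, int(cy) - half), min(n_rows, int(cy) + half + 1)
        cols = np.arange(c_lo, c_hi) + 0.5
        rows = np.arange(r_lo, r_hi) + 0.5
        g = np.exp(-((rows[:, None] - cy) ** 2 + (cols[None, :] - cx) ** 2) / (2 * s_px**2))
        expected[f, r_lo:r_hi, c_lo:c_hi] += photons_per_molecule * g / (2 * np.pi * s_px**2)
    if n_clipped:
        log.info("generate_frames: %d molecules outside the frame stack were clipped", n_clipped)
    return np.clip(rng.poisson(expected), 0, 65535).astype(np.uint16)
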