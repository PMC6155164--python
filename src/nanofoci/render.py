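"""Rendering localization tables to a pixel grid and segmenting clusters.

A localization table is converted to a pseudo-image on a fine grid (20 nm
pixels by default), restricted to a manually drawn nucleus region of
interest, binarized with an automatic Otsu threshold computed from the
in-ROI pixel histogram, and labeled into connected clusters. Clusters are
the unit of all downstream colocalization and focus statistics.

Coordinate conventions
----------------------
Coordinates are in nanometres. Pixels are 0-based with half-open bins:
pixel (row i, col j) covers x in [x0 + j*p, x0 + (j+1)*p) and y likewise,
where p is the pixel size and (x0, y0) the grid origin. Images are indexed
``[row, col]`` = ``[y, x]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon
from skimage import measure

log = logging.getLogger(__name__)

DEFAULT_PIXEL_NM = 20.0


class SegmentationError(RuntimeError):
    """Raised when a nucleus cannot be segmented (e.g. constant in-ROI image)."""


@dataclass(frozen=True)
class GridSpec:
    """Render grid: origin (nm of the lower corner of pixel (0, 0)), shape, pixel size."""

    origin_nm: tuple[float, float]  # (x0, y0)
    shape: tuple[int, int]  # (n_rows, n_cols)
    pixel_nm: float = DEFAULT_PIXEL_NM

    @classmethod
    def for_bounds(cls, x_min: float, y_min: float, x_max: float, y_max: float, pixel_nm: float = DEFAULT_PIXEL_NM, pad_px: int = 2) -> "GridSpec":
        x0 = x_min - pad_px * pixel_nm
        y0 = y_min - pad_px * pixel_nm
        n_cols = int(np.ceil((x_max - x0) / pixel_nm)) + pad_px
        n_rows = int(np.ceil((y_max - y0) / pixel_nm)) + pad_px
        return cls(origin_nm=(x0, y0), shape=(n_rows, n_cols), pixel_nm=pixel_nm)

    def to_pixel(self, x_nm: np.ndarray, y_nm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map nm coordinates to (row, col) integer pixel indices (may be out of range)."""
        col = np.floor((np.asarray(x_nm, float) - self.origin_nm[0]) / self.pixel_nm).astype(int)
        row = np.floor((np.asarray(y_nm, float) - self.origin_nm[1]) / self.pixel_nm).astype(int)
        return row, col

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """nm coordinates of pixel centers as (x_centers[cols], y_centers[rows])."""
        x0, y0 = self.origin_nm
        xs = x0 + (np.arange(self.shape[1]) + 0.5) * self.pixel_nm
        ys = y0 + (np.arange(self.shape[0]) + 0.5) * self.pixel_nm
        return xs, ys

    @property
    def pixel_area_nm2(self) -> float:
        return self.pixel_nm**2


@dataclass
class RenderedImage:
    channel: str
    grid: GridSpec
    data: np.ndarray  # float array, shape = grid.shape
    n_dropped: int = 0  # localizations outside the grid

    def __post_init__(self) -> None:
        if self.data.shape != tuple(self.grid.shape):
            raise ValueError("image shape does not match grid")


class NucleusROI:
    """Nucleus region of interest: a simple polygon (nm) and/or a grid mask.

    Real analyses outline each nucleus by hand on the nascent-DNA channel;
    here ROIs come either from such polygons (GeoJSON) or from the scene
    generator. The polygon and its rasterization agree on pixel-center
    membership: a pixel belongs to the ROI iff its center lies inside the
    polygon.
    """

    def __init__(self, polygon: Polygon | Sequence[tuple[float, float]] | None = None, mask: np.ndarray | None = None, grid: GridSpec | None = None):
        if polygon is None and mask is None:
            raise ValueError("NucleusROI needs a polygon or a mask")
        if polygon is not None and not isinstance(polygon, Polygon):
            polygon = Polygon(polygon)
        if polygon is not None:
            if not polygon.is_valid or polygon.area <= 0:
                raise ValueError("ROI polygon must be simple, closed, with positive area")
        self.polygon = polygon
        self._mask = mask
        self._mask_grid = grid

    @classmethod
    def from_ellipse(cls, center_nm: tuple[float, float], semi_axes_nm: tuple[float, float], n_vertices: int = 128) -> "NucleusROI":
        t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
        cx, cy = center_nm
        a, b = semi_axes_nm
        return cls(polygon=Polygon(np.column_stack([cx + a * np.cos(t), cy + b * np.sin(t)])))

    @property
    def area_um2(self) -> float:
        if self.polygon is not None:
            return float(self.polygon.area) / 1e6
        assert self._mask is not None and self._mask_grid is not None
        return float(self._mask.sum()) * self._mask_grid.pixel_area_nm2 / 1e6

    def mask(self, grid: GridSpec) -> np.ndarray:
        """Boolean mask of the ROI on ``grid`` (pixel-center membership)."""
        if self.polygon is None:
            if self._mask_grid != grid:
                raise ValueError("mask-only ROI defined on a different grid")
            return self._mask
        xs, ys = grid.pixel_centers()
        xx, yy = np.meshgrid(xs, ys)
        return shapely.contains_xy(self.polygon, xx.ravel(), yy.ravel()).reshape(grid.shape)

    def contains(self, x_nm: np.ndarray, y_nm: np.ndarray) -> np.ndarray:
        if self.polygon is not None:
            return shapely.contains_xy(self.polygon, np.asarray(x_nm, float), np.asarray(y_nm, float))
        row, col = self._mask_grid.to_pixel(x_nm, y_nm)
        ok = (row >= 0) & (row < self._mask.shape[0]) & (col >= 0) & (col < self._mask.shape[1])
        out = np.zeros_like(ok)
        out[ok] = self._mask[row[ok], col[ok]]
        return out

    def bounds(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) in nm."""
        if self.polygon is not None:
            return self.polygon.bounds
        g = self._mask_grid
        rows, cols = np.nonzero(self._mask)
        x0, y0 = g.origin_nm
        return (
            x0 + cols.min() * g.pixel_nm,
            y0 + rows.min() * g.pixel_nm,
            x0 + (cols.max() + 1) * g.pixel_nm,
            y0 + (rows.max() + 1) * g.pixel_nm,
        )

    def default_grid(self, pixel_nm: float = DEFAULT_PIXEL_NM) -> GridSpec:
        x_min, y_min, x_max, y_max = self.bounds()
        return GridSpec.for_bounds(x_min, y_min, x_max, y_max, pixel_nm)


@dataclass
class Cluster:
    """One segmented cluster: an 8-connected component of above-threshold pixels."""

    id: int
    channel: str
    rows: np.ndarray
    cols: np.ndarray
    intensities: np.ndarray
    area_nm2: float
    com_nm: tuple[float, float]  # intensity-weighted center of mass (x, y)

    @property
    def n_pixels(self) -> int:
        return len(self.rows)


@dataclass
class ClusterSet:
    channel: str
    grid: GridSpec
    clusters: list[Cluster]
    label_image: np.ndarray  # int labels, 0 = background
    threshold: float
    roi: NucleusROI | None = None

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def total_area_nm2(self) -> float:
        return float(sum(c.area_nm2 for c in self.clusters))

    def binary_mask(self) -> np.ndarray:
        return self.label_image > 0

    def centers_of_mass(self) -> np.ndarray:
        if not self.clusters:
            return np.empty((0, 2))
        return np.array([c.com_nm for c in self.clusters])


def render(
    table: pd.DataFrame,
    grid: GridSpec,
    mode: Literal["counts", "gaussian"] = "counts",
    channel: str | None = None,
) -> RenderedImage:
    """Render a localization table onto a pixel grid.

    counts mode: each localization adds 1 to its containing pixel, so the
    image sum equals the number of in-grid localizations. gaussian mode:
    each localization is spread as a normalized 2D Gaussian of s.d. equal to
    its ``precision_nm``. Localizations outside the grid are dropped and
    counted in ``n_dropped``.
    """
    if channel is not None and "channel" in table.columns:
        table = table[table["channel"] == channel]
    name = channel if channel is not None else (str(table["channel"].iloc[0]) if "channel" in table.columns and len(table) else "")
    x = table["x_nm"].to_numpy(float)
    y = table["y_nm"].to_numpy(float)
    row, col = grid.to_pixel(x, y)
    ok = (row >= 0) & (row < grid.shape[0]) & (col >= 0) & (col < grid.shape[1])
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("render: dropped %d/%d localizations outside the grid", n_dropped, len(x))
    img = np.zeros(grid.shape, float)
    if mode == "counts":
        np.add.at(img, (row[ok], col[ok]), 1.0)
    elif mode == "gaussian":
        prec = table["precision_nm"].to_numpy(float) if "precision_nm" in table.columns else np.full(len(x), 10.0)
        _render_gaussian(img, grid, x[ok], y[ok], np.maximum(prec[ok], 1e-3))
    else:
        raise ValueError(f"unknown render mode {mode!r}")
    return RenderedImage(channel=name, grid=grid, data=img, n_dropped=n_dropped)


def _render_gaussian(img: np.ndarray, grid: GridSpec, x: np.ndarray, y: np.ndarray, sd_nm: np.ndarray) -> None:
    p = grid.pixel_nm
    x0, y0 = grid.origin_nm
    for xi, yi, si in zip(x, y, sd_nm):
        s_px = si / p
        half = max(1, int(np.ceil(3 * s_px)))
        cr = int((yi - y0) / p)
        cc = int((xi - x0) / p)
        r_lo, r_hi = max(0, cr - half), min(img.shape[0], cr + half + 1)
        c_lo, c_hi = max(0, cc - half), min(img.shape[1], cc + half + 1)
        rr = np.arange(r_lo, r_hi)
        cc_ = np.arange(c_lo, c_hi)
        yc = y0 + (rr + 0.5) * p
        xc = x0 + (cc_ + 0.5) * p
        g = np.exp(-((yc[:, None] - yi) ** 2 + (xc[None, :] - xi) ** 2) / (2 * si**2))
        total = g.sum()
        if total > 0:
            img[r_lo:r_hi, c_lo:c_hi] += g / total


def _otsu_threshold(values: np.ndarray) -> float:
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(values))


def segment_channel(image: RenderedImage, roi: NucleusROI, connectivity: int = 2) -> ClusterSet:
    """Threshold one rendered channel inside the nucleus ROI and label clusters.

    The Otsu threshold is computed from the histogram of in-ROI pixels only
    (zeros included: in sparse single-molecule renders the empty interior is
    part of the background class, and excluding it would inflate the
    threshold). Pixels strictly above the threshold are labeled by
    8-connectivity (``connectivity=2``); no minimum cluster size is applied,
    so single-pixel clusters are kept. Cluster centers of mass are
    intensity-weighted, in nm.

    Raises
    ------
    SegmentationError
        If the in-ROI image is constant (Otsu undefined).
    """
    roi_mask = roi.mask(image.grid)
    values = image.data[roi_mask]
    if values.size == 0:
        raise SegmentationError(f"channel {image.channel!r}: ROI contains no pixels on this grid")
    if np.all(values == values.flat[0]):
        raise SegmentationError(f"channel {image.channel!r}: constant in-ROI image, Otsu threshold undefined")
    thr = _otsu_threshold(values)
    binary = (image.data > thr) & roi_mask
    labels = measure.label(binary, connectivity=connectivity)
    clusters: list[Cluster] = []
    px = image.grid.pixel_nm
    x0, y0 = image.grid.origin_nm
    for rp in measure.regionprops(labels, intensity_image=image.data):
        rows, cols = rp.coords[:, 0], rp.coords[:, 1]
        w = image.data[rows, cols]
        wsum = w.sum()
        com_x = x0 + (np.sum((cols + 0.5) * w) / wsum) * px
        com_y = y0 + (np.sum((rows + 0.5) * w) / wsum) * px
        clusters.append(
            Cluster(
                id=int(rp.label),
                channel=image.channel,
                rows=rows,
                cols=cols,
                intensities=w,
                area_nm2=float(rp.area) * image.grid.pixel_area_nm2,
                com_nm=(float(com_x), float(com_y)),
            )
        )
    return ClusterSet(channel=image.channel, grid=image.grid, clusters=clusters, label_image=labels, threshold=thr, roi=roi)


def disc_cluster_set(
    centers_nm: np.ndarray,
    radii_nm: np.ndarray,
    grid: GridSpec,
    channel: str,
    roi: NucleusROI | None = None,
    clip_to_roi: bool = True,
) -> ClusterSet:
    """Build a ClusterSet of disc-shaped masks directly from centers and radii.

    Bypasses rendering and segmentation; used to construct known cluster
    geometries for calibration experiments and tests. Discs are rasterized
    on ``grid``; with ``clip_to_roi`` their pixels are restricted to the ROI
    (as segmentation would). Overlapping discs keep their own identity in
    ``clusters`` but later discs overwrite earlier ones in the label image.
    """
    from skimage.draw import disk

    labels = np.zeros(grid.shape, int)
    roi_mask = roi.mask(grid) if (roi is not None and clip_to_roi) else None
    px = grid.pixel_nm
    x0, y0 = grid.origin_nm
    clusters: list[Cluster] = []
    for i, (c, r) in enumerate(zip(np.asarray(centers_nm, float), np.asarray(radii_nm, float)), start=1):
        rr, cc = disk(((c[1] - y0) / px - 0.5, (c[0] - x0) / px - 0.5), r / px, shape=grid.shape)
        if roi_mask is not None:
            keep = roi_mask[rr, cc]
            rr, cc = rr[keep], cc[keep]
        if rr.size == 0:
            continue
        labels[rr, cc] = i
        w = np.ones(rr.size)
        clusters.append(
            Cluster(
                id=i,
                channel=channel,
                rows=rr,
                cols=cc,
                intensities=w,
                area_nm2=float(rr.size) * grid.pixel_area_nm2,
                com_nm=(float(x0 + (cc.mean() + 0.5) * px), float(y0 + (rr.mean() + 0.5) * px)),
            )
        )
    return ClusterSet(channel=channel, grid=grid, clusters=clusters, label_image=labels, threshold=0.5, roi=roi)


def cluster_summary(cluster_set: ClusterSet) -> pd.DataFrame:
    """One row per cluster: id, channel, pixel count, area (nm^2), center of mass (nm)."""
    rows = [
        {
            "cluster_id": c.id,
            "channel": c.channel,
            "n_pixels": c.n_pixels,
            "area_nm2": c.area_nm2,
            "com_x_nm": c.com_nm[0],
            "com_y_nm": c.com_nm[1],
        }
        for c in cluster_set.clusters
    ]
    return pd.DataFrame(rows, columns=["cluster_id", "channel", "n_pixels", "area_nm2", "com_x_nm", "com_y_nm"])
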