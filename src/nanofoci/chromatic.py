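"""Polynomial chromatic registration between color channels.

Multi-color single-molecule microscopes show field-dependent offsets of a few
tens to hundreds of nanometres between color channels (chromatic aberration
plus geometric misalignment of the detection paths). The standard correction
images a field of multi-color fiducial beads, matches the bead localizations
across channels, fits a low-order bivariate polynomial mapping one channel's
coordinates onto the reference channel, and applies that map to every
localization before rendering. This module implements a degree-3 (ten
monomials per axis) least-squares morph map, mutual-nearest-neighbor bead
matching, and residual diagnostics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError, cKDTree

log = logging.getLogger(__name__)


class MatchingError(RuntimeError):
    """No bead pairs could be matched between the two channels."""


class FittingError(RuntimeError):
    """The polynomial design matrix is rank-deficient (e.g. collinear beads)."""


def polynomial_terms(degree: int) -> list[tuple[int, int]]:
    """Monomial exponents (i, j) with i + j <= degree, row-major by (i, j)."""
    return [(i, j) for i in range(degree + 1) for j in range(degree + 1 - i)]


def _design_matrix(x: np.ndarray, y: np.ndarray, degree: int) -> np.ndarray:
    terms = polynomial_terms(degree)
    return np.column_stack([x**i * y**j for i, j in terms])


def evaluate_polynomial(coeff_x: np.ndarray, coeff_y: np.ndarray, x: np.ndarray, y: np.ndarray, degree: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate a bivariate polynomial coordinate map at points (x, y)."""
    a = _design_matrix(np.asarray(x, float), np.asarray(y, float), degree)
    return a @ np.asarray(coeff_x, float), a @ np.asarray(coeff_y, float)


def identity_coefficients(degree: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient vectors of the identity map in the package's monomial order."""
    terms = polynomial_terms(degree)
    cx = np.zeros(len(terms))
    cy = np.zeros(len(terms))
    cx[terms.index((1, 0))] = 1.0
    cy[terms.index((0, 1))] = 1.0
    return cx, cy


@dataclass
class ChromaticMap:
    """A fitted polynomial map from ``source_channel`` coordinates onto ``target_channel``.

    Coefficients are ordered row-major over monomials x^i y^j with
    i + j <= degree (10 terms per axis at degree 3).
    """

    source_channel: str
    target_channel: str
    degree: int
    coeff_x: np.ndarray
    coeff_y: np.ndarray
    residuals_nm: np.ndarray = field(default_factory=lambda: np.empty(0))
    #: Training bead positions in the source channel; used to flag extrapolation.
    training_points: np.ndarray | None = None

    def __post_init__(self) -> None:
        n_terms = len(polynomial_terms(self.degree))
        self.coeff_x = np.asarray(self.coeff_x, float)
        self.coeff_y = np.asarray(self.coeff_y, float)
        if self.coeff_x.shape != (n_terms,) or self.coeff_y.shape != (n_terms,):
            raise ValueError(f"degree {self.degree} map needs {n_terms} coefficients per axis")

    @property
    def median_residual_nm(self) -> float:
        return float(np.median(self.residuals_nm)) if self.residuals_nm.size else float("nan")

    def transform(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return evaluate_polynomial(self.coeff_x, self.coeff_y, x, y, self.degree)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "source_channel": self.source_channel,
            "target_channel": self.target_channel,
            "degree": self.degree,
            "terms": polynomial_terms(self.degree),
            "coeff_x": self.coeff_x.tolist(),
            "coeff_y": self.coeff_y.tolist(),
            "residuals_nm": np.asarray(self.residuals_nm).tolist(),
            "training_points": None if self.training_points is None else np.asarray(self.training_points).tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "ChromaticMap":
        return cls(
            source_channel=d["source_channel"],
            target_channel=d["target_channel"],
            degree=int(d["degree"]),
            coeff_x=np.asarray(d["coeff_x"], float),
            coeff_y=np.asarray(d["coeff_y"], float),
            residuals_nm=np.asarray(d.get("residuals_nm", []), float),
            training_points=None if d.get("training_points") is None else np.asarray(d["training_points"], float),
        )

    @classmethod
    def from_json(cls, path) -> "ChromaticMap":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def match_beads(table_a: pd.DataFrame, table_b: pd.DataFrame, max_pair_distance_nm: float = 500.0) -> pd.DataFrame:
    """Match beads across two channels by mutual nearest neighbors.

    Parameters
    ----------
    table_a, table_b:
        Localization tables with ``x_nm``/``y_nm`` columns (one row per bead).
    max_pair_distance_nm:
        Gate on the pair distance; pairs further apart are not matched.

    Returns
    -------
    DataFrame with columns ``xa_nm, ya_nm, xb_nm, yb_nm, distance_nm``; one
    row per mutual-nearest-neighbor pair. Unmatched beads are dropped (the
    counts are logged).

    Raises
    ------
    MatchingError
        If no pair passes the gate.
    """
    if len(table_a) == 0 or len(table_b) == 0:
        raise MatchingError("empty bead table")
    pa = table_a[["x_nm", "y_nm"]].to_numpy(float)
    pb = table_b[["x_nm", "y_nm"]].to_numpy(float)
    tree_a, tree_b = cKDTree(pa), cKDTree(pb)
    d_ab, nn_ab = tree_b.query(pa, k=1)  # for each a, nearest b
    _, nn_ba = tree_a.query(pb, k=1)  # for each b, nearest a
    idx_a = np.arange(len(pa))
    mutual = (nn_ba[nn_ab] == idx_a) & (d_ab <= max_pair_distance_nm)
    n_pairs = int(mutual.sum())
    log.info("match_beads: %d/%d (a) and %d (b) beads -> %d mutual pairs", n_pairs, len(pa), len(pb), n_pairs)
    if n_pairs == 0:
        raise MatchingError(
            f"no mutual-nearest-neighbor pairs within {max_pair_distance_nm} nm "
            f"({len(pa)} beads in a, {len(pb)} in b; min cross distance {d_ab.min():.1f} nm)"
        )
    ia = idx_a[mutual]
    ib = nn_ab[mutual]
    return pd.DataFrame(
        {
            "xa_nm": pa[ia, 0],
            "ya_nm": pa[ia, 1],
            "xb_nm": pb[ib, 0],
            "yb_nm": pb[ib, 1],
            "distance_nm": d_ab[mutual],
        }
    )


def fit_polynomial_map(
    pairs: pd.DataFrame,
    degree: int = 3,
    source_channel: str = "source",
    target_channel: str = "target",
) -> ChromaticMap:
    """Least-squares fit of a bivariate polynomial mapping channel a onto channel b.

    ``pairs`` is the output of :func:`match_beads`: source coordinates in
    ``xa_nm``/``ya_nm``, target coordinates in ``xb_nm``/``yb_nm``. Each target
    axis is regressed on the monomials of the source coordinates. Residual
    pair distances after mapping are stored on the returned map.
    """
    n_terms = len(polynomial_terms(degree))
    if len(pairs) < n_terms:
        raise FittingError(f"need >= {n_terms} pairs for degree {degree}, got {len(pairs)}")
    if len(pairs) < 30:
        log.warning("fit_polynomial_map: only %d bead pairs; map may be poorly constrained", len(pairs))
    xa = pairs["xa_nm"].to_numpy(float)
    ya = pairs["ya_nm"].to_numpy(float)
    xb = pairs["xb_nm"].to_numpy(float)
    yb = pairs["yb_nm"].to_numpy(float)
    # Center/scale the design for conditioning, then fold the scaling back in.
    x0, y0 = xa.mean(), ya.mean()
    s = max(xa.std(), ya.std(), 1.0)
    a = _design_matrix((xa - x0) / s, (ya - y0) / s, degree)
    if np.linalg.matrix_rank(a) < n_terms:
        raise FittingError("rank-deficient design matrix (beads collinear or degenerate)")
    cx, *_ = np.linalg.lstsq(a, xb, rcond=None)
    cy, *_ = np.linalg.lstsq(a, yb, rcond=None)
    # Convert scaled-basis coefficients to raw-coordinate coefficients by
    # expanding ((x-x0)/s)^i ((y-y0)/s)^j with the binomial theorem.
    coeff_x = _unscale_coefficients(cx, degree, x0, y0, s)
    coeff_y = _unscale_coefficients(cy, degree, x0, y0, s)
    fx, fy = evaluate_polynomial(coeff_x, coeff_y, xa, ya, degree)
    residuals = np.hypot(fx - xb, fy - yb)
    return ChromaticMap(
        source_channel=source_channel,
        target_channel=target_channel,
        degree=degree,
        coeff_x=coeff_x,
        coeff_y=coeff_y,
        residuals_nm=residuals,
        training_points=np.column_stack([xa, ya]),
    )


def _unscale_coefficients(c: np.ndarray, degree: int, x0: float, y0: float, s: float) -> np.ndarray:
    from math import comb

    terms = polynomial_terms(degree)
    index = {t: k for k, t in enumerate(terms)}
    out = np.zeros(len(terms))
    for (i, j), ck in zip(terms, c):
        if ck == 0.0:
            continue
        for p in range(i + 1):
            for q in range(j + 1):
                out[index[(p, q)]] += (
                    ck
                    * comb(i, p)
                    * comb(j, q)
                    * ((-x0) ** (i - p))
                    * ((-y0) ** (j - q))
                    / s ** (i + j)
                )
    return out


def apply_map(table: pd.DataFrame, cmap: ChromaticMap, channel: str | None = None) -> pd.DataFrame:
    """Apply a fitted chromatic map to a localization table.

    Coordinates are transformed; every other column is preserved. Rows whose
    coordinates fall outside the convex hull of the training beads are still
    corrected but flagged in a boolean ``extrapolated`` column, since the
    polynomial is unconstrained there.
    """
    if channel is not None and cmap.source_channel not in ("source", channel):
        raise ValueError(f"map is for channel {cmap.source_channel!r}, table is {channel!r}")
    out = table.copy()
    x = table["x_nm"].to_numpy(float)
    y = table["y_nm"].to_numpy(float)
    fx, fy = cmap.transform(x, y)
    out["x_nm"] = fx
    out["y_nm"] = fy
    if cmap.training_points is not None and len(cmap.training_points) >= 3:
        try:
            hull = Delaunay(cmap.training_points)
            outside = hull.find_simplex(np.column_stack([x, y])) < 0
        except QhullError:
            outside = np.ones(len(x), bool)
        out["extrapolated"] = outside
        n_out = int(outside.sum())
        if n_out:
            log.info("apply_map: %d/%d localizations outside the bead hull (extrapolated)", n_out, len(x))
    return out
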