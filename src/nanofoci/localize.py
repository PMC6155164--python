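"""Single-molecule localization from raw camera frames.

Candidate emitters are detected as local maxima in a lightly smoothed,
background-subtracted frame and refined by least-squares 2D Gaussian fits.
Fits are accepted only if the spot's full width at half maximum does not
exceed 640 nm and its signal-to-noise ratio is better than 3, where SNR is
defined as fitted amplitude over the background standard deviation. The
background mean and s.d. are estimated per frame on a 2 x 2 um window
centered at the frame's minimum-intensity pixel, which keeps bright spots
out of the noise estimate.

This is a deliberately simple single-emitter localizer: overlapping
emitters (candidates closer than one FWHM) are jointly rejected rather than
fitted together, and there is no drift correction or 3D support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.ndimage import gaussian_filter
from skimage.feature import peak_local_max

from ._util import FWHM_PER_SD, fwhm_to_sd

log = logging.getLogger(__name__)

DEFAULT_SNR_MIN = 3.0
DEFAULT_FWHM_MAX_NM = 640.0
BACKGROUND_WINDOW_UM = 2.0

LOC_COLUMNS = ["x_nm", "y_nm", "frame", "channel", "intensity", "precision_nm", "fwhm_nm", "snr"]


def estimate_background(frame: np.ndarray, pixel_nm: float, window_um: float = BACKGROUND_WINDOW_UM) -> tuple[float, float]:
    """Background mean and s.d. of one frame.

    Computed over a square window of side ``window_um`` centered at the
    frame's minimum-intensity pixel (ties broken by scan order), so that
    emitters elsewhere in the frame do not contaminate the estimate. If the
    frame is smaller than the window, the window is clipped to the frame
    (logged).
    """
    frame = np.asarray(frame, float)
    half = max(1, int(round(window_um * 1000.0 / pixel_nm)) // 2)
    r0, c0 = np.unravel_index(np.argmin(frame), frame.shape)
    r_lo, r_hi = r0 - half, r0 + half
    c_lo, c_hi = c0 - half, c0 + half
    if r_lo < 0 or c_lo < 0 or r_hi > frame.shape[0] or c_hi > frame.shape[1]:
        log.debug("estimate_background: window clipped to frame bounds")
    win = frame[max(0, r_lo) : min(frame.shape[0], r_hi), max(0, c_lo) : min(frame.shape[1], c_hi)]
    return float(win.mean()), float(win.std())


def _gauss2d(coords, amp, x0, y0, sx, sy, offset):
    x, y = coords
    return (amp * np.exp(-((x - x0) ** 2 / (2 * sx**2) + (y - y0) ** 2 / (2 * sy**2))) + offset).ravel()


@dataclass
class _Fit:
    x_px: float
    y_px: float
    amp: float
    sx_px: float
    sy_px: float

    @property
    def fwhm_px(self) -> float:
        return FWHM_PER_SD * float(np.sqrt(self.sx_px * self.sy_px))


def _fit_candidate(frame: np.ndarray, row: int, col: int, half: int, bg_mean: float, sd_guess_px: float) -> _Fit | None:
    r_lo, r_hi = max(0, row - half), min(frame.shape[0], row + half + 1)
    c_lo, c_hi = max(0, col - half), min(frame.shape[1], col + half + 1)
    win = frame[r_lo:r_hi, c_lo:c_hi]
    if win.size < 9:
        return None
    yy, xx = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    p0 = [max(float(frame[row, col] - bg_mean), 1e-3), float(col), float(row), sd_guess_px, sd_guess_px, bg_mean]
    lb = [0.0, c_lo - 0.5, r_lo - 0.5, 0.3, 0.3, -np.inf]
    ub = [np.inf, c_hi - 0.5, r_hi - 0.5, 4.0 * half, 4.0 * half, np.inf]
    try:
        popt, _ = optimize.curve_fit(_gauss2d, (xx, yy), win.ravel(), p0=p0, bounds=(lb, ub), maxfev=2000)
    except RuntimeError:
        return None
    amp, x0, y0, sx, sy, _ = popt
    # reject fits pinned to the window edge
    if not (c_lo <= x0 <= c_hi - 1 and r_lo <= y0 <= r_hi - 1):
        return None
    return _Fit(x_px=float(x0), y_px=float(y0), amp=float(amp), sx_px=float(sx), sy_px=float(sy))


def localize_stack(
    stack: np.ndarray,
    pixel_nm: float,
    snr_min: float = DEFAULT_SNR_MIN,
    fwhm_max_nm: float = DEFAULT_FWHM_MAX_NM,
    channel: str = "0",
    expected_fwhm_nm: float = 300.0,
) -> pd.DataFrame:
    """Localize single molecules in an image stack.

    Parameters
    ----------
    stack:
        (n_frames, rows, cols) array, or a single 2D frame.
    pixel_nm:
        Camera pixel size in nm (required; there is no default because the
        nm coordinates of the output depend on it).
    snr_min, fwhm_max_nm:
        Acceptance filters: fitted amplitude / background s.d. must exceed
        ``snr_min`` and the geometric-mean FWHM must not exceed
        ``fwhm_max_nm``.
    expected_fwhm_nm:
        Initial guess for the PSF width; also sets the fitting window.

    Returns
    -------
    DataFrame with columns x_nm, y_nm, frame, channel, intensity,
    precision_nm, fwhm_nm, snr. The per-localization precision is the
    Thompson-style estimate sigma / sqrt(N) with N = 2*pi*amp*sx*sy taken as
    a photon-count proxy; it is a relative quality score, not a calibrated
    uncertainty, since camera gain is not modeled.
    """
    if pixel_nm is None or pixel_nm <= 0:
        raise ValueError("pixel_nm must be a positive number")
    stack = np.asarray(stack, float)
    if stack.ndim == 2:
        stack = stack[None]
    sd_guess_px = fwhm_to_sd(expected_fwhm_nm) / pixel_nm
    half = max(3, int(np.ceil(2.5 * max(sd_guess_px, fwhm_to_sd(fwhm_max_nm) / pixel_nm / 2.0))))
    rows_out: list[dict] = []
    n_pair_rejected = 0
    for f_idx, frame in enumerate(stack):
        if not np.any(frame):
            continue
        bg_mean, bg_sd = estimate_background(frame, pixel_nm)
        bg_sd = max(bg_sd, 1e-9)
        smoothed = gaussian_filter(frame - bg_mean, sigma=1.0)
        # generous candidate gate; the fitted-amplitude SNR filter is final
        peaks = peak_local_max(smoothed, min_distance=2, threshold_abs=0.5 * snr_min * bg_sd, exclude_border=False)
        fits: list[_Fit] = []
        for r, c in peaks:
            fit = _fit_candidate(frame, int(r), int(c), half, bg_mean, sd_guess_px)
            if fit is not None:
                fits.append(fit)
        # joint rejection of overlapping emitters: pairs closer than 1 FWHM
        drop = np.zeros(len(fits), bool)
        for i in range(len(fits)):
            for j in range(i + 1, len(fits)):
                d_px = np.hypot(fits[i].x_px - fits[j].x_px, fits[i].y_px - fits[j].y_px)
                gate = max(fits[i].fwhm_px, fits[j].fwhm_px)
                if d_px < gate:
                    drop[i] = drop[j] = True
        n_pair_rejected += int(drop.sum())
        for keep, fit in zip(~drop, fits):
            if not keep:
                continue
            fwhm_nm = fit.fwhm_px * pixel_nm
            snr = fit.amp / bg_sd
            if not (0.0 < fwhm_nm <= fwhm_max_nm) or snr <= snr_min:
                continue
            n_photons = max(2.0 * np.pi * fit.amp * fit.sx_px * fit.sy_px, 1.0)
            sd_nm = np.sqrt(fit.sx_px * fit.sy_px) * pixel_nm
            rows_out.append(
                {
                    "x_nm": (fit.x_px + 0.5) * pixel_nm,
                    "y_nm": (fit.y_px + 0.5) * pixel_nm,
                    "frame": f_idx,
                    "channel": channel,
                    "intensity": fit.amp,
                    "precision_nm": sd_nm / np.sqrt(n_photons),
                    "fwhm_nm": fwhm_nm,
                    "snr": snr,
                }
            )
    if n_pair_rejected:
        log.info("localize_stack: jointly rejected %d overlapping candidates", n_pair_rejected)
    return pd.DataFrame(rows_out, columns=LOC_COLUMNS)
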