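"""Shared numeric helpers and conventions used across the package."""

from __future__ import annotations

import numpy as np

#: FWHM = 2 * sqrt(2 * ln 2) * sigma for a Gaussian.
FWHM_PER_SD: float = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sd(fwhm: float) -> float:
    """Convert a Gaussian full width at half maximum to its standard deviation."""
    return float(fwhm) / FWHM_PER_SD


def sd_to_fwhm(sd: float) -> float:
    """Convert a Gaussian standard deviation to its full width at half maximum."""
    return float(sd) * FWHM_PER_SD


def spawn_rng(seed: int, *key: int) -> np.random.Generator:
    """Derive an independent generator from a master seed and a counter key.

    Sub-streams (e.g. the 20 Monte Carlo randomizations of one nucleus) are
    derived deterministically from the master seed through a SeedSequence
    spawn key, so a fixed master seed reproduces every stream bit-for-bit.
    """
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=tuple(int(k) for k in key)))


class ConfigurationError(ValueError):
    """Raised for invalid configuration (mixtures not summing to one, unknown class names, ...)."""


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place an object under its constraints."""
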