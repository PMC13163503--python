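"""The eight-pattern spectral preprocessing battery.

The same code path serves ROI-averaged calibration spectra and per-pixel
imaging spectra, so any noise amplification a pattern introduces is identical
in both stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

PATTERNS = (
    "none",
    "smooth",
    "d1",
    "d2",
    "snv",
    "snv_smooth",
    "snv_d1",
    "snv_d2",
)


@dataclass(frozen=True)
class PreprocessSpec:
    pattern: str = "none"
    window: int = 9
    polyorder: int = 2

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}; choose from {PATTERNS}")
        if self.window % 2 == 0 or self.window <= self.polyorder:
            raise ValueError("window must be odd and greater than polyorder")


def savitzky_golay(
    spectra: np.ndarray, window: int = 9, polyorder: int = 2, deriv: int = 0
) -> np.ndarray:
    """Savitzky-Golay smoothing / differentiation along the last axis.

    Edges use a polynomial fit over the truncated terminal window, keeping
    the band axis length unchanged. Derivatives are in per-band units
    (delta = 1).
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.shape[-1] < window:
        raise ValueError(
            f"spectrum length {spectra.shape[-1]} shorter than window {window}"
        )
    return savgol_filter(
        spectra, window_length=window, polyorder=polyorder, deriv=deriv,
        delta=1.0, axis=-1, mode="interp",
    )


def snv(spectra: np.ndarray, on_error: str = "raise") -> np.ndarray:
    """Standard normal variate: per spectrum, (x - mean) / sd with ddof=1.

    Constant spectra either raise or, with ``on_error='nan'``, propagate as
    all-NaN rows so downstream maps can mask them.
    """
    spectra = np.asarray(spectra, dtype=float)
    mean = spectra.mean(axis=-1, keepdims=True)
    sd = spectra.std(axis=-1, ddof=1, keepdims=True)
    zero = sd == 0
    if np.any(zero):
        if on_error == "raise":
            raise ValueError("SNV undefined for constant spectrum")
        sd = np.where(zero, np.nan, sd)
    return (spectra - mean) / sd


def apply_pattern(
    spectra: np.ndarray, spec: PreprocessSpec, on_error: str = "raise"
) -> np.ndarray:
    """Apply one named pattern; SNV runs first in the combined patterns."""
    x = np.asarray(spectra, dtype=float)
    pattern = spec.pattern
    if pattern == "none":
        return x.copy()
    if pattern.startswith("snv"):
        x = snv(x, on_error=on_error)
        pattern = pattern[len("snv"):].lstrip("_") or "none"
    if pattern == "none":
        return x
    deriv = {"smooth": 0, "d1": 1, "d2": 2}[pattern]
    if np.isnan(x).any():
        # keep failed (NaN) rows out of the filter, restore after
        flat = x.reshape(-1, x.shape[-1])
        ok = ~np.isnan(flat).any(axis=1)
        out = np.full_like(flat, np.nan)
        if ok.any():
            out[ok] = savitzky_golay(flat[ok], spec.window, spec.polyorder, deriv)
        return out.reshape(x.shape)
    return savitzky_golay(x, spec.window, spec.polyorder, deriv)
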