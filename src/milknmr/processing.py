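"""Spectrum handling: referencing, window integration and bucketing.

A :class:`Spectrum` is a 1D ``1H`` spectrum stored on a strictly descending
ppm axis. This module turns spectra into the ten named quantification
integrals (trapezoidal areas over the library windows) and into the
631-bin, 0.01-ppm bucket vector (0.03-6.34 ppm) used by the chemometrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .library import INTEGRAL_NAMES, IntegrationWindow, default_windows
from .quantify import IntegralSet

__all__ = [
    "Spectrum",
    "BucketVector",
    "reference_shift",
    "integrate",
    "extract_integral_set",
    "bucket",
    "BUCKET_LO",
    "BUCKET_HI",
    "BUCKET_WIDTH",
]

BUCKET_LO = 0.03
BUCKET_HI = 6.34
BUCKET_WIDTH = 0.01
REFERENCE_PPM = 0.172


@dataclass
class Spectrum:
    """A 1D spectrum: descending ppm axis, intensity, acquisition metadata."""

    ppm: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ValueError("ppm and intensity must be 1D arrays of equal length")
        if np.isnan(self.ppm).any() or np.isnan(self.intensity).any():
            raise ValueError("spectrum contains NaN")
        d = np.diff(self.ppm)
        if np.all(d > 0):  # accept ascending input, store descending
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif not np.all(d < 0):
            raise ValueError("ppm axis must be strictly monotonic")

    def __len__(self) -> int:
        return self.ppm.size

    def ascending(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (ppm, intensity) in ascending-ppm order."""
        return self.ppm[::-1], self.intensity[::-1]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"ppm": self.ppm, "intensity": self.intensity}).to_csv(
            path, index=False)

    @staticmethod
    def from_csv(path: str | Path, meta: dict | None = None) -> "Spectrum":
        df = pd.read_csv(path)
        return Spectrum(df["ppm"].to_numpy(), df["intensity"].to_numpy(),
                        meta=meta or {})


@dataclass
class BucketVector:
    """Fixed-width bucket integrals: 631 bins of 0.01 ppm over 0.03-6.34 ppm."""

    values: np.ndarray
    edges: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.edges = np.asarray(self.edges, dtype=float)
        if self.values.size != self.edges.size - 1:
            raise ValueError("edges must have one more element than values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("bucket values must be finite")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def __len__(self) -> int:
        return self.values.size


def _cumulative(spectrum: Spectrum):
    x, y = spectrum.ascending()
    return x, np.concatenate(([0.0], cumulative_trapezoid(y, x)))


def integrate(spectrum: Spectrum, window: IntegrationWindow | tuple,
              baseline: str = "none") -> float:
    """Trapezoidal area of the spectrum over ``[lo_ppm, hi_ppm)``.

    Integration uses the native axis with linear interpolation at the
    window edges, so areas are exactly additive over adjacent windows.
    With ``baseline="linear"`` the straight line through the two window
    edge intensities is subtracted first (off by default: baseline is
    assumed corrected upstream).
    """
    if isinstance(window, IntegrationWindow):
        lo, hi = window.lo_ppm, window.hi_ppm
    else:
        lo, hi = window
    x, cum = _cumulative(spectrum)
    if lo < x[0] or hi > x[-1]:
        raise ValueError(f"window [{lo}, {hi}) outside spectrum axis "
                         f"[{x[0]:.3f}, {x[-1]:.3f}]")
    clo, chi = np.interp([lo, hi], x, cum)
    area = float(chi - clo)
    if baseline == "linear":
        y_lo, y_hi = np.interp([lo, hi], *spectrum.ascending())
        area -= 0.5 * (y_lo + y_hi) * (hi - lo)
    elif baseline != "none":
        raise ValueError(f"unknown baseline mode {baseline!r}")
    return area


def reference_shift(spectrum: Spectrum, nominal_ppm: float = REFERENCE_PPM,
                    search_halfwidth: float = 0.05) -> Spectrum:
    """Translate the ppm axis so the reference maximum sits at ``nominal_ppm``.

    The reference singlet (hexamethylcyclotrisiloxane, 0.172 ppm) is sought
    within ``nominal_ppm +/- search_halfwidth``; a spectrum with no
    resolvable peak there (e.g. flat) raises ``ValueError``.
    """
    x, y = spectrum.ascending()
    mask = (x >= nominal_ppm - search_halfwidth) & (x <= nominal_ppm + search_halfwidth)
    if not mask.any():
        raise ValueError("reference not found: search window outside axis")
    ywin = y[mask]
    med = np.median(ywin)
    mad = np.median(np.abs(ywin - med))
    peak = ywin.max()
    if peak <= med + 5.0 * max(mad, 1e-300):
        raise ValueError("reference not found near nominal position")
    observed = x[mask][int(np.argmax(ywin))]
    delta = nominal_ppm - observed
    return Spectrum(spectrum.ppm + delta, spectrum.intensity.copy(),
                    meta={**spectrum.meta, "reference_shift_ppm": float(delta)})


def extract_integral_set(spectrum: Spectrum,
                         windows: list[IntegrationWindow] | None = None) -> IntegralSet:
    """Integrate the ten named quantification windows of a spectrum."""
    windows = windows if windows is not None else default_windows()
    by_name = {w.name: w for w in windows}
    missing = [n for n in INTEGRAL_NAMES if n not in by_name]
    if missing:
        raise ValueError(f"missing integration window(s): {missing}")
    vals = {n: integrate(spectrum, by_name[n]) for n in INTEGRAL_NAMES}
    provenance = {n: (by_name[n].lo_ppm, by_name[n].hi_ppm) for n in INTEGRAL_NAMES}
    return IntegralSet(
        i088=vals["I0.88"], i095=vals["I0.95"], d=vals["I2.02"], c=vals["I2.33"],
        i277=vals["I2.77"], i281=vals["I2.81"], i499=vals["I4.99"],
        i580=vals["I5.80"], i599=vals["I5.99"], i628=vals["I6.28"],
        meta={"windows": provenance},
    )


def bucket(spectrum: Spectrum, lo: float = BUCKET_LO, hi: float = BUCKET_HI,
           width: float = BUCKET_WIDTH) -> BucketVector:
    """Fixed-size bucketing: trapezoidal area per half-open 0.01-ppm bin.

    Bins are ``[lo + k*width, lo + (k+1)*width)``; areas are computed from
    the cumulative integral, so the bins partition the full-range area
    exactly.
    """
    x, cum = _cumulative(spectrum)
    if lo < x[0] or hi > x[-1]:
        raise ValueError("spectrum axis does not cover the bucketing range")
    n = int(round((hi - lo) / width))
    edges = lo + width * np.arange(n + 1)
    cum_at_edges = np.interp(edges, x, cum)
    return BucketVector(values=np.diff(cum_at_edges), edges=edges)
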