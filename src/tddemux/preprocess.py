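"""Spectrum-level noise estimation and S/N peak filtering.

Each centroided spectrum gets its own noise intensity level ``h``: a
histogram of all peak intensities is built and ``h`` is the middle value
of the bin with the highest frequency.  Peaks with intensity below
``r1*h`` (MS1) or ``r2*h`` (MS/MS) are removed; the boundary value is
kept (only strictly smaller intensities are noise).  Defaults ``r1 = 3``
and ``r2 = 1``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .spectra_io import CentroidSpectrum

__all__ = ["NoiseModel", "compute_noise_level", "filter_peaks", "filter_run"]


@dataclass(frozen=True)
class NoiseModel:
    """Per-spectrum noise level with the MS1/MS2 signal-to-noise ratios."""

    noise_level_h: float
    snr_ms1_r1: float = 3.0
    snr_ms2_r2: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_level_h < 0:
            raise ValueError("noise level must be non-negative")
        if self.snr_ms1_r1 <= 0 or self.snr_ms2_r2 <= 0:
            raise ValueError("S/N ratios must be positive")

    def threshold(self, ms_level: int) -> float:
        r = self.snr_ms1_r1 if ms_level == 1 else self.snr_ms2_r2
        return r * self.noise_level_h


def compute_noise_level(intensities, num_bins: int | None = None) -> float:
    """Noise level ``h`` = center of the modal intensity-histogram bin.

    Binning is equal-width over ``[0, max]`` with ``max(10, ceil(sqrt(n)))``
    bins unless ``num_bins`` overrides it; modal ties resolve to the
    lower-intensity bin.  An empty spectrum yields ``h = 0`` with a
    warning; a constant spectrum yields that constant (degenerate
    histogram).
    """
    arr = np.asarray(intensities, dtype=float).ravel()
    if arr.size == 0:
        warnings.warn("empty spectrum: noise level set to 0", stacklevel=2)
        return 0.0
    if np.any(arr < 0):
        raise ValueError("intensities must be non-negative")
    top = float(arr.max())
    if top == float(arr.min()):
        return top
    if num_bins is None:
        num_bins = max(10, math.ceil(math.sqrt(arr.size)))
    edges = np.linspace(0.0, top, num_bins + 1)
    counts, _ = np.histogram(arr, bins=edges)
    i = int(np.argmax(counts))  # argmax -> first (lowest-intensity) modal bin
    return float(0.5 * (edges[i] + edges[i + 1]))


def filter_peaks(spectrum: CentroidSpectrum, model: NoiseModel) -> CentroidSpectrum:
    """Remove peaks with intensity strictly below ``r*h``; order preserved."""
    thr = model.threshold(spectrum.ms_level)
    keep = spectrum.peaks[:, 1] >= thr if spectrum.peaks.size else slice(None)
    return CentroidSpectrum(
        spectrum.cycle_index,
        spectrum.ms_level,
        spectrum.window_index,
        spectrum.peaks[keep].copy() if spectrum.peaks.size else spectrum.peaks.copy(),
    )


def filter_run(
    scans,
    snr_ms1_r1: float = 3.0,
    snr_ms2_r2: float = 1.0,
    num_bins: int | None = None,
) -> list[CentroidSpectrum]:
    """Estimate a noise level per scan and filter every scan of a run."""
    out = []
    for s in scans:
        h = compute_noise_level(s.intensity, num_bins=num_bins) if len(s.peaks) else 0.0
        out.append(filter_peaks(s, NoiseModel(h, snr_ms1_r1, snr_ms2_r2)))
    return out
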