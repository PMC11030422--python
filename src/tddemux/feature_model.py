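"""Precursor and fragment feature containers and XIC arithmetic.

A top-down DIA run is organised in cycles (one MS1 scan followed by one
MS/MS scan per isolation window).  Every deconvoluted feature carries an
extracted ion chromatogram (XIC): a dense vector ``[a_1, ..., a_k]`` with
one total-intensity entry per cycle.  A single charge proteoform feature
(SCPF) collects all isotopic envelopes of one charge state of a proteoform
feature; fragment features are the analogous objects in one isolation
window's LC-MS/MS map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .spectra_io import RunLayout

logger = logging.getLogger(__name__)

__all__ = [
    "SCPF",
    "FragmentFeature",
    "as_xic",
    "apex_cycle",
    "apex_cycle_distance",
    "assign_scpf_to_window",
    "link_envelopes",
]


def as_xic(values: Sequence[float], num_cycles: int | None = None) -> np.ndarray:
    """Validate and return an XIC as a float array.

    Entries must be non-negative; if ``num_cycles`` is given the length must
    match the run's cycle count.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("XIC must be one-dimensional")
    if num_cycles is not None and x.size != num_cycles:
        raise ValueError(f"XIC length {x.size} != run cycle count {num_cycles}")
    if np.any(x < 0):
        raise ValueError("XIC intensities must be non-negative")
    return x


@dataclass
class SCPF:
    """Single charge proteoform feature.

    ``window_index`` is 1-based and is set only by
    :func:`assign_scpf_to_window` (``None`` = unassigned).
    """

    feature_id: str
    proteoform_feature_id: str
    mono_mass: float  # neutral monoisotopic, Da
    charge: int
    mz_envelope: list[tuple[float, float]]  # (m/z, intensity) isotopic peaks
    xic: np.ndarray
    window_index: int | None = None

    def __post_init__(self) -> None:
        self.xic = as_xic(self.xic)
        if self.mono_mass <= 0:
            raise ValueError(f"SCPF {self.feature_id}: non-positive mass")
        if self.charge < 1:
            raise ValueError(f"SCPF {self.feature_id}: charge must be >= 1")

    @property
    def total_intensity(self) -> float:
        return float(self.xic.sum())

    @property
    def num_cycles(self) -> int:
        """Number of cycles in which the feature is observed (``c``)."""
        return int(np.count_nonzero(self.xic))


@dataclass
class FragmentFeature:
    """Deconvoluted fragment feature from one isolation window's map."""

    feature_id: str
    window_index: int  # 1-based; fragments always belong to one window
    mono_mass: float
    charge: int
    xic: np.ndarray

    def __post_init__(self) -> None:
        self.xic = as_xic(self.xic)
        if self.mono_mass <= 0:
            raise ValueError(f"fragment {self.feature_id}: non-positive mass")
        if self.charge < 1:
            raise ValueError(f"fragment {self.feature_id}: charge must be >= 1")

    @property
    def total_intensity(self) -> float:
        return float(self.xic.sum())

    @property
    def num_cycles(self) -> int:
        return int(np.count_nonzero(self.xic))


def apex_cycle(xic: np.ndarray) -> int:
    """1-based index of the cycle with maximum intensity.

    Ties are broken toward the earliest cycle so the result is
    deterministic.
    """
    x = np.asarray(xic, dtype=float)
    if x.size == 0 or not np.any(x > 0):
        raise ValueError("empty feature: XIC has no positive entry")
    return int(np.argmax(x)) + 1


def apex_cycle_distance(a: np.ndarray, b: np.ndarray) -> int:
    """Absolute difference between the apex cycle indexes of two XICs."""
    return abs(apex_cycle(a) - apex_cycle(b))


def assign_scpf_to_window(scpf: SCPF, layout: "RunLayout") -> int | None:
    """Assign an SCPF to the isolation window holding >50% of its intensity.

    The rule is a strict majority on observed isotopic-peak intensities:
    with non-overlapping windows at most one window can qualify.  Returns
    the 1-based window index (also stored on the SCPF) or ``None``.
    """
    if not scpf.mz_envelope:
        raise ValueError(f"SCPF {scpf.feature_id}: empty m/z envelope")
    total = sum(i for _, i in scpf.mz_envelope)
    if total <= 0:
        raise ValueError(f"SCPF {scpf.feature_id}: zero envelope intensity")
    assigned = None
    for w, (lo, hi) in enumerate(layout.windows, start=1):
        inside = sum(i for mz, i in scpf.mz_envelope if lo <= mz < hi)
        if inside > 0.5 * total:
            assigned = w
            break
    scpf.window_index = assigned
    return assigned


def link_envelopes(
    records: Iterable[tuple[int, float, int, float]],
    num_cycles: int,
    ppm_tol: float = 10.0,
    max_cycle_gap: int = 1,
    kind: str = "fragment",
    window_index: int = 1,
    id_prefix: str = "F",
) -> list:
    """Greedy per-scan envelope linking into features (plumbing helper).

    ``records`` are per-scan deconvolution results ``(cycle, mono_mass,
    charge, intensity)``.  Records with the same charge whose masses agree
    within ``ppm_tol`` and that are separated by at most ``max_cycle_gap``
    cycles are merged into one feature; per-cycle intensities are summed,
    so total intensity is conserved.
    """
    recs = sorted(records, key=lambda r: (r[2], r[1], r[0]))
    features: list = []
    groups: list[list[tuple[int, float, int, float]]] = []
    for rec in recs:
        if groups:
            seed = groups[-1][0]
            if rec[2] == seed[2] and abs(rec[1] - seed[1]) <= ppm_tol * 1e-6 * seed[1]:
                groups[-1].append(rec)
                continue
        groups.append([rec])

    counter = 0
    for grp in groups:
        grp = sorted(grp, key=lambda r: r[0])
        # split runs separated by more than max_cycle_gap cycles
        chains: list[list[tuple[int, float, int, float]]] = [[grp[0]]]
        for rec in grp[1:]:
            if rec[0] - chains[-1][-1][0] > max_cycle_gap:
                chains.append([rec])
            else:
                chains[-1].append(rec)
        for chain in chains:
            xic = np.zeros(num_cycles)
            weight = 0.0
            mass = 0.0
            for cyc, m, _z, inten in chain:
                if not 1 <= cyc <= num_cycles:
                    raise ValueError(f"cycle {cyc} outside run of {num_cycles} cycles")
                xic[cyc - 1] += inten
                mass += m * inten
                weight += inten
            mass /= weight
            charge = chain[0][2]
            counter += 1
            fid = f"{id_prefix}{counter:05d}"
            if kind == "scpf":
                features.append(
                    SCPF(fid, fid, mass, charge, mz_envelope=[], xic=xic)
                )
            else:
                features.append(
                    FragmentFeature(fid, window_index, mass, charge, xic=xic)
                )
    logger.debug("linked %d records into %d features", len(recs), len(features))
    return features
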