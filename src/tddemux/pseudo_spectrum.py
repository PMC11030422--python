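"""Three-round fragment filtering and greedy pseudo MS/MS spectrum generation.

For each isolation window, SCPFs are processed in decreasing order of total
intensity.  For the current SCPF the remaining fragment pool is filtered in
three rounds:

1. *Co-elution gate* — drop fragments whose apex cycle distance from the
   SCPF exceeds ``min{t, floor(c/2)}`` where ``c`` is the number of cycles
   the SCPF is observed in (``t = 3`` by default).  Survivors form ``L``.
2. *Model score* — keep fragments whose logistic match score exceeds a
   cutoff (0.55 by default).  If fewer than 25 pass, the top 25 of ``L``
   by score are reported without filtering (fallback).
3. *Mass-group quotas* — split survivors into a low-mass (< 1500 Da) and a
   high-mass group; keep the 25 best-scoring low masses and the ``T - 25``
   best-scoring high masses, with ``T = 2(l - 1)`` and the precursor
   residue count ``l`` estimated from the precursor mass via the Averagine
   average residue mass.

Fragments used in one pseudo spectrum are removed from the pool before the
next SCPF is processed, so a window's pseudo spectra never share fragments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .feature_model import SCPF, FragmentFeature, apex_cycle
from .pair_scoring import PairModel, compute_attributes, intensity_rank_map

logger = logging.getLogger(__name__)

__all__ = [
    "AVERAGINE_RESIDUE_MASS",
    "CascadeParams",
    "PseudoFragment",
    "PseudoSpectrum",
    "round1_filter",
    "score_candidates",
    "round2_filter",
    "estimate_fragment_quota",
    "round3_filter",
    "generate_window_pseudo_spectra",
    "demux_run",
]

#: Average mass of the Averagine model amino-acid residue
#: (C4.9384 H7.7583 N1.3577 O1.4773 S0.0417), Da.
AVERAGINE_RESIDUE_MASS = 111.1254


@dataclass(frozen=True)
class CascadeParams:
    """Tunable parameters of the three filtering rounds."""

    t: int = 3  # round-1 apex-distance parameter, cycles
    score_cutoff: float = 0.55  # round-2 logistic score cutoff
    min_keep: int = 25  # round-2 fallback size
    low_mass_bound: float = 1500.0  # Da, low/high mass group boundary
    low_quota: int = 25  # round-3 low-mass group quota
    avg_residue_mass: float = AVERAGINE_RESIDUE_MASS

    def __post_init__(self) -> None:
        if min(self.t, self.min_keep, self.low_quota) < 1:
            raise ValueError("t, min_keep and low_quota must be positive")
        if not 0 < self.score_cutoff < 1:
            raise ValueError("score_cutoff must be in (0, 1)")
        if self.low_mass_bound <= 0 or self.avg_residue_mass <= 0:
            raise ValueError("masses must be positive")


class PseudoFragment(NamedTuple):
    mass: float  # neutral monoisotopic, Da
    intensity: float
    charge: int
    feature_id: str


@dataclass
class PseudoSpectrum:
    """One demultiplexed MS/MS spectrum: an SCPF plus its fragment masses."""

    scpf_id: str
    precursor_mass: float
    precursor_charge: int
    precursor_intensity: float
    window_index: int
    fragments: list[PseudoFragment] = field(default_factory=list)
    used_fallback: bool = False

    @property
    def fragment_ids(self) -> set[str]:
        return {f.feature_id for f in self.fragments}


def round1_filter(
    scpf: SCPF, fragments: Sequence[FragmentFeature], t: int = 3
) -> list[FragmentFeature]:
    """Keep fragments whose apex cycle distance is <= ``min{t, floor(c/2)}``."""
    cutoff = min(t, scpf.num_cycles // 2)
    apex = apex_cycle(scpf.xic)
    return [f for f in fragments if abs(apex_cycle(f.xic) - apex) <= cutoff]


def score_candidates(
    scpf: SCPF, candidates: Sequence[FragmentFeature], model: PairModel
) -> np.ndarray:
    """Logistic match score of every fragment in ``L`` against the SCPF."""
    if not candidates:
        return np.empty(0)
    rank_map = intensity_rank_map(candidates)
    X = np.stack(
        [
            compute_attributes(scpf, f, candidates, rank_map).as_array()
            for f in candidates
        ]
    )
    return model.score_matrix(X)


def round2_filter(
    scpf: SCPF,
    candidates: Sequence[FragmentFeature],
    model: PairModel,
    score_cutoff: float = 0.55,
    min_keep: int = 25,
) -> tuple[list[tuple[FragmentFeature, float]], bool]:
    """Score-based filtering with the top-``min_keep`` fallback.

    Returns score-ordered ``(fragment, score)`` pairs and a flag telling
    whether the fallback branch (fewer than ``min_keep`` above the cutoff,
    so the top ``min_keep`` of ``L`` are reported without filtering) fired.
    """
    scores = score_candidates(scpf, candidates, model)
    ranked = sorted(
        zip(candidates, scores),
        key=lambda fs: (-fs[1], fs[0].mono_mass, fs[0].feature_id),
    )
    passing = [(f, float(s)) for f, s in ranked if s > score_cutoff]
    if len(passing) >= min_keep:
        return passing, False
    return [(f, float(s)) for f, s in ranked[:min_keep]], True


def estimate_fragment_quota(
    precursor_mass: float, avg_residue_mass: float = AVERAGINE_RESIDUE_MASS
) -> int:
    """Expected theoretical terminal-fragment count ``T = 2(l - 1)``.

    The residue count ``l`` is the precursor mass divided by the Averagine
    average residue mass, rounded to the nearest integer and clamped at 2
    so that ``T >= 2``.
    """
    if precursor_mass <= 0:
        raise ValueError("precursor mass must be positive")
    l = max(2, int(np.floor(precursor_mass / avg_residue_mass + 0.5)))
    return 2 * (l - 1)


def round3_filter(
    scored: Sequence[tuple[FragmentFeature, float]],
    quota_T: int,
    low_mass_bound: float = 1500.0,
    low_quota: int = 25,
) -> list[tuple[FragmentFeature, float]]:
    """Mass-group quotas: best 25 low masses plus best ``T - 25`` high masses.

    For small precursors ``T`` may drop below the low quota; the low quota
    is then clamped to ``T`` and the high quota to zero so at most ``T``
    fragments are ever reported.
    """
    key = lambda fs: (-fs[1], fs[0].mono_mass, fs[0].feature_id)
    low = sorted((fs for fs in scored if fs[0].mono_mass < low_mass_bound), key=key)
    high = sorted((fs for fs in scored if fs[0].mono_mass >= low_mass_bound), key=key)
    n_low = min(low_quota, quota_T)
    n_high = max(0, quota_T - low_quota)
    return low[:n_low] + high[:n_high]


def generate_window_pseudo_spectra(
    fragments: Sequence[FragmentFeature],
    scpfs: Sequence[SCPF],
    model: PairModel,
    params: CascadeParams = CascadeParams(),
) -> list[PseudoSpectrum]:
    """Greedy pseudo-spectrum generation for one isolation window.

    SCPFs are processed in decreasing total intensity (ties broken by
    ascending mass then id); each runs the three-round cascade against the
    *remaining* fragment pool and consumes the fragments it reports.  An
    SCPF whose round-1 list ``L`` is empty emits no spectrum (logged).
    """
    pool: dict[str, FragmentFeature] = {}
    for f in fragments:
        if f.feature_id in pool:
            raise ValueError(f"duplicate fragment id {f.feature_id}")
        pool[f.feature_id] = f
    ordered = sorted(
        scpfs, key=lambda s: (-s.total_intensity, s.mono_mass, s.feature_id)
    )
    spectra: list[PseudoSpectrum] = []
    for scpf in ordered:
        L = round1_filter(scpf, list(pool.values()), params.t)
        if not L:
            logger.info("SCPF %s: no co-eluting fragments, skipped", scpf.feature_id)
            continue
        survivors, fallback = round2_filter(
            scpf, L, model, params.score_cutoff, params.min_keep
        )
        T = estimate_fragment_quota(scpf.mono_mass, params.avg_residue_mass)
        final = round3_filter(survivors, T, params.low_mass_bound, params.low_quota)
        spec = PseudoSpectrum(
            scpf_id=scpf.feature_id,
            precursor_mass=scpf.mono_mass,
            precursor_charge=scpf.charge,
            precursor_intensity=scpf.total_intensity,
            window_index=scpf.window_index if scpf.window_index is not None else -1,
            fragments=sorted(
                (
                    PseudoFragment(f.mono_mass, f.total_intensity, f.charge, f.feature_id)
                    for f, _s in final
                ),
                key=lambda pf: (pf.mass, pf.feature_id),
            ),
            used_fallback=fallback,
        )
        for f, _s in final:
            del pool[f.feature_id]
        spectra.append(spec)
    return spectra


def demux_run(
    scpfs: Sequence[SCPF],
    fragments: Sequence[FragmentFeature],
    model: PairModel,
    params: CascadeParams = CascadeParams(),
) -> tuple[list[PseudoSpectrum], list[dict]]:
    """Demultiplex a whole run window by window.

    SCPFs must already carry window assignments; unassigned SCPFs are
    ignored.  Returns all pseudo spectra plus a per-window report with the
    counts a user wants to audit (SCPFs, fragments, spectra, fallbacks).
    """
    frags_by_window: dict[int, list[FragmentFeature]] = {}
    for f in fragments:
        frags_by_window.setdefault(f.window_index, []).append(f)
    scpfs_by_window: dict[int, list[SCPF]] = {}
    for s in scpfs:
        if s.window_index is not None:
            scpfs_by_window.setdefault(s.window_index, []).append(s)

    spectra: list[PseudoSpectrum] = []
    report: list[dict] = []
    for w in sorted(set(frags_by_window) | set(scpfs_by_window)):
        w_scpfs = scpfs_by_window.get(w, [])
        w_frags = frags_by_window.get(w, [])
        w_specs = generate_window_pseudo_spectra(w_frags, w_scpfs, model, params)
        spectra.extend(w_specs)
        report.append(
            {
                "window_index": w,
                "num_scpfs": len(w_scpfs),
                "num_fragments": len(w_frags),
                "num_pseudo_spectra": len(w_specs),
                "num_fallback": sum(s.used_fallback for s in w_specs),
            }
        )
    return spectra, report
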