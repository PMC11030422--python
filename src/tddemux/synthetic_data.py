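"""Synthetic top-down DIA runs with full ground truth.

The generator emulates the acquisition scheme the demultiplexer targets: a
gas-phase-fractionated run covering one precursor m/z range with contiguous
narrow isolation windows, one MS1 scan plus one MS/MS scan per window per
cycle.  Each synthetic proteoform is a random amino-acid sequence with a
Gaussian elution profile sampled at cycle centers (truncated at 1% of peak
height); its b/y fragment ladder co-elutes with the precursor (optional
apex jitter), with geometrically decaying intensities.  Decoy fragment
features with unrelated masses and elution profiles model chimeric signal.
Everything it emits round-trips through the package's own readers, and the
ground-truth tables map every feature to its source proteoform.

What it deliberately does *not* model: isotope-resolved peak shapes,
charge-state envelope structure, retention-time drift, or fragmentation
physics — the demultiplexer never looks at those.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

from .feature_model import SCPF, FragmentFeature, assign_scpf_to_window
from .pair_scoring import build_pair_table, label_pairs
from .postprocess import DECONV_MASS_ERROR, ProteoformID
from .spectra_io import (
    CentroidSpectrum,
    RunLayout,
    uniform_layout,
    write_feature_table,
    write_layout,
    write_peak_lists,
    write_proteoform_catalog,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AMINO_ACIDS",
    "WATER_MONO",
    "PROTON_MASS",
    "SimConfig",
    "SyntheticProteoform",
    "SyntheticRun",
    "sequence_mono_mass",
    "by_ion_masses",
    "simulate_run",
    "make_pair_training_set",
    "sample_pair_attributes",
    "plant_duplicate_clusters",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
WATER_MONO = _pmass.calculate_mass(formula="H2O")
PROTON_MASS = 1.00727646688
ISOTOPE_SPACING = 1.00335  # average isotopic peak spacing, Da

_RESIDUE = {aa: _pmass.std_aa_mass[aa] for aa in AMINO_ACIDS}


def sequence_mono_mass(sequence: str) -> float:
    """Neutral monoisotopic mass of an unmodified sequence."""
    return sum(_RESIDUE[aa] for aa in sequence) + WATER_MONO


def by_ion_masses(sequence: str) -> np.ndarray:
    """Sorted neutral b- and y-ion masses of a sequence.

    b_i = sum of the first i residue masses; y_i = sum of the last i
    residue masses + water (standard conventions).
    """
    res = np.array([_RESIDUE[aa] for aa in sequence])
    b = np.cumsum(res[:-1])
    y = np.cumsum(res[::-1][:-1]) + WATER_MONO
    return np.sort(np.concatenate([b, y]))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a simulated TD-DIA run.

    Defaults mirror one gas-phase fraction of the targeted acquisition
    scheme: 720-800 m/z precursor range cut into 4 m/z isolation windows
    (20 MS/MS scans per cycle) over a 64-cycle run.
    """

    seed: int
    num_cycles: int = 64
    precursor_mz_range: tuple[float, float] = (720.0, 800.0)
    window_width: float = 4.0
    num_proteoforms: int = 20
    coisolation_fraction: float = 0.3  # fraction placed into an occupied window
    coisolation_apex_separation: int | None = None  # cycles; None = random apexes
    min_length: int = 40
    max_length: int = 90
    elution_sigma_range: tuple[float, float] = (1.5, 3.0)  # cycles
    apex_margin: int = 10  # keep apexes this far from the run edges
    apex_jitter: float = 0.0  # max |fragment apex - precursor apex|, cycles
    fragment_decay: float = 0.97  # geometric intensity decay per ion index
    fragment_intensity_scale: float = 0.2
    min_fragment_mass: float = 200.0
    fragment_max_charge: int = 2
    emit_fragment_ladders: bool = True  # False = decoy-only MS/MS maps
    decoy_fragments_per_window: int = 200
    coeluting_decoy_fraction: float = 0.4  # decoys eluting near some precursor
    noise_peaks_per_spectrum: int = 150

    def __post_init__(self) -> None:
        if self.num_proteoforms < 1 or self.num_cycles < 8:
            raise ValueError("need at least one proteoform and 8 cycles")
        if not 0 <= self.coisolation_fraction <= 0.5:
            raise ValueError("coisolation_fraction must be in [0, 0.5]")

    @property
    def layout(self) -> RunLayout:
        lo, hi = self.precursor_mz_range
        return uniform_layout(self.num_cycles, lo, hi, self.window_width)


@dataclass
class SyntheticProteoform:
    proteoform_id: str
    sequence: str
    mono_mass: float
    charge: int
    mz: float
    window_index: int
    apex_cycle: int
    sigma: float  # elution profile width, cycles
    peak_intensity: float
    by_masses: np.ndarray
    coisolated_with: str | None = None


@dataclass
class SyntheticRun:
    """A simulated run plus its bookkeeping tables."""

    config: SimConfig
    layout: RunLayout
    proteoforms: list[SyntheticProteoform]
    scpfs: list[SCPF]
    fragments: list[FragmentFeature]
    truth: pd.DataFrame  # fragment_id, window_index, source_id, ion_type, ion_mass
    catalog: dict[str, np.ndarray]  # proteoform id -> sorted b/y masses
    spectra: list[CentroidSpectrum] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_layout(self.layout, outdir / "layout.json")
        write_feature_table(self.scpfs, self.fragments, outdir / "features.tsv")
        write_proteoform_catalog(self.catalog, outdir / "catalog.tsv")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        if self.spectra:
            write_peak_lists(self.spectra, outdir / "peaks.txt")


def _gaussian_xic(
    num_cycles: int, center: float, sigma: float, peak: float
) -> np.ndarray:
    """Gaussian elution profile at cycle centers, truncated at 1% of peak."""
    cycles = np.arange(1, num_cycles + 1, dtype=float)
    x = peak * np.exp(-0.5 * ((cycles - center) / sigma) ** 2)
    x[x < 0.01 * peak] = 0.0
    return x


def _sample_proteoform(
    rng: np.random.Generator,
    cfg: SimConfig,
    layout: RunLayout,
    index: int,
    target_window: int,
    apex: int,
    host: SyntheticProteoform | None = None,
) -> SyntheticProteoform:
    """Rejection-sample a sequence and charge landing in the target window."""
    lo, hi = layout.windows[target_window - 1]
    for _ in range(20000):
        length = int(rng.integers(cfg.min_length, cfg.max_length + 1))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
        m = sequence_mono_mass(seq)
        for z in range(3, 61):
            mz = m / z + PROTON_MASS
            # 0.5 m/z margin keeps the whole isotopic envelope inside
            if lo + 0.5 <= mz < hi - 0.5:
                return SyntheticProteoform(
                    proteoform_id=f"PF{index:03d}",
                    sequence=seq,
                    mono_mass=m,
                    charge=z,
                    mz=mz,
                    window_index=target_window,
                    apex_cycle=apex,
                    sigma=float(rng.uniform(*cfg.elution_sigma_range)),
                    peak_intensity=float(10 ** rng.uniform(5.5, 7.0)),
                    by_masses=by_ion_masses(seq),
                    coisolated_with=None if host is None else host.proteoform_id,
                )
    raise RuntimeError(f"infeasible window packing for window {target_window}")


def _coisolated_apex(
    rng: np.random.Generator, cfg: SimConfig, host_apex: int
) -> int:
    lo, hi = cfg.apex_margin, cfg.num_cycles - cfg.apex_margin
    sep = cfg.coisolation_apex_separation
    if sep is None:
        return int(rng.integers(lo, hi + 1))
    options = [a for a in (host_apex - sep, host_apex + sep) if lo <= a <= hi]
    if not options:
        raise RuntimeError("apex separation does not fit inside the run")
    return int(options[rng.integers(len(options))])


def simulate_run(config: SimConfig, with_peak_lists: bool = False) -> SyntheticRun:
    """Generate a complete synthetic run (features, truth, optional peaks).

    Deterministic given the config (the seed is part of it).  The first
    ``(1 - coisolation_fraction)`` of the proteoforms are hosts placed
    round-robin over the isolation windows; the rest are co-isolated
    partners sharing a host's window (and, when configured, eluting at a
    fixed apex separation from it).
    """
    rng = np.random.default_rng(config.seed)
    layout = config.layout
    W = layout.num_windows
    n_co = int(round(config.coisolation_fraction * config.num_proteoforms))
    n_host = config.num_proteoforms - n_co

    proteoforms: list[SyntheticProteoform] = []
    lo, hi = config.apex_margin, config.num_cycles - config.apex_margin
    for i in range(n_host):
        apex = int(rng.integers(lo, hi + 1))
        proteoforms.append(
            _sample_proteoform(rng, config, layout, i, (i % W) + 1, apex)
        )
    for j in range(n_co):
        host = proteoforms[j % n_host]
        apex = _coisolated_apex(rng, config, host.apex_cycle)
        proteoforms.append(
            _sample_proteoform(
                rng, config, layout, n_host + j, host.window_index, apex, host=host
            )
        )

    scpfs: list[SCPF] = []
    fragments: list[FragmentFeature] = []
    truth_rows: list[dict] = []
    frag_counter = 0

    for pf in proteoforms:
        xic = _gaussian_xic(config.num_cycles, pf.apex_cycle, pf.sigma, pf.peak_intensity)
        envelope = [
            (pf.mz + i * ISOTOPE_SPACING / pf.charge, rel * pf.peak_intensity)
            for i, rel in enumerate((0.30, 0.30, 0.25, 0.15))
        ]
        scpf = SCPF(
            feature_id=f"S{pf.proteoform_id}_z{pf.charge}",
            proteoform_feature_id=pf.proteoform_id,
            mono_mass=pf.mono_mass,
            charge=pf.charge,
            mz_envelope=envelope,
            xic=xic,
        )
        assigned = assign_scpf_to_window(scpf, layout)
        if assigned != pf.window_index:  # pragma: no cover - generator self-check
            raise RuntimeError("window bookkeeping violated")
        scpfs.append(scpf)

        res = np.array([_RESIDUE[aa] for aa in pf.sequence])
        ladders = {
            "b": np.cumsum(res[:-1]),
            "y": np.cumsum(res[::-1][:-1]) + WATER_MONO,
        }
        if not config.emit_fragment_ladders:
            ladders = {}
        for ion_type, ladder in ladders.items():
            for ion_index, ion_mass in enumerate(ladder, start=1):
                if ion_mass < config.min_fragment_mass:
                    continue
                inten = (
                    pf.peak_intensity
                    * config.fragment_intensity_scale
                    * config.fragment_decay**ion_index
                    * float(np.exp(rng.normal(0.0, 0.3)))
                )
                center = pf.apex_cycle + (
                    float(rng.uniform(-config.apex_jitter, config.apex_jitter))
                    if config.apex_jitter > 0
                    else 0.0
                )
                sigma_f = pf.sigma * float(rng.uniform(0.9, 1.15))
                xic = _gaussian_xic(config.num_cycles, center, sigma_f, inten)
                if not xic.any():  # jittered outside the run: undetectable
                    continue
                frag_counter += 1
                fid = f"F{frag_counter:05d}"
                fragments.append(
                    FragmentFeature(
                        feature_id=fid,
                        window_index=pf.window_index,
                        mono_mass=float(ion_mass),
                        charge=int(rng.integers(1, config.fragment_max_charge + 1)),
                        xic=xic,
                    )
                )
                truth_rows.append(
                    {
                        "fragment_id": fid,
                        "window_index": pf.window_index,
                        "source_id": pf.proteoform_id,
                        "ion_type": ion_type,
                        "ion_index": ion_index,
                        "ion_mass": float(ion_mass),
                    }
                )

    # Decoys model chimeric fragment signal.  A fraction co-elutes with a
    # randomly chosen precursor of the window (fragments of unidentified
    # co-isolated proteoforms); the rest elute anywhere in the run.
    occupied = sorted({pf.window_index for pf in proteoforms})
    pf_by_window: dict[int, list[SyntheticProteoform]] = {}
    for pf in proteoforms:
        pf_by_window.setdefault(pf.window_index, []).append(pf)
    for w in occupied:
        hosts = pf_by_window[w]
        for _ in range(config.decoy_fragments_per_window):
            frag_counter += 1
            fid = f"F{frag_counter:05d}"
            mass = float(rng.uniform(config.min_fragment_mass, 12000.0))
            if rng.random() < config.coeluting_decoy_fraction:
                near = hosts[int(rng.integers(len(hosts)))]
                center = near.apex_cycle + float(rng.uniform(-2.0, 2.0))
            else:
                center = float(rng.uniform(3, config.num_cycles - 2))
            sigma_f = float(rng.uniform(*config.elution_sigma_range))
            inten = float(10 ** rng.uniform(3.5, 5.5))
            fragments.append(
                FragmentFeature(
                    feature_id=fid,
                    window_index=w,
                    mono_mass=mass,
                    charge=int(rng.integers(1, config.fragment_max_charge + 1)),
                    xic=_gaussian_xic(config.num_cycles, center, sigma_f, inten),
                )
            )
            truth_rows.append(
                {
                    "fragment_id": fid,
                    "window_index": w,
                    "source_id": "decoy",
                    "ion_type": "",
                    "ion_index": 0,
                    "ion_mass": mass,
                }
            )

    truth = pd.DataFrame(truth_rows)
    catalog = {pf.proteoform_id: pf.by_masses for pf in proteoforms}
    run = SyntheticRun(config, layout, proteoforms, scpfs, fragments, truth, catalog)
    if with_peak_lists:
        run.spectra = _simulate_peak_lists(run, rng)
    logger.info(
        "simulated run: %d proteoforms, %d SCPFs, %d fragment features",
        len(proteoforms),
        len(scpfs),
        len(fragments),
    )
    return run


def _simulate_peak_lists(
    run: SyntheticRun, rng: np.random.Generator
) -> list[CentroidSpectrum]:
    """Centroided scans: feature peaks scaled by the XIC plus noise peaks."""
    cfg = run.config
    layout = run.layout
    frag_by_window: dict[int, list[FragmentFeature]] = {}
    for f in run.fragments:
        frag_by_window.setdefault(f.window_index, []).append(f)

    scans: list[CentroidSpectrum] = []
    mz_lo, mz_hi = layout.precursor_range
    for cyc in range(1, cfg.num_cycles + 1):
        peaks = []
        for s in run.scpfs:
            frac = s.xic[cyc - 1] / s.xic.max() if s.xic.max() else 0.0
            if frac > 0:
                peaks.extend((mz, i * frac) for mz, i in s.mz_envelope)
        noise = np.column_stack(
            [
                rng.uniform(mz_lo, mz_hi, cfg.noise_peaks_per_spectrum),
                rng.exponential(2e3, cfg.noise_peaks_per_spectrum),
            ]
        )
        ms1 = np.vstack([np.array(peaks).reshape(-1, 2), noise])
        scans.append(CentroidSpectrum(cyc, 1, None, ms1))
        for w in range(1, layout.num_windows + 1):
            peaks = []
            for f in frag_by_window.get(w, []):
                frac = f.xic[cyc - 1]
                if frac > 0:
                    peaks.append((f.mono_mass / f.charge + PROTON_MASS, frac))
            noise = np.column_stack(
                [
                    rng.uniform(400.0, 2000.0, cfg.noise_peaks_per_spectrum),
                    rng.exponential(2e3, cfg.noise_peaks_per_spectrum),
                ]
            )
            ms2 = np.vstack([np.array(peaks).reshape(-1, 2), noise])
            scans.append(CentroidSpectrum(cyc, 2, w, ms2))
    return scans


def make_pair_training_set(
    run: SyntheticRun, t: int = 3, ppm_tol: float = 10.0
) -> pd.DataFrame:
    """Labeled SCPF-fragment pair table for model training.

    Pairs are formed per window exactly as the demultiplexer's round-1
    gate would (apex cycle distance cutoff; no greedy consumption — a
    fragment may pair with several SCPFs).  Two label columns come back:
    ``label`` from :func:`tddemux.pair_scoring.label_pairs` and
    ``truth_label`` from the generator's own brute-force ladder match —
    two independent code paths computing the same definition.
    """
    pairs = build_pair_table(run.scpfs, run.fragments, t)
    if pairs.empty:
        return pairs
    labeled = label_pairs(pairs, run.catalog, ppm_tol)

    # independent brute-force labeling straight from the generator's ladders
    truth = []
    for pfid, m in zip(labeled["proteoform_feature_id"], labeled["fragment_mass"]):
        ladder = run.catalog[pfid]
        truth.append(
            int(any(abs(m - th) <= ppm_tol * 1e-6 * th for th in ladder))
        )
    labeled["truth_label"] = truth
    return labeled


def sample_pair_attributes(
    n: int = 10_000, positive_fraction: float = 0.25, seed: int = 0
) -> pd.DataFrame:
    """Parametric labeled attribute sample for model-recovery checks.

    Positives carry elevated shared XIC (Beta(8, 2)) and better (smaller)
    normalized intensity ranks (Beta(1.5, 5)); negatives the reverse.
    Cycle-number ratios overlap heavily between classes.
    """
    rng = np.random.default_rng(seed)
    n_pos = int(round(n * positive_fraction))
    n_neg = n - n_pos

    def clip_rank(x: np.ndarray) -> np.ndarray:
        return np.clip(x, 1e-6, 1.0)

    pos = pd.DataFrame(
        {
            "norm_intensity_rank": clip_rank(rng.beta(1.5, 5.0, n_pos)),
            "norm_cycle_number": np.clip(rng.normal(1.0, 0.25, n_pos), 0.05, 2.5),
            "shared_xic": rng.beta(8.0, 2.0, n_pos),
            "label": 1,
        }
    )
    neg = pd.DataFrame(
        {
            "norm_intensity_rank": clip_rank(rng.beta(2.5, 1.2, n_neg)),
            "norm_cycle_number": np.clip(rng.normal(0.8, 0.45, n_neg), 0.05, 3.0),
            "shared_xic": rng.beta(1.5, 6.0, n_neg),
            "label": 0,
        }
    )
    out = pd.concat([pos, neg], ignore_index=True)
    return out.sample(frac=1.0, random_state=seed).reset_index(drop=True)


def plant_duplicate_clusters(
    num_clusters: int = 30,
    max_extra_copies: int = 4,
    run_ids: Sequence[str] = ("run1", "run2", "run3"),
    ppm_jitter: float = 3.0,
    seed: int = 0,
) -> tuple[dict[str, list[ProteoformID]], list[ProteoformID]]:
    """Plant duplicate-identification clusters across runs, with the answer.

    Each cluster is one protein: a base identification (the most intense
    member) plus copies whose masses differ by 0 or ±1.00235 Da plus a
    small ppm-scale jitter, spread over the given runs.  Returns the
    per-run identification lists and the expected survivors (the cluster
    bases).  Base masses of different clusters are far apart and proteins
    are distinct, so clusters are exactly the duplicate-equivalence
    components.
    """
    rng = np.random.default_rng(seed)
    per_run: dict[str, list[ProteoformID]] = {r: [] for r in run_ids}
    survivors: list[ProteoformID] = []
    for c in range(num_clusters):
        protein = f"PROT{c:03d}"
        base_mass = 5000.0 + 1000.0 * c + float(rng.uniform(0, 500))
        base_int = float(10 ** rng.uniform(6.0, 7.0))
        base = ProteoformID(
            protein_accession=protein,
            mono_mass=base_mass,
            scpf_intensity=base_int,
            run_id=str(run_ids[int(rng.integers(len(run_ids)))]),
            proteoform_id=f"{protein}_base",
        )
        survivors.append(base)
        per_run[base.run_id].append(base)
        for k in range(int(rng.integers(1, max_extra_copies + 1))):
            offset = float(rng.choice([0.0, DECONV_MASS_ERROR, -DECONV_MASS_ERROR]))
            jitter = base_mass * 1e-6 * float(rng.uniform(-ppm_jitter, ppm_jitter))
            dup = ProteoformID(
                protein_accession=protein,
                mono_mass=base_mass + offset + jitter,
                scpf_intensity=base_int * float(rng.uniform(0.05, 0.9)),
                run_id=str(run_ids[int(rng.integers(len(run_ids)))]),
                proteoform_id=f"{protein}_dup{k}",
            )
            per_run[dup.run_id].append(dup)
    return per_run, survivors
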