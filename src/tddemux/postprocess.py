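"""Duplicate-proteoform removal within a run and merging across runs.

Database search of pseudo spectra reports one proteoform per spectrum, so
the same proteoform is typically identified several times — including with
precursor masses off by ±1.00235 Da, a common top-down deconvolution error
(a mis-picked monoisotopic peak).  Identifications are ranked by SCPF
intensity; each one is compared against all better-ranked identifications
and removed when it duplicates any of them.  Gas-phase-fractionated runs
are merged by pooling their (already deduplicated) lists and deduplicating
the union the same way.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "DECONV_MASS_ERROR",
    "ProteoformID",
    "is_duplicate",
    "dedup_run",
    "merge_runs",
    "read_identifications",
    "write_identifications",
]

#: Common deconvolution mass error: one mis-assigned isotopic peak, Da.
DECONV_MASS_ERROR = 1.00235


@dataclass(frozen=True)
class ProteoformID:
    """One proteoform identification from a database search."""

    protein_accession: str
    mono_mass: float  # neutral monoisotopic precursor mass, Da
    scpf_intensity: float
    run_id: str = ""
    proteoform_id: str = ""
    evalue: float | None = None

    def __post_init__(self) -> None:
        if self.mono_mass <= 0 or self.scpf_intensity <= 0:
            raise ValueError("mass and intensity must be positive")


def is_duplicate(
    m1: float,
    m2: float,
    same_protein: bool,
    ppm_tol: float = 10.0,
    offset: float = DECONV_MASS_ERROR,
) -> bool:
    """Duplicate rule: same protein and masses equal up to a ±offset error.

    True iff ``min(|m1-m2|, |m1-m2-offset|, |m1-m2+offset|)`` is within
    ``ppm_tol`` parts per million of the larger mass (the more permissive,
    symmetric reference).
    """
    if not same_protein:
        return False
    d = m1 - m2
    residual = min(abs(d), abs(d - offset), abs(d + offset))
    return residual <= ppm_tol * 1e-6 * max(m1, m2)


def _ranked(ids: Iterable[ProteoformID]) -> list[ProteoformID]:
    return sorted(
        ids,
        key=lambda p: (
            -p.scpf_intensity,
            p.mono_mass,
            p.protein_accession,
            p.run_id,
            p.proteoform_id,
        ),
    )


def dedup_run(
    ids: Sequence[ProteoformID], ppm_tol: float = 10.0
) -> list[ProteoformID]:
    """Remove duplicates, keeping the highest-SCPF-intensity representative.

    Identifications are ranked by decreasing SCPF intensity; following the
    order, each is compared with *all* better-ranked identifications
    (kept or removed) and dropped when it duplicates any of them.  Output
    preserves rank order, so the most intense member of every duplicate
    cluster survives.  Idempotent.
    """
    ranked = _ranked(ids)
    kept: list[ProteoformID] = []
    for i, p in enumerate(ranked):
        dup = any(
            is_duplicate(
                p.mono_mass,
                q.mono_mass,
                p.protein_accession == q.protein_accession,
                ppm_tol,
            )
            for q in ranked[:i]
        )
        if not dup:
            kept.append(p)
    return kept


def merge_runs(
    run_lists: Sequence[Sequence[ProteoformID]], ppm_tol: float = 10.0
) -> list[ProteoformID]:
    """Pool per-run identification lists and deduplicate the union."""
    pooled: list[ProteoformID] = [p for run in run_lists for p in run]
    return dedup_run(pooled, ppm_tol)


_ID_FIELDS = ["proteoform_id", "protein_accession", "mono_mass", "scpf_intensity", "run_id", "evalue"]


def write_identifications(ids: Sequence[ProteoformID], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_ID_FIELDS)
        for p in _ranked(ids):
            writer.writerow(
                [
                    p.proteoform_id,
                    p.protein_accession,
                    repr(p.mono_mass),
                    repr(p.scpf_intensity),
                    p.run_id,
                    "" if p.evalue is None else repr(p.evalue),
                ]
            )


def read_identifications(path: str | Path) -> list[ProteoformID]:
    out: list[ProteoformID] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                ProteoformID(
                    protein_accession=row["protein_accession"],
                    mono_mass=float(row["mono_mass"]),
                    scpf_intensity=float(row["scpf_intensity"]),
                    run_id=row.get("run_id", ""),
                    proteoform_id=row.get("proteoform_id", ""),
                    evalue=float(row["evalue"]) if row.get("evalue") else None,
                )
            )
    return out
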