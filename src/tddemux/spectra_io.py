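"""File formats: peak lists, feature tables, catalogs and pseudo-spectrum output.

Formats
-------
* Peak lists: centroided mzML (a minimal streaming reader covering the
  subset the pipeline needs) or an internal plain-text format —
  ``S<TAB>cycle<TAB>level<TAB>window`` scan headers followed by
  ``P<TAB>mz<TAB>intensity`` peak lines — which is the canonical text
  fixture format.
* Feature tables: TSV with dense XIC columns (semicolon-separated, one
  entry per cycle).  Masses are neutral monoisotopic Da throughout.
* Pseudo spectra: msalign-style ``BEGIN IONS``/``END IONS`` blocks with one
  ``mass<TAB>intensity<TAB>charge`` line per fragment, consumable by
  top-down database search engines.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .feature_model import SCPF, FragmentFeature, as_xic

logger = logging.getLogger(__name__)

__all__ = [
    "RunLayout",
    "CentroidSpectrum",
    "PeakListParseError",
    "FeatureTableError",
    "uniform_layout",
    "read_layout",
    "write_layout",
    "read_peak_lists",
    "write_peak_lists",
    "read_feature_table",
    "write_feature_table",
    "read_proteoform_catalog",
    "write_proteoform_catalog",
    "write_pseudo_spectra",
    "read_pseudo_spectra",
]


class PeakListParseError(ValueError):
    """Raised when a peak-list file violates the cycle structure."""


class FeatureTableError(ValueError):
    """Raised on malformed feature-table rows (carries the row number)."""


@dataclass(frozen=True)
class RunLayout:
    """Cycle structure of a DIA run: MS1 + one MS/MS scan per window.

    ``windows`` are ``(mz_start, mz_end)`` pairs, non-overlapping and
    sorted; window indices are 1-based everywhere.
    """

    num_cycles: int
    windows: tuple[tuple[float, float], ...]
    precursor_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.num_cycles < 1:
            raise ValueError("num_cycles must be positive")
        object.__setattr__(self, "windows", tuple(map(tuple, self.windows)))
        lo, hi = self.precursor_range
        prev_end = None
        for start, end in self.windows:
            if end <= start:
                raise ValueError(f"window ({start}, {end}) is empty")
            if start < lo - 1e-9 or end > hi + 1e-9:
                raise ValueError(f"window ({start}, {end}) outside precursor range")
            if prev_end is not None and start < prev_end - 1e-9:
                raise ValueError("windows overlap or are unsorted")
            prev_end = end

    @property
    def num_windows(self) -> int:
        return len(self.windows)

    def window_of(self, mz: float) -> int | None:
        """1-based index of the window containing ``mz`` (half-open)."""
        for w, (start, end) in enumerate(self.windows, start=1):
            if start <= mz < end:
                return w
        return None


def uniform_layout(
    num_cycles: int, mz_lo: float, mz_hi: float, window_width: float
) -> RunLayout:
    """Layout with contiguous equal-width isolation windows.

    E.g. a 720-800 m/z precursor range with 4 m/z windows gives the 20
    MS/MS scans per cycle of a gas-phase-fractionated top-down DIA run.
    """
    n = int(round((mz_hi - mz_lo) / window_width))
    if abs(n * window_width - (mz_hi - mz_lo)) > 1e-6:
        raise ValueError("precursor range is not a multiple of window width")
    windows = tuple(
        (mz_lo + i * window_width, mz_lo + (i + 1) * window_width) for i in range(n)
    )
    return RunLayout(num_cycles, windows, (mz_lo, mz_hi))


def write_layout(layout: RunLayout, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "num_cycles": layout.num_cycles,
                "windows": [list(w) for w in layout.windows],
                "precursor_range": list(layout.precursor_range),
            },
            indent=1,
        )
    )


def read_layout(path: str | Path) -> RunLayout:
    d = json.loads(Path(path).read_text())
    return RunLayout(
        d["num_cycles"],
        tuple((a, b) for a, b in d["windows"]),
        tuple(d["precursor_range"]),
    )


@dataclass
class CentroidSpectrum:
    """One centroided scan with its position in the cycle structure."""

    cycle_index: int
    ms_level: int
    window_index: int | None  # None iff ms_level == 1
    peaks: np.ndarray  # (n, 2) array of (m/z, intensity), sorted by m/z

    def __post_init__(self) -> None:
        p = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if p.size and np.any(p[:, 1] < 0):
            raise ValueError("negative peak intensity")
        order = np.argsort(p[:, 0], kind="stable") if p.size else slice(None)
        self.peaks = p[order]
        if (self.ms_level == 1) != (self.window_index is None):
            raise ValueError("window_index must be absent iff ms_level == 1")

    @property
    def mz(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def intensity(self) -> np.ndarray:
        return self.peaks[:, 1]


# ---------------------------------------------------------------------------
# peak lists


def _validate_cycles(
    scans: list[CentroidSpectrum], layout: RunLayout
) -> list[CentroidSpectrum]:
    """Check the 1 MS1 + W MS/MS structure cycle by cycle."""
    w = layout.num_windows
    by_cycle: dict[int, list[CentroidSpectrum]] = {}
    for s in scans:
        by_cycle.setdefault(s.cycle_index, []).append(s)
    for cyc in sorted(by_cycle):
        group = by_cycle[cyc]
        n_ms1 = sum(1 for s in group if s.ms_level == 1)
        n_ms2 = sum(1 for s in group if s.ms_level == 2)
        if n_ms1 != 1 or n_ms2 != w:
            raise PeakListParseError(
                f"cycle {cyc}: expected 1 MS1 + {w} MS/MS scans, "
                f"got {n_ms1} MS1 + {n_ms2} MS/MS"
            )
    return scans


def _read_text_peak_lists(path: Path, layout: RunLayout) -> list[CentroidSpectrum]:
    scans: list[CentroidSpectrum] = []
    header: tuple[int, int, int | None] | None = None
    peaks: list[tuple[float, float]] = []

    def flush() -> None:
        if header is not None:
            scans.append(CentroidSpectrum(header[0], header[1], header[2], np.array(peaks).reshape(-1, 2)))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "S":
                flush()
                cyc, level = int(parts[1]), int(parts[2])
                win = None if parts[3] in ("-", "") else int(parts[3])
                header, peaks = (cyc, level, win), []
            elif parts[0] == "P":
                if header is None:
                    raise PeakListParseError(f"line {lineno}: peak before scan header")
                peaks.append((float(parts[1]), float(parts[2])))
            else:
                raise PeakListParseError(f"line {lineno}: unknown record {parts[0]!r}")
    flush()
    return scans


def _decode_binary_array(elem) -> np.ndarray:
    """Decode one mzML <binaryDataArray> (64/32-bit float, zlib or none)."""
    import base64
    import zlib

    dtype = "<f8"
    compressed = False
    for cv in elem.iter("{*}cvParam"):
        acc = cv.get("accession", "")
        if acc == "MS:1000521":
            dtype = "<f4"
        elif acc == "MS:1000574":
            compressed = True
    binary = elem.find("{*}binary")
    raw = base64.b64decode(binary.text or "")
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml_peak_lists(path: Path, layout: RunLayout) -> list[CentroidSpectrum]:
    """Minimal centroided-mzML reader (streaming, lxml).

    Covers the subset the pipeline needs: ms level, m/z and intensity
    arrays, and the MS/MS isolation-window target m/z, which is mapped to
    the layout's window index (falling back to acquisition order when no
    target is recorded).
    """
    from lxml import etree

    scans: list[CentroidSpectrum] = []
    cycle = 0
    ms2_in_cycle = 0
    for _event, elem in etree.iterparse(str(path), tag="{*}spectrum"):
        level = None
        target = None
        for cv in elem.iter("{*}cvParam"):
            acc = cv.get("accession", "")
            if acc == "MS:1000511":
                level = int(cv.get("value"))
            elif acc == "MS:1000827":
                target = float(cv.get("value"))
        arrays = {}
        for bda in elem.iter("{*}binaryDataArray"):
            accs = {cv.get("accession", "") for cv in bda.iter("{*}cvParam")}
            if "MS:1000514" in accs:
                arrays["mz"] = _decode_binary_array(bda)
            elif "MS:1000515" in accs:
                arrays["intensity"] = _decode_binary_array(bda)
        if level is None or "mz" not in arrays or "intensity" not in arrays:
            raise PeakListParseError(f"{path}: spectrum missing ms level or arrays")
        peaks = (
            np.column_stack([arrays["mz"], arrays["intensity"]])
            if arrays["mz"].size
            else np.empty((0, 2))
        )
        if level == 1:
            cycle += 1
            ms2_in_cycle = 0
            scans.append(CentroidSpectrum(cycle, 1, None, peaks))
        else:
            if cycle == 0:
                raise PeakListParseError("MS/MS scan before the first MS1 scan")
            ms2_in_cycle += 1
            win = layout.window_of(target) if target is not None else None
            if win is None:
                win = ms2_in_cycle  # fall back to acquisition order
            scans.append(CentroidSpectrum(cycle, 2, win, peaks))
        elem.clear(keep_tail=True)
    return scans


def read_peak_lists(path: str | Path, layout: RunLayout) -> list[CentroidSpectrum]:
    """Read centroided scans in acquisition order and index them by cycle.

    mzML input is dispatched on the file extension; anything else is parsed
    as the internal text format.  Raises :class:`PeakListParseError` naming
    the offending cycle when a cycle does not contain exactly one MS1 scan
    followed by one MS/MS scan per isolation window.
    """
    path = Path(path)
    if path.suffix.lower() == ".mzml":
        scans = _read_mzml_peak_lists(path, layout)
    else:
        scans = _read_text_peak_lists(path, layout)
    if not scans:
        warnings.warn(f"{path}: empty peak list", stacklevel=2)
        return []
    return _validate_cycles(scans, layout)


def write_peak_lists(scans: Iterable[CentroidSpectrum], path: str | Path) -> None:
    """Write scans in the internal text peak-list format."""
    with open(path, "w") as fh:
        fh.write("# tddemux peak list v1: S cycle level window / P mz intensity\n")
        for s in scans:
            win = "-" if s.window_index is None else str(s.window_index)
            fh.write(f"S\t{s.cycle_index}\t{s.ms_level}\t{win}\n")
            for mz, inten in s.peaks:
                fh.write(f"P\t{float(mz)!r}\t{float(inten)!r}\n")


# ---------------------------------------------------------------------------
# feature tables

_FEATURE_HEADER = [
    "feature_id",
    "feature_type",
    "proteoform_feature_id",
    "mono_mass",
    "charge",
    "window_index",
    "envelope",
    "xic",
]


def _fmt_floats(values: Iterable[float]) -> str:
    return ";".join(repr(float(v)) for v in values)


def write_feature_table(
    scpfs: Sequence[SCPF],
    fragments: Sequence[FragmentFeature],
    path: str | Path,
) -> None:
    """Serialize SCPFs and fragment features to one TSV (lossless floats)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_FEATURE_HEADER) + "\n")
        for s in scpfs:
            env = ";".join(f"{float(mz)!r}:{float(i)!r}" for mz, i in s.mz_envelope)
            win = "" if s.window_index is None else str(s.window_index)
            fh.write(
                f"{s.feature_id}\tscpf\t{s.proteoform_feature_id}\t{float(s.mono_mass)!r}\t"
                f"{s.charge}\t{win}\t{env}\t{_fmt_floats(s.xic)}\n"
            )
        for f in fragments:
            fh.write(
                f"{f.feature_id}\tfragment\t\t{float(f.mono_mass)!r}\t"
                f"{f.charge}\t{f.window_index}\t\t{_fmt_floats(f.xic)}\n"
            )


def read_feature_table(
    path: str | Path, num_cycles: int | None = None
) -> tuple[list[SCPF], list[FragmentFeature]]:
    """Read a feature TSV back into SCPF and fragment-feature lists.

    Round-trips losslessly through :func:`write_feature_table`.  Validation
    failures raise :class:`FeatureTableError` with the 1-based row number.
    """
    scpfs: list[SCPF] = []
    fragments: list[FragmentFeature] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _FEATURE_HEADER:
            raise FeatureTableError(f"unexpected header {header}")
        for row, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_FEATURE_HEADER):
                raise FeatureTableError(f"row {row}: expected {len(_FEATURE_HEADER)} columns")
            fid, ftype, pfid, mass_s, charge_s, win_s, env_s, xic_s = parts
            try:
                mass = float(mass_s)
                xic = as_xic([float(v) for v in xic_s.split(";")], num_cycles)
                if mass <= 0:
                    raise ValueError("non-positive mass")
                if ftype == "scpf":
                    env = []
                    if env_s:
                        for tok in env_s.split(";"):
                            mz_s, i_s = tok.split(":")
                            env.append((float(mz_s), float(i_s)))
                    scpfs.append(
                        SCPF(
                            fid,
                            pfid,
                            mass,
                            int(charge_s),
                            env,
                            xic,
                            window_index=int(win_s) if win_s else None,
                        )
                    )
                elif ftype == "fragment":
                    fragments.append(
                        FragmentFeature(fid, int(win_s), mass, int(charge_s), xic)
                    )
                else:
                    raise ValueError(f"unknown feature_type {ftype!r}")
            except ValueError as exc:
                raise FeatureTableError(f"row {row}: {exc}") from exc
    return scpfs, fragments


# ---------------------------------------------------------------------------
# proteoform catalogs (identified proteoforms with their b/y ladders)


def write_proteoform_catalog(
    catalog: Mapping[str, Sequence[float]], path: str | Path
) -> None:
    """TSV of proteoform id -> neutral b/y fragment masses (Da)."""
    with open(path, "w") as fh:
        fh.write("proteoform_id\tby_masses\n")
        for pfid in sorted(catalog):
            fh.write(f"{pfid}\t{_fmt_floats(catalog[pfid])}\n")


def read_proteoform_catalog(path: str | Path) -> dict[str, np.ndarray]:
    catalog: dict[str, np.ndarray] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            pfid, masses = line.rstrip("\n").split("\t")
            catalog[pfid] = np.array(
                [float(v) for v in masses.split(";")] if masses else [], dtype=float
            )
    return catalog


# ---------------------------------------------------------------------------
# pseudo spectra (msalign-style)

_TOPPIC_EXTRA = ("FILE_NAME", "SPECTRUM_ID", "TITLE", "SCANS", "RETENTION_TIME",
                 "LEVEL", "MS_ONE_ID", "MS_ONE_SCAN", "ACTIVATION")


def write_pseudo_spectra(
    specs: Sequence,
    path: str | Path,
    dialect: str = "minimal",
) -> None:
    """Write pseudo MS/MS spectra as msalign-style text blocks.

    Spectra are ordered by precursor (SCPF) intensity rank and fragments by
    ascending mass, so output is deterministic.  ``dialect`` controls the
    header fields: ``"minimal"`` writes only the precursor fields; search
    engines wanting the fuller TopPIC-era header set can use ``"toppic"``.
    """
    if dialect not in ("minimal", "toppic"):
        raise ValueError(f"unknown msalign dialect {dialect!r}")
    ordered = sorted(
        specs,
        key=lambda s: (-s.precursor_intensity, s.precursor_mass, s.scpf_id),
    )
    with open(path, "w") as fh:
        fh.write("# tddemux pseudo MS/MS spectra (msalign-style)\n")
        for idx, spec in enumerate(ordered):
            fh.write("BEGIN IONS\n")
            fh.write(f"ID={idx}\n")
            if dialect == "toppic":
                fh.write("FRACTION_ID=0\n")
                for key in _TOPPIC_EXTRA:
                    fh.write(f"{key}={'HCD' if key == 'ACTIVATION' else idx if 'ID' in key or 'SCAN' in key else 0}\n")
            fh.write(f"SPECTRUM_TYPE=PSEUDO\n")
            fh.write(f"WINDOW_INDEX={spec.window_index}\n")
            fh.write(f"SCPF_ID={spec.scpf_id}\n")
            fh.write(f"PRECURSOR_MASS={float(spec.precursor_mass)!r}\n")
            fh.write(f"PRECURSOR_CHARGE={spec.precursor_charge}\n")
            fh.write(f"PRECURSOR_INTENSITY={float(spec.precursor_intensity)!r}\n")
            for frag in sorted(spec.fragments, key=lambda f: (f.mass, f.feature_id)):
                fh.write(f"{float(frag.mass)!r}\t{float(frag.intensity)!r}\t{frag.charge}\n")
            fh.write("END IONS\n\n")


def read_pseudo_spectra(path: str | Path) -> list:
    """Parse a pseudo-spectrum file back (round-trip check and reuse)."""
    from .pseudo_spectrum import PseudoFragment, PseudoSpectrum

    specs: list[PseudoSpectrum] = []
    fields: dict[str, str] = {}
    frags: list[PseudoFragment] = []
    in_block = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                in_block, fields, frags = True, {}, []
            elif line == "END IONS":
                specs.append(
                    PseudoSpectrum(
                        scpf_id=fields["SCPF_ID"],
                        precursor_mass=float(fields["PRECURSOR_MASS"]),
                        precursor_charge=int(fields["PRECURSOR_CHARGE"]),
                        precursor_intensity=float(fields["PRECURSOR_INTENSITY"]),
                        window_index=int(fields["WINDOW_INDEX"]),
                        fragments=frags,
                    )
                )
                in_block = False
            elif in_block and "=" in line:
                key, _, val = line.partition("=")
                fields[key] = val
            elif in_block:
                mass_s, inten_s, charge_s = line.split("\t")
                frags.append(
                    PseudoFragment(float(mass_s), float(inten_s), int(charge_s), f"frag{len(frags)}")
                )
    return specs
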