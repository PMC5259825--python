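"""Reading, writing and pairing of experimental and library spectra.

MGF is handled through :mod:`pyteomics.mgf`.  NIST-style MSP library records
are parsed by a small reader here (record-level errors skip the record and
are counted rather than aborting the whole library).  Intensities are read
and preserved but play no role in peak selection, which uses m/z only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mgf as _ptmgf

from .chemistry import (
    STANDARD_RESIDUES,
    AminoAcidTable,
    MassConstants,
    peptide_mass,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "LibrarySpectrum",
    "SpectrumPair",
    "SpectraParseError",
    "read_mgf",
    "write_mgf",
    "read_msp",
    "write_msp",
    "pair_spectra",
]

HCD, ETD = "HCD", "ETD"


class SpectraParseError(ValueError):
    """Malformed spectrum input."""


@dataclass
class Spectrum:
    """One MS/MS scan.

    ``parent_mass`` (m_p) is the neutral peptide mass derived from the
    precursor m/z and charge.  Peaks are kept sorted by m/z.
    """

    title: str
    precursor_mz: float
    charge: int
    parent_mass: float
    mode: str
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.charge < 1:
            raise SpectraParseError(f"{self.title}: precursor charge must be >= 1")
        if self.mode not in (HCD, ETD):
            raise SpectraParseError(f"{self.title}: mode must be HCD or ETD")
        if self.mz.shape != self.intensity.shape:
            raise SpectraParseError(f"{self.title}: m/z and intensity length mismatch")
        if np.any(self.mz <= 0) or np.any(self.intensity < 0):
            raise SpectraParseError(f"{self.title}: invalid peak values")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class LibrarySpectrum(Spectrum):
    """A Spectrum annotated with its (correct) peptide sequence."""

    peptide: str = ""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not self.peptide:
            raise SpectraParseError(f"{self.title}: library record lacks a peptide")


@dataclass
class SpectrumPair:
    """An HCD/ETD pair believed to share a precursor peptide."""

    hcd: Spectrum
    etd: Spectrum
    tolerance: float = 0.02

    def __post_init__(self) -> None:
        if self.hcd.mode != HCD or self.etd.mode != ETD:
            raise SpectraParseError("pair must combine one HCD and one ETD spectrum")
        if abs(self.hcd.parent_mass - self.etd.parent_mass) > self.tolerance:
            raise SpectraParseError(
                "parent masses differ beyond pairing tolerance: "
                f"{self.hcd.parent_mass:.4f} vs {self.etd.parent_mass:.4f}"
            )

    @property
    def parent_mass(self) -> float:
        return 0.5 * (self.hcd.parent_mass + self.etd.parent_mass)


def _neutral_from_precursor(precursor_mz: float, charge: int,
                            constants: MassConstants) -> float:
    return precursor_mz * charge - charge * constants.m_H


def read_mgf(path: str | Path, mode: str,
             constants: MassConstants | None = None) -> list[Spectrum]:
    """Read an MGF file into :class:`Spectrum` objects.

    ``mode`` labels every scan in the file as HCD or ETD (paired acquisitions
    are normally stored per-mode).  The neutral parent mass is computed from
    PEPMASS and CHARGE.
    """
    constants = constants or MassConstants.monoisotopic()
    out: list[Spectrum] = []
    try:
        with _ptmgf.MGF(str(path)) as reader:
            for i, entry in enumerate(reader):
                params = entry["params"]
                title = str(params.get("title", f"scan_{i}"))
                try:
                    pepmass = float(params["pepmass"][0])
                    charge = int(params["charge"][0])
                except (KeyError, TypeError, IndexError) as exc:
                    raise SpectraParseError(
                        f"{path}: scan {title!r} lacks PEPMASS/CHARGE"
                    ) from exc
                out.append(Spectrum(
                    title=title,
                    precursor_mz=pepmass,
                    charge=charge,
                    parent_mass=_neutral_from_precursor(pepmass, charge, constants),
                    mode=mode,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                ))
    except SpectraParseError:
        raise
    except Exception as exc:  # malformed block / non-numeric peak line
        raise SpectraParseError(f"{path}: MGF parse failure: {exc}") from exc
    if not out:
        logger.warning("%s: no spectra found", path)
    return out


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> None:
    entries = []
    for s in spectra:
        entries.append({
            "m/z array": s.mz,
            "intensity array": s.intensity,
            "params": {
                "title": s.title,
                "pepmass": s.precursor_mz,
                "charge": s.charge,
            },
        })
    _ptmgf.write(entries, str(path), file_mode="w")


_MOD_MARKERS = ("(", "[", "+", "-")


def _parse_msp_name(name: str) -> tuple[str, int, bool]:
    """Parse 'SEQ/charge[...]' -> (sequence, charge, modified?)."""
    seq, _, rest = name.partition("/")
    modified = any(ch in seq for ch in _MOD_MARKERS)
    charge_str = rest
    for sep in ("_", " "):
        if sep in charge_str:
            charge_str, _, tail = charge_str.partition(sep)
            if tail and tail not in ("0",):
                modified = True
    try:
        charge = int(charge_str)
    except ValueError:
        raise SpectraParseError(f"cannot parse charge from Name {name!r}")
    if any(aa not in STANDARD_RESIDUES for aa in seq):
        modified = True
    return seq, charge, modified


def read_msp(
    path: str | Path,
    mode: str,
    constants: MassConstants | None = None,
    table: AminoAcidTable | None = None,
    include_modified: bool = False,
    consistency_tol: float = 0.1,
) -> list[LibrarySpectrum]:
    """Read a NIST-style MSP spectral library.

    Records whose Name field carries modification tokens are skipped by
    default (training uses unmodified peptides).  Records whose declared
    "Num peaks" disagrees with the actual peak count, or whose annotated
    peptide mass is inconsistent with the precursor beyond
    ``consistency_tol`` (Da), are skipped with a logged count.
    """
    constants = constants or MassConstants.monoisotopic()
    table = table or AminoAcidTable.monoisotopic()
    text = Path(path).read_text()
    records = [r for r in text.split("\n\n") if r.strip()]
    out: list[LibrarySpectrum] = []
    skipped_modified = skipped_bad = 0
    for rec in records:
        header: dict[str, str] = {}
        peaks: list[tuple[float, float]] = []
        declared = None
        in_peaks = False
        bad = False
        for line in rec.splitlines():
            line = line.strip()
            if not line:
                continue
            if in_peaks:
                parts = line.replace("\t", " ").split()
                try:
                    peaks.append((float(parts[0]), float(parts[1])))
                except (IndexError, ValueError):
                    bad = True
                    break
                continue
            if ":" in line:
                key, _, val = line.partition(":")
                key = key.strip().lower()
                header[key] = val.strip()
                if key == "num peaks":
                    declared = int(val)
                    in_peaks = True
        name = header.get("name")
        if bad or name is None or declared is None or declared != len(peaks):
            skipped_bad += 1
            continue
        try:
            seq, charge, modified = _parse_msp_name(name)
        except SpectraParseError:
            skipped_bad += 1
            continue
        if modified and not include_modified:
            skipped_modified += 1
            continue
        if "precursormz" in header:
            pre_mz = float(header["precursormz"])
            parent = _neutral_from_precursor(pre_mz, charge, constants)
        elif "mw" in header:
            parent = float(header["mw"])
            pre_mz = (parent + charge * constants.m_H) / charge
        else:
            skipped_bad += 1
            continue
        if abs(peptide_mass(seq, table, constants) - parent) > consistency_tol:
            skipped_bad += 1
            continue
        mz = [p[0] for p in peaks]
        inten = [p[1] for p in peaks]
        try:
            out.append(LibrarySpectrum(
                title=name, precursor_mz=pre_mz, charge=charge,
                parent_mass=parent, mode=mode, mz=mz, intensity=inten,
                peptide=seq,
            ))
        except SpectraParseError:
            skipped_bad += 1
    if skipped_modified or skipped_bad:
        logger.info("%s: skipped %d modified and %d malformed/inconsistent records",
                    path, skipped_modified, skipped_bad)
    return out


def write_msp(spectra: Sequence[LibrarySpectrum], path: str | Path) -> None:
    lines: list[str] = []
    for s in spectra:
        lines.append(f"Name: {s.peptide}/{s.charge}")
        lines.append(f"MW: {s.parent_mass:.5f}")
        lines.append(f"PrecursorMZ: {s.precursor_mz:.5f}")
        lines.append(f"Num peaks: {len(s)}")
        for mz, inten in zip(s.mz, s.intensity):
            lines.append(f"{mz:.5f}\t{inten:.2f}")
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def pair_spectra(hcd: Iterable[Spectrum], etd: Iterable[Spectrum],
                 tolerance: float = 0.02) -> list[SpectrumPair]:
    """Greedy 1:1 pairing of HCD with ETD spectra.

    Spectra sharing an identical title are paired first (annotated datasets);
    the remainder are matched by parent mass, closest |delta m| first, within
    ``tolerance`` Da.  Unpaired spectra are reported via logging.
    """
    hcd, etd = list(hcd), list(etd)
    pairs: list[SpectrumPair] = []
    used_h: set[int] = set()
    used_e: set[int] = set()
    etd_by_title = {s.title: j for j, s in enumerate(etd)}
    for i, h in enumerate(hcd):
        j = etd_by_title.get(h.title)
        if j is not None and j not in used_e:
            if abs(h.parent_mass - etd[j].parent_mass) <= tolerance:
                pairs.append(SpectrumPair(h, etd[j], tolerance))
                used_h.add(i)
                used_e.add(j)
    candidates = sorted(
        (abs(h.parent_mass - e.parent_mass), i, j)
        for i, h in enumerate(hcd) if i not in used_h
        for j, e in enumerate(etd) if j not in used_e
        if abs(h.parent_mass - e.parent_mass) <= tolerance
    )
    for dm, i, j in candidates:
        if i in used_h or j in used_e:
            continue
        pairs.append(SpectrumPair(hcd[i], etd[j], tolerance))
        used_h.add(i)
        used_e.add(j)
    n_un = (len(hcd) - len(used_h)) + (len(etd) - len(used_e))
    if n_un:
        logger.info("pair_spectra: %d spectra left unpaired", n_un)
    return pairs
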