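"""Amino-acid and fragment-ion mass arithmetic.

Every selection criterion, tag and graph edge in this package reduces to
residue-mass bookkeeping, which lives here.  Two mass regimes are supported:

* **monoisotopic** (default) — residue masses from the standard monoisotopic
  table, proton/water/ammonia masses to five decimals;
* **integer toy mode** — every mass rounded to the nearest integer
  (S=87, E=129, proton=1, H2O=18, NH3=17).  This regime exists so that
  small hand-checkable examples work out exactly and is also convenient in
  tests.

Isoleucine and leucine share a residue mass; sequencing output reports the
canonical ``L`` and flags the ambiguity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from pyteomics import mass as _ptmass
import yaml

__all__ = [
    "STANDARD_RESIDUES",
    "AminoAcidTable",
    "MassConstants",
    "FragmentIon",
    "InvalidResidueError",
    "residue_mass",
    "peptide_mass",
    "theoretical_fragments",
]

#: The 20 standard residue symbols.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

_MONO = {aa: _ptmass.std_aa_mass[aa] for aa in STANDARD_RESIDUES}

#: Nominal (integer) residue masses used by the toy regime.
_INTEGER = {aa: round(m) for aa, m in _MONO.items()}

_PROTON = _ptmass.nist_mass["H+"][0][0]          # 1.00728
_H_ATOM = _ptmass.nist_mass["H"][0][0]           # 1.00783
_WATER = _ptmass.calculate_mass(formula="H2O")   # 18.01056
_NH3 = _ptmass.calculate_mass(formula="NH3")     # 17.02655
_CO = _ptmass.calculate_mass(formula="CO")       # 27.99491


class InvalidResidueError(KeyError):
    """Raised when a symbol is not one of the 20 standard residues."""


@dataclass(frozen=True)
class AminoAcidTable:
    """Residue symbol -> residue mass (Da).

    ``integer_mode`` marks the toy regime where all masses are integers.
    """

    masses: dict[str, float]
    integer_mode: bool = False

    def __post_init__(self) -> None:
        if set(self.masses) != set(STANDARD_RESIDUES):
            raise ValueError("table must contain exactly the 20 standard residues")
        if any(m <= 0 for m in self.masses.values()):
            raise ValueError("residue masses must be positive")
        if self.integer_mode and any(m != int(m) for m in self.masses.values()):
            raise ValueError("integer mode requires integer masses")

    @classmethod
    def monoisotopic(cls) -> "AminoAcidTable":
        return cls(dict(_MONO), integer_mode=False)

    @classmethod
    def integer_toy(cls) -> "AminoAcidTable":
        return cls(dict(_INTEGER), integer_mode=True)

    @classmethod
    def from_config(cls, path: str | Path) -> "AminoAcidTable":
        """Load a table from a YAML/JSON file.

        The file may state ``integer_mode`` and override individual residue
        masses under ``masses`` (e.g. for fixed modifications); unlisted
        residues fall back to the monoisotopic defaults.
        """
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        integer_mode = bool(data.get("integer_mode", False))
        base = dict(_INTEGER if integer_mode else _MONO)
        base.update({str(k): float(v) for k, v in (data.get("masses") or {}).items()})
        return cls(base, integer_mode=integer_mode)

    def __getitem__(self, symbol: str) -> float:
        try:
            return self.masses[symbol]
        except KeyError:
            raise InvalidResidueError(f"unknown residue symbol {symbol!r}") from None


@dataclass(frozen=True)
class MassConstants:
    """Small-molecule masses threaded through the selection arithmetic.

    ``m_H`` is the charge-carrier (proton) mass used both for charge-state
    conversion and in the complementarity relations (m_p + 2 m_H for b/y,
    m_p + 3 m_H for c/z).  ``losses`` maps loss names to the neutral-loss
    masses considered during peak selection (water and ammonia).
    """

    m_H: float = _PROTON
    h_atom: float = _H_ATOM
    water: float = _WATER
    co: float = _CO
    losses: dict[str, float] = field(
        default_factory=lambda: {"H2O": _WATER, "NH3": _NH3}
    )

    def __post_init__(self) -> None:
        if not self.losses:
            raise ValueError("losses list must be non-empty")

    @classmethod
    def monoisotopic(cls) -> "MassConstants":
        return cls()

    @classmethod
    def integer_toy(cls) -> "MassConstants":
        return cls(m_H=1.0, h_atom=1.0, water=18.0, co=28.0,
                   losses={"H2O": 18.0, "NH3": 17.0})

    @property
    def nh3(self) -> float:
        return self.losses["NH3"] if "NH3" in self.losses else _NH3

    def loss_offsets(self) -> tuple[float, ...]:
        """Offsets sigma explored during selection: 0 and +/- each loss mass."""
        out = [0.0]
        for m in self.losses.values():
            out.extend((m, -m))
        return tuple(out)


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical backbone fragment.

    ``neutral`` is the neutral fragment mass; ``mz`` its m/z at ``charge``.
    ``loss`` names the neutral loss applied (None for the plain ion).
    """

    series: str
    index: int
    charge: int
    loss: str | None
    neutral: float
    mz: float

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.index < 1:
            raise ValueError("position index must be >= 1")
        if self.mz <= 0:
            raise ValueError("m/z must be positive")


def residue_mass(symbol: str, table: AminoAcidTable) -> float:
    """Mass of one residue; raises :class:`InvalidResidueError` otherwise."""
    return table[symbol]


def peptide_mass(sequence: str, table: AminoAcidTable,
                 constants: MassConstants) -> float:
    """Neutral peptide mass: residue sum plus one water."""
    return sum(table[aa] for aa in sequence) + constants.water


def _series_neutral(series: str, prefix: float, suffix: float,
                    constants: MassConstants, z_variant: str) -> float:
    if series == "b":
        return prefix
    if series == "a":
        return prefix - constants.co
    if series == "c":
        return prefix + constants.nh3
    if series == "y":
        return suffix + constants.water
    if series == "x":
        return suffix + constants.water + constants.co
    if series == "z":
        base = suffix + constants.water - constants.nh3
        if z_variant == "z+1":  # z-dot: radical with one extra hydrogen
            base += constants.h_atom
        return base
    raise ValueError(f"unknown ion series {series!r}")


def theoretical_fragments(
    sequence: str,
    series: Iterable[str],
    max_charge: int,
    losses: Sequence[str | None],
    table: AminoAcidTable,
    constants: MassConstants,
    z_variant: str = "z+1",
) -> list[FragmentIon]:
    """Complete fragment ladders for the requested series/charges/losses.

    N-terminal series (a/b/c) at position k cover the first k residues;
    C-terminal series (x/y/z) cover the last k.  ``z_variant`` selects the
    z-ion convention: ``"z+1"`` (z-dot, the ETD radical ion, default) or
    ``"z"`` (y minus ammonia).
    """
    series = sorted(set(series))
    if not series:
        raise ValueError("series set must not be empty")
    if len(sequence) < 2:
        raise ValueError("peptide must have at least 2 residues")
    if max_charge < 1:
        raise ValueError("max charge must be >= 1")
    res = [table[aa] for aa in sequence]
    total = sum(res)
    out: list[FragmentIon] = []
    prefix = 0.0
    for k in range(1, len(sequence)):
        prefix += res[k - 1]
        suffix = total - prefix
        for s in series:
            nterm = s in "abc"
            base = _series_neutral(s, prefix, suffix, constants, z_variant)
            index = k if nterm else len(sequence) - k
            for loss in losses:
                neutral = base - (constants.losses[loss] if loss else 0.0)
                if neutral <= 0:
                    continue
                for z in range(1, max_charge + 1):
                    mz = (neutral + z * constants.m_H) / z
                    out.append(FragmentIon(s, index, z, loss, neutral, mz))
    out.sort(key=lambda f: (f.mz, f.series, f.index, f.charge, f.loss or ""))
    return out


def to_charge1(mz: float, charge: int, constants: MassConstants) -> float:
    """Re-express an m/z observed at ``charge`` as its charge-1 equivalent."""
    return charge * mz - (charge - 1) * constants.m_H


def canonical_il(sequence: str) -> str:
    """Collapse isoleucine onto leucine (they are isobaric)."""
    return sequence.replace("I", "L")
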