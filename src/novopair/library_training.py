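"""Training significance scores from annotated spectral libraries.

Each selection criterion (amino-acid difference, ion complementarity) is run
on every annotated library spectrum; its per-spectrum accuracy is the
fraction of selected peaks that are real fragment ions of the annotated
peptide.  The library score of a criterion is the unweighted mean of these
per-spectrum accuracies over the spectra where the criterion selected
anything.

HCD complementarity behaves differently for peak pairs in the middle of the
m/z range than for pairs near the ends, so the HCD model carries a split
score (s_comp_middle / s_comp_end); ETD keeps a single complementarity
score.  The amino-acid difference uses one pooled score rather than one per
residue pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .chemistry import AminoAcidTable, MassConstants, peptide_mass, theoretical_fragments
from .merge import LossPairPolicy, expand_charges, select_aa_difference, select_complementarity
from .spectra_io import HCD, LibrarySpectrum

__all__ = [
    "CriterionAccuracy",
    "ScoreModel",
    "TrainingError",
    "annotate_real_ions",
    "spectrum_criterion_accuracy",
    "train",
]

SERIES_BY_MODE = {"HCD": ("b", "y"), "ETD": ("c", "z")}
LOSS_VARIANTS = (None, "H2O", "NH3")


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class CriterionAccuracy:
    """Per-spectrum selection accuracy of one criterion."""

    spectrum_id: str
    criterion: str            # 'aa' | 'comp' | 'compM' | 'compE'
    n_select: int
    n_real: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_real <= self.n_select):
            raise ValueError("need 0 <= n_real <= n_select")

    @property
    def skipped(self) -> bool:
        return self.n_select == 0

    @property
    def accuracy(self) -> float:
        if self.skipped:
            raise ValueError("accuracy undefined when nothing was selected")
        return self.n_real / self.n_select


@dataclass
class ScoreModel:
    """Trained significance scores for one fragmentation mode.

    HCD models carry the positional complementarity split
    (``s_comp_middle``/``s_comp_end``); ETD models a single ``s_comp``.
    """

    mode: str
    s_aa: float
    s_comp: float | None = None
    s_comp_middle: float | None = None
    s_comp_end: float | None = None
    n_spectra: int = 1
    metadata: dict = field(default_factory=dict)

    SCHEMA_VERSION = 1

    def __post_init__(self) -> None:
        if self.mode == HCD:
            required = (self.s_aa, self.s_comp_middle, self.s_comp_end)
        else:
            required = (self.s_aa, self.s_comp)
        if any(v is None for v in required):
            raise ValueError(f"model for {self.mode} is missing required scores")
        if any(not (0.0 <= v <= 1.0) for v in required):
            raise ValueError("scores must lie in [0, 1]")
        if self.n_spectra < 1:
            raise ValueError("n_spectra must be >= 1")

    def to_json(self, path: str | Path) -> None:
        data = {
            "schema_version": self.SCHEMA_VERSION,
            "mode": self.mode,
            "s_aa": self.s_aa,
            "s_comp": self.s_comp,
            "s_comp_middle": self.s_comp_middle,
            "s_comp_end": self.s_comp_end,
            "n_spectra": self.n_spectra,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(data, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ScoreModel":
        data = json.loads(Path(path).read_text())
        data.pop("schema_version", None)
        return cls(**data)

    @classmethod
    def uniform(cls, mode: str, value: float = 1.0) -> "ScoreModel":
        """A flat model (every criterion scores ``value``); handy for toys."""
        if mode == HCD:
            return cls(mode=mode, s_aa=value, s_comp_middle=value, s_comp_end=value)
        return cls(mode=mode, s_aa=value, s_comp=value)


def annotate_real_ions(
    spec: LibrarySpectrum,
    table: AminoAcidTable,
    constants: MassConstants,
    tolerance: float = 0.01,
    consistency_tol: float = 0.1,
) -> np.ndarray:
    """Boolean mask over the spectrum's peaks: True where a peak matches a
    theoretical fragment of the annotated peptide.

    The fragment space is the mode's series (b/y for HCD, c/z for ETD) at
    charges 1..n-1 with no loss, -H2O and -NH3.  The tolerance boundary is
    closed.  A spectrum whose annotated-peptide mass disagrees with the
    precursor beyond ``consistency_tol`` is rejected.
    """
    expected = peptide_mass(spec.peptide, table, constants)
    if abs(expected - spec.parent_mass) > consistency_tol:
        raise TrainingError(
            f"{spec.title}: annotated peptide mass {expected:.4f} inconsistent "
            f"with precursor-derived {spec.parent_mass:.4f}"
        )
    frags = theoretical_fragments(
        spec.peptide, SERIES_BY_MODE[spec.mode], max(spec.charge - 1, 1),
        LOSS_VARIANTS, table, constants,
    )
    theo = np.array(sorted(f.mz for f in frags))
    idx = np.searchsorted(theo, spec.mz)
    real = np.zeros(len(spec), dtype=bool)
    for shift in (0, -1):
        j = np.clip(idx + shift, 0, len(theo) - 1)
        real |= np.abs(spec.mz - theo[j]) <= tolerance
    return real


def _selected_ions(
    spec: LibrarySpectrum,
    table: AminoAcidTable,
    constants: MassConstants,
    theta: float,
    loss_pair_policy: LossPairPolicy,
) -> dict[str, set[int]]:
    """Source-peak indices selected per criterion tag (once per ion)."""
    hypotheses = expand_charges(spec, constants)
    aa: set[int] = set()
    for hyp in hypotheses:
        for hit in select_aa_difference(hyp, table, constants, theta):
            aa.add(int(hyp.source_index[hit.peak_index]))
    comp_hits = select_complementarity(
        hypotheses, spec.mode, spec.parent_mass, constants, theta,
        loss_pair_policy=loss_pair_policy, corroborated=frozenset(aa),
    )
    sel: dict[str, set[int]] = {"aa": aa}
    if spec.mode == HCD:
        sel["compM"] = {m[1] for h in comp_hits if h.middle for m in (h.u, h.v)}
        sel["compE"] = {m[1] for h in comp_hits if not h.middle for m in (h.u, h.v)}
    else:
        sel["comp"] = {m[1] for h in comp_hits for m in (h.u, h.v)}
    return sel


def spectrum_criterion_accuracy(
    spec: LibrarySpectrum,
    criterion: str,
    table: AminoAcidTable,
    constants: MassConstants,
    theta: float = 0.01,
    tolerance: float | None = None,
    loss_pair_policy: LossPairPolicy = "corroborated",
) -> CriterionAccuracy:
    """Accuracy of one criterion on one annotated spectrum.

    ``tolerance`` (real-ion annotation) defaults to theta.
    """
    tolerance = theta if tolerance is None else tolerance
    sel = _selected_ions(spec, table, constants, theta, loss_pair_policy)
    if criterion not in sel:
        raise ValueError(f"criterion {criterion!r} not defined for {spec.mode}")
    real = annotate_real_ions(spec, table, constants, tolerance)
    ions = sel[criterion]
    return CriterionAccuracy(
        spectrum_id=spec.title, criterion=criterion,
        n_select=len(ions), n_real=int(sum(real[i] for i in ions)),
    )


def train(
    library: Sequence[LibrarySpectrum],
    mode: str,
    table: AminoAcidTable | None = None,
    constants: MassConstants | None = None,
    theta: float = 0.01,
    tolerance: float | None = None,
    loss_pair_policy: LossPairPolicy = "corroborated",
) -> ScoreModel:
    """Train a :class:`ScoreModel` on an annotated library.

    Each score is the mean per-spectrum accuracy over contributing spectra
    (those where the criterion selected at least one ion); mass-inconsistent
    spectra are dropped.  Raises :class:`TrainingError` if any required
    criterion has no contributing spectrum.
    """
    table = table or AminoAcidTable.monoisotopic()
    constants = constants or MassConstants.monoisotopic()
    tolerance = theta if tolerance is None else tolerance
    criteria = ("aa", "compM", "compE") if mode == HCD else ("aa", "comp")
    accs: dict[str, list[float]] = {c: [] for c in criteria}
    n_used = 0
    for spec in library:
        if spec.mode != mode:
            raise TrainingError(f"{spec.title}: mode {spec.mode} in a {mode} library")
        try:
            sel = _selected_ions(spec, table, constants, theta, loss_pair_policy)
            real = annotate_real_ions(spec, table, constants, tolerance)
        except TrainingError:
            continue
        n_used += 1
        for c in criteria:
            ions = sel[c]
            if ions:
                accs[c].append(sum(real[i] for i in ions) / len(ions))
    missing = [c for c in criteria if not accs[c]]
    if missing:
        raise TrainingError(f"no contributing spectra for criteria: {missing}")
    means = {c: float(np.mean(v)) for c, v in accs.items()}
    meta = {"theta": theta, "tolerance": tolerance,
            "losses": list(constants.losses),
            "loss_pair_policy": loss_pair_policy,
            "contributing": {c: len(v) for c, v in accs.items()}}
    if mode == HCD:
        return ScoreModel(mode=mode, s_aa=means["aa"],
                          s_comp_middle=means["compM"], s_comp_end=means["compE"],
                          n_spectra=n_used, metadata=meta)
    return ScoreModel(mode=mode, s_aa=means["aa"], s_comp=means["comp"],
                      n_spectra=n_used, metadata=meta)
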