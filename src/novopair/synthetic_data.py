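"""Simulation of annotated libraries and HCD/ETD spectrum pairs.

The generator emulates the statistical structure the sequencing algorithm
assumes: complete b/y (HCD) and c/z (ETD) fragment ladders of a shared
precursor peptide, optionally thinned by detection dropout, decorated with
water/ammonia loss satellites, perturbed by Gaussian m/z jitter, and mixed
with uniform noise peaks kept well away (>= 3 theta) from every theoretical
fragment so that ground-truth labels stay unambiguous.  Intensities are
drawn from a simple lognormal and play no role in the algorithm.

Peptides are tryptic-like (C-terminal K or R); isoleucine is excluded from
the alphabet because it is isobaric with leucine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemistry import AminoAcidTable, MassConstants, peptide_mass, theoretical_fragments
from .spectra_io import ETD, HCD, LibrarySpectrum, Spectrum, SpectrumPair

__all__ = ["SimulationConfig", "SimulatedPair", "simulate_pair",
           "simulate_library", "random_peptide"]

ALPHABET = "ACDEFGHKLMNPQRSTVWY"  # 19 residues, I folded into L
SERIES = {HCD: ("b", "y"), ETD: ("c", "z")}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the spectrum simulator.

    ``noise_fraction`` is the fraction of the final peak list that is noise;
    ``detection_probability`` is the chance a theoretical fragment produces
    a peak; ``loss_probability`` the chance each detected fragment also
    shows a loss satellite; ``mz_jitter_sd`` the m/z error s.d. in Da.
    """

    length_range: tuple[int, int] = (7, 12)
    charge_range: tuple[int, int] = (2, 3)
    loss_probability: float = 0.2
    noise_fraction: float = 0.0
    detection_probability: float = 1.0
    mz_jitter_sd: float = 0.0
    theta: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.loss_probability, self.noise_fraction,
                  self.detection_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.mz_jitter_sd < 0:
            raise ValueError("jitter must be non-negative")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


@dataclass
class SimulatedPair:
    """A spectrum pair plus ground truth."""

    pair: SpectrumPair
    peptide: str
    hcd_real: np.ndarray  # per-peak labels, aligned with pair.hcd.mz
    etd_real: np.ndarray


def random_peptide(rng: np.random.Generator, config: SimulationConfig) -> str:
    lo, hi = config.length_range
    length = int(rng.integers(lo, hi + 1))
    body = "".join(rng.choice(list(ALPHABET), size=length - 1))
    return body + rng.choice(["K", "R"])


def _simulate_spectrum(
    peptide: str,
    mode: str,
    charge: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    rng_noise: np.random.Generator,
    table: AminoAcidTable,
    constants: MassConstants,
    title: str,
) -> tuple[Spectrum, np.ndarray]:
    """One simulated spectrum.

    Noise m/z values come from their own generator, drawn sequentially, so
    that for a fixed seed the noise peaks at a lower noise fraction are a
    prefix of those at a higher one — noise levels form a nested, paired
    design that isolates the effect of noise from resampling variance.
    """
    base = theoretical_fragments(peptide, SERIES[mode], max(charge - 1, 1),
                                 [None], table, constants)
    with_loss = theoretical_fragments(peptide, SERIES[mode], max(charge - 1, 1),
                                      ["H2O", "NH3"], table, constants)
    mzs: list[float] = []
    for frag in base:
        if rng.random() >= config.detection_probability:
            continue
        mzs.append(frag.mz)
    loss_pool = [f.mz for f in with_loss]
    for mz in list(loss_pool):
        if rng.random() < config.loss_probability:
            mzs.append(mz)
    if config.mz_jitter_sd > 0:
        mzs = [mz + rng.normal(0.0, config.mz_jitter_sd) for mz in mzs]
    n_real = len(mzs)
    # exclusion zone around every theoretical fragment keeps labels unambiguous
    theo = np.array(sorted(f.mz for f in base + with_loss))
    f = config.noise_fraction
    n_noise = int(round(n_real * f / (1.0 - f))) if f < 1.0 else 0
    parent = peptide_mass(peptide, table, constants)
    precursor_mz = (parent + charge * constants.m_H) / charge
    hi = max(precursor_mz * charge, 200.0)
    noise: list[float] = []
    while len(noise) < n_noise:
        cand = float(rng_noise.uniform(100.0, hi))
        j = np.searchsorted(theo, cand)
        near = min(
            abs(cand - theo[k]) for k in (max(j - 1, 0), min(j, len(theo) - 1))
        )
        if near >= 3 * config.theta:
            noise.append(cand)
    all_mz = np.array(mzs + noise)
    real = np.array([True] * n_real + [False] * n_noise)
    intensity = np.concatenate([
        100.0 * rng.lognormal(0.0, 0.6, size=n_real),
        10.0 * np.array([rng_noise.lognormal(0.0, 0.6) for _ in range(n_noise)]),
    ]) if len(all_mz) else np.array([])
    order = np.argsort(all_mz, kind="stable")
    spec = Spectrum(
        title=title, precursor_mz=precursor_mz, charge=charge,
        parent_mass=parent, mode=mode,
        mz=all_mz[order], intensity=intensity[order],
    )
    return spec, real[order]


def simulate_pair(
    peptide: str,
    config: SimulationConfig,
    table: AminoAcidTable | None = None,
    constants: MassConstants | None = None,
    charge: int | None = None,
    seed: int | None = None,
) -> SimulatedPair:
    """Simulate one HCD/ETD pair of the given peptide with ground truth."""
    if len(peptide) < 2:
        raise ValueError("peptide must have at least 2 residues")
    table = table or AminoAcidTable.monoisotopic()
    constants = constants or MassConstants.monoisotopic()
    ss = np.random.SeedSequence(config.seed if seed is None else seed)
    rng = np.random.default_rng(ss)
    sub_h, sub_e = ss.spawn(2)
    if charge is None:
        lo, hi = config.charge_range
        charge = int(rng.integers(lo, hi + 1))
    hcd, hcd_real = _simulate_spectrum(
        peptide, HCD, charge, config, np.random.default_rng(sub_h),
        np.random.default_rng(sub_h.spawn(1)[0]), table, constants,
        title=f"sim|{peptide}|HCD")
    etd, etd_real = _simulate_spectrum(
        peptide, ETD, charge, config, np.random.default_rng(sub_e),
        np.random.default_rng(sub_e.spawn(1)[0]), table, constants,
        title=f"sim|{peptide}|ETD")
    pair = SpectrumPair(hcd, etd, tolerance=max(config.theta, 0.02))
    return SimulatedPair(pair=pair, peptide=peptide,
                         hcd_real=hcd_real, etd_real=etd_real)


def simulate_library(
    n_peptides: int,
    config: SimulationConfig,
    mode: str,
    table: AminoAcidTable | None = None,
    constants: MassConstants | None = None,
) -> list[LibrarySpectrum]:
    """Simulate an annotated single-mode spectral library."""
    if n_peptides < 1:
        raise ValueError("need at least one peptide")
    table = table or AminoAcidTable.monoisotopic()
    constants = constants or MassConstants.monoisotopic()
    records = np.random.SeedSequence(config.seed).spawn(n_peptides)
    out: list[LibrarySpectrum] = []
    for i, record_seed in enumerate(records):
        rng = np.random.default_rng(record_seed)
        rng_noise = np.random.default_rng(record_seed.spawn(1)[0])
        peptide = random_peptide(rng, config)
        lo, hi = config.charge_range
        charge = int(rng.integers(lo, hi + 1))
        spec, _real = _simulate_spectrum(
            peptide, mode, charge, config, rng, rng_noise, table, constants,
            title=f"lib|{i}|{peptide}|{mode}")
        out.append(LibrarySpectrum(
            title=spec.title, precursor_mz=spec.precursor_mz,
            charge=spec.charge, parent_mass=spec.parent_mass, mode=mode,
            mz=spec.mz, intensity=spec.intensity, peptide=peptide,
        ))
    return out
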