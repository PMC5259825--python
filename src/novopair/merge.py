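"""Merging an HCD/ETD spectrum pair into one scored spectrum.

Two selection criteria pull peaks into the merged spectrum ``S_m``:

* **amino-acid mass difference** — a peak ``v`` is selected (as the middle
  ion) if peaks ``u < v < t`` exist with both ``v - u`` and ``t - v`` equal
  to a residue mass, up to a neutral-loss offset sigma in {0, +/-H2O, +/-NH3}
  per side, within the threshold theta;
* **ion complementarity** — peaks ``u`` and ``v`` are both selected when
  ``u+ + v+`` equals ``m_p + 2 m_H`` (HCD, b/y) or ``m_p + 3 m_H`` (ETD,
  c/z) up to a sigma offset, within theta.

Both criteria run on every charge hypothesis of a spectrum (all ions assumed
at charge i, re-expressed at charge 1, for i = 1 .. n-1); complementary
partners may come from different hypotheses of the same spectrum, which is
how multiply charged fragments are recognised.  Each selected peak carries
the library-trained significance score of the criteria that fired;
multi-criterion peaks sum the scores of the distinct criteria.

Loss-shifted complementary pairs (sigma != 0) are by default only accepted
when at least one member is corroborated by an exact (sigma = 0) selection —
an uncorroborated pair sum deficient by exactly one loss mass is weak
evidence.  ``loss_pair_policy="all"`` accepts every pair satisfying the
relation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .chemistry import AminoAcidTable, MassConstants, to_charge1
from .spectra_io import HCD, Spectrum, SpectrumPair

__all__ = [
    "ChargeHypothesis",
    "ScoredPeak",
    "MergedSpectrum",
    "AADifferenceHit",
    "ComplementarityHit",
    "expand_charges",
    "select_aa_difference",
    "select_complementarity",
    "merge_pair",
]

LossPairPolicy = Literal["corroborated", "all"]


@dataclass(frozen=True)
class ChargeHypothesis:
    """A spectrum's peaks re-expressed at charge 1 under assumed charge i."""

    spectrum: Spectrum
    charge: int
    mz1: np.ndarray          # charge-1 m/z, ascending
    source_index: np.ndarray  # index into spectrum.mz

    def __len__(self) -> int:
        return len(self.mz1)


@dataclass
class ScoredPeak:
    """A merged-spectrum peak with its accumulated significance score.

    ``criteria`` records which criterion tags fired ('aa', 'comp', 'compM',
    'compE'); ``score`` is the sum over distinct criteria.  ``sources`` holds
    (mode, source peak index, assumed charge) provenance triples.
    """

    mz1: float
    score: float
    criteria: frozenset[str]
    sources: frozenset[tuple[str, int, int]]


@dataclass
class MergedSpectrum:
    """The merged spectrum S_m: selected, scored, coalesced charge-1 peaks."""

    peaks: list[ScoredPeak]
    parent_mass: float
    theta: float

    def __post_init__(self) -> None:
        self.peaks.sort(key=lambda p: p.mz1)
        for a, b in zip(self.peaks, self.peaks[1:]):
            if b.mz1 - a.mz1 <= self.theta:
                raise ValueError("merged spectrum contains un-coalesced duplicates")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz1(self) -> np.ndarray:
        return np.array([p.mz1 for p in self.peaks])

    @property
    def scores(self) -> np.ndarray:
        return np.array([p.score for p in self.peaks])


@dataclass(frozen=True)
class AADifferenceHit:
    """Middle ion v selected by the amino-acid difference criterion."""

    peak_index: int        # index into the hypothesis
    mz1: float
    witnesses: tuple       # (u_idx, t_idx, left residue, sigma_l, right residue, sigma_r)


@dataclass(frozen=True)
class ComplementarityHit:
    """A complementary pair (u, v); members may span charge hypotheses."""

    u: tuple[int, int, float]  # (hypothesis charge, source peak index, mz1)
    v: tuple[int, int, float]
    sigma: float
    middle: bool               # both members in the middle two m/z quarters


def expand_charges(spectrum: Spectrum,
                   constants: MassConstants) -> list[ChargeHypothesis]:
    """Build the n-1 charge hypotheses of a spectrum (i = 1 .. n-1)."""
    n = spectrum.charge
    if n < 2:
        raise ValueError(
            f"{spectrum.title}: precursor charge {n} leaves no fragment "
            "charge states to hypothesise"
        )
    out = []
    for i in range(1, n):
        mz1 = to_charge1(spectrum.mz, i, constants)
        out.append(ChargeHypothesis(
            spectrum=spectrum, charge=i, mz1=np.asarray(mz1, dtype=float),
            source_index=np.arange(len(spectrum.mz)),
        ))
    return out


def _sigma_patterns(constants: MassConstants) -> list[tuple[float, float]]:
    """(sigma_left, sigma_right) pairs consistent with the middle ion's loss.

    A middle ion that lost a neutral of mass m sits m short of its left
    residue gap and m beyond its right one, so the admissible patterns are
    (0, 0) and (-m, +m) for each loss considered.
    """
    patterns = [(0.0, 0.0)]
    patterns.extend((-m, m) for m in constants.losses.values())
    return patterns


def _shifted_targets(table: AminoAcidTable, shift: float) -> np.ndarray:
    vals = sorted({m + shift for m in table.masses.values() if m + shift > 0})
    return np.array(vals)


def _matches_any(diffs: np.ndarray, targets: np.ndarray,
                 theta: float) -> np.ndarray:
    """Boolean mask: each diff within theta (closed) of some target."""
    idx = np.searchsorted(targets, diffs)
    ok = np.zeros(diffs.shape, dtype=bool)
    for shift in (0, -1):
        j = np.clip(idx + shift, 0, len(targets) - 1)
        ok |= np.abs(diffs - targets[j]) <= theta
    return ok


def select_aa_difference(
    hypothesis: ChargeHypothesis,
    table: AminoAcidTable,
    constants: MassConstants,
    theta: float,
) -> list[AADifferenceHit]:
    """Middle ions v with residue-mass differences to some u < v < t.

    Each side may use its own sigma offset (0 or +/- a loss mass), as when a
    water-loss ion sits a loss short of its left neighbour and a loss beyond
    its right one.
    """
    mz = hypothesis.mz1
    p = len(mz)
    if p < 3:
        return []
    diffs = mz[None, :] - mz[:, None]          # diffs[u, v] = mz[v] - mz[u]
    witnesses: dict[int, list] = {}
    for sigma_l, sigma_r in _sigma_patterns(constants):
        left = np.triu(
            _matches_any(diffs, _shifted_targets(table, sigma_l), theta), k=1)
        right = np.triu(
            _matches_any(diffs, _shifted_targets(table, sigma_r), theta), k=1)
        has_left = left.any(axis=0)            # v has matching u < v
        has_right = right.any(axis=1)          # v has matching t > v
        for v in range(1, p - 1):
            if has_left[v] and has_right[v]:
                u = int(np.nonzero(left[:, v])[0][0])
                t = int(np.nonzero(right[v, :])[0][0])
                witnesses.setdefault(v, []).append((u, t, sigma_l, sigma_r))
    return [AADifferenceHit(v, float(mz[v]), tuple(wit))
            for v, wit in sorted(witnesses.items())]


def select_complementarity(
    hypotheses: Sequence[ChargeHypothesis],
    mode: str,
    parent_mass: float,
    constants: MassConstants,
    theta: float,
    loss_pair_policy: LossPairPolicy = "corroborated",
    corroborated: frozenset[int] = frozenset(),
) -> list[ComplementarityHit]:
    """Complementary peak pairs across all charge hypotheses of one spectrum.

    The pair sum is tested against ``m_p + 2 m_H`` (HCD) or ``m_p + 3 m_H``
    (ETD) with sigma offsets.  ``corroborated`` names source-peak indices
    already selected by an exact criterion; under the default policy a
    sigma != 0 pair needs at least one corroborated member (exact pairs
    corroborate their own members first).
    """
    k = 2 if mode == HCD else 3
    target = parent_mass + k * constants.m_H
    pool: list[tuple[float, int, int]] = []  # (mz1, hyp charge, source idx)
    for hyp in hypotheses:
        for mz1, src in zip(hyp.mz1, hyp.source_index):
            pool.append((float(mz1), hyp.charge, int(src)))
    pool.sort()
    offsets = constants.loss_offsets()
    raw: list[tuple[float, tuple, tuple]] = []
    for a in range(len(pool)):
        for b in range(a + 1, len(pool)):
            ua, ub = pool[a], pool[b]
            if ua[2] == ub[2]:
                continue  # same source ion under two charge assumptions
            s = ua[0] + ub[0]
            for sigma in offsets:
                if abs(target - s - sigma) <= theta:
                    raw.append((sigma, ua, ub))
                    break
    exact = [(s, a, b) for s, a, b in raw if s == 0.0]
    lossy = [(s, a, b) for s, a, b in raw if s != 0.0]
    if loss_pair_policy == "corroborated":
        support = set(corroborated)
        support.update(m[2] for _, a, b in exact for m in (a, b))
        lossy = [(s, a, b) for s, a, b in lossy
                 if a[2] in support or b[2] in support]
    axis_max = max((v[0] for v in pool), default=0.0)
    lo, hi = axis_max / 4.0, 3.0 * axis_max / 4.0
    hits = []
    for sigma, ua, ub in exact + lossy:
        middle = (lo <= ua[0] < hi) and (lo <= ub[0] < hi)
        hits.append(ComplementarityHit(
            u=(ua[1], ua[2], ua[0]), v=(ub[1], ub[2], ub[0]),
            sigma=sigma, middle=middle,
        ))
    return hits


def _comp_score(model, middle_pairs: bool) -> float:
    """Complementarity score from a trained model, honouring the HCD split."""
    if model.mode == HCD:
        return model.s_comp_middle if middle_pairs else model.s_comp_end
    return model.s_comp


def _select_spectrum(
    spectrum: Spectrum,
    mode: str,
    model,
    table: AminoAcidTable,
    constants: MassConstants,
    theta: float,
    loss_pair_policy: LossPairPolicy,
) -> dict[tuple[int, int], tuple[float, set[str], float]]:
    """Run both criteria; return (charge, src) -> (mz1, criteria, score)."""
    hypotheses = expand_charges(spectrum, constants)
    selected: dict[tuple[int, int], tuple[float, set[str], float]] = {}

    def add(charge: int, src: int, mz1: float, tag: str, score: float) -> None:
        key = (charge, src)
        if key in selected:
            mz0, tags, total = selected[key]
            if tag not in tags:
                selected[key] = (mz0, tags | {tag}, total + score)
        else:
            selected[key] = (mz1, {tag}, score)

    aa_selected: set[int] = set()
    for hyp in hypotheses:
        for hit in select_aa_difference(hyp, table, constants, theta):
            src = int(hyp.source_index[hit.peak_index])
            aa_selected.add(src)
            add(hyp.charge, src, hit.mz1, "aa", model.s_aa)

    comp_hits = select_complementarity(
        hypotheses, mode, spectrum.parent_mass, constants, theta,
        loss_pair_policy=loss_pair_policy, corroborated=frozenset(aa_selected),
    )
    # a peak in several pairs gets the complementarity criterion once,
    # at the best (largest) positional score among its pairs
    best: dict[tuple[int, int, float], tuple[str, float]] = {}
    for hit in comp_hits:
        for charge, src, mz1 in (hit.u, hit.v):
            tag = ("compM" if hit.middle else "compE") if mode == HCD else "comp"
            score = _comp_score(model, hit.middle)
            key = (charge, src, mz1)
            if key not in best or score > best[key][1]:
                best[key] = (tag, score)
    for (charge, src, mz1), (tag, score) in best.items():
        add(charge, src, mz1, tag, score)
    return selected


def _coalesce(raw: list[ScoredPeak], theta: float) -> list[ScoredPeak]:
    """Merge selected peaks within theta into single score-summed peaks.

    Iterated to a fixed point: weighted-mean positions can land two fused
    clusters back within theta of each other.
    """
    peaks = sorted(raw, key=lambda p: p.mz1)
    while True:
        out: list[ScoredPeak] = []
        cluster: list[ScoredPeak] = []
        for p in peaks:
            if cluster and p.mz1 - cluster[-1].mz1 > theta:
                out.append(_fuse(cluster))
                cluster = []
            cluster.append(p)
        if cluster:
            out.append(_fuse(cluster))
        if len(out) == len(peaks):
            return out
        peaks = out


def _fuse(cluster: list[ScoredPeak]) -> ScoredPeak:
    if len(cluster) == 1:
        return cluster[0]
    total = sum(p.score for p in cluster)
    if total > 0:
        mz = sum(p.mz1 * p.score for p in cluster) / total
    else:
        mz = sum(p.mz1 for p in cluster) / len(cluster)
    return ScoredPeak(
        mz1=mz, score=total,
        criteria=frozenset().union(*(p.criteria for p in cluster)),
        sources=frozenset().union(*(p.sources for p in cluster)),
    )


def merge_pair(
    pair: SpectrumPair,
    hcd_model,
    etd_model,
    table: AminoAcidTable,
    constants: MassConstants,
    theta: float = 0.01,
    loss_pair_policy: LossPairPolicy = "corroborated",
) -> MergedSpectrum:
    """Merge one HCD/ETD pair into the scored spectrum S_m.

    Unselected peaks are dropped; selected peaks closer than theta coalesce
    at the score-weighted mean m/z with summed scores.
    """
    for model, want in ((hcd_model, HCD), (etd_model, "ETD")):
        if model is None or getattr(model, "mode", None) != want:
            raise ValueError(f"a trained {want} score model is required")
    raw: list[ScoredPeak] = []
    for spectrum, mode, model in (
        (pair.hcd, HCD, hcd_model),
        (pair.etd, "ETD", etd_model),
    ):
        sel = _select_spectrum(spectrum, mode, model, table, constants, theta,
                               loss_pair_policy)
        for (charge, src), (mz1, tags, score) in sel.items():
            raw.append(ScoredPeak(
                mz1=mz1, score=score, criteria=frozenset(tags),
                sources=frozenset({(mode, src, charge)}),
            ))
    return MergedSpectrum(_coalesce(raw, theta), pair.parent_mass, theta)
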