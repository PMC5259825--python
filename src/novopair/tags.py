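"""Sequence-tag generation, extension, scoring and selection.

A length-3 tag is read off four peaks whose three consecutive charge-1 m/z
differences each match a residue mass within theta.  Tags overlapping in two
residues *and* in their supporting peaks are repeatedly concatenated into
longer tags until closure.  Tags are scored by a weighted mean of their
supporting peaks' significance scores and the top ``Sel`` are kept as
sequencing anchors.

The printed weighting 1 + 0.1*min{l, l_t - l} (position l = 1 .. l_t+1) is
asymmetric — the first peak of a length-3 tag weighs 1.1, the last 0.9.  A
``symmetric`` option replaces it with 1 + 0.1*min{l-1, l_t+1-l}, which
down-weights both ends equally; the printed form is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

from .chemistry import AminoAcidTable
from .merge import MergedSpectrum

__all__ = ["Tag", "TagSet", "generate_tags", "extend_tags", "score_tag",
           "select_tags", "tags_from_merged"]

WeightScheme = Literal["printed", "symmetric"]


@dataclass(frozen=True)
class Tag:
    """A partial sequence with its supporting peaks.

    A tag of length ``l_t`` is supported by ``l_t + 1`` peaks whose
    consecutive differences spell out the residues.  ``modes`` records the
    fragmentation mode(s) of the source peaks.
    """

    sequence: str
    peaks: tuple[float, ...]        # charge-1 m/z, ascending
    peak_scores: tuple[float, ...]  # ss of each supporting peak (0 if unknown)
    modes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(self.sequence) < 3:
            raise ValueError("tags are at least three residues long")
        if len(self.peaks) != len(self.sequence) + 1:
            raise ValueError("a length-l tag needs l+1 supporting peaks")
        if len(self.peak_scores) != len(self.peaks):
            raise ValueError("one score per supporting peak")
        if any(b <= a for a, b in zip(self.peaks, self.peaks[1:])):
            raise ValueError("supporting peaks must ascend")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate_masses(self, table: AminoAcidTable, theta: float) -> bool:
        """Re-check that peak differences match the residue string."""
        return all(
            abs((b - a) - table[aa]) <= theta
            for a, b, aa in zip(self.peaks, self.peaks[1:], self.sequence)
        )


@dataclass
class TagSet:
    tags: list[Tag] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tags)

    def __iter__(self):
        return iter(self.tags)


def _sort_key(tag: Tag, scores: dict[Tag, float]):
    return (-scores[tag], -tag.length, tag.sequence, tag.peaks)


def generate_tags(
    peaks: Sequence[tuple[float, float]],
    table: AminoAcidTable,
    theta: float,
    modes: Sequence[frozenset[str]] | None = None,
) -> TagSet:
    """Length-3 tags from every 4-peak chain with residue-mass differences.

    ``peaks`` is a sequence of (charge-1 m/z, significance score); an
    optional parallel ``modes`` sequence carries per-peak provenance.  When
    several residues fit one difference within theta (I/L always; Q/K and
    others in the integer toy regime), one tag per residue string is
    emitted, isoleucine reported as canonical L.
    """
    pts = sorted(range(len(peaks)), key=lambda i: peaks[i][0])
    mz = [peaks[i][0] for i in pts]
    ss = [peaks[i][1] for i in pts]
    md = [modes[i] if modes else frozenset() for i in pts]
    n = len(mz)
    if n < 4:
        return TagSet()
    # adjacency: labels[i][j] = residues matching mz[j]-mz[i]
    residues = sorted(set(table.masses) - {"I"})
    succ: list[list[tuple[int, str]]] = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = mz[j] - mz[i]
            for aa in residues:
                if abs(d - table[aa]) <= theta:
                    succ[i].append((j, aa))
    seen: set[tuple[str, tuple[float, ...]]] = set()
    tags: list[Tag] = []
    for i in range(n):
        for j, a1 in succ[i]:
            for k, a2 in succ[j]:
                for l, a3 in succ[k]:
                    seq = a1 + a2 + a3
                    pk = (mz[i], mz[j], mz[k], mz[l])
                    if (seq, pk) in seen:
                        continue
                    seen.add((seq, pk))
                    tags.append(Tag(
                        sequence=seq, peaks=pk,
                        peak_scores=(ss[i], ss[j], ss[k], ss[l]),
                        modes=md[i] | md[j] | md[k] | md[l],
                    ))
    return TagSet(tags)


def _try_concat(ti: Tag, tj: Tag, theta: float) -> Tag | None:
    """Concatenate when ti's 2-residue suffix is tj's prefix and the three
    shared supporting peaks coincide within theta."""
    if ti.sequence[-2:] != tj.sequence[:2]:
        return None
    if any(abs(a - b) > theta
           for a, b in zip(ti.peaks[-3:], tj.peaks[:3])):
        return None
    return Tag(
        sequence=ti.sequence + tj.sequence[2:],
        peaks=ti.peaks + tj.peaks[3:],
        peak_scores=ti.peak_scores + tj.peak_scores[3:],
        modes=ti.modes | tj.modes,
    )


def extend_tags(tagset: TagSet, theta: float) -> TagSet:
    """Closure of pairwise tag concatenation.

    New tags join the pool and are themselves extension candidates; the
    process stops when no new (sequence, peaks) combination appears, so the
    result does not depend on merge order.
    """
    pool: dict[tuple[str, tuple[float, ...]], Tag] = {
        (t.sequence, t.peaks): t for t in tagset
    }
    frontier = list(pool.values())
    while frontier:
        fresh: list[Tag] = []
        current = list(pool.values())
        for ti in current:
            for tj in current:
                new = _try_concat(ti, tj, theta)
                if new is None:
                    continue
                key = (new.sequence, new.peaks)
                if key not in pool:
                    pool[key] = new
                    fresh.append(new)
        frontier = fresh
    return TagSet(sorted(pool.values(),
                         key=lambda t: (t.peaks, t.sequence)))


def score_tag(tag: Tag, scheme: WeightScheme = "printed") -> float:
    """Weighted mean of the supporting peaks' significance scores.

    printed:   s_t = (1/(l_t+1)) * sum_{l=1..l_t+1} ss_l * (1 + 0.1*min{l, l_t-l})
    symmetric: weights 1 + 0.1*min{l-1, l_t+1-l}, equal at both ends.
    """
    lt = tag.length
    total = 0.0
    for pos, ss in enumerate(tag.peak_scores, start=1):
        if scheme == "printed":
            w = 1.0 + 0.1 * min(pos, lt - pos)
        else:
            w = 1.0 + 0.1 * min(pos - 1, lt + 1 - pos)
        total += ss * w
    return total / (lt + 1)


def select_tags(tagset: TagSet, sel: int,
                scheme: WeightScheme = "printed") -> TagSet:
    """Top-``sel`` tags by score; ties broken longer-first, then by sequence."""
    scores = {t: score_tag(t, scheme) for t in tagset}
    ranked = sorted(tagset, key=lambda t: _sort_key(t, scores))
    return TagSet(ranked[:sel])


def tags_from_merged(
    merged: MergedSpectrum,
    table: AminoAcidTable,
    theta: float,
    sel: int = 10,
    scheme: WeightScheme = "printed",
) -> TagSet:
    """Generate, extend and select tags on a merged spectrum.

    The per-spectrum tag quota is honoured per fragmentation mode: the
    ``sel`` best tags whose peaks trace back to HCD and the ``sel`` best
    tracing back to ETD are kept (a tag drawing on both modes counts toward
    each of its modes).
    """
    peaks = [(p.mz1, p.score) for p in merged.peaks]
    modes = [frozenset(s[0] for s in p.sources) for p in merged.peaks]
    tagset = extend_tags(generate_tags(peaks, table, theta, modes), theta)
    scores = {t: score_tag(t, scheme) for t in tagset}
    ranked = sorted(tagset, key=lambda t: _sort_key(t, scores))
    kept: list[Tag] = []
    quota: dict[str, int] = {}
    for tag in ranked:
        tag_modes = tag.modes or frozenset({"?"})
        if any(quota.get(m, 0) < sel for m in tag_modes):
            kept.append(tag)
            for m in tag_modes:
                quota[m] = quota.get(m, 0) + 1
    return TagSet(kept)
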