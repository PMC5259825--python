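"""Tag-anchored spectrum-graph sequencing over a merged HCD/ETD spectrum.

Every merged peak is mapped into N-terminal prefix-mass space under each
fragment-series interpretation its source mode supports (HCD peaks as b and
y ions, ETD peaks as c and z ions); interpretations of complementary ions of
the same backbone cleavage land on the same prefix mass and coalesce into
one vertex with summed significance score.  Edges connect vertices whose
mass difference matches one residue (residue edge) or a sum of two or three
residues (gap edge).  Peptides are source-to-sink paths; selected tags pin
down anchor vertices so that path search runs only over the short segments
between an anchor and a terminus.

Segment search returns the exact top-K paths by accumulated vertex score,
computed by a K-best dynamic program over the DAG in mass order.  Candidates
assembled around each tag are ranked by the sum of their path vertices'
scores (cs); ties break toward fewer gap edges, then lexicographically.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from itertools import combinations_with_replacement, permutations, product
from typing import Sequence

import networkx as nx

from .chemistry import AminoAcidTable, MassConstants, peptide_mass
from .merge import MergedSpectrum
from .spectra_io import ETD, HCD
from .tags import Tag, TagSet

logger = logging.getLogger(__name__)

__all__ = [
    "SpectrumGraph",
    "SegmentPath",
    "Candidate",
    "build_graph",
    "enumerate_segment_paths",
    "assemble_and_rank",
]

_MAX_GAP_RESIDUES = 3
_MAX_FILLS_PER_EDGE = 16
_MAX_SEQS_PER_PATH = 8


@dataclass
class SpectrumGraph:
    """DAG of prefix-mass interpretations of the merged spectrum.

    Vertices are integer ids with ``mass`` and ``score`` attributes; the
    source sits at mass 0 and the sink at the total residue mass
    m_p - water.  Edge attribute ``labels`` lists (kind, residues) options,
    kind 'residue' or 'gap'; gap residues are stored as a sorted multiset
    string and expanded to ordered sequences during assembly.
    """

    graph: nx.DiGraph
    source: int
    sink: int
    theta: float

    @property
    def residue_total(self) -> float:
        return self.graph.nodes[self.sink]["mass"]

    def mass(self, v: int) -> float:
        return self.graph.nodes[v]["mass"]

    def score(self, v: int) -> float:
        return self.graph.nodes[v]["score"]

    def vertices_by_mass(self) -> list[int]:
        return sorted(self.graph.nodes, key=lambda v: (self.mass(v), v))

    def nearest_vertex(self, mass: float, tol: float) -> int | None:
        best, best_d = None, tol
        for v in self.graph.nodes:
            d = abs(self.mass(v) - mass)
            if d <= best_d:
                best, best_d = v, d
        return best


@dataclass(frozen=True)
class SegmentPath:
    """One source-to-target path inside a segment."""

    vertices: tuple[int, ...]
    score: float
    n_gap_edges: int


@dataclass(frozen=True)
class Candidate:
    """A full-length peptide candidate."""

    sequence: str
    score: float                    # cs: sum of path vertex scores
    path: tuple[int, ...]
    n_gap_edges: int
    anchor: str | None = None       # oriented tag sequence, None if tagless

    @property
    def il_ambiguous(self) -> bool:
        return "L" in self.sequence


def _interpretations(mode: str, mz1: float, parent_mass: float,
                     constants: MassConstants) -> list[tuple[str, float]]:
    """Prefix-mass readings of one charge-1 peak under its mode's series."""
    m_H = constants.m_H
    if mode == HCD:
        return [("b", mz1 - m_H),
                ("y", parent_mass + m_H - mz1)]
    return [("c", mz1 - m_H - constants.nh3),
            ("z", parent_mass + m_H - mz1 - constants.nh3 + constants.h_atom)]


def _multi_residue_sums(table: AminoAcidTable) -> list[tuple[float, str]]:
    """Sorted (mass, multiset string) for all 2- and 3-residue combinations."""
    residues = sorted(set(table.masses) - {"I"})
    out = []
    for r in (2, 3):
        for combo in combinations_with_replacement(residues, r):
            out.append((sum(table[aa] for aa in combo), "".join(combo)))
    out.sort()
    return out


def build_graph(
    merged: MergedSpectrum,
    parent_mass: float,
    table: AminoAcidTable,
    constants: MassConstants,
    theta: float,
) -> SpectrumGraph:
    """Build the spectrum graph for a merged spectrum.

    Interpretations whose prefix mass falls outside (0, m_p - water) are
    skipped; those within theta of a terminus duplicate the source/sink and
    are folded into it (with score discarded — terminal vertices lie on
    every path, so they cannot discriminate candidates).
    """
    residue_total = parent_mass - constants.water
    interps: list[tuple[float, float]] = []  # (prefix mass, peak score)
    n_skipped = 0
    for peak in merged.peaks:
        peak_modes = {s[0] for s in peak.sources} or {HCD, ETD}
        for mode in sorted(peak_modes):
            for _series, prefix in _interpretations(
                    mode, peak.mz1, parent_mass, constants):
                if prefix <= theta or prefix >= residue_total - theta:
                    if prefix < -theta or prefix > residue_total + theta:
                        n_skipped += 1
                    continue
                interps.append((prefix, peak.score))
    if n_skipped:
        logger.debug("build_graph: %d interpretations outside mass range",
                     n_skipped)
    interps.sort()
    g = nx.DiGraph()
    g.add_node(0, mass=0.0, score=0.0)
    next_id = 1
    cluster: list[tuple[float, float]] = []

    def flush() -> None:
        nonlocal next_id
        if not cluster:
            return
        total = sum(s for _, s in cluster)
        if total > 0:
            mass = sum(m * s for m, s in cluster) / total
        else:
            mass = sum(m for m, _ in cluster) / len(cluster)
        g.add_node(next_id, mass=mass, score=total)
        next_id += 1

    for prefix, score in interps:
        if cluster and prefix - cluster[-1][0] > theta:
            flush()
            cluster = []
        cluster.append((prefix, score))
    flush()
    sink = next_id
    g.add_node(sink, mass=residue_total, score=0.0)

    sums = _multi_residue_sums(table)
    sum_masses = [m for m, _ in sums]
    residues = sorted(set(table.masses) - {"I"})
    max_span = sums[-1][0] + theta
    nodes = sorted(g.nodes, key=lambda v: (g.nodes[v]["mass"], v))
    for i, u in enumerate(nodes):
        mu = g.nodes[u]["mass"]
        for v in nodes[i + 1:]:
            d = g.nodes[v]["mass"] - mu
            if d > max_span:
                break
            if d <= theta:
                continue
            labels: list[tuple[str, str]] = []
            for aa in residues:
                if abs(d - table[aa]) <= theta:
                    labels.append(("residue", aa))
            lo = bisect.bisect_left(sum_masses, d - theta)
            hi = bisect.bisect_right(sum_masses, d + theta)
            gaps = sorted(sums[lo:hi], key=lambda t: (abs(t[0] - d), t[1]))
            labels.extend(("gap", ms) for _, ms in gaps[:_MAX_FILLS_PER_EDGE])
            if labels:
                g.add_edge(u, v, labels=labels)
    return SpectrumGraph(graph=g, source=0, sink=sink, theta=theta)


def enumerate_segment_paths(
    sg: SpectrumGraph,
    start: int,
    end: int,
    k: int,
) -> list[SegmentPath]:
    """Exact top-k paths from ``start`` to ``end`` by accumulated vertex score.

    A k-best-per-vertex dynamic program over the DAG in mass order; search is
    confined to vertices whose mass lies within the segment.  Ties rank
    paths with fewer gap edges first, then by vertex mass sequence, making
    the output deterministic.  An unreachable ``end`` yields an empty list
    (the caller marks the segment gap-only).
    """
    if start not in sg.graph or end not in sg.graph:
        raise ValueError("anchor vertices must exist in the graph")
    g = sg.graph
    lo, hi = sg.mass(start), sg.mass(end)
    nodes = [v for v in sg.vertices_by_mass()
             if lo - sg.theta <= sg.mass(v) <= hi + sg.theta]
    # entry: (score, n_gaps, vertices)
    best: dict[int, list[tuple[float, int, tuple[int, ...]]]] = {
        start: [(sg.score(start), 0, (start,))]
    }

    def entry_key(e):
        return (-e[0], e[1], tuple(sg.mass(v) for v in e[2]))

    allowed = set(nodes)
    for v in nodes:
        if v == start:
            continue
        merged: list[tuple[float, int, tuple[int, ...]]] = []
        for u in g.pred[v]:
            if u not in allowed or u not in best:
                continue
            kinds = {kind for kind, _ in g.edges[u, v]["labels"]}
            gap_step = 0 if "residue" in kinds else 1
            for score, gaps, path in best[u]:
                merged.append((score + sg.score(v), gaps + gap_step, path + (v,)))
        if merged:
            merged.sort(key=entry_key)
            best[v] = merged[:k]
    return [SegmentPath(vertices=path, score=score, n_gap_edges=gaps)
            for score, gaps, path in best.get(end, [])]


def _expand_labels(sg: SpectrumGraph, path: Sequence[int]) -> list[tuple[str, int]]:
    """Materialise up to a few residue strings for one vertex path.

    Returns (sequence, n_gap_edges) options; residue labels are preferred
    over gap fills, and gap multisets expand to their distinct orderings.
    """
    options: list[list[tuple[str, int]]] = []
    for u, v in zip(path, path[1:]):
        opts: list[tuple[str, int]] = []
        for kind, res in sg.graph.edges[u, v]["labels"]:
            if kind == "residue":
                opts.append((res, 0))
            else:
                for perm in sorted({"".join(p) for p in permutations(res)}):
                    opts.append((perm, 1))
        options.append(opts)
    out: list[tuple[str, int]] = []
    for combo in product(*options):
        out.append(("".join(s for s, _ in combo), sum(gpe for _, gpe in combo)))
        if len(out) >= _MAX_SEQS_PER_PATH * 4:
            break
    out.sort(key=lambda t: (t[1], t[0]))
    return out[:_MAX_SEQS_PER_PATH]


def _anchor_placements(
    sg: SpectrumGraph,
    tag: Tag,
    parent_mass: float,
    constants: MassConstants,
) -> list[tuple[tuple[int, ...], str]]:
    """Map a tag's supporting peaks onto graph vertices.

    Each fragmentation mode the tag draws on offers an N-terminal and a
    C-terminal series reading; a placement is kept when every supporting
    peak lands on an existing vertex (within theta) in strictly ascending
    prefix order.  C-terminal readings reverse the tag sequence.
    """
    placements = []
    modes = tag.modes or frozenset({HCD, ETD})
    seen: set[tuple[tuple[int, ...], str]] = set()
    for mode in sorted(modes):
        for series_idx, reverse in ((0, False), (1, True)):
            prefixes = []
            for mz1 in tag.peaks:
                series = _interpretations(mode, mz1, parent_mass, constants)
                prefixes.append(series[series_idx][1])
            if reverse:
                prefixes = prefixes[::-1]
            if any(b <= a for a, b in zip(prefixes, prefixes[1:])):
                continue
            vertices = []
            ok = True
            for p in prefixes:
                v = sg.nearest_vertex(p, sg.theta)
                if v is None:
                    ok = False
                    break
                vertices.append(v)
            if not ok or len(set(vertices)) != len(vertices):
                continue
            oriented = tag.sequence[::-1] if reverse else tag.sequence
            key = (tuple(vertices), oriented)
            if key not in seen:
                seen.add(key)
                placements.append(key)
    return placements


def assemble_and_rank(
    sg: SpectrumGraph,
    tagset: TagSet,
    parent_mass: float,
    table: AminoAcidTable,
    constants: MassConstants,
    k: int = 10,
    c: int = 3,
) -> list[Candidate]:
    """Assemble candidates around each anchored tag and return the top C.

    For each tag placement the segments source->first-anchor and
    last-anchor->sink are searched (top-``k`` paths each) and combined; the
    candidate score cs is the sum of the scores of all vertices on the full
    path.  Candidates are deduplicated by sequence (best score kept),
    mass-validated against the parent mass, and ranked by (cs, fewer gaps,
    sequence).  If no tag anchors at all, a tagless source-to-sink search is
    used as a fallback.
    """
    placements: list[tuple[tuple[int, ...], str | None]] = []
    for tag in tagset:
        placements.extend(_anchor_placements(sg, tag, parent_mass, constants))
    if not placements:
        placements = [((sg.source, sg.sink), None)]
        logger.debug("assemble_and_rank: no tag anchored; tagless search")

    best: dict[str, Candidate] = {}
    for anchors, oriented in placements:
        if oriented is None:
            lefts = enumerate_segment_paths(sg, sg.source, sg.sink, k)
            rights = [SegmentPath((sg.sink,), sg.score(sg.sink), 0)]
            mid_seq = ""
            anchor_vertices: tuple[int, ...] = ()
        else:
            lefts = enumerate_segment_paths(sg, sg.source, anchors[0], k)
            rights = enumerate_segment_paths(sg, anchors[-1], sg.sink, k)
            mid_seq = oriented
            anchor_vertices = anchors
        for lp in lefts:
            for rp in rights:
                path = lp.vertices + anchor_vertices[1:] + rp.vertices[1:]
                if len(set(path)) != len(path):
                    continue
                cs = sum(sg.score(v) for v in path)
                for lseq, lg in _expand_labels(sg, lp.vertices):
                    for rseq, rg in _expand_labels(sg, rp.vertices):
                        seq = lseq + mid_seq + rseq
                        if not seq:
                            continue
                        pm = peptide_mass(seq, table, constants)
                        if abs(pm - parent_mass) > sg.theta * (len(seq) + 1):
                            continue
                        cand = Candidate(
                            sequence=seq, score=cs, path=path,
                            n_gap_edges=lg + rg,
                            anchor=oriented,
                        )
                        prev = best.get(seq)
                        if prev is None or (-cand.score, cand.n_gap_edges) < (
                                -prev.score, prev.n_gap_edges):
                            best[seq] = cand
    ranked = sorted(best.values(),
                    key=lambda cd: (-cd.score, cd.n_gap_edges, cd.sequence))
    return ranked[:c]
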