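# Methods

`novopair` sequences peptides de novo from *pairs* of tandem mass spectra of
the same precursor acquired under two fragmentation regimes: HCD
(higher-energy collisional dissociation, dominated by b/y ions) and ETD
(electron transfer dissociation, dominated by c/z ions).  The two spectra
carry complementary evidence about the same backbone cleavages; the method
merges them into a single scored peak list, reads sequence tags off it, and
searches a tag-anchored spectrum graph for full-length candidates.  What
distinguishes it from plain spectrum-graph sequencing is that the peak
selection criteria carry *significance scores trained on annotated spectral
libraries*: each criterion's score is the empirical probability that a peak
it selects is a true fragment ion, and those probabilities propagate through
tag scoring, path search and candidate ranking.

## Peak selection and spectrum merging

For a spectrum with precursor charge n, every fragment ion is hypothesised
to carry each charge i = 1 .. n-1 in turn, and its m/z is re-expressed at
charge 1 (`mz1 = i*mz - (i-1)*m_H`).  Two criteria select peaks across all
charge hypotheses of a spectrum (threshold θ, default 0.01 Da; neutral-loss
masses m ∈ {H2O, NH3}):

* **Amino-acid difference.**  A middle ion v is selected when peaks
  u < v < t exist with v−u and t−v both equal to a residue mass up to a
  loss offset.  The two offsets must be jointly explainable by v's own loss
  state: either both zero, or (−m, +m) for one loss mass m — a fragment
  that lost a neutral of mass m sits m *short* of its left residue gap and
  m *beyond* its right one.  Allowing the two sides to take arbitrary
  independent offsets would additionally select ions whose pattern
  (+m, −m) implies that both neighbours, but not the ion itself, are loss
  fragments; that weaker, less parsimonious evidence is deliberately
  excluded.

* **Ion complementarity.**  Peaks u, v (possibly from different charge
  hypotheses of the same spectrum) are both selected when
  u⁺ + v⁺ = m_p + 2·m_H (HCD, b/y) or m_p + 3·m_H (ETD, c/z) up to a loss
  offset, within θ.  Exact (offset-0) pairs are accepted unconditionally.
  Loss-shifted pairs are accepted only when at least one member is
  *corroborated* — already selected by the amino-acid difference test or by
  an exact pair.  An uncorroborated pair whose sum is deficient by exactly
  one loss mass is weak evidence: any two noise peaks with that sum would
  qualify.  `loss_pair_policy="all"` switches to the unconditional rule.

A selected peak's score ss is the sum of the library-trained scores of the
*distinct* criteria that selected it; satisfying one criterion through
several witnesses does not multiply its contribution.  Selected peaks
closer than θ coalesce at their score-weighted mean m/z with summed scores;
unselected peaks are dropped.  Complementarity between an HCD peak and an
ETD peak is not tested — the relations are defined per spectrum.

## Library training

On each annotated library spectrum the same selectors run, and a selected
ion counts as *real* when its observed m/z lies within the annotation
tolerance (default θ) of any theoretical fragment of the annotated peptide
(b/y or c/z per mode, charges 1..n−1, no loss/−H2O/−NH3).  A criterion's
per-spectrum accuracy is real/selected; the library score is the unweighted
mean over spectra where the criterion selected at least one ion.  Spectra
whose annotated peptide mass disagrees with the precursor by more than
0.1 Da are rejected.

HCD complementarity uses a positional split: the m/z axis up to the highest
charge-1 value considered is cut into four equal parts, a pair is "middle"
when both members fall in the two central quarters, and separate scores
s_compM / s_compE are trained and applied.  ETD keeps a single
complementarity score (its positional variation is small), and the
amino-acid difference keeps one pooled score rather than 400 residue-pair
scores.  An ion appearing in both middle and end pairs is scored once, at
the larger of the two positional scores.

## Tags

Length-3 tags are read off the merged spectrum: every ascending 4-peak
chain whose three consecutive differences each match a residue mass within
θ yields one tag (one per residue string when masses are ambiguous;
isoleucine is reported as leucine).  Tags whose sequences overlap by two
residues and whose three shared supporting peaks coincide within θ are
concatenated, repeatedly, until no new (sequence, peaks) combination
appears; the closure is order-independent.

A tag of length l_t supported by peaks with scores ss_1 .. ss_{l_t+1} is
scored

    s_t = 1/(l_t+1) · Σ_{l=1..l_t+1} ss_l · (1 + 0.1·min{l, l_t−l})

exactly in this form by default, although the weights are asymmetric (for
l_t = 3 the first peak weighs 1.1 and the last 0.9, giving 1.025 for unit
scores).  A `symmetric` option uses 1 + 0.1·min{l−1, l_t+1−l}, which
down-weights both ends equally (1.05 for the same tag); the intent behind
the asymmetric form is ambiguous, so both readings ship and the printed one
is the default.  The top `Sel` tags (default 10) are kept per fragmentation
mode, honouring the per-experimental-spectrum quota.

## Spectrum graph and search

Vertices are prefix-mass interpretations of merged peaks: an HCD peak at
charge-1 m/z x is read as b (prefix = x − m_H) and as y (prefix =
m_p + m_H − x); an ETD peak as c (x − m_H − NH3) and z-dot analogously.
Interpretations of complementary ions of the same cleavage coincide and
coalesce into one vertex with summed score, which is what makes true
cleavage sites stand out: a site confirmed by b, y, c and z evidence
carries up to four summed scores.  The z-ion convention is configurable
(z-dot = y − NH3 + H by default, or plain y − NH3).  Edges connect vertices
whose mass difference matches one residue, or a sum of two or three
residues (gap edges, expanded to ordered fills only when a candidate string
is materialised, capped at 16 multisets per edge and 8 strings per path).

Selected tags are anchored into the graph (each mode offers an N- and a
C-terminal reading; C-terminal readings reverse the tag), splitting the
mass axis into a left segment (source to first anchor) and a right segment
(last anchor to sink).  Each segment is searched for its top-K paths
(default K = 10) by accumulated vertex score.  The search is an exact
K-best dynamic program over the DAG in mass order rather than a heuristic
best-first expansion: path scores are pure vertex sums, so the DP
guarantees the true top-K deterministically, which a score-ordered
best-first search without an admissible bound cannot.  Ties break toward
fewer gap edges, then lexicographically smaller mass sequences.

Candidates are assembled as left-path + oriented tag + right-path, must
match the parent mass within θ·(length+1), are deduplicated by sequence,
scored by cs = Σ vertex scores along the path, and ranked (ties: fewer gap
edges, then lexicographic); the top C (default 3) are returned.  When no
tag anchors, a tagless source-to-sink search keeps the pair sequenceable.

## Parameters

| parameter | meaning | default |
|---|---|---|
| θ | selection/graph mass tolerance (Da) | 0.01 |
| Sel | tags kept per experimental spectrum | 10 |
| K | paths per partial segment | 10 |
| C | candidates output per spectra pair | 3 |
| pair tolerance | parent-mass match for HCD/ETD pairing (Da) | 0.02 |
| annotation tolerance | real-ion match in training (Da) | θ |

An integer "toy mode" mass table (S = 87, E = 129, m_H = 1, H2O = 18,
NH3 = 17) exists for exact hand-checkable arithmetic on small examples.
The proton mass serves as m_H both in charge conversion and in the
complementarity relations; for c/z pairs the exact offset is
2·proton + 1 hydrogen atom, which differs from 3·m_H by one electron mass
(0.00055 Da), well inside θ.

## Synthetic data

The simulator generates tryptic-like peptides (C-terminal K/R, isoleucine
excluded as isobaric with leucine), lengths 7–12 and precursor charges 2–3
by default, with complete b/y and c/z ladders at fragment charges 1..n−1.
Optional corruptions: per-fragment detection dropout, loss satellites
(probability 0.2 per loss fragment by default), Gaussian m/z jitter, and
uniform noise peaks on [100, precursor m/z · charge] rejected within 3θ of
every theoretical fragment so ground-truth labels stay unambiguous.  Noise
m/z values are drawn sequentially from a dedicated per-record random
substream, so for a fixed seed the noise at a lower fraction is a prefix of
the noise at a higher one — noise levels form a nested paired design and
score degradation can be read off without resampling variance.

What the simulator does *not* emulate: realistic intensity structure,
isotope clusters, co-isolation, modified peptides, and the correlated noise
of real instruments.  Green tests on simulated data therefore demonstrate
algorithmic correctness (selection precision, training consistency, exact
search, round-trip sequencing), not expected accuracy on real datasets.
Training runs in the test suite use 50-spectrum libraries and the
end-to-end check uses 100 simulated pairs; both finish in seconds.

## Known limitations

* The ranking score is a pure vertex-score sum; the amino-acid-composition
  features and the multi-feature ranking of the predecessor method are out
  of scope.
* Intensities are read and preserved but unused — all criteria operate on
  m/z only.
* Modified peptides (including phosphopeptides) are excluded from training
  and not generated; the residue table is overridable from a config file as
  a hook for fixed modifications.
* Gap-edge fills are capped; pathological spectra with many long gaps may
  not enumerate every fill combination.
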