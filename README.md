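# novopair

De novo peptide sequencing from paired HCD/ETD tandem mass spectra,
assisted by annotated spectral libraries.

Modern proteomics workflows often acquire two MS/MS spectra of the same
precursor peptide under different fragmentation regimes: HCD yields mostly
b/y ions, ETD mostly c/z ions.  Each spectrum alone may be too sparse to
sequence; together they cover complementary backbone cleavages.  `novopair`
merges such a pair into one scored spectrum and sequences it — and it uses
annotated spectral libraries (NIST-style MSP) as *training data*, not as a
search space, so it can still identify peptides absent from any library.

It is aimed at researchers who work with paired-fragmentation MS/MS data
and want a transparent, fully scriptable sequencing pipeline with a
built-in simulator for validation.

## Method in brief

Peaks are selected into the merged spectrum `S_m` by two criteria, applied
over all charge hypotheses i = 1..n−1 of each spectrum (peaks re-expressed
at charge 1):

* amino-acid mass difference: peaks u < v < t with
  |(v⁺−u⁺) − a_i ± σ| ≤ θ and |(t⁺−v⁺) − a_j ± σ| ≤ θ select the middle
  ion v (a_i, a_j residue masses; σ a neutral-loss offset, H2O/NH3);
* ion complementarity: |m_p + 2m_H − (v⁺+u⁺) ± σ| ≤ θ (HCD) or
  |m_p + 3m_H − (v⁺+u⁺) ± σ| ≤ θ (ETD) selects both u and v.

Each criterion carries a significance score trained on an annotated
library: the mean, over library spectra, of the fraction of its selections
that are true fragment ions (HCD complementarity is split into
middle-of-spectrum vs end-of-spectrum pair scores).  A selected peak's
score `ss` sums the scores of the distinct criteria that fired.

Length-3 sequence tags are read off `S_m` from 4-peak chains with residue
mass differences, extended by two-residue overlap, and scored

    s_t = 1/(l_t+1) · Σ_l ss_l · (1 + 0.1·min{l, l_t−l})

The top `Sel` tags anchor a spectrum-graph search: merged peaks map to
prefix-mass vertices (b/y/c/z interpretations; complementary readings of
the same cleavage coalesce with summed scores), and each segment between a
tag and a terminus is searched for its top-`K` paths by accumulated vertex
score.  Candidates are ranked by the path score sum `cs` and the top `C`
are reported.  Defaults: θ = 0.01 Da, Sel = 10, K = 10, C = 3.

See `docs/methods.md` for the full model, numerical conventions, and
limitations.

## Worked example

Simulate three noise-free HCD/ETD pairs and two 20-spectrum training
libraries, train, and sequence (the `novopair` console script wraps the
library; everything is also callable from Python):

```sh
novopair simulate --mode pair --n 3 --seed 100 --out demo.mgf   # writes demo_hcd.mgf, demo_etd.mgf
novopair simulate --mode hcd  --n 20 --seed 101 --out-format msp --out lib_hcd.msp
novopair simulate --mode etd  --n 20 --seed 102 --out-format msp --out lib_etd.msp
novopair train --library lib_hcd.msp --mode hcd --out hcd_model.json
novopair train --library lib_etd.msp --mode etd --out etd_model.json
novopair sequence --hcd demo_hcd.mgf --etd demo_etd.mgf \
    --hcd-model hcd_model.json --etd-model etd_model.json
```

On a clean library every trained score is exactly 1.0 (no selected peak can
be false when no noise exists), and the candidate table prints:

```
pair_id  title                 rank  sequence       cs    n_gap_edges
0        sim|TDPCGLAPYWR|HCD   1     TDPCGLAPYWR    74.0  0
0        sim|TDPCGLAPYWR|HCD   2     TDPCGLAPYAAVT  71.0  1
0        sim|TDPCGLAPYWR|HCD   3     TDPCGLAPYAGLT  71.0  1
1        sim|WWARREMYRGK|HCD   1     WWARREMYRGK    74.0  0
1        sim|WWARREMYRGK|HCD   2     DEKARREMYRGK   70.0  1
1        sim|WWARREMYRGK|HCD   3     DKEARREMYRGK   70.0  1
2        sim|PNPSNRR|HCD       1     PGGPSNRR       86.0  0
2        sim|PNPSNRR|HCD       2     PNPSNRR        85.0  0
2        sim|PNPSNRR|HCD       3     PNPSGGRR       85.0  1
```

`cs` is the sum of the significance scores of the peaks supporting each
candidate; a fully supported peptide wins over alternatives that bridge
unsupported stretches with 2–3-residue gap edges.  The first two pairs
recover the true peptide at rank 1.  The third shows a genuine ambiguity:
a glycine pair (GG) is isobaric with asparagine (N) to 0.0004 Da, so the
GG reading — which here picks up one extra coincidental vertex — edges out
the true sequence, which still appears at rank 2 of 3.

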