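import numpy as np
import pytest

from novopair.chemistry import AminoAcidTable, MassConstants
from novopair.merge import (
    ChargeHypothesis,
    expand_charges,
    merge_pair,
    select_aa_difference,
    select_complementarity,
)
from novopair.spectra_io import Spectrum
from novopair.synthetic_data import SimulationConfig, simulate_pair


def _hyp(mz_values, spectrum=None, charge=1):
    mz = np.asarray(sorted(mz_values), dtype=float)
    if spectrum is None:
        spectrum = Spectrum("h", 500.0, 2, 990.0, "HCD", mz, np.ones_like(mz))
    return ChargeHypothesis(spectrum, charge, mz, np.arange(len(mz)))


def brute_force_middle_ions(mz, table, constants, theta):
    """O(p^3) triple scan over all peaks: the reference for aa-difference.

    A middle ion's own loss state must explain both sides, so the offset
    pattern is (0, 0) or (-m, +m) per loss mass m.
    """
    patterns = [(0.0, 0.0)] + [(-m, m) for m in constants.losses.values()]
    masses = list(table.masses.values())
    selected = set()
    p = len(mz)
    for u in range(p):
        for v in range(u + 1, p):
            for t in range(v + 1, p):
                dl, dr = mz[v] - mz[u], mz[t] - mz[v]
                for sl, sr in patterns:
                    left = any(abs(dl - (a + sl)) <= theta for a in masses)
                    right = any(abs(dr - (a + sr)) <= theta for a in masses)
                    if left and right:
                        selected.add(v)
    return selected


class TestExpandCharges:
    def test_worked_example_etd(self, toy_pair, toy_constants):
        hyps = expand_charges(toy_pair.etd, toy_constants)
        assert len(hyps) == 2
        assert list(hyps[0].mz1) == [132, 182, 234]
        assert list(hyps[1].mz1) == [263, 363, 467]

    def test_charge2_single_identity_hypothesis(self, toy_pair, toy_constants):
        hyps = expand_charges(toy_pair.hcd, toy_constants)
        assert len(hyps) == 1
        assert list(hyps[0].mz1) == [130, 199, 277, 346]

    def test_empty_spectrum(self, toy_constants):
        s = Spectrum("e", 200.0, 3, 597.0, "ETD", [], [])
        hyps = expand_charges(s, toy_constants)
        assert len(hyps) == 2 and all(len(h) == 0 for h in hyps)

    def test_degenerate_precursor(self, toy_constants):
        s = Spectrum("d", 200.0, 1, 199.0, "HCD", [100.0], [1.0])
        with pytest.raises(ValueError):
            expand_charges(s, toy_constants)


class TestAADifference:
    def test_worked_example_selects_only_199(self, toy_pair, toy_table,
                                             toy_constants):
        hyp = expand_charges(toy_pair.hcd, toy_constants)[0]
        hits = select_aa_difference(hyp, toy_table, toy_constants, 0.0)
        assert [h.mz1 for h in hits] == [199.0]

    def test_two_peaks_no_triple(self, toy_table, toy_constants):
        assert select_aa_difference(_hyp([100, 187]), toy_table,
                                    toy_constants, 0.0) == []

    def test_exact_residue_differences(self, toy_table, toy_constants):
        hits = select_aa_difference(_hyp([100, 187, 244]), toy_table,
                                    toy_constants, 0.0)
        assert [h.mz1 for h in hits] == [187.0]

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, seed, mono_table, mono_constants):
        rng = np.random.default_rng(seed)
        mz = np.sort(rng.uniform(100, 1500, size=rng.integers(5, 50)))
        hyp = _hyp(mz)
        got = {h.mz1 for h in select_aa_difference(
            hyp, mono_table, mono_constants, 0.01)}
        want = {mz[v] for v in brute_force_middle_ions(
            mz, mono_table, mono_constants, 0.01)}
        assert got == want

    def test_ladder_interior_selected(self, mono_table, mono_constants):
        # clean b-ladder of GASA: interior peaks have residue gaps both sides
        g, a, s = mono_table["G"], mono_table["A"], mono_table["S"]
        mz = np.cumsum([58.0, a, s, a])
        hits = select_aa_difference(_hyp(mz), mono_table, mono_constants, 0.001)
        assert {h.mz1 for h in hits} == {mz[1], mz[2]}


class TestComplementarity:
    def test_worked_example_hcd_pair(self, toy_pair, toy_table, toy_constants):
        hyps = expand_charges(toy_pair.hcd, toy_constants)
        aa = {1}  # peak 199 pre-selected by aa-difference
        hits = select_complementarity(hyps, "HCD", 492.0, toy_constants, 0.0,
                                      corroborated=frozenset(aa))
        assert len(hits) == 1
        assert {hits[0].u[2], hits[0].v[2]} == {199.0, 277.0}

    def test_uncorroborated_loss_pair_rejected(self, toy_pair, toy_constants):
        hyps = expand_charges(toy_pair.hcd, toy_constants)
        hits = select_complementarity(hyps, "HCD", 492.0, toy_constants, 0.0)
        assert hits == []

    def test_literal_policy_keeps_all_loss_pairs(self, toy_pair, toy_constants):
        hyps = expand_charges(toy_pair.hcd, toy_constants)
        hits = select_complementarity(hyps, "HCD", 492.0, toy_constants, 0.0,
                                      loss_pair_policy="all")
        sums = sorted({h.u[2] + h.v[2] for h in hits})
        assert sums == [476.0]
        assert len(hits) == 2  # (130,346) and (199,277)

    def test_worked_example_etd_cross_hypothesis(self, toy_pair, toy_constants):
        hyps = expand_charges(toy_pair.etd, toy_constants)
        hits = select_complementarity(hyps, "ETD", 492.0, toy_constants, 0.0)
        assert len(hits) == 1
        hit = hits[0]
        assert {hit.u[2], hit.v[2]} == {132.0, 363.0}
        partner = hit.v if hit.v[2] == 363.0 else hit.u
        assert partner[0] == 2          # assumed charge of the 363 reading
        assert partner[1] == 1          # source peak observed at 182
        assert hit.sigma == 0.0

    def test_no_match_empty(self, toy_table, toy_constants):
        hyps = [_hyp([100, 150, 190])]
        assert select_complementarity(hyps, "HCD", 492.0, toy_constants,
                                      0.0) == []

    def test_pair_members_both_selected(self, mono_constants):
        # symmetric by construction: one hit reports both u and v
        m_p = 900.0
        target = m_p + 2 * mono_constants.m_H
        hyps = [_hyp([300.0, target - 300.0])]
        hits = select_complementarity(hyps, "HCD", m_p, mono_constants, 0.01)
        assert len(hits) == 1
        assert {round(hits[0].u[2], 3), round(hits[0].v[2], 3)} == {
            300.0, round(target - 300.0, 3)}


class TestMergePair:
    def test_worked_example_merged_spectrum(self, toy_pair, toy_table,
                                            toy_constants, sentinel_models):
        hcd_model, etd_model = sentinel_models
        merged = merge_pair(toy_pair, hcd_model, etd_model, toy_table,
                            toy_constants, theta=0.0)
        got = {p.mz1: (p.score, tuple(sorted(p.criteria))) for p in merged.peaks}
        assert set(got) == {132.0, 199.0, 277.0, 363.0}
        assert got[132.0] == (pytest.approx(etd_model.s_comp), ("comp",))
        assert got[363.0] == (pytest.approx(etd_model.s_comp), ("comp",))
        assert got[199.0] == (pytest.approx(hcd_model.s_aa + hcd_model.s_comp_end),
                              ("aa", "compE"))
        assert got[277.0] == (pytest.approx(hcd_model.s_comp_end), ("compE",))

    def test_inferred_charge_recorded(self, toy_pair, toy_table, toy_constants,
                                      sentinel_models):
        merged = merge_pair(toy_pair, *sentinel_models, toy_table,
                            toy_constants, theta=0.0)
        peak = next(p for p in merged.peaks if p.mz1 == 363.0)
        assert peak.sources == {("ETD", 1, 2)}

    def test_empty_spectra_give_empty_merge(self, toy_table, toy_constants,
                                            sentinel_models):
        from novopair.spectra_io import SpectrumPair
        hcd = Spectrum("h", 247.0, 2, 492.0, "HCD", [], [])
        etd = Spectrum("e", 165.0, 3, 492.0, "ETD", [], [])
        merged = merge_pair(SpectrumPair(hcd, etd), *sentinel_models,
                            toy_table, toy_constants, theta=0.0)
        assert len(merged) == 0

    def test_multiple_witnesses_score_once(self, toy_table, toy_constants,
                                           sentinel_models):
        """A peak matching the aa-difference via two triples scores aa once."""
        from novopair.spectra_io import SpectrumPair
        # ladder G-A-[v]-A-G around v=285: two (u,t) witnesses for v
        mz = [100, 157, 214, 285, 356, 413]  # diffs 57,57,71,71,57
        m_p = 2000.0  # far from any complementarity
        hcd = Spectrum("h", (m_p + 2) / 2, 2, m_p, "HCD", mz, np.ones(len(mz)))
        etd = Spectrum("e", (m_p + 3) / 3, 3, m_p, "ETD", [], [])
        merged = merge_pair(SpectrumPair(hcd, etd), *sentinel_models,
                            toy_table, toy_constants, theta=0.0)
        by_mz = {p.mz1: p for p in merged.peaks}
        assert by_mz[285.0].score == pytest.approx(sentinel_models[0].s_aa)

    def test_score_is_sum_over_distinct_criteria(self, toy_pair, toy_table,
                                                 toy_constants, sentinel_models):
        hcd_model, etd_model = sentinel_models
        per_criterion = {
            "aa": {"HCD": hcd_model.s_aa, "ETD": etd_model.s_aa},
            "comp": {"ETD": etd_model.s_comp},
            "compM": {"HCD": hcd_model.s_comp_middle},
            "compE": {"HCD": hcd_model.s_comp_end},
        }
        merged = merge_pair(toy_pair, hcd_model, etd_model, toy_table,
                            toy_constants, theta=0.0)
        for p in merged.peaks:
            mode = next(iter(p.sources))[0]
            expected = sum(per_criterion[c][mode] for c in p.criteria)
            assert p.score == pytest.approx(expected)

    def test_noise_free_selection_precision_is_one(self, mono_table,
                                                   mono_constants,
                                                   uniform_models):
        """With no noise peaks, every selected peak is a true fragment."""
        for seed, pep in ((0, "LGEYGFQNALK"), (1, "TVMENFVAFVDK")):
            sim = simulate_pair(pep, SimulationConfig(seed=seed), charge=3)
            merged = merge_pair(sim.pair, *uniform_models, mono_table,
                                mono_constants, theta=0.01)
            labels = {"HCD": sim.hcd_real, "ETD": sim.etd_real}
            for p in merged.peaks:
                for mode, src, _z in p.sources:
                    assert labels[mode][src]

    def test_coalescing_sums_scores(self, toy_table, toy_constants):
        from novopair.merge import ScoredPeak, _coalesce
        peaks = [
            ScoredPeak(100.000, 1.0, frozenset({"aa"}), frozenset({("HCD", 0, 1)})),
            ScoredPeak(100.004, 2.0, frozenset({"comp"}), frozenset({("ETD", 1, 1)})),
            ScoredPeak(150.0, 0.5, frozenset({"aa"}), frozenset({("HCD", 2, 1)})),
        ]
        out = _coalesce(peaks, 0.01)
        assert len(out) == 2
        assert out[0].score == pytest.approx(3.0)
        assert out[0].criteria == {"aa", "comp"}
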