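"""Label-mass arithmetic, fragment generation, spectrum matching,
target-decoy q-values, and ratio quantification/aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pmass

from iptlpipe.iptl_quant import (CHANNEL_A, CHANNEL_B, Candidate, Matcher,
                                 PeptideSpectrumMatch, Spectrum,
                                 aggregate_protein, compute_qvalues,
                                 filter_psms, label_masses, match_spectrum,
                                 quantify_spectrum, reversed_decoys,
                                 theoretical_fragments)
from iptlpipe.synthetic_data import simulate_iptl_run

# independent atomic-mass oracle (CODATA/AME monoisotopic values)
H = 1.00782503207
D = 2.01410177785
C = 12.0
O16 = 15.99491461957
O18 = 17.99915961286
PROTON = 1.00727646688


class TestLabelMasses:
    def test_light_dimethyl_is_two_ch2(self, scheme):
        assert scheme.n_term_delta["light"] == pytest.approx(2 * (C + 2 * H),
                                                             abs=1e-9)
        assert scheme.n_term_delta["light"] == pytest.approx(28.031300,
                                                             abs=1e-6)

    def test_heavy_dimethyl_and_gap(self, scheme):
        assert scheme.n_term_delta["heavy"] == pytest.approx(32.056407,
                                                             abs=1e-5)
        assert scheme.n_term_gap == pytest.approx(4 * (D - H), abs=1e-9)
        assert scheme.n_term_gap == pytest.approx(4.025108, abs=2e-6)

    def test_double_18o_and_precursor_gap(self, scheme):
        assert scheme.c_term_gap == pytest.approx(2 * (O18 - O16), abs=1e-9)
        assert scheme.c_term_gap == pytest.approx(4.008490, abs=1e-6)
        assert scheme.precursor_gap == pytest.approx(0.016618, abs=2e-6)

    def test_orientation_invariant(self, scheme):
        # membrane samples carry the heavy N terminus (channel A)
        assert scheme.sample_channel("membrane") == CHANNEL_A
        assert scheme.sample_channel("cytosolic") == CHANNEL_B
        swapped = scheme.swapped()
        assert swapped.sample_channel("membrane") == CHANNEL_B


class TestTheoreticalFragments:
    def test_counts(self, scheme):
        frags = theoretical_fragments("AGK", scheme, CHANNEL_A)
        assert sum(f[0] == "b" for f in frags) == 2
        assert sum(f[0] == "y" for f in frags) == 2
        with pytest.raises(ValueError):
            theoretical_fragments("A", scheme, CHANNEL_A)

    def test_channel_gaps_constant_across_indices(self, scheme):
        pep = "LWETQGVAK"
        fa = theoretical_fragments(pep, scheme, CHANNEL_A)
        fb = theoretical_fragments(pep, scheme, CHANNEL_B)
        for (ta, ia, ma, _), (tb, ib, mb, _) in zip(fa, fb):
            assert (ta, ia) == (tb, ib)
            gap = ma - mb
            if ta == "b":
                assert gap == pytest.approx(scheme.n_term_gap, abs=1e-9)
            else:
                assert gap == pytest.approx(-scheme.c_term_gap, abs=1e-9)

    @pytest.mark.parametrize("pep", ["NLADVVNK", "PEPTIDER", "AGK"])
    def test_mz_against_residue_mass_oracle(self, scheme, pep):
        """b/y m/z agree with an independent pyteomics mass summation."""
        for channel in (CHANNEL_A, CHANNEL_B):
            n_d, c_d = scheme.channel_deltas(channel)
            for ion, i, mz, z in theoretical_fragments(pep, scheme, channel):
                if ion == "b":
                    ref = pmass.fast_mass(pep[:i], ion_type="b", charge=1) + n_d
                else:
                    ref = pmass.fast_mass(pep[-i:], ion_type="y", charge=1) + c_d
                assert mz == pytest.approx(ref, abs=1e-6)


def _spectrum_for(pep, scheme, ratio=1.0, fraction="cytosolic", sid="s1"):
    ch_s = scheme.sample_channel(fraction)
    ch_t = scheme.standard_channel(fraction)
    mz, inten = [], []
    for (fs, ft) in zip(theoretical_fragments(pep, scheme, ch_s),
                        theoretical_fragments(pep, scheme, ch_t)):
        mz += [fs[2], ft[2]]
        inten += [1e5 * ratio, 1e5]
    order = np.argsort(mz)
    return Spectrum(spectrum_id=sid, mz=np.array(mz)[order],
                    intensity=np.array(inten)[order], sample_id="x",
                    fraction=fraction)


class TestMatching:
    CANDS = [Candidate("NLADVVNK", "p1"), Candidate("LWETQGVAK", "p2"),
             Candidate("AGDDIK", "p3")]

    def test_generated_spectrum_matches_source_peptide(self, scheme):
        cands = self.CANDS + reversed_decoys(self.CANDS)
        s = _spectrum_for("LWETQGVAK", scheme)
        m = match_spectrum(s, cands)
        assert m.peptide == "LWETQGVAK" and not m.is_decoy

    def test_agrees_with_exhaustive_scoring(self, scheme):
        """Vectorized matcher equals brute-force per-candidate counting."""
        cands = self.CANDS + reversed_decoys(self.CANDS)
        s = _spectrum_for("NLADVVNK", scheme, ratio=2.0)
        matcher = Matcher(cands, scheme, 0.01)
        mz = np.sort(s.mz)

        def brute(pep):
            hits = 0
            for ch in (CHANNEL_A, CHANNEL_B):
                for _, _, t, _ in theoretical_fragments(pep, scheme, ch):
                    if np.min(np.abs(mz - t)) <= 0.01:
                        hits += 1
            return hits
        best = max(sorted(matcher.candidates,
                          key=lambda c: (c.peptide, c.is_decoy)),
                   key=lambda c: brute(c.peptide))
        got = matcher.match(s)
        assert got.peptide == best.peptide
        assert got.score == brute(best.peptide)

    def test_zero_tolerance_scores_nothing(self, scheme):
        s = _spectrum_for("AGDDIK", scheme)
        shifted = Spectrum("s", s.mz + 0.005, s.intensity, fraction="cytosolic")
        m = match_spectrum(shifted, self.CANDS, tol_mz=1e-9)
        assert m.score == 0

    def test_empty_candidates_rejected(self, scheme):
        with pytest.raises(ValueError):
            match_spectrum(_spectrum_for("AGDDIK", scheme), [])


def _psm(i, score, decoy=False):
    return PeptideSpectrumMatch(f"s{i}", "PEP", "p", decoy, score)


class TestQValues:
    def test_enumerated_example(self):
        """Targets {10, 9, 8}, decoy {8.5}: q(9) = 0, q(8) = 1/3."""
        psms = [_psm(0, 10), _psm(1, 9), _psm(2, 8), _psm(3, 8.5, True)]
        compute_qvalues(psms)
        q = {p.score: p.q_value for p in psms if not p.is_decoy}
        assert q[10] == 0.0
        assert q[9] == 0.0
        assert q[8] == pytest.approx(1 / 3)

    def test_all_decoys_below_targets(self):
        psms = [_psm(i, 10 + i) for i in range(5)]
        psms += [_psm(10 + i, i, True) for i in range(3)]
        compute_qvalues(psms)
        assert all(p.q_value == 0.0 for p in psms if not p.is_decoy)

    def test_order_invariance(self, rng):
        scores = rng.normal(10, 3, size=40)
        decoys = rng.random(40) < 0.4
        psms = [_psm(i, s, d) for i, (s, d) in enumerate(zip(scores, decoys))]
        compute_qvalues(psms)
        q1 = {p.spectrum_id: p.q_value for p in psms}
        perm = list(psms)
        rng.shuffle(perm)
        compute_qvalues(perm)
        assert {p.spectrum_id: p.q_value for p in perm} == q1

    @given(st.lists(st.tuples(st.floats(0, 100), st.booleans()),
                    min_size=2, max_size=60))
    @settings(derandomize=True, max_examples=50)
    def test_q_in_unit_interval_and_monotone(self, items):
        psms = [_psm(i, s, d) for i, (s, d) in enumerate(items)]
        compute_qvalues(psms)
        ordered = sorted(psms, key=lambda p: p.score)
        qs = [p.q_value for p in ordered]
        assert all(0.0 <= q <= 1.0 for q in qs)
        assert all(a >= b for a, b in zip(qs, qs[1:]))  # non-increasing

    def test_no_decoys_warns(self):
        psms = [_psm(0, 5), _psm(1, 6)]
        with pytest.warns(UserWarning):
            compute_qvalues(psms)
        assert all(p.q_value == 0.0 for p in psms)


class TestQuantifySpectrum:
    def _quant(self, scheme, ratios, fraction="cytosolic"):
        pep = "AGDDIKK"[:len(ratios) + 1]  # any peptide with enough fragments
        pep = "NLADVVNK"
        ch_s = scheme.sample_channel(fraction)
        ch_t = scheme.standard_channel(fraction)
        mz, inten = [], []
        frags_s = theoretical_fragments(pep, scheme, ch_s)
        frags_t = theoretical_fragments(pep, scheme, ch_t)
        for k, (fs, ft) in enumerate(zip(frags_s, frags_t)):
            if k >= len(ratios):
                break
            mz += [fs[2], ft[2]]
            inten += [100.0 * ratios[k], 100.0]
        order = np.argsort(mz)
        s = Spectrum("s", np.array(mz)[order], np.array(inten)[order],
                     fraction=fraction)
        psm = PeptideSpectrumMatch("s", pep, "p", False, 10, 0.0)
        return quantify_spectrum(s, psm, scheme)

    def test_constant_pairs(self, scheme):
        r = self._quant(scheme, [2.0, 2.0, 2.0])
        assert r.log2_ratio == pytest.approx(1.0)
        assert r.n_fragment_pairs == 3

    def test_median_of_two(self, scheme):
        # pair ratios {1, 4} -> median of {0, 2} in log2 = 1.0
        r = self._quant(scheme, [1.0, 4.0])
        assert r.log2_ratio == pytest.approx(1.0)

    def test_channel_swap_negates(self, scheme, tiny_sc, tiny_proteome):
        """Regenerating spectra with sample/standard orientation swapped and
        quantifying with the original scheme negates every log2 ratio."""
        sc = tiny_sc.noiseless()
        sid = sc.sample_id("C_limited", "light", 1, 7.5)
        swapped = scheme.swapped()
        for fraction in ("membrane", "cytosolic"):
            a, truth = simulate_iptl_run(tiny_proteome, sc, sid, fraction,
                                         seed=1, scheme=scheme)
            b, _ = simulate_iptl_run(tiny_proteome, sc, sid, fraction,
                                     seed=1, scheme=swapped)
            lookup = truth.set_index("spectrum_id")
            for ea, eb in zip(a, b):
                sa, sb = Spectrum.from_mgf(ea), Spectrum.from_mgf(eb)
                t = lookup.loc[sa.spectrum_id]
                if t.peptide == "":
                    continue
                psm = PeptideSpectrumMatch(sa.spectrum_id, t.peptide,
                                           t.protein_id, False, 10, 0.0)
                ra = quantify_spectrum(sa, psm, scheme)
                rb = quantify_spectrum(sb, psm, scheme)
                assert ra.log2_ratio == pytest.approx(t.true_log2_ratio,
                                                      abs=1e-9)
                assert rb.log2_ratio == pytest.approx(-ra.log2_ratio,
                                                      abs=1e-9)


class TestAggregateProtein:
    def _sr(self, val, pep="PEPTIDEK", sid="s"):
        from iptlpipe.iptl_quant import SpectrumRatio
        return SpectrumRatio(sid, pep, "p", "cytosolic", "sample1", val, 3)

    def test_single_peptide_three_spectra(self):
        out = aggregate_protein([self._sr(1.0), self._sr(1.0), self._sr(1.0)])
        assert out == (1.0, 0.0, 3)

    def test_lone_spectrum_peptide_dropped(self):
        assert aggregate_protein([self._sr(2.0)]) is None

    def test_two_spectra_se(self):
        out = aggregate_protein([self._sr(0.0), self._sr(2.0)])
        mean, se, n = out
        assert mean == pytest.approx(1.0)
        assert se == pytest.approx(1.0)  # sd(sqrt(2)) / sqrt(2)
        assert n == 2

    def test_mixed_peptides_filter(self):
        ratios = [self._sr(1.0, "AAAAK"), self._sr(1.0, "AAAAK"),
                  self._sr(99.0, "CCCCK")]  # lone-spectrum peptide removed
        mean, se, n = aggregate_protein(ratios)
        assert mean == pytest.approx(1.0)
        assert n == 2
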