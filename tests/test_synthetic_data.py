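"""Generator behavior: determinism, digestion rules, growth model shapes,
standard-peptide areas and qPCR arithmetic."""

import io

import numpy as np
import pandas as pd
import pytest
from pyteomics import mgf as pymgf

from iptlpipe import default_scenario, digest, make_toy_proteome, tiny_scenario
from iptlpipe.synthetic_data import (PR_PEPTIDES, simulate_calibration,
                                     simulate_growth, simulate_iptl_run,
                                     simulate_pr_standard_areas,
                                     simulate_qpcr, Scenario)


class TestToyProteome:
    def test_deterministic_fasta(self, tmp_path):
        a, b = tmp_path / "a.fasta", tmp_path / "b.fasta"
        make_toy_proteome(50, 300, seed=7).to_fasta(a)
        make_toy_proteome(50, 300, seed=7).to_fasta(b)
        assert a.read_bytes() == b.read_bytes()

    def test_pr_entry_contains_standard_peptides(self):
        prot = make_toy_proteome(50, 300, seed=7)
        pr_seq = prot.sequence(prot.pr_id)
        assert all(p in pr_seq for p in PR_PEPTIDES)
        # and they are proper tryptic products
        for p in PR_PEPTIDES:
            assert p in digest(pr_seq, {"trypsin"})

    def test_record_count_and_validation(self, tmp_path):
        prot = make_toy_proteome(2, 50, seed=1)
        assert len(prot.entries) == 2
        with pytest.raises(ValueError):
            make_toy_proteome(1, 50, seed=1)

    def test_tryptic_peptides_typical_length(self):
        prot = make_toy_proteome(30, 400, seed=3)
        lengths = [len(p) for _, s in prot.entries
                   for p in digest(s, {"trypsin"}, min_length=1)]
        assert 6 <= np.median(lengths) <= 20


class TestDigest:
    @pytest.mark.parametrize("seq,enzymes,expected", [
        ("AAAKAAAR", {"trypsin"}, []),              # 4-mers removed by filter
        ("AAAAKPAAAA", {"trypsin"}, ["AAAAKPAAAA"]),  # no cleavage before P
        ("AAADKAAADR", {"trypsin"}, ["AAADK", "AAADR"]),
        ("AAAWAAADF", {"chymotrypsin"}, ["AAADF"]),   # AAAW removed (len 4)
    ])
    def test_cleavage_rules(self, seq, enzymes, expected):
        assert digest(seq, enzymes) == expected

    def test_before_length_filter(self):
        assert digest("AAAKAAAR", {"trypsin"}, min_length=1) == ["AAAK", "AAAR"]

    def test_combined_equals_sequential(self, tiny_proteome):
        for _, seq in tiny_proteome.entries[:3]:
            combined = set(digest(seq, {"trypsin", "chymotrypsin"},
                                  min_length=1))
            sequential = {p2 for p1 in digest(seq, {"trypsin"}, min_length=1)
                          for p2 in digest(p1, {"chymotrypsin"}, min_length=1)}
            assert combined == sequential

    def test_missed_cleavages(self):
        peps = digest("AAADKAAADR", {"trypsin"}, missed_cleavages=1)
        assert "AAADKAAADR" in peps

    def test_unknown_enzyme(self):
        with pytest.raises(ValueError):
            digest("AAAK", {"pepsin"})


class TestSpectraSimulation:
    def test_byte_identical_mgf(self, tiny_sc, tiny_proteome, tmp_path):
        sid = tiny_sc.sample_id("C_limited", "light", 1, 7.5)
        files = []
        for name in ("a.mgf", "b.mgf"):
            path = tmp_path / name
            simulate_iptl_run(tiny_proteome, tiny_sc, sid, "membrane",
                              seed=5, out_path=path)
            files.append(path.read_bytes())
        assert files[0] == files[1]

    def test_noiseless_fragment_pairs_exact(self, tiny_sc, tiny_proteome,
                                            scheme):
        sc = tiny_sc.noiseless()
        sid = sc.sample_id("C_limited", "light", 1, 7.5)
        entries, truth = simulate_iptl_run(tiny_proteome, sc, sid,
                                           "cytosolic", seed=1)
        real = truth[truth.peptide != ""]
        by_id = {t.spectrum_id: t for t in real.itertuples()}
        from iptlpipe.iptl_quant import Spectrum, theoretical_fragments
        for e in entries:
            s = Spectrum.from_mgf(e)
            t = by_id.get(s.spectrum_id)
            if t is None:
                continue
            ch_s = scheme.sample_channel("cytosolic")
            ch_t = scheme.standard_channel("cytosolic")
            mz = dict(zip(np.round(s.mz, 6), s.intensity))
            ratio = 2.0 ** t.true_log2_ratio
            for (fs, ft) in zip(theoretical_fragments(t.peptide, scheme, ch_s),
                                theoretical_fragments(t.peptide, scheme, ch_t)):
                r = mz[round(fs[2], 6)] / mz[round(ft[2], 6)]
                assert r == pytest.approx(ratio, rel=1e-9)

    def test_mgf_roundtrip_readable(self, tiny_sc, tiny_proteome, tmp_path):
        sid = tiny_sc.sample_id("N_limited", "dark", 2,
                                tiny_sc.timepoints_h[1])
        path = tmp_path / "s.mgf"
        entries, _ = simulate_iptl_run(tiny_proteome, tiny_sc, sid,
                                       "membrane", seed=2, out_path=path)
        with pymgf.read(str(path)) as reader:
            read_back = list(reader)
        assert len(read_back) == len(entries)

    def test_unknown_sample_rejected(self, tiny_sc, tiny_proteome):
        with pytest.raises(ValueError, match="not in scenario"):
            simulate_iptl_run(tiny_proteome, tiny_sc, "nope", "membrane", 1)


class TestGrowth:
    def test_noiseless_exponential_slope(self):
        sc = default_scenario().noiseless()
        g = simulate_growth(sc, "C_limited", "dark", 1, seed=0)
        early = g[g.time_h <= 6.0]
        slope = np.polyfit(early.time_h, np.log(early.od), 1)[0]
        # logistic growth: early ln-OD slope approaches mu_max from below
        assert slope == pytest.approx(0.14, rel=0.02)

    def test_n_limited_cfu_collapse(self):
        sc = default_scenario()
        g = simulate_growth(sc, "N_limited", "light", 1, seed=3)
        assert (g.loc[g.time_h > 100, "cfu_per_ml"] == 0).all()

    def test_c_limited_survival_with_od_decline(self):
        sc = default_scenario().noiseless()
        g = simulate_growth(sc, "C_limited", "dark", 1, seed=0)
        late = g[g.time_h > 100]
        assert (late.cfu_per_ml > 0).all()
        assert (late.od < 0.9 * g.od.max()).all()

    def test_determinism(self):
        sc = default_scenario()
        a = simulate_growth(sc, "C_limited", "light", 2, seed=9)
        b = simulate_growth(sc, "C_limited", "light", 2, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestPrAreasAndQpcr:
    def test_noiseless_area_ratio_equals_amount_ratio(self):
        sc = default_scenario().noiseless()
        areas = simulate_pr_standard_areas(sc, seed=1)
        row = areas.iloc[0]
        expected = (sc.pr_amount_pmol_true(row.condition, 0) / sc.spike_pmol)
        assert row.native_area / row.standard_area == pytest.approx(expected)

    def test_peptides_share_sample_truth(self):
        sc = default_scenario().noiseless()
        areas = simulate_pr_standard_areas(sc, seed=1)
        ratios = areas.assign(r=areas.native_area / areas.standard_area)
        spread = ratios.groupby("sample_id").r.agg(lambda v: v.max() - v.min())
        assert (spread.abs() < 1e-12).all()

    def test_qpcr_ct_doubles_per_halving(self):
        sc = default_scenario().noiseless()
        ct = simulate_qpcr(sc, "PR", seed=0).set_index("sample_id")
        s = sc.sample_table()
        # two samples whose true PR quantities differ exactly 2-fold
        a = s[(s.condition == "C_limited") & (s.light == "light")].iloc[0]
        q_a = sc.transcript_quantity_true("PR", "C_limited", "light", 0)
        q_b = sc.transcript_quantity_true("PR", "N_limited", "light", 0)
        b = s[(s.condition == "N_limited") & (s.light == "light")].iloc[0]
        dct = ct.loc[b.sample_id].ct - ct.loc[a.sample_id].ct
        assert dct == pytest.approx(np.log2(q_a / q_b))

    def test_qpcr_deterministic(self):
        sc = default_scenario()
        a = simulate_qpcr(sc, "blh", seed=4)
        b = simulate_qpcr(sc, "blh", seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_calibration_noiseless_exact(self):
        sc = default_scenario().noiseless()
        cal = simulate_calibration(sc, seed=0)
        np.testing.assert_allclose(cal.cells_per_ml,
                                   sc.calibration_slope * cal.od)


class TestScenario:
    def test_yaml_roundtrip(self, tmp_path, tiny_sc):
        path = tmp_path / "sc.yaml"
        tiny_sc.to_yaml(path)
        back = Scenario.from_yaml(path)
        assert back == tiny_sc

    def test_validation(self):
        with pytest.raises(ValueError):
            tiny_scenario(timepoints_h=(2.0, 1.0, 3.0))
        with pytest.raises(ValueError):
            tiny_scenario(replicates=1)

    def test_default_truths(self):
        sc = default_scenario()
        assert sc.pr_stationary_fold_change_true() == pytest.approx(4.4)
        assert max(sc.pr_copies_per_cell["C_limited"]) == pytest.approx(5606)
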