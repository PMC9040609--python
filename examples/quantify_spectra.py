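"""Quantify diDO-IPTL spectra for one simulated LC-MS run.

Simulates one cytosolic-fraction run, matches each spectrum against the
digested toy proteome plus reversed-sequence decoys, controls spectrum-
level FDR at q < 0.1%, extracts sample/standard log2 ratios from fragment
pairs, and compares the protein-level estimates with the generator truth.
"""

from iptlpipe import Spectrum, make_toy_proteome, tiny_scenario
from iptlpipe.pipeline import quantify_spectra
from iptlpipe.synthetic_data import simulate_iptl_run, true_profiles

scenario = tiny_scenario()
proteome = make_toy_proteome(scenario.n_proteins, scenario.mean_length,
                             seed=scenario.seed)
sample = scenario.sample_id("C_limited", "light", 1, 7.5)
entries, truth = simulate_iptl_run(proteome, scenario, sample,
                                   "cytosolic", seed=3)
spectra = [Spectrum.from_mgf(e) for e in entries]
psms, ratios, quant = quantify_spectra(spectra, proteome)

profiles = true_profiles(scenario, proteome)
truth_col = profiles[("C_limited", "light", 0)]

print(f"{len(spectra)} spectra ({truth.peptide.eq('').sum()} pure noise), "
      f"{len(ratios)} quantified after q < 0.001")
print(f"{'protein':<10} {'estimate':>9} {'truth':>7} {'SE':>6} {'spectra':>8}")
for row in quant.itertuples():
    print(f"{row.protein_id:<10} {row.log2_ratio:>9.3f} "
          f"{truth_col[row.protein_id]:>7.2f} {row.se:>6.3f} "
          f"{row.n_spectra:>8d}")
print("\nEstimates are log2 sample/standard ratios; with per-fragment noise")
print("sd 0.1 (log2) each protein lands within a few hundredths of truth.")
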