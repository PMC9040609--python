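import numpy as np
import pytest

from iptlpipe import label_masses, make_toy_proteome, tiny_scenario
from iptlpipe.synthetic_data import true_profiles


@pytest.fixture(scope="session")
def noiseless_e2e():
    """Full pipeline run on a noiseless miniature study, shared across
    round-trip tests: simulate every (sample, fraction) run, quantify,
    build and consolidate the expression table."""
    from iptlpipe import expression_tables
    from iptlpipe.iptl_quant import Spectrum
    from iptlpipe.pipeline import quantify_spectra
    from iptlpipe.synthetic_data import simulate_iptl_run

    sc = tiny_scenario(noise_spectra_fraction=0.0,
                       spectra_per_peptide_mean=2.0).noiseless()
    proteome = make_toy_proteome(sc.n_proteins, sc.mean_length, seed=sc.seed)
    profiles = true_profiles(sc, proteome)
    spectra = []
    for _, m in sc.metadata_table().iterrows():
        entries, _ = simulate_iptl_run(proteome, sc, m.sample_id, m.fraction,
                                       seed=11, profiles=profiles)
        spectra.extend(Spectrum.from_mgf(e) for e in entries)
    psms, ratios, quant = quantify_spectra(spectra, proteome)
    expr = expression_tables.build_expression_table(quant,
                                                    sc.metadata_table())
    consolidated = expression_tables.consolidate_table(expr)
    return dict(scenario=sc, proteome=proteome, profiles=profiles,
                psms=psms, ratios=ratios, quant=quant, expr=expr,
                consolidated=consolidated)


@pytest.fixture(scope="session")
def scheme():
    return label_masses()


@pytest.fixture(scope="session")
def tiny_sc():
    return tiny_scenario()


@pytest.fixture(scope="session")
def tiny_proteome(tiny_sc):
    return make_toy_proteome(tiny_sc.n_proteins, tiny_sc.mean_length,
                             seed=tiny_sc.seed)


@pytest.fixture(scope="session")
def tiny_truth(tiny_sc, tiny_proteome):
    return true_profiles(tiny_sc, tiny_proteome)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
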