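"""End-to-end orchestration: simulate -> quantify -> tables -> diffexpr ->
PR absolute quantification -> physiology, with fixed seeds throughout.

Also provides the reference scenario recovery used to validate the
pipeline: regenerating the default study over several seeds and measuring
the stationary-phase PR fold change, maximum copies/cell, and C-limited
growth parameters against the scenario's ground truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import diff_expr, expression_tables, physiology, pr_absolute
from .iptl_quant import (CYTOSOLIC, MEMBRANE, Candidate, Matcher, Spectrum,
                         aggregate_protein, compute_qvalues, filter_psms,
                         label_masses, quantify_spectrum, reversed_decoys)
from .synthetic_data import (FRACTION_ENZYMES, Scenario, ToyProteome,
                             default_scenario, digest, simulate_calibration,
                             simulate_growth_all, simulate_pr_standard_areas,
                             tiny_scenario, write_study)

log = logging.getLogger("iptlpipe")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    scenario: str = "caim519"     # built-in name or YAML path
    seed: int = 1
    outdir: str = "iptlpipe_out"
    tol_mz: float = 0.01
    q_max: float = 0.001          # spectrum-level q-value threshold (<0.1%)
    fdr_alpha: float = 0.05       # BH threshold for differential calls
    min_spectra_per_peptide: int = 2

    def __post_init__(self):
        if not (0 < self.q_max < 1):
            raise ValueError("q_max must lie in (0, 1)")

    def load_scenario(self) -> Scenario:
        if self.scenario == "caim519":
            return default_scenario()
        if self.scenario == "tiny":
            return tiny_scenario()
        return Scenario.from_yaml(self.scenario)


# ---------------------------------------------------------------------------
# spectrum-level quantification pipeline

def build_candidates(proteome: ToyProteome, fraction: str,
                     max_length: int = 30) -> list[Candidate]:
    """Target + reversed-decoy peptide candidates for one fraction."""
    targets = []
    seen = set()
    for pid, seq in proteome.entries:
        for pep in digest(seq, FRACTION_ENZYMES[fraction]):
            if len(pep) <= max_length and pep not in seen:
                seen.add(pep)
                targets.append(Candidate(pep, pid, False))
    return targets + reversed_decoys(targets)


def quantify_spectra(spectra: list[Spectrum], proteome: ToyProteome,
                     tol_mz: float = 0.01, q_max: float = 0.001,
                     min_spectra_per_peptide: int = 2, scheme=None):
    """Match, FDR-filter, and quantify a batch of spectra.

    Returns (psm table, spectrum-ratio table, protein x sample table).
    q-values are computed per fraction (each fraction is a separate
    target-decoy search space).
    """
    scheme = scheme or label_masses()
    psm_rows, ratio_objs = [], []
    for fraction in sorted({s.fraction for s in spectra}):
        sub = [s for s in spectra if s.fraction == fraction]
        matcher = Matcher(build_candidates(proteome, fraction), scheme, tol_mz)
        psms = [matcher.match(s) for s in sub]
        compute_qvalues(psms)
        passing = {p.spectrum_id: p for p in filter_psms(psms, q_max)}
        for p in psms:
            psm_rows.append(dict(
                spectrum_id=p.spectrum_id, peptide=p.peptide,
                protein_id=p.protein_id, is_decoy=p.is_decoy,
                score=p.score, q_value=p.q_value, fraction=fraction))
        for s in sub:
            p = passing.get(s.spectrum_id)
            if p is None:
                continue
            r = quantify_spectrum(s, p, scheme, tol_mz)
            if r is None:
                log.info("spectrum %s dropped: no fragment pairs",
                         s.spectrum_id)
                continue
            ratio_objs.append(r)
    ratio_df = pd.DataFrame([vars(r) for r in ratio_objs])
    quant_rows = []
    if len(ratio_df):
        for (pid, sid, frac), g in _group_ratios(ratio_objs):
            agg = aggregate_protein(g, min_spectra_per_peptide)
            if agg is None:
                continue
            log2, se, n = agg
            quant_rows.append(dict(protein_id=pid, sample_id=sid,
                                   fraction=frac, log2_ratio=log2,
                                   se=se, n_spectra=n))
    return pd.DataFrame(psm_rows), ratio_df, pd.DataFrame(quant_rows)


def _group_ratios(ratios):
    groups: dict = {}
    for r in ratios:
        groups.setdefault((r.protein_id, r.sample_id, r.fraction),
                          []).append(r)
    return sorted(groups.items())


def read_mgf_dir(spectra_dir) -> list[Spectrum]:
    from pyteomics import mgf as pymgf
    spectra = []
    for path in sorted(Path(spectra_dir).glob("*.mgf")):
        with pymgf.read(str(path)) as reader:
            spectra.extend(Spectrum.from_mgf(e) for e in reader)
    return spectra


# ---------------------------------------------------------------------------
# scenario recovery (reference-scenario truths)

def recover_pr_metrics(scenario: Scenario, seed: int) -> dict:
    """One-seed recovery of the PR absolute-quantification quantities."""
    areas = simulate_pr_standard_areas(scenario, seed)
    growth = simulate_growth_all(scenario, seed)
    cal = simulate_calibration(scenario, seed)
    calib = pr_absolute.CellCalibration.fit(cal.od, cal.cells_per_ml)
    amounts = pr_absolute.quantify_samples(
        areas, growth, calib, volume_ml=scenario.sample_volume_ml)
    phase_map = expression_tables.assign_phase(sorted(scenario.timepoints_h))
    fc, fc_err = pr_absolute.condition_fold_change(amounts, phase_map)
    gs = physiology.growth_summary(growth)
    c = gs[gs.condition == "C_limited"]
    n = gs[gs.condition == "N_limited"]
    return dict(
        pr_fold_change=fc, pr_fold_change_err=fc_err,
        max_copies_per_cell=pr_absolute.max_copies_per_cell(amounts,
                                                            "C_limited"),
        mu_max_C=float(c.mu_max.mean()), od_max_C=float(c.od_max.mean()),
        mu_max_N=float(n.mu_max.mean()), od_max_N=float(n.od_max.mean()),
    )


def recover_study_metrics(base_seed: int, n_seeds: int = 10,
                          scenario: Scenario | None = None) -> dict:
    """Mean recovered metrics over independently regenerated studies."""
    scenario = scenario or default_scenario()
    per_seed = [recover_pr_metrics(scenario, int(base_seed) * 1000 + i)
                for i in range(n_seeds)]
    out = {k: float(np.mean([d[k] for d in per_seed]))
           for k in per_seed[0]}
    out["n_seeds"] = n_seeds
    return out


# ---------------------------------------------------------------------------
# full run

def run_all(config: RunConfig) -> dict:
    """Execute every stage and write tables plus a summary JSON.

    Reruns with the same config are byte-identical.  Returns the summary.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenario = config.load_scenario()
    log.info("[simulate] writing study to %s", outdir)
    paths = write_study(scenario, outdir, config.seed)

    log.info("[quantify] matching and quantifying spectra")
    proteome = ToyProteome.from_fasta(paths["fasta"])
    spectra = read_mgf_dir(paths["spectra_dir"])
    psms, ratios, quant = quantify_spectra(
        spectra, proteome, config.tol_mz, config.q_max,
        config.min_spectra_per_peptide)
    psms.to_csv(outdir / "psms.csv", index=False)
    ratios.to_csv(outdir / "spectrum_ratios.csv", index=False)
    quant.to_csv(outdir / "protein_quant.csv", index=False)

    log.info("[tables] building expression tables")
    metadata = pd.read_csv(paths["metadata"])
    expr = expression_tables.build_expression_table(quant, metadata)
    expr.to_csv(outdir / "expression_long.csv", index=False)
    consolidated = expression_tables.consolidate_table(expr)
    consolidated.to_csv(outdir / "expression_consolidated.csv", index=False)
    frac = expression_tables.fraction_summary(quant)

    log.info("[diffexpr] fitting contrasts")
    phases = [None] + sorted(expr.phase.unique())
    sig_counts = {}
    for cond in scenario.conditions:
        results = {}
        for ph in phases:
            res = diff_expr.test_contrast(expr, diff_expr.light_vs_dark(cond, ph),
                                          alpha=config.fdr_alpha)
            results[ph or diff_expr.ALL_PHASES] = res
        report = diff_expr.phase_report(results)
        report.to_csv(outdir / f"diffexpr_light_vs_dark_{cond}.csv",
                      index=False)
        sig_counts[f"light_vs_dark_{cond}"] = int(len(report))
    results = {}
    for ph in phases:
        results[ph or diff_expr.ALL_PHASES] = diff_expr.test_contrast(
            expr, diff_expr.c_vs_n(ph), alpha=config.fdr_alpha)
    report = diff_expr.phase_report(results)
    report.to_csv(outdir / "diffexpr_N_vs_C.csv", index=False)
    sig_counts["N_vs_C"] = int(len(report))

    log.info("[pr] absolute PR quantification")
    areas = pd.read_csv(paths["areas"])
    growth = pd.read_csv(paths["growth"])
    calib_df = pd.read_csv(paths["calibration"])
    calib = pr_absolute.CellCalibration.fit(calib_df.od,
                                            calib_df.cells_per_ml)
    amounts = pr_absolute.quantify_samples(
        areas, growth, calib, volume_ml=scenario.sample_volume_ml)
    amounts.to_csv(outdir / "pr_abundance.csv", index=False)
    phase_map = expression_tables.assign_phase(sorted(scenario.timepoints_h))
    fc, fc_err = pr_absolute.condition_fold_change(amounts, phase_map)

    log.info("[physiology] growth and qPCR analytics")
    gsum = physiology.growth_summary(growth)
    gsum.to_csv(outdir / "growth_summary.csv", index=False)
    qpcr = pd.read_csv(paths["qpcr"])
    rel_frames, peaks = [], {}
    for gene in ("PR", "blh", "rpoS"):
        rel = physiology.qpcr_relative_table(qpcr, gene)
        rel_frames.append(rel)
        for cond in scenario.conditions:
            for light in scenario.lights:
                sub = rel[(rel.condition == cond) & (rel.light == light)]
                try:
                    p = physiology.detect_peaks(sub)
                except ValueError:
                    p = []
                peaks[f"{gene}:{cond}:{light}"] = p
    pd.concat(rel_frames, ignore_index=True).to_csv(
        outdir / "qpcr_relative.csv", index=False)
    pd.DataFrame([dict(series=k, peak_times_h=";".join(f"{t:g}" for t in v))
                  for k, v in sorted(peaks.items())]).to_csv(
        outdir / "peaks.csv", index=False)

    summary = dict(
        scenario=scenario.name, seed=config.seed,
        fraction_summary=frac,
        growth={cond: dict(
            mu_max=float(gsum[gsum.condition == cond].mu_max.mean()),
            od_max=float(gsum[gsum.condition == cond].od_max.mean()))
            for cond in scenario.conditions},
        pr=dict(stationary_fold_change_C_over_N=fc,
                fold_change_err=fc_err,
                max_copies_per_cell=pr_absolute.max_copies_per_cell(
                    amounts, "C_limited")),
        significant_proteins=sig_counts,
    )
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1,
                                                    sort_keys=True))
    return summary
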