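"""Synthetic study generator: toy proteome, labeled MS2 spectra, growth,
PR standard-peptide areas, and qPCR tables with known ground truth.

The generator emulates a batch-culture nutrient-limitation study of a
proteorhodopsin (PR)-bearing marine *Vibrio*: triplicate C-limited and
N-limited cultures grown under continuous light or dark, sampled at nine
proteomic time points (every 1.5 h from 7.5 to 15 h, then 27.5, 51.5 and
75.5 h).  Each sample yields two peptide fractions (membrane, cytosolic)
labeled with inverse diDO-IPTL channel orientation against a pooled
internal standard; PR itself is quantified separately from MS1 peak-area
ratios against heavy-lysine synthetic standard peptides.

Every output is a pure function of (scenario, seed), so a fixed seed gives
byte-identical files and the full pipeline can be validated by round-trip
against the stored ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as pymgf

from .iptl_quant import (CHANNEL_A, CYTOSOLIC, MEMBRANE, LabelScheme,
                         label_masses, precursor_mz, theoretical_fragments)

AVOGADRO = 6.02214076e23

#: the two PR tryptic peptides used as absolute-quantification targets
PR_PEPTIDES = ("LWETQGVAK", "NLADVVNK")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# residue frequencies tuned so tryptic peptides are typically 6-20 residues
# (K+R frequency ~0.115 -> mean tryptic length ~9)
_AA_FREQ = {
    "A": 0.080, "C": 0.015, "D": 0.055, "E": 0.065, "F": 0.040,
    "G": 0.070, "H": 0.022, "I": 0.058, "K": 0.060, "L": 0.090,
    "M": 0.024, "N": 0.045, "P": 0.030, "Q": 0.040, "R": 0.055,
    "S": 0.065, "T": 0.055, "V": 0.070, "W": 0.013, "Y": 0.048,
}

_ENZYME_RULES = {
    "trypsin": "KR",
    "chymotrypsin": "FWYLM",
}

FRACTION_ENZYMES = {
    MEMBRANE: frozenset({"chymotrypsin", "trypsin"}),
    CYTOSOLIC: frozenset({"trypsin"}),
}


# ---------------------------------------------------------------------------
# toy proteome and in-silico digestion

@dataclass(frozen=True)
class ToyProteome:
    """A small randomly generated proteome with one PR-like entry."""

    entries: tuple  # of (protein_id, sequence)
    pr_id: str

    def sequence(self, protein_id: str) -> str:
        for pid, seq in self.entries:
            if pid == protein_id:
                return seq
        raise KeyError(protein_id)

    def to_fasta(self, path) -> None:
        records = [SeqRecord(Seq(seq), id=pid, description="")
                   for pid, seq in self.entries]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path, pr_marker: str = PR_PEPTIDES[0]) -> "ToyProteome":
        entries = tuple((r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta"))
        pr_id = next((pid for pid, seq in entries if pr_marker in seq), entries[0][0])
        return cls(entries=entries, pr_id=pr_id)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    aas = np.array(list(_AA_FREQ))
    p = np.array(list(_AA_FREQ.values()))
    p = p / p.sum()
    return "".join(rng.choice(aas, size=length, p=p))


def make_toy_proteome(n_proteins: int, mean_length: int = 300,
                      seed: int = 0) -> ToyProteome:
    """Random proteome whose first entry is PR-like.

    The PR-like entry embeds the two standard peptides LWETQGVAK and
    NLADVVNK as proper tryptic peptides (preceded by K, not followed by P).
    Deterministic for a fixed seed.
    """
    if n_proteins < 2:
        raise ValueError("n_proteins must be >= 2")
    rng = np.random.default_rng(seed)

    def seg(n):
        s = _random_sequence(rng, n)
        # keep the embedded standard peptides cleavable: no P after K
        return ("A" + s[1:]) if s.startswith("P") else s

    pr_seq = (seg(40) + "K" + PR_PEPTIDES[0] + seg(60) + "K"
              + PR_PEPTIDES[1] + seg(40))
    entries = [("PR_00001", pr_seq)]
    for i in range(2, n_proteins + 1):
        length = max(50, int(rng.normal(mean_length, mean_length / 5)))
        entries.append((f"VC_{i:05d}", _random_sequence(rng, length)))
    return ToyProteome(entries=tuple(entries), pr_id="PR_00001")


def _cleavage_sites(sequence: str, enzymes) -> list[int]:
    for e in enzymes:
        if e not in _ENZYME_RULES:
            raise ValueError(f"unknown enzyme {e!r}")
    residues = "".join(_ENZYME_RULES[e] for e in enzymes)
    sites = [i + 1 for i in range(len(sequence) - 1)
             if sequence[i] in residues and sequence[i + 1] != "P"]
    return sites


def digest(sequence: str, enzymes={"trypsin"}, missed_cleavages: int = 0,
           min_length: int = 5) -> list[str]:
    """In-silico protease digestion.

    Trypsin cleaves C-terminal to K/R, chymotrypsin (broad specificity)
    C-terminal to F/W/Y/L/M, neither before proline; passing both enzymes
    applies the union of the cleavage rules, equivalent to sequential
    digestion.  Products shorter than ``min_length`` (default 5) are
    discarded.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    sites = _cleavage_sites(sequence, enzymes)
    bounds = [0] + sites + [len(sequence)]
    peptides = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(bounds))):
            peptides.append(sequence[bounds[i]:bounds[j]])
    return [p for p in peptides if len(p) >= min_length]


# ---------------------------------------------------------------------------
# scenario definition

@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth with optional post-stationary OD decline or CFU
    collapse, plus viability endpoints per light condition."""

    mu_max: float                 # 1/h
    od_max: float                 # OD660 plateau
    od0: float = 0.005            # inoculation OD660
    od_decline_onset_h: float | None = None
    od_decline_rate: float = 0.0  # 1/h, applied after onset
    cfu_decline_onset_h: float | None = None
    cfu_decline_rate: float = 0.0
    cfu_zero_h: float | None = None   # CFU = 0 from this time on
    terminal_alive: dict = field(default_factory=lambda: {"light": 0.85,
                                                          "dark": 0.85})


@dataclass(frozen=True)
class NoiseParams:
    spectrum_sd: float = 0.1   # per-fragment lognormal sd, log2 units
    od_sd: float = 0.01        # multiplicative Gaussian sd on OD
    ct_sd: float = 0.15        # additive Gaussian sd on Ct, cycles
    area_sd: float = 0.15      # lognormal sd on MS1 area ratios (ln units)
    cfu_sd: float = 0.10       # lognormal sd on CFU counts (ln units)
    calib_sd: float = 0.03     # lognormal sd on calibration cell counts

    def __post_init__(self):
        if any(v < 0 for v in dataclasses.asdict(self).values()):
            raise ValueError("noise sds must be >= 0")

    def zeroed(self) -> "NoiseParams":
        return NoiseParams(0, 0, 0, 0, 0, 0)


@dataclass(frozen=True)
class Scenario:
    """Ground-truth description of one simulated study."""

    name: str = "caim519"
    conditions: tuple = ("C_limited", "N_limited")
    lights: tuple = ("light", "dark")
    replicates: int = 3
    timepoints_h: tuple = (7.5, 9.0, 10.5, 12.0, 13.5, 15.0, 27.5, 51.5, 75.5)
    # sampling cadence: every 1.5 h through 15 h, then every 24 h, plus the
    # proteomic timepoints 27.5/51.5/75.5 h
    growth_times_h: tuple = tuple(np.arange(0, 15.1, 1.5)) + (
        27.5, 39.0, 51.5, 63.0, 75.5, 87.0, 99.5, 111.0, 123.5, 147.5, 171.5)
    growth: dict = field(default_factory=dict)
    noise: NoiseParams = field(default_factory=NoiseParams)
    pr_copies_per_cell: dict = field(default_factory=dict)  # condition -> tuple
    calibration_slope: float = 1.0e9   # cells/mL per OD660 unit
    calibration_intercept: float = 0.0
    sample_volume_ml: float = 4.5      # culture volume per proteomic sample
    spike_pmol: float = 0.375          # 0.75 uL x 0.5 pmol/uL heavy standard
    qpcr_efficiency: float = 2.0
    # proteome / spectra parameters
    n_proteins: int = 40
    mean_length: int = 300
    n_light_responsive: int = 4
    n_cn_responsive: int = 8
    effect_size: float = 2.0
    spectra_per_peptide_min: int = 2
    spectra_per_peptide_mean: float = 3.0
    max_peptides_per_protein: int = 3
    noise_spectra_fraction: float = 0.1
    base_intensity: float = 1.0e5
    seed: int = 519

    def __post_init__(self):
        tp = np.asarray(self.timepoints_h)
        if not np.all(np.diff(tp) > 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")

    # -- sample bookkeeping -------------------------------------------------

    def sample_id(self, condition, light, replicate, timepoint) -> str:
        return f"{condition}:{light}:rep{replicate}:t{timepoint:g}"

    def sample_table(self) -> pd.DataFrame:
        rows = []
        for cond in self.conditions:
            for light in self.lights:
                for rep in range(1, self.replicates + 1):
                    for k, tp in enumerate(self.timepoints_h):
                        rows.append(dict(
                            sample_id=self.sample_id(cond, light, rep, tp),
                            condition=cond, light=light, replicate=rep,
                            timepoint_h=tp, tp_index=k))
        return pd.DataFrame(rows)

    def metadata_table(self) -> pd.DataFrame:
        """Per (sample, fraction) metadata, one row per LC-MS run."""
        s = self.sample_table()
        return (pd.concat([s.assign(fraction=MEMBRANE),
                           s.assign(fraction=CYTOSOLIC)])
                .sort_values(["sample_id", "fraction"]).reset_index(drop=True))

    # -- growth-model truths ------------------------------------------------

    def _gp(self, condition) -> GrowthParams:
        return self.growth[condition]

    def od_true(self, condition, t) -> np.ndarray:
        gp = self._gp(condition)
        t = np.asarray(t, dtype=float)
        ratio = (gp.od_max - gp.od0) / gp.od0
        od = gp.od_max / (1.0 + ratio * np.exp(-gp.mu_max * t))
        if gp.od_decline_onset_h is not None:
            dt = np.clip(t - gp.od_decline_onset_h, 0, None)
            od = od * np.exp(-gp.od_decline_rate * dt)
        return od

    def cfu_true(self, condition, t) -> np.ndarray:
        gp = self._gp(condition)
        t = np.asarray(t, dtype=float)
        # cultivable counts track the undeclined logistic curve
        ratio = (gp.od_max - gp.od0) / gp.od0
        base = gp.od_max / (1.0 + ratio * np.exp(-gp.mu_max * t))
        cfu = self.calibration_slope * base
        if gp.cfu_decline_onset_h is not None:
            dt = np.clip(t - gp.cfu_decline_onset_h, 0, None)
            cfu = cfu * np.exp(-gp.cfu_decline_rate * dt)
        if gp.cfu_zero_h is not None:
            cfu = np.where(t >= gp.cfu_zero_h, 0.0, cfu)
        return cfu

    def alive_true(self, condition, light, t) -> np.ndarray:
        gp = self._gp(condition)
        t = np.asarray(t, dtype=float)
        hi, lo = 0.95, gp.terminal_alive[light]
        return lo + (hi - lo) / (1.0 + np.exp((t - 50.0) / 10.0))

    def cells_per_ml_true(self, condition, t) -> np.ndarray:
        return (self.calibration_intercept
                + self.calibration_slope * self.od_true(condition, t))

    def cells_analyzed_true(self, condition, tp) -> float:
        return float(self.cells_per_ml_true(condition, tp) * self.sample_volume_ml)

    def pr_amount_pmol_true(self, condition, tp_index) -> float:
        """True PR amount (pmol) in one proteomic sample."""
        tp = self.timepoints_h[tp_index]
        copies = self.pr_copies_per_cell[condition][tp_index]
        cells = self.cells_analyzed_true(condition, tp)
        return copies * cells / AVOGADRO * 1e12

    def pr_stationary_fold_change_true(self) -> float:
        """True C/N ratio of stationary-phase (last two timepoints) mean
        PR amounts."""
        n = len(self.timepoints_h)
        stat = range(n - 2, n)
        m = {c: np.mean([self.pr_amount_pmol_true(c, k) for k in stat])
             for c in ("C_limited", "N_limited")}
        return m["C_limited"] / m["N_limited"]

    # -- transcript truths --------------------------------------------------

    _QPCR_SHAPES = {
        "recA": (1, 1, 1, 1, 1, 1, 1, 1, 1),
        "PR":   (0.10, 0.15, 0.25, 0.50, 1.00, 1.60, 2.00, 0.90, 0.50),
        "rpoS": (0.30, 0.50, 0.80, 1.20, 2.00, 1.60, 1.00, 0.60, 0.50),
        "blh":  (0.20, 0.20, 0.30, 0.40, 0.60, 0.80, 1.50, 0.80, 2.50),
    }

    def transcript_quantity_true(self, gene, condition, light, tp_index) -> float:
        shape = np.asarray(self._QPCR_SHAPES[gene], dtype=float)
        if shape.size != len(self.timepoints_h):
            # resample the canonical 9-point shape onto this grid
            shape = np.interp(np.linspace(0, 1, len(self.timepoints_h)),
                              np.linspace(0, 1, shape.size), shape)
        q = 1e-6 * shape[tp_index]
        if gene == "recA":
            return float(q)
        if condition == "C_limited":
            q = q * 2.0
            # PR transcription modestly higher in the dark under C limitation
            if gene == "PR" and light == "dark" and tp_index >= 3:
                q = q * 2.3
        return float(q)

    # -- misc ----------------------------------------------------------------

    def noiseless(self) -> "Scenario":
        return replace(self, noise=self.noise.zeroed())

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)

        def conv(x):
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            if isinstance(x, (tuple, list)):
                return [conv(v) for v in x]
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            return x
        return conv(d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        d = dict(d)
        d["growth"] = {k: GrowthParams(**v) for k, v in d.get("growth", {}).items()}
        d["noise"] = NoiseParams(**d.get("noise", {}))
        for key in ("conditions", "lights", "timepoints_h", "growth_times_h"):
            if key in d:
                d[key] = tuple(d[key])
        d["pr_copies_per_cell"] = {k: tuple(v) for k, v
                                   in d.get("pr_copies_per_cell", {}).items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# shape of the PR protein trajectory: rises through exponential growth and
# plateaus around the transition to stationary phase
_PR_SHAPE = np.array([0.12, 0.20, 0.32, 0.50, 0.68, 0.82, 0.96, 1.00, 0.98])

#: maximum PR expression level (copies/cell) under C limitation
PR_MAX_COPIES = 5606.0
#: true stationary-phase C/N fold change of PR protein abundance
PR_FOLD_CHANGE = 4.4


def default_scenario(seed: int = 519) -> Scenario:
    """The reference study scenario: growth truths mu_max 0.14/0.15 1/h and
    OD_max 0.72/0.83 (C/N), PR plateau maximum 5,606 copies/cell under C
    limitation, and a 4.4-fold C/N stationary-phase PR abundance ratio."""
    growth = {
        "C_limited": GrowthParams(
            mu_max=0.14, od_max=0.72,
            od_decline_onset_h=70.0, od_decline_rate=0.015,
            cfu_decline_onset_h=70.0, cfu_decline_rate=0.005,
            terminal_alive={"light": 0.82, "dark": 0.88}),
        "N_limited": GrowthParams(
            mu_max=0.15, od_max=0.83,
            cfu_decline_onset_h=27.5, cfu_decline_rate=0.08,
            cfu_zero_h=99.0,
            terminal_alive={"light": 0.05, "dark": 0.20}),
    }
    sc = Scenario(growth=growth, seed=seed,
                  pr_copies_per_cell={"C_limited": tuple(PR_MAX_COPIES * _PR_SHAPE),
                                      "N_limited": tuple(PR_MAX_COPIES * _PR_SHAPE)})
    # scale the N-limited copies/cell trajectory so the true stationary
    # (last two timepoints) amount ratio C/N is exactly the target value
    raw = sc.pr_stationary_fold_change_true()
    n_traj = tuple(PR_MAX_COPIES * _PR_SHAPE * raw / PR_FOLD_CHANGE)
    return replace(sc, pr_copies_per_cell={"C_limited": tuple(PR_MAX_COPIES * _PR_SHAPE),
                                           "N_limited": n_traj})


def tiny_scenario(seed: int = 7, **overrides) -> Scenario:
    """A miniature scenario (few proteins, short time course) for fast
    end-to-end runs and tests."""
    base = default_scenario(seed=seed)
    keep = (0, 4, 8)  # one timepoint per phase
    kwargs = dict(
        name="tiny",
        replicates=2,
        timepoints_h=tuple(base.timepoints_h[k] for k in keep),
        pr_copies_per_cell={c: tuple(base.pr_copies_per_cell[c][k] for k in keep)
                            for c in base.conditions},
        n_proteins=8, mean_length=120,
        n_light_responsive=1, n_cn_responsive=2,
        max_peptides_per_protein=2,
        noise_spectra_fraction=0.15,
    )
    kwargs.update(overrides)
    return replace(base, **kwargs)


# ---------------------------------------------------------------------------
# true expression profiles

def true_profiles(scenario: Scenario, proteome: ToyProteome) -> pd.DataFrame:
    """True log2 sample/standard abundance ratios, protein x sample group.

    Columns are a MultiIndex (condition, light, tp_index); replicates share
    the biological truth.  Most proteins sit at 0 (so each sample's true
    median is 0 and the median-zero normalization is truth-preserving);
    a few are light-responsive, a few respond to the limiting nutrient,
    and the PR-like protein is more abundant under C limitation with a
    trajectory that plateaus into stationary phase.
    """
    rng = np.random.default_rng(scenario.seed)
    n_tp = len(scenario.timepoints_h)
    ids = [pid for pid, _ in proteome.entries]
    others = [p for p in ids if p != proteome.pr_id]
    rng.shuffle(others)
    n_l = min(scenario.n_light_responsive, len(others) // 3)
    n_c = min(scenario.n_cn_responsive, len(others) // 3)
    light_up = set(others[:n_l])
    cn_resp = {p: (1 if i % 2 == 0 else -1)
               for i, p in enumerate(others[n_l:n_l + n_c])}

    cols = pd.MultiIndex.from_tuples(
        [(c, l, k) for c in scenario.conditions for l in scenario.lights
         for k in range(n_tp)],
        names=["condition", "light", "tp_index"])
    df = pd.DataFrame(0.0, index=pd.Index(ids, name="protein_id"), columns=cols)
    e = scenario.effect_size
    ramp = np.linspace(0.5, 1.0, n_tp)  # effects strengthen into stationary
    for c in scenario.conditions:
        for l in scenario.lights:
            for k in range(n_tp):
                col = (c, l, k)
                for p in light_up:
                    df.loc[p, col] = e * ramp[k] if l == "light" else 0.0
                for p, sign in cn_resp.items():
                    # positive sign: higher under N limitation convention:
                    # positive = higher under N limitation
                    df.loc[p, col] = (sign * e * ramp[k]
                                      if c == "N_limited" else 0.0)
                # PR protein: higher under C limitation, plateauing profile
                pr = 1.5 * _PR_SHAPE[min(k, len(_PR_SHAPE) - 1)]
                df.loc[proteome.pr_id, col] = pr if c == "C_limited" else pr - 1.0
    return df


# ---------------------------------------------------------------------------
# spectra simulation

def _select_peptides(proteome: ToyProteome, fraction: str,
                     max_per_protein: int, rng: np.random.Generator):
    """Quantifiable peptides per protein: unique in the proteome, 5-25
    residues, at most ``max_per_protein`` chosen per protein."""
    enzymes = FRACTION_ENZYMES[fraction]
    per_protein = {pid: [p for p in digest(seq, enzymes) if len(p) <= 25]
                   for pid, seq in proteome.entries}
    counts: dict[str, int] = {}
    for peps in per_protein.values():
        for p in set(peps):
            counts[p] = counts.get(p, 0) + 1
    out = {}
    for pid, peps in per_protein.items():
        uniq = sorted({p for p in peps if counts[p] == 1})
        if len(uniq) > max_per_protein:
            idx = rng.choice(len(uniq), size=max_per_protein, replace=False)
            uniq = [uniq[i] for i in sorted(idx)]
        out[pid] = uniq
    return out


def simulate_iptl_run(proteome: ToyProteome, scenario: Scenario,
                      sample_id: str, fraction: str, seed: int,
                      out_path=None, scheme: LabelScheme | None = None,
                      profiles: pd.DataFrame | None = None):
    """Simulate one labeled LC-MS run: an MGF file plus ground-truth rows.

    Each selected peptide yields >= ``spectra_per_peptide_min`` spectra
    containing b/y fragment peaks for both label channels; the sample
    channel's intensities are scaled by the protein's true ratio and every
    fragment intensity carries multiplicative lognormal noise.  A
    configurable fraction of pure-noise spectra (decoy fodder) is appended.
    """
    scheme = scheme or label_masses()
    st = scenario.sample_table()
    row = st[st.sample_id == sample_id]
    if row.empty:
        raise ValueError(f"sample {sample_id!r} not in scenario")
    row = row.iloc[0]
    if profiles is None:
        profiles = true_profiles(scenario, proteome)
    rng = np.random.default_rng([scenario.seed, seed,
                                 zlib.crc32(sample_id.encode()),
                                 0 if fraction == MEMBRANE else 1])
    peptides = _select_peptides(proteome, fraction,
                                scenario.max_peptides_per_protein, rng)
    if not any(peptides.values()):
        raise ValueError("no peptides: digest produced nothing quantifiable")

    ch_s = scheme.sample_channel(fraction)
    ch_t = scheme.standard_channel(fraction)
    sd = scenario.noise.spectrum_sd
    spectra, truth_rows = [], []
    n = 0
    for pid, peps in sorted(peptides.items()):
        tl = float(profiles.loc[pid, (row.condition, row.light, row.tp_index)])
        ratio = 2.0 ** tl
        for pep in peps:
            extra = scenario.spectra_per_peptide_mean - scenario.spectra_per_peptide_min
            n_spec = scenario.spectra_per_peptide_min + (
                rng.poisson(extra) if extra > 0 else 0)
            for _ in range(n_spec):
                n += 1
                sid = f"{sample_id}/{fraction}/{n:05d}"
                base = scenario.base_intensity * 2.0 ** rng.uniform(-1, 1)
                fr_s = theoretical_fragments(pep, scheme, ch_s)
                fr_t = theoretical_fragments(pep, scheme, ch_t)
                mzs, intens = [], []
                for (_, _, mz_s, _), (_, _, mz_t, _) in zip(fr_s, fr_t):
                    mzs.append(mz_s)
                    intens.append(base * ratio * 2.0 ** rng.normal(0.0, sd)
                                  if sd > 0 else base * ratio)
                    mzs.append(mz_t)
                    intens.append(base * 2.0 ** rng.normal(0.0, sd)
                                  if sd > 0 else base)
                order = np.argsort(mzs)
                spectra.append(dict(
                    title=f"id={sid}|sample={sample_id}|fraction={fraction}",
                    mz=np.asarray(mzs)[order],
                    intensity=np.asarray(intens)[order],
                    pepmass=precursor_mz(pep, scheme, ch_s, charge=2),
                ))
                truth_rows.append(dict(
                    spectrum_id=sid, sample_id=sample_id, fraction=fraction,
                    peptide=pep, protein_id=pid, true_log2_ratio=tl))
    n_noise = int(round(scenario.noise_spectra_fraction * len(spectra)))
    for j in range(n_noise):
        n += 1
        sid = f"{sample_id}/{fraction}/{n:05d}"
        k = rng.integers(20, 50)
        mzs = np.sort(rng.uniform(150.0, 1500.0, size=k))
        intens = scenario.base_intensity * np.exp(rng.normal(0, 1, size=k))
        spectra.append(dict(
            title=f"id={sid}|sample={sample_id}|fraction={fraction}",
            mz=mzs, intensity=intens,
            pepmass=float(rng.uniform(300.0, 900.0))))
        truth_rows.append(dict(
            spectrum_id=sid, sample_id=sample_id, fraction=fraction,
            peptide="", protein_id="", true_log2_ratio=np.nan))

    entries = [dict(
        params={"title": s["title"], "pepmass": s["pepmass"], "charge": "2+"},
        **{"m/z array": s["mz"], "intensity array": s["intensity"]})
        for s in spectra]
    if out_path is not None:
        with open(out_path, "w") as fh:
            pymgf.write(entries, fh)
    return entries, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# growth, PR areas, calibration, qPCR

def simulate_growth(scenario: Scenario, condition: str, light: str,
                    replicate: int, seed: int) -> pd.DataFrame:
    """OD/CFU/viability time series for one culture."""
    if condition not in scenario.growth:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng([scenario.seed, seed,
                                 list(scenario.conditions).index(condition),
                                 list(scenario.lights).index(light), replicate])
    t = np.asarray(scenario.growth_times_h, dtype=float)
    od = scenario.od_true(condition, t)
    cfu = scenario.cfu_true(condition, t)
    alive = scenario.alive_true(condition, light, t)
    nz = scenario.noise
    if nz.od_sd > 0:
        od = od * (1.0 + rng.normal(0.0, nz.od_sd, size=t.size))
    if nz.cfu_sd > 0:
        cfu = cfu * np.exp(rng.normal(0.0, nz.cfu_sd, size=t.size))
    cfu = np.where(scenario.cfu_true(condition, t) == 0.0, 0.0, cfu)
    alive = np.clip(alive + rng.normal(0.0, 0.02, size=t.size)
                    if nz.od_sd > 0 else alive, 0.0, 1.0)
    return pd.DataFrame(dict(
        condition=condition, light=light, replicate=replicate,
        time_h=t, od=np.clip(od, 1e-6, None), cfu_per_ml=cfu,
        alive_fraction=alive))


def simulate_growth_all(scenario: Scenario, seed: int) -> pd.DataFrame:
    frames = []
    for cond in scenario.conditions:
        for light in scenario.lights:
            for rep in range(1, scenario.replicates + 1):
                frames.append(simulate_growth(scenario, cond, light, rep, seed))
    return pd.concat(frames, ignore_index=True)


def simulate_pr_standard_areas(scenario: Scenario, seed: int) -> pd.DataFrame:
    """MS1 peak areas per (sample, peptide, species).

    The heavy standard is spiked at a fixed 0.375 pmol per mix (0.75 uL of
    0.5 pmol/uL stock); the native/standard area ratio equals the
    native/spiked amount ratio times lognormal noise.
    """
    if not scenario.pr_copies_per_cell:
        raise ValueError("scenario has no pr_copies_per_cell ground truth")
    rng = np.random.default_rng([scenario.seed, seed, 101])
    rows = []
    for _, s in scenario.sample_table().iterrows():
        amount = scenario.pr_amount_pmol_true(s.condition, s.tp_index)
        true_ratio = amount / scenario.spike_pmol
        for pep in PR_PEPTIDES:
            std_area = 1.0e7
            noise = (np.exp(rng.normal(0.0, scenario.noise.area_sd))
                     if scenario.noise.area_sd > 0 else 1.0)
            rows.append(dict(
                sample_id=s.sample_id, condition=s.condition, light=s.light,
                replicate=s.replicate, timepoint_h=s.timepoint_h,
                peptide=pep, native_area=std_area * true_ratio * noise,
                standard_area=std_area))
    return pd.DataFrame(rows)


def simulate_calibration(scenario: Scenario, seed: int,
                         n_points: int = 10) -> pd.DataFrame:
    """Paired (OD, cells/mL) calibration observations.

    Points are log-spaced across the full OD range the cultures traverse
    (0.01 to 0.9) so cell densities predicted for early-exponential samples
    interpolate rather than extrapolate."""
    rng = np.random.default_rng([scenario.seed, seed, 202])
    od = np.geomspace(0.01, 0.9, n_points)
    cells = scenario.calibration_intercept + scenario.calibration_slope * od
    if scenario.noise.calib_sd > 0:
        cells = cells * np.exp(rng.normal(0.0, scenario.noise.calib_sd,
                                          size=od.size))
    return pd.DataFrame(dict(od=od, cells_per_ml=cells))


def simulate_qpcr(scenario: Scenario, gene: str, seed: int) -> pd.DataFrame:
    """Ct table for one gene: Ct = -log_E(quantity) + Gaussian noise."""
    e = scenario.qpcr_efficiency
    if not (1.0 < e <= 2.0):
        raise ValueError("primer efficiency must be in (1, 2]")
    if gene not in scenario._QPCR_SHAPES:
        raise ValueError(f"unknown gene {gene!r}")
    rng = np.random.default_rng([scenario.seed, seed, 303,
                                 sorted(scenario._QPCR_SHAPES).index(gene)])
    rows = []
    for _, s in scenario.sample_table().iterrows():
        q = scenario.transcript_quantity_true(gene, s.condition, s.light,
                                              s.tp_index)
        ct = -np.log(q) / np.log(e)
        if scenario.noise.ct_sd > 0:
            ct = ct + rng.normal(0.0, scenario.noise.ct_sd)
        rows.append(dict(sample_id=s.sample_id, condition=s.condition,
                         light=s.light, replicate=s.replicate,
                         timepoint_h=s.timepoint_h, gene=gene,
                         ct=float(ct), efficiency=e))
    return pd.DataFrame(rows)


def simulate_qpcr_all(scenario: Scenario, seed: int,
                      genes=("PR", "blh", "rpoS", "recA")) -> pd.DataFrame:
    return pd.concat([simulate_qpcr(scenario, g, seed) for g in genes],
                     ignore_index=True)


# ---------------------------------------------------------------------------
# whole-study writer

def write_study(scenario: Scenario, outdir, seed: int,
                include_spectra: bool = True) -> dict:
    """Write every input file of one simulated study to ``outdir``.

    Produces FASTA proteome, per-(sample, fraction) MGF spectra, metadata
    CSV, growth CSV, PR standard-peptide area CSV, OD-to-cells calibration
    CSV, qPCR Ct CSV, the scenario YAML and a ground-truth JSON sidecar.
    Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteome = make_toy_proteome(scenario.n_proteins, scenario.mean_length,
                                 seed=scenario.seed)
    paths = {"fasta": outdir / "proteome.fasta",
             "metadata": outdir / "metadata.csv",
             "growth": outdir / "growth.csv",
             "areas": outdir / "pr_areas.csv",
             "calibration": outdir / "calibration.csv",
             "qpcr": outdir / "qpcr.csv",
             "scenario": outdir / "scenario.yaml",
             "truth": outdir / "ground_truth.json",
             "spectra_dir": outdir / "spectra"}
    proteome.to_fasta(paths["fasta"])
    scenario.metadata_table().to_csv(paths["metadata"], index=False)
    simulate_growth_all(scenario, seed).to_csv(paths["growth"], index=False)
    simulate_pr_standard_areas(scenario, seed).to_csv(paths["areas"], index=False)
    simulate_calibration(scenario, seed).to_csv(paths["calibration"], index=False)
    simulate_qpcr_all(scenario, seed).to_csv(paths["qpcr"], index=False)
    scenario.to_yaml(paths["scenario"])

    profiles = true_profiles(scenario, proteome)
    truth_frames = []
    if include_spectra:
        paths["spectra_dir"].mkdir(exist_ok=True)
        for _, m in scenario.metadata_table().iterrows():
            fname = (m.sample_id.replace(":", "_") + f"_{m.fraction}.mgf")
            _, truth = simulate_iptl_run(
                proteome, scenario, m.sample_id, m.fraction, seed,
                out_path=paths["spectra_dir"] / fname, profiles=profiles)
            truth_frames.append(truth)
        pd.concat(truth_frames, ignore_index=True).to_csv(
            outdir / "spectrum_truth.csv", index=False)
        paths["spectrum_truth"] = outdir / "spectrum_truth.csv"

    cells = {c: {f"{tp:g}": scenario.cells_analyzed_true(c, tp)
                 for tp in scenario.timepoints_h}
             for c in scenario.conditions}
    truth = dict(scenario=scenario.to_dict(),
                 seed=seed,
                 true_log2_profiles={
                     pid: {f"{c}:{l}:{k}": float(v)
                           for (c, l, k), v in profiles.loc[pid].items()}
                     for pid in profiles.index},
                 cells_analyzed_true=cells,
                 pr_stationary_fold_change=scenario.pr_stationary_fold_change_true())
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths
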