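"""Normalized, replicate-consolidated, fraction-resolved expression tables.

Implements the bookkeeping rules of the quantification workflow: per-sample
median-zero normalization of log2 ratios (abundance on a per-amount-total-
protein basis), consolidation of biological triplicates with combined error
sqrt(sigma_x^2 + mu_SE^2), assignment of dual-fraction proteins to the
fraction with more quantified spectra, and growth-phase designation of
timepoints (3 exponential / 4 transition / 2 stationary for the default
nine-point course).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .iptl_quant import CYTOSOLIC, MEMBRANE

PHASES = ("exponential", "transition", "stationary")

#: canonical phase partition sizes for the nine-timepoint design
DEFAULT_PHASE_SIZES = (3, 4, 2)


def normalize_sample(values):
    """Center one sample's log2 ratios on zero median.

    Even-count medians use the midpoint convention, so the output median is
    exactly zero and normalization is idempotent.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot normalize an empty sample")
    return arr - np.median(arr)


def normalize_table(df: pd.DataFrame, sample_cols=("sample_id", "fraction"),
                    value_col: str = "log2_ratio") -> pd.DataFrame:
    """Median-zero normalize per LC-MS sample (every ``sample_cols`` group)."""
    out = df.copy()
    out[value_col] = out.groupby(list(sample_cols))[value_col].transform(
        lambda v: v - v.median())
    return out


def consolidate_replicates(log2_values, ses):
    """Consolidate per-replicate (log2, SE) into (mean, combined error, n).

    The combined error is sqrt(sigma_x^2 + mu_SE^2) where sigma_x is the
    between-replicate sample standard deviation (n-1 denominator) and mu_SE
    the mean of the per-replicate standard errors.  A single replicate is
    passed through with its own SE and flagged low-confidence (n = 1).
    """
    x = np.asarray(log2_values, dtype=float)
    s = np.asarray(ses, dtype=float)
    ok = np.isfinite(x) & np.isfinite(s)
    x, s = x[ok], s[ok]
    if x.size == 0:
        raise ValueError("no finite replicate values")
    if x.size == 1:
        return float(x[0]), float(s[0]), 1
    sigma_x = float(np.std(x, ddof=1))
    mu_se = float(np.mean(s))
    return float(np.mean(x)), float(np.hypot(sigma_x, mu_se)), int(x.size)


def assign_fraction(spectra_by_fraction: dict) -> str:
    """Resolve a protein quantified in both fractions to one fraction.

    Uses the fraction with the greater total number of quantified spectra;
    ties go to cytosolic.  Single-fraction proteins keep their fraction.
    """
    present = {f: n for f, n in spectra_by_fraction.items() if n and n > 0}
    if not present:
        raise ValueError("protein quantified in no fraction")
    if len(present) == 1:
        return next(iter(present))
    if present.get(MEMBRANE, 0) > present.get(CYTOSOLIC, 0):
        return MEMBRANE
    return CYTOSOLIC


def assign_phase(timepoints, sizes=None) -> dict:
    """Map ordered timepoints to growth phases.

    Nine timepoints get the canonical 3/4/2 exponential/transition/
    stationary split; other counts are split proportionally (largest-
    remainder apportionment of 3:4:2, each phase >= 1 point).
    """
    tps = list(timepoints)
    if len(tps) < 3:
        raise ValueError("need at least 3 timepoints to designate phases")
    if sorted(tps) != tps:
        raise ValueError("timepoints must be sorted")
    n = len(tps)
    if sizes is None:
        if n == 9:
            sizes = DEFAULT_PHASE_SIZES
        else:
            quota = np.array(DEFAULT_PHASE_SIZES, dtype=float) * n / 9.0
            sizes = np.maximum(np.floor(quota).astype(int), 1)
            rem = quota - np.floor(quota)
            while sizes.sum() < n:
                k = int(np.argmax(rem))
                sizes[k] += 1
                rem[k] = -1
            while sizes.sum() > n:
                k = int(np.argmax(sizes))
                sizes[k] -= 1
            sizes = tuple(int(s) for s in sizes)
    if sum(sizes) != n:
        raise ValueError("phase sizes must partition the timepoints")
    out, i = {}, 0
    for phase, k in zip(PHASES, sizes):
        for tp in tps[i:i + k]:
            out[tp] = phase
        i += k
    return out


def fraction_summary(assignments: pd.DataFrame) -> dict:
    """Counts of membrane-only / cytosolic-only / dual-fraction proteins.

    ``assignments`` needs columns protein_id, fraction, n_spectra (one row
    per protein x fraction in which it was quantified).  The partition
    identity membrane_only + cytosolic_only + both = total always holds,
    and assigned counts partition the dual-fraction set.
    """
    if assignments.empty:
        return dict(membrane_only=0, cytosolic_only=0, both=0, total=0,
                    assigned_membrane=0, assigned_cytosolic=0)
    pv = (assignments.groupby(["protein_id", "fraction"])["n_spectra"]
          .sum().unstack(fill_value=0))
    for f in (MEMBRANE, CYTOSOLIC):
        if f not in pv.columns:
            pv[f] = 0
    in_m, in_c = pv[MEMBRANE] > 0, pv[CYTOSOLIC] > 0
    both = pv[in_m & in_c]
    assigned = both.apply(
        lambda r: assign_fraction({MEMBRANE: r[MEMBRANE],
                                   CYTOSOLIC: r[CYTOSOLIC]}), axis=1)
    return dict(
        membrane_only=int((in_m & ~in_c).sum()),
        cytosolic_only=int((in_c & ~in_m).sum()),
        both=int((in_m & in_c).sum()),
        total=int(len(pv)),
        assigned_membrane=int((in_m & ~in_c).sum())
        + int((assigned == MEMBRANE).sum()),
        assigned_cytosolic=int((in_c & ~in_m).sum())
        + int((assigned == CYTOSOLIC).sum()),
    )


def build_expression_table(quant: pd.DataFrame,
                           metadata: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-replicate expression table from protein x sample results.

    ``quant`` carries one row per (protein_id, sample_id, fraction) with
    log2_ratio, se and n_spectra (output of the spectrum-level pipeline);
    ``metadata`` maps sample_id to condition/light/replicate/timepoint.
    Steps: per-sample median-zero normalization, dual-fraction resolution,
    phase annotation.  Replicates are kept separate here; consolidation is
    a separate step so differential testing can use replicate-level values.
    """
    df = normalize_table(quant)
    # resolve each protein to a single fraction by total spectrum count
    totals = (df.groupby(["protein_id", "fraction"])["n_spectra"].sum()
              .unstack(fill_value=0))
    keep = {}
    for pid, row in totals.iterrows():
        keep[pid] = assign_fraction({f: row.get(f, 0) for f in row.index})
    df = df[df.apply(lambda r: keep[r.protein_id] == r.fraction, axis=1)]
    df = df.rename(columns={"fraction": "fraction_assigned"})
    meta_cols = ["sample_id", "condition", "light", "replicate", "timepoint_h"]
    df = df.merge(metadata[meta_cols].drop_duplicates(), on="sample_id")
    phases = assign_phase(sorted(df.timepoint_h.unique()))
    df["phase"] = df.timepoint_h.map(phases)
    return df.reset_index(drop=True)


def consolidate_table(expr: pd.DataFrame) -> pd.DataFrame:
    """Consolidate the tidy table across replicates per protein x
    (condition, light, timepoint)."""
    rows = []
    keys = ["protein_id", "fraction_assigned", "condition", "light",
            "timepoint_h", "phase"]
    for key, g in expr.groupby(keys):
        mean, err, n = consolidate_replicates(g.log2_ratio.values, g.se.values)
        rows.append(dict(zip(keys, key), log2=mean, error=err,
                         n_replicates=n,
                         n_spectra=int(g.n_spectra.sum()),
                         low_confidence=n < 2))
    return pd.DataFrame(rows)
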