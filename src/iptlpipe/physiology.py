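"""Growth-curve, survival and transcript analytics.

Covers the culture-level measurements of the study: maximum specific
growth rate (sliding-window regression of ln OD against time), growth
yield, CFU from spot plating, efficiency-corrected qPCR relative
expression against a reference gene, detection of significant transcript
peaks, stationary-phase survival summaries, and the defined-medium C/N
ratio arithmetic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

#: carbon atoms per maltose molecule (C12H22O11)
MALTOSE_CARBONS = 12


def media_cn_ratio(c_source_mm: float, n_source_mm: float,
                   carbons_per_molecule: int = MALTOSE_CARBONS,
                   nitrogens_per_molecule: int = 1) -> float:
    """Molar C/N ratio of a defined medium.

    Default stoichiometry is maltose (12 C per molecule) as sole carbon
    source and NH4Cl (1 N) as sole nitrogen source: e.g. 2.78 mM maltose
    with 2 mM NH4Cl gives 16.68:1.
    """
    if c_source_mm < 0 or n_source_mm <= 0:
        raise ValueError("concentrations must be positive")
    return (c_source_mm * carbons_per_molecule) / (n_source_mm
                                                   * nitrogens_per_molecule)


def growth_rate(times, od, window: int = 3) -> float:
    """Maximum specific growth rate mu_max (1/h).

    The maximum over sliding windows of the least-squares slope of ln(OD)
    against time.  Windows containing nonpositive OD are skipped; an error
    is raised when no window is valid.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(od, dtype=float)
    if window < 2:
        raise ValueError("window must be >= 2")
    best = None
    for i in range(0, t.size - window + 1):
        seg = y[i:i + window]
        if np.any(seg <= 0):
            continue
        slope = stats.linregress(t[i:i + window], np.log(seg)).slope
        if best is None or slope > best:
            best = float(slope)
    if best is None:
        raise ValueError("no window with all-positive OD values")
    return best


def od_max(od) -> float:
    """Growth yield: the maximum OD over the series."""
    arr = np.asarray(od, dtype=float)
    if arr.size == 0:
        raise ValueError("empty OD series")
    return float(arr.max())


def cfu_from_spots(colonies: int, dilution_factor: float,
                   spot_volume_ml: float) -> float:
    """CFU/mL from serial-dilution spot plating."""
    if colonies < 0 or dilution_factor < 0:
        raise ValueError("counts and dilution factor must be >= 0")
    if spot_volume_ml <= 0:
        raise ValueError("spot volume must be > 0")
    return colonies * dilution_factor / spot_volume_ml


def qpcr_relative(target_ct: float, target_eff: float,
                  reference_ct: float, reference_eff: float) -> float:
    """Efficiency-corrected relative expression E_t^(-Ct_t) / E_r^(-Ct_r).

    Calibrator-free single-sample form; the reference gene (recA in this
    study) normalizes for input amount.
    """
    for e in (target_eff, reference_eff):
        if not (0 < e <= 2.0):
            raise ValueError("primer efficiency must be in (0, 2]")
    return float(target_eff ** (-target_ct) / reference_eff ** (-reference_ct))


def qpcr_relative_table(ct_table: pd.DataFrame, target_gene: str,
                        reference_gene: str = "recA") -> pd.DataFrame:
    """Per-sample relative expression of one gene against the reference."""
    t = ct_table[ct_table.gene == target_gene].set_index("sample_id")
    r = ct_table[ct_table.gene == reference_gene].set_index("sample_id")
    common = t.index.intersection(r.index)
    if common.empty:
        raise ValueError("no shared samples between target and reference")
    rows = []
    for sid in common:
        rows.append(dict(
            sample_id=sid, gene=target_gene,
            condition=t.at[sid, "condition"], light=t.at[sid, "light"],
            replicate=t.at[sid, "replicate"],
            timepoint_h=t.at[sid, "timepoint_h"],
            relative_expression=qpcr_relative(
                t.at[sid, "ct"], t.at[sid, "efficiency"],
                r.at[sid, "ct"], r.at[sid, "efficiency"])))
    return pd.DataFrame(rows)


def detect_peaks(series: pd.DataFrame, reference_time: float = 9.0,
                 alpha: float = 0.05, value_col: str = "relative_expression",
                 time_col: str = "timepoint_h") -> list[float]:
    """Significant local maxima of a replicated time series.

    A timepoint is a peak when its replicate mean exceeds both neighbors'
    means (boundary points use their single neighbor) and a two-sided
    Welch t-test against the reference-time replicates (mid-exponential,
    t = 9 h by default) gives p < alpha.
    """
    g = series.groupby(time_col)[value_col]
    means = g.mean()
    times = means.index.to_numpy()
    if times.size < 3:
        raise ValueError("need >= 3 timepoints")
    if reference_time not in means.index:
        raise ValueError(f"reference time {reference_time} not in series")
    ref_vals = series.loc[series[time_col] == reference_time, value_col].values
    if ref_vals.size < 2 or series.groupby(time_col).size().min() < 2:
        raise ValueError("need >= 2 replicates per timepoint")
    peaks = []
    for i, tp in enumerate(times):
        m = means.iloc[i]
        left_ok = i == 0 or m > means.iloc[i - 1]
        right_ok = i == times.size - 1 or m > means.iloc[i + 1]
        if not (left_ok and right_ok):
            continue
        vals = series.loc[series[time_col] == tp, value_col].values
        if tp == reference_time:
            continue
        res = stats.ttest_ind(vals, ref_vals, equal_var=False)
        if res.pvalue < alpha and m > np.mean(ref_vals):
            peaks.append(float(tp))
    return peaks


def survival_summary(curve: pd.DataFrame) -> dict:
    """Stationary-phase survival report for one culture.

    Returns the onset of OD decline (first time after the maximum with
    OD < 0.9 x OD_max, or None), the first time CFU reaches zero (or
    None), and the terminal alive fraction (None if not recorded).
    """
    df = curve.sort_values("time_h")
    t = df.time_h.to_numpy()
    od = df.od.to_numpy()
    peak = float(od.max())
    i_peak = int(np.argmax(od))
    decline = None
    for i in range(i_peak + 1, t.size):
        if od[i] < 0.9 * peak:
            decline = float(t[i])
            break
    cfu_zero = None
    if "cfu_per_ml" in df:
        z = df.loc[df.cfu_per_ml == 0, "time_h"]
        if not z.empty:
            cfu_zero = float(z.iloc[0])
    alive = (float(df.alive_fraction.iloc[-1])
             if "alive_fraction" in df else None)
    return dict(od_max=peak, od_decline_onset_h=decline,
                cfu_zero_time_h=cfu_zero, terminal_alive_fraction=alive)


def growth_summary(growth: pd.DataFrame, window: int = 3) -> pd.DataFrame:
    """mu_max, OD_max and survival summary per culture."""
    rows = []
    for (cond, light, rep), g in growth.groupby(
            ["condition", "light", "replicate"]):
        s = survival_summary(g)
        rows.append(dict(condition=cond, light=light, replicate=rep,
                         mu_max=growth_rate(g.time_h, g.od, window=window),
                         **s))
    return pd.DataFrame(rows)
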