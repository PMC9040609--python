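"""Absolute proteorhodopsin quantification from heavy-standard peptides.

Two synthetic PR peptides (LWETQGVAK and NLADVVNK) carrying 13C6,15N2-
lysine are spiked at a known amount (0.75 uL of a 0.5 pmol/uL stock =
0.375 pmol per analyzed mix); the native amount follows from the MS1
native/standard peak-area ratio averaged over the two peptides.  Cell
numbers come from an OD-to-cell-density calibration (linear fit of
cells/mL against OD660) scaled by the harvested culture volume, giving
copies per cell via Avogadro's number, and condition fold changes from
stationary-phase means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class StandardSpike:
    """Heavy standard-peptide spike definition."""

    peptides: tuple = ("LWETQGVAK", "NLADVVNK")
    stock_pmol_per_ul: float = 0.5
    spike_volume_ul: float = 0.75
    sample_volume_ul: float = 7.25

    def __post_init__(self):
        if min(self.stock_pmol_per_ul, self.spike_volume_ul,
               self.sample_volume_ul) <= 0:
            raise ValueError("spike volumes and concentration must be > 0")

    @property
    def spiked_pmol(self) -> float:
        return self.stock_pmol_per_ul * self.spike_volume_ul


@dataclass
class CellCalibration:
    """Linear OD660 -> cells/mL calibration (ordinary least squares)."""

    slope: float
    intercept: float
    residual_sd: float = 0.0
    n_points: int = 0

    @classmethod
    def fit(cls, od, cells_per_ml) -> "CellCalibration":
        od = np.asarray(od, dtype=float)
        cells = np.asarray(cells_per_ml, dtype=float)
        if od.size < 3:
            raise ValueError("calibration needs >= 3 (OD, cells/mL) points")
        res = stats.linregress(od, cells)
        if res.slope <= 0:
            raise ValueError("calibration slope must be positive")
        resid = cells - (res.intercept + res.slope * od)
        sd = float(np.std(resid, ddof=2)) if od.size > 2 else 0.0
        return cls(slope=float(res.slope), intercept=float(res.intercept),
                   residual_sd=sd, n_points=int(od.size))

    def cells_per_ml(self, od) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(od, dtype=float)


def integrate_peak(times, intensities) -> float:
    """Trapezoidal peak area over the provided chromatographic window."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.size < 2:
        raise ValueError("need >= 2 points to integrate")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(y, t))


def amount_from_ratio(native_area, standard_area,
                      spike: StandardSpike | None = None) -> float:
    """Native amount (pmol) in the analyzed mix from one peak-area ratio."""
    spike = spike or StandardSpike()
    if standard_area <= 0:
        raise ValueError("standard not detected (standard_area <= 0)")
    if native_area < 0:
        raise ValueError("native_area must be >= 0")
    return float(native_area / standard_area) * spike.spiked_pmol


def cells_from_od(od: float, calibration: CellCalibration,
                  volume_ml: float = 4.5) -> float:
    """Cells in the harvested sample (default 4.5 mL culture volume)."""
    if od < 0:
        raise ValueError("od must be >= 0")
    return float(calibration.cells_per_ml(od) * volume_ml)


def copies_per_cell(native_amount_mol: float, n_cells: float) -> float:
    """Protein copies per cell from a molar amount and a cell count."""
    if n_cells <= 0:
        raise ValueError("n_cells must be > 0")
    return native_amount_mol * AVOGADRO / n_cells


def quantify_samples(areas: pd.DataFrame, growth: pd.DataFrame,
                     calibration: CellCalibration,
                     spike: StandardSpike | None = None,
                     volume_ml: float = 4.5) -> pd.DataFrame:
    """Per-sample PR amount (pmol) and copies/cell.

    ``areas`` has one row per (sample, peptide) with native_area and
    standard_area plus condition/light/replicate/timepoint_h columns; the
    per-sample ratio is the mean over the two peptides.  ``growth``
    provides the OD at each sample's timepoint for the matching culture.
    """
    spike = spike or StandardSpike()
    od_lut = growth.set_index(["condition", "light", "replicate",
                               "time_h"]).od
    rows = []
    for sid, g in areas.groupby("sample_id", sort=True):
        ratios = g.native_area.values / g.standard_area.values
        mean_ratio = float(np.mean(ratios))
        pmol = mean_ratio * spike.spiked_pmol
        s = g.iloc[0]
        od = float(od_lut.loc[(s.condition, s.light, s.replicate,
                               s.timepoint_h)])
        n_cells = cells_from_od(od, calibration, volume_ml)
        if n_cells <= 0:
            raise ValueError(
                f"calibration predicts {n_cells:g} cells at OD {od:g} for "
                f"{sid}; calibration range does not cover this sample")
        rows.append(dict(sample_id=sid, condition=s.condition, light=s.light,
                         replicate=int(s.replicate),
                         timepoint_h=float(s.timepoint_h),
                         mean_ratio=mean_ratio, pr_pmol=pmol, od=od,
                         n_cells=n_cells,
                         copies_per_cell=copies_per_cell(pmol * 1e-12,
                                                         n_cells)))
    return pd.DataFrame(rows)


def condition_fold_change(amounts: pd.DataFrame, phase_map: dict,
                          numerator: str = "C_limited",
                          denominator: str = "N_limited"):
    """Stationary-phase plateau ratio of PR abundance between conditions.

    Means are taken over stationary-phase samples per condition (pooling
    light conditions and replicates); the error is propagated from the
    per-condition standard deviations of per-sample amounts.
    """
    df = amounts.copy()
    df["phase"] = df.timepoint_h.map(phase_map)
    stat = df[df.phase == "stationary"]
    groups = {}
    for cond in (numerator, denominator):
        vals = stat.loc[stat.condition == cond, "pr_pmol"].values
        if vals.size < 2:
            raise ValueError(f"{cond} has <2 stationary observations")
        groups[cond] = vals
    m_n, m_d = np.mean(groups[numerator]), np.mean(groups[denominator])
    if m_d == 0:
        raise ValueError("denominator stationary mean is zero")
    ratio = float(m_n / m_d)
    rel = np.sqrt(
        np.var(groups[numerator], ddof=1) / len(groups[numerator]) / m_n**2
        + np.var(groups[denominator], ddof=1) / len(groups[denominator]) / m_d**2)
    return ratio, float(ratio * rel)


def trajectory(amounts: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Per-timepoint mean amount and copies/cell for one condition."""
    sub = amounts[amounts.condition == condition]
    return (sub.groupby("timepoint_h")[["pr_pmol", "copies_per_cell"]]
            .mean().reset_index())


def max_copies_per_cell(amounts: pd.DataFrame,
                        condition: str = "C_limited") -> float:
    """Maximum of the per-timepoint mean copies/cell trajectory."""
    return float(trajectory(amounts, condition).copies_per_cell.max())
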