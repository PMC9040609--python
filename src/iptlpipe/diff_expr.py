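"""Moderated differential expression between growth conditions.

Pairwise contrasts (light vs dark, C- vs N-limited) are fitted per growth
phase and across all phases, pooling replicate x timepoint observations
within a phase as exchangeable.  Per-protein residual variances are shrunk
toward a global prior by empirical Bayes: the prior (s0^2, d0) is estimated
by the method of moments on the log-variance distribution (the scaled-F
model of limma's fitFDist), and the moderated t-statistic uses d0 + d_g
degrees of freedom.  Significance calls use Benjamini-Hochberg FDR < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

ALL_PHASES = "all"


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison on the tidy per-replicate expression table.

    ``factor`` is the column split into groups A and B; ``phase`` restricts
    to one growth phase (None pools all phases); ``where`` adds fixed
    filters (e.g. restrict a light/dark contrast to one medium).
    """

    name: str
    factor: str
    level_a: str
    level_b: str
    phase: str | None = None
    where: dict = field(default_factory=dict)

    def select(self, expr: pd.DataFrame) -> pd.DataFrame:
        df = expr
        for col, val in self.where.items():
            df = df[df[col] == val]
        if self.phase is not None:
            df = df[df.phase == self.phase]
        return df


def light_vs_dark(condition: str, phase: str | None = None) -> Contrast:
    suffix = phase or ALL_PHASES
    return Contrast(name=f"light_vs_dark_{condition}_{suffix}",
                    factor="light", level_a="light", level_b="dark",
                    phase=phase, where={"condition": condition})


def c_vs_n(phase: str | None = None) -> Contrast:
    """N-over-C comparison (positive effect = higher under N limitation)."""
    suffix = phase or ALL_PHASES
    return Contrast(name=f"N_vs_C_{suffix}", factor="condition",
                    level_a="N_limited", level_b="C_limited", phase=phase)


def fit_contrast(expr: pd.DataFrame, contrast: Contrast,
                 value_col: str = "log2_ratio") -> pd.DataFrame:
    """Per-protein effect and pooled residual variance for one contrast.

    effect = mean(A) - mean(B) in log2 units; s2 is the pooled two-group
    variance with d_g = n_A + n_B - 2 residual df.  Proteins with fewer
    than two observations in either group are skipped.
    """
    df = contrast.select(expr)
    rows = []
    for pid, g in df.groupby("protein_id"):
        a = g.loc[g[contrast.factor] == contrast.level_a, value_col].values
        b = g.loc[g[contrast.factor] == contrast.level_b, value_col].values
        if a.size < 2 or b.size < 2:
            continue
        ss = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2))
        dg = a.size + b.size - 2
        rows.append(dict(protein_id=pid,
                         effect=float(a.mean() - b.mean()),
                         s2=float(ss / dg), df=int(dg),
                         n_a=int(a.size), n_b=int(b.size)))
    return pd.DataFrame(rows,
                        columns=["protein_id", "effect", "s2", "df",
                                 "n_a", "n_b"])


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_prior(s2, dg):
    """Method-of-moments fit of the scaled-F variance prior (s0^2, d0).

    Models s2_g ~ s0^2 * F(d_g, d0) via the moments of log variances:
    e_g = log(s2_g) - digamma(d_g/2) + log(d_g/2) has variance
    trigamma(d_g/2) + trigamma(d0/2), giving d0 by trigamma inversion and
    s0^2 from the mean.  Returns d0 = inf when the observed spread is no
    larger than expected from the residual df alone.
    """
    s2 = np.asarray(s2, dtype=float)
    dg = np.asarray(dg, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0) & (dg > 0)
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive variances to fit the prior")
    z = np.log(s2[ok])
    half = dg[ok] / 2.0
    e = z - special.digamma(half) + np.log(half)
    if np.var(e, ddof=1) < 1e-15:
        # degenerate sample with no dispersion at all: the common variance
        # is its own prior and moderation leaves it untouched
        return float(np.exp(np.mean(z))), np.inf
    evar = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, half)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0)
                            - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0sq = float(np.exp(np.mean(e)))
    return s0sq, d0


def ebayes_moderate(fits: pd.DataFrame, d0: float | None = None,
                    s0sq: float | None = None) -> pd.DataFrame:
    """Moderated t and two-sided p per protein.

    s2_tilde = (d0 s0^2 + d_g s2_g)/(d0 + d_g);
    t = effect / (s_tilde * sqrt(1/n_A + 1/n_B)) on d0 + d_g df.
    The prior is estimated from the data unless supplied.  If every
    variance is zero the ordinary t-statistic is used with a warning.
    """
    out = fits.copy()
    if d0 is None or s0sq is None:
        try:
            s0sq, d0 = estimate_prior(out.s2.values, out.df.values)
        except ValueError:
            warnings.warn("all residual variances are zero or missing; "
                          "falling back to the ordinary t-statistic")
            s0sq, d0 = 0.0, 0.0
    dg = out.df.values.astype(float)
    if np.isinf(d0):
        s2_post = np.full(len(out), s0sq)
        df_total = np.full(len(out), np.inf)
    elif d0 == 0:
        s2_post = out.s2.values
        df_total = dg
    else:
        s2_post = (d0 * s0sq + dg * out.s2.values) / (d0 + dg)
        df_total = d0 + dg
    scale = np.sqrt(s2_post * (1.0 / out.n_a.values + 1.0 / out.n_b.values))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = out.effect.values / scale
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out["s2_post"] = s2_post
    out["t"] = t
    out["p"] = p
    out.attrs["d0"] = float(d0)
    out.attrs["s0sq"] = float(s0sq)
    return out


def bh_fdr(pvalues, alpha: float = 0.05):
    """Benjamini-Hochberg adjusted p-values (monotonized step-up)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=alpha, method="fdr_bh")[1]


def test_contrast(expr: pd.DataFrame, contrast: Contrast,
                  alpha: float = 0.05, **prior) -> pd.DataFrame:
    """fit_contrast + ebayes_moderate + BH adjustment in one step."""
    fits = fit_contrast(expr, contrast)
    if fits.empty:
        for col in ("s2_post", "t", "p", "p_adj"):
            fits[col] = []
        fits["significant"] = []
        return fits
    out = ebayes_moderate(fits, **prior)
    out["p_adj"] = bh_fdr(out.p.values, alpha=alpha)
    out["significant"] = out.p_adj < alpha
    return out


def phase_report(results_by_phase: dict) -> pd.DataFrame:
    """Per-phase fold-change table for proteins significant anywhere.

    ``results_by_phase`` maps phase name (including "all") to a tested
    contrast result.  One row per protein significant in at least one
    phase; each phase column holds the log2 fold change where the protein
    is significant in that phase and NaN elsewhere.
    """
    phases = list(results_by_phase)
    sig_proteins: list[str] = []
    for res in results_by_phase.values():
        if len(res):
            sig_proteins.extend(res.loc[res.significant, "protein_id"])
    index = sorted(dict.fromkeys(sig_proteins))
    table = pd.DataFrame(np.nan, index=pd.Index(index, name="protein_id"),
                         columns=phases)
    for phase, res in results_by_phase.items():
        if not len(res):
            continue
        sig = res[res.significant].set_index("protein_id")
        for pid in sig.index:
            table.loc[pid, phase] = sig.at[pid, "effect"]
    return table.reset_index()
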