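"""Moderated differential expression of protein log2 SILAC ratios.

One-sample design: within each replicate run, the log2 ratio of the
treatment channel over the control channel is the observation, and the
null hypothesis is mean zero.  Per-protein residual variances s2 (df =
n - 1) are shrunk toward a precursor-count-conditional prior in the
empirical-Bayes fashion of the moderated t-test:

    s2_post = (d0 * s2_prior(count) + df * s2) / (d0 + df)
    t_mod   = log2_fc / sqrt(s2_post / n),   p ~ t(df + d0)

The prior trend s2_prior(count) is a lowess fit of log s2 on
log(precursor count): proteins quantified from many precursors have
systematically smaller ratio variance, and borrowing strength along this
trend is what the spectral-count-aware variant of the moderated test
adds over a single pooled prior.  The prior degrees of freedom d0 are
estimated by method of moments on the log variance ratios
log(s2 / s2_prior), whose theoretical spread under the model is
trigamma(df/2) + trigamma(d0/2) (scaled-F sampling distribution);
the trigamma term is inverted numerically.  The lowess trend estimates
E[log s2 | count] = log s2_prior + E[log F(df, d0)], so the known log-F
mean is subtracted to de-bias the prior — except in the exactly
degenerate zero-scatter case, where the observed common variance is the
prior and d0 = +inf.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "fit_protein_stats",
    "VariancePrior",
    "estimate_variance_prior",
    "moderate_and_test",
    "adjust_bh",
    "call_significance",
    "trigamma_inverse",
]

#: variance floor before logging, guards s2 == 0 proteins
S2_FLOOR = 1e-12
#: stand-in degrees of freedom when d0 = +inf (t indistinguishable from normal)
D0_CAP = 1e6


def fit_protein_stats(ratios: pd.DataFrame, n_precursors: pd.Series | None = None) -> pd.DataFrame:
    """Per-protein mean, variance and df from replicate log2 ratios.

    ``ratios`` is protein x replicate (one time point / condition).
    Proteins with fewer than 2 present values are excluded — they carry
    no variance information and are reported without test statistics
    downstream.
    """
    n = ratios.notna().sum(axis=1)
    keep = n >= 2
    sub = ratios.loc[keep]
    out = pd.DataFrame(
        {
            "log2_fc": sub.mean(axis=1, skipna=True),
            "s2": sub.var(axis=1, ddof=1, skipna=True),
            "df": (n[keep] - 1).astype(float),
            "n": n[keep].astype(int),
        }
    )
    if n_precursors is not None:
        out["n_precursors"] = n_precursors.reindex(out.index).fillna(1).astype(int)
    return out


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


@dataclass(frozen=True)
class VariancePrior:
    """Count-conditional prior variance trend plus prior df d0.

    ``log_counts`` / ``log_s2_prior`` tabulate the de-biased trend on the
    observed log precursor counts; prediction interpolates (constant
    extrapolation outside the observed range).
    """

    log_counts: np.ndarray
    log_s2_prior: np.ndarray
    d0: float

    def s2_prior(self, counts) -> np.ndarray:
        lc = np.log(np.maximum(np.asarray(counts, dtype=float), 1.0))
        return np.exp(np.interp(lc, self.log_counts, self.log_s2_prior))

    @classmethod
    def constant(cls, s2: float, d0: float) -> "VariancePrior":
        v = np.log(max(s2, S2_FLOOR))
        return cls(np.array([0.0, 1.0]), np.array([v, v]), float(d0))


def _log_f_mean(df: float, d0: float) -> float:
    # E[log F(df, d0)]; the d0-dependent part vanishes as d0 -> inf
    m = special.digamma(df / 2.0) - np.log(df / 2.0)
    if np.isfinite(d0):
        m += np.log(d0 / 2.0) - special.digamma(d0 / 2.0)
    return float(m)


def estimate_variance_prior(stats_df: pd.DataFrame, span: float = 0.75, min_proteins: int = 20) -> VariancePrior:
    """Fit the count-variance trend and prior degrees of freedom.

    ``stats_df`` needs columns s2, df, n_precursors.  Requires at least
    ``min_proteins`` proteins with df >= 1.
    """
    sub = stats_df.loc[stats_df["df"] >= 1]
    if len(sub) < min_proteins:
        raise ValueError(
            f"only {len(sub)} proteins with df >= 1 (< {min_proteins}); "
            "too few to estimate a variance prior — use an unmoderated t-test"
        )
    s2 = np.maximum(sub["s2"].to_numpy(float), S2_FLOOR)
    counts = np.maximum(sub["n_precursors"].to_numpy(float), 1.0)
    dfs = sub["df"].to_numpy(float)
    y = np.log(s2)
    x = np.log(counts)

    if np.unique(x).size == 1:
        # constant covariate: single pooled prior
        grid_x = np.array([x[0] - 1.0, x[0] + 1.0])
        trend = np.full(2, y.mean())
        resid = y - y.mean()
    else:
        grid_x = np.unique(x)
        # it=0: no robustifying iterations — log chi-square residuals are
        # left-skewed, and downweighting that tail would bias the
        # conditional mean (and hence the prior) upward
        trend = lowess(y, x, frac=span, it=0, xvals=grid_x)
        resid = y - np.interp(x, grid_x, trend)

    # method of moments on the log variance ratios
    resid_var = float(np.var(resid, ddof=1)) if len(resid) > 1 else 0.0
    mean_trigamma = float(np.mean(special.polygamma(1, dfs / 2.0)))
    excess = resid_var - mean_trigamma
    if resid_var < 1e-12:
        # exactly degenerate: no scatter at all, the trend IS the prior
        return VariancePrior(grid_x, trend, np.inf)
    d0 = 2.0 * trigamma_inverse(excess) if excess > 0 else np.inf

    # de-bias: trend estimates log s2_prior + E[log F(df, d0)]
    mean_df = float(np.mean(dfs))
    trend = trend - _log_f_mean(mean_df, d0)
    return VariancePrior(grid_x, trend, d0)


def moderate_and_test(stats_df: pd.DataFrame, prior: VariancePrior) -> pd.DataFrame:
    """Squeeze variances toward the prior and compute moderated t / p.

    Adds s2_prior, s2_post, t_mod and two-sided p to a copy of
    ``stats_df``.  With d0 = 0 this is the ordinary one-sample t-test;
    with d0 = +inf the posterior variance equals the prior exactly.
    """
    out = stats_df.copy()
    counts = out["n_precursors"] if "n_precursors" in out else pd.Series(1, index=out.index)
    s2_prior = prior.s2_prior(counts)
    s2 = out["s2"].to_numpy(float)
    dfs = out["df"].to_numpy(float)
    n = out["n"].to_numpy(float)

    if np.isinf(prior.d0):
        s2_post = s2_prior.copy()
        df_total = np.full_like(dfs, D0_CAP)
    else:
        s2_post = (prior.d0 * s2_prior + dfs * s2) / (prior.d0 + dfs)
        df_total = dfs + prior.d0

    with np.errstate(divide="ignore", invalid="ignore"):
        t = out["log2_fc"].to_numpy(float) / np.sqrt(s2_post / n)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    zero_var = s2_post <= 0
    if zero_var.any():
        log.warning("%d protein(s) with zero posterior variance; p left absent", int(zero_var.sum()))
        p[zero_var] = np.nan
    out["s2_prior"] = s2_prior
    out["s2_post"] = s2_post
    out["d0"] = prior.d0
    out["t_mod"] = t
    out["p"] = p
    return out


def adjust_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving).

    NaN inputs yield NaN outputs and do not count toward m.
    """
    p = np.asarray(pvals, dtype=float)
    if np.nanmin(p, initial=0.0) < 0 or np.nanmax(p, initial=0.0) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def call_significance(
    results: pd.DataFrame,
    fc_threshold: float = 0.585,
    alpha: float = 0.05,
    unique_only: bool = True,
) -> pd.DataFrame:
    """Flag significantly up/down proteins on BH-adjusted p-values.

    up:   p_adj < alpha and log2_fc >  fc_threshold
    down: p_adj < alpha and log2_fc < -fc_threshold

    Only unique protein groups (single accession, no ';') are eligible
    when ``unique_only`` is set, matching standard practice for SILAC
    ratio tests on protein groups.
    """
    out = results.copy()
    if "p_adj" not in out.columns:
        out["p_adj"] = adjust_bh(out["p"].to_numpy())
    eligible = pd.Series(True, index=out.index)
    if unique_only:
        eligible = ~out.index.to_series().astype(str).str.contains(";")
    sig = (out["p_adj"] < alpha) & eligible
    out["significant_up"] = sig & (out["log2_fc"] > fc_threshold)
    out["significant_down"] = sig & (out["log2_fc"] < -fc_threshold)
    return out
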