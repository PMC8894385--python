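"""logCPM transform and two-group moderated differential expression.

Counts are transformed to log2 counts-per-million with the half-count
offset,

    logCPM = log2( (count + 0.5) / (lib_size + 1) × 10⁶ ),

and each miRNA is tested between the low-serum (contractile-inducing)
and normal-serum groups with an empirical-Bayes moderated t-statistic:
gene-wise residual variances s²_g (d_g degrees of freedom each) are
shrunk toward a prior (d0, s0²) fitted by moment matching on the
log-variance scale, giving posterior variances

    s̃²_g = (d0·s0² + d_g·s²_g) / (d0 + d_g)

and t = log2FC / (s̃_g·√(1/n₁ + 1/n₂)) on d0 + d_g degrees of freedom.
p-values are Benjamini–Hochberg adjusted across all miRNAs.

Call thresholds follow the volcano convention: |log2FC| > 0.6 together
with either raw p < 0.05 or BH-FDR < 0.05 (``use_fdr``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEThresholds",
    "ModeratedFit",
    "logcpm",
    "fit_moderated",
    "call_de",
    "trigamma_inverse",
]


@dataclass(frozen=True)
class DEThresholds:
    lfc: float = 0.6
    alpha: float = 0.05
    use_fdr: bool = False


@dataclass(frozen=True)
class ModeratedFit:
    """Result container: per-miRNA table plus the fitted global prior."""

    table: pd.DataFrame
    d0: float
    s0_squared: float


def logcpm(
    counts: pd.DataFrame, lib_sizes: pd.Series | np.ndarray | None = None
) -> pd.DataFrame:
    """log2 counts-per-million with a 0.5 count / 1 library offset.

    ``lib_sizes`` defaults to the column sums.  Negative counts are
    rejected.
    """
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if lib_sizes is None:
        libs = arr.sum(axis=0)
    else:
        libs = np.asarray(lib_sizes, dtype=float)
        if libs.shape != (arr.shape[1],):
            raise ValueError("lib_sizes length must match sample count")
    if not (libs > 0).all():
        raise ValueError("library sizes must be positive")
    out = np.log2((arr + 0.5) / (libs + 1.0) * 1e6)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def trigamma_inverse(x: float, tol: float = 1e-8, maxit: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma_inverse requires a positive argument")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(maxit):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < tol * y:
            break
    return float(y)


def _fit_log_variance_prior(
    s2: np.ndarray, df_resid: float
) -> tuple[float, float]:
    """Moment-match the scaled-F prior for gene variances on the log scale.

    Returns (d0, s0²); d0 = inf denotes full shrinkage (used when the
    observed spread of log s² is no wider than sampling noise alone).
    """
    s2 = np.clip(s2, 1e-300, None)
    z = np.log(s2)
    e = z - special.digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    ebar = e.mean()
    if len(e) < 2:
        return np.inf, float(np.exp(ebar))
    excess = e.var(ddof=1) - special.polygamma(1, df_resid / 2.0)
    if excess <= 0:
        warnings.warn(
            "no excess variance dispersion; using full shrinkage (d0=inf)",
            stacklevel=3,
        )
        return np.inf, float(np.exp(ebar))
    d0 = 2.0 * trigamma_inverse(excess)
    s0sq = np.exp(
        ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
    )
    return float(d0), float(s0sq)


def fit_moderated(
    log_expr: pd.DataFrame,
    groups: pd.Series,
    treatment: str = "low_serum",
    reference: str = "normal_serum",
    d0_override: float | None = None,
) -> ModeratedFit:
    """Two-group moderated t per miRNA on a logCPM matrix.

    ``groups`` maps sample (column) → group label; log2FC is
    treatment − reference group mean.  ``d0_override`` fixes the prior
    degrees of freedom (0 reduces to the ordinary pooled two-sample t).
    """
    groups = groups.reindex(log_expr.columns)
    if groups.isna().any():
        raise ValueError("every sample column needs a group label")
    m1 = groups == treatment
    m2 = groups == reference
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per group")
    x1 = log_expr.loc[:, m1.to_numpy()].to_numpy(dtype=float)
    x2 = log_expr.loc[:, m2.to_numpy()].to_numpy(dtype=float)

    mu1, mu2 = x1.mean(axis=1), x2.mean(axis=1)
    lfc = mu1 - mu2
    df_resid = n1 + n2 - 2
    ss = ((x1 - mu1[:, None]) ** 2).sum(axis=1) + (
        (x2 - mu2[:, None]) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid

    if np.all(s2 == 0):
        warnings.warn(
            "zero residual variance everywhere; falling back to ordinary t",
            stacklevel=2,
        )
        d0, s0sq = 0.0, 0.0
    elif d0_override is not None:
        d0 = float(d0_override)
        s0sq = float(np.median(s2)) if np.isfinite(d0) and d0 > 0 else 0.0
    else:
        d0, s0sq = _fit_log_variance_prior(s2, df_resid)

    if d0 == 0.0:
        post_var = s2
        df_total = np.full_like(s2, float(df_resid))
    elif np.isinf(d0):
        post_var = np.full_like(s2, s0sq)
        df_total = np.full_like(s2, np.inf)
    else:
        post_var = (d0 * s0sq + df_resid * s2) / (d0 + df_resid)
        df_total = np.full_like(s2, d0 + df_resid)

    se = np.sqrt(post_var * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, np.where(lfc == 0, 0.0, np.inf))
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)
    fdr = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "mean_logcpm": log_expr.to_numpy(dtype=float).mean(axis=1),
            "log2fc": lfc,
            "t_moderated": t,
            "p_value": p,
            "fdr": fdr,
        },
        index=log_expr.index,
    )
    return ModeratedFit(table=table, d0=d0, s0_squared=s0sq)


def call_de(
    fit: ModeratedFit | pd.DataFrame,
    thresholds: DEThresholds | None = None,
) -> pd.DataFrame:
    """Volcano-style up/down/ns calls.

    up:   log2fc >  lfc and significant;
    down: log2fc < −lfc and significant;
    significance is raw p < alpha, or BH-FDR < alpha with ``use_fdr``.
    Adds ``call`` and ``neg_log10_p`` columns (volcano-ready export).
    """
    t = thresholds or DEThresholds()
    table = fit.table if isinstance(fit, ModeratedFit) else fit
    sig = (table["fdr"] if t.use_fdr else table["p_value"]) < t.alpha
    call = np.full(len(table), "ns", dtype=object)
    call[(table["log2fc"] > t.lfc) & sig] = "up"
    call[(table["log2fc"] < -t.lfc) & sig] = "down"
    out = table.copy()
    out["call"] = call
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(table["p_value"])
    return out
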