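"""Two-group differential expression with empirical-Bayes moderated t-statistics.

The model is the standard two-sample comparison on log2-scale expression:
per gene, log2FC = mean(treated) - mean(control), with a pooled within-group
variance s2 on df = n_t + n_c - 2 degrees of freedom. Gene-wise variances are
shrunk toward a common prior by empirical-Bayes moderation,

    s2_tilde = (d0 * s0^2 + df * s2) / (d0 + df),

with the prior degrees of freedom d0 and prior variance s0^2 estimated by
method-of-moments on log(s2) (the scaled-F model: s2 ~ s0^2 * F(df, d0)).
Moderated t-statistics are referred to a Student-t distribution with
d0 + df degrees of freedom, and p-values are Benjamini-Hochberg adjusted.

Differentially expressed genes (DEGs) are those with |log2FC| strictly
greater than 0.5 and adjusted p strictly below 0.01 by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

TREATED = "treated"
CONTROL = "control"


@dataclass
class ExpressionMatrix:
    """Log2-scale expression, genes x samples, with a two-group design."""

    values: pd.DataFrame          # index = gene symbols, columns = samples
    group: pd.Series              # per-sample label in {treated, control}

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene symbols: {list(dups[:5])}")
        bad = set(self.group.unique()) - {TREATED, CONTROL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        self.group = self.group.reindex(self.values.columns)
        if self.group.isna().any():
            raise ValueError("every sample column needs a group label")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def samples_in(self, label: str) -> pd.DataFrame:
        return self.values.loc[:, self.group[self.group == label].index]


@dataclass(frozen=True)
class DEGCriteria:
    """DEG filter thresholds; both inequalities are strict."""

    min_abs_log2fc: float = 0.5
    max_adj_p: float = 0.01

    def __post_init__(self) -> None:
        if self.min_abs_log2fc <= 0 or self.max_adj_p <= 0:
            raise ValueError("thresholds must be strictly positive")


def read_expression(matrix_path: str | Path, samples_path: str | Path) -> ExpressionMatrix:
    """Load a TSV expression matrix (first column = gene) and a sample sheet.

    The sample sheet is two columns (sample, group) with group labels
    'treated'/'control'.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    sheet = pd.read_csv(samples_path, sep="\t")
    group = pd.Series(sheet.iloc[:, 1].values, index=sheet.iloc[:, 0].values)
    return ExpressionMatrix(values=values, group=group)


def fit_two_group(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene log2FC, pooled variance and residual degrees of freedom.

    Returns a DataFrame indexed by gene with columns log2fc, s2, df,
    n_treated, n_control. Requires >=2 replicates per group.
    """
    t = expr.samples_in(TREATED)
    c = expr.samples_in(CONTROL)
    n_t, n_c = t.shape[1], c.shape[1]
    if n_t < 2 or n_c < 2:
        raise ValueError(
            f"insufficient replicates: {n_t} treated, {n_c} control (need >=2 each)"
        )
    vals = expr.values.to_numpy()
    if not np.isfinite(vals).all():
        raise ValueError("expression values must be finite")
    log2fc = t.mean(axis=1) - c.mean(axis=1)
    ss = t.var(axis=1, ddof=1) * (n_t - 1) + c.var(axis=1, ddof=1) * (n_c - 1)
    df = n_t + n_c - 2
    out = pd.DataFrame({
        "log2fc": log2fc,
        "s2": ss / df,
        "df": float(df),
        "n_treated": n_t,
        "n_control": n_c,
    })
    return out


def ebayes_moderate(
    s2: np.ndarray | pd.Series,
    df: np.ndarray | pd.Series | float,
    *,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> tuple[float, float, np.ndarray]:
    """Estimate (d0, s0^2) and return moderated variances s2_tilde.

    Under the scaled-F model, z = log(s2) satisfies
      E[z]   = log(s0^2) + psi(df/2) - log(df/2) - psi(d0/2) + log(d0/2)
      Var[z] = psi'(df/2) + psi'(d0/2),
    so d0 solves psi'(d0/2) = var(z) - psi'(df/2) and s0^2 follows from the
    mean. When the observed spread of log-variances is no larger than the
    sampling noise, d0 is infinite and every s2_tilde equals s0^2.

    `d0` / `s0_sq` may be fixed (e.g. d0=0 disables shrinkage entirely).
    """
    s2 = np.asarray(s2, dtype=float)
    df_arr = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    if s2.size < 2 and d0 is None:
        raise ValueError("need >=2 genes to estimate the variance prior")
    if np.all(s2 == 0) and (d0 is None or s0_sq is None):
        raise ValueError("degenerate variance distribution: all s2 are zero")

    if d0 == 0 and s0_sq is None:
        s0_sq = 0.0  # unused: no shrinkage
    if d0 is None or s0_sq is None:
        est_d0, est_s0 = _fit_f_dist(s2, df_arr)
        if d0 is None:
            d0 = est_d0
        if s0_sq is None:
            s0_sq = est_s0

    if d0 == 0:
        s2_tilde = s2.copy()
    elif math.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
    else:
        s2_tilde = (d0 * s0_sq + df_arr * s2) / (d0 + df_arr)
    return float(d0), float(s0_sq), s2_tilde


def _fit_f_dist(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of s2 ~ s0^2 F(df, d0) on the log scale."""
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("degenerate variance distribution: too few positive s2")
    z = np.log(s2[ok])
    dfk = df[ok]
    e = z - special.digamma(dfk / 2.0) + np.log(dfk / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, dfk / 2.0).mean()
    if evar <= 0:
        return math.inf, float(np.exp(emean))
    # invert trigamma: psi'(d0/2) = evar
    lo, hi = 1e-8, 1e8
    half_d0 = optimize.brentq(lambda x: special.polygamma(1, x) - evar, lo, hi)
    d0 = 2.0 * half_d0
    s0_sq = np.exp(emean + special.digamma(half_d0) - math.log(half_d0))
    return float(d0), float(s0_sq)


def moderated_t(
    log2fc: np.ndarray | pd.Series,
    s2_tilde: np.ndarray | pd.Series,
    n_treated: int,
    n_control: int,
    df: float,
    d0: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t = log2fc / sqrt(s2_tilde * (1/n_t + 1/n_c)), p from t(d0+df).

    Genes with zero moderated variance and zero log2fc get t=0, p=1; a zero
    variance with nonzero log2fc is an error rather than a silent infinity.
    """
    log2fc = np.asarray(log2fc, dtype=float)
    s2_tilde = np.asarray(s2_tilde, dtype=float)
    bad = (s2_tilde == 0) & (log2fc != 0)
    if bad.any():
        raise ValueError(
            f"infinite statistic: zero moderated variance with nonzero log2FC "
            f"for {int(bad.sum())} gene(s)"
        )
    se = np.sqrt(s2_tilde * (1.0 / n_treated + 1.0 / n_control))
    t_mod = np.zeros_like(log2fc)
    nz = se > 0
    t_mod[nz] = log2fc[nz] / se[nz]
    total_df = (d0 + df) if not math.isinf(d0) else math.inf
    if math.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), total_df)
    return t_mod, np.minimum(p, 1.0)


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_analysis(
    expr: ExpressionMatrix,
    *,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> pd.DataFrame:
    """Full pipeline: fit, moderate, test, adjust.

    Returns a DataFrame indexed by gene with columns log2fc, s2, df, t_mod,
    p, p_adj (plus d0/s0_sq as attrs).
    """
    fit = fit_two_group(expr)
    d0_hat, s0_hat, s2_tilde = ebayes_moderate(
        fit["s2"].to_numpy(), fit["df"].to_numpy(), d0=d0, s0_sq=s0_sq
    )
    n_t = int(fit["n_treated"].iloc[0])
    n_c = int(fit["n_control"].iloc[0])
    t_mod, p = moderated_t(
        fit["log2fc"].to_numpy(), s2_tilde, n_t, n_c, float(fit["df"].iloc[0]), d0_hat
    )
    out = fit[["log2fc", "s2", "df"]].copy()
    out["s2_tilde"] = s2_tilde
    out["t_mod"] = t_mod
    out["p"] = p
    out["p_adj"] = bh_adjust(p)
    out.attrs["d0"] = d0_hat
    out.attrs["s0_sq"] = s0_hat
    return out


def select_degs(results: pd.DataFrame, criteria: DEGCriteria = DEGCriteria()) -> pd.DataFrame:
    """Filter to DEGs: |log2fc| > threshold AND p_adj < threshold, both strict.

    Adds a 'direction' column ('up' for log2fc > 0, 'down' otherwise).
    """
    mask = (results["log2fc"].abs() > criteria.min_abs_log2fc) & (
        results["p_adj"] < criteria.max_adj_p
    )
    degs = results.loc[mask].copy()
    degs["direction"] = np.where(degs["log2fc"] > 0, "up", "down")
    return degs


def write_de_table(results: pd.DataFrame, path: str | Path) -> None:
    """Write a limma-compatible TSV: gene, log2FC, t, P.Value, adj.P.Val."""
    out = pd.DataFrame({
        "gene": results.index,
        "log2FC": results["log2fc"].to_numpy(),
        "t": results["t_mod"].to_numpy(),
        "P.Value": results["p"].to_numpy(),
        "adj.P.Val": results["p_adj"].to_numpy(),
    })
    out.to_csv(path, sep="\t", index=False)
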