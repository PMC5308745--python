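"""Paired differential expression with an empirical-Bayes moderated t-statistic.

Per gene, paired log2 differences d_i (tumor - normal, i = 1..n) give the
ordinary statistics mean(d) and s^2. The moderated test shrinks each
gene's variance toward a common prior value s0^2 with prior degrees of
freedom d0:

    s_tilde^2 = (d0 * s0^2 + (n-1) * s^2) / (d0 + n - 1)
    t_tilde   = mean(d) / (s_tilde / sqrt(n))        ~ t with n-1+d0 df

The hyperparameters (d0, s0^2) are estimated by moment matching on
z = log(s^2): under the scaled-F model z has variance
trigamma((n-1)/2) + trigamma(d0/2), so d0 comes from inverting the
trigamma function on the excess variance of z, and s0^2 from the mean of
z after removing the chi-square bias terms. d0 = 0 recovers the plain
paired t-test; d0 -> infinity pins every gene's variance at s0^2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import norm, t as t_dist

from .dmp import adjust_bh
from .io import ExpressionMatrix, SampleDesign


def quantile_normalize(intensity: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization: force every sample to the mean empirical
    distribution. Ties are assigned in stable sorted order."""
    arr = intensity.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(arr.shape[0])
    for j in range(arr.shape[1]):
        ranks[order[:, j], j] = rows
    mean_sorted = np.sort(arr, axis=0).mean(axis=1)
    out = mean_sorted[ranks]
    return pd.DataFrame(out, index=intensity.index, columns=intensity.columns)


def normalize_expression(expr: ExpressionMatrix, quantile: bool = True) -> ExpressionMatrix:
    """Quantile-normalize, move to log2(intensity + 1), collapse to genes.

    Multiple features mapping to one gene are collapsed by keeping the
    feature with the highest mean (normalized) intensity. Features with
    no gene symbol are dropped. The returned matrix is indexed by gene
    symbol and holds log2 values.
    """
    intensity = quantile_normalize(expr.intensity) if quantile else expr.intensity.astype(float)
    log2 = np.log2(intensity + 1.0)
    symbols = expr.gene_symbols
    keep = symbols != ""
    log2 = log2.loc[keep.values]
    mean_int = intensity.loc[keep.values].mean(axis=1)
    picker = pd.DataFrame({"gene": symbols[keep].values, "mean": mean_int.values},
                          index=log2.index)
    # stable representative per gene: highest mean, feature id breaking ties
    picker = picker.sort_values(["gene", "mean"], ascending=[True, False], kind="stable")
    chosen = picker.drop_duplicates("gene", keep="first")
    collapsed = log2.loc[chosen.index]
    collapsed.index = pd.Index(chosen["gene"].values, name="gene")
    collapsed = collapsed.sort_index()
    return ExpressionMatrix(
        collapsed, pd.Series(collapsed.index, index=collapsed.index, name="gene_symbol")
    )


def _trigamma_inverse(y: float) -> float:
    # Newton iteration on x -> trigamma(x) - y; monotone decreasing, convex
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = polygamma(1, x)
        step = tri * (1.0 - tri / y) / polygamma(2, x)
        x += step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, residual_df: int) -> tuple[float, float]:
    """Moment-matching fit of (d0, s0^2) from gene-level sample variances."""
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size < 2:
        raise ValueError("variance prior fit impossible: fewer than two genes with s^2 > 0")
    d = residual_df
    z = np.log(positive)
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    excess = float(np.var(z, ddof=1) - polygamma(1, d / 2.0))
    if excess <= 0:
        # no excess spread beyond chi-square sampling noise: variances are
        # effectively common; the prior is their geometric mean so that
        # identical observed s^2 shrink to themselves
        d0 = np.inf
        log_s0_sq = float(np.mean(z))
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        log_s0_sq = float(np.mean(e) + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return d0, float(np.exp(log_s0_sq))


def moderated_paired_test(
    log_expr: ExpressionMatrix,
    design: SampleDesign,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> pd.DataFrame:
    """Per-gene moderated paired t-test on a log2, gene-collapsed matrix.

    Returns a frame indexed by gene with log2_fc (mean paired tumor -
    normal difference), t and p_value; the fitted hyperparameters live in
    ``result.attrs`` (d0, s0_sq, n_pairs). Pass ``d0``/``s0_sq`` to
    override the empirical-Bayes fit (d0=0 gives the plain paired t).
    """
    pairs = design.pairs()
    if len(pairs) < 2:
        raise ValueError("need >=2 complete pairs")
    tum = log_expr.intensity[[t for t, _ in pairs]].to_numpy(dtype=float)
    nor = log_expr.intensity[[n for _, n in pairs]].to_numpy(dtype=float)
    diffs = tum - nor
    n = diffs.shape[1]
    mean_d = diffs.mean(axis=1)
    s2 = diffs.var(axis=1, ddof=1)
    resid_df = n - 1

    if d0 is None:
        d0, s0_fit = estimate_prior(s2, resid_df)
        if s0_sq is None:
            s0_sq = s0_fit
    elif d0 > 0 and s0_sq is None:
        _, s0_sq = estimate_prior(s2, resid_df)

    if d0 == 0:
        s_tilde_sq = s2
        df = float(resid_df)
    elif np.isinf(d0):
        s_tilde_sq = np.full_like(s2, s0_sq)
        df = np.inf
    else:
        s_tilde_sq = (d0 * s0_sq + resid_df * s2) / (d0 + resid_df)
        df = float(resid_df + d0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = mean_d / np.sqrt(s_tilde_sq / n)
    if np.isinf(df):
        p = 2.0 * norm.sf(np.abs(t_stat))
    else:
        p = 2.0 * t_dist.sf(np.abs(t_stat), df)
    p = np.where(np.isnan(t_stat), 1.0, np.minimum(1.0, p))

    out = pd.DataFrame(
        {"log2_fc": mean_d, "t": t_stat, "p_value": p},
        index=log_expr.intensity.index.rename("gene"),
    )
    out.attrs.update({"d0": float(d0), "s0_sq": float(s0_sq) if s0_sq is not None else None,
                      "n_pairs": n})
    return out


def call_degs(
    results: pd.DataFrame,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Apply the fold-change + FDR call rule to moderated-test results.

    direction is up/down iff |log2_fc| >= log2(fc_threshold) (boundary
    inclusive) and the BH-adjusted p is < alpha; none otherwise.
    """
    if fc_threshold < 1:
        raise ValueError("fold-change threshold must be >= 1")
    out = results.copy()
    out["fdr"] = adjust_bh(out["p_value"].to_numpy())
    lfc_gate = np.abs(out["log2_fc"]) >= np.log2(fc_threshold)
    called = lfc_gate & (out["fdr"] < alpha)
    out["direction"] = "none"
    out.loc[called & (out["log2_fc"] > 0), "direction"] = "up"
    out.loc[called & (out["log2_fc"] < 0), "direction"] = "down"
    return out
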