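"""Probe QC, paired differential methylation testing, and genomic-context summaries.

The paired Wilcoxon signed-rank test is implemented with an exact null
distribution for n <= 25 pairs (dynamic programming over doubled midranks,
so tied absolute differences are handled exactly) and a normal
approximation with continuity correction beyond that. Zero differences
are discarded by default (classic Wilcoxon); the Pratt variant keeps them
in the ranking.

DMP calling follows the two-gate rule |delta beta| > threshold AND test
statistic (raw p or BH-adjusted FDR) < alpha. At n=6 pairs the exact
two-sided signed-rank p cannot fall below 2/2^6 = 0.03125, so a
genome-wide FDR gate at 0.05 is empty at that cohort size; the raw-p gate
is therefore the default and both gates are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from .io import (
    CGI_CLASSES,
    CGI_RELATED,
    PROMOTER_REGIONS,
    REGION_CLASSES,
    BetaMatrix,
    ProbeAnnotationTable,
    SampleDesign,
)

EXACT_N_MAX = 25  # exact enumeration cutoff; beyond this, normal approximation

SEX_CHROMOSOMES = {"X", "Y", "chrX", "chrY"}


@dataclass(frozen=True)
class SignedRankResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n_used: int  # pairs contributing to the statistic
    degenerate: bool = False  # all differences zero

    def __float__(self) -> float:
        return self.p_value


@lru_cache(maxsize=256)
def _exact_two_sided_p(doubled_ranks: tuple[int, ...]) -> np.ndarray:
    """Two-sided p for every value of the doubled statistic 2*W+.

    Enumerates the exact null distribution of W+ over the 2^n equiprobable
    sign assignments by polynomial multiplication: each rank r contributes
    a factor (1 + z^{2r})/2. Doubling makes midranks integral.
    """
    total = sum(doubled_ranks)
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in doubled_ranks:
        nxt = pmf.copy()
        nxt[r:] += pmf[: total + 1 - r]
        pmf = nxt / 2.0
    cdf = np.cumsum(pmf)
    sf = np.cumsum(pmf[::-1])[::-1]
    return np.minimum(1.0, 2.0 * np.minimum(cdf, sf))


def _signed_rank_from_diffs(d: np.ndarray, zero_method: str) -> SignedRankResult:
    if zero_method not in ("discard", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")
    nonzero = d != 0
    if not nonzero.any():
        return SignedRankResult(0.0, 1.0, 0, degenerate=True)
    if zero_method == "discard":
        dd = d[nonzero]
        ranks = rankdata(np.abs(dd))
    else:  # pratt: rank including zeros, then drop the zeros' ranks
        ranks_all = rankdata(np.abs(d))
        dd = d[nonzero]
        ranks = ranks_all[nonzero]
    w_pos = float(ranks[dd > 0].sum())
    n = len(dd)
    if n <= EXACT_N_MAX:
        doubled = tuple(sorted(int(round(2 * r)) for r in ranks))
        table = _exact_two_sided_p(doubled)
        p = float(table[int(round(2 * w_pos))])
    else:
        mu = ranks.sum() / 2.0
        sigma = np.sqrt(np.sum(ranks**2) / 4.0)
        shift = w_pos - mu
        z = (shift - 0.5 * np.sign(shift)) / sigma  # continuity correction
        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return SignedRankResult(w_pos, p, n)


def paired_wilcoxon(
    beta_tumor: np.ndarray | list[float],
    beta_normal: np.ndarray | list[float],
    zero_method: str = "discard",
) -> SignedRankResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Pairs with a missing value are dropped; at least 3 complete pairs are
    required. All-zero differences yield p = 1 with ``degenerate=True``.
    """
    x = np.asarray(beta_tumor, dtype=float)
    y = np.asarray(beta_normal, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    d = x[ok] - y[ok]
    if len(d) < 3:
        raise ValueError(f"need >=3 complete pairs, got {len(d)}")
    return _signed_rank_from_diffs(d, zero_method)


def adjust_bh(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_probes(
    beta: BetaMatrix,
    ann: ProbeAnnotationTable,
    detection_threshold: float = 0.05,
) -> tuple[BetaMatrix, dict[str, int]]:
    """Remove unreliable and confounded probes.

    A probe is removed if its detection p exceeds the threshold in ANY
    sample, if it lies on a sex chromosome, or if its SNP or multi-mapping
    flag is set. Returns the filtered matrix and per-rule removal counts
    (a probe tripping several rules is counted under each).
    """
    if not 0 < detection_threshold < 1:
        raise ValueError(f"detection threshold must be in (0,1), got {detection_threshold}")
    missing = set(beta.probe_ids) - set(ann.probe_ids)
    if missing:
        raise ValueError(f"{len(missing)} probes lack annotation (first: {sorted(missing)[0]!r})")
    t = ann.table.loc[beta.probe_ids]
    bad_det = (beta.detection_p > detection_threshold).any(axis=1).to_numpy()
    sex = t["chromosome"].isin(SEX_CHROMOSOMES).to_numpy()
    snp = t["snp_flag"].to_numpy(dtype=bool)
    multi = t["multimap_flag"].to_numpy(dtype=bool)
    report = {
        "detection": int(bad_det.sum()),
        "sex_chromosome": int(sex.sum()),
        "snp": int(snp.sum()),
        "multimap": int(multi.sum()),
    }
    keep = ~(bad_det | sex | snp | multi)
    kept_ids = [p for p, k in zip(beta.probe_ids, keep) if k]
    return beta.subset_probes(kept_ids), report


def call_dmps(
    beta: BetaMatrix,
    design: SampleDesign,
    delta_threshold: float = 0.2,
    alpha: float = 0.05,
    gate: str = "raw_p",
    zero_method: str = "discard",
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Per-probe paired test, BH correction, and DMP calls.

    Returns a frame indexed by probe id with mean_beta_normal,
    mean_beta_cancer, delta_beta (cancer - normal), p_value, fdr and
    direction in {hyper, hypo, none}. A probe is called iff
    |delta_beta| > delta_threshold and the gate statistic (raw p or FDR)
    is < alpha. Probes with fewer than ``min_pairs`` complete pairs are
    skipped and listed in ``result.attrs['skipped_probes']``.
    """
    if gate not in ("raw_p", "fdr"):
        raise ValueError(f"gate must be 'raw_p' or 'fdr', got {gate!r}")
    pairs = design.pairs()
    if not pairs:
        raise ValueError("design contains no paired subjects")
    tumor_ids = [t for t, _ in pairs]
    normal_ids = [n for _, n in pairs]
    tum = beta.beta[tumor_ids].to_numpy(dtype=float)
    nor = beta.beta[normal_ids].to_numpy(dtype=float)
    complete = ~(np.isnan(tum) | np.isnan(nor))

    rows, skipped = [], []
    for i, probe in enumerate(beta.probe_ids):
        ok = complete[i]
        if ok.sum() < min_pairs:
            skipped.append(probe)
            continue
        tv, nv = tum[i, ok], nor[i, ok]
        res = _signed_rank_from_diffs(tv - nv, zero_method)
        rows.append((probe, float(nv.mean()), float(tv.mean()), res.p_value, res.degenerate))

    if not rows:
        raise ValueError("no probe has enough complete pairs")
    out = pd.DataFrame(
        rows, columns=["probe_id", "mean_beta_normal", "mean_beta_cancer", "p_value", "degenerate"]
    ).set_index("probe_id")
    out["delta_beta"] = out["mean_beta_cancer"] - out["mean_beta_normal"]
    out["fdr"] = adjust_bh(out["p_value"].to_numpy())
    stat = out["p_value"] if gate == "raw_p" else out["fdr"]
    called = (out["delta_beta"].abs() > delta_threshold) & (stat < alpha)
    out["direction"] = "none"
    out.loc[called & (out["delta_beta"] > 0), "direction"] = "hyper"
    out.loc[called & (out["delta_beta"] < 0), "direction"] = "hypo"
    out = out[["mean_beta_normal", "mean_beta_cancer", "delta_beta",
               "p_value", "fdr", "direction", "degenerate"]]
    out.attrs["skipped_probes"] = skipped
    out.attrs["gate"] = gate
    return out


@dataclass(frozen=True)
class ContextSummary:
    """DMP counts/fractions over region and CGI classes, split by direction."""

    region_counts: pd.DataFrame  # index direction, columns region classes
    region_fractions: pd.DataFrame
    cgi_counts: pd.DataFrame
    cgi_fractions: pd.DataFrame
    promoter_fraction: pd.Series  # per direction: probes with >=1 promoter assignment
    cgi_related_fraction: pd.Series  # per direction: Island/Shore/Shelf probes


def summarize_regions(dmps: pd.DataFrame, ann: ProbeAnnotationTable) -> ContextSummary:
    """Genomic-context distribution of called DMPs (Figure-1-style summary).

    A probe contributes once per distinct region class it carries across
    its gene assignments; probes with no gene count as Intergenic. The
    promoter region is TSS1500 u TSS200 u 5'UTR u 1st exon. Directions
    with zero DMPs get NaN fractions.
    """
    called = dmps[dmps["direction"].isin(["hyper", "hypo"])]
    missing = set(called.index) - set(ann.probe_ids)
    if missing:
        raise ValueError(f"DMP {sorted(missing)[0]!r} lacks annotation")
    t = ann.table
    directions = ["hyper", "hypo"]
    region_counts = pd.DataFrame(0, index=directions, columns=list(REGION_CLASSES))
    cgi_counts = pd.DataFrame(0, index=directions, columns=list(CGI_CLASSES))
    promoter_hits = pd.Series(0, index=directions)
    cgi_related = pd.Series(0, index=directions)
    n_probes = pd.Series(0, index=directions)

    for probe, direction in called["direction"].items():
        row = t.loc[probe]
        regions = set(row["region_classes"]) or {"Intergenic"}
        for r in regions:
            region_counts.loc[direction, r] += 1
        cgi_counts.loc[direction, row["cgi_class"]] += 1
        n_probes[direction] += 1
        if regions & PROMOTER_REGIONS:
            promoter_hits[direction] += 1
        if row["cgi_class"] in CGI_RELATED:
            cgi_related[direction] += 1

    def _frac(counts: pd.DataFrame) -> pd.DataFrame:
        totals = counts.sum(axis=1)
        return counts.div(totals.where(totals > 0), axis=0)

    return ContextSummary(
        region_counts=region_counts,
        region_fractions=_frac(region_counts),
        cgi_counts=cgi_counts,
        cgi_fractions=_frac(cgi_counts),
        promoter_fraction=promoter_hits / n_probes.where(n_probes > 0),
        cgi_related_fraction=cgi_related / n_probes.where(n_probes > 0),
    )


@dataclass(frozen=True)
class SampleTree:
    """Agglomerative clustering of samples: scipy linkage matrix + leaf order."""

    sample_ids: list[str]  # lexicographically sorted leaf labels
    merges: np.ndarray  # scipy linkage matrix over sample_ids
    leaf_order: list[str]


def cluster_samples(beta_subset: BetaMatrix) -> SampleTree:
    """Average-linkage clustering of samples on 1 - Pearson correlation.

    Samples are sorted lexicographically before clustering so the tree is
    invariant to input column order (fixed tie-breaking).
    """
    if len(beta_subset.sample_ids) < 2:
        raise ValueError("clustering needs >=2 samples")
    cols = sorted(beta_subset.sample_ids)
    corr = beta_subset.beta[cols].corr(method="pearson")  # pairwise-complete
    dist = (1.0 - corr).clip(lower=0.0)
    np.fill_diagonal(dist.values, 0.0)
    z = linkage(squareform(dist.to_numpy(), checks=False), method="average")
    order = [cols[i] for i in leaves_list(z)]
    return SampleTree(sample_ids=cols, merges=z, leaf_order=order)
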