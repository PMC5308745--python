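"""Validation-stage statistics for candidate methylation markers.

Covers the wet-lab follow-up of an array screen: quantifying percent
methylation from MS-HRM melt curves against a standard dilution series,
interval scoring of the estimates, paired group comparison of the scores,
qPCR relative expression (2^-ddCt), methylation-expression correlation,
inter-observer agreement (Cohen's kappa), ROC/AUC with a Youden-optimal
cutoff, and clinicopathological association tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations
from math import factorial

import numpy as np
from scipy import stats

from .curves import MeltCurve, StandardCurveSet
from .dmp import SignedRankResult, paired_wilcoxon

#: right-closed interval scoring bins for percent methylation, categories 1-6
CATEGORY_BOUNDS = [(0.0, 10.0), (10.0, 25.0), (25.0, 50.0), (50.0, 75.0), (75.0, 85.0), (85.0, 100.0)]


def quantify_methylation(
    sample_curve: MeltCurve,
    standards: StandardCurveSet,
    grid_step_percent: float = 0.1,
    monotone_tolerance: float = 0.05,
) -> float:
    """Percent methylation of a sample curve by standard-curve matching.

    The estimate m-hat minimizes the sum of squared deviations between
    the sample curve and the linear interpolation (in mixture fraction m)
    of the bracketing standard curves, searched on a ``grid_step_percent``
    grid over [0, 100]. Ties resolve to the lowest m. A normalized sample
    curve that rises by more than ``monotone_tolerance`` anywhere triggers
    a warning (melt curves should be non-increasing).
    """
    grid = standards.temperature
    if sample_curve.temperature.shape != grid.shape or not np.allclose(
        sample_curve.temperature, grid
    ):
        raise ValueError("sample and standards use different temperature grids")
    f = sample_curve.fluorescence
    if np.any(np.diff(f) > monotone_tolerance):
        warnings.warn(
            f"curve {sample_curve.label!r} is non-monotone beyond tolerance", stacklevel=2
        )
    fracs = standards.fractions
    curves = standards.curve_matrix()
    m_grid = np.arange(0.0, 100.0 + grid_step_percent / 2, grid_step_percent) / 100.0
    m_grid = np.clip(m_grid, fracs[0], fracs[-1])
    # piecewise-linear interpolation of the standard curves in m, vectorized
    idx = np.clip(np.searchsorted(fracs, m_grid, side="right") - 1, 0, len(fracs) - 2)
    lo, hi = fracs[idx], fracs[idx + 1]
    w = (m_grid - lo) / (hi - lo)
    pred = (1 - w)[:, None] * curves[idx] + w[:, None] * curves[idx + 1]
    sse = np.sum((pred - f[None, :]) ** 2, axis=1)
    best = int(np.argmin(sse))  # argmin takes the first (lowest m) on ties
    return float(round(m_grid[best] * 100.0, 10))


def categorize_methylation(percent: float) -> int:
    """Interval score 1-6 for a percent methylation estimate.

    Bins are right-closed: [0,10], (10,25], (25,50], (50,75], (75,85],
    (85,100]; the printed integer interval labels 0-10 / 11-25 / ... are
    preserved at their integer endpoints.
    """
    if not 0 <= percent <= 100:
        raise ValueError(f"percent methylation {percent} outside [0, 100]")
    for cat, (lo, hi) in enumerate(CATEGORY_BOUNDS, start=1):
        if percent <= hi:
            return cat
    return 6  # pragma: no cover - unreachable given the range check


def compare_category_groups(
    tumor_cats: np.ndarray | list[int],
    normal_cats: np.ndarray | list[int],
    zero_method: str = "discard",
) -> SignedRankResult:
    """Exact paired signed-rank test on interval scores (n >= 5 pairs)."""
    tumor_cats = np.asarray(tumor_cats, dtype=float)
    normal_cats = np.asarray(normal_cats, dtype=float)
    if tumor_cats.shape != normal_cats.shape:
        raise ValueError("paired category vectors must have equal length")
    if len(tumor_cats) < 5:
        raise ValueError(f"need >=5 pairs, got {len(tumor_cats)}")
    return paired_wilcoxon(tumor_cats, normal_cats, zero_method=zero_method)


def ddct_fold_change(
    ct_target_case: float, ct_ref_case: float, ct_target_ctrl: float, ct_ref_ctrl: float
) -> float:
    """Relative expression 2^-ddCt with a reference-gene normalization.

    ddCt = (Ct_target - Ct_reference) in the case minus the same
    difference in the control; one cycle less equals a doubling.
    """
    cts = (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl)
    if any(c <= 0 for c in cts):
        raise ValueError("Ct values must be positive")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(x)
    rhos = np.empty(factorial(n))
    for i, perm in enumerate(permutations(range(n))):
        rhos[i] = np.corrcoef(rx[list(perm)], ry)[0, 1]
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def meth_expr_correlation(
    meth: np.ndarray | list[float],
    expr: np.ndarray | list[float],
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlation between methylation and expression with a two-sided p.

    Pearson uses the t-distribution p; Spearman uses an exact permutation
    p for n <= 8 and the large-sample approximation beyond.
    """
    x = np.asarray(meth, dtype=float)
    y = np.asarray(expr, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
        if len(x) <= 8:
            p = _spearman_exact_p(x, y, float(r))
        return float(r), float(p)
    raise ValueError(f"unknown method {method!r}")


def cohen_kappa(ratings_a: np.ndarray | list, ratings_b: np.ndarray | list) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e) with chance agreement p_e
    from the raters' marginal products. Two constant, equal raters give 1."""
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValueError("rating vectors must be equal-length and nonempty")
    cats = np.unique(np.concatenate([a, b]))
    n = len(a)
    p_o = float(np.mean(a == b))
    pa = np.array([np.mean(a == c) for c in cats])
    pb = np.array([np.mean(b == c) for c in cats])
    p_e = float(pa @ pb)
    if p_e >= 1.0 - 1e-15:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray  # ascending, on the original score scale
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    best_cutoff: float
    best_sensitivity: float
    best_specificity: float
    direction: str


def roc_analysis(
    scores: np.ndarray | list[float],
    labels: np.ndarray | list[str],
    direction: str = "higher_is_case",
) -> ROCResult:
    """Empirical ROC over all distinct thresholds with trapezoid AUC.

    ``labels`` contains "case"/"control". The reported cutoff maximizes
    the Youden index J = Se + Sp - 1 and is placed at the midpoint
    between adjacent distinct scores (ties resolve to the lower
    threshold). The trapezoid AUC equals the Mann-Whitney concordance
    probability, with tied score pairs counted one half.
    """
    if direction not in ("higher_is_case", "lower_is_case"):
        raise ValueError(f"unknown direction {direction!r}")
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    is_case = lab == "case"
    is_ctrl = lab == "control"
    if not (is_case | is_ctrl).all():
        raise ValueError("labels must be 'case' or 'control'")
    if is_case.sum() == 0 or is_ctrl.sum() == 0:
        raise ValueError("both classes must be present")
    sign = 1.0 if direction == "higher_is_case" else -1.0
    z = sign * s

    distinct = np.unique(z)
    # candidate thresholds: midpoints between adjacent distinct scores plus
    # one below and one above everything (classify case iff z >= threshold)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[distinct[0] - 1.0], mids, [distinct[-1] + 1.0]])
    n_case, n_ctrl = int(is_case.sum()), int(is_ctrl.sum())
    se = np.array([(z[is_case] >= t).mean() for t in thresholds])
    sp = np.array([(z[is_ctrl] < t).mean() for t in thresholds])

    # descending threshold order walks the curve from (0,0) to (1,1) with
    # se and fpr jointly non-decreasing, which keeps vertices with tied fpr
    # in curve order for the trapezoid rule
    fpr = 1.0 - sp
    auc = float(np.trapezoid(se[::-1], fpr[::-1]))

    j = se + sp - 1.0
    best_idx = int(np.flatnonzero(j >= j.max() - 1e-12)[0])  # lowest threshold on ties
    best_t = thresholds[best_idx]
    return ROCResult(
        thresholds=sign * thresholds if sign > 0 else np.sort(sign * thresholds),
        sensitivity=se,
        specificity=sp,
        auc=auc,
        best_cutoff=float(sign * best_t),
        best_sensitivity=float(se[best_idx]),
        best_specificity=float(sp[best_idx]),
        direction=direction,
    )


def variance_ratio_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F-test of variance equality (used to pick Student vs Welch)."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb == 0 or va == 0:
        return 0.0
    f = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    p = 2.0 * min(stats.f.cdf(f, dfa, dfb), stats.f.sf(f, dfa, dfb))
    return float(min(1.0, p))


def clinicopath_association(
    values_by_group: tuple[np.ndarray, np.ndarray] | None = None,
    counts_2x2: np.ndarray | list[list[int]] | None = None,
) -> float:
    """Association of a marker with a two-level clinical feature.

    Continuous values: unpaired t-test — Student's when a two-sided F-test
    of variance equality gives p > 0.05, Welch's otherwise. Counts:
    Fisher's exact two-sided p by hypergeometric enumeration. Exactly one
    input form must be given.
    """
    if (values_by_group is None) == (counts_2x2 is None):
        raise ValueError("give exactly one of values_by_group or counts_2x2")
    if counts_2x2 is not None:
        table = np.asarray(counts_2x2, dtype=int)
        if table.shape != (2, 2):
            raise ValueError("counts_2x2 must be a 2x2 table")
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    a, b = (np.asarray(v, dtype=float) for v in values_by_group)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    equal_var = variance_ratio_test(a, b) > 0.05
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.pvalue)
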