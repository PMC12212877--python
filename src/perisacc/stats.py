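"""Statistics for condition contrasts of reafferent responses.

Implements the modulation index (change - control)/(change + control), a
trial-level permutation test (10,000 repetitions by default, with exact
enumeration on small problems), time-resolved ROC discrimination with
bootstrap 95% confidence bands, an additivity analysis of combined
feature changes, proportion comparisons, and thin wrappers over the
standard rank-based tests (Wilcoxon signed-rank, rank-sum,
Kruskal-Wallis) and Pearson/Spearman correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps
from scipy.special import comb

__all__ = [
    "ModulationResult",
    "ROCTimecourse",
    "modulation_index",
    "permutation_test",
    "roc_auc",
    "roc_timecourse",
    "additivity_analysis",
    "proportion_elevated",
    "signed_rank",
    "rank_sum",
    "kruskal_wallis",
    "correlation",
]

EXACT_ENUMERATION_LIMIT = 20_000
SIGNIFICANCE_ALPHA = 0.05


@dataclass
class ModulationResult:
    """Change-vs-control contrast for one neuron."""

    neuron_id: int
    condition_pair: tuple[str, str]  # (change condition, control condition)
    r_change: float  # spikes/s
    r_control: float
    mi: float
    perm_p: float
    individually_significant: bool


@dataclass
class ROCTimecourse:
    """Area under the ROC curve per time bin with a 95% confidence band."""

    t: np.ndarray  # bin centers, ms
    auc: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_change: int
    n_control: int


def modulation_index(r_change: float, r_control: float) -> float:
    """(change - control) / (change + control); in [-1, 1].

    Defined as 0 (with a warning) when both inputs are zero.
    """
    if r_change < 0 or r_control < 0:
        raise ValueError("rates must be non-negative")
    total = r_change + r_control
    if total == 0:
        warnings.warn("modulation index of (0, 0) defined as 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    return (r_change - r_control) / total


def _mean_diff(a: np.ndarray, b: np.ndarray) -> float:
    return float(a.mean() - b.mean())


def permutation_test(
    values_a, values_b,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = 0,
) -> float:
    """Two-sided permutation test on the difference of group means.

    When the number of equal-size relabelings C(n_a+n_b, n_a) is at most
    20,000 the null distribution is enumerated exactly (the observed
    labeling counts, no +1 correction); otherwise ``n_perm`` Monte-Carlo
    permutations are drawn and p = (c + 1)/(n_perm + 1), which can never
    be zero.  Degenerate inputs (all values identical) give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    pool = np.concatenate([a, b])
    if np.all(pool == pool[0]):
        return 1.0
    observed = abs(_mean_diff(a, b))
    n_a, n = len(a), len(pool)

    if comb(n, n_a, exact=True) <= EXACT_ENUMERATION_LIMIT:
        total = 0
        extreme = 0
        # |mean_a - mean_b| is a monotone function of the group-A sum
        s_pool = pool.sum()
        for idx in combinations(range(n), n_a):
            s_a = pool[list(idx)].sum()
            stat = abs(s_a / n_a - (s_pool - s_a) / (n - n_a))
            total += 1
            if stat >= observed - 1e-12:
                extreme += 1
        return extreme / total

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # vectorized: permute indices in blocks
    count = 0
    block = 2000
    done = 0
    while done < n_perm:
        k = min(block, n_perm - done)
        keys = rng.random((k, n))
        order = np.argsort(keys, axis=1)
        perm = pool[order]
        stat = np.abs(perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1))
        count += int(np.count_nonzero(stat >= observed - 1e-12))
        done += k
    return (count + 1) / (n_perm + 1)


def roc_auc(values_control, values_change) -> float:
    """P(change > control) + 0.5 P(tie), Mann-Whitney with midranks.

    Values above 0.5 mean higher measures on change trials.
    """
    c = np.asarray(values_control, dtype=float)
    g = np.asarray(values_change, dtype=float)
    if len(c) == 0 or len(g) == 0:
        raise ValueError("both groups must be non-empty")
    ranks = sps.rankdata(np.concatenate([g, c]))
    r_g = ranks[: len(g)].sum()
    u = r_g - len(g) * (len(g) + 1) / 2.0
    return float(u / (len(g) * len(c)))


def _auc_from_counts(counts_c: np.ndarray, counts_g: np.ndarray) -> np.ndarray:
    """Vectorized AUC from integer-count histograms.

    ``counts_c``/``counts_g``: (..., n_levels) histograms over shared
    count levels.  Returns AUC of change vs control per leading index.
    """
    cum_c = np.cumsum(counts_c, axis=-1)
    below = np.concatenate(
        [np.zeros_like(cum_c[..., :1]), cum_c[..., :-1]], axis=-1)
    wins = (counts_g * below).sum(axis=-1) + 0.5 * (counts_g * counts_c).sum(axis=-1)
    n_c = counts_c.sum(axis=-1)
    n_g = counts_g.sum(axis=-1)
    return wins / (n_c * n_g)


def roc_timecourse(
    raster_control,
    raster_change,
    bin_width: float = 50.0,
    step: float = 10.0,
    n_boot: int = 2000,
    seed: int | np.random.Generator | None = 0,
    span: tuple[float, float] | None = None,
    min_trials: int = 5,
) -> ROCTimecourse:
    """Time-resolved ROC discrimination between change and control trials.

    Spike counts are taken per trial in sliding bins of ``bin_width`` ms
    stepped by ``step`` ms across the rasters' span; each bin yields an
    ROC AUC (change above control) with a 95% percentile-bootstrap
    confidence interval over ``n_boot`` resamples of trials within each
    group.
    """
    if raster_control.n_trials < min_trials or raster_change.n_trials < min_trials:
        raise ValueError(f"need at least {min_trials} trials per group")
    if raster_control.span != raster_change.span and span is None:
        raise ValueError("rasters must share a span (or pass one explicitly)")
    lo, hi = span or raster_control.span
    centers = np.arange(lo + bin_width / 2.0, hi - bin_width / 2.0 + 0.5 * step, step)
    edges_lo = centers - bin_width / 2.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def counts_matrix(raster):
        m = np.empty((raster.n_trials, len(centers)), dtype=np.int64)
        for i, s in enumerate(raster.trials):
            ss = np.sort(s)
            m[i] = (np.searchsorted(ss, edges_lo + bin_width, side="right")
                    - np.searchsorted(ss, edges_lo, side="left"))
        return m

    cc = counts_matrix(raster_control)
    cg = counts_matrix(raster_change)
    n_c, n_g = cc.shape[0], cg.shape[0]
    max_count = int(max(cc.max(initial=0), cg.max(initial=0))) + 1

    auc = np.empty(len(centers))
    ci_lo = np.empty(len(centers))
    ci_hi = np.empty(len(centers))
    for j in range(len(centers)):
        hist_c = np.bincount(cc[:, j], minlength=max_count).astype(float)
        hist_g = np.bincount(cg[:, j], minlength=max_count).astype(float)
        auc[j] = float(_auc_from_counts(hist_c, hist_g))
        if n_boot == 0:  # point estimates only
            ci_lo[j] = ci_hi[j] = auc[j]
            continue
        # bootstrap by multinomial resampling of the count histograms
        p_c = hist_c / n_c
        p_g = hist_g / n_g
        bs_c = rng.multinomial(n_c, p_c, size=n_boot).astype(float)
        bs_g = rng.multinomial(n_g, p_g, size=n_boot).astype(float)
        bs = _auc_from_counts(bs_c, bs_g)
        ci_lo[j], ci_hi[j] = np.percentile(bs, [2.5, 97.5])
        ci_lo[j] = min(ci_lo[j], auc[j])
        ci_hi[j] = max(ci_hi[j], auc[j])
    return ROCTimecourse(t=centers, auc=auc, ci_lo=ci_lo, ci_hi=ci_hi,
                         n_change=n_g, n_control=n_c)


def additivity_analysis(mi_sf, mi_shape, mi_combined) -> dict:
    """Summed single-feature indices vs the combined-change index.

    Computes per neuron the sum mi_sf + mi_shape (both against the shared
    control) and its Pearson correlation with mi_combined.
    """
    a = np.asarray(mi_sf, dtype=float)
    b = np.asarray(mi_shape, dtype=float)
    c = np.asarray(mi_combined, dtype=float)
    if not (len(a) == len(b) == len(c)):
        raise ValueError("index vectors must have equal length")
    if len(a) < 3:
        raise ValueError("correlation undefined for fewer than 3 neurons")
    summed = a + b
    r, p = sps.pearsonr(summed, c)
    return {"summed": summed, "r": float(r), "p": float(p)}


def proportion_elevated(results_a: list[ModulationResult],
                        results_b: list[ModulationResult] | None = None) -> dict:
    """Fraction of neurons with positive modulation index, per set.

    With two sets, the proportions are compared with a conditional exact
    two-proportion (Fisher) test.
    """
    def summarize(results):
        if not results:
            raise ValueError("empty result set")
        n_up = sum(1 for r in results if r.mi > 0)
        return n_up, len(results)

    n1, t1 = summarize(results_a)
    out = {"n_elevated": n1, "n_total": t1, "fraction": n1 / t1}
    if results_b is not None:
        n2, t2 = summarize(results_b)
        table = [[n1, t1 - n1], [n2, t2 - n2]]
        out.update({
            "n_elevated_b": n2, "n_total_b": t2, "fraction_b": n2 / t2,
            "p": float(sps.fisher_exact(table)[1]),
        })
    return out


# ---------------------------------------------------------------------------
# thin wrappers over standard rank-based tests (delegated, not re-derived)


def signed_rank(x, y=None) -> float:
    """Wilcoxon signed-rank p (x vs 0, or paired x vs y); all-zero diffs -> p = 1."""
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    if len(d) < 2:
        raise ValueError("need at least 2 observations")
    if np.all(d == 0):
        warnings.warn("all differences zero; signed-rank p defined as 1",
                      RuntimeWarning, stacklevel=2)
        return 1.0
    return float(sps.wilcoxon(d, zero_method="wilcox").pvalue)


def rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p."""
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    return float(sps.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def kruskal_wallis(*groups) -> float:
    """Kruskal-Wallis omnibus p across two or more groups."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    return float(sps.kruskal(*groups).pvalue)


def correlation(x, y, method: str = "pearson") -> tuple[float, float]:
    """(r, two-sided p) by Pearson (default) or Spearman correlation."""
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)
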