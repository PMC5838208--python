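"""Per-site and whole-distribution statistics.

The site-level machinery of the pipeline: pooled empirical CDFs and their
summaries (Cohen's d, skewness), Cramer's V on methylation-status contingency
tables, one-sample signed-rank tests against beta = 0.5, two-sample
(optionally location-shifted) rank-sum tests, the Hodges-Lehmann shift
estimate, Storey q-values and the Dice overlap index.

Rank tests are exact (full null distribution of the rank statistic, computed
once per sample-size configuration and cached) whenever the total number of
observations is at most ``EXACT_N_MAX`` and the data carry no ties; otherwise
a tie-corrected normal approximation with continuity correction is used.
Both scalar and vectorised (sites x samples) entry points share the same
cached null distributions, so a genome-wide scan and a single-site call give
identical p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import stats
from statsmodels.distributions.empirical_distribution import ECDF

#: Largest total observation count for which exact rank-null enumeration is used.
EXACT_N_MAX = 25

#: p-values are clipped into [P_CLIP, 1 - P_CLIP] before any normal-quantile
#: transform (keeps Stouffer z-scores finite downstream).
P_CLIP = 1e-15

Side = Literal["less", "greater"]

LOW, MEDIUM, HIGH = "low", "medium", "high"
STATUS_LEVELS = (LOW, MEDIUM, HIGH)


class DegenerateDataError(ValueError):
    """Raised when a statistic is undefined on the given data."""


def clip_p(p):
    """Clip p-values away from 0 and 1 (shared bound for all z transforms)."""
    return np.clip(p, P_CLIP, 1.0 - P_CLIP)


# ---------------------------------------------------------------------------
# exact null distributions of rank statistics (no ties), cached per size
# ---------------------------------------------------------------------------

@lru_cache(maxsize=128)
def _signed_rank_cdf_sf(n: int) -> tuple[np.ndarray, np.ndarray]:
    """CDF and survival function of the positive-rank sum W+ for n untied,
    nonzero differences under the symmetric null (2^n sign assignments)."""
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r else counts
        counts = counts + shifted
    pmf = counts / 2.0**n
    cdf = np.cumsum(pmf)
    sf = np.cumsum(pmf[::-1])[::-1]  # P(W+ >= w)
    return cdf, sf


@lru_cache(maxsize=128)
def _rank_sum_cdf_sf(n: int, m: int) -> tuple[np.ndarray, np.ndarray]:
    """CDF and survival function of the rank sum W of the first group (size n)
    among n+m untied observations (all C(n+m, n) rank splits equally likely).

    Indexed by W directly, W in [0, n*(n+m)] with mass only on the feasible
    range [n(n+1)/2, n(n+m) + ... ]; infeasible entries carry zero mass.
    """
    N = n + m
    max_w = n * N
    counts = np.zeros((n + 1, max_w + 1))
    counts[0, 0] = 1.0
    for r in range(1, N + 1):
        for k in range(min(n, r), 0, -1):
            counts[k, r:] += counts[k - 1, :-r]
    pmf = counts[n] / comb(N, n)
    cdf = np.cumsum(pmf)
    sf = np.cumsum(pmf[::-1])[::-1]
    return cdf, sf


# ---------------------------------------------------------------------------
# one-sample signed-rank test against beta = 0.5
# ---------------------------------------------------------------------------

def one_sample_test_vs_half(
    values: Sequence[float], side: Side, exact_n_max: int = EXACT_N_MAX
) -> tuple[float, bool]:
    """One-sided Wilcoxon signed-rank p-value for the site median versus 0.5.

    Values exactly equal to 0.5 are dropped (zero-difference convention).
    Returns ``(p, degenerate)``; ``degenerate`` is True when every value
    equals 0.5, in which case p = 1.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise DegenerateDataError("no non-missing values")
    d = v - 0.5
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 1.0, True
    absd = np.abs(d)
    ranks = stats.rankdata(absd)
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(absd).size != n
    if not has_ties and n <= exact_n_max:
        cdf, sf = _signed_rank_cdf_sf(n)
        w = int(round(w_plus))
        p = sf[w] if side == "greater" else cdf[w]
        return float(p), False
    # tie-corrected normal approximation with continuity correction
    mu = n * (n + 1) / 4.0
    tie_term = _tie_correction_signed(absd)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return 1.0, True
    sd = np.sqrt(var)
    if side == "greater":
        z = (w_plus - 0.5 - mu) / sd
        return float(stats.norm.sf(z)), False
    z = (w_plus + 0.5 - mu) / sd
    return float(stats.norm.cdf(z)), False


def _tie_correction_signed(absd: np.ndarray) -> float:
    _, cnt = np.unique(absd, return_counts=True)
    return float((cnt**3 - cnt).sum()) / 48.0


def methylation_status(
    values: Sequence[float], alpha: float = 0.025, family: str = "nonparametric"
) -> str:
    """Call a site low / medium / high methylated within one group.

    Low iff the one-sided test of location < 0.5 rejects at ``alpha``; high
    iff location > 0.5 rejects; medium otherwise. ``family`` selects the
    signed-rank test (default) or the one-sample t test — note that the exact
    signed-rank test cannot reject at alpha = 0.025 with fewer than six
    observations (its smallest attainable p at n = 5 is 1/32), so tiny groups
    need the t family for non-degenerate calls.
    """
    if family == "t":
        v = np.asarray(values, dtype=float)
        v = v[~np.isnan(v)]
        p_less = float(stats.ttest_1samp(v, 0.5, alternative="less").pvalue)
        p_greater = float(stats.ttest_1samp(v, 0.5, alternative="greater").pvalue)
    else:
        p_less, _ = one_sample_test_vs_half(values, "less")
        p_greater, _ = one_sample_test_vs_half(values, "greater")
    if p_less < alpha:
        return LOW
    if p_greater < alpha:
        return HIGH
    return MEDIUM


# ---------------------------------------------------------------------------
# two-sample (shifted) rank-sum test
# ---------------------------------------------------------------------------

def two_sample_shift_test(
    case: Sequence[float],
    ref: Sequence[float],
    shift: float = 0.0,
    side: Side = "greater",
    exact_n_max: int = EXACT_N_MAX,
) -> float:
    """Mann-Whitney p-value for H1: the case distribution exceeds the
    reference by more than ``shift`` (or falls below, for ``side='less'``).

    Case values are reduced by ``shift`` before ranking, so ``shift = 0``
    reproduces the plain rank-sum test. Exact when the total sample size is
    at most ``exact_n_max`` and there are no cross-group ties; tie-corrected
    normal approximation with continuity correction otherwise.
    """
    x = np.asarray(case, dtype=float)
    y = np.asarray(ref, dtype=float)
    x = x[~np.isnan(x)] - shift
    y = y[~np.isnan(y)]
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise DegenerateDataError("empty group in two-sample test")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n].sum())
    has_ties = np.unique(pooled).size != n + m
    if not has_ties and n + m <= exact_n_max:
        cdf, sf = _rank_sum_cdf_sf(n, m)
        wi = int(round(w))
        return float(sf[wi] if side == "greater" else cdf[wi])
    mu = n * (n + m + 1) / 2.0
    var = _rank_sum_var(n, m, pooled)
    if var <= 0:
        return 1.0
    sd = np.sqrt(var)
    if side == "greater":
        return float(stats.norm.sf((w - 0.5 - mu) / sd))
    return float(stats.norm.cdf((w + 0.5 - mu) / sd))


def _rank_sum_var(n: int, m: int, pooled: np.ndarray) -> float:
    N = n + m
    _, cnt = np.unique(pooled, return_counts=True)
    tie = float((cnt**3 - cnt).sum())
    return n * m / 12.0 * (N + 1 - tie / (N * (N - 1)))


# ---------------------------------------------------------------------------
# vectorised genome-wide scans (sites x samples matrices)
# ---------------------------------------------------------------------------

def rank_sum_test_rows(
    case_mat: np.ndarray,
    ref_mat: np.ndarray,
    shift: float = 0.0,
    side: Side = "greater",
    exact_n_max: int = EXACT_N_MAX,
) -> np.ndarray:
    """Row-wise ``two_sample_shift_test`` over a sites x samples split matrix.

    Rows with missing values or within-row ties fall back to the scalar path;
    complete untied rows share one cached exact null distribution, which makes
    the genome-wide scan linear in the number of sites.
    """
    case_mat = np.asarray(case_mat, dtype=float)
    ref_mat = np.asarray(ref_mat, dtype=float)
    n, m = case_mat.shape[1], ref_mat.shape[1]
    pooled = np.concatenate([case_mat - shift, ref_mat], axis=1)
    p = np.empty(pooled.shape[0])
    ok = ~np.isnan(pooled).any(axis=1)
    srt = np.sort(pooled[ok], axis=1)
    untied = np.ones(ok.sum(), dtype=bool)
    if srt.shape[1] > 1:
        untied = (np.diff(srt, axis=1) != 0).all(axis=1)
    fast = np.zeros_like(ok)
    fast[np.nonzero(ok)[0][untied]] = True
    if fast.any():
        sub = pooled[fast]
        order = np.argsort(sub, axis=1, kind="stable")
        ranks = np.empty_like(sub)
        rng = np.arange(1, n + m + 1, dtype=float)
        np.put_along_axis(ranks, order, np.broadcast_to(rng, sub.shape), axis=1)
        w = ranks[:, :n].sum(axis=1).round().astype(int)
        if n + m <= exact_n_max:
            cdf, sf = _rank_sum_cdf_sf(n, m)
            p[fast] = sf[w] if side == "greater" else cdf[w]
        else:
            mu = n * (n + m + 1) / 2.0
            sd = np.sqrt(n * m * (n + m + 1) / 12.0)
            if side == "greater":
                p[fast] = stats.norm.sf((w - 0.5 - mu) / sd)
            else:
                p[fast] = stats.norm.cdf((w + 0.5 - mu) / sd)
    slow = ~fast
    for i in np.nonzero(slow)[0]:
        p[i] = two_sample_shift_test(case_mat[i], ref_mat[i], shift, side, exact_n_max)
    return p


def signed_rank_test_rows(
    mat: np.ndarray, side: Side, exact_n_max: int = EXACT_N_MAX
) -> np.ndarray:
    """Row-wise ``one_sample_test_vs_half`` over a sites x samples matrix."""
    mat = np.asarray(mat, dtype=float)
    n = mat.shape[1]
    p = np.empty(mat.shape[0])
    d = mat - 0.5
    absd = np.abs(d)
    clean = ~np.isnan(mat).any(axis=1) & (d != 0.0).all(axis=1)
    srt = np.sort(absd[clean], axis=1)
    untied = np.ones(clean.sum(), dtype=bool)
    if n > 1:
        untied = (np.diff(srt, axis=1) != 0).all(axis=1)
    fast = np.zeros_like(clean)
    fast[np.nonzero(clean)[0][untied]] = True
    if fast.any():
        sub_abs = absd[fast]
        order = np.argsort(sub_abs, axis=1, kind="stable")
        ranks = np.empty_like(sub_abs)
        rng = np.arange(1, n + 1, dtype=float)
        np.put_along_axis(ranks, order, np.broadcast_to(rng, sub_abs.shape), axis=1)
        w = np.where(d[fast] > 0, ranks, 0.0).sum(axis=1).round().astype(int)
        if n <= exact_n_max:
            cdf, sf = _signed_rank_cdf_sf(n)
            p[fast] = sf[w] if side == "greater" else cdf[w]
        else:
            mu = n * (n + 1) / 4.0
            sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
            if side == "greater":
                p[fast] = stats.norm.sf((w - 0.5 - mu) / sd)
            else:
                p[fast] = stats.norm.cdf((w + 0.5 - mu) / sd)
    for i in np.nonzero(~fast)[0]:
        p[i], _ = one_sample_test_vs_half(mat[i], side, exact_n_max)
    return p


def methylation_status_rows(
    mat: np.ndarray, alpha: float = 0.025, family: str = "nonparametric"
) -> np.ndarray:
    """Vectorised low/medium/high status calls, one per row."""
    if family == "t":
        res_l = stats.ttest_1samp(mat, 0.5, axis=1, nan_policy="omit", alternative="less")
        res_g = stats.ttest_1samp(mat, 0.5, axis=1, nan_policy="omit", alternative="greater")
        p_less = np.asarray(res_l.pvalue)
        p_greater = np.asarray(res_g.pvalue)
    else:
        p_less = signed_rank_test_rows(mat, "less")
        p_greater = signed_rank_test_rows(mat, "greater")
    out = np.full(mat.shape[0], MEDIUM, dtype=object)
    out[p_less < alpha] = LOW
    out[(p_less >= alpha) & (p_greater < alpha)] = HIGH
    return out


# ---------------------------------------------------------------------------
# Hodges-Lehmann shift
# ---------------------------------------------------------------------------

def hodges_lehmann(case: Sequence[float], ref: Sequence[float]) -> float:
    """Median of all pairwise case-minus-reference differences.

    Positive values mean up-methylation in the case group.
    """
    x = np.asarray(case, dtype=float)
    y = np.asarray(ref, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise DegenerateDataError("empty group in Hodges-Lehmann estimate")
    return float(np.median(np.subtract.outer(x, y)))


def hodges_lehmann_rows(
    case_mat: np.ndarray, ref_mat: np.ndarray, chunk: int = 50_000
) -> np.ndarray:
    """Row-wise Hodges-Lehmann shift over sites x samples matrices.

    Missing values are handled pairwise-complete (a pair contributes only when
    both members are observed). Chunked to bound peak memory on genome-scale
    matrices.
    """
    case_mat = np.asarray(case_mat, dtype=float)
    ref_mat = np.asarray(ref_mat, dtype=float)
    out = np.empty(case_mat.shape[0])
    for lo in range(0, case_mat.shape[0], chunk):
        hi = min(lo + chunk, case_mat.shape[0])
        diffs = case_mat[lo:hi, :, None] - ref_mat[lo:hi, None, :]
        out[lo:hi] = np.nanmedian(diffs.reshape(hi - lo, -1), axis=1)
    return out


# ---------------------------------------------------------------------------
# pooled distribution summaries
# ---------------------------------------------------------------------------

@dataclass
class DistributionSummary:
    """Summary of one pooled sample of beta values: moments plus the ecdf."""

    n: int
    mean: float
    sd: float
    skewness: float
    ecdf: Callable[[np.ndarray], np.ndarray]


def pooled_ecdf(beta, group: str, sites: Sequence[str] | None = None) -> DistributionSummary:
    """Pool every non-missing beta value of one group (optionally restricted
    to a site subset) and summarise the resulting single sample.

    With fully observed data the Kaplan-Meier estimate of the CDF reduces to
    the plain empirical CDF, which is what is computed.
    """
    vals = beta.group_values(group)
    if sites is not None:
        idx = {s: i for i, s in enumerate(beta.site_ids)}
        rows = [idx[s] for s in sites]
        if not rows:
            raise DegenerateDataError("empty site subset")
        vals = vals[rows]
    pooled = vals[~np.isnan(vals)].ravel()
    if pooled.size == 0:
        raise DegenerateDataError("no non-missing values in group")
    return DistributionSummary(
        n=int(pooled.size),
        mean=float(pooled.mean()),
        sd=float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0,
        skewness=float(stats.skew(pooled)),
        ecdf=ECDF(pooled),
    )


def cohens_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Cohen's d effect size with the pooled standard deviation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise DegenerateDataError("Cohen's d needs at least two values per group")
    nx, ny = x.size, y.size
    s2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if s2 <= 0:
        raise DegenerateDataError("zero pooled variance")
    return float((x.mean() - y.mean()) / np.sqrt(s2))


# ---------------------------------------------------------------------------
# contingency tables and Cramer's V
# ---------------------------------------------------------------------------

@dataclass
class ContingencyTable:
    """Cross-tabulation of methylation status (e.g. REF rows x CASE columns)."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.counts.sum() <= 0:
            raise ValueError("empty table")


def cramers_v(table: ContingencyTable) -> tuple[float, float, float]:
    """Cramer's V association coefficient with its Pearson chi-square and p.

    V = sqrt(chi2 / (N * (min(r, c) - 1))).
    """
    counts = table.counts
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise DegenerateDataError("all-zero row or column in contingency table")
    chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)
    n = counts.sum()
    r, c = counts.shape
    v = float(np.sqrt(chi2 / (n * (min(r, c) - 1))))
    return v, float(chi2), float(p)


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def storey_pi0(
    p: np.ndarray, lambdas: np.ndarray | None = None, eval_lambda: float | None = None
) -> float:
    """Estimate the null proportion pi0 from a p-value sample.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on the grid
    lambda = 0.05, 0.10, ..., 0.95 is smoothed with a cubic least-squares fit
    (the df = 3 smoother) and read off at the largest grid point, then clipped
    into (0, 1].
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    if eval_lambda is None:
        eval_lambda = float(lambdas[-1])
    pi0_l = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    coef = np.polyfit(lambdas, pi0_l, deg=3)
    pi0 = float(np.polyval(coef, eval_lambda))
    return float(min(max(pi0, 1e-8), 1.0))


def storey_qvalues(p: Sequence[float], pi0: float | None = None) -> tuple[np.ndarray, float]:
    """Storey q-values: q_(i) = pi0 * m * p_(i) / i with running-minimum
    monotonisation from the largest p downward. With pi0 forced to 1 this is
    exactly Benjamini-Hochberg."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise DegenerateDataError("empty p-value list")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values outside [0, 1]")
    if pi0 is None:
        pi0 = 1.0 if p.size < 20 else storey_pi0(p)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, float(pi0)


def dice_index(a: set, b: set) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); zero when both sets are empty."""
    if not a and not b:
        return 0.0
    return 2.0 * len(set(a) & set(b)) / (len(a) + len(b))
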