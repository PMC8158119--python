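"""Nonparametric and regression statistics for small two-arm trials.

From-scratch implementations of the procedures a small randomized trial
with count outcomes needs: the Wilcoxon rank-sum test (exact permutation
distribution under mid-ranks, or tie-corrected normal approximation with
continuity correction), the Pearson chi-square test for a 2x2 table,
Pearson correlation, ordinary least-squares regression, per-arm summary
tables, and the standard two-sample normal-theory sample-size formula.

Distribution tail areas come from scipy; every test statistic and
enumeration is computed here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

#: Exact rank-sum enumeration is used automatically up to this pooled size.
EXACT_THRESHOLD = 20


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample or contingency test."""

    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    exact: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value out of range: {self.p_value}")


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit: coefficients, standard errors, t statistics, p-values, R^2."""

    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    r_squared: float
    residual_sd: float
    n: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.coef, "se": self.se,
                             "t": self.t, "p": self.p},
                            index=pd.Index(self.names, name="term"))


# -- Wilcoxon rank-sum ----------------------------------------------------

def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


@lru_cache(maxsize=256)
def _rank_sum_distribution(doubled_ranks: tuple[int, ...], n1: int):
    """Counts of each doubled rank-sum over all C(N, n1) group assignments.

    Ranks are doubled so mid-ranks (half-integers under ties) become
    integers; a subset-sum dynamic program counts assignments.  Returns
    (sums offset base, counts array, total).
    """
    total_sum = sum(doubled_ranks)
    # ways[k][s] = number of k-subsets of the first i items with doubled sum s
    ways = [np.zeros(total_sum + 1, dtype=object) for _ in range(n1 + 1)]
    ways[0][0] = 1
    for r in doubled_ranks:
        for k in range(n1, 0, -1):
            shifted = np.zeros(total_sum + 1, dtype=object)
            shifted[r:] = ways[k - 1][:total_sum + 1 - r]
            ways[k] = ways[k] + shifted
    counts = ways[n1]
    total = math.comb(len(doubled_ranks), n1)
    return counts, total


def wilcoxon_rank_sum(x, y, mode: str = "auto",
                      continuity: bool = True) -> TestResult:
    """Two-sided Wilcoxon rank-sum test on two independent samples.

    The statistic is W, the mid-rank sum of the first sample.  Exact mode
    enumerates every assignment of the observed (tied) ranks to the two
    groups and sums the probability of rank sums at least as far from the
    null mean n1(N+1)/2 as observed, in both tails.  Normal mode uses the
    tie-corrected variance with an optional 0.5 continuity correction.
    ``auto`` picks exact when n1 + n2 <= EXACT_THRESHOLD.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    N = n1 + n2
    ranks = _midranks(np.concatenate([x, y]))
    w_obs = float(ranks[:n1].sum())
    mean_w = n1 * (N + 1) / 2.0
    if mode not in ("auto", "exact", "normal"):
        raise ValidationError(f"unknown rank-sum mode {mode!r}")
    use_exact = mode == "exact" or (mode == "auto" and N <= EXACT_THRESHOLD)
    if use_exact:
        doubled = tuple(int(round(2 * r)) for r in ranks)
        counts, total = _rank_sum_distribution(doubled, n1)
        dev = abs(2 * w_obs - 2 * mean_w)
        sums = np.arange(counts.size)
        extreme = np.abs(sums - 2 * mean_w) >= dev - 1e-9
        p = float(sum(counts[extreme]) / total)
        return TestResult(w_obs, min(p, 1.0), "wilcoxon-rank-sum (exact)",
                          (n1, n2), exact=True)
    # tie-corrected normal approximation
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts ** 3) - tie_counts).sum())
    var_w = n1 * n2 * (N + 1) / 12.0 - n1 * n2 * tie_term / (12.0 * N * (N - 1))
    if var_w <= 0:  # all observations identical
        return TestResult(w_obs, 1.0, "wilcoxon-rank-sum (normal)", (n1, n2))
    diff = w_obs - mean_w
    cc = 0.5 if continuity else 0.0
    z = (abs(diff) - cc) / math.sqrt(var_w)
    p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
    return TestResult(w_obs, p, "wilcoxon-rank-sum (normal)", (n1, n2))


# -- chi-square -----------------------------------------------------------

def chi_square_2x2(a: int, b: int, c: int, d: int,
                   yates: bool = False) -> TestResult:
    """Pearson chi-square test (1 df) for the 2x2 table [[a, b], [c, d]].

    Yates continuity correction is off by default, matching the convention
    that reproduces the published fertilization-rate p-values.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValidationError(f"counts must be non-negative integers, got {(a, b, c, d)}")
    n = a + b + c + d
    margins = [a + b, c + d, a + c, b + d]
    if any(mgn == 0 for mgn in margins):
        raise ValidationError(f"all table margins must be positive, got {margins}")
    dev = abs(a * d - b * c)
    if yates:
        dev = max(0.0, dev - n / 2.0)
    chi2 = n * dev ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(sps.chi2.sf(chi2, 1))
    return TestResult(chi2, p, "chi-square (Yates)" if yates else "chi-square",
                      (a + b, c + d))


# -- correlation and regression -------------------------------------------

def pearson_correlation(x, y) -> TestResult:
    """Pearson r with its two-sided t-based p-value (n >= 3 pairs)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("paired samples must have equal length")
    n = x.size
    if n < 3:
        raise ValidationError("correlation requires at least 3 pairs")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValidationError("correlation undefined for zero-variance input")
    r = float(((x - x.mean()) * (y - y.mean())).sum() / ((n - 1) * sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return TestResult(r, 0.0, "pearson", (n,))
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = float(2 * sps.t.sf(abs(t), n - 2))
    return TestResult(r, p, "pearson", (n,))


def linear_regression(y, X, names: list[str] | None = None,
                      add_intercept: bool = True) -> RegressionFit:
    """Ordinary least squares of y on the columns of X.

    The design matrix is intercept-augmented by default and must be full
    rank; rank deficiency raises an error naming the offending columns.
    Standard errors come from the unbiased residual variance.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, k = X.shape
    if names is None:
        names = [f"x{j}" for j in range(k)]
    if add_intercept:
        X = np.column_stack([np.ones(n), X])
        names = ["intercept"] + list(names)
    p = X.shape[1]
    if n < p + 1:
        raise ValidationError(f"need at least {p + 1} rows for {p} coefficients, got {n}")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name columns that do not increase the rank when added left-to-right
        bad = []
        r = 0
        for j in range(p):
            rj = np.linalg.matrix_rank(X[:, :j + 1])
            if rj == r:
                bad.append(names[j])
            r = rj
        raise ValidationError(f"design matrix is rank deficient; collinear columns: {bad}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - p
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2 * sps.t.sf(np.abs(t), dof)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    return RegressionFit(tuple(names), beta, se, t, np.asarray(pvals),
                         r2, math.sqrt(s2), n)


# -- summary tables -------------------------------------------------------

def group_summary(table: pd.DataFrame, variables: list[str],
                  by: str = "arm", mode: str = "auto") -> pd.DataFrame:
    """Mean +/- SD per arm with rank-sum p-values, one row per variable.

    SD uses the n-1 denominator; the formatted column is "x.xx +/- y.yy".
    """
    if by not in table.columns:
        raise ValidationError(f"grouping column {by!r} not in table")
    arms = sorted(table[by].unique())
    if len(arms) != 2:
        raise ValidationError(f"expected exactly two arms, got {arms}")
    rows = []
    for var in variables:
        if var not in table.columns:
            raise ValidationError(f"unknown variable {var!r}")
        g0 = table.loc[table[by] == arms[0], var].dropna().to_numpy(float)
        g1 = table.loc[table[by] == arms[1], var].dropna().to_numpy(float)
        res = wilcoxon_rank_sum(g0, g1, mode=mode)
        rows.append({
            "variable": var,
            arms[0]: f"{g0.mean():.2f} ± {g0.std(ddof=1):.2f}",
            arms[1]: f"{g1.mean():.2f} ± {g1.std(ddof=1):.2f}",
            "p_value": res.p_value,
            "method": res.method,
        })
    return pd.DataFrame(rows).set_index("variable")


# -- sample size ----------------------------------------------------------

@dataclass(frozen=True)
class SampleSizeInputs:
    """Inputs to the two-sample normal-theory sample-size formula."""

    z_alpha_half: float = 1.96
    z_beta: float = 0.8416
    sigma: float = 1.0
    delta: float = 1.0
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")
        if self.delta == 0:
            raise ValidationError("delta must be nonzero")
        if not (0.0 <= self.dropout < 1.0):
            raise ValidationError("dropout must be in [0, 1)")


def sample_size(inputs: SampleSizeInputs) -> tuple[int, int]:
    """Per-group n = ceil(2 (z_a/2 + z_b)^2 sigma^2 / delta^2), then inflated
    by 1 / (1 - dropout).  Returns (unadjusted, inflated)."""
    raw = 2.0 * (inputs.z_alpha_half + inputs.z_beta) ** 2 \
        * inputs.sigma ** 2 / inputs.delta ** 2
    unadjusted = math.ceil(raw - 1e-12)
    inflated = math.ceil(unadjusted / (1.0 - inputs.dropout) - 1e-12)
    return unadjusted, inflated


# -- small enumeration oracle (used by the test suite) ---------------------

def exact_rank_sum_p_by_enumeration(x, y) -> float:
    """Independent oracle: brute-force itertools enumeration of the exact
    two-sided rank-sum p-value.  Exponential; intended for pooled n <= 12."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, N = x.size, x.size + y.size
    ranks = _midranks(np.concatenate([x, y]))
    mean_w = n1 * (N + 1) / 2.0
    dev = abs(ranks[:n1].sum() - mean_w)
    hits = total = 0
    for comb in itertools.combinations(range(N), n1):
        total += 1
        if abs(ranks[list(comb)].sum() - mean_w) >= dev - 1e-9:
            hits += 1
    return hits / total
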