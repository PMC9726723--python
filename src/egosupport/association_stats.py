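"""Bivariate association statistics for the support-network analysis.

Implements the inferential toolkit the analysis plan calls for:

* Welch's unequal-variance t-test (raw samples or printed summaries),
* OLS with cluster-robust (sandwich) standard errors for tie-level
  predictors clustered within egos,
* Pearson chi-square with an optional Fisher-exact fallback for sparse 2x2
  tables,
* Katz log-scale confidence intervals for the risk ratio,
* Cornfield's approximate-exact confidence limits for the odds ratio of a
  2x2 table, with the classical 1/2 continuity correction.

Cornfield's method fits, for a candidate odds ratio ``psi`` and the
observed margins, the exposed-case cell A(psi) solving

    psi = A * D / (B * C),   B = n1 - A,  C = m1 - A,  D = m0 - n1 + A,

with variance V(A) = (1/A + 1/B + 1/C + 1/D)^-1, and takes as limits the
psi at the cells solving A = a -/+ cc -/+ z * sqrt(V(A)) (cc is an optional
1/2 continuity correction, off by default to match the convention of the
standard epidemiological packages).  The limits are found by the classical
fixed-point iteration; when a table has a cell at or near its margin the
iteration for the *upper* limit does not converge — the quadratic
approximation degenerates there — and that limit is reported as unbounded,
as classical implementations do.  A non-convergent lower limit falls back
to exact bisection of the same equation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["TwoByTwoTable", "AssociationResult", "welch_t_test",
           "welch_from_summary", "cluster_robust_ols", "pearson_chi_square",
           "risk_ratio_katz", "odds_ratio_cornfield"]


@dataclass(frozen=True)
class TwoByTwoTable:
    """Cell counts for an exposure x outcome table.

    ``a``: exposed & outcome+, ``b``: exposed & outcome-,
    ``c``: unexposed & outcome+, ``d``: unexposed & outcome-.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")
        if self.total < 1:
            raise ValueError("empty 2x2 table")

    @property
    def n1(self) -> int:  # exposed row margin
        return self.a + self.b

    @property
    def n0(self) -> int:  # unexposed row margin
        return self.c + self.d

    @property
    def m1(self) -> int:  # outcome+ column margin
        return self.a + self.c

    @property
    def m0(self) -> int:  # outcome- column margin
        return self.b + self.d

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class AssociationResult:
    """Estimate, interval, test statistic and p-value with a method label."""

    estimate: float
    ci_lower: float
    ci_upper: float
    statistic: float
    df: float
    p_value: float
    method: str
    alpha: float = 0.05
    n: int | None = None
    upper_unbounded: bool = False


# ---------------------------------------------------------------------------
# Welch t-test


def welch_from_summary(mean1, se1, n1, mean2, se2, n2,
                       alpha: float = 0.05) -> AssociationResult:
    """Welch's unequal-variance t-test from group summaries (mean, SE, n).

    t = (mean1 - mean2) / sqrt(se1^2 + se2^2) with Satterthwaite degrees of
    freedom (se1^2 + se2^2)^2 / (se1^4/(n1-1) + se2^4/(n2-1)).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = se1 ** 2 + se2 ** 2
    if pooled <= 0:
        raise ValueError("degenerate input: zero pooled standard error")
    diff = mean1 - mean2
    se = math.sqrt(pooled)
    t = diff / se
    df = pooled ** 2 / (se1 ** 4 / (n1 - 1) + se2 ** 4 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return AssociationResult(estimate=diff, ci_lower=diff - tcrit * se,
                             ci_upper=diff + tcrit * se, statistic=t, df=df,
                             p_value=float(p), method="welch_t", alpha=alpha,
                             n=int(n1 + n2))


def welch_t_test(x, y, alpha: float = 0.05) -> AssociationResult:
    """Welch's t-test from two raw samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    se1 = x.std(ddof=1) / math.sqrt(x.size)
    se2 = y.std(ddof=1) / math.sqrt(y.size)
    return welch_from_summary(float(x.mean()), float(se1), x.size,
                              float(y.mean()), float(se2), y.size, alpha=alpha)


# ---------------------------------------------------------------------------
# Cluster-robust OLS


def cluster_robust_ols(y, X, cluster, names=None, add_intercept: bool = True,
                       alpha: float = 0.05):
    """OLS with ego-cluster-robust (sandwich) standard errors.

    The variance is ``c * (X'X)^-1 (sum_g s_g s_g') (X'X)^-1`` with cluster
    score sums ``s_g = X_g' u_g`` and the small-sample factor
    ``c = G/(G-1) * (N-1)/(N-K)``; inference uses the t distribution with
    G - 1 degrees of freedom (G = number of clusters).  With singleton
    clusters this reduces exactly to HC1 heteroskedasticity-robust errors.

    Returns a list of :class:`AssociationResult`, one per coefficient, in
    column order (intercept first when ``add_intercept``).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = y.size
    if X.shape[0] != n or len(cluster) != n:
        raise ValueError("y, X and cluster must have matching lengths")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    names = list(names)
    if add_intercept:
        X = np.column_stack([np.ones(n), X])
        names = ["intercept"] + names
    k = X.shape[1]

    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # name the columns past the numerical rank under pivoted QR
        from scipy.linalg import qr
        _, _, piv = qr(X, mode="economic", pivoting=True)
        bad = sorted(piv[rank:])
        raise ValueError("design matrix is rank deficient; collinear columns: "
                         + ", ".join(names[j] for j in bad))

    codes, _ = pd_factorize(cluster)
    G = int(codes.max()) + 1
    if G < 2:
        raise ValueError("cluster-robust inference needs at least 2 clusters")
    if n <= k:
        raise ValueError("more parameters than observations")

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    u = y - X @ beta
    xtx_inv = np.linalg.inv(X.T @ X)
    scores = X * u[:, None]
    meat = np.zeros((k, k))
    for g in range(G):
        s_g = scores[codes == g].sum(axis=0)
        meat += np.outer(s_g, s_g)
    corr = (G / (G - 1)) * ((n - 1) / (n - k))
    V = corr * xtx_inv @ meat @ xtx_inv
    se = np.sqrt(np.clip(np.diag(V), 0.0, None))  # guard tiny negative round-off
    df = G - 1
    tcrit = stats.t.ppf(1 - alpha / 2, df)

    results = []
    for j in range(k):
        t = beta[j] / se[j] if se[j] > 0 else math.inf
        p = 2.0 * stats.t.sf(abs(t), df)
        results.append(AssociationResult(
            estimate=float(beta[j]), ci_lower=float(beta[j] - tcrit * se[j]),
            ci_upper=float(beta[j] + tcrit * se[j]), statistic=float(t),
            df=float(df), p_value=float(p),
            method=f"ols_cluster_robust:{names[j]}", alpha=alpha, n=n))
    return results


def pd_factorize(values):
    """Integer codes for cluster labels (stable order of first appearance)."""
    import pandas as pd
    codes, uniques = pd.factorize(np.asarray(values), sort=False)
    if (codes < 0).any():
        raise ValueError("cluster labels contain missing values")
    return codes, uniques


# ---------------------------------------------------------------------------
# Chi-square / Fisher


def pearson_chi_square(table, fisher_fallback: bool = True,
                       alpha: float = 0.05) -> AssociationResult:
    """Pearson chi-square test of independence on an r x c count table.

    On a 2x2 table with any expected cell below 5 and ``fisher_fallback``
    on, reports Fisher's exact p instead (labelled ``fisher_exact``).
    No continuity correction is applied to the chi-square itself.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if obs.sum() < 1:
        raise ValueError("degenerate input: all-zero table")
    # drop all-zero rows/columns so expected counts are well defined
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        # no variation left: independence trivially not rejected
        return AssociationResult(estimate=math.nan, ci_lower=math.nan,
                                 ci_upper=math.nan, statistic=0.0, df=0.0,
                                 p_value=1.0, method="pearson_chi2",
                                 alpha=alpha, n=int(obs.sum()))
    res = stats.chi2_contingency(obs, correction=False)
    if (fisher_fallback and obs.shape == (2, 2)
            and (res.expected_freq < 5).any()):
        p = stats.fisher_exact(obs.astype(int))[1]
        return AssociationResult(estimate=math.nan, ci_lower=math.nan,
                                 ci_upper=math.nan, statistic=math.nan,
                                 df=math.nan, p_value=float(p),
                                 method="fisher_exact", alpha=alpha,
                                 n=int(obs.sum()))
    return AssociationResult(estimate=math.nan, ci_lower=math.nan,
                             ci_upper=math.nan, statistic=float(res.statistic),
                             df=float(res.dof), p_value=float(res.pvalue),
                             method="pearson_chi2", alpha=alpha,
                             n=int(obs.sum()))


# ---------------------------------------------------------------------------
# Risk ratio (Katz)


def risk_ratio_katz(t: TwoByTwoTable, alpha: float = 0.05) -> AssociationResult:
    """Risk ratio with the Katz log-scale confidence interval.

    RR = (a/n1) / (c/n0);
    CI = exp(ln RR +/- z * sqrt(b/(a*n1) + d/(c*n0))).
    """
    z = stats.norm.ppf(1 - alpha / 2)
    if t.n1 == 0 or t.n0 == 0:
        raise ValueError("both exposure groups must be non-empty")
    if t.a == 0 and t.c == 0:
        raise ValueError("no outcome events in either group")
    if t.c == 0:
        return AssociationResult(estimate=math.inf, ci_lower=math.nan,
                                 ci_upper=math.inf, statistic=math.nan,
                                 df=math.nan, p_value=math.nan,
                                 method="katz_rr:infinite", alpha=alpha,
                                 n=t.total, upper_unbounded=True)
    rr = (t.a / t.n1) / (t.c / t.n0)
    if t.a == 0:
        # zero estimate: one-sided upper bound from the one-event correction
        upper = math.exp(z * math.sqrt(1 / t.n1 + t.d / (t.c * t.n0)))
        return AssociationResult(estimate=0.0, ci_lower=0.0, ci_upper=upper,
                                 statistic=math.nan, df=math.nan,
                                 p_value=math.nan, method="katz_rr:zero",
                                 alpha=alpha, n=t.total)
    se_log = math.sqrt(t.b / (t.a * t.n1) + t.d / (t.c * t.n0))
    log_rr = math.log(rr)
    return AssociationResult(estimate=rr,
                             ci_lower=math.exp(log_rr - z * se_log),
                             ci_upper=math.exp(log_rr + z * se_log),
                             statistic=log_rr / se_log if se_log > 0 else math.inf,
                             df=math.nan,
                             p_value=2.0 * stats.norm.sf(abs(log_rr / se_log))
                             if se_log > 0 else 0.0,
                             method="katz_rr", alpha=alpha, n=t.total)


# ---------------------------------------------------------------------------
# Cornfield odds-ratio interval


def _cell_bounds(t: TwoByTwoTable):
    """Open admissible interval for the fitted exposed-case cell A."""
    return max(0.0, float(t.n1 - t.m0)), min(float(t.n1), float(t.m1))


def _variance(A: float, t: TwoByTwoTable) -> float:
    B = t.n1 - A
    C = t.m1 - A
    D = t.m0 - t.n1 + A
    if min(A, B, C, D) <= 0:
        return 0.0
    return 1.0 / (1.0 / A + 1.0 / B + 1.0 / C + 1.0 / D)


def _psi_at(A: float, t: TwoByTwoTable) -> float:
    B = t.n1 - A
    C = t.m1 - A
    D = t.m0 - t.n1 + A
    if B <= 0 or C <= 0:
        return math.inf
    return A * max(D, 0.0) / (B * C)


def _limit_fixed_point(t, target: float, sign: float, z: float,
                       tol: float, max_iter: int):
    """Classical Cornfield iteration A_{k+1} = target + sign*z*sqrt(V(A_k)).

    Returns (A, converged).  ``target`` is a -/+ cc; ``sign`` is -1 for the
    lower limit, +1 for the upper.
    """
    lo, hi = _cell_bounds(t)
    margin = 1e-9 * max(1.0, hi - lo)
    A = min(max(target - sign * 0.5, lo + margin), hi - margin)
    for _ in range(max_iter):
        A_next = target + sign * z * math.sqrt(_variance(A, t))
        A_next = min(max(A_next, lo + margin), hi - margin)
        if abs(A_next - A) <= tol * max(1.0, abs(A)):
            return A_next, True
        A = A_next
    return A, False


def _limit_bisection(t, target: float, sign: float, z: float,
                     tol: float) -> float | None:
    """Exact root of A - target - sign*z*sqrt(V(A)) = 0 within the bounds."""
    lo, hi = _cell_bounds(t)
    margin = 1e-12 * max(1.0, hi - lo)
    if sign < 0:
        L, H = lo + margin, min(target, hi - margin)
    else:
        L, H = max(target, lo + margin), hi - margin
    if L >= H:
        return None

    def f(A):
        return (target - A) + sign * z * math.sqrt(_variance(A, t))

    fL, fH = f(L), f(H)
    if fL * fH > 0:
        return None
    for _ in range(500):
        M = 0.5 * (L + H)
        fM = f(M)
        if fM == 0.0 or (H - L) < tol:
            return M
        if fL * fM <= 0:
            H, fH = M, fM
        else:
            L, fL = M, fM
    return 0.5 * (L + H)


def odds_ratio_cornfield(t: TwoByTwoTable, alpha: float = 0.05,
                         continuity_correction: float = 0.0,
                         cap: float = 1e6, tol: float = 1e-8,
                         max_iter: int = 500) -> AssociationResult:
    """Cross-product odds ratio with Cornfield's confidence limits.

    Limits come from the classical fixed-point iteration on the fitted
    exposed-case cell (see module docstring).  A non-convergent or
    above-``cap`` upper limit is flagged unbounded; a non-convergent lower
    limit is re-solved exactly by bisection.
    """
    if t.n1 == 0 or t.n0 == 0 or t.m1 == 0 or t.m0 == 0:
        raise ValueError("all four margins must be positive")
    z = stats.norm.ppf(1 - alpha / 2)
    cc = float(continuity_correction)
    or_point = (t.a * t.d / (t.b * t.c)) if t.b > 0 and t.c > 0 else math.inf

    # Lower limit
    A_low, ok = _limit_fixed_point(t, t.a - cc, -1.0, z, tol, max_iter)
    if not ok:
        A_exact = _limit_bisection(t, t.a - cc, -1.0, z, tol)
        if A_exact is None:
            raise RuntimeError("Cornfield lower limit did not converge")
        A_low = A_exact
    lower = _psi_at(A_low, t)
    lo_bound, hi_bound = _cell_bounds(t)
    if A_low <= lo_bound + 1e-8 * max(1.0, hi_bound - lo_bound):
        lower = 0.0  # fitted cell pinned at its floor: no positive lower limit

    # Upper limit
    unbounded = False
    if not math.isfinite(or_point):
        upper = math.inf
        unbounded = True
    else:
        A_up, ok = _limit_fixed_point(t, t.a + cc, +1.0, z, tol, max_iter)
        upper = _psi_at(A_up, t) if ok else math.inf
        if not ok or upper > cap:
            upper = math.inf
            unbounded = True

    return AssociationResult(estimate=or_point, ci_lower=float(lower),
                             ci_upper=float(upper), statistic=math.nan,
                             df=math.nan, p_value=math.nan,
                             method="cornfield_or", alpha=alpha, n=t.total,
                             upper_unbounded=unbounded)
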