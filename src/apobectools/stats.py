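"""Exact small-sample nonparametric tests and effect sizes.

The exact paths enumerate the full null distribution with rational
arithmetic, so p-values are reported both as floats and as integer
numerator/denominator pairs:

* Mann-Whitney U — dynamic programming over the distribution of U
  (restricted-partition counts), denominator C(n1+n2, n1);
* Wilcoxon signed rank — subset-sum DP over the 2^n sign patterns;
* Fisher 2x2 — hypergeometric enumeration of all tables with the observed
  margins.

Ties fall back to the usual mid-rank normal approximations with tie
correction (flagged ``exact=False``).  Two-sided exact p-values are computed
by tail doubling, the convention under which small-sample results are
conventionally reported (e.g. p = 2/924 for complete separation at n=6 vs 6).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import UndefinedResultError, ValidationError

SIDEDNESS = ("two", "greater", "less")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    sidedness: str
    exact: bool
    p_exact: Optional[Fraction] = None  # rational p when computed exactly
    extra: dict = field(default_factory=dict)

    @property
    def p_numerator(self) -> Optional[int]:
        return self.p_exact.numerator if self.p_exact is not None else None

    @property
    def p_denominator(self) -> Optional[int]:
        return self.p_exact.denominator if self.p_exact is not None else None


def _check_sidedness(sidedness: str) -> None:
    if sidedness not in SIDEDNESS:
        raise ValidationError(f"sidedness must be one of {SIDEDNESS}, got {sidedness!r}")


# ---------------------------------------------------------------------------
# Mann-Whitney U


def mwu_null_counts(n1: int, n2: int) -> list[int]:
    """Number of group labelings yielding each U value, for U = 0..n1*n2.

    The generating function of the null U distribution is the Gaussian
    binomial coefficient [n1+n2 choose n1]_q = prod_{i=1..n1}
    (1 - q^(n2+i)) / (1 - q^i); each factor pair is applied by a prefix-sum
    recurrence (the 1/(1-q^i) part) followed by a shifted subtraction, with
    exact integer coefficients throughout.  Intermediate partial products are
    themselves Gaussian binomials of degree <= n1*n2, so truncation is safe.
    """
    deg = n1 * n2
    poly = [1] + [0] * deg
    for i in range(1, n1 + 1):
        acc = [0] * (deg + 1)
        for u in range(deg + 1):
            acc[u] = poly[u]
            if u >= i:
                acc[u] += acc[u - i]
        shift = n2 + i
        poly = [acc[u] - (acc[u - shift] if u >= shift else 0) for u in range(deg + 1)]
    return poly


def mann_whitney_u_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    """U statistic of ``x`` relative to ``y`` (pairs with x > y, ties = 1/2)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def exact_u_pvalue(u: float, n1: int, n2: int, sidedness: str = "two") -> Fraction:
    """Exact p-value from the null distribution of U (no ties).

    Two-sided p is the doubled smaller tail: min(1, 2 P(U <= min(u, n1 n2 - u))).
    """
    _check_sidedness(sidedness)
    counts = mwu_null_counts(n1, n2)
    total = math.comb(n1 + n2, n1)
    ui = int(round(u))
    if sidedness == "less":
        num = sum(counts[: ui + 1])
    elif sidedness == "greater":
        num = sum(counts[ui:])
    else:
        lo = min(ui, n1 * n2 - ui)
        num = 2 * sum(counts[: lo + 1])
    return min(Fraction(num, total), Fraction(1))


def mann_whitney_exact(
    x: Sequence[float], y: Sequence[float], sidedness: str = "two"
) -> TestResult:
    """Mann-Whitney U test, exact when the pooled sample is tie-free.

    With ties, mid-ranks and the tie-corrected normal approximation are used
    and the result is flagged ``exact=False``.
    """
    _check_sidedness(sidedness)
    x, y = list(map(float, x)), list(map(float, y))
    if not x or not y:
        raise ValidationError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    u = mann_whitney_u_statistic(x, y)
    pooled = x + y
    has_ties = len(set(pooled)) < len(pooled)
    if not has_ties and n1 + n2 <= 60:
        p = exact_u_pvalue(u, n1, n2, sidedness)
        return TestResult(
            statistic=u,
            p_value=float(p),
            method="mann-whitney-exact",
            sidedness=sidedness,
            exact=True,
            p_exact=p,
        )
    # mid-rank normal approximation with tie correction
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    sigma = math.sqrt(sigma2)
    if sigma == 0:
        raise UndefinedResultError("zero variance: all observations identical")
    if sidedness == "greater":
        p_val = float(sps.norm.sf((u - mu - 0.5) / sigma))
    elif sidedness == "less":
        p_val = float(sps.norm.cdf((u - mu + 0.5) / sigma))
    else:
        z = (abs(u - mu) - 0.5) / sigma
        p_val = float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))
    return TestResult(
        statistic=u,
        p_value=p_val,
        method="mann-whitney-normal-approx",
        sidedness=sidedness,
        exact=False,
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed rank


def wilcoxon_signed_rank(
    differences: Sequence[float],
    sidedness: str = "two",
    zero_policy: str = "wilcoxon",
    exact_max_n: int = 25,
) -> TestResult:
    """Signed-rank test of paired differences against zero.

    ``zero_policy='wilcoxon'`` drops zero differences before ranking (the
    original procedure); ``'pratt'`` ranks zeros with the rest and then drops
    them.  The exact path enumerates all 2^n sign patterns by subset-sum DP
    and requires untied integer ranks and n <= ``exact_max_n``; otherwise the
    tie-corrected normal approximation is used.  The statistic reported is
    W+, the sum of ranks of the positive differences.
    """
    _check_sidedness(sidedness)
    if zero_policy not in ("wilcoxon", "pratt"):
        raise ValidationError(f"unknown zero_policy {zero_policy!r}")
    d = np.asarray(list(differences), dtype=float)
    if d.size == 0:
        raise ValidationError("no differences supplied")
    if np.all(d == 0):
        raise UndefinedResultError("all paired differences are zero")
    if zero_policy == "wilcoxon":
        d = d[d != 0]
        ranks = sps.rankdata(np.abs(d))
    else:  # pratt: rank including zeros, then drop them
        ranks_all = sps.rankdata(np.abs(d))
        keep = d != 0
        d, ranks = d[keep], ranks_all[keep]
    n = d.size
    w_plus = float(ranks[d > 0].sum())
    untied = len(set(np.abs(d))) == n
    integer_ranks = np.allclose(ranks, np.round(ranks))

    if untied and integer_ranks and n <= exact_max_n:
        rank_ints = [int(round(r)) for r in ranks]
        max_w = sum(rank_ints)
        dp = [0] * (max_w + 1)
        dp[0] = 1
        for r in rank_ints:
            for w in range(max_w, r - 1, -1):
                dp[w] += dp[w - r]
        total = 2**n
        wi = int(round(w_plus))
        if sidedness == "less":
            p = Fraction(sum(dp[: wi + 1]), total)
        elif sidedness == "greater":
            p = Fraction(sum(dp[wi:]), total)
        else:
            p = min(
                Fraction(1),
                2 * min(Fraction(sum(dp[: wi + 1]), total), Fraction(sum(dp[wi:]), total)),
            )
        p = min(p, Fraction(1))
        return TestResult(
            statistic=w_plus,
            p_value=float(p),
            method=f"wilcoxon-signed-rank-exact[{zero_policy}]",
            sidedness=sidedness,
            exact=True,
            p_exact=p,
            extra={"n": n},
        )

    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - float((tie_counts**3 - tie_counts).sum()) / 48.0
    sigma = math.sqrt(sigma2)
    if sigma == 0:
        raise UndefinedResultError("zero variance in signed-rank statistic")
    if sidedness == "greater":
        p_val = float(sps.norm.sf((w_plus - mu - 0.5) / sigma))
    elif sidedness == "less":
        p_val = float(sps.norm.cdf((w_plus - mu + 0.5) / sigma))
    else:
        z = (abs(w_plus - mu) - 0.5) / sigma
        p_val = float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))
    return TestResult(
        statistic=w_plus,
        p_value=p_val,
        method=f"wilcoxon-signed-rank-normal-approx[{zero_policy}]",
        sidedness=sidedness,
        exact=False,
        extra={"n": n},
    )


# ---------------------------------------------------------------------------
# Fisher exact


def fisher_exact_2x2(table, sidedness: str = "two") -> TestResult:
    """Fisher's exact test on a 2x2 contingency table.

    The two-sided p-value sums the probabilities of all tables (with the
    observed margins) whose point probability does not exceed the observed
    one — evaluated in exact rational arithmetic, so no floating-point
    tolerance is needed for the comparison.
    """
    _check_sidedness(sidedness)
    t = np.asarray(table, dtype=object)
    if t.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    if min(a, b, c, d) < 0:
        raise ValidationError("table entries must be nonnegative integers")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def point(ai: int) -> Fraction:
        return Fraction(math.comb(r1, ai) * math.comb(r2, c1 - ai), denom)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = point(a)
    if sidedness == "greater":
        p = sum((point(ai) for ai in range(a, hi + 1)), Fraction(0))
    elif sidedness == "less":
        p = sum((point(ai) for ai in range(lo, a + 1)), Fraction(0))
    else:
        p = sum((point(ai) for ai in range(lo, hi + 1) if point(ai) <= p_obs), Fraction(0))
    p = min(p, Fraction(1))
    if b * c > 0:
        odds = (a * d) / (b * c)
    else:
        odds = math.inf if a * d > 0 else math.nan
    return TestResult(
        statistic=odds,
        p_value=float(p),
        method="fisher-exact",
        sidedness=sidedness,
        exact=True,
        p_exact=p,
    )


# ---------------------------------------------------------------------------
# Spearman correlation (with optional pair bootstrap)


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    bootstrap: Optional[dict] = None,
) -> TestResult:
    """Spearman rank correlation with mid-ranks and a t-approximation p-value.

    ``bootstrap={'B': 1000, 'seed': 17}`` additionally resamples (x, y) pairs
    with replacement and reports the mean correlation and 95% percentile
    confidence interval across replicates; replicates in which either
    resampled margin is constant are dropped (and counted).  The analytic p
    is approximate and flagged as such in the method label when bootstrapping.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValidationError("Spearman correlation requires n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedResultError("constant input: rank correlation undefined")

    def _rho(xv, yv) -> float:
        rx, ry = sps.rankdata(xv), sps.rankdata(yv)
        rx = rx - rx.mean()
        ry = ry - ry.mean()
        return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))

    rho = _rho(x, y)
    if abs(rho) >= 1.0:
        p_val = 0.0
    else:
        tstat = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p_val = float(2.0 * sps.t.sf(abs(tstat), df=n - 2))
    extra: dict = {}
    method = "spearman-t-approx"
    if bootstrap is not None:
        B = int(bootstrap.get("B", 1000))
        rng = np.random.default_rng(bootstrap.get("seed", 0))
        reps = []
        dropped = 0
        for _ in range(B):
            idx = rng.integers(0, n, size=n)
            xb, yb = x[idx], y[idx]
            if np.all(xb == xb[0]) or np.all(yb == yb[0]):
                dropped += 1
                continue
            reps.append(_rho(xb, yb))
        if not reps:
            raise UndefinedResultError("every bootstrap replicate was degenerate")
        reps_arr = np.array(reps)
        extra = {
            "bootstrap_B": B,
            "bootstrap_dropped": dropped,
            "bootstrap_mean_r": float(reps_arr.mean()),
            "ci_low": float(np.percentile(reps_arr, 2.5)),
            "ci_high": float(np.percentile(reps_arr, 97.5)),
        }
        method = "spearman-bootstrap(p approximate)"
    return TestResult(
        statistic=rho,
        p_value=p_val,
        method=method,
        sidedness="two",
        exact=False,
        extra=extra,
    )


# ---------------------------------------------------------------------------
# Effect size


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Cohen's d with (n-1)-weighted pooled standard deviation."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 observations")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var <= 0:
        raise UndefinedResultError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))
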