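"""Inferential layer: group comparisons, correlations, pregnancy model.

Group comparisons use the Mann-Whitney U test.  The asymptotic variant
uses the normal approximation with tie-corrected variance and **no**
continuity correction (the convention of major commercial statistics
packages); the exact variant evaluates the permutation null of the
rank-sum over all group assignments, handling ties through midranks, via
a subset-sum dynamic program.  Spearman rank correlations, normality
checks (Shapiro-Wilk and Lilliefors-corrected Kolmogorov-Smirnov), and a
binary logistic pregnancy model adjusted for semen parameters, age, and
BMI complete the layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.tools.sm_exceptions import PerfectSeparationError


@dataclass
class TestResult:
    test: str
    statistic: float
    n: tuple[int, ...]
    p_value: float
    method: str = ""
    tie_corrected: bool = False
    degenerate: bool = False
    extra: dict = field(default_factory=dict)


@dataclass
class RegressionResult:
    outcome: str
    cn_variable: str
    table: pd.DataFrame  # coef, se, z, p per covariate
    covariates: tuple[str, ...]
    n: int
    converged: bool
    separation: bool = False
    llf: float = float("nan")

    def coefficient(self, name: str) -> float:
        return float(self.table.loc[name, "coef"])

    def p(self, name: str) -> float:
        return float(self.table.loc[name, "p"])


# ------------------------------------------------------------- descriptives


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float
    sd_defined: bool = True

    def to_row(self) -> dict:
        return {"n": self.n, "mean": self.mean, "sd": self.sd,
                "median": self.median, "min": self.min, "max": self.max}


def descriptive_summary(values: Sequence[float]) -> GroupSummary:
    """Mean, sample SD (n-1), median (midpoint for even n), and range."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("descriptive_summary needs at least one value")
    sd_defined = x.size > 1
    return GroupSummary(
        n=int(x.size),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if sd_defined else 0.0,
        median=float(np.median(x)),
        min=float(x.min()),
        max=float(x.max()),
        sd_defined=sd_defined,
    )


# ------------------------------------------------------------- Mann-Whitney


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _exact_ranksum_tail(ranks: np.ndarray, n_a: int, s_obs: float) -> tuple[float, float]:
    """P(S <= s_obs) and P(S >= s_obs) for the rank-sum of a random size-n_a
    subset, by dynamic programming over (doubled) midranks.

    Counts are exact in float64 up to combined n ~ 60 (far beyond the exact
    cap), since C(n, n/2) < 2^53 there.
    """
    r2 = np.round(ranks * 2).astype(np.int64)  # midranks are multiples of 0.5
    total = int(r2.sum())
    # dp[k][s] = number of size-k subsets with doubled-rank-sum s
    dp = np.zeros((n_a + 1, total + 1))
    dp[0, 0] = 1.0
    for r in r2:
        for k in range(n_a, 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    dist = dp[n_a]
    n_comb = dist.sum()
    s2 = int(round(s_obs * 2))
    lower = dist[: s2 + 1].sum() / n_comb
    upper = dist[s2:].sum() / n_comb
    return float(lower), float(upper)


def mann_whitney_u(
    group_a: Sequence[float],
    group_b: Sequence[float],
    method: str = "auto",
    exact_cap: int = 25,
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    The reported statistic is U for ``group_a`` (number of (a, b) pairs
    with a > b, ties counting 1/2).  ``method``:

    * ``"asymptotic"`` - normal approximation, tie-corrected variance,
      no continuity correction;
    * ``"exact"`` - full permutation null of the rank-sum (midranks), two-
      sided p = min(1, 2 * min(lower tail, upper tail));
    * ``"auto"`` - exact when the combined sample size is <= ``exact_cap``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    n_a, n_b = a.size, b.size
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([a, b])
    ranks = _midranks(combined)
    r_a = ranks[:n_a].sum()
    u_a = r_a - n_a * (n_a + 1) / 2.0
    n = n_a + n_b
    if np.all(combined == combined[0]):
        return TestResult("mann_whitney_u", float(u_a), (n_a, n_b), 1.0,
                          method="degenerate", degenerate=True)
    use_exact = method == "exact" or (method == "auto" and n <= exact_cap)
    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    if use_exact:
        lower, upper = _exact_ranksum_tail(ranks, n_a, r_a)
        p = min(1.0, 2.0 * min(lower, upper))
        meth = "exact"
    else:
        mu = n_a * n_b / 2.0
        tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
        var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            return TestResult("mann_whitney_u", float(u_a), (n_a, n_b), 1.0,
                              method="degenerate", degenerate=True)
        z = (u_a - mu) / math.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(z))
        meth = "asymptotic"
    return TestResult("mann_whitney_u", float(u_a), (n_a, n_b), float(p),
                      method=meth, tie_corrected=has_ties)


# ----------------------------------------------------------------- Spearman


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation (midranks for ties), two-sided t-approx p.

    Pairs with a missing value in either variable are dropped
    (pairwise-complete).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult("spearman", float("nan"), (int(x.size),), float("nan"),
                          method="degenerate", degenerate=True)
    rho, p = sps.spearmanr(x, y)
    return TestResult("spearman", float(rho), (int(x.size),), float(p), method="t-approx")


# ---------------------------------------------------------------- normality


def normality_tests(values: Sequence[float]) -> tuple[TestResult, TestResult]:
    """(Kolmogorov-Smirnov with Lilliefors correction, Shapiro-Wilk).

    Reported for distribution QC only; group comparisons stay
    non-parametric regardless of the outcome.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise ValueError("normality tests need n >= 3")
    if np.all(x == x[0]):
        flag = TestResult("constant", float("nan"), (int(x.size),), float("nan"), degenerate=True)
        return flag, flag
    ks_stat, ks_p = lilliefors(x, dist="norm")
    sw_stat, sw_p = sps.shapiro(x)
    return (
        TestResult("kolmogorov_smirnov_lilliefors", float(ks_stat), (int(x.size),), float(ks_p)),
        TestResult("shapiro_wilk", float(sw_stat), (int(x.size),), float(sw_p)),
    )


# --------------------------------------------------------------- regression

REGRESSION_COVARIATES = ("conc_mio_per_ml", "motility_pct", "morphology_pct", "age", "bmi")


def pregnancy_regression(
    records: pd.DataFrame,
    cn_variable: str = "active_cn",
    covariates: Sequence[str] = REGRESSION_COVARIATES,
    standardize: bool = True,
    min_records: int = 20,
) -> RegressionResult:
    """Binary logistic model: pregnancy ~ CN + semen parameters + age + BMI.

    Rows with pregnancy "unknown" or missing covariates are dropped.
    Continuous covariates are z-scored by default so coefficients are
    per-SD log-odds.  Perfect separation and non-convergence are flagged,
    with no p-values reported in the separated case.
    """
    cols = [cn_variable, *covariates]
    df = records.loc[records["pregnancy"].isin(["yes", "no"]), ["pregnancy", *cols]].dropna()
    n = len(df)
    if n < min_records:
        raise ValueError(f"need >= {min_records} complete records, got {n}")
    y = (df["pregnancy"] == "yes").to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("pregnancy outcome has a single class")
    X = df[cols].to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            zero = [c for c, s in zip(cols, sd) if s == 0]
            raise ValueError(f"constant covariate(s): {zero}")
        X = (X - X.mean(axis=0)) / sd
    X = sm.add_constant(X, has_constant="add")
    names = ["const", *cols]
    separation = False
    converged = False
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation warnings handled below
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
        converged = bool(fit.mle_retvals.get("converged", False))
        params = fit.params
        bse = fit.bse
        llf = float(fit.llf)
        # huge coefficients with huge SEs indicate quasi-separation
        if np.any(np.abs(params[1:]) > 20):
            separation = True
    except (PerfectSeparationError, np.linalg.LinAlgError):
        separation = True
        params = np.full(len(names), np.nan)
        bse = np.full(len(names), np.nan)
        llf = float("nan")
    if separation:
        table = pd.DataFrame({"coef": params, "se": np.nan, "z": np.nan, "p": np.nan}, index=names)
        return RegressionResult("pregnancy", cn_variable, table, tuple(cols), n,
                                converged=False, separation=True, llf=llf)
    z = params / bse
    p = 2 * sps.norm.sf(np.abs(z))
    table = pd.DataFrame({"coef": params, "se": bse, "z": z, "p": p}, index=names)
    return RegressionResult("pregnancy", cn_variable, table, tuple(cols), n,
                            converged=converged, separation=False, llf=llf)


# ------------------------------------------------------------------- minima


@dataclass
class MinimumCnResult:
    k: int
    overall_minima: tuple[float, ...]
    pregnancy_minima: tuple[float, ...]
    floor: float  # smallest active CN among pregnancy samples
    comparison: TestResult | None


def minimum_cn_analysis(records: pd.DataFrame, k: int = 5,
                        value_column: str = "active_cn") -> MinimumCnResult:
    """The k smallest active CNs overall vs. within the pregnancy group.

    The pregnancy-group minimum is the empirical floor of copies observed
    to be compatible with establishing a pregnancy.  With k = 1 no test is
    run (flagged by a ``None`` comparison).
    """
    overall = np.sort(records[value_column].dropna().to_numpy())
    preg = np.sort(records.loc[records["pregnancy"] == "yes", value_column].dropna().to_numpy())
    if overall.size < k or preg.size < k:
        raise ValueError(f"need >= {k} samples in each stratum")
    lo_all = overall[:k]
    lo_preg = preg[:k]
    comparison = mann_whitney_u(lo_all, lo_preg, method="auto") if k > 1 else None
    return MinimumCnResult(
        k=k,
        overall_minima=tuple(float(v) for v in lo_all),
        pregnancy_minima=tuple(float(v) for v in lo_preg),
        floor=float(lo_preg[0]),
        comparison=comparison,
    )
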