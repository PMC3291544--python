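"""Fluctuation-rate estimation and the hotspot/association statistics.

Rates are reported as events per cell per generation ("per cell division").
The central estimator is the median of per-culture rate values from a
fluctuation test, with a two-sided nonparametric (order-statistic) 95%
confidence interval: the narrowest symmetric pair of order statistics whose
Binomial(n, 1/2) coverage reaches 95% (the actual coverage achieved is
reported, since with small n no pair may reach 95%).

Per-arm duplication rates partition a strain's total GCR rate according to
the observed duplication spectrum; a test strain's spectrum is compared
against a control's by scaling the control's per-arm rates by the bulk
rate ratio and taking observed/expected ratios (log2 reported), with
explicit conventions for arms unobserved in either strain.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RateEstimate",
    "ArmRateTable",
    "TestResult",
    "estimate_gcr_rate",
    "fold_change",
    "round_fold",
    "arm_duplication_rates",
    "expected_arm_rates",
    "mc_multinomial_test",
    "exact_binomial_overrep",
    "fisher_exact_2x2",
    "paired_exact_test",
    "hypergeom_overlap",
    "rank_sum_test",
    "adjust_bonferroni",
]


# ---------------------------------------------------------------------------
# rate estimates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateEstimate:
    median: float
    ci_low: float
    ci_high: float
    n: int
    coverage: float  # actual coverage of the order-statistic interval
    fold_over_reference: float | None = None

    def __post_init__(self):
        if not (self.ci_low <= self.median <= self.ci_high):
            raise ValueError("confidence interval must bracket the median")

    def format(self) -> str:
        """Rate-table style string, e.g. '8.4 [5.9-9.6]e-08'."""
        exp = math.floor(math.log10(self.median)) if self.median > 0 else 0
        scale = 10.0 ** exp

        def mant(x: float) -> str:
            return f"{x / scale:.1f}".rstrip("0").rstrip(".")

        s = f"{mant(self.median)} [{mant(self.ci_low)}-{mant(self.ci_high)}]e{exp:+03d}"
        if self.fold_over_reference is not None:
            s += f" ({self.fold_over_reference:g})"
        return s


def estimate_gcr_rate(per_culture_rates: Sequence[float], level: float = 0.95) -> RateEstimate:
    """Median rate with a two-sided nonparametric CI from order statistics.

    For sorted values x(1) <= ... <= x(n), the interval (x(i), x(n+1-i))
    has exact coverage 1 - 2 * P(Bin(n, 1/2) <= i-1).  The narrowest such
    interval with coverage >= ``level`` is used; if none reaches the level
    (small n), the full range (x(1), x(n)) is returned with its actual
    coverage.
    """
    x = np.sort(np.asarray(per_culture_rates, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("need at least one per-culture rate")
    if np.any(x < 0):
        raise ValueError("per-culture rates must be nonnegative")
    median = float(np.median(x))
    if n == 1:
        return RateEstimate(median, float(x[0]), float(x[0]), 1, 0.0)
    best_i, best_cov = 1, 1.0 - 2.0 * sps.binom.cdf(0, n, 0.5)
    for i in range(n // 2, 0, -1):  # narrowest first
        cov = 1.0 - 2.0 * sps.binom.cdf(i - 1, n, 0.5)
        if cov >= level:
            best_i, best_cov = i, cov
            break
    return RateEstimate(
        median=median,
        ci_low=float(x[best_i - 1]),
        ci_high=float(x[n - best_i]),
        n=n,
        coverage=float(best_cov),
    )


def round_fold(fold: float, integer_snap: float = 0.02) -> float:
    """Round a fold change for reporting: 2 significant figures, then snap
    to the nearest integer when within ``integer_snap`` (relative)."""
    if fold == 0:
        return 0.0
    r = float(f"{fold:.2g}")
    nearest = round(r)
    if nearest >= 1 and abs(r - nearest) <= integer_snap * nearest:
        return float(nearest)
    return r


def fold_change(test: RateEstimate, reference: RateEstimate) -> float:
    """Rounded fold of a test strain's median rate over a reference strain's."""
    if reference.median <= 0:
        raise ValueError("reference median rate must be positive")
    return round_fold(test.median / reference.median)


# ---------------------------------------------------------------------------
# per-arm duplication rates and observed/expected comparison
# ---------------------------------------------------------------------------

@dataclass
class ArmRateTable:
    """Per-arm duplication counts and rates for one strain.

    ``table`` is indexed by arm key with columns ``count``, ``rate`` and
    ``upper_limit`` (True where count 0 and the rate is the upper-limit
    value rather than an observation).
    """

    table: pd.DataFrame
    total_rate: float  # the strain's total selected-GCR rate
    n_isolates: int  # GCRs analyzed
    n_duplications: int  # duplication-bearing GCRs among them

    @property
    def rates(self) -> pd.Series:
        return self.table["rate"]

    @property
    def upper_limit_rate(self) -> float:
        """Rate attributable to one hypothetical event: total rate / #duplications."""
        if self.n_duplications == 0:
            return self.total_rate
        return self.total_rate / self.n_duplications


def arm_duplication_rates(
    total_rate: float,
    arm_counts: Mapping[str, int],
    n_isolates: int,
    arm_universe: Sequence[str],
    n_duplications: int | None = None,
) -> ArmRateTable:
    """Observed per-arm duplication rates.

    r_arm = R_total * n_arm / N, where N is the number of GCRs analyzed.
    Arms with no observed duplication get rate 0 and an upper-limit
    annotation (their rate is bounded above by R_total / #duplications).
    """
    if n_isolates <= 0:
        raise ValueError("n_isolates must be positive")
    if n_duplications is None:
        n_duplications = sum(arm_counts.values())
    rows = []
    for arm in arm_universe:
        cnt = int(arm_counts.get(arm, 0))
        rows.append(
            {
                "arm": arm,
                "count": cnt,
                "rate": total_rate * cnt / n_isolates,
                "upper_limit": cnt == 0,
            }
        )
    table = pd.DataFrame(rows).set_index("arm")
    return ArmRateTable(table, total_rate, n_isolates, n_duplications)


def expected_arm_rates(
    control: ArmRateTable,
    test: ArmRateTable,
    test_rate_ci: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Observed-vs-expected per-arm duplication rates of a test strain.

    The expected rate of each arm is the control's observed arm rate scaled
    by S = (sum of test arm rates) / (sum of control arm rates), i.e. the
    null hypothesis that the test genotype changes every arm's duplication
    rate by the same bulk factor.  Conventions for unobserved arms:

    * control count 0, test count > 0: the control rate is replaced by its
      upper limit (control total rate / control #duplications) before
      scaling;
    * test count 0, control count > 0: the test's upper-limit rate stands
      in for the observation if it is below the expectation, otherwise the
      ratio is set to 1;
    * both 0: ratio 1.

    If ``test_rate_ci`` (the test strain's bulk-rate 95% CI) is given, each
    arm is flagged significant when its observed rate falls outside the
    control arm rate scaled by the CI-derived fold interval
    (ci / control median-rate analogue, here the control total rate).
    """
    if not control.table.index.equals(test.table.index):
        raise ValueError("control and test tables must share the same arm universe")
    s_control = float(control.rates.sum())
    s_test = float(test.rates.sum())
    if s_control <= 0:
        raise ValueError("control strain has zero total duplication rate")
    scale = s_test / s_control

    rows = []
    for arm in control.table.index:
        c_cnt = int(control.table.loc[arm, "count"])
        t_cnt = int(test.table.loc[arm, "count"])
        c_rate = float(control.table.loc[arm, "rate"])
        t_rate = float(test.table.loc[arm, "rate"])
        if c_cnt == 0 and t_cnt == 0:
            expected = control.upper_limit_rate * scale
            observed = t_rate
            ratio = 1.0
        elif c_cnt == 0:
            expected = control.upper_limit_rate * scale
            observed = t_rate
            ratio = observed / expected
        elif t_cnt == 0:
            expected = c_rate * scale
            upper = test.upper_limit_rate
            if upper < expected:
                observed = upper
                ratio = observed / expected
            else:
                observed = t_rate
                ratio = 1.0
        else:
            expected = c_rate * scale
            observed = t_rate
            ratio = observed / expected
        rows.append(
            {
                "arm": arm,
                "observed_count": t_cnt,
                "observed_rate": observed,
                "expected_rate": expected,
                "obs_exp_ratio": ratio,
                "log2_ratio": math.log2(ratio) if ratio > 0 else float("-inf"),
            }
        )
    out = pd.DataFrame(rows).set_index("arm")
    if test_rate_ci is not None:
        lo_fold = test_rate_ci[0] / control.total_rate
        hi_fold = test_rate_ci[1] / control.total_rate
        base = control.rates.where(control.rates > 0, control.upper_limit_rate)
        out["expected_low"] = base * lo_fold
        out["expected_high"] = base * hi_fold
        out["significant"] = (out["observed_rate"] < out["expected_low"]) | (
            out["observed_rate"] > out["expected_high"]
        )
        # an arm never observed in either strain carries no evidence
        both_zero = (out["observed_count"] == 0) & (control.table["count"] == 0)
        out.loc[both_zero, "significant"] = False
    return out


# ---------------------------------------------------------------------------
# hypothesis tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"p-value {self.pvalue} outside [0, 1]")


def _pearson_chi2(observed: np.ndarray, expected: np.ndarray) -> np.ndarray:
    return (((observed - expected) ** 2) / expected).sum(axis=-1)


def _g_statistic(observed: np.ndarray, expected: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = observed * np.log(observed / expected)
    return 2.0 * np.where(observed > 0, terms, 0.0).sum(axis=-1)


def mc_multinomial_test(
    observed_counts: Sequence[int],
    probabilities: Sequence[float],
    replicates: int = 2000,
    seed: int | np.random.Generator = 0,
    statistic: str = "pearson",
) -> TestResult:
    """Monte-Carlo multinomial goodness-of-fit test.

    Observed counts are compared with N*p via a discrepancy statistic
    (Pearson chi-square by default, log-likelihood-ratio ``"g"`` as an
    option); the null distribution is sampled by drawing ``replicates``
    multinomials, and the empirical p-value is (k + 1) / (R + 1) where k
    replicates reached a discrepancy at least as large as observed.
    """
    obs = np.asarray(observed_counts, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if obs.shape != p.shape:
        raise ValueError("observed counts and probabilities differ in dimension")
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("probabilities must sum to 1")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    n = int(round(obs.sum()))
    expected = n * p
    stat_fn = {"pearson": _pearson_chi2, "g": _g_statistic}[statistic]
    # guard zero-probability categories out of the discrepancy
    keep = p > 0
    obs_stat = float(stat_fn(obs[keep], expected[keep]))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sims = rng.multinomial(n, p, size=replicates).astype(float)
    sim_stats = stat_fn(sims[:, keep], expected[keep])
    k = int(np.sum(sim_stats >= obs_stat - 1e-12))
    return TestResult(
        statistic=obs_stat,
        pvalue=(k + 1) / (replicates + 1),
        method=f"monte-carlo multinomial ({statistic})",
        params={"replicates": replicates, "n": n, "categories": int(keep.sum())},
    )


def exact_binomial_overrep(k: int, n: int, p_arm: float) -> TestResult:
    """One-sided upper-tail exact binomial test P(X >= k), X ~ Bin(n, p)."""
    if not (0 <= k <= n):
        raise ValueError("k must lie in [0, n]")
    if not (0.0 < p_arm < 1.0):
        raise ValueError("p_arm must lie in (0, 1)")
    if k == 0:
        return TestResult(0.0, 1.0, "exact binomial (upper tail)",
                          {"n": n, "p": p_arm})
    pval = float(sps.binom.pmf(np.arange(k, n + 1), n, p_arm).sum())
    return TestResult(
        statistic=float(k),
        pvalue=min(1.0, pval),
        method="exact binomial (upper tail)",
        params={"n": n, "p": p_arm},
    )


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 contingency table."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(
        statistic=float(odds), pvalue=float(p), method="fisher exact (two-sided)",
        params={"table": t.tolist()},
    )


def paired_exact_test(b: int, c: int) -> TestResult:
    """Exact binomial substitute for McNemar's test on discordant pairs.

    Two-sided p = min(1, 2 * P(X <= min(b, c))), X ~ Bin(b + c, 1/2).
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    n = b + c
    if n == 0:
        warnings.warn("no discordant pairs; test is uninformative", stacklevel=2)
        return TestResult(0.0, 1.0, "exact binomial (paired)", {"b": b, "c": c})
    p = min(1.0, 2.0 * float(sps.binom.cdf(min(b, c), n, 0.5)))
    return TestResult(float(min(b, c)), p, "exact binomial (paired)", {"b": b, "c": c})


def hypergeom_overlap(population: int, reference: int, drawn: int, overlap: int) -> TestResult:
    """Upper-tail hypergeometric overlap test P(X >= overlap)."""
    if not (0 <= reference <= population and 0 <= drawn <= population):
        raise ValueError("inconsistent population parameters")
    if overlap > min(reference, drawn) or overlap < 0:
        raise ValueError("overlap outside feasible range")
    p = float(sps.hypergeom.sf(overlap - 1, population, reference, drawn))
    return TestResult(
        statistic=float(overlap), pvalue=min(1.0, p), method="hypergeometric (upper tail)",
        params={"M": population, "K": reference, "n": drawn},
    )


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact for small samples without ties, normal approximation with tie
    correction otherwise; degenerate all-tied input gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return TestResult(float(len(x) * len(y) / 2), 1.0, "wilcoxon rank-sum", {})
    has_ties = len(np.unique(combined)) < len(combined)
    small = len(x) <= 25 and len(y) <= 25
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic), pvalue=float(res.pvalue),
        method=f"wilcoxon rank-sum ({method})", params={"n1": len(x), "n2": len(y)},
    )


def adjust_bonferroni(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[float, list[bool]]:
    """Bonferroni-corrected per-test threshold alpha/m and reject decisions."""
    m = len(p_values)
    if m < 1:
        raise ValueError("need at least one p-value")
    threshold = alpha / m
    return threshold, [p < threshold for p in p_values]
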