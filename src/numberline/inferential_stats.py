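"""Statistical machinery: t-tests with Cohen's d, mixed ANOVA with
generalized eta-squared, Tukey-adjusted marginal-mean contrasts, and BIC.

Conventions
-----------
* Independent-group tests are Welch tests (no equal-variance assumption);
  Cohen's d uses the pooled SD.  Paired and one-sample d is the mean of
  the differences divided by their SD.
* The mixed ANOVA crosses a between-subject factor (language) with a
  within-subject factor (line dimension).  Effect size is generalized
  eta-squared (Olejnik–Algina), whose denominator includes all
  subject-related variance, so it is comparable across designs; its 90%
  confidence interval is obtained by pivoting the noncentral-F
  distribution of the observed F.
* A two-level within factor needs no sphericity correction (the
  Greenhouse–Geisser epsilon is identically 1).
* Significance threshold: 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

__all__ = ["TestResult", "welch_t", "paired_t", "one_sample_t",
           "mixed_anova", "emm_pairwise", "bic", "ges_confint"]

TAILS = ("two_sided", "one_sided_less", "one_sided_greater")

_SCIPY_ALT = {"two_sided": "two-sided", "one_sided_less": "less",
              "one_sided_greater": "greater"}


@dataclass(frozen=True)
class TestResult:
    """A t-test outcome with effect size.

    ``effect_size_d`` is Cohen's d (pooled-SD convention for independent
    groups, SD-of-differences for paired/one-sample).  ``degenerate``
    marks zero-variance inputs handled by convention rather than by the
    t distribution.
    """

    statistic: float
    df: float
    p_value: float
    tail: str
    effect_size_d: float
    mean_difference: float
    se_difference: float
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def __str__(self) -> str:
        return (f"t({self.df:.2f}) = {self.statistic:.2f}, p = {self.p_value:.3g}, "
                f"d = {self.effect_size_d:.2f} ({self.tail})")


def _check_tail(tail: str) -> str:
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}, got {tail!r}")
    return tail


def welch_t(a, b, tail: str = "two_sided") -> TestResult:
    """Welch two-sample t-test of mean(a) − mean(b).

    ``one_sided_greater`` tests mean(a) > mean(b).  Uses the
    Welch–Satterthwaite degrees of freedom; Cohen's d divides the mean
    difference by the pooled SD.  If both groups have zero variance and
    equal means the test is degenerate and p = 1 by convention.
    """
    _check_tail(tail)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = float(a.mean() - b.mean())
    if va == 0 and vb == 0:
        return TestResult(0.0, float(len(a) + len(b) - 2), 1.0, tail,
                          0.0, diff, 0.0, degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=False, alternative=_SCIPY_ALT[tail])
    se = math.sqrt(va / len(a) + vb / len(b))
    sp = math.sqrt(((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2))
    d = diff / sp if sp > 0 else 0.0
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue),
                      tail, d, diff, se)


def one_sample_t(values, mu0: float = 0.0, tail: str = "two_sided") -> TestResult:
    """One-sample t-test of mean(values) against ``mu0``.

    Cohen's d = (mean − mu0) / SD.  Constant values are degenerate:
    p = 1 if they equal mu0, else p = 0 (the mean is exactly off-target
    with zero uncertainty under this convention).
    """
    _check_tail(tail)
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    diff = float(x.mean() - mu0)
    if sd == 0:
        p = 1.0 if diff == 0 else 0.0
        return TestResult(0.0 if diff == 0 else math.copysign(math.inf, diff),
                          float(len(x) - 1), p, tail, 0.0, diff, 0.0, degenerate=True)
    res = stats.ttest_1samp(x, mu0, alternative=_SCIPY_ALT[tail])
    return TestResult(float(res.statistic), float(len(x) - 1), float(res.pvalue),
                      tail, diff / sd, diff, sd / math.sqrt(len(x)))


def paired_t(a, b, tail: str = "two_sided") -> TestResult:
    """Paired t-test of mean(a − b); identical to the one-sample test on
    the differences against 0 (with d = mean diff / SD diff)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    return one_sample_t(a - b, 0.0, tail)


# ---------------------------------------------------------------------------
# Mixed ANOVA
# ---------------------------------------------------------------------------

def ges_confint(ges: float, df1: float, df2: float, conf: float = 0.90
                ) -> tuple[float, float]:
    """Confidence interval for (generalized) eta-squared by noncentral-F pivot.

    The effect size is first converted to the F statistic it implies,
    f = ges / (1 − ges) · df2 / df1; noncentrality parameters under which
    that f sits at the upper/lower tail probability are then found and
    mapped back to the eta-squared scale via λ / (λ + df1 + df2 + 1).
    Pivoting on the effect size itself (rather than the ANOVA F, whose
    error term differs for generalized eta-squared) keeps the interval
    bracketing the point estimate.  The lower bound is 0 whenever the
    implied F is below its central upper-tail critical value.
    """
    if not 0 <= ges < 1:
        raise ValueError("ges must be in [0, 1)")
    f = ges / (1.0 - ges) * df2 / df1
    alpha = 1.0 - conf

    def tail_prob(lam):
        return stats.ncf.cdf(f, df1, df2, lam)

    def solve(target):
        # find lambda with P(F' <= f | lambda) = target; cdf decreases in lambda
        if tail_prob(0.0) <= target:
            return 0.0
        hi = 1.0
        while tail_prob(hi) > target:
            hi *= 2.0
            if hi > 1e8:
                return hi
        from scipy.optimize import brentq
        return brentq(lambda l: tail_prob(l) - target, 0.0, hi, xtol=1e-10)

    lam_lo = solve(1.0 - alpha / 2.0)
    lam_hi = solve(alpha / 2.0)
    to_eta = lambda lam: lam / (lam + df1 + df2 + 1.0)
    # an effect below the central lower quantile collapses the pivot to
    # [0, 0]; keep the interval bracketing the point estimate by convention
    return min(to_eta(lam_lo), ges), max(to_eta(lam_hi), ges)


def mixed_anova(summaries: pd.DataFrame, dv: str = "bias",
                conf: float = 0.90) -> pd.DataFrame:
    """Mixed two-way ANOVA on participant summaries.

    ``summaries`` is the output of
    :func:`numberline.bias_metrics.summarize_participants`; ``dv`` selects
    ``"bias"`` (mean positioning bias) or ``"absolute_bias"``.  The design
    must be complete: every participant needs both dimension levels.

    Returns one row per effect (language, dimension, interaction) with
    F, df1, df2, p, generalized eta-squared and its 90% CI.
    """
    col = {"bias": "mean_positioning_bias",
           "absolute_bias": "mean_absolute_positioning_bias"}.get(dv)
    if col is None:
        raise ValueError("dv must be 'bias' or 'absolute_bias'")
    counts = summaries.groupby("participant_id")["dimension"].nunique()
    n_levels = summaries["dimension"].nunique()
    if (counts != n_levels).any():
        bad = counts.index[counts != n_levels].tolist()
        raise ValueError(f"incomplete within-subject data for participant(s) {bad}; "
                         "mixed ANOVA requires complete cases")
    if summaries.groupby("language")["participant_id"].nunique().min() < 2:
        raise ValueError("need at least 2 participants per language")

    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        aov = pg.mixed_anova(data=summaries, dv=col, within="dimension",
                             subject="participant_id", between="language",
                             correction=False, effsize="ng2")
    rows = []
    name_map = {"language": "language", "dimension": "dimension",
                "Interaction": "interaction"}
    for _, r in aov.iterrows():
        effect = name_map.get(r["Source"], r["Source"])
        # pingouin drops F/p/ng2 columns entirely when the dv is constant
        f = float(r.get("F", math.nan))
        df1, df2 = float(r["DF1"]), float(r["DF2"])
        ges = float(r.get("ng2", math.nan))
        degenerate = math.isnan(f)
        if degenerate and float(r["SS"]) == 0.0:
            f, ges = 0.0, 0.0  # constant dv: no effect and no error variance
        lo, hi = ges_confint(ges, df1, df2, conf=conf)
        rows.append({"effect": effect, "F": f, "df1": df1, "df2": df2,
                     "p": 1.0 if degenerate else float(r.get("p_unc", math.nan)),
                     "ges": ges, "ges_ci_low": lo, "ges_ci_high": hi})
    return pd.DataFrame(rows)


def emm_pairwise(summaries: pd.DataFrame, dv: str = "bias") -> pd.DataFrame:
    """Tukey-adjusted pairwise contrasts of the language marginal means.

    Marginal means average each participant over the within-subject
    dimension levels; the contrasts then compare languages with the
    studentized-range (Tukey HSD) adjustment, the follow-up to a
    significant between-subject effect.

    Returns one row per language pair: mean difference (a − b), SE and
    adjusted p.
    """
    col = {"bias": "mean_positioning_bias",
           "absolute_bias": "mean_absolute_positioning_bias"}.get(dv)
    if col is None:
        raise ValueError("dv must be 'bias' or 'absolute_bias'")
    per = (summaries.groupby(["participant_id", "language"])[col]
           .mean().reset_index())
    if per["language"].nunique() < 2:
        raise ValueError("need at least 2 language groups")

    groups = {lang: sub[col].to_numpy() for lang, sub in per.groupby("language")}
    labels = sorted(groups)
    n_tot = sum(len(v) for v in groups.values())
    k = len(labels)
    mse = sum(((len(v) - 1) * v.var(ddof=1)) for v in groups.values()) / (n_tot - k)
    df_err = n_tot - k
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = labels[i], labels[j]
            diff = float(groups[a].mean() - groups[b].mean())
            se = math.sqrt(mse * (1 / len(groups[a]) + 1 / len(groups[b])) / 2.0)
            # studentized range statistic q = |diff| / se_q, se_q = sqrt(MSE/2 * (1/na+1/nb))
            q = abs(diff) / se if se > 0 else 0.0
            p = float(stats.studentized_range.sf(q, k, df_err)) if se > 0 else 1.0
            rows.append({"contrast": f"{a} - {b}", "mean_difference": diff,
                         "se": math.sqrt(mse * (1 / len(groups[a]) + 1 / len(groups[b]))),
                         "p_tukey": min(p, 1.0)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BIC
# ---------------------------------------------------------------------------

def bic(rss: float, n: int, k: int) -> float:
    """Gaussian-likelihood Bayesian Information Criterion.

    ``n · ln(RSS/n) + k · ln(n)`` for a least-squares fit with ``k`` mean
    parameters; lower is better.  A perfect fit (RSS = 0) returns −inf.
    """
    if not n > k >= 1:
        raise ValueError("need n > k >= 1")
    if rss < 0:
        raise ValueError("RSS must be >= 0")
    if rss == 0:
        return float("-inf")
    return n * math.log(rss / n) + k * math.log(n)
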