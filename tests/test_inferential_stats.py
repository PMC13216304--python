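"""t-tests, mixed ANOVA, Tukey contrasts and BIC against hand oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import numberline as nl
from conftest import build_trials


class TestWelch:
    def test_identical_groups_null(self):
        res = nl.welch_t([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_oracle(self):
        """Textbook Welch formulas evaluated by hand for a={0,0,1,1}, b={10,10,11,11}."""
        a, b = [0.0, 0, 1, 1], [10.0, 10, 11, 11]
        va = vb = 1.0 / 3.0                       # sample variances
        se = math.sqrt(va / 4 + vb / 4)           # sqrt(1/6)
        t_hand = (0.5 - 10.5) / se                # -10 * sqrt(6)/1 -> -24.494897...
        df_hand = (va / 4 + vb / 4) ** 2 / (
            (va / 4) ** 2 / 3 + (vb / 4) ** 2 / 3)  # = 6 exactly
        d_hand = -10.0 / math.sqrt(1.0 / 3.0)     # pooled SD = sqrt(1/3)
        res = nl.welch_t(a, b)
        assert res.statistic == pytest.approx(t_hand, rel=1e-12)
        assert res.df == pytest.approx(df_hand, rel=1e-12)
        assert res.effect_size_d == pytest.approx(d_hand, rel=1e-12)
        assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t_hand), df_hand),
                                            rel=1e-12)
        assert res.p_value < 1e-5 and abs(res.effect_size_d) > 5

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 2, 9)
        r1, r2 = nl.welch_t(a, b), nl.welch_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_degenerate_zero_variance(self):
        res = nl.welch_t([1.0, 1, 1], [1.0, 1, 1])
        assert res.degenerate and res.p_value == 1.0

    def test_one_sided_half_of_two_sided_in_direction(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(1, 1, 10), rng.normal(0, 1, 10)
        two = nl.welch_t(a, b, "two_sided")
        one = nl.welch_t(a, b, "one_sided_greater")
        assert one.p_value == pytest.approx(two.p_value / 2)


class TestPairedAndOneSample:
    def test_hand_oracle_one_sample(self):
        """values {-1,-2,-3} vs 0: mean -2, sd 1 -> t = -2*sqrt(3)."""
        res = nl.one_sample_t([-1.0, -2.0, -3.0], 0.0)
        assert res.statistic == pytest.approx(-2.0 * math.sqrt(3.0), rel=1e-12)
        assert res.df == 2
        assert res.effect_size_d == pytest.approx(-2.0, rel=1e-12)

    def test_paired_equals_one_sample_on_differences(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1, 15)
        assert nl.paired_t(a, b) == nl.one_sample_t(a - b, 0.0)

    def test_equal_pairs_null(self):
        a = np.arange(5.0)
        res = nl.paired_t(a, a)
        assert res.statistic == 0.0 and res.degenerate


def _anova_hand_oracle(summaries, col):
    """Textbook SS decomposition for a balanced 1-between x 1-within design.

    Independent of the package's ANOVA path: computes all sums of squares
    from cell/subject/group means directly.
    """
    df = summaries.rename(columns={col: "y"})
    grand = df["y"].mean()
    a = df["language"].nunique()
    w = df["dimension"].nunique()
    n_per_group = df.groupby("language")["participant_id"].nunique().iloc[0]
    n_subj = df["participant_id"].nunique()

    group_means = df.groupby("language")["y"].mean()
    dim_means = df.groupby("dimension")["y"].mean()
    cell_means = df.groupby(["language", "dimension"])["y"].mean()
    subj_means = df.groupby("participant_id")["y"].mean()
    group_of = df.groupby("participant_id")["language"].first()

    ss_between = w * n_per_group * ((group_means - grand) ** 2).sum()
    ss_subj = w * ((subj_means - group_of.map(group_means)) ** 2).sum()
    ss_within = a * n_per_group * ((dim_means - grand) ** 2).sum()
    ss_cells = n_per_group * ((cell_means - grand) ** 2).sum()
    ss_inter = ss_cells - ss_between - ss_within
    ss_total = ((df["y"] - grand) ** 2).sum()
    ss_err_w = ss_total - ss_between - ss_subj - ss_within - ss_inter

    df_err_w = (n_subj - a) * (w - 1)
    f_between = (ss_between / (a - 1)) / (ss_subj / (n_subj - a))
    f_within = (ss_within / (w - 1)) / (ss_err_w / df_err_w)
    f_inter = (ss_inter / ((a - 1) * (w - 1))) / (ss_err_w / df_err_w)
    return f_between, f_within, f_inter


class TestMixedAnova:
    def _summaries(self, seed=0, shift=None, lang_offsets=None, n=8):
        lang_offsets = lang_offsets or {"English": 0.0, "German": 0.0, "Mandarin": 0.0}
        rng = np.random.default_rng(seed)
        rows = []
        for lang, off in lang_offsets.items():
            for i in range(n):
                base = rng.normal(off, 1.0)
                for dim in ("horizontal", "vertical"):
                    y = base + rng.normal(0, 0.5)
                    if shift and dim == "vertical":
                        y += shift
                    rows.append(dict(participant_id=f"{lang}{i}", language=lang,
                                     dimension=dim, mean_positioning_bias=y,
                                     mean_absolute_positioning_bias=abs(y),
                                     mean_rt_ms=800.0, n_trials=10))
        return pd.DataFrame(rows)

    def test_matches_hand_ss_decomposition(self):
        summaries = self._summaries(seed=3, shift=0.4,
                                    lang_offsets={"English": 0, "German": 0.5,
                                                  "Mandarin": -1.0})
        aov = nl.mixed_anova(summaries, dv="bias").set_index("effect")
        fb, fw, fi = _anova_hand_oracle(summaries, "mean_positioning_bias")
        assert aov.loc["language", "F"] == pytest.approx(fb, rel=1e-8)
        assert aov.loc["dimension", "F"] == pytest.approx(fw, rel=1e-8)
        assert aov.loc["interaction", "F"] == pytest.approx(fi, rel=1e-8)

    def test_constant_dv_gives_zero_f(self):
        summaries = self._summaries()
        summaries["mean_positioning_bias"] = 3.0
        aov = nl.mixed_anova(summaries, dv="bias")
        assert np.allclose(aov["F"], 0.0)

    def test_language_offset_detected(self):
        summaries = self._summaries(seed=4, lang_offsets={"English": 0, "German": 0,
                                                          "Mandarin": -2.0}, n=12)
        aov = nl.mixed_anova(summaries, dv="bias").set_index("effect")
        assert aov.loc["language", "p"] < 0.01
        assert aov.loc["dimension", "F"] < 2.0

    def test_dimension_shift_detected_without_interaction(self):
        summaries = self._summaries(seed=5, shift=1.0, n=12)
        aov = nl.mixed_anova(summaries, dv="bias").set_index("effect")
        assert aov.loc["dimension", "p"] < 0.001
        assert aov.loc["interaction", "p"] > 0.05

    def test_ci_brackets_point_estimate(self):
        aov = nl.mixed_anova(self._summaries(seed=6, shift=0.3), dv="bias")
        assert ((aov["ges_ci_low"] <= aov["ges"] + 1e-12)
                & (aov["ges"] <= aov["ges_ci_high"] + 1e-12)).all()

    def test_incomplete_cases_rejected(self):
        summaries = self._summaries().iloc[1:]
        with pytest.raises(ValueError, match="complete"):
            nl.mixed_anova(summaries, dv="bias")


class TestGesConfint:
    def test_reproduces_reference_intervals(self):
        """Spot checks against published 90% CIs for this design size."""
        lo, hi = nl.ges_confint(0.113, 2, 231)
        assert lo == pytest.approx(0.054, abs=0.005)
        assert hi == pytest.approx(0.177, abs=0.005)
        lo, hi = nl.ges_confint(0.046, 1, 231)
        assert lo == pytest.approx(0.012, abs=0.005)
        assert hi == pytest.approx(0.098, abs=0.005)

    @pytest.mark.parametrize("ges", [0.0, 0.001, 0.05, 0.3, 0.9])
    def test_bracket_invariant(self, ges):
        lo, hi = nl.ges_confint(ges, 2, 40)
        assert lo <= ges <= hi


class TestEmmPairwise:
    def _summaries(self, offsets, n=10, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for lang, off in offsets.items():
            for i in range(n):
                for dim in ("horizontal", "vertical"):
                    rows.append(dict(participant_id=f"{lang}{i}", language=lang,
                                     dimension=dim,
                                     mean_positioning_bias=rng.normal(off, 1.0),
                                     mean_absolute_positioning_bias=1.0,
                                     mean_rt_ms=800.0, n_trials=10))
        return pd.DataFrame(rows)

    def test_two_identical_plus_one_shifted(self):
        res = nl.emm_pairwise(self._summaries(
            {"English": 0.0, "German": 0.0, "Mandarin": -3.0}), dv="bias")
        res = res.set_index("contrast")
        assert res.loc["English - German", "p_tukey"] > 0.05
        assert res.loc["English - Mandarin", "p_tukey"] < 0.001
        assert res.loc["German - Mandarin", "p_tukey"] < 0.001

    def test_tukey_never_below_unadjusted(self):
        summaries = self._summaries({"English": 0.0, "German": 0.3, "Mandarin": -0.4},
                                    seed=5)
        res = nl.emm_pairwise(summaries, dv="bias")
        per = (summaries.groupby(["participant_id", "language"])
               ["mean_positioning_bias"].mean().reset_index())
        groups = {l: s["mean_positioning_bias"].to_numpy()
                  for l, s in per.groupby("language")}
        k = len(groups)
        n_tot = sum(len(v) for v in groups.values())
        mse = sum((len(v) - 1) * v.var(ddof=1) for v in groups.values()) / (n_tot - k)
        for _, row in res.iterrows():
            a, b = row["contrast"].split(" - ")
            t = abs(row["mean_difference"]) / math.sqrt(
                mse * (1 / len(groups[a]) + 1 / len(groups[b])))
            p_raw = 2 * stats.t.sf(t, n_tot - k)
            assert row["p_tukey"] >= p_raw - 1e-12

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            nl.emm_pairwise(self._summaries({"English": 0.0}), dv="bias")


class TestBic:
    def test_doubling_rss(self):
        assert nl.bic(2.0, 50, 3) - nl.bic(1.0, 50, 3) == pytest.approx(50 * math.log(2))

    def test_extra_parameter_cost(self):
        assert nl.bic(1.0, 50, 4) - nl.bic(1.0, 50, 3) == pytest.approx(math.log(50))

    def test_perfect_fit(self):
        assert nl.bic(0.0, 50, 3) == float("-inf")

    @pytest.mark.parametrize("n,k", [(3, 3), (2, 0)])
    def test_invalid_sizes(self, n, k):
        with pytest.raises(ValueError):
            nl.bic(1.0, n, k)
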