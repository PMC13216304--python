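"""Target-pair analyses: inverted-pair distances, teens vs twenties, and
decade difference scores.

Three complementary probes of digit-level distortion:

* **Inverted pairs** — the 17 digit-reversal pairs above 20 (23–32,
  24–42, …, 89–98).  If the unit digit is overweighted (number-word
  inversion), members of a pair are pulled towards each other, shrinking
  the mean placed distance below its veridical value of 477/17 ≈ 28.06
  units.
* **Teens vs twenties** — English teen number words are inverted
  ("fourteen") while twenty-words are not, so teens should be relatively
  overestimated compared to the matching-unit twenties (13–19 vs 23–29).
* **Decade difference scores** — how far the placed distance of two
  targets straddling a decade break (e.g. 29/31) exceeds their true
  distance; positive scores indicate the decade digit dominates (the
  left-digit effect).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .inferential_stats import TestResult, one_sample_t, paired_t, welch_t
from .trial_data import retained

__all__ = ["INVERTED_PAIRS", "DECADE_BREAK_PAIRS", "TEEN_TARGETS",
           "TWENTY_TARGETS", "inverted_pair_distances", "h1_test",
           "teen_twenty_bias", "teen_twenty_tests", "decade_difference_scores",
           "decade_difference_tests"]

#: The 17 digit-reversal pairs with both members above 20.
INVERTED_PAIRS: tuple[tuple[int, int], ...] = (
    (23, 32), (24, 42), (25, 52), (26, 62), (27, 72), (28, 82), (29, 92),
    (34, 43), (37, 73), (39, 93), (48, 84), (56, 65), (58, 85), (67, 76),
    (69, 96), (78, 87), (89, 98),
)

#: Adjacent stimulus pairs straddling a decade break (true distance 2).
DECADE_BREAK_PAIRS: tuple[tuple[int, int], ...] = (
    (19, 21), (29, 31), (39, 41), (89, 91),
)

TEEN_TARGETS: tuple[int, ...] = (13, 14, 15, 16, 17, 18, 19)
TWENTY_TARGETS: tuple[int, ...] = (23, 24, 25, 26, 27, 28, 29)


def _per_target_means(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean placing position per participant × target (orientations pooled)."""
    df = retained(trials)
    return (df.groupby(["participant_id", "language", "target"])["placing_position"]
            .mean().reset_index())


def _pair_scores(trials: pd.DataFrame, pairs, score: str) -> pd.DataFrame:
    """Per-participant mean pair score.

    ``score="distance"`` → |placed(large) − placed(small)| per pair;
    ``score="decade_difference"`` → placed distance − true distance.
    Pairs with a missing member are skipped (divisor adjusted) with a
    warning.
    """
    means = _per_target_means(trials)
    wide = means.pivot_table(index=["participant_id", "language"],
                             columns="target", values="placing_position")
    rows = []
    warned_pairs: set = set()
    for (pid, lang), row in wide.iterrows():
        vals, used = [], 0
        for small, large in pairs:
            if small not in row.index or large not in row.index \
                    or pd.isna(row.get(small)) or pd.isna(row.get(large)):
                warned_pairs.add((small, large))
                continue
            placed = abs(float(row[large]) - float(row[small]))
            vals.append(placed if score == "distance"
                        else placed - (large - small))
            used += 1
        if used:
            rows.append({"participant_id": pid, "language": lang,
                         "mean_score": float(np.mean(vals)), "n_pairs": used})
    if warned_pairs:
        warnings.warn(f"pair(s) {sorted(warned_pairs)} missing for some "
                      "participants; skipped with adjusted divisor", stacklevel=3)
    return pd.DataFrame(rows, columns=["participant_id", "language",
                                       "mean_score", "n_pairs"])


# ---------------------------------------------------------------------------
# Inverted pairs
# ---------------------------------------------------------------------------

def inverted_pair_distances(trials: pd.DataFrame,
                            pairs=INVERTED_PAIRS) -> pd.DataFrame:
    """Mean placed distance over the inverted number pairs, per participant.

    Placing positions are first averaged per target within participant,
    then the absolute distance between the pair members' means is averaged
    over pairs (unweighted).
    """
    return _pair_scores(trials, pairs, score="distance")


def h1_test(distances: pd.DataFrame) -> dict:
    """One-tailed Welch test: German pair distances smaller than English.

    Stronger unit-digit weighting in German should pull digit-reversal
    pairs together.  Returns the test plus per-group mean/SD.
    """
    groups = {lang: sub["mean_score"].to_numpy()
              for lang, sub in distances.groupby("language")}
    for lang in ("German", "English"):
        if lang not in groups:
            raise ValueError(f"missing language group {lang!r}")
    res = welch_t(groups["German"], groups["English"], tail="one_sided_less")
    summary = {lang: {"mean": float(v.mean()), "sd": float(v.std(ddof=1)),
                      "n": len(v)} for lang, v in groups.items()}
    return {"test": res, "groups": summary}


# ---------------------------------------------------------------------------
# Teens vs twenties
# ---------------------------------------------------------------------------

def teen_twenty_bias(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant mean positioning bias over teens and over twenties.

    Participants lacking retained responses in either decade are dropped.
    Columns: participant_id, language, teen_bias, twenty_bias.
    """
    df = retained(trials)
    df = df[df["target"].isin(TEEN_TARGETS + TWENTY_TARGETS)].copy()
    df["bias"] = df["placing_position"] - df["target"]
    df["decade"] = np.where(df["target"].isin(TEEN_TARGETS), "teen", "twenty")
    wide = (df.groupby(["participant_id", "language", "decade"])["bias"].mean()
            .unstack("decade"))
    wide = wide.dropna(subset=["teen", "twenty"]).reset_index()
    return wide.rename(columns={"teen": "teen_bias", "twenty": "twenty_bias"})


def teen_twenty_tests(biases: pd.DataFrame, language: str) -> dict[str, TestResult]:
    """H2-style tests within one language.

    One-tailed paired t-test of teen > twenty bias (relative teen
    overestimation) plus one-sample tests of each decade's bias against 0
    (absolute under-/overestimation).
    """
    sub = biases[biases["language"] == language]
    if len(sub) < 2:
        raise ValueError(f"need >= 2 participants for language {language!r}")
    teen = sub["teen_bias"].to_numpy()
    twenty = sub["twenty_bias"].to_numpy()
    return {
        "teen_gt_twenty": paired_t(teen, twenty, tail="one_sided_greater"),
        "teen_vs_zero": one_sample_t(teen, 0.0, tail="two_sided"),
        "twenty_vs_zero": one_sample_t(twenty, 0.0, tail="two_sided"),
    }


# ---------------------------------------------------------------------------
# Decade difference scores
# ---------------------------------------------------------------------------

def decade_difference_scores(trials: pd.DataFrame,
                             pairs=DECADE_BREAK_PAIRS) -> pd.DataFrame:
    """Per-participant mean decade difference score.

    For each pair straddling a decade break, placed distance minus true
    numerical distance, averaged over pairs.  Zero for any affine
    responder with unit slope; positive under a left-digit effect.
    """
    return _pair_scores(trials, pairs, score="decade_difference")


def decade_difference_tests(scores: pd.DataFrame) -> pd.DataFrame:
    """Group layer: mean, SE and a one-sample test vs 0 per language."""
    rows = []
    for lang, sub in scores.groupby("language"):
        vals = sub["mean_score"].to_numpy()
        if len(vals) < 2:
            continue
        res = one_sample_t(vals, 0.0, tail="two_sided")
        rows.append({"language": lang, "mean": float(vals.mean()),
                     "se": float(vals.std(ddof=1) / np.sqrt(len(vals))),
                     "n": len(vals), "t": res.statistic, "df": res.df,
                     "p": res.p_value, "d": res.effect_size_d})
    return pd.DataFrame(rows)
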