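"""Intra-decade regression slopes: the operational measure of the
number-word inversion effect.

Within each decade, placing positions are regressed on target numbers
individually per participant (both orientations pooled, trial level).  A
slope of 1 is veridical responding; slopes below 1 mean the unit digit
contributes less than it should (left-digit bias); speakers of an
inverting language (German) are expected to show *steeper* slopes than
non-inverting groups because the unit digit, spoken first, is weighted
more.  Teen targets never enter the group tests — English teen number
words are themselves inverted, so the first decade is not diagnostic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inferential_stats import TestResult, welch_t
from .trial_data import retained

__all__ = ["decade_slope", "slope_table", "participant_mean_slope",
           "compare_slope_groups", "ANALYSIS_DECADES"]

#: Decades entering the group analyses (> 20; teens illustrative only).
ANALYSIS_DECADES: tuple[int, ...] = (20, 30, 40, 50, 60, 70, 80, 90)


def decade_slope(trials: pd.DataFrame, decade: int) -> float | None:
    """OLS slope of placing position on target within one decade.

    ``trials`` are one participant's retained trials; all responses in the
    decade are pooled across orientations.  Returns ``None`` when fewer
    than 2 distinct targets have responses (slope undefined).
    """
    sub = trials[(trials["target"] >= decade) & (trials["target"] < decade + 10)]
    x = sub["target"].to_numpy(dtype=float)
    y = sub["placing_position"].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        return None
    return float(np.polyfit(x, y, 1)[0])


def slope_table(trials: pd.DataFrame, decades=ANALYSIS_DECADES) -> pd.DataFrame:
    """Per-participant, per-decade slopes over preprocessed trials.

    Undefined slopes (fewer than 2 distinct targets in the decade) are
    omitted, not imputed.  Columns: participant_id, language, decade,
    slope, n_targets, n_trials.
    """
    df = retained(trials)
    rows = []
    for (pid, lang), sub in df.groupby(["participant_id", "language"], sort=True):
        for dec in decades:
            d = sub[(sub["target"] >= dec) & (sub["target"] < dec + 10)]
            s = decade_slope(sub, dec)
            if s is None:
                continue
            rows.append({"participant_id": pid, "language": lang, "decade": dec,
                         "slope": s, "n_targets": int(d["target"].nunique()),
                         "n_trials": len(d)})
    return pd.DataFrame(rows, columns=["participant_id", "language", "decade",
                                       "slope", "n_targets", "n_trials"])


def participant_mean_slope(slopes: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean slope across decades, one row per participant.

    Decades missing for a participant simply reduce the divisor.
    """
    g = slopes.groupby(["participant_id", "language"], sort=True)
    out = g.agg(mean_slope=("slope", "mean"), n_decades=("slope", "size")).reset_index()
    return out


def compare_slope_groups(mean_slopes: pd.DataFrame) -> dict[str, TestResult]:
    """The three preplanned group comparisons of mean individual slopes.

    Welch t-tests: German > English (one-tailed), German > Mandarin
    (one-tailed), and English vs Mandarin (two-tailed, completeness), each
    with Cohen's d.  ``mean_slopes`` is the output of
    :func:`participant_mean_slope` over all three languages.
    """
    groups = {lang: sub["mean_slope"].to_numpy()
              for lang, sub in mean_slopes.groupby("language")}
    for lang in ("English", "German", "Mandarin"):
        if lang not in groups or len(groups[lang]) < 2:
            raise ValueError(f"need >= 2 participants for language {lang!r}")
    return {
        "german_gt_english": welch_t(groups["German"], groups["English"],
                                     tail="one_sided_greater"),
        "german_gt_mandarin": welch_t(groups["German"], groups["Mandarin"],
                                      tail="one_sided_greater"),
        "english_vs_mandarin": welch_t(groups["English"], groups["Mandarin"],
                                       tail="two_sided"),
    }
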