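"""Positioning-bias metrics and per-participant aggregation.

*Positioning bias* is the signed difference between the placing position
(on the direction-normalised 0–100 scale) and the target's true linear
position; it reflects global under-/overestimation.  *Absolute positioning
bias* takes absolute values first, so errors in opposite directions cannot
cancel — it is equivalent to percent absolute error (PAE) on a 0–100 line.

Group statistics in this package are participant-level: trial biases are
averaged within participant × dimension before any test or ANOVA sees
them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .trial_data import retained

__all__ = ["positioning_bias", "add_bias_columns", "summarize_participants",
           "rt_profile", "group_summary"]


def positioning_bias(placing_position, target):
    """Signed bias: placing position − true position (both on 0–100)."""
    return np.asarray(placing_position, dtype=float) - np.asarray(target, dtype=float)


def add_bias_columns(trials: pd.DataFrame) -> pd.DataFrame:
    """Attach ``bias`` and ``abs_bias`` columns to preprocessed trials."""
    df = trials.copy()
    df["bias"] = positioning_bias(df["placing_position"], df["target"])
    df["abs_bias"] = df["bias"].abs()
    return df


def summarize_participants(trials: pd.DataFrame, targets=None) -> pd.DataFrame:
    """Per-participant × dimension means of bias, absolute bias and RT.

    Operates on preprocessed trials; excluded and training trials are
    dropped, and an optional ``targets`` filter restricts the summary to a
    subset of target numbers (used by the teen/twenty analyses).
    Participants contribute one row per dimension they have retained
    trials in; a participant with no retained trials in a dimension is
    simply absent from that row (with a warning).

    Columns: participant_id, language, dimension, mean_positioning_bias,
    mean_absolute_positioning_bias, mean_rt_ms, n_trials.
    """
    df = add_bias_columns(retained(trials))
    if targets is not None:
        df = df[df["target"].isin(list(targets))]
    if df.empty:
        return pd.DataFrame(columns=[
            "participant_id", "language", "dimension", "mean_positioning_bias",
            "mean_absolute_positioning_bias", "mean_rt_ms", "n_trials"])
    g = df.groupby(["participant_id", "language", "orientation"], sort=True)
    out = g.agg(mean_positioning_bias=("bias", "mean"),
                mean_absolute_positioning_bias=("abs_bias", "mean"),
                mean_rt_ms=("rt_ms", "mean"),
                n_trials=("bias", "size")).reset_index()
    out = out.rename(columns={"orientation": "dimension"})
    n_dims = df["orientation"].nunique()
    incomplete = (out.groupby("participant_id").size() < n_dims)
    if incomplete.any():
        warnings.warn(
            f"{int(incomplete.sum())} participant(s) lack retained trials in some "
            "dimension", stacklevel=2)
    return out


def rt_profile(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-(language, target) mean RT and mean absolute bias.

    Descriptive companion table for spotting a speed–accuracy trade-off:
    a trade-off would show longer RTs where absolute bias is *smaller*;
    parallel profiles mean RT mirrors positioning difficulty.
    """
    df = add_bias_columns(retained(trials))
    df = df[df["rt_ms"].notna()]
    g = df.groupby(["language", "target"], sort=True)
    return g.agg(mean_rt_ms=("rt_ms", "mean"),
                 mean_absolute_positioning_bias=("abs_bias", "mean"),
                 n_trials=("rt_ms", "size")).reset_index()


def group_summary(summaries: pd.DataFrame) -> pd.DataFrame:
    """Group-level means ± SEM per language × dimension (figure-style table)."""
    g = summaries.groupby(["language", "dimension"], sort=True)
    out = g.agg(
        mean_bias=("mean_positioning_bias", "mean"),
        sem_bias=("mean_positioning_bias", "sem"),
        mean_abs_bias=("mean_absolute_positioning_bias", "mean"),
        sem_abs_bias=("mean_absolute_positioning_bias", "sem"),
        mean_rt_ms=("mean_rt_ms", "mean"),
        n_participants=("participant_id", "size")).reset_index()
    return out
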