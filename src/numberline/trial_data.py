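"""Trial-level data model for the 0–100 number-line estimation (NLE) task.

A trial is one touch response to a two-digit target number presented with a
1000-px line (axis coordinates −500 … +500) shown in horizontal or vertical
orientation.  Participants choose which end of the line is the "small" end,
so every participant × orientation carries an inferred line *direction*
(``ascending`` = small numbers at the axis-minimum end).  This module owns

* the :class:`LineSpec`, :class:`Trial` and :class:`Participant` records and
  the canonical CSV schema used throughout the package,
* pixel → 0–100 conversion with direction normalisation ("placing position"),
* the response exclusion rules (off the line axis, > 150 px perpendicular
  deviation, timeout),
* direction inference from the target/touch correlation, with a diagnostic
  for participants who switch direction mid-task.

All analysis stages operate on a :class:`pandas.DataFrame` of trials using
the column names in :data:`TRIAL_COLUMNS`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Constants: the experiment's printed design
# ---------------------------------------------------------------------------

#: The 50 experimental target numbers (two-digit, 0–100 line).
STIMULI: tuple[int, ...] = (
    13, 14, 15, 16, 17, 18, 19,
    21, 23, 24, 25, 26, 27, 28, 29,
    31, 32, 34, 37, 39,
    41, 42, 43, 46, 48,
    51, 52, 54, 56, 58,
    62, 63, 65, 67, 69,
    72, 73, 76, 78, 79,
    82, 84, 85, 87, 89,
    91, 92, 93, 96, 98,
)

#: Training targets, shown in this order before each orientation block.
TRAINING_TARGETS: tuple[int, ...] = (70, 30, 50)

LANGUAGES: tuple[str, ...] = ("English", "German", "Mandarin")
ORIENTATIONS: tuple[str, ...] = ("horizontal", "vertical")
DIRECTIONS: tuple[str, ...] = ("ascending", "descending")

#: Maximum tolerated perpendicular distance from the line, px (strict >).
OFF_AXIS_LIMIT_PX: int = 150

#: Response window, ms; slower trials time out and are repeated.
TIMEOUT_MS: float = 2500.0

#: Raw trial CSV columns (required on read).
TRIAL_COLUMNS: tuple[str, ...] = (
    "participant_id", "language", "orientation", "direction", "target",
    "repetition", "touch_axis_px", "touch_off_axis_px", "rt_ms", "is_training",
)

#: Extra columns present in the preprocessed CSV variant.
DERIVED_COLUMNS: tuple[str, ...] = ("placing_position", "excluded", "exclusion_reason")

PARTICIPANT_COLUMNS: tuple[str, ...] = (
    "participant_id", "language", "age", "gender", "handedness", "start_orientation",
)

EXCLUSION_REASONS: tuple[str, ...] = (
    "none", "off_line_axis", "off_line_perpendicular", "timeout",
)


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LineSpec:
    """Geometry of the presented number line.

    The line spans 1000 px of an "axis" coordinate (x for horizontal lines,
    y for vertical ones) and sits at a fixed "off-axis" coordinate.  The
    same code path therefore serves both orientations.
    """

    orientation: str = "horizontal"
    axis_min_px: int = -500
    axis_max_px: int = 500
    off_axis_center_px: int = 0
    direction: str = "ascending"

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if not self.axis_min_px < self.axis_max_px:
            raise ValueError("axis_min_px must be < axis_max_px")

    @property
    def span_px(self) -> int:
        return self.axis_max_px - self.axis_min_px

    @property
    def px_per_unit(self) -> float:
        """Pixels per number-line unit (0–100 scale)."""
        return self.span_px / 100.0


@dataclass
class Trial:
    """One touch response (raw pixels plus derived placing position)."""

    participant_id: str
    language: str
    orientation: str
    target: int
    repetition: int
    touch_axis_px: float
    touch_off_axis_px: float
    rt_ms: float | None = None
    direction: str = "ascending"
    is_training: bool = False
    placing_position: float | None = None
    excluded: bool = False
    exclusion_reason: str = "none"


@dataclass
class Participant:
    participant_id: str
    language: str
    age: float | None = None
    gender: str | None = None
    handedness: str | None = None
    start_orientation: str = "horizontal"
    inferred_direction_by_orientation: dict[str, str] = field(default_factory=dict)
    direction_switcher: bool = False


# ---------------------------------------------------------------------------
# Coordinate conversion
# ---------------------------------------------------------------------------

def convert_touch(touch_axis_px, direction="ascending", line: LineSpec | None = None):
    """Convert an on-line axis coordinate (px) to a 0–100 placing position.

    ``ascending`` maps ``axis_min_px → 0`` and ``axis_max_px → 100``;
    ``descending`` lines are numerically turned around so that a smaller
    outcome always corresponds to a response towards the small end of the
    number line.  Accepts scalars or arrays; the caller is responsible for
    excluding touches outside the axis range first.
    """
    if line is None:
        line = LineSpec()
    px = np.asarray(touch_axis_px, dtype=float)
    pos = (px - line.axis_min_px) / line.px_per_unit
    if isinstance(direction, str):
        if direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {direction!r}")
        if direction == "descending":
            pos = 100.0 - pos
    else:
        desc = np.asarray(direction) == "descending"
        pos = np.where(desc, 100.0 - pos, pos)
    return float(pos) if np.ndim(touch_axis_px) == 0 else pos


# ---------------------------------------------------------------------------
# Exclusion rules
# ---------------------------------------------------------------------------

def apply_exclusions(trials: pd.DataFrame, line: LineSpec | None = None) -> tuple[pd.DataFrame, dict]:
    """Flag invalid responses and compute placing positions for the rest.

    Rules, applied in order per trial:

    1. ``timeout`` — no response within the window (``rt_ms`` missing or
       ≥ the 2500 ms window); such trials carry no coordinates.
    2. ``off_line_axis`` — the along-line coordinate lies beyond either
       line end.
    3. ``off_line_perpendicular`` — the perpendicular coordinate deviates
       from the line by strictly more than 150 px.

    Returns the full table with ``placing_position``, ``excluded`` and
    ``exclusion_reason`` columns filled in (retained trials get reason
    ``"none"``), plus a log dict with counts and fractions per reason.
    Fractions are relative to all recorded touch responses, i.e. timeouts
    are not part of the denominator.  Idempotent: reapplying to its own
    output changes nothing.
    """
    if line is None:
        line = LineSpec()
    df = trials.copy()
    n = len(df)
    if n == 0:
        for col, val in (("placing_position", np.nan), ("excluded", False),
                         ("exclusion_reason", "none")):
            if col not in df:
                df[col] = pd.Series([], dtype=object if col == "exclusion_reason" else float)
        log = {"n_total": 0, "n_touches": 0, "counts": {r: 0 for r in EXCLUSION_REASONS[1:]},
               "fractions": {r: float("nan") for r in EXCLUSION_REASONS[1:]}}
        return df, log

    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    axis = pd.to_numeric(df["touch_axis_px"], errors="coerce")
    off = pd.to_numeric(df["touch_off_axis_px"], errors="coerce")

    timeout = rt.isna() | (rt >= TIMEOUT_MS) | axis.isna()
    off_axis = ~timeout & ((axis < line.axis_min_px) | (axis > line.axis_max_px))
    perp = (~timeout & ~off_axis
            & ((off - line.off_axis_center_px).abs() > OFF_AXIS_LIMIT_PX))

    reason = np.full(n, "none", dtype=object)
    reason[perp.to_numpy()] = "off_line_perpendicular"
    reason[off_axis.to_numpy()] = "off_line_axis"
    reason[timeout.to_numpy()] = "timeout"
    excluded = reason != "none"

    pos = convert_touch(axis.to_numpy(), df["direction"].to_numpy(), line)
    pos = np.where(excluded, np.nan, pos)

    df["placing_position"] = pos
    df["excluded"] = excluded
    df["exclusion_reason"] = reason

    n_touches = int((~timeout).sum())
    counts = {r: int((reason == r).sum()) for r in EXCLUSION_REASONS[1:]}
    fractions = {r: (counts[r] / n_touches if n_touches else float("nan"))
                 for r in EXCLUSION_REASONS[1:]}
    log = {"n_total": n, "n_touches": n_touches, "counts": counts, "fractions": fractions}
    return df, log


def retained(trials: pd.DataFrame, include_training: bool = False) -> pd.DataFrame:
    """Analysis-ready subset: preprocessed, not excluded, non-training."""
    if "excluded" not in trials:
        raise ValueError("trials must be preprocessed with apply_exclusions first")
    keep = ~trials["excluded"].astype(bool)
    if not include_training and "is_training" in trials:
        keep &= ~trials["is_training"].astype(bool)
    return trials.loc[keep]


# ---------------------------------------------------------------------------
# Direction inference
# ---------------------------------------------------------------------------

def infer_direction(trials: pd.DataFrame, window: int = 25,
                    switch_r_threshold: float = 0.5) -> tuple[str | None, bool]:
    """Infer the line direction chosen by one participant in one orientation.

    The direction is ``ascending`` when targets correlate positively with
    the touched axis coordinate (small numbers at the axis-minimum end),
    ``descending`` otherwise.  A sliding-window correlation (default 25
    trials, in presentation order) flags *direction switchers*: the
    diagnostic is true when one window correlates above ``+threshold`` and
    another below ``−threshold``.  Switchers are removed before analysis.

    Returns ``(direction, switched)``; direction is ``None`` (undetermined,
    flag for manual review) with fewer than 10 usable trials.
    """
    axis = pd.to_numeric(trials["touch_axis_px"], errors="coerce")
    ok = axis.notna()
    t = trials.loc[ok, "target"].to_numpy(dtype=float)
    a = axis[ok].to_numpy(dtype=float)
    if len(t) < 10:
        return None, False
    r_all = _safe_corr(t, a)
    direction = "ascending" if r_all >= 0 else "descending"

    switched = False
    if len(t) >= 2 * window:
        rs = [_safe_corr(t[i:i + window], a[i:i + window])
              for i in range(0, len(t) - window + 1)]
        rs = [r for r in rs if not math.isnan(r)]
        if rs and max(rs) > switch_r_threshold and min(rs) < -switch_r_threshold:
            switched = True
    return direction, switched


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def infer_directions_by_participant(trials: pd.DataFrame, window: int = 25) -> pd.DataFrame:
    """Run :func:`infer_direction` per participant × orientation.

    Returns a table ``(participant_id, orientation, direction, switched)``.
    """
    rows = []
    for (pid, orient), sub in trials.groupby(["participant_id", "orientation"], sort=True):
        direction, switched = infer_direction(sub, window=window)
        rows.append({"participant_id": pid, "orientation": orient,
                     "direction": direction, "switched": switched})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

class TrialFormatError(ValueError):
    """Raised on malformed trial/participant CSV input."""


def read_trials(path) -> pd.DataFrame:
    """Read a trial CSV (raw or preprocessed variant), validating content.

    Raises :class:`TrialFormatError` naming the missing column, or the
    offending row for unknown labels / unparseable numbers.  Row numbers in
    messages are 1-based data rows (header excluded).
    """
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(f"missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        return df

    bad_lang = ~df["language"].isin(LANGUAGES)
    if bad_lang.any():
        row = int(np.flatnonzero(bad_lang)[0]) + 1
        raise TrialFormatError(
            f"row {row}: unknown language label {df['language'].iloc[row - 1]!r}")
    bad_orient = ~df["orientation"].isin(ORIENTATIONS)
    if bad_orient.any():
        row = int(np.flatnonzero(bad_orient)[0]) + 1
        raise TrialFormatError(
            f"row {row}: unknown orientation {df['orientation'].iloc[row - 1]!r}")
    for col in ("target", "repetition"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna())[0]) + 1
            raise TrialFormatError(f"row {row}: non-numeric value in column {col!r}")
        df[col] = vals.astype(int)
    for col in ("touch_axis_px", "touch_off_axis_px", "rt_ms"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["is_training"] = df["is_training"].astype(bool)
    if "excluded" in df.columns:
        df["excluded"] = df["excluded"].astype(bool)
    return df


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write trials to CSV; lossless round trip with :func:`read_trials`."""
    cols = [c for c in TRIAL_COLUMNS + DERIVED_COLUMNS if c in trials.columns]
    trials.to_csv(path, index=False, columns=cols)


def read_participants(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PARTICIPANT_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(f"missing required column(s): {', '.join(missing)}")
    if len(df) and df["participant_id"].duplicated().any():
        dup = df["participant_id"][df["participant_id"].duplicated()].iloc[0]
        raise TrialFormatError(f"duplicate participant_id {dup!r}")
    return df


def write_participants(participants: pd.DataFrame, path) -> None:
    cols = [c for c in PARTICIPANT_COLUMNS if c in participants.columns]
    participants.to_csv(path, index=False, columns=cols)
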