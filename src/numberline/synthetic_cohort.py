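"""Synthetic cohorts for the number-line estimation task.

Generates trial-level data with the statistical structure the analysis
assumes, so every downstream stage (preprocessing, bias metrics, slopes,
pair tests, power-model fitting) can be exercised end-to-end without
behavioral data in hand.  Each simulated participant completes the full
session:

* 50 printed targets × 4 repetitions per orientation (400 experimental
  trials) plus 3 training trials (70, 30, 50) before each block,
* quasi-randomized order per block — consecutive targets never share a
  unit digit and differ by at least 10,
* responses drawn from the cyclical power model: latent position =
  two-cycle prediction under the group's (β, δ) + a group bias offset +
  Gaussian trial noise, clipped to the line, then emitted as raw touch
  pixels under the participant's sampled line direction,
* timeouts injected at a configurable rate, with the missed trial
  repeated at the end of the block (where the adjacency constraints may
  be violated, as in the real procedure).

Default group parameters follow the fitted study values: curvature
β ≈ 0.9 everywhere, unit-digit weight δ ≈ 0.87 (German), 0.83 (English),
0.59 (Mandarin), a stronger underestimation offset for Mandarin speakers,
and trial noise of 5 number-line units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .power_model import predict_cyclical
from .trial_data import (LANGUAGES, ORIENTATIONS, PARTICIPANT_COLUMNS, STIMULI,
                         TIMEOUT_MS, TRAINING_TARGETS, TRIAL_COLUMNS, LineSpec)

__all__ = ["CohortSpec", "DesignSequence", "build_design", "simulate_responses",
           "simulate_participant", "make_cohort", "default_study_specs"]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for one language group.

    ``bias_offset`` (number-line units) shifts every response after the
    power-model transform — negative values emulate global
    underestimation.  ``direction_probabilities`` gives the probability of
    an ascending line per orientation (most participants read left-to-right
    and a majority bottom-to-top on vertical lines).
    """

    language: str
    n_participants: int
    beta: float = 0.9
    delta: float = 0.83
    bias_offset: float = -1.5
    noise_sd: float = 5.0
    direction_probabilities: dict = field(
        default_factory=lambda: {"horizontal": 0.98, "vertical": 0.80})
    timeout_rate: float = 0.005
    seed: int = 0
    cycles: str = "two"

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.timeout_rate <= 1:
            raise ValueError("timeout_rate must be in [0, 1]")
        for o, p in self.direction_probabilities.items():
            if o not in ORIENTATIONS:
                raise ValueError(f"unknown orientation {o!r}")
            if not 0 <= p <= 1:
                raise ValueError(f"direction probability for {o!r} not in [0, 1]")


def default_study_specs(n_participants: tuple[int, int, int] = (80, 78, 76),
                        noise_sd: float = 5.0, seed: int = 0) -> list[CohortSpec]:
    """Study-sized cohort specs: English/German/Mandarin with the fitted
    group parameters and sample sizes 80/78/76."""
    pars = {
        "English": dict(delta=0.83, bias_offset=-1.6),
        "German": dict(delta=0.87, bias_offset=-1.5),
        "Mandarin": dict(delta=0.59, bias_offset=-2.8),
    }
    return [CohortSpec(language=lang, n_participants=n, beta=0.9,
                       noise_sd=noise_sd, seed=seed + i, **pars[lang])
            for i, (lang, n) in enumerate(zip(LANGUAGES, n_participants))]


@dataclass
class DesignSequence:
    """Ordered trial list for one session: (target, orientation, block)."""

    entries: list  # (target, orientation, block_index, is_training)
    reps: int = 4

    def experimental(self) -> list:
        return [e for e in self.entries if not e[3]]

    def validate(self, stimuli=STIMULI) -> None:
        """Check counts and both adjacency constraints per block."""
        from collections import Counter
        exp = self.experimental()
        per_orient: dict = {}
        for tgt, orient, _, _ in exp:
            per_orient.setdefault(orient, []).append(tgt)
        for orient, tgts in per_orient.items():
            counts = Counter(tgts)
            for s in stimuli:
                if counts[s] != self.reps:
                    raise AssertionError(
                        f"target {s} appears {counts[s]}× (expected {self.reps}) "
                        f"in {orient} block")
            for a, b in zip(tgts, tgts[1:]):
                if a % 10 == b % 10:
                    raise AssertionError(f"adjacent targets {a},{b} share a unit digit")
                if abs(a - b) < 10:
                    raise AssertionError(f"adjacent targets {a},{b} closer than 10")


# ---------------------------------------------------------------------------
# Quasi-randomized design
# ---------------------------------------------------------------------------

def _constrained_sequence(stimuli, reps, rng, max_restarts=200):
    """Random order of ``stimuli × reps`` where consecutive items never
    share a unit digit and always differ by ≥ 10.

    Randomized greedy with restarts: at each position draw uniformly from
    the admissible remaining multiset; dead ends trigger a restart.  The
    printed 50-target set leaves many admissible choices at every step, so
    restarts are rare.
    """
    stim = np.asarray(list(stimuli))
    units = stim % 10
    total = len(stim) * reps
    for _ in range(max_restarts):
        counts = np.full(len(stim), reps, dtype=float)
        seq = []
        prev_idx = -1
        ok = True
        for _pos in range(total):
            mask = counts > 0
            if prev_idx >= 0:
                mask &= (units != units[prev_idx]) & (np.abs(stim - stim[prev_idx]) >= 10)
            if not mask.any():
                ok = False
                break
            w = np.where(mask, counts, 0.0)
            cum = np.cumsum(w)
            idx = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
            seq.append(int(stim[idx]))
            counts[idx] -= 1
            prev_idx = idx
        if ok:
            return seq
    raise RuntimeError(
        "could not build a quasi-randomized block; relax the adjacency "
        "constraints or use a larger stimulus set")


def build_design(stimuli=STIMULI, reps: int = 4, orientations=ORIENTATIONS,
                 seed: int | np.random.Generator = 0,
                 include_training: bool = True) -> DesignSequence:
    """Quasi-randomized session design, deterministic given the seed.

    One block per orientation, each a constrained permutation of
    ``stimuli × reps``; training trials (70, 30, 50 in that order) precede
    each block when ``include_training``.
    """
    if not stimuli:
        raise ValueError("stimulus list must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    entries = []
    for block, orient in enumerate(orientations):
        if include_training:
            entries.extend((t, orient, block, True) for t in TRAINING_TARGETS)
        entries.extend((t, orient, block, False)
                       for t in _constrained_sequence(stimuli, reps, rng))
    return DesignSequence(entries=entries, reps=reps)


# ---------------------------------------------------------------------------
# Response simulation
# ---------------------------------------------------------------------------

def simulate_responses(design: DesignSequence, spec: CohortSpec,
                       participant_id: str = "P000",
                       rng: np.random.Generator | None = None,
                       start_orientation: str | None = None) -> pd.DataFrame:
    """Simulate one participant's raw trials (pixel space) for a design.

    Latent placing position = cyclical power-model prediction of the target
    under (β, δ) + group bias offset + N(0, noise_sd), clipped to [0, 100];
    converted to integer axis pixels under the participant's sampled line
    direction.  Perpendicular touch scatter is N(0, 40) px around the line,
    so a small fraction of responses genuinely violates the 150 px rule.
    Timed-out trials carry no coordinates and are re-queued at the end of
    their block.  RT is a base plus a distance-to-anchor term (anchors at
    the midpoint and upper end), purely so RT summaries have structure.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    line = LineSpec()

    directions = {o: ("ascending" if rng.random() < p else "descending")
                  for o, p in spec.direction_probabilities.items()}
    for o in ORIENTATIONS:
        directions.setdefault(o, "ascending")

    # latent model predictions, one per distinct target
    all_targets = sorted({e[0] for e in design.entries})
    pred = {t: predict_cyclical(float(t), spec.beta, spec.delta, cycles=spec.cycles)
            for t in all_targets}

    # expand the design into per-block queues; timed-out trials re-enter at
    # the end of their block (multi-pass, so a repeat can itself time out)
    blocks: dict = {}
    for tgt, orient, block, training in design.entries:
        blocks.setdefault((block, orient), []).append((tgt, training))

    frames = []
    for (block, orient), queue in sorted(blocks.items()):
        order: list[tuple[int, bool, bool]] = []  # target, training, timed_out
        pending = list(queue)
        while pending:
            flags = rng.random(len(pending)) < spec.timeout_rate
            nxt = []
            for (tgt, training), missed in zip(pending, flags):
                order.append((tgt, training, bool(missed)))
                if missed:
                    nxt.append((tgt, training))
            pending = nxt

        tgts = np.array([t for t, _, _ in order], dtype=float)
        training = np.array([tr for _, tr, _ in order], dtype=bool)
        missed = np.array([m for _, _, m in order], dtype=bool)
        n = len(order)
        latent = np.array([pred[int(t)] for t in tgts])
        pos = np.clip(latent + spec.bias_offset + rng.normal(0.0, spec.noise_sd, n),
                      0.0, 100.0)
        if directions[orient] == "descending":
            axis_px = line.axis_max_px - pos * line.px_per_unit
        else:
            axis_px = pos * line.px_per_unit + line.axis_min_px
        off_px = line.off_axis_center_px + rng.normal(0.0, 40.0, n)
        anchor_dist = np.minimum(np.abs(tgts - 50.0), np.abs(tgts - 100.0))
        rt = np.minimum(600.0 + 14.0 * anchor_dist + rng.gamma(2.0, 90.0, n),
                        TIMEOUT_MS - 1.0)
        frames.append(pd.DataFrame({
            "participant_id": participant_id, "language": spec.language,
            "orientation": orient, "direction": directions[orient],
            "target": tgts.astype(int),
            "touch_axis_px": np.where(missed, np.nan, np.round(axis_px)),
            "touch_off_axis_px": np.where(missed, np.nan, np.round(off_px)),
            "rt_ms": np.where(missed, np.nan, rt),
            "is_training": training}))
    df = pd.concat(frames, ignore_index=True)
    # repetition index per orientation (training numbered separately)
    df["repetition"] = (df.groupby(["orientation", "target", "is_training"])
                        .cumcount() + 1)
    return df[list(TRIAL_COLUMNS)]


def simulate_participant(spec: CohortSpec, participant_id: str,
                         rng: np.random.Generator,
                         start_orientation: str = "horizontal") -> pd.DataFrame:
    """Fresh quasi-randomized design + simulated responses for one person."""
    orientations = (("horizontal", "vertical") if start_orientation == "horizontal"
                    else ("vertical", "horizontal"))
    design = build_design(orientations=orientations, seed=rng)
    return simulate_responses(design, spec, participant_id=participant_id, rng=rng,
                              start_orientation=start_orientation)


_AGE_MEAN = {"English": 21.4, "German": 24.6, "Mandarin": 19.6}


def make_cohort(specs: list[CohortSpec], master_seed: int | None = None
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full multi-language dataset: concatenated trials + participant table.

    Language labels must be distinct.  Per-participant seeds derive
    deterministically from the master seed (default: the first spec's
    seed), so the same seed reproduces the dataset byte for byte.  Half of
    each group starts with the horizontal orientation.
    """
    labels = [s.language for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate language labels in cohort specs: {labels}")
    if master_seed is None:
        master_seed = specs[0].seed if specs else 0

    trial_frames, participants = [], []
    pid_counter = 0
    for spec_idx, spec in enumerate(specs):
        ss = np.random.SeedSequence([int(master_seed), spec_idx, int(spec.seed)])
        child_seeds = ss.spawn(spec.n_participants)
        for j in range(spec.n_participants):
            pid = f"{spec.language[:2].upper()}{pid_counter:04d}"
            pid_counter += 1
            rng = np.random.default_rng(child_seeds[j])
            start = "horizontal" if j % 2 == 0 else "vertical"
            trials = simulate_participant(spec, pid, rng, start_orientation=start)
            trial_frames.append(trials)
            participants.append(dict(
                participant_id=pid, language=spec.language,
                age=round(float(rng.normal(_AGE_MEAN.get(spec.language, 22.0), 3.0)), 1),
                gender=("female" if rng.random() < 0.68 else "male"),
                handedness=("right" if rng.random() < 0.93 else "left"),
                start_orientation=start))
    trials_df = (pd.concat(trial_frames, ignore_index=True) if trial_frames
                 else pd.DataFrame(columns=list(TRIAL_COLUMNS)))
    participants_df = pd.DataFrame(participants, columns=list(PARTICIPANT_COLUMNS))
    return trials_df, participants_df
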