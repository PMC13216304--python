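"""Shared fixtures: programmatic trial tables and small simulated cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import numberline as nl


def build_trials(placing_fn, languages=("English", "German", "Mandarin"),
                 n_participants=2, reps_per_orientation=1, targets=nl.STIMULI,
                 rt_ms=800.0):
    """Preprocessed-style trial table with placing positions from a callable.

    ``placing_fn(target, participant_index, language)`` returns the placing
    position on the 0–100 scale.  All trials are retained, non-training.
    """
    rows = []
    for lang in languages:
        for i in range(n_participants):
            pid = f"{lang[:2]}{i:02d}"
            for orient in nl.ORIENTATIONS:
                for rep in range(1, reps_per_orientation + 1):
                    for t in targets:
                        pos = float(placing_fn(t, i, lang))
                        rows.append(dict(
                            participant_id=pid, language=lang, orientation=orient,
                            direction="ascending", target=int(t), repetition=rep,
                            touch_axis_px=pos * 10 - 500, touch_off_axis_px=0.0,
                            rt_ms=rt_ms, is_training=False,
                            placing_position=pos, excluded=False,
                            exclusion_reason="none"))
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def perfect_trials():
    """Veridical responders: placing position equals the target everywhere."""
    return build_trials(lambda t, i, lang: t)


@pytest.fixture(scope="session")
def small_cohort():
    """Three-language simulated cohort (5 participants each), preprocessed.

    Group parameters follow the fitted study ordering (German's unit weight
    largest, Mandarin's smallest; Mandarin underestimates most).
    """
    specs = [
        nl.CohortSpec("English", 5, beta=0.9, delta=0.83, bias_offset=-1.6,
                      noise_sd=3.0, seed=101),
        nl.CohortSpec("German", 5, beta=0.9, delta=0.87, bias_offset=-1.5,
                      noise_sd=3.0, seed=102),
        nl.CohortSpec("Mandarin", 5, beta=0.9, delta=0.59, bias_offset=-2.8,
                      noise_sd=3.0, seed=103),
    ]
    trials, participants = nl.make_cohort(specs, master_seed=42)
    trials, _ = nl.apply_exclusions(trials)
    return trials, participants


@pytest.fixture(scope="session")
def identity_cohort():
    """Noise-free, unbiased, uncurved cohort: every response is veridical."""
    specs = [nl.CohortSpec(lang, 2, beta=1.0, delta=1.0, bias_offset=0.0,
                           noise_sd=0.0, timeout_rate=0.0, seed=7 + i)
             for i, lang in enumerate(nl.LANGUAGES)]
    trials, _ = nl.make_cohort(specs, master_seed=7)
    trials, _ = nl.apply_exclusions(trials)
    return trials
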