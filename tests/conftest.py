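"""Shared fixtures: small synthetic sessions reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from checkdyn.core import TrialRecord
from checkdyn.synth import AgentPolicy, TaskConfig, simulate_task


@pytest.fixture(scope="session")
def default_session_trials():
    """A 30-block behavioral session under the default agent (seed 7)."""
    return simulate_task(TaskConfig(n_blocks=30), AgentPolicy(), 7)


def make_work_trial(
    i: int,
    t0: float,
    feedback: str = "COR",
    gauge: int = 1,
    block: int = 1,
    required: int = 14,
    correct: int = 0,
    side: str = "RIGHT",
    difficulty: int = 2,
    rt: float = 0.5,
) -> TrialRecord:
    """Minimal hand-built WORK trial with a regular event layout."""
    events = {
        "lever_onset": t0,
        "lever_touch": t0 + 1.0,
        "cue_onset": t0 + 1.3,
        "target_onset": t0 + 2.3,
        "target_touch": t0 + 2.3 + rt,
        "feedback_onset": t0 + 3.0 + rt,
        "end_of_trial": t0 + 4.5 + rt,
    }
    return TrialRecord(
        trial_index=i,
        session_id="toy",
        choice="WORK",
        cued_side=side,
        difficulty=difficulty,
        feedback=feedback,
        gauge_level=gauge,
        block_index=block,
        block_required_correct=required,
        correct_count_in_block=correct,
        events=events,
        response_time_s=1.0,
        reaction_time_s=rt,
    )


def make_check_trial(
    i: int,
    t0: float,
    gauge: int = 1,
    block: int = 1,
    required: int = 14,
    correct: int = 0,
) -> TrialRecord:
    events = {
        "lever_onset": t0,
        "lever_touch": t0 + 1.0,
        "gauge_onset": t0 + 1.05,
        "end_of_trial": t0 + 1.85,
    }
    return TrialRecord(
        trial_index=i,
        session_id="toy",
        choice="CHECK",
        cued_side="NA",
        difficulty=None,
        feedback="NA",
        gauge_level=gauge,
        block_index=block,
        block_required_correct=required,
        correct_count_in_block=correct,
        events=events,
        response_time_s=1.0,
        reaction_time_s=float("nan"),
    )
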