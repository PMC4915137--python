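"""Shared data model, session I/O, event alignment and spike binning.

Every downstream stage (behavioral regressions, sliding GLMs, group GLMMs,
clustering, population decoding, gaze analysis) works from the two record
types defined here: :class:`TrialRecord` for the behavioral structure of a
dual-task session (Work = cued visual categorization, Check = consult the
bonus gauge) and :class:`UnitSpikeTrain` for the spike timestamps of one
isolated unit recorded in MCC or LPFC.

Sessions are stored as plain delimited text (CSV or TSV, autodetected from
the extension): one trial table, one long-format spike list, optionally one
gaze-sample table.  All timestamps are seconds from session start.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CHOICES = ("WORK", "CHECK", "CONTROL")
SIDES = ("LEFT", "RIGHT", "NA")
FEEDBACKS = ("COR", "INC", "NA")
AREAS = ("MCC", "LPFC")

#: Canonical within-trial event order used to validate timestamp monotonicity.
EVENT_ORDER = (
    "lever_onset",
    "lever_touch",
    "gauge_onset",
    "cue_onset",
    "target_onset",
    "target_touch",
    "feedback_onset",
    "end_of_trial",
)

GAUGE_MIN, GAUGE_MAX = 1, 7
BLOCK_LENGTHS = (14, 21, 29, 36)


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class ValidationError(ValueError):
    """A record violates a domain invariant; the message names the record."""


@dataclass
class TrialRecord:
    """One behavioral trial: choice, outcome, gauge state and event times."""

    trial_index: int
    session_id: str
    choice: str
    cued_side: str
    difficulty: int | None
    feedback: str
    gauge_level: int
    block_index: int
    block_required_correct: int
    correct_count_in_block: int
    events: dict[str, float] = field(default_factory=dict)
    response_time_s: float = float("nan")
    reaction_time_s: float = float("nan")

    def validate(self) -> None:
        tag = f"trial {self.trial_index} (session {self.session_id})"
        if self.choice not in CHOICES:
            raise ValidationError(f"{tag}: unknown choice {self.choice!r}")
        if self.cued_side not in SIDES:
            raise ValidationError(f"{tag}: unknown cued_side {self.cued_side!r}")
        if self.feedback not in FEEDBACKS:
            raise ValidationError(f"{tag}: unknown feedback {self.feedback!r}")
        # Feedback exists only for completed Work trials.
        if self.choice in ("CHECK", "CONTROL"):
            if self.feedback != "NA":
                raise ValidationError(f"{tag}: {self.choice} trial carries feedback")
        elif self.feedback == "NA":
            raise ValidationError(f"{tag}: WORK trial without feedback")
        if not GAUGE_MIN <= self.gauge_level <= GAUGE_MAX:
            raise ValidationError(f"{tag}: gauge_level {self.gauge_level} outside 1-7")
        if self.block_index < 1:
            raise ValidationError(f"{tag}: block_index {self.block_index} < 1")
        if self.block_required_correct not in BLOCK_LENGTHS:
            raise ValidationError(
                f"{tag}: block_required_correct {self.block_required_correct} "
                f"not in {BLOCK_LENGTHS}"
            )
        if not 0 <= self.correct_count_in_block <= self.block_required_correct:
            raise ValidationError(
                f"{tag}: correct_count_in_block {self.correct_count_in_block} "
                f"outside [0, {self.block_required_correct}]"
            )
        ordered = [self.events[e] for e in EVENT_ORDER if e in self.events]
        if any(b <= a for a, b in zip(ordered, ordered[1:])):
            raise ValidationError(f"{tag}: event timestamps not strictly increasing")


@dataclass
class UnitSpikeTrain:
    """Spike timestamps (seconds, sorted) of one isolated unit."""

    unit_id: str
    area: str
    session_id: str
    spike_times_s: np.ndarray
    quality_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if self.area not in AREAS:
            raise ValidationError(f"unit {self.unit_id}: unknown area {self.area!r}")
        if np.any(np.diff(self.spike_times_s) < 0):
            raise ValidationError(f"unit {self.unit_id}: spike times not sorted")


@dataclass(frozen=True)
class AlignmentSpec:
    """Sliding-window grid around one trial event.

    Bins are half-open ``[t, t + width)`` with the bin timestamp taken at the
    bin center; the default grid is 200 ms windows stepped by 50 ms.
    """

    event_name: str
    window_start_s: float
    window_end_s: float
    bin_width_s: float = 0.200
    bin_step_s: float = 0.050

    def __post_init__(self) -> None:
        if self.window_end_s <= self.window_start_s:
            raise ValueError("window_end_s must exceed window_start_s")
        if self.bin_width_s <= 0 or self.bin_step_s <= 0:
            raise ValueError("bin width and step must be positive")

    @property
    def n_bins(self) -> int:
        span = self.window_end_s - self.window_start_s
        return int(math.floor((span - self.bin_width_s) / self.bin_step_s + 1e-9)) + 1

    @property
    def bin_starts_s(self) -> np.ndarray:
        return self.window_start_s + self.bin_step_s * np.arange(self.n_bins)

    @property
    def bin_centers_s(self) -> np.ndarray:
        return self.bin_starts_s + self.bin_width_s / 2.0


@dataclass
class BinnedCountMatrix:
    """Trials x bins spike counts for one unit under one alignment."""

    counts: np.ndarray
    bin_centers_s: np.ndarray
    trial_ids: np.ndarray
    alignment: AlignmentSpec


# ---------------------------------------------------------------------------
# Session I/O (delimited text)
# ---------------------------------------------------------------------------

_TRIAL_COLUMNS = [
    "trial_index",
    "session_id",
    "choice",
    "cued_side",
    "difficulty",
    "feedback",
    "gauge_level",
    "block_index",
    "block_required_correct",
    "correct_count_in_block",
    "response_time_s",
    "reaction_time_s",
]
_SPIKE_COLUMNS = ["unit_id", "area", "session_id", "spike_time_s"]


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    """Flatten TrialRecords to a table; event times become ``t_<event>`` columns."""
    rows = []
    for tr in trials:
        row = {c: getattr(tr, c) for c in _TRIAL_COLUMNS}
        for ev in EVENT_ORDER:
            row[f"t_{ev}"] = tr.events.get(ev, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_trials(df: pd.DataFrame, validate: bool = True) -> list[TrialRecord]:
    missing = [c for c in _TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial table missing required columns: {missing}")
    trials = []
    for _, row in df.iterrows():
        events = {}
        for ev in EVENT_ORDER:
            col = f"t_{ev}"
            if col in df.columns and pd.notna(row[col]):
                events[ev] = float(row[col])
        diff = row["difficulty"]
        tr = TrialRecord(
            trial_index=int(row["trial_index"]),
            session_id=str(row["session_id"]),
            choice=str(row["choice"]),
            cued_side="NA" if pd.isna(row["cued_side"]) else str(row["cued_side"]),
            difficulty=None if pd.isna(diff) else int(diff),
            feedback="NA" if pd.isna(row["feedback"]) else str(row["feedback"]),
            gauge_level=int(row["gauge_level"]),
            block_index=int(row["block_index"]),
            block_required_correct=int(row["block_required_correct"]),
            correct_count_in_block=int(row["correct_count_in_block"]),
            events=events,
            response_time_s=float(row["response_time_s"]),
            reaction_time_s=float(row["reaction_time_s"]),
        )
        if validate:
            tr.validate()
        trials.append(tr)
    return trials


def write_session(trials, units, trial_table_path, spikes_path) -> None:
    """Write a session to two delimited-text files (CSV/TSV by extension)."""
    trials_to_frame(trials).to_csv(trial_table_path, sep=_sep_for(trial_table_path), index=False)
    rows = []
    for u in units:
        for t in u.spike_times_s:
            rows.append((u.unit_id, u.area, u.session_id, t))
    pd.DataFrame(rows, columns=_SPIKE_COLUMNS).to_csv(
        spikes_path, sep=_sep_for(spikes_path), index=False
    )


def read_session(trial_table_path, spikes_path):
    """Read and validate a session; returns (trials, units).

    Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` (naming the trial) for invariant violations.
    """
    tdf = pd.read_csv(trial_table_path, sep=_sep_for(trial_table_path))
    trials = frame_to_trials(tdf)
    sdf = pd.read_csv(spikes_path, sep=_sep_for(spikes_path))
    missing = [c for c in _SPIKE_COLUMNS if c not in sdf.columns]
    if missing:
        raise SchemaError(f"spike table missing required columns: {missing}")
    units = []
    for (uid, area, sid), grp in sdf.groupby(["unit_id", "area", "session_id"], sort=True):
        units.append(
            UnitSpikeTrain(
                unit_id=str(uid),
                area=str(area),
                session_id=str(sid),
                spike_times_s=np.sort(grp["spike_time_s"].to_numpy(float)),
            )
        )
    return trials, units


def read_gaze(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in ("t_s", "x_deg", "y_deg") if c not in df.columns]
    if missing:
        raise SchemaError(f"gaze table missing required columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------


def bin_counts(
    unit: UnitSpikeTrain, trials: list[TrialRecord], align: AlignmentSpec
) -> BinnedCountMatrix:
    """Count spikes per trial in the sliding-window grid around one event.

    Entry (i, j) is the number of spikes falling in
    ``[event_i + start + j*step, event_i + start + j*step + width)``.
    Trials missing the alignment event are dropped (logged).
    """
    if not trials:
        raise ValueError("bin_counts: empty trial list")
    kept = [t for t in trials if align.event_name in t.events]
    if not kept:
        raise ValueError(f"bin_counts: event {align.event_name!r} absent from all trials")
    if len(kept) < len(trials):
        logger.info(
            "bin_counts: dropped %d/%d trials missing event %r",
            len(trials) - len(kept), len(trials), align.event_name,
        )
    starts = align.bin_starts_s
    if align.bin_step_s == align.bin_width_s:
        # contiguous bins: build both edges from one array so a spike on a
        # boundary lands in exactly one bin (conservation is exact)
        edges = align.window_start_s + align.bin_step_s * np.arange(align.n_bins + 1)
        los, his = edges[:-1], edges[1:]
    else:
        los, his = starts, starts + align.bin_width_s
    spikes = unit.spike_times_s
    counts = np.empty((len(kept), align.n_bins), dtype=np.int64)
    for i, tr in enumerate(kept):
        t0 = tr.events[align.event_name]
        lo = np.searchsorted(spikes, t0 + los, side="left")
        hi = np.searchsorted(spikes, t0 + his, side="left")
        counts[i] = hi - lo
    return BinnedCountMatrix(
        counts=counts,
        bin_centers_s=align.bin_centers_s,
        trial_ids=np.array([t.trial_index for t in kept]),
        alignment=align,
    )


# ---------------------------------------------------------------------------
# Contingency statistics
# ---------------------------------------------------------------------------


def pearson_chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]], df=1.

    No continuity correction is applied; the p-value is the chi2(1) upper
    tail.  Raises if any margin is zero (statistic undefined).
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("pearson_chi2_2x2: zero margin, statistic undefined")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)
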