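"""Synthetic session generator with known ground truth.

Emulates the structure of the dual-task "checking" paradigm: an agent
repeatedly chooses between Working (a cued left/right categorization with
three difficulty levels) and Checking a 7-step bonus gauge that fills with
correct Work trials.  A block ends when the gauge is full *and* the agent
checks (the bonus stays available until collected); the bonus is worth seven
regular rewards.  On top of the behavioral stream the module generates
overdispersed (gamma-Poisson) spike trains with factor tuning — feedback
valence, Check-vs-Work, cued side, gauge level, distance to the next check —
whose latencies can differ by area, plus gaze samples with lever fixations.

The generator is the test bed for every downstream stage: all of its
parameters are ground truth, and the same seed always reproduces the same
session bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import BLOCK_LENGTHS, TrialRecord, UnitSpikeTrain

FACTORS = ("FEEDBACK", "CHECKWORK", "CUED_SIDE", "GAUGE", "DISTANCE_TO_CHECK")

#: Anchor event for each tunable factor's rate bump.
FACTOR_ANCHOR = {
    "FEEDBACK": "feedback_onset",
    "CHECKWORK": "lever_touch",
    "CUED_SIDE": "cue_onset",
    "GAUGE": "end_of_trial",
    "DISTANCE_TO_CHECK": "end_of_trial",
}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaskConfig:
    """Task timing and structure (defaults follow the monkey-A schedule)."""

    block_lengths: tuple[int, ...] = BLOCK_LENGTHS
    n_blocks: int = 8
    gauge_steps: int = 7
    lever_hold_s: float = 0.700
    cue_duration_s: float = 0.600
    delay_s: float = 0.400
    target_to_feedback_s: float = 0.700
    feedback_to_eot_s: float = 1.500
    eot_duration_s: float = 0.800
    inter_trial_s: float = 0.700
    gauge_view_s: float = 0.800
    post_check_s: float = 1.800
    timeout_s: float = 2.000
    reward_ml: float = 0.5
    bonus_ml: float = 3.5
    difficulty_accuracies: tuple[float, float, float] = (0.70, 0.80, 0.90)
    control_fraction: float = 0.0
    max_trials_per_block: int = 2000

    def __post_init__(self) -> None:
        if abs(self.bonus_ml / self.reward_ml - 7.0) > 1e-9:
            raise ValueError("bonus must be worth 7 regular rewards")
        accs = self.difficulty_accuracies
        if not all(0 < a < 1 for a in accs) or not accs[0] < accs[1] < accs[2]:
            raise ValueError("difficulty_accuracies must be strictly increasing in (0,1)")


@dataclass(frozen=True)
class AgentPolicy:
    """Logistic checking policy plus log-normal response/reaction times.

    ``P(check) = logit^-1(beta0 + beta_gauge*gauge + beta_prev_incorrect*[prev INC]
    + beta_speed[speed])`` where speed 1..4 is the rank of the block's required
    correct count.  The default coefficients are calibrated so that the agent
    checks on roughly 12.5% of trials with checking odds rising steeply with
    the gauge, and checks less right after an error.
    """

    beta0: float = -5.0
    beta_gauge: float = 0.55
    beta_prev_incorrect: float = -1.0
    beta_speed: tuple[float, float, float, float] = (0.0, 0.1, 0.2, 0.3)
    rt_mu_by_difficulty: tuple[float, float, float] = (-0.90, -0.80, -0.70)
    rt_sigma: float = 0.18
    post_error_slowing: float = 0.10
    response_time_mu: float = -0.35
    response_time_sigma: float = 0.20

    def check_logit(self, gauge: int, prev_incorrect: bool, speed: int) -> float:
        return (
            self.beta0
            + self.beta_gauge * gauge
            + self.beta_prev_incorrect * float(prev_incorrect)
            + self.beta_speed[speed - 1]
        )

    def check_probability(self, gauge: int, prev_incorrect: bool, speed: int) -> float:
        return 1.0 / (1.0 + math.exp(-self.check_logit(gauge, prev_incorrect, speed)))


@dataclass(frozen=True)
class EffectSpec:
    """One additive rate bump tied to a task factor.

    ``amplitude_hz`` is the rate difference between the factor's two poles
    (COR-INC, CHECK-WORK, RIGHT-LEFT; for GAUGE the full 1->7 swing, for
    DISTANCE_TO_CHECK the bump at distance 0 relative to far trials), applied
    as a boxcar (or half-Gaussian) starting ``latency_s`` after the factor's
    anchor event.
    """

    factor: str
    amplitude_hz: float
    latency_s: float
    duration_s: float
    shape: str = "boxcar"

    def __post_init__(self) -> None:
        if self.factor not in FACTORS:
            raise ValueError(f"unknown factor {self.factor!r}; expected one of {FACTORS}")
        if self.shape not in ("boxcar", "half_gaussian"):
            raise ValueError(f"unknown effect shape {self.shape!r}")


@dataclass(frozen=True)
class TuningSpec:
    """Generative tuning of one unit: baseline, NB dispersion, effects."""

    unit_id: str
    area: str
    baseline_rate_hz: float
    dispersion: float = math.inf  # NB shape theta; inf = Poisson
    effects: tuple[EffectSpec, ...] = ()
    dynamic_code_group: int | None = None


@dataclass(frozen=True)
class GazeParams:
    """Inter-trial lever-scanning model for the gaze generator."""

    sample_rate_hz: float = 186.0
    work_pos_deg: tuple[float, float] = (-8.0, 0.0)
    check_pos_deg: tuple[float, float] = (8.0, 0.0)
    lever_size_deg: float = 2.0
    scan_beta0: float = -0.5
    scan_beta_gauge: float = -0.29
    scan_beta_check: float = 1.2
    fixation_duration_s: tuple[float, float] = (0.180, 0.400)
    noise_sd_deg: float = 0.15


@dataclass
class SimulatedSession:
    """A full synthetic session plus the ground truth that generated it."""

    trials: list[TrialRecord]
    spikes: list[UnitSpikeTrain]
    gaze: pd.DataFrame | None
    policy: AgentPolicy
    tuning: tuple[TuningSpec, ...]
    config: TaskConfig
    seed: int


# ---------------------------------------------------------------------------
# Gauge map
# ---------------------------------------------------------------------------


def gauge_level(correct_count: int, required: int) -> int:
    """Linear 7-step gauge map: ``min(7, 1 + floor(7*k/required))``.

    Level 1 at an empty gauge, level 7 at (and near) block completion,
    monotone non-decreasing in ``correct_count``.
    """
    if not 0 <= correct_count <= required:
        raise ValueError(f"correct_count {correct_count} outside [0, {required}]")
    return min(7, 1 + (7 * correct_count) // required)


# ---------------------------------------------------------------------------
# Behavioral simulation
# ---------------------------------------------------------------------------


def _speed_rank(required: int, block_lengths: tuple[int, ...]) -> int:
    return sorted(block_lengths).index(required) + 1


def simulate_task(
    config: TaskConfig, policy: AgentPolicy, seed: int | np.random.Generator
) -> list[TrialRecord]:
    """Simulate the agent through ``config.n_blocks`` blocks of the dual task.

    A block ends when the required number of correct Work trials has been
    reached *and* the agent subsequently checks (collecting the bonus); the
    full gauge persists until that check.  Raises ``RuntimeError`` if a block
    exceeds ``config.max_trials_per_block`` trials (degenerate never-checking
    policy).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    trials: list[TrialRecord] = []
    t = 0.0
    trial_index = 0
    prev_feedback = "NA"
    session_id = "synthetic"

    for block_index in range(1, config.n_blocks + 1):
        required = int(rng.choice(config.block_lengths))
        speed = _speed_rank(required, config.block_lengths)
        correct = 0
        n_in_block = 0
        while True:
            if n_in_block >= config.max_trials_per_block:
                raise RuntimeError(
                    f"block {block_index} exceeded {config.max_trials_per_block} trials; "
                    "checking policy makes the bonus unreachable"
                )
            gauge = gauge_level(correct, required)
            p_check = policy.check_probability(gauge, prev_feedback == "INC", speed)
            is_check = rng.random() < p_check

            events = {"lever_onset": t}
            response_time = float(
                rng.lognormal(policy.response_time_mu, policy.response_time_sigma)
            )
            t_touch = t + response_time + config.lever_hold_s
            events["lever_touch"] = t_touch

            if is_check:
                events["gauge_onset"] = t_touch + 0.050
                t_end = events["gauge_onset"] + config.gauge_view_s
                events["end_of_trial"] = t_end
                tr = TrialRecord(
                    trial_index=trial_index,
                    session_id=session_id,
                    choice="CHECK",
                    cued_side="NA",
                    difficulty=None,
                    feedback="NA",
                    gauge_level=gauge,
                    block_index=block_index,
                    block_required_correct=required,
                    correct_count_in_block=correct,
                    events=events,
                    response_time_s=response_time,
                    reaction_time_s=float("nan"),
                )
                trials.append(tr)
                trial_index += 1
                n_in_block += 1
                prev_feedback = "NA"  # check trials carry no COR/INC outcome
                t = t_end + config.post_check_s
                if correct >= required:  # bonus delivered; block over
                    break
            else:
                difficulty = int(rng.integers(1, 4))
                accuracy = config.difficulty_accuracies[difficulty - 1]
                cued_side = "RIGHT" if rng.random() < 0.5 else "LEFT"
                is_correct = rng.random() < accuracy
                log_rt = (
                    policy.rt_mu_by_difficulty[difficulty - 1]
                    + policy.post_error_slowing * float(prev_feedback == "INC")
                    + policy.rt_sigma * rng.standard_normal()
                )
                reaction_time = float(np.exp(log_rt))
                events["cue_onset"] = t_touch + 0.300
                events["target_onset"] = events["cue_onset"] + config.cue_duration_s + config.delay_s
                events["target_touch"] = events["target_onset"] + reaction_time
                events["feedback_onset"] = events["target_touch"] + config.target_to_feedback_s
                t_eot = events["feedback_onset"] + (
                    config.feedback_to_eot_s if is_correct else config.timeout_s
                )
                events["end_of_trial"] = t_eot
                tr = TrialRecord(
                    trial_index=trial_index,
                    session_id=session_id,
                    choice="WORK",
                    cued_side=cued_side,
                    difficulty=difficulty,
                    feedback="COR" if is_correct else "INC",
                    gauge_level=gauge,
                    block_index=block_index,
                    block_required_correct=required,
                    correct_count_in_block=correct,
                    events=events,
                    response_time_s=response_time,
                    reaction_time_s=reaction_time,
                )
                trials.append(tr)
                trial_index += 1
                n_in_block += 1
                prev_feedback = tr.feedback
                if is_correct:
                    correct = min(correct + 1, required)
                t = t_eot + config.eot_duration_s + config.inter_trial_s
    return trials


def distance_to_check(trials: list[TrialRecord]) -> np.ndarray:
    """Trials remaining before the next CHECK (0 on the check trial itself).

    Trials after the last check of the session get a large sentinel (10**6).
    """
    n = len(trials)
    dist = np.full(n, 10**6, dtype=np.int64)
    next_check = None
    for i in range(n - 1, -1, -1):
        if trials[i].choice == "CHECK":
            next_check = i
        if next_check is not None:
            dist[i] = next_check - i
    return dist


# ---------------------------------------------------------------------------
# Spike simulation
# ---------------------------------------------------------------------------


def _effect_drive(effect: EffectSpec, trial: TrialRecord, dist: int) -> float:
    """Signed 0..1 drive of one effect on one trial (times |amplitude|)."""
    f = effect.factor
    if f == "FEEDBACK":
        if trial.feedback == "NA":
            return 0.0
        pole = "COR" if effect.amplitude_hz >= 0 else "INC"
        return 1.0 if trial.feedback == pole else 0.0
    if f == "CHECKWORK":
        pole = "CHECK" if effect.amplitude_hz >= 0 else "WORK"
        return 1.0 if trial.choice == pole else 0.0
    if f == "CUED_SIDE":
        if trial.cued_side == "NA":
            return 0.0
        pole = "RIGHT" if effect.amplitude_hz >= 0 else "LEFT"
        return 1.0 if trial.cued_side == pole else 0.0
    if f == "GAUGE":
        frac = (trial.gauge_level - 1) / 6.0
        return frac if effect.amplitude_hz >= 0 else 1.0 - frac
    if f == "DISTANCE_TO_CHECK":
        # Ramp rising over the last trials before a check: full at dist 0,
        # zero from dist 4 outward.
        return max(0.0, 1.0 - dist / 4.0)
    raise ValueError(f"unknown factor {f!r}")


def _rate_breakpoints(
    spec: TuningSpec, trial: TrialRecord, span: tuple[float, float], dist: int
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant rate profile (edges, rates) over the trial span.

    Boxcar effects are exact; half-Gaussian effects are discretized at 10 ms.
    Rates are clipped at zero after summing.
    """
    t0, t1 = span
    edges = {t0, t1}
    bumps = []  # (start, end, rate array or scalar)
    for eff in spec.effects:
        anchor = FACTOR_ANCHOR[eff.factor]
        if anchor not in trial.events:
            continue
        drive = _effect_drive(eff, trial, dist)
        if drive == 0.0:
            continue
        amp = abs(eff.amplitude_hz) * drive
        a = trial.events[anchor] + eff.latency_s
        b = a + eff.duration_s
        a, b = max(a, t0), min(b, t1)
        if b <= a:
            continue
        if eff.shape == "boxcar":
            edges.update((a, b))
            bumps.append((a, b, amp, None))
        else:  # half_gaussian: rising flank of a Gaussian peaking at b
            grid = np.arange(a, b, 0.010)
            edges.update(grid.tolist())
            edges.add(b)
            sigma = max(eff.duration_s / 2.5, 1e-3)
            vals = amp * np.exp(-0.5 * ((grid - b) / sigma) ** 2)
            bumps.append((a, b, None, (grid, vals)))
    edge_arr = np.array(sorted(edges))
    seg_start = edge_arr[:-1]
    rates = np.full(seg_start.shape, spec.baseline_rate_hz)
    for a, b, amp, hg in bumps:
        inside = (seg_start >= a - 1e-12) & (seg_start < b - 1e-12)
        if hg is None:
            rates[inside] += amp
        else:
            grid, vals = hg
            idx = np.searchsorted(grid, seg_start[inside], side="right") - 1
            rates[inside] += vals[np.clip(idx, 0, len(vals) - 1)]
    return edge_arr, np.clip(rates, 0.0, None)


def simulate_spikes(
    trials: list[TrialRecord],
    specs: list[TuningSpec] | tuple[TuningSpec, ...],
    seed: int | np.random.Generator,
) -> list[UnitSpikeTrain]:
    """Generate gamma-Poisson (negative-binomial marginal) spike trains.

    Per trial and unit a gamma multiplier with shape ``dispersion`` scales a
    piecewise-constant rate (baseline plus factor bumps); spikes are drawn as
    an inhomogeneous Poisson process given the multiplier, so counts in any
    window have an NB marginal with the requested dispersion.
    """
    if not specs:
        raise ValueError("simulate_spikes: no tuning specs")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dists = distance_to_check(trials)
    # Trial spans partition the session timeline (no double coverage).
    spans = []
    for i, tr in enumerate(trials):
        start = tr.events["lever_onset"] - 0.5
        if i + 1 < len(trials):
            end = trials[i + 1].events["lever_onset"] - 0.5
        else:
            end = tr.events["end_of_trial"] + 2.5
        spans.append((start, end))

    units = []
    session_id = trials[0].session_id if trials else "synthetic"
    for spec in specs:
        all_spikes = []
        clipped = 0
        total_segments = 0
        for tr, span, dist in zip(trials, spans, dists):
            edges, rates = _rate_breakpoints(spec, tr, span, int(dist))
            total_segments += len(rates)
            clipped += int(np.sum(rates == 0.0))
            g = 1.0 if math.isinf(spec.dispersion) else rng.gamma(
                spec.dispersion, 1.0 / spec.dispersion
            )
            durations = np.diff(edges)
            lam = rates * durations * g
            counts = rng.poisson(lam)
            for k in np.nonzero(counts)[0]:
                all_spikes.append(rng.uniform(edges[k], edges[k + 1], counts[k]))
        times = np.sort(np.concatenate(all_spikes)) if all_spikes else np.empty(0)
        units.append(
            UnitSpikeTrain(
                unit_id=spec.unit_id,
                area=spec.area,
                session_id=session_id,
                spike_times_s=times,
                quality_flags={
                    "clip_fraction": clipped / max(total_segments, 1),
                    "dynamic_code_group": spec.dynamic_code_group,
                },
            )
        )
    return units


# ---------------------------------------------------------------------------
# Population factories
# ---------------------------------------------------------------------------

#: Default latency offsets (s) emulating the reported area asymmetries:
#: MCC earlier for feedback and Check/Work, LPFC earlier for the cued side.
#: These are emulation targets for the generator, not estimates.
AREA_LATENCY_OFFSET = {
    ("MCC", "FEEDBACK"): 0.10,
    ("LPFC", "FEEDBACK"): 0.25,
    ("MCC", "CHECKWORK"): 0.15,
    ("LPFC", "CHECKWORK"): 0.30,
    ("MCC", "CUED_SIDE"): 0.30,
    ("LPFC", "CUED_SIDE"): 0.12,
    ("MCC", "GAUGE"): 0.20,
    ("LPFC", "GAUGE"): 0.30,
    ("MCC", "DISTANCE_TO_CHECK"): 0.20,
    ("LPFC", "DISTANCE_TO_CHECK"): 0.30,
}


def make_population(
    n_units: int,
    area: str,
    seed: int | np.random.Generator,
    tuned_fraction: float = 0.5,
    factors: tuple[str, ...] = ("FEEDBACK", "CHECKWORK", "CUED_SIDE"),
    amplitude_hz: float = 8.0,
    duration_s: float = 0.6,
    baseline_range_hz: tuple[float, float] = (2.0, 12.0),
    dispersion: float = 2.0,
    n_dynamic_groups: int = 0,
    group_latency_step_s: float = 0.25,
) -> list[TuningSpec]:
    """Build a tuned population for one area.

    A ``tuned_fraction`` of units receives one effect drawn from ``factors``
    (random sign) at the area's default latency; with ``n_dynamic_groups`` > 0
    the tuned units are split into groups expressing the factor at staggered
    latencies, producing a sequential (dynamic) population code.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    specs = []
    n_tuned = int(round(tuned_fraction * n_units))
    for i in range(n_units):
        baseline = float(rng.uniform(*baseline_range_hz))
        effects: tuple[EffectSpec, ...] = ()
        group = None
        if i < n_tuned:
            factor = factors[i % len(factors)]
            latency = AREA_LATENCY_OFFSET[(area, factor)]
            if n_dynamic_groups > 0:
                group = i % n_dynamic_groups
                latency = latency + group * group_latency_step_s
            sign = 1.0 if rng.random() < 0.5 else -1.0
            effects = (
                EffectSpec(
                    factor=factor,
                    amplitude_hz=sign * amplitude_hz,
                    latency_s=latency,
                    duration_s=duration_s,
                ),
            )
        specs.append(
            TuningSpec(
                unit_id=f"{area}_{i:03d}",
                area=area,
                baseline_rate_hz=baseline,
                dispersion=dispersion,
                effects=effects,
                dynamic_code_group=group,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# Psychometric calibration
# ---------------------------------------------------------------------------


def calibrate_difficulty(
    history: pd.DataFrame,
    targets: tuple[float, float, float] = (0.70, 0.80, 0.90),
) -> np.ndarray:
    """Invert a fitted psychometric curve at the target accuracies.

    ``history`` needs columns ``orientation_deg`` (absolute cue orientation)
    and ``correct`` (0/1).  Fits accuracy ~ logistic(orientation) and returns
    the orientations eliciting the target accuracies, clipped to the observed
    orientation range.  Raises on complete separation; a flat psychometric
    (|slope| ~ 0) raises with a 'degenerate' diagnostic.
    """
    import statsmodels.api as sm

    x = history["orientation_deg"].to_numpy(float)
    y = history["correct"].to_numpy(int)
    if y.min() == y.max():
        raise ValueError(
            "complete separation: all outcomes identical; widen the orientation range"
        )
    X = sm.add_constant(x)
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    b0, b1 = fit.params
    if abs(b1) < 1e-8:
        raise ValueError("degenerate psychometric: accuracy does not depend on orientation")
    logits = np.log(np.array(targets) / (1.0 - np.array(targets)))
    orientations = (logits - b0) / b1
    return np.clip(orientations, x.min(), x.max())


# ---------------------------------------------------------------------------
# Gaze simulation
# ---------------------------------------------------------------------------


def simulate_gaze(
    trials: list[TrialRecord],
    params: GazeParams,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Generate 186 Hz gaze samples over each pre-decision period.

    For every trial the period from 1 s before the previous trial's EoT to
    the lever touch is covered.  The agent always fixates the lever it is
    about to touch; with probability following a logistic in gauge level and
    the upcoming choice it first scans the other lever too.  Returns a table
    (t_s, x_deg, y_deg, trial_index).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dt = 1.0 / params.sample_rate_hz
    frames = []
    for i in range(1, len(trials)):
        prev, tr = trials[i - 1], trials[i]
        t_start = prev.events["end_of_trial"] - 1.0
        t_end = tr.events["lever_touch"]
        if t_end - t_start < 0.5:
            continue
        n = int((t_end - t_start) / dt)
        t = t_start + dt * np.arange(n)
        x = np.zeros(n)
        y = np.zeros(n)
        target_pos = params.check_pos_deg if tr.choice == "CHECK" else params.work_pos_deg
        other_pos = params.work_pos_deg if tr.choice == "CHECK" else params.check_pos_deg
        logit = (
            params.scan_beta0
            + params.scan_beta_gauge * tr.gauge_level
            + params.scan_beta_check * float(tr.choice == "CHECK")
        )
        scans = rng.random() < 1.0 / (1.0 + math.exp(-logit))
        # Final fixation on the touched lever, ending at the touch.
        d_final = float(rng.uniform(*params.fixation_duration_s))
        final_mask = t >= t_end - d_final
        x[final_mask], y[final_mask] = target_pos
        if scans:
            n_extra = 1 + int(rng.poisson(1.0))
            cursor = t_end - d_final - 0.2
            for j in range(n_extra):
                d = float(rng.uniform(*params.fixation_duration_s))
                pos = other_pos if j % 2 == 0 else target_pos
                m = (t >= cursor - d) & (t < cursor)
                x[m], y[m] = pos
                cursor -= d + 0.25
        x += params.noise_sd_deg * rng.standard_normal(n)
        y += params.noise_sd_deg * rng.standard_normal(n)
        frames.append(
            pd.DataFrame(
                {"t_s": t, "x_deg": x, "y_deg": y, "trial_index": tr.trial_index}
            )
        )
    if not frames:
        return pd.DataFrame(columns=["t_s", "x_deg", "y_deg", "trial_index"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Full session
# ---------------------------------------------------------------------------


def simulate_session(
    config: TaskConfig | None = None,
    policy: AgentPolicy | None = None,
    tuning: list[TuningSpec] | tuple[TuningSpec, ...] | None = None,
    gaze_params: GazeParams | None = None,
    seed: int = 0,
    with_gaze: bool = True,
) -> SimulatedSession:
    """Simulate behavior, spikes and gaze from a single seed (bit-exact)."""
    config = config or TaskConfig()
    policy = policy or AgentPolicy()
    if tuning is None:
        rng0 = np.random.default_rng(seed)
        tuning = tuple(
            make_population(12, "MCC", rng0, factors=("FEEDBACK", "CHECKWORK"))
            + make_population(12, "LPFC", rng0, factors=("CUED_SIDE",))
        )
    gaze_params = gaze_params or GazeParams()
    rng = np.random.default_rng(seed)
    trials = simulate_task(config, policy, rng)
    spikes = simulate_spikes(trials, tuning, rng)
    gaze = simulate_gaze(trials, gaze_params, rng) if with_gaze else None
    return SimulatedSession(
        trials=trials,
        spikes=spikes,
        gaze=gaze,
        policy=policy,
        tuning=tuple(tuning),
        config=config,
        seed=seed,
    )
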