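"""Gaze preprocessing, lever-fixation detection and oculomotor GLMs.

The pre-decision period (1 s before the End-of-Trial signal up to the next
lever touch) carries free oculomotor behavior: whether the animal scans both
lever positions, when it last fixates a lever before touching one, and how
many lever fixations it makes.  Raw gaze samples are resampled to 186 Hz
and cleaned with a GCV-selected smoothing spline (trials with more than 20%
bad samples are excluded); fixations are dwell episodes of at least 150 ms
inside a window of 2.5 lever sizes around each lever, with episodes on the
same lever closer than 150 ms merged.  Three GLMs relate the measures to
gauge level, distance to check, previous performance and the upcoming
choice: binomial for scanning, Gaussian for the last-fixation latency,
Poisson for the fixation count on scan trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.interpolate import make_smoothing_spline

logger = logging.getLogger(__name__)

MIN_FIXATION_S = 0.150
MERGE_GAP_S = 0.150
BAD_FRACTION_LIMIT = 0.20
WINDOW_SCALE = 2.5  # lever window = 2.5x the lever size


@dataclass(frozen=True)
class LeverGeometry:
    """Screen positions (deg) and size of the Work and Check levers."""

    work_pos_deg: tuple[float, float] = (-8.0, 0.0)
    check_pos_deg: tuple[float, float] = (8.0, 0.0)
    lever_size_deg: float = 2.0

    @property
    def half_window_deg(self) -> float:
        return WINDOW_SCALE * self.lever_size_deg / 2.0


@dataclass(frozen=True)
class FixationEvent:
    lever: str  # 'WORK_POS' | 'CHECK_POS'
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def preprocess_gaze(
    samples: pd.DataFrame,
    sample_rate_hz: float = 186.0,
    bad_mask: np.ndarray | None = None,
    max_abs_deg: float = 40.0,
) -> tuple[pd.DataFrame, bool]:
    """Resample to 186 Hz and spline-interpolate bad segments.

    Bad samples are NaNs, off-range samples (|x| or |y| > ``max_abs_deg``,
    e.g. blinks), or an explicit ``bad_mask``.  Good samples feed a
    smoothing spline whose penalty is selected by generalized
    cross-validation; the spline fills the gaps on the uniform grid.
    Returns ``(cleaned, excluded)`` — ``excluded`` is True when more than
    20% of the trace is bad, in which case the raw resample is returned
    unfilled.
    """
    t = samples["t_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("gaze timestamps must be strictly increasing")
    x = samples["x_deg"].to_numpy(float)
    y = samples["y_deg"].to_numpy(float)
    bad = ~np.isfinite(x) | ~np.isfinite(y)
    bad |= (np.abs(np.nan_to_num(x)) > max_abs_deg) | (np.abs(np.nan_to_num(y)) > max_abs_deg)
    if bad_mask is not None:
        bad |= np.asarray(bad_mask, bool)
    dt = 1.0 / sample_rate_hz
    grid = np.arange(t[0], t[-1], dt)
    frac_bad = float(bad.mean())
    excluded = frac_bad > BAD_FRACTION_LIMIT
    out = {}
    for name, v in (("x_deg", x), ("y_deg", y)):
        good = ~bad & np.isfinite(v)
        if not bad.any():
            out[name] = np.interp(grid, t, v)
            continue
        if excluded or good.sum() < 10:
            out[name] = np.interp(grid, t[good], v[good]) if good.any() else np.full_like(grid, np.nan)
            continue
        tg, vg = t[good], v[good]
        if len(tg) > 400:  # the GCV solve is cubic-ish in n; thin the support
            idx = np.unique(np.linspace(0, len(tg) - 1, 400).astype(int))
            tg, vg = tg[idx], vg[idx]
        spl = make_smoothing_spline(tg, vg)  # GCV-selected penalty
        vv = np.interp(grid, t[good], v[good])
        gap = np.interp(grid, t, bad.astype(float)) > 0.5
        vv[gap] = spl(grid[gap])
        out[name] = vv
    cleaned = pd.DataFrame({"t_s": grid, "x_deg": out["x_deg"], "y_deg": out["y_deg"]})
    return cleaned, excluded


def _dwell_episodes(t: np.ndarray, inside: np.ndarray):
    """(start, end) times of consecutive runs of inside samples."""
    if not inside.any():
        return []
    dt = np.median(np.diff(t)) if len(t) > 1 else 0.0
    idx = np.flatnonzero(inside)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    ends = np.r_[idx[breaks], idx[-1]]
    return [(float(t[a]), float(t[b] + dt)) for a, b in zip(starts, ends)]


def detect_fixations(
    cleaned: pd.DataFrame,
    geometry: LeverGeometry,
    t_start: float | None = None,
    t_end: float | None = None,
) -> list[FixationEvent]:
    """Lever fixations: dwell >= 150 ms inside a lever window, merged per lever.

    Episodes on the same lever separated by <= 150 ms are merged before the
    duration threshold is applied.  ``t_start``/``t_end`` restrict the
    analysis period (typically 1 s before EoT to the lever touch).
    """
    t = cleaned["t_s"].to_numpy(float)
    x = cleaned["x_deg"].to_numpy(float)
    y = cleaned["y_deg"].to_numpy(float)
    mask = np.ones(len(t), bool)
    if t_start is not None:
        mask &= t >= t_start
    if t_end is not None:
        mask &= t <= t_end
    t, x, y = t[mask], x[mask], y[mask]
    events: list[FixationEvent] = []
    half = geometry.half_window_deg
    for lever, (cx, cy) in (
        ("WORK_POS", geometry.work_pos_deg),
        ("CHECK_POS", geometry.check_pos_deg),
    ):
        inside = (np.abs(x - cx) <= half) & (np.abs(y - cy) <= half)
        episodes = _dwell_episodes(t, inside)
        merged: list[list[float]] = []
        for a, b in episodes:
            if merged and a - merged[-1][1] <= MERGE_GAP_S:
                merged[-1][1] = b
            else:
                merged.append([a, b])
        for a, b in merged:
            if b - a >= MIN_FIXATION_S:
                events.append(FixationEvent(lever=lever, start_s=a, end_s=b))
    return sorted(events, key=lambda e: e.start_s)


def gaze_measures(fixations: list[FixationEvent], touch_s: float) -> dict:
    """Scan / last-fixation latency / fixation count for one pre-decision period.

    ``scan`` is 1 when both lever windows were fixated; the latency is the
    END of the last lever fixation relative to the touch (negative =
    before); ``n_fixations`` is defined only on scan trials.
    """
    levers = {f.lever for f in fixations}
    scan = int({"WORK_POS", "CHECK_POS"} <= levers)
    latency = max((f.end_s for f in fixations), default=np.nan) - touch_s if fixations else np.nan
    return {
        "scan": scan,
        "last_fixation_latency_s": float(latency) if fixations else np.nan,
        "n_fixations": len(fixations) if scan else np.nan,
    }


def session_gaze_measures(
    gaze: pd.DataFrame,
    trials,
    geometry: LeverGeometry | None = None,
    sample_rate_hz: float = 186.0,
) -> pd.DataFrame:
    """Per-trial oculomotor measures plus model covariates for a session.

    The pre-decision period of trial i runs from 1 s before trial i-1's EoT
    to trial i's lever touch.  Trials with no usable gaze, or excluded in
    cleaning, are dropped.
    """
    from .behavior import previous_performance
    from .synth import distance_to_check

    geometry = geometry or LeverGeometry()
    prev = previous_performance(trials)
    dists = distance_to_check(trials)
    rows = []
    by_trial = dict(tuple(gaze.groupby("trial_index"))) if "trial_index" in gaze else {}
    for i in range(1, len(trials)):
        tr = trials[i]
        sub = by_trial.get(tr.trial_index)
        if sub is None or len(sub) < 20 or prev[i] not in ("COR", "INC"):
            continue
        if tr.choice not in ("CHECK", "WORK"):
            continue
        try:
            cleaned, excluded = preprocess_gaze(sub, sample_rate_hz)
        except ValueError:
            continue
        if excluded:
            continue
        touch = tr.events["lever_touch"]
        t0 = trials[i - 1].events["end_of_trial"] - 1.0
        fix = detect_fixations(cleaned, geometry, t_start=t0, t_end=touch)
        m = gaze_measures(fix, touch)
        m.update(
            trial_index=tr.trial_index,
            gauge=float(tr.gauge_level),
            dist_to_check=float(min(dists[i], 20)),
            prev=1.0 if prev[i] == "INC" else 0.0,
            checkwork=1.0 if tr.choice == "CHECK" else 0.0,
        )
        rows.append(m)
    return pd.DataFrame(rows)


def gaze_glms(measures: pd.DataFrame, min_trials: int = 50) -> dict:
    """The three oculomotor GLMs on a per-trial measures table.

    Scan ~ gauge + dist + prev + checkwork (binomial); last-fixation latency
    ~ same (Gaussian, identity link); n_fixations ~ same (Poisson, scan
    trials only).  Separation or degenerate responses are flagged rather
    than raised.
    """
    if len(measures) < min_trials:
        raise ValueError(f"need >= {min_trials} trials with gaze, got {len(measures)}")
    formula_rhs = "gauge + dist_to_check + prev + checkwork"
    out: dict[str, object] = {}
    try:
        scan_fit = smf.glm(
            f"scan ~ {formula_rhs}", data=measures, family=sm.families.Binomial()
        ).fit()
        if np.any(np.abs(scan_fit.params) > 30):
            out["scan"] = None
            out["scan_flag"] = "separation suspected"
        else:
            out["scan"] = scan_fit
    except Exception as exc:
        out["scan"] = None
        out["scan_flag"] = str(exc)
    lat = measures.dropna(subset=["last_fixation_latency_s"])
    out["latency"] = smf.ols(f"last_fixation_latency_s ~ {formula_rhs}", data=lat).fit()
    nf = measures[(measures["scan"] == 1) & np.isfinite(measures["n_fixations"])]
    if len(nf) >= 10:
        out["n_fixations"] = smf.glm(
            f"n_fixations ~ {formula_rhs}", data=nf, family=sm.families.Poisson()
        ).fit()
    else:
        out["n_fixations"] = None
    return out
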