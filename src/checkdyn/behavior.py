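"""Behavioral stage: checking model, RT model, reward rate, re-check distance.

Four descriptive/regression analyses of the trial stream:

* :func:`fit_check_model` — logistic regression of the odds of Checking on
  gauge size, previous-trial performance, gauge speed and block number.
* :func:`fit_rt_model` — linear model of log reaction time on difficulty,
  previous performance and block number.
* :func:`reward_rate_profile` — within-block reward rate per time decile,
  observed and under a no-checking counterfactual that excludes the time
  spent checking.
* :func:`distance_vs_gauge` — how the gauge size seen at one check predicts
  the number of trials before the next check.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .core import TrialRecord

logger = logging.getLogger(__name__)


def previous_performance(trials: list[TrialRecord]) -> list[str]:
    """Three-level previous-trial outcome per trial: COR, INC or CHECK.

    The first trial (no predecessor) gets 'NA'.
    """
    out = ["NA"]
    for prev in trials[:-1]:
        if prev.choice == "CHECK":
            out.append("CHECK")
        elif prev.choice == "CONTROL":
            out.append("NA")
        else:
            out.append(prev.feedback)
    return out


def trials_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    """Covariate table used by the behavioral models."""
    lengths = tuple(sorted({t.block_required_correct for t in trials}))
    from .synth import _speed_rank

    df = pd.DataFrame(
        {
            "trial_index": [t.trial_index for t in trials],
            "choice": [t.choice for t in trials],
            "check": [int(t.choice == "CHECK") for t in trials],
            "gauge": [t.gauge_level for t in trials],
            "prev": previous_performance(trials),
            "speed": [_speed_rank(t.block_required_correct, lengths) for t in trials],
            "block": [t.block_index for t in trials],
            "difficulty": [t.difficulty for t in trials],
            "feedback": [t.feedback for t in trials],
            "rt": [t.reaction_time_s for t in trials],
        }
    )
    return df


def fit_check_model(trials: list[TrialRecord]):
    """Binomial GLM: check ~ Gauge + PreviousPerformance + Speed + BlockNumber.

    Reference levels are COR for previous performance and speed 1.  CONTROL
    trials and the session's first trial are excluded.  Returns the fitted
    statsmodels results object (estimates, SEs, z, p per term).
    """
    df = trials_frame(trials)
    df = df[(df["choice"] != "CONTROL") & (df["prev"] != "NA")].copy()
    n_check, n_work = int(df["check"].sum()), int((1 - df["check"]).sum())
    if n_check < 2 or n_work < 2:
        raise ValueError(f"need >=2 checks and >=2 works (got {n_check}, {n_work})")
    df["prev"] = pd.Categorical(df["prev"], categories=["COR", "INC", "CHECK"])
    df["speed"] = pd.Categorical(df["speed"], categories=sorted(df["speed"].unique()))
    formula = "check ~ gauge + C(prev) + C(speed) + block"
    if df["speed"].nunique() < 2:
        formula = "check ~ gauge + C(prev) + block"
    try:
        fit = smf.glm(formula, data=df, family=sm.families.Binomial()).fit()
    except Exception as exc:  # pragma: no cover - statsmodels raise path
        raise ValueError(f"check model failed (possible separation): {exc}") from exc
    if np.any(np.abs(fit.params) > 30):
        raise ValueError(
            "complete separation suspected in check model: "
            f"extreme coefficients {dict(fit.params[np.abs(fit.params) > 30])}"
        )
    return fit


def fit_rt_model(trials: list[TrialRecord]):
    """OLS of log RT on difficulty, previous performance and block number.

    Uses completed WORK trials preceded by a COR or INC outcome.  Returns
    (fit, anova_table) with type-II ANOVA p-values per term.
    """
    df = trials_frame(trials)
    df = df[(df["choice"] == "WORK") & df["prev"].isin(["COR", "INC"])].copy()
    df = df[np.isfinite(df["rt"])]
    if (df["rt"] <= 0).any():
        raise ValueError("non-positive reaction times")
    df["log_rt"] = np.log(df["rt"])
    df["difficulty"] = df["difficulty"].astype(int)
    df["prev"] = pd.Categorical(df["prev"], categories=["COR", "INC"])
    fit = smf.ols("log_rt ~ C(difficulty) + C(prev) + block", data=df).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    return fit, anova


# ---------------------------------------------------------------------------
# Reward rate
# ---------------------------------------------------------------------------


def _block_spans(trials: list[TrialRecord]):
    """Yield (block_index, list of trials) for completed (bonus-earning) blocks."""
    by_block: dict[int, list[TrialRecord]] = {}
    for t in trials:
        by_block.setdefault(t.block_index, []).append(t)
    for b, ts in sorted(by_block.items()):
        last = ts[-1]
        completed = (
            last.choice == "CHECK" and last.correct_count_in_block >= last.block_required_correct
        )
        yield b, ts, completed


def reward_rate_profile(
    trials: list[TrialRecord],
    reward_ml: float = 0.5,
    bonus_ml: float = 3.5,
    n_deciles: int = 10,
) -> pd.DataFrame:
    """Reward rate (ml/min) per within-block time decile, with a no-check counterfactual.

    Each completed block's elapsed time is split into ``n_deciles`` equal
    bins.  The observed rate divides the reward delivered in a bin by the
    bin's duration; the counterfactual divides by the bin duration minus the
    time spent on Check trials inside the bin (reward unchanged), emulating
    an agent that never pays the time cost of checking.  The final decile
    contains the bonus.  Blocks without a bonus delivery are excluded (logged).
    Returns per (block, decile) rows plus the per-decile mean across blocks
    under block = -1.
    """
    rows = []
    n_excluded = 0
    for b, ts, completed in _block_spans(trials):
        if not completed:
            n_excluded += 1
            continue
        t0 = ts[0].events["lever_onset"]
        t1 = ts[-1].events["end_of_trial"]
        edges = np.linspace(t0, t1, n_deciles + 1)
        reward = np.zeros(n_deciles)
        check_time = np.zeros(n_deciles)
        for i, tr in enumerate(ts):
            span_end = ts[i + 1].events["lever_onset"] if i + 1 < len(ts) else t1
            if tr.feedback == "COR":
                k = min(np.searchsorted(edges, tr.events["feedback_onset"], "right") - 1, n_deciles - 1)
                reward[k] += reward_ml
            if tr.choice == "CHECK":
                # Apportion the full check-trial span across the bins it covers.
                a, z = tr.events["lever_onset"], span_end
                lo = np.clip(edges[:-1], a, z)
                hi = np.clip(edges[1:], a, z)
                check_time += np.maximum(hi - lo, 0.0)
        reward[-1] += bonus_ml  # bonus delivered at the block-ending check
        dur = np.diff(edges)
        with np.errstate(divide="ignore"):
            rate_with = reward / (dur / 60.0)
            cf_dur = np.maximum(dur - check_time, 1e-9)
            rate_without = reward / (cf_dur / 60.0)
        for k in range(n_deciles):
            rows.append(
                {
                    "block": b,
                    "decile": k + 1,
                    "reward_ml": reward[k],
                    "time_s": dur[k],
                    "check_time_s": check_time[k],
                    "rate_with_check": rate_with[k],
                    "rate_without_check": rate_without[k],
                }
            )
    if n_excluded:
        logger.info("reward_rate_profile: excluded %d blocks without bonus", n_excluded)
    if not rows:
        raise ValueError("no completed blocks")
    df = pd.DataFrame(rows)
    mean = (
        df.groupby("decile", as_index=False)[
            ["reward_ml", "time_s", "check_time_s", "rate_with_check", "rate_without_check"]
        ]
        .mean()
        .assign(block=-1)
    )
    return pd.concat([df, mean], ignore_index=True)


# ---------------------------------------------------------------------------
# Distance to next check vs observed gauge
# ---------------------------------------------------------------------------


def distance_vs_gauge(trials: list[TrialRecord], n_strata: int = 3) -> dict:
    """Distance (trials) between consecutive checks vs the gauge seen first.

    For every pair of consecutive checks within a block, records the gauge
    level observed at the first check and the number of trials until the
    next.  Pairs are stratified by how many trials had been performed in the
    block at the first check (tertiles by default).  Returns the pair table,
    per (gauge, stratum) means, and Pearson/Spearman correlations.
    """
    from scipy import stats

    pairs = []
    by_block: dict[int, list[TrialRecord]] = {}
    for t in trials:
        by_block.setdefault(t.block_index, []).append(t)
    for b, ts in sorted(by_block.items()):
        check_pos = [i for i, t in enumerate(ts) if t.choice == "CHECK"]
        for i, j in zip(check_pos, check_pos[1:]):
            pairs.append(
                {
                    "block": b,
                    "gauge_seen": ts[i].gauge_level,
                    "distance": j - i,
                    "trials_in_block": i + 1,
                }
            )
    table = pd.DataFrame(pairs)
    if table.empty:
        return {"pairs": table, "means": table, "pearson": (np.nan, np.nan), "spearman": (np.nan, np.nan)}
    if table["trials_in_block"].nunique() >= n_strata:
        table["stratum"] = pd.qcut(
            table["trials_in_block"], n_strata, labels=False, duplicates="drop"
        )
    else:
        table["stratum"] = 0
    means = (
        table.groupby(["gauge_seen", "stratum"], as_index=False)["distance"]
        .agg(["mean", "count"])
        .rename(columns={"mean": "mean_distance", "count": "n"})
    )
    if table["gauge_seen"].nunique() > 1 and table["distance"].nunique() > 1:
        pear = stats.pearsonr(table["gauge_seen"], table["distance"])
        spear = stats.spearmanr(table["gauge_seen"], table["distance"])
        pearson = (float(pear.statistic), float(pear.pvalue))
        spearman = (float(spear.statistic), float(spear.pvalue))
    else:
        pearson = spearman = (np.nan, np.nan)
    return {"pairs": table, "means": means, "pearson": pearson, "spearman": spearman}
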