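"""Per-unit time-resolved encoding via sliding Poisson/negative-binomial GLMs.

Spike counts in overlapping 200 ms bins (50 ms step) are regressed on task
factors, bin by bin.  Each bin starts as a Poisson GLM; when the residual
deviance per degree of freedom signals overdispersion, a negative-binomial
fit is attempted and retained if a likelihood-ratio test on the NB shape
parameter is significant.  A unit is classified as encoding a factor when
the factor's p-value stays below 0.05 for at least four consecutive bins
(350 ms on the stepped grid) inside a predefined epoch; its preference sign
is the sign of the Wald Z at the maximal |Z| within the significant run.

Sign conventions match the rest of the pipeline: positive Z means greater
activity for Correct feedback, Check decisions, or Right cued choices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import AlignmentSpec, TrialRecord, UnitSpikeTrain, bin_counts, pearson_chi2_2x2

logger = logging.getLogger(__name__)

#: Overdispersion ratio above which the NB refit is attempted, and the LRT
#: level at which it is retained.
DISPERSION_TRIGGER = 1.2
NB_LRT_ALPHA = 0.05


@dataclass(frozen=True)
class ModelSpec:
    """A sliding-GLM formula: named terms mapped onto trial covariates."""

    name: str
    terms: tuple[str, ...]
    alignment_events: tuple[str, ...]


#: Feedback-period model: feedback valence, the upcoming Check/Work decision,
#: and the gauge level as a 1-7 covariate.  Aligned on feedback onset and EoT;
#: the synthetic pseudo-event ``next_lever_touch`` (the next trial's lever
#: touch) supports the peri-decision epoch for the next-decision term.
FEEDBACK_MODEL = ModelSpec(
    name="FEEDBACK_MODEL",
    terms=("feedback", "checkwork", "gauge"),
    alignment_events=("feedback_onset", "end_of_trial", "next_lever_touch"),
)

#: Cued-decision model: chosen side, difficulty, gauge covariate.  Aligned on
#: cue onset and target touch.
CUED_MODEL = ModelSpec(
    name="CUED_MODEL",
    terms=("space", "difficulty", "gauge"),
    alignment_events=("cue_onset", "target_touch"),
)

MODELS = {m.name: m for m in (FEEDBACK_MODEL, CUED_MODEL)}


def build_design(trials: list[TrialRecord], spec: ModelSpec):
    """Covariate table and eligible trials for one model.

    Returns ``(design, eligible_trials)``.  Coding: feedback COR=1/INC=0,
    checkwork (next decision) CHECK=1/WORK=0, space RIGHT=1/LEFT=0,
    difficulty and gauge as linear covariates.
    """
    from dataclasses import replace as _replace

    rows = []
    eligible = []
    for i, tr in enumerate(trials):
        if tr.choice != "WORK" or tr.feedback == "NA":
            continue
        row = {}
        if "feedback" in spec.terms:
            row["feedback"] = 1.0 if tr.feedback == "COR" else 0.0
        if "checkwork" in spec.terms:
            if i + 1 >= len(trials) or trials[i + 1].choice not in ("CHECK", "WORK"):
                continue
            row["checkwork"] = 1.0 if trials[i + 1].choice == "CHECK" else 0.0
        if "space" in spec.terms:
            if tr.cued_side == "NA":
                continue
            row["space"] = 1.0 if tr.cued_side == "RIGHT" else 0.0
        if "difficulty" in spec.terms:
            if tr.difficulty is None:
                continue
            row["difficulty"] = float(tr.difficulty)
        if "gauge" in spec.terms:
            row["gauge"] = float(tr.gauge_level)
        rows.append(row)
        if i + 1 < len(trials) and "lever_touch" in trials[i + 1].events:
            tr = _replace(
                tr,
                events={**tr.events, "next_lever_touch": trials[i + 1].events["lever_touch"]},
            )
        eligible.append(tr)
    design = pd.DataFrame(rows, columns=list(spec.terms))
    return design, eligible


def compute_vif(design: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factor per regressor: 1 / (1 - R^2_j).

    Exact collinearity yields ``inf`` with a warning.
    """
    if design.shape[1] < 2:
        raise ValueError("VIF needs at least two regressors")
    X = design.to_numpy(float)
    vifs = {}
    for j, name in enumerate(design.columns):
        yj = X[:, j]
        others = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        beta, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        ss_res = np.sum(resid**2)
        if ss_tot == 0 or ss_res / ss_tot < 1e-12:
            warnings.warn(f"exact collinearity involving {name!r}; VIF infinite")
            vifs[name] = float("inf")
        else:
            vifs[name] = float(1.0 / (ss_res / ss_tot))
    return vifs


def fit_bin_glm(
    counts: np.ndarray,
    design: pd.DataFrame,
    spec: ModelSpec,
    dispersion_trigger: float = DISPERSION_TRIGGER,
    nb_lrt_alpha: float = NB_LRT_ALPHA,
    min_trials_per_level: int = 10,
) -> dict:
    """Fit one time bin: Poisson GLM with a validated NB fallback.

    Returns a record with family, dispersion ratio, per-term (coef, z, p)
    and a ``converged`` flag.  Overdispersion triggers an NB refit which is
    retained only when the likelihood-ratio test on the NB shape parameter
    (chi2, df=1) is significant.
    """
    counts = np.asarray(counts)
    rec: dict = {"family": "POISSON", "converged": True, "degenerate": False}
    for lvl_col in design.columns:
        vals = design[lvl_col].to_numpy()
        if len(np.unique(vals)) <= 4:  # categorical-ish term
            _, n_per = np.unique(vals, return_counts=True)
            if n_per.min() < min_trials_per_level:
                rec["converged"] = False
                rec["flag"] = f"fewer than {min_trials_per_level} trials in a level of {lvl_col}"
    X = np.column_stack([np.ones(len(design)), design.to_numpy(float)])
    names = list(design.columns)
    if counts.max() == 0:
        rec["degenerate"] = True
        rec["converged"] = False
        rec["dispersion_ratio"] = np.nan
        for t in names:
            rec[f"coef_{t}"], rec[f"z_{t}"], rec[f"p_{t}"] = 0.0, 0.0, 1.0
        return rec
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pois = sm.GLM(counts, X, family=sm.families.Poisson()).fit()
        disp = pois.deviance / pois.df_resid
        rec["dispersion_ratio"] = float(disp)
        chosen = pois
        if disp > dispersion_trigger:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                nb = sm.NegativeBinomial(counts, X).fit(
                    disp=0, maxiter=100, start_params=np.r_[pois.params, 0.1]
                )
            if nb.mle_retvals.get("converged", False):
                lr = 2.0 * (nb.llf - pois.llf)
                p_lrt = stats.chi2.sf(max(lr, 0.0), df=1)
                if p_lrt < nb_lrt_alpha:
                    chosen = nb
                    rec["family"] = "NEGBIN"
        params = np.asarray(chosen.params)
        zvals = np.asarray(chosen.tvalues)
        pvals = np.asarray(chosen.pvalues)
        for k, t in enumerate(names, start=1):
            rec[f"coef_{t}"] = float(params[k])
            rec[f"z_{t}"] = float(zvals[k])
            rec[f"p_{t}"] = float(pvals[k]) if np.isfinite(pvals[k]) else 1.0
    except Exception as exc:
        rec["converged"] = False
        rec["flag"] = f"fit failed: {exc}"
        rec.setdefault("dispersion_ratio", np.nan)
        for t in names:
            rec[f"coef_{t}"], rec[f"z_{t}"], rec[f"p_{t}"] = np.nan, np.nan, 1.0
    return rec


@dataclass
class EncodingProfile:
    """Per-bin sliding-GLM results for one unit under one model/alignment."""

    unit_id: str
    area: str
    model: ModelSpec
    alignment: AlignmentSpec
    records: pd.DataFrame  # one row per bin
    vif: dict[str, float] = field(default_factory=dict)


def encode_unit(
    unit: UnitSpikeTrain,
    trials: list[TrialRecord],
    spec: ModelSpec,
    alignment: AlignmentSpec,
    **fit_kwargs,
) -> EncodingProfile:
    """Run the sliding GLM over every bin of the alignment grid."""
    design, eligible = build_design(trials, spec)
    if design.empty:
        raise ValueError("no eligible trials for model " + spec.name)
    binned = bin_counts(unit, eligible, alignment)
    keep = np.isin([t.trial_index for t in eligible], binned.trial_ids)
    design = design.loc[keep].reset_index(drop=True)
    vif = compute_vif(design) if design.shape[1] >= 2 else {}
    rows = []
    for j, center in enumerate(binned.bin_centers_s):
        rec = fit_bin_glm(binned.counts[:, j], design, spec, **fit_kwargs)
        rec["bin_center_s"] = float(center)
        rows.append(rec)
    return EncodingProfile(
        unit_id=unit.unit_id,
        area=unit.area,
        model=spec,
        alignment=alignment,
        records=pd.DataFrame(rows),
        vif=vif,
    )


# ---------------------------------------------------------------------------
# Significance classification
# ---------------------------------------------------------------------------


def significant_runs(p: np.ndarray, ok: np.ndarray, alpha: float, n_consec: int):
    """Indices of runs of >= n_consec consecutive converged bins with p < alpha."""
    hit = (p < alpha) & ok
    runs = []
    start = None
    for i, h in enumerate(np.append(hit, False)):
        if h and start is None:
            start = i
        elif not h and start is not None:
            if i - start >= n_consec:
                runs.append((start, i))
            start = None
    return runs


def classify_profile(
    profile: EncodingProfile,
    epoch: tuple[float, float],
    alpha: float = 0.05,
    n_consec: int = 4,
) -> dict:
    """Apply the four-consecutive-bin rule per term within an epoch.

    Significant terms get the signed maximal |Z| inside the significant runs
    and the time of the first significant bin; nonsignificant terms get
    max_abs_z = 0 (the convention the clustering features rely on).
    """
    df = profile.records
    centers = df["bin_center_s"].to_numpy()
    in_epoch = (centers >= epoch[0]) & (centers <= epoch[1])
    ok = df["converged"].to_numpy(bool)
    out = {"unit_id": profile.unit_id, "area": profile.area}
    for t in profile.model.terms:
        p = np.where(in_epoch, df[f"p_{t}"].to_numpy(), 1.0)
        runs = significant_runs(p, ok, alpha, n_consec)
        if runs:
            z = df[f"z_{t}"].to_numpy()
            best = 0.0
            first = np.inf
            for a, b in runs:
                seg = z[a:b]
                zi = seg[np.argmax(np.abs(seg))]
                if abs(zi) > abs(best):
                    best = zi
                first = min(first, centers[a])
            out[f"{t}_significant"] = True
            out[f"{t}_sign"] = int(np.sign(best))
            out[f"{t}_max_abs_z"] = float(abs(best))
            out[f"{t}_signed_max_z"] = float(best)
            out[f"{t}_first_sig_s"] = float(first)
        else:
            out[f"{t}_significant"] = False
            out[f"{t}_sign"] = 0
            out[f"{t}_max_abs_z"] = 0.0
            out[f"{t}_signed_max_z"] = 0.0
            out[f"{t}_first_sig_s"] = np.nan
    return out


def classify_units(
    profiles: list[EncodingProfile],
    epochs: dict[str, tuple[float, float]],
    alpha: float = 0.05,
    n_consec: int = 4,
    use_terms: dict[str, tuple[str, ...]] | None = None,
) -> dict:
    """Classify every unit and compare encoding proportions between areas.

    ``epochs`` maps ``"MODEL:event"`` (or just the model name) to the
    (start, end) test window in aligned seconds; ``use_terms`` with the same
    keys restricts which terms a profile contributes when the same model is
    run on several alignments.  Returns the per-unit classification table,
    per-area proportion table, pairwise area chi2 per term, and the
    Check/Space congruence cross-table (counts of units significant for both
    factors whose preference signs agree, per area).
    """

    def _lookup(d, profile):
        key = f"{profile.model.name}:{profile.alignment.event_name}"
        if key in d:
            return d[key]
        return d.get(profile.model.name)

    merged: dict[tuple[str, str], dict] = {}
    for p in profiles:
        epoch = _lookup(epochs, p)
        if epoch is None:
            raise KeyError(f"no epoch configured for {p.model.name}:{p.alignment.event_name}")
        r = classify_profile(p, epoch, alpha=alpha, n_consec=n_consec)
        keep = _lookup(use_terms, p) if use_terms else None
        if keep is not None:
            r = {
                k: v
                for k, v in r.items()
                if k in ("unit_id", "area") or any(k.startswith(f"{t}_") for t in keep)
            }
        key = (r["unit_id"], r["area"])
        merged.setdefault(key, {"unit_id": r["unit_id"], "area": r["area"]}).update(r)
    table = pd.DataFrame(list(merged.values()))
    terms = sorted(
        {c.rsplit("_significant", 1)[0] for c in table.columns if c.endswith("_significant")}
    )
    prop_rows = []
    chi2: dict[str, tuple[float, float]] = {}
    for t in terms:
        col = f"{t}_significant"
        counts = {}
        for area in ("MCC", "LPFC"):
            sub = table[table["area"] == area]
            n_sig = int(sub[col].fillna(False).sum())
            counts[area] = (n_sig, len(sub))
            prop_rows.append(
                {
                    "term": t,
                    "area": area,
                    "n_significant": n_sig,
                    "n_units": len(sub),
                    "proportion": n_sig / len(sub) if len(sub) else np.nan,
                }
            )
        (a, na), (b, nb) = counts["MCC"], counts["LPFC"]
        if na and nb and 0 < a + b < na + nb:
            chi2[t] = pearson_chi2_2x2(a, na - a, b, nb - b)
    congruence = {}
    if {"checkwork_significant", "space_significant"} <= set(table.columns):
        for area in ("MCC", "LPFC"):
            sub = table[table["area"] == area]
            both = sub[
                sub["checkwork_significant"].fillna(False)
                & sub["space_significant"].fillna(False)
            ]
            congruent = int((both["checkwork_sign"] == both["space_sign"]).sum())
            congruence[area] = {
                "n_checkwork": int(sub["checkwork_significant"].fillna(False).sum()),
                "n_both": len(both),
                "n_congruent": congruent,
            }
    return {
        "classification": table,
        "proportions": pd.DataFrame(prop_rows),
        "area_chi2": chi2,
        "congruence": congruence,
    }


def feature_correlation(
    table: pd.DataFrame, term_a: str, term_b: str, by_area: bool = True
) -> dict:
    """Pearson r of max |Z| features between two terms across units.

    Zeros for nonsignificant units are kept, mirroring the clustering
    feature convention.  Returns per-area (r, p); NA when degenerate.
    """
    out = {}
    groups = table.groupby("area") if by_area else [("ALL", table)]
    for area, sub in groups:
        if len(sub) < 20:
            out[area] = (np.nan, np.nan)
            continue
        x = sub[f"{term_a}_max_abs_z"].to_numpy(float)
        y = sub[f"{term_b}_max_abs_z"].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            out[area] = (np.nan, np.nan)
            continue
        r = stats.pearsonr(x, y)
        out[area] = (float(r.statistic), float(r.pvalue))
    return out
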