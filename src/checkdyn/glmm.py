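"""Group-level Poisson mixed models with observation-level random effects.

The group analysis asks whether the *population* of units in an area encodes
a task factor, bin by bin: spike counts from all units enter one Poisson
regression with the task factors as fixed effects and the unit identity as a
random intercept, so heterogeneous baselines do not masquerade as effects.
Because spike counts are overdispersed relative to Poisson, an
observation-level random effect (OLRE) — one Gaussian random intercept per
count — absorbs the extra-Poisson variance, exactly as a log-normal
mixture would.

Fitting uses a Laplace approximation of the marginal likelihood (the same
strategy as lme4's ``glmer``): for candidate variance components the joint
penalized Poisson log-likelihood is maximized over fixed and random effects
with a sparse Newton solver, the random effects are integrated out by the
Laplace formula, and the variance components maximize that approximate
marginal likelihood.  The marginal log-likelihood also yields the AIC used
to compare fits with and without the OLRE.  No maintained Python package
fits Poisson GLMMs with crossed observation-level effects and reports a
marginal AIC, so the Laplace machinery is implemented here and is validated
in the tests against the degenerate-limit Poisson GLM and an independent
``glmer`` fit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats
from scipy.special import gammaln
from scipy.sparse.linalg import splu

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupModelSpec:
    """Fixed terms plus the random structure of the group model.

    ``fixed`` names columns of the long table (e.g. checkwork, gauge, prev).
    The random structure is a unit intercept by default; ``olre`` adds the
    observation-level effect; ``random_slopes`` optionally gives units random
    slopes for the named fixed terms (heavier, off by default).
    """

    fixed: tuple[str, ...] = ("checkwork", "gauge", "prev")
    olre: bool = True
    random_slopes: tuple[str, ...] = ()


@dataclass
class GroupBinFit:
    """One bin's mixed-model fit."""

    estimates: pd.DataFrame  # term, beta, se, z, p, ci_lo, ci_hi
    variance_components: dict[str, float]
    loglik: float
    aic: float
    deviance: float
    converged: bool
    singular: bool
    method: str  # 'laplace' or 'pql'
    aic_no_olre: float | None = None
    deviance_no_olre: float | None = None


# ---------------------------------------------------------------------------
# Laplace-approximate Poisson GLMM
# ---------------------------------------------------------------------------


def _random_design(df: pd.DataFrame, spec: GroupModelSpec):
    """Sparse random-effects design Z and the grouping of its columns.

    Returns (Z, groups) where groups is a list of (name, column slice) —
    one variance component per group.
    """
    units = pd.Categorical(df["unit_id"])
    n = len(df)
    n_u = len(units.categories)
    blocks = []
    groups = []
    col0 = 0
    # unit intercepts
    Zu = sparse.csc_matrix(
        (np.ones(n), (np.arange(n), units.codes)), shape=(n, n_u)
    )
    blocks.append(Zu)
    groups.append(("unit_intercept", slice(col0, col0 + n_u)))
    col0 += n_u
    for term in spec.random_slopes:
        Zs = sparse.csc_matrix(
            (df[term].to_numpy(float), (np.arange(n), units.codes)), shape=(n, n_u)
        )
        blocks.append(Zs)
        groups.append((f"unit_slope_{term}", slice(col0, col0 + n_u)))
        col0 += n_u
    if spec.olre:
        blocks.append(sparse.eye(n, format="csc"))
        groups.append(("olre", slice(col0, col0 + n)))
        col0 += n
    Z = sparse.hstack(blocks, format="csc")
    return Z, groups


def _inner_mode(y, X, Z, prec, psi0=None, max_iter=50, tol=1e-8):
    """Newton maximization of the joint penalized Poisson log-likelihood.

    ``prec`` is the diagonal prior precision for the random effects.
    Returns (beta, b, H_lu, Hbb_lu, joint_loglik_kernel, converged).
    """
    n, p = X.shape
    q = Z.shape[1]
    Xs = sparse.csc_matrix(X)
    psi = np.zeros(p + q) if psi0 is None else psi0.copy()
    A = sparse.hstack([Xs, Z], format="csc")
    P = sparse.diags(np.concatenate([np.zeros(p), prec]), format="csc")
    ll_old = -np.inf
    converged = False
    lu = None
    for _ in range(max_iter):
        eta = A @ psi
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        grad = A.T @ (y - mu) - P @ psi
        W = sparse.diags(mu, format="csc")
        H = (A.T @ W @ A + P).tocsc()
        lu = splu(H.tocsc(), permc_spec="MMD_AT_PLUS_A")
        step = lu.solve(grad)
        # line search on the penalized objective
        def objective(v):
            e = np.clip(A @ v, -30, 30)
            return float(np.sum(y * e - np.exp(e)) - 0.5 * v @ (P @ v))

        f0 = objective(psi)
        alpha = 1.0
        for _ in range(30):
            cand = psi + alpha * step
            if objective(cand) >= f0 - 1e-12:
                break
            alpha *= 0.5
        psi = psi + alpha * step
        ll = objective(psi)
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            converged = True
            ll_old = ll
            break
        ll_old = ll
    beta, b = psi[:p], psi[p:]
    eta = np.clip(A @ psi, -30, 30)
    mu = np.exp(eta)
    W = sparse.diags(mu, format="csc")
    Hbb = (Z.T @ W @ Z + sparse.diags(prec)).tocsc()
    H = (A.T @ W @ A + P).tocsc()
    return beta, b, H, Hbb, ll_old, converged, psi


def _sparse_logdet(M: sparse.csc_matrix) -> float:
    lu = splu(M, permc_spec="MMD_AT_PLUS_A")
    return float(np.sum(np.log(np.abs(lu.U.diagonal()))))


def _laplace_loglik(y, X, Z, groups, log_vars, psi0=None):
    """Laplace-approximate marginal log-likelihood at given log-variances."""
    q = Z.shape[1]
    prec = np.empty(q)
    logv = {}
    for (name, sl), lv in zip(groups, log_vars):
        v = math.exp(lv)
        prec[sl] = 1.0 / v
        logv[name] = lv
    beta, b, H, Hbb, kernel, conv, psi = _inner_mode(y, X, Z, prec, psi0)
    # joint log-density including the Gaussian prior normalization
    n_b = q
    prior_norm = -0.5 * float(np.sum(np.log(2 * math.pi / prec)))
    g = kernel - float(np.sum(gammaln(y + 1))) + prior_norm
    ll = g + 0.5 * n_b * math.log(2 * math.pi) - 0.5 * _sparse_logdet(Hbb)
    return ll, beta, b, H, conv, psi


def fit_group_bin(
    long_df: pd.DataFrame,
    spec: GroupModelSpec,
    count_col: str = "count",
    compare_olre: bool = True,
    min_units: int = 10,
) -> GroupBinFit:
    """Fit the Poisson mixed model for one time bin.

    ``long_df`` needs columns ``unit_id``, ``count`` and every fixed term.
    Returns Wald estimates per fixed effect, variance components, the
    Laplace marginal log-likelihood/AIC and — when the spec includes an OLRE
    and ``compare_olre`` — the AIC of the OLRE-free fit for comparison.
    A variance component collapsing to ~0 is pinned and flagged singular,
    not an error.
    """
    n_units = long_df["unit_id"].nunique()
    if n_units < min_units:
        raise ValueError(f"need >= {min_units} units, got {n_units}")
    y = long_df[count_col].to_numpy(float)
    X = np.column_stack(
        [np.ones(len(long_df))] + [long_df[t].to_numpy(float) for t in spec.fixed]
    )
    names = ["intercept", *spec.fixed]

    def _fit(sub_spec: GroupModelSpec):
        Z, groups = _random_design(long_df, sub_spec)
        x0 = np.full(len(groups), math.log(0.25))
        state = {"psi": None}

        def neg(lv):
            ll, *_, psi = _laplace_loglik(y, X, Z, groups, lv, state["psi"])
            state["psi"] = psi
            return -ll

        res = optimize.minimize(
            neg, x0, method="Nelder-Mead",
            options={"xatol": 2e-3, "fatol": 1e-3, "maxiter": 80},
        )
        lv = np.clip(res.x, -12.0, 6.0)
        ll, beta, b, H, conv, psi = _laplace_loglik(y, X, Z, groups, lv, state["psi"])
        vcomp = {name: float(math.exp(v)) for (name, _), v in zip(groups, lv)}
        singular = any(v < 1e-4 for v in vcomp.values())
        n_par = X.shape[1] + len(groups)
        aic = -2.0 * ll + 2.0 * n_par
        # Wald covariance of beta: top-left block of the joint Hessian inverse
        p = X.shape[1]
        lu = splu(H.tocsc(), permc_spec="MMD_AT_PLUS_A")
        cov = np.column_stack(
            [lu.solve(np.eye(H.shape[0], 1, -k).ravel()) for k in range(p)]
        )[:p]
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        return ll, beta, se, vcomp, singular, aic, conv and res.success

    ll, beta, se, vcomp, singular, aic, conv = _fit(spec)
    aic_no, dev_no = None, None
    if spec.olre and compare_olre:
        from dataclasses import replace

        ll0, *_rest = _fit(replace(spec, olre=False))
        n_par0 = X.shape[1] + 1 + len(spec.random_slopes)
        aic_no = -2.0 * ll0 + 2.0 * n_par0
        dev_no = -2.0 * ll0
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    est = pd.DataFrame(
        {
            "term": names,
            "beta": beta,
            "se": se,
            "z": z,
            "p": pvals,
            "ci_lo": beta - 1.96 * se,
            "ci_hi": beta + 1.96 * se,
        }
    )
    return GroupBinFit(
        estimates=est,
        variance_components=vcomp,
        loglik=float(ll),
        aic=float(aic),
        deviance=float(-2.0 * ll),
        converged=bool(conv),
        singular=bool(singular),
        method="laplace",
        aic_no_olre=None if aic_no is None else float(aic_no),
        deviance_no_olre=None if dev_no is None else float(dev_no),
    )


# ---------------------------------------------------------------------------
# Timecourse
# ---------------------------------------------------------------------------


@dataclass
class GroupFitTimecourse:
    """Per-bin fixed-effect estimates across the alignment grid."""

    table: pd.DataFrame  # bin_center_s, term, beta, se, z, p, significant
    bin_fits: dict[float, GroupBinFit] = field(default_factory=dict)


def group_long_table(
    units,
    trials,
    alignment,
    scan: dict[int, int] | None = None,
    max_trials: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Long (unit x trial x bin) count table with group-model covariates.

    Covariates: ``checkwork`` (1=Check), ``gauge`` (1-7), ``prev``
    (1=previous trial incorrect), optional ``scan`` per trial index.
    Eligible trials are Check/Work choices whose previous trial ended COR or
    INC (so ``prev`` is defined).  ``max_trials`` subsamples eligible trials
    (keeping every Check, which is the rare class) to bound the mixed-model
    problem size.
    """
    from .behavior import previous_performance
    from .core import bin_counts

    prev = previous_performance(trials)
    keep = [
        i
        for i, tr in enumerate(trials)
        if tr.choice in ("CHECK", "WORK") and prev[i] in ("COR", "INC")
    ]
    if max_trials is not None and len(keep) > max_trials:
        rng = np.random.default_rng(seed)
        checks = [i for i in keep if trials[i].choice == "CHECK"]
        works = [i for i in keep if trials[i].choice == "WORK"]
        n_work = max(max_trials - len(checks), len(checks))
        works = sorted(rng.choice(works, size=min(n_work, len(works)), replace=False))
        keep = sorted(checks + list(works))
    kept_trials = [trials[i] for i in keep]
    cov = pd.DataFrame(
        {
            "trial_index": [t.trial_index for t in kept_trials],
            "checkwork": [1.0 if t.choice == "CHECK" else 0.0 for t in kept_trials],
            "gauge": [float(t.gauge_level) for t in kept_trials],
            "prev": [1.0 if prev[keep[j]] == "INC" else 0.0 for j in range(len(keep))],
        }
    )
    if scan is not None:
        cov["scan"] = [float(scan.get(t.trial_index, 0)) for t in kept_trials]
    frames = []
    for u in units:
        bm = bin_counts(u, kept_trials, alignment)
        sub = cov[cov["trial_index"].isin(bm.trial_ids)].reset_index(drop=True)
        for j, center in enumerate(bm.bin_centers_s):
            f = sub.copy()
            f["count"] = bm.counts[:, j]
            f["bin_center_s"] = float(center)
            f["unit_id"] = u.unit_id
            frames.append(f)
    return pd.concat(frames, ignore_index=True)


def glmm_timecourse(
    long_df: pd.DataFrame,
    spec: GroupModelSpec,
    alpha: float = 0.05,
    compare_olre: bool = False,
) -> GroupFitTimecourse:
    """Fit :func:`fit_group_bin` independently at every bin.

    Significance markers are per-bin at ``alpha`` with no multiplicity
    correction (matching the display convention of the source analyses);
    bins whose fit fails are reported missing, never interpolated.
    """
    rows = []
    fits: dict[float, GroupBinFit] = {}
    for center, sub in long_df.groupby("bin_center_s", sort=True):
        try:
            fit = fit_group_bin(sub, spec, compare_olre=compare_olre)
        except Exception as exc:
            logger.warning("glmm_timecourse: bin %.3f failed: %s", center, exc)
            continue
        fits[float(center)] = fit
        for _, r in fit.estimates.iterrows():
            rows.append(
                {
                    "bin_center_s": float(center),
                    "term": r["term"],
                    "beta": r["beta"],
                    "se": r["se"],
                    "z": r["z"],
                    "p": r["p"],
                    "significant": bool(r["p"] < alpha),
                    "singular": fit.singular,
                }
            )
    return GroupFitTimecourse(table=pd.DataFrame(rows), bin_fits=fits)
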