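"""Regularized linear population decoding with cross-temporal generalization.

Units recorded in different sessions are combined into pseudotrials: for
each repetition every neuron contributes spike counts from its own randomly
sampled trials of the matching condition, yielding synthetic simultaneous
population vectors.  A ridge (Tikhonov) readout with classes coded +/-1 is
trained on a 60% partition (regularization chosen by 5-fold CV minimizing
the sum of squared errors on the training partition only) and scored on the
held-out 40%.  Repeating the under-sampling 200 times gives the mean
decoding rate; training at time t and testing at t+i exposes whether the
population code is static (square generalization) or dynamic (a diagonal
band).  Significance comes from re-running the full pipeline on label
shuffles within each neuron's trial set.  A Lasso variant decodes the
distance to the next check from inter-trial activity and counts, per
neuron, how often its coefficient survives the L1 penalty — the
contributing-neuron census.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import AlignmentSpec, TrialRecord, UnitSpikeTrain, bin_counts

logger = logging.getLogger(__name__)

#: Default log-spaced Tikhonov grid (the data do not pin the scale; config key).
DEFAULT_LAMBDAS = np.logspace(-3, 3, 20)


# ---------------------------------------------------------------------------
# Pseudotrial machinery
# ---------------------------------------------------------------------------


def class_variable(name: str):
    """Trial -> class label (or None to exclude) for the decodable factors.

    ``checkwork`` keeps only trials preceded by a correct cued decision, the
    same eligibility the behavioral structure imposes on real checks.
    """

    def feedback(trials, i):
        t = trials[i]
        return t.feedback if t.feedback in ("COR", "INC") else None

    def checkwork(trials, i):
        if i == 0 or trials[i - 1].feedback != "COR":
            return None
        t = trials[i]
        return t.choice if t.choice in ("CHECK", "WORK") else None

    def cued(trials, i):
        t = trials[i]
        return t.cued_side if t.cued_side in ("LEFT", "RIGHT") else None

    try:
        return {"feedback": feedback, "checkwork": checkwork, "cued": cued}[name]
    except KeyError:
        raise ValueError(f"unknown class variable {name!r}") from None


@dataclass
class PopulationCounts:
    """Per-unit binned counts and class labels, the decoder's input."""

    counts: list[np.ndarray]  # per unit: (n_trials_u, n_bins)
    labels: list[np.ndarray]  # per unit: (n_trials_u,) class strings
    unit_ids: list[str]
    classes: tuple[str, str]
    bin_centers_s: np.ndarray


def population_counts(
    units: list[UnitSpikeTrain],
    trials: list[TrialRecord],
    class_var: str,
    align: AlignmentSpec,
    n_per_condition: int = 20,
) -> PopulationCounts:
    """Bin every unit and attach class labels; drop units below the trial floor."""
    label_fn = class_variable(class_var)
    labels_all = [label_fn(trials, i) for i in range(len(trials))]
    keep = [i for i, lab in enumerate(labels_all) if lab is not None]
    kept_trials = [trials[i] for i in keep]
    kept_labels = np.array([labels_all[i] for i in keep])
    classes = tuple(sorted(np.unique(kept_labels)))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    counts, labels, unit_ids = [], [], []
    n_dropped = 0
    centers = align.bin_centers_s
    for u in units:
        bm = bin_counts(u, kept_trials, align)
        mask = np.isin([t.trial_index for t in kept_trials], bm.trial_ids)
        labs = kept_labels[mask]
        if min((labs == c).sum() for c in classes) < n_per_condition:
            n_dropped += 1
            continue
        counts.append(bm.counts)
        labels.append(labs)
        unit_ids.append(u.unit_id)
        centers = bm.bin_centers_s
    if n_dropped:
        logger.info("population_counts: dropped %d units below the trial floor", n_dropped)
    if not counts:
        raise ValueError("no eligible units")
    return PopulationCounts(counts, labels, unit_ids, classes, centers)


def assemble_pseudotrials(
    pop: PopulationCounts,
    n_per_condition: int,
    rng: np.random.Generator,
    permute_labels: bool = False,
):
    """One repetition's pseudotrial tensor: (2*n_per, n_units, n_bins), y in {-1,+1}.

    Each neuron's trials are sampled without replacement within the
    repetition; ``permute_labels`` shuffles the class labels within each
    neuron's trial set first (the permutation-null construction).
    """
    n_units = len(pop.counts)
    n_bins = pop.counts[0].shape[1]
    X = np.empty((2 * n_per_condition, n_units, n_bins))
    y = np.concatenate([np.full(n_per_condition, -1.0), np.full(n_per_condition, 1.0)])
    for u in range(n_units):
        labs = pop.labels[u]
        if permute_labels:
            labs = rng.permutation(labs)
        for k, cls in enumerate(pop.classes):
            idx = np.flatnonzero(labs == cls)
            pick = rng.choice(idx, size=n_per_condition, replace=False)
            X[k * n_per_condition : (k + 1) * n_per_condition, u, :] = pop.counts[u][pick]
    return X, y


def stratified_split(y: np.ndarray, train_frac: float, rng: np.random.Generator):
    """Per-class 60/40 split of pseudotrial indices (no degenerate partitions)."""
    tr, te = [], []
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        k = int(round(train_frac * len(idx)))
        k = min(max(k, 1), len(idx) - 1)
        tr.append(idx[:k])
        te.append(idx[k:])
    return np.concatenate(tr), np.concatenate(te)


# ---------------------------------------------------------------------------
# Ridge readout
# ---------------------------------------------------------------------------


@dataclass
class LinearReadout:
    """A linear decoder: sign(X @ weights + intercept) predicts the class."""

    weights: np.ndarray
    intercept: float
    regularization: str
    selected_lambda: float
    converged: bool = True

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(X @ self.weights + self.intercept >= 0, 1.0, -1.0)

    def accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        if not self.converged:
            return 0.5
        return float(np.mean(self.predict(X) == y))


def _ridge_path(Xtr: np.ndarray, ytr: np.ndarray, lambdas: np.ndarray):
    """Closed-form ridge solutions for every lambda via one SVD.

    Returns (W, b): W[k] are the weights at lambdas[k], b[k] the intercepts.
    Centered formulation, so the intercept is unpenalized.
    """
    xm = Xtr.mean(axis=0)
    ym = ytr.mean()
    Xc = Xtr - xm
    yc = ytr - ym
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    uy = U.T @ yc
    # shrinkage factors s/(s^2 + lam), per lambda
    W = np.einsum("kj,jp->kp", (s / (s[None, :] ** 2 + lambdas[:, None])) * uy[None, :], Vt)
    b = ym - W @ xm
    return W, b


def train_ridge(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray = DEFAULT_LAMBDAS,
    n_folds: int = 5,
    rng: np.random.Generator | None = None,
) -> LinearReadout:
    """Ridge readout with lambda chosen by 5-fold CV on the training SSE.

    Classes are coded +/-1; for each lambda the squared error summed over
    the folds' held-out pseudotrials is computed and the minimizer is refit
    on the full training partition.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("training partition needs both classes")
    rng = rng or np.random.default_rng()
    lambdas = np.asarray(lambdas, float)
    n = len(y)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    sse = np.zeros(len(lambdas))
    for f in folds:
        mask = np.ones(n, bool)
        mask[f] = False
        if len(np.unique(y[mask])) < 2 or not mask.any():
            continue
        W, b = _ridge_path(X[mask], y[mask], lambdas)
        pred = X[f] @ W.T + b  # (n_val, n_lambda)
        sse += np.sum((pred - y[f][:, None]) ** 2, axis=0)
    k = int(np.argmin(sse))
    W, b = _ridge_path(X, y, lambdas[k : k + 1])
    return LinearReadout(
        weights=W[0],
        intercept=float(b[0]),
        regularization="TIKHONOV",
        selected_lambda=float(lambdas[k]),
    )


# ---------------------------------------------------------------------------
# Timecourse and cross-temporal decoding
# ---------------------------------------------------------------------------


@dataclass
class DecodingResult:
    """Decoding accuracies, their permutation null, and derived statistics."""

    bin_centers_s: np.ndarray
    accuracy: np.ndarray  # (n_bins, n_rep) or (n_bins, n_bins, n_rep)
    classes: tuple[str, str]
    class_var: str
    mode: str  # 'timecourse' | 'crosstemporal' | 'distance'
    null_accuracy: np.ndarray | None = None  # (n_bins, n_perm) mean-over-rep nulls
    p_per_bin: np.ndarray | None = None
    first_significant_s: float | None = None
    nonzero_fraction: pd.DataFrame | None = None  # lasso census
    extras: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> np.ndarray:
        return self.accuracy.mean(axis=-1)


def _decode_rep(
    pop: PopulationCounts,
    n_per_condition: int,
    lambdas: np.ndarray,
    train_frac: float,
    rng: np.random.Generator,
    cross: bool,
    permute_labels: bool = False,
) -> np.ndarray:
    """One repetition: accuracy per bin (or per train x test bin if cross)."""
    X, y = assemble_pseudotrials(pop, n_per_condition, rng, permute_labels)
    tr, te = stratified_split(y, train_frac, rng)
    n_bins = X.shape[2]
    if cross:
        acc = np.empty((n_bins, n_bins))
        for jt in range(n_bins):
            model = train_ridge(X[tr, :, jt], y[tr], lambdas, rng=rng)
            for jv in range(n_bins):
                acc[jt, jv] = model.accuracy(X[te, :, jv], y[te])
        return acc
    acc = np.empty(n_bins)
    for j in range(n_bins):
        model = train_ridge(X[tr, :, j], y[tr], lambdas, rng=rng)
        acc[j] = model.accuracy(X[te, :, j], y[te])
    return acc


def decode_timecourse(
    units: list[UnitSpikeTrain],
    trials: list[TrialRecord],
    class_var: str,
    align: AlignmentSpec,
    n_per_condition: int = 20,
    n_rep: int = 200,
    train_frac: float = 0.6,
    lambdas: np.ndarray = DEFAULT_LAMBDAS,
    seed: int | np.random.Generator = 0,
    cross_temporal: bool = False,
) -> DecodingResult:
    """Per-bin (or cross-temporal) ridge decoding averaged over repetitions."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pop = population_counts(units, trials, class_var, align, n_per_condition)
    reps = [
        _decode_rep(pop, n_per_condition, lambdas, train_frac, rng, cross_temporal)
        for _ in range(n_rep)
    ]
    acc = np.stack(reps, axis=-1)
    return DecodingResult(
        bin_centers_s=pop.bin_centers_s,
        accuracy=acc,
        classes=pop.classes,
        class_var=class_var,
        mode="crosstemporal" if cross_temporal else "timecourse",
    )


def cross_temporal(
    units, trials, class_var, align, **kwargs
) -> DecodingResult:
    """Train at bin t, test at bin t'; diagonal matches :func:`decode_timecourse`."""
    return decode_timecourse(units, trials, class_var, align, cross_temporal=True, **kwargs)


def permutation_null(
    units: list[UnitSpikeTrain],
    trials: list[TrialRecord],
    class_var: str,
    align: AlignmentSpec,
    observed: DecodingResult,
    n_perm: int = 1000,
    n_per_condition: int = 20,
    n_rep: int | None = None,
    train_frac: float = 0.6,
    lambdas: np.ndarray = DEFAULT_LAMBDAS,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> DecodingResult:
    """Permutation significance for a timecourse decoding result.

    Class labels are shuffled independently within each neuron's trial set
    before pseudotrial assembly and the full pipeline re-runs; each
    permutation's statistic is the mean accuracy over repetitions, and
    ``p = (1 + #{null >= observed}) / (1 + n_perm)`` per bin (add-one rule;
    accuracy has a one-sided alternative).  Fills ``null_accuracy``,
    ``p_per_bin`` and ``first_significant_s`` on a copy of ``observed``.
    """
    if n_perm < 100:
        logger.warning("permutation_null: n_perm=%d is low; p-values are coarse", n_perm)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_rep is None:
        n_rep = observed.accuracy.shape[-1]
    pop = population_counts(units, trials, class_var, align, n_per_condition)
    n_bins = len(pop.bin_centers_s)
    null = np.empty((n_bins, n_perm))
    for m in range(n_perm):
        reps = np.stack(
            [
                _decode_rep(
                    pop, n_per_condition, lambdas, train_frac, rng, False, permute_labels=True
                )
                for _ in range(n_rep)
            ],
            axis=-1,
        )
        null[:, m] = reps.mean(axis=-1)
    obs_mean = observed.mean_accuracy
    p = (1.0 + np.sum(null >= obs_mean[:, None], axis=1)) / (1.0 + n_perm)
    sig = p < alpha
    first = float(observed.bin_centers_s[np.argmax(sig)]) if sig.any() else None
    return DecodingResult(
        bin_centers_s=observed.bin_centers_s,
        accuracy=observed.accuracy,
        classes=observed.classes,
        class_var=observed.class_var,
        mode=observed.mode,
        null_accuracy=null,
        p_per_bin=p,
        first_significant_s=first,
    )


def compare_areas(
    res_a: DecodingResult,
    res_b: DecodingResult,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank-test (Kruskal-Wallis) comparison of two areas' decoders, per bin.

    Only bins where at least one area decodes significantly (its permutation
    p < alpha) are tested; the Bonferroni factor is exactly the number of
    eligible bins.  Returns a table with the corrected p and which area
    leads where significant.
    """
    if res_a.accuracy.shape != res_b.accuracy.shape:
        raise ValueError("results must share bin grid and repetition count")
    if res_a.p_per_bin is None or res_b.p_per_bin is None:
        raise ValueError("run permutation_null on both results first")
    eligible = np.flatnonzero((res_a.p_per_bin < alpha) | (res_b.p_per_bin < alpha))
    rows = []
    m = len(eligible)
    for j in eligible:
        stat, p = stats.kruskal(res_a.accuracy[j], res_b.accuracy[j])
        p_corr = min(p * m, 1.0)
        leader = None
        if p_corr < alpha:
            leader = "A" if res_a.accuracy[j].mean() > res_b.accuracy[j].mean() else "B"
        rows.append(
            {
                "bin_center_s": res_a.bin_centers_s[j],
                "statistic": stat,
                "p_corrected": p_corr,
                "correction_factor": m,
                "leader": leader,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Lasso distance-to-check decoding
# ---------------------------------------------------------------------------


def _intertrial_counts(
    units: list[UnitSpikeTrain],
    trials: list[TrialRecord],
    window_s: float = 2.0,
):
    """Spike counts in the inter-trial window (EoT to +window) per unit/trial."""
    align = AlignmentSpec("end_of_trial", 0.0, window_s, bin_width_s=window_s, bin_step_s=window_s)
    out = []
    for u in units:
        bm = bin_counts(u, trials, align)
        out.append((bm.trial_ids, bm.counts[:, 0]))
    return out


def lasso_distance_decoding(
    units: list[UnitSpikeTrain],
    trials: list[TrialRecord],
    distances: tuple[int, ...] = (0, 1, 2, 3),
    reference: tuple[int, int] = (5, 10),
    n_per_class: int = 15,
    n_rep: int = 200,
    train_frac: float = 0.6,
    lambdas: np.ndarray | None = None,
    census_threshold: float = 0.10,
    max_iter: int = 1000,
    seed: int | np.random.Generator = 0,
    pairwise: tuple[tuple[int, int], ...] = ((0, 1), (0, 2)),
) -> dict:
    """Decode distance-to-check classes from inter-trial activity with a Lasso.

    For each distance d in ``distances`` the correct-preceded trials exactly
    d trials before a check are decoded against a reference set at distance
    ``reference[0]``..``reference[1]``, with the same 60/40 split and 5-fold
    CV selection of the L1 penalty.  A non-converged fit contributes 50%.
    Returns per-distance DecodingResults with a per-neuron census of
    non-zero coefficients (thresholded at ``census_threshold``), the
    pairwise Venn counts of contributing neurons, and direct pairwise
    decodings (e.g. n vs n-1).
    """
    from sklearn.linear_model import Lasso

    from .synth import distance_to_check

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if lambdas is None:
        # On standardized features with +/-1 targets the informative sparse
        # regime sits near alpha_max ~ max correlation (<~1); penalties much
        # below ~0.15 saturate the active set at these sample sizes and make
        # the non-zero census uninterpretable.
        lambdas = np.logspace(-0.8, 0.5, 6)
    dists = distance_to_check(trials)
    prev_ok = np.zeros(len(trials), bool)
    for i in range(1, len(trials)):
        prev_ok[i] = trials[i - 1].feedback == "COR"
    correct = np.array([t.feedback == "COR" for t in trials])
    eligible = prev_ok & correct  # correct trials preceded by a correct decision

    counts = _intertrial_counts(units, trials)
    index_of = {t.trial_index: i for i, t in enumerate(trials)}

    def trials_at(condition) -> list[np.ndarray]:
        """Per-unit count vectors for trials matching a distance condition."""
        per_unit = []
        for ids, c in counts:
            pos = np.array([index_of[i] for i in ids])
            m = eligible[pos] & condition(dists[pos])
            per_unit.append(c[m])
        return per_unit

    def decode_two_sets(set_a, set_b, rng) -> tuple[np.ndarray, np.ndarray]:
        """Repeated lasso decoding of two per-unit trial sets; returns
        (accuracy per rep, nonzero-coefficient indicator per rep x unit).

        Features are standardized on the training partition so the common
        L1 penalty treats high- and low-rate neurons alike.
        """
        import warnings as _warnings

        from sklearn.exceptions import ConvergenceWarning

        n_units = len(set_a)
        accs = np.empty(n_rep)
        nonzero = np.zeros((n_rep, n_units), bool)
        for r in range(n_rep):
            Xa = np.column_stack([rng.choice(a, n_per_class, replace=False) for a in set_a])
            Xb = np.column_stack([rng.choice(b, n_per_class, replace=False) for b in set_b])
            X = np.vstack([Xa, Xb]).astype(float)
            y = np.r_[np.full(n_per_class, 1.0), np.full(n_per_class, -1.0)]
            tr, te = stratified_split(y, train_frac, rng)
            mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0)
            sd[sd == 0] = 1.0
            X = (X - mu) / sd
            # 5-fold CV over the penalty grid on the training partition
            order = rng.permutation(tr)
            folds = np.array_split(order, 5)
            sse = np.zeros(len(lambdas))
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", ConvergenceWarning)
                for f in folds:
                    m = np.setdiff1d(tr, f)
                    if len(np.unique(y[m])) < 2:
                        continue
                    for k, lam in enumerate(lambdas):
                        mdl = Lasso(alpha=lam, max_iter=max_iter)
                        mdl.fit(X[m], y[m])
                        sse[k] += float(np.sum((mdl.predict(X[f]) - y[f]) ** 2))
                lam = lambdas[int(np.argmin(sse))]
                mdl = Lasso(alpha=lam, max_iter=max_iter)
                mdl.fit(X[tr], y[tr])
            converged = int(np.max(np.atleast_1d(mdl.n_iter_))) < max_iter
            if not converged:
                accs[r] = 0.5
                continue
            pred = np.where(mdl.predict(X[te]) >= 0, 1.0, -1.0)
            accs[r] = float(np.mean(pred == y[te]))
            nonzero[r] = mdl.coef_ != 0
        return accs, nonzero

    ref_sets = trials_at(lambda d: (d >= reference[0]) & (d <= reference[1]))
    results: dict[int, DecodingResult] = {}
    census_sets: dict[int, set[int]] = {}
    unit_ids = [u.unit_id for u in units]
    for d in distances:
        d_sets = trials_at(lambda x, d=d: x == d)
        n_min = min(min(len(a) for a in d_sets), min(len(r) for r in ref_sets))
        if n_min < n_per_class:
            logger.info("distance %d: only %d trials (< %d); reported missing", d, n_min, n_per_class)
            results[d] = None
            continue
        accs, nonzero = decode_two_sets(d_sets, ref_sets, rng)
        frac = nonzero.mean(axis=0)
        census = pd.DataFrame({"unit_id": unit_ids, "nonzero_fraction": frac})
        census["contributing"] = frac >= census_threshold
        results[d] = DecodingResult(
            bin_centers_s=np.array([1.0]),
            accuracy=accs[None, :],
            classes=(f"n-{d}" if d else "n", "reference"),
            class_var="distance",
            mode="distance",
            nonzero_fraction=census,
        )
        census_sets[d] = set(np.flatnonzero(census["contributing"].to_numpy()))
    venn = {}
    for a in census_sets:
        for b in census_sets:
            if a < b:
                venn[(a, b)] = {
                    "only_a": len(census_sets[a] - census_sets[b]),
                    "only_b": len(census_sets[b] - census_sets[a]),
                    "both": len(census_sets[a] & census_sets[b]),
                }
    pairwise_results = {}
    for a, b in pairwise:
        sa = trials_at(lambda x, a=a: x == a)
        sb = trials_at(lambda x, b=b: x == b)
        n_min = min(min(len(s) for s in sa), min(len(s) for s in sb))
        if n_min < n_per_class:
            pairwise_results[(a, b)] = None
            continue
        accs, _ = decode_two_sets(sa, sb, rng)
        pairwise_results[(a, b)] = float(accs.mean())
    return {"by_distance": results, "venn": venn, "pairwise": pairwise_results}


# ---------------------------------------------------------------------------
# Nonlinear control
# ---------------------------------------------------------------------------


def svm_rbf_control(
    units: list[UnitSpikeTrain],
    trials: list[TrialRecord],
    class_var: str,
    align: AlignmentSpec,
    n_per_condition: int = 20,
    n_rep: int = 50,
    train_frac: float = 0.6,
    C_grid: tuple[float, ...] = (0.1, 1.0, 10.0),
    gamma_grid: tuple[str, ...] = ("scale",),
    seed: int | np.random.Generator = 0,
) -> DecodingResult:
    """RBF-kernel SVM under the identical resampling protocol (sanity control).

    Hyperparameters are chosen per repetition by 5-fold CV accuracy on the
    training partition; output is bin-by-bin comparable to the ridge result.
    """
    from sklearn.model_selection import GridSearchCV
    from sklearn.svm import SVC

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pop = population_counts(units, trials, class_var, align, n_per_condition)
    n_bins = len(pop.bin_centers_s)
    acc = np.empty((n_bins, n_rep))
    grid = {"C": list(C_grid), "gamma": list(gamma_grid)}
    for r in range(n_rep):
        X, y = assemble_pseudotrials(pop, n_per_condition, rng)
        tr, te = stratified_split(y, train_frac, rng)
        for j in range(n_bins):
            search = GridSearchCV(SVC(kernel="rbf"), grid, cv=5, scoring="accuracy")
            search.fit(X[tr, :, j], y[tr])
            acc[j, r] = float(np.mean(search.predict(X[te, :, j]) == y[te]))
    return DecodingResult(
        bin_centers_s=pop.bin_centers_s,
        accuracy=acc,
        classes=pop.classes,
        class_var=class_var,
        mode="timecourse",
        extras={"classifier": "svm_rbf"},
    )
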