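"""Population decoding: pseudotrials, ridge oracle, nulls, lasso, SVM."""

from __future__ import annotations

import numpy as np
import pytest

from checkdyn.core import AlignmentSpec
from checkdyn.decoding import (
    DEFAULT_LAMBDAS,
    PopulationCounts,
    assemble_pseudotrials,
    compare_areas,
    decode_timecourse,
    lasso_distance_decoding,
    permutation_null,
    population_counts,
    stratified_split,
    svm_rbf_control,
    train_ridge,
)
from checkdyn.synth import (
    AgentPolicy,
    EffectSpec,
    TaskConfig,
    TuningSpec,
    make_population,
    simulate_spikes,
    simulate_task,
)


def synthetic_pop(n_units=12, n_trials=60, n_bins=3, signal=0.0, seed=0):
    """Hand-built PopulationCounts with optional class-mean separation."""
    rng = np.random.default_rng(seed)
    counts, labels = [], []
    for u in range(n_units):
        lab = np.array(["A", "B"])[rng.integers(0, 2, n_trials)]
        base = rng.poisson(5.0, (n_trials, n_bins)).astype(float)
        base[lab == "A"] += signal * rng.uniform(0.5, 1.5)
        counts.append(base)
        labels.append(lab)
    return PopulationCounts(
        counts, labels, [f"u{u}" for u in range(n_units)], ("A", "B"),
        np.linspace(0, 1, n_bins),
    )


class TestPseudotrials:
    def test_two_classes_give_forty_pseudotrials(self):
        pop = synthetic_pop()
        X, y = assemble_pseudotrials(pop, 20, np.random.default_rng(0))
        assert X.shape == (40, 12, 3)
        assert (y == 1).sum() == 20 and (y == -1).sum() == 20

    def test_same_seed_same_sampling(self):
        pop = synthetic_pop()
        X1, _ = assemble_pseudotrials(pop, 15, np.random.default_rng(7))
        X2, _ = assemble_pseudotrials(pop, 15, np.random.default_rng(7))
        np.testing.assert_array_equal(X1, X2)

    def test_marginal_class_means_match_source_trials(self):
        pop = synthetic_pop(signal=3.0, seed=1)
        rng = np.random.default_rng(2)
        sums = np.zeros((2, len(pop.counts)))
        n_rep = 200
        for _ in range(n_rep):
            X, y = assemble_pseudotrials(pop, 10, rng)
            sums[0] += X[y == -1, :, 0].mean(axis=0)
            sums[1] += X[y == 1, :, 0].mean(axis=0)
        for u in range(len(pop.counts)):
            for k, cls in enumerate(pop.classes):
                true_mean = pop.counts[u][pop.labels[u] == cls, 0].mean()
                assert sums[k, u] / n_rep == pytest.approx(true_mean, rel=0.05)

    def test_stratified_split_keeps_both_classes(self):
        y = np.r_[np.full(20, -1.0), np.full(20, 1.0)]
        tr, te = stratified_split(y, 0.6, np.random.default_rng(0))
        assert len(tr) == 24 and len(te) == 16
        assert set(np.unique(y[tr])) == {-1.0, 1.0}
        assert set(np.unique(y[te])) == {-1.0, 1.0}


class TestTrainRidge:
    def test_matches_normal_equations_oracle(self):
        """Closed-form centered ridge solution on a fixed 5x3 matrix."""
        X = np.array(
            [[1.0, 2.0, 0.5], [0.0, 1.0, 1.5], [2.0, 0.0, 1.0], [1.5, 1.0, 0.0], [0.5, 2.0, 2.0]]
        )
        y = np.array([1.0, -1.0, 1.0, -1.0, 1.0])
        lam = 0.7
        model = train_ridge(X, y, lambdas=np.array([lam]), rng=np.random.default_rng(0))
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        w = np.linalg.solve(Xc.T @ Xc + lam * np.eye(3), Xc.T @ yc)
        np.testing.assert_allclose(model.weights, w, atol=1e-8)
        assert model.intercept == pytest.approx(y.mean() - X.mean(axis=0) @ w, abs=1e-8)

    def test_matches_sklearn_ridge(self):
        from sklearn.linear_model import Ridge

        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (30, 8))
        y = np.sign(rng.normal(0, 1, 30))
        lam = 3.0
        model = train_ridge(X, y, lambdas=np.array([lam]), rng=rng)
        sk = Ridge(alpha=lam).fit(X, y)
        np.testing.assert_allclose(model.weights, sk.coef_, atol=1e-6)
        assert model.intercept == pytest.approx(sk.intercept_, abs=1e-6)

    def test_huge_lambda_shrinks_to_class_prior(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (40, 5))
        y = np.r_[np.full(20, 1.0), np.full(20, -1.0)]
        model = train_ridge(X, y, lambdas=np.array([1e12]), rng=rng)
        assert np.max(np.abs(model.weights)) < 1e-6

    def test_separable_toy_reaches_full_training_accuracy(self):
        y = np.r_[np.full(10, 1.0), np.full(10, -1.0)]
        X = np.c_[y * 3.0 + 0.1 * np.arange(20), np.ones(20)]
        model = train_ridge(X, y, lambdas=np.array([1e-3]), rng=np.random.default_rng(0))
        assert model.accuracy(X, y) == 1.0

    def test_unconverged_readout_scores_fifty_percent(self):
        model = train_ridge(
            np.eye(4), np.array([1.0, 1.0, -1.0, -1.0]),
            lambdas=np.array([1.0]), rng=np.random.default_rng(0),
        )
        model.converged = False
        assert model.accuracy(np.eye(4), np.array([1.0, 1.0, -1.0, -1.0])) == 0.5


class TestDecodeTimecourse:
    @pytest.fixture(scope="class")
    def trials(self):
        return simulate_task(TaskConfig(n_blocks=20), AgentPolicy(), 13)

    def test_untuned_population_decodes_at_chance(self, trials):
        specs = [TuningSpec(f"u{i}", "MCC", 6.0, 2.0) for i in range(20)]
        units = simulate_spikes(trials, specs, 0)
        align = AlignmentSpec("lever_touch", -0.2, 0.4)
        res = decode_timecourse(
            units, trials, "checkwork", align, n_per_condition=12, n_rep=100, seed=1
        )
        assert np.all(np.abs(res.mean_accuracy - 0.5) < 0.05)

    def test_planted_signal_latency_recovered(self, trials):
        specs = [
            TuningSpec(
                f"u{i}", "MCC", 6.0, 2.0,
                (EffectSpec("CHECKWORK", 9.0, -0.2, 0.7),) if i < 8 else (),
            )
            for i in range(25)
        ]
        units = simulate_spikes(trials, specs, 1)
        align = AlignmentSpec("lever_touch", -1.0, 0.8)
        res = decode_timecourse(
            units, trials, "checkwork", align, n_per_condition=12, n_rep=30, seed=2
        )
        above = res.bin_centers_s[res.mean_accuracy > 0.65]
        assert len(above) > 0
        assert above[0] == pytest.approx(-0.2, abs=0.15)

    def test_amplitude_monotonicity(self, trials):
        accs = []
        for amp in (5.0, 10.0):
            specs = [
                TuningSpec(
                    f"u{i}", "MCC", 6.0, 2.0,
                    (EffectSpec("CHECKWORK", amp, 0.0, 0.4),) if i < 8 else (),
                )
                for i in range(20)
            ]
            units = simulate_spikes(trials, specs, 3)
            align = AlignmentSpec("lever_touch", 0.0, 0.4, bin_width_s=0.4, bin_step_s=0.4)
            res = decode_timecourse(
                units, trials, "checkwork", align, n_per_condition=12, n_rep=30, seed=4
            )
            accs.append(res.mean_accuracy[0])
        assert accs[1] >= accs[0] - 0.03

    def test_cross_temporal_static_code_generalizes(self):
        pop_trials = simulate_task(TaskConfig(n_blocks=16), AgentPolicy(), 14)
        specs = [
            TuningSpec(
                f"u{i}", "MCC", 6.0, 2.0,
                (EffectSpec("FEEDBACK", 8.0 if i % 2 else -8.0, 0.0, 1.2),) if i < 10 else (),
            )
            for i in range(20)
        ]
        units = simulate_spikes(pop_trials, specs, 5)
        align = AlignmentSpec("feedback_onset", 0.0, 1.2, bin_width_s=0.3, bin_step_s=0.3)
        res = decode_timecourse(
            units, pop_trials, "feedback", align,
            n_per_condition=15, n_rep=15, seed=6, cross_temporal=True,
        )
        acc = res.mean_accuracy  # (train, test)
        diag = np.diag(acc)
        assert diag.min() > 0.8
        off = acc[~np.eye(len(diag), dtype=bool)]
        assert off.min() > 0.7  # static code: transfer stays high

    def test_cross_temporal_diagonal_matches_timecourse(self):
        pop_trials = simulate_task(TaskConfig(n_blocks=12), AgentPolicy(), 15)
        specs = [
            TuningSpec(
                f"u{i}", "MCC", 5.0, 2.0,
                (EffectSpec("FEEDBACK", 7.0, 0.1, 0.5),) if i < 6 else (),
            )
            for i in range(15)
        ]
        units = simulate_spikes(pop_trials, specs, 7)
        align = AlignmentSpec("feedback_onset", 0.0, 0.8, bin_width_s=0.4, bin_step_s=0.4)
        kw = dict(n_per_condition=12, n_rep=40)
        tc = decode_timecourse(units, pop_trials, "feedback", align, seed=8, **kw)
        ct = decode_timecourse(
            units, pop_trials, "feedback", align, seed=9, cross_temporal=True, **kw
        )
        np.testing.assert_allclose(np.diag(ct.mean_accuracy), tc.mean_accuracy, atol=0.05)


class TestPermutationNull:
    def test_extreme_observation_gets_add_one_p(self):
        trials = simulate_task(TaskConfig(n_blocks=16), AgentPolicy(), 16)
        specs = [
            TuningSpec(
                f"u{i}", "MCC", 6.0, 2.0, (EffectSpec("FEEDBACK", 12.0, 0.1, 0.5),)
            )
            for i in range(12)
        ]
        units = simulate_spikes(trials, specs, 0)
        align = AlignmentSpec("feedback_onset", 0.1, 0.6, bin_width_s=0.5, bin_step_s=0.5)
        obs = decode_timecourse(
            units, trials, "feedback", align, n_per_condition=15, n_rep=10, seed=1
        )
        res = permutation_null(
            units, trials, "feedback", align, obs,
            n_perm=30, n_per_condition=15, n_rep=5, seed=2,
        )
        assert res.p_per_bin[0] == pytest.approx(1.0 / 31.0)
        assert res.null_accuracy.mean() == pytest.approx(0.5, abs=0.03)
        assert res.first_significant_s is not None


class TestCompareAreas:
    @staticmethod
    def _result(acc, p):
        from checkdyn.decoding import DecodingResult

        return DecodingResult(
            bin_centers_s=np.arange(acc.shape[0], dtype=float),
            accuracy=acc, classes=("A", "B"), class_var="feedback",
            mode="timecourse", p_per_bin=p,
        )

    def test_equivalent_areas_show_no_significant_bins(self):
        rng = np.random.default_rng(0)
        acc_a = 0.7 + 0.02 * rng.standard_normal((3, 50))
        acc_b = 0.7 + 0.02 * rng.standard_normal((3, 50))
        p = np.array([0.01, 0.01, 0.5])
        out = compare_areas(self._result(acc_a, p), self._result(acc_b, p))
        assert (out["correction_factor"] == 2).all()
        assert (out["leader"].isna()).all()

    def test_stronger_area_flagged_as_leader(self):
        rng = np.random.default_rng(1)
        acc_a = 0.85 + 0.02 * rng.standard_normal((2, 60))
        acc_b = 0.60 + 0.02 * rng.standard_normal((2, 60))
        p = np.array([0.01, 0.01])
        out = compare_areas(self._result(acc_a, p), self._result(acc_b, p))
        assert (out["leader"] == "A").all()

    def test_no_eligible_bins_yields_empty_table(self):
        rng = np.random.default_rng(2)
        acc = 0.5 + 0.02 * rng.standard_normal((2, 30))
        p = np.array([0.5, 0.9])
        out = compare_areas(self._result(acc, p), self._result(acc + 0.001, p))
        assert out.empty


class TestLassoDistance:
    @pytest.fixture(scope="class")
    def ramp_session(self):
        trials = simulate_task(TaskConfig(n_blocks=40), AgentPolicy(), 17)
        rng = np.random.default_rng(18)
        specs = []
        for i in range(30):
            effects = ()
            if i < 10:  # ramp units fire increasingly close to a check
                effects = (EffectSpec("DISTANCE_TO_CHECK", 12.0, 0.1, 1.8),)
            specs.append(TuningSpec(f"u{i:02d}", "MCC", float(rng.uniform(3, 8)), 2.0, effects))
        units = simulate_spikes(trials, specs, 19)
        return units, trials, specs

    def test_precheck_ramp_decodable_and_census_finds_ramp_units(self, ramp_session):
        units, trials, specs = ramp_session
        out = lasso_distance_decoding(
            units, trials, distances=(1, 3), n_per_class=12, n_rep=40, seed=20
        )
        res1, res3 = out["by_distance"][1], out["by_distance"][3]
        assert res1 is not None
        assert res1.accuracy.mean() > 0.65  # n-1 is well above chance
        if res3 is not None:
            assert res3.accuracy.mean() < res1.accuracy.mean()
        census = res1.nonzero_fraction
        ramp_ids = {s.unit_id for s in specs if s.effects}
        contributing = set(census[census["contributing"]]["unit_id"])
        assert len(contributing & ramp_ids) >= 0.6 * len(ramp_ids)

    def test_missing_distance_reported_not_raised(self, ramp_session):
        units, trials, _ = ramp_session
        out = lasso_distance_decoding(
            units, trials, distances=(1,), n_per_class=10_000, n_rep=5, seed=21
        )
        assert out["by_distance"][1] is None


class TestSvmControl:
    def test_xor_geometry_beats_linear_readout(self):
        """A 2-unit XOR code is invisible to the ridge but not to the RBF SVM.

        The joint population matrix is fed directly (pseudotrial resampling
        would precisely destroy the cross-neuron structure XOR relies on).
        """
        from sklearn.svm import SVC

        rng = np.random.default_rng(0)
        n = 200
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.integers(0, 2, n).astype(float)
        y = np.where(x1 == x2, 1.0, -1.0)
        X = np.c_[x1 * 8.0, x2 * 8.0] + rng.normal(0, 0.5, (n, 2))
        accs_lin, accs_svm = [], []
        for _ in range(10):
            tr, te = stratified_split(y, 0.6, rng)
            lin = train_ridge(X[tr], y[tr], DEFAULT_LAMBDAS, rng=rng)
            accs_lin.append(lin.accuracy(X[te], y[te]))
            svm = SVC(kernel="rbf", C=10.0).fit(X[tr], y[tr])
            accs_svm.append(np.mean(svm.predict(X[te]) == y[te]))
        assert np.mean(accs_lin) < 0.65  # linear readout cannot solve XOR
        assert np.mean(accs_svm) > np.mean(accs_lin) + 0.2

    def test_matches_ridge_on_linearly_separable_signal(self):
        trials = simulate_task(TaskConfig(n_blocks=14), AgentPolicy(), 23)
        specs = [
            TuningSpec(
                f"u{i}", "MCC", 6.0, 2.0,
                (EffectSpec("FEEDBACK", 10.0, 0.1, 0.5),) if i < 8 else (),
            )
            for i in range(16)
        ]
        units = simulate_spikes(trials, specs, 24)
        align = AlignmentSpec("feedback_onset", 0.1, 0.6, bin_width_s=0.5, bin_step_s=0.5)
        kw = dict(n_per_condition=15, n_rep=15)
        ridge = decode_timecourse(units, trials, "feedback", align, seed=25, **kw)
        svm = svm_rbf_control(units, trials, "feedback", align, seed=26, **kw)
        assert abs(svm.mean_accuracy[0] - ridge.mean_accuracy[0]) < 0.05

    def test_chance_on_untuned_population(self):
        trials = simulate_task(TaskConfig(n_blocks=12), AgentPolicy(), 27)
        specs = [TuningSpec(f"u{i}", "LPFC", 6.0, 2.0) for i in range(10)]
        units = simulate_spikes(trials, specs, 28)
        align = AlignmentSpec("feedback_onset", 0.0, 0.5, bin_width_s=0.5, bin_step_s=0.5)
        res = svm_rbf_control(
            units, trials, "feedback", align, n_per_condition=12, n_rep=15, seed=29
        )
        assert res.mean_accuracy[0] == pytest.approx(0.5, abs=0.12)
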