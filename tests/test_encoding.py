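"""Sliding-GLM encoding: VIF, family selection, run rule, classification."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from checkdyn.core import AlignmentSpec
from checkdyn.encoding import (
    CUED_MODEL,
    FEEDBACK_MODEL,
    classify_units,
    compute_vif,
    encode_unit,
    feature_correlation,
    fit_bin_glm,
    significant_runs,
)
from checkdyn.synth import (
    AgentPolicy,
    EffectSpec,
    TaskConfig,
    TuningSpec,
    simulate_spikes,
    simulate_task,
)


class TestVif:
    def test_orthogonal_design_has_unit_vifs(self):
        design = pd.DataFrame({"a": [1, 1, 0, 0] * 5, "b": [1, 0, 1, 0] * 5})
        assert compute_vif(design) == pytest.approx({"a": 1.0, "b": 1.0})

    def test_correlation_half_gives_four_thirds(self):
        # two standardized regressors with exact correlation 0.5
        n = 40
        rng = np.random.default_rng(0)
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        a = (a - a.mean()) / a.std()
        b = b - b.mean()
        b -= a * (a @ b) / (a @ a)  # orthogonalize
        b /= b.std()
        x2 = 0.5 * a + np.sqrt(1 - 0.25) * b
        vifs = compute_vif(pd.DataFrame({"a": a, "b": x2}))
        assert vifs["a"] == pytest.approx(1 / (1 - 0.25), rel=1e-9)
        assert vifs["b"] == pytest.approx(4 / 3, rel=1e-9)

    def test_matches_brute_force_r2(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((60, 3))
        X[:, 2] += 0.7 * X[:, 0]
        design = pd.DataFrame(X, columns=["a", "b", "c"])
        vifs = compute_vif(design)
        import statsmodels.api as sm

        for j, name in enumerate(design.columns):
            others = sm.add_constant(np.delete(X, j, axis=1))
            r2 = sm.OLS(X[:, j], others).fit().rsquared
            assert vifs[name] == pytest.approx(1 / (1 - r2), rel=1e-8)

    def test_exact_collinearity_reported_infinite(self):
        x = np.arange(10.0)
        with pytest.warns(UserWarning, match="collinearity"):
            vifs = compute_vif(pd.DataFrame({"a": x, "b": 2 * x}))
        assert np.isinf(vifs["a"])


class TestFitBinGlm:
    @staticmethod
    def _design(n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "feedback": rng.integers(0, 2, n).astype(float),
                "checkwork": rng.integers(0, 2, n).astype(float),
                "gauge": rng.integers(1, 8, n).astype(float),
            }
        ), rng

    def test_poisson_coefficient_recovered(self):
        design, rng = self._design(400)
        eta = np.log(2.0) + 0.5 * design["feedback"].to_numpy()
        counts = rng.poisson(np.exp(eta))
        rec = fit_bin_glm(counts, design, FEEDBACK_MODEL)
        assert rec["family"] == "POISSON"
        assert rec["coef_feedback"] == pytest.approx(0.5, abs=3 * 0.08)
        assert rec["p_feedback"] < 1e-4

    def test_negative_binomial_selected_on_overdispersed_counts(self):
        hits = 0
        n_rep = 30
        for s in range(n_rep):
            design, rng = self._design(250, seed=s)
            mult = rng.gamma(2.0, 0.5, len(design))  # NB dispersion theta=2
            counts = rng.poisson(3.0 * mult)
            rec = fit_bin_glm(counts, design, FEEDBACK_MODEL)
            hits += rec["family"] == "NEGBIN"
            assert rec["dispersion_ratio"] > 1.0
        assert hits >= 0.9 * n_rep

    def test_poisson_data_rarely_triggers_nb(self):
        """The NB fallback fires at about the LRT's nominal rate on Poisson data."""
        fires = 0
        n_rep = 150
        for s in range(n_rep):
            design, rng = self._design(150, seed=1000 + s)
            counts = rng.poisson(3.0, len(design))
            rec = fit_bin_glm(counts, design, FEEDBACK_MODEL)
            fires += rec["family"] == "NEGBIN"
        assert fires / n_rep < 0.06

    def test_all_zero_counts_flagged_degenerate(self):
        design, _ = self._design(50)
        rec = fit_bin_glm(np.zeros(50, dtype=int), design, FEEDBACK_MODEL)
        assert rec["degenerate"] and not rec["converged"]


class TestRunRule:
    @pytest.mark.parametrize(
        "pvals, expected",
        [
            ([0.2, 0.01, 0.01, 0.01, 0.01, 0.3], True),
            ([0.01, 0.01, 0.01, 0.2, 0.01], False),
            ([0.01] * 4, True),
            ([0.01] * 3, False),
        ],
    )
    def test_four_consecutive_bin_rule(self, pvals, expected):
        p = np.array(pvals)
        runs = significant_runs(p, np.ones_like(p, bool), 0.05, 4)
        assert bool(runs) is expected

    def test_unconverged_bin_breaks_a_run(self):
        p = np.array([0.01] * 8)
        ok = np.ones(8, bool)
        ok[4] = False
        runs = significant_runs(p, ok, 0.05, 4)
        assert runs == [(0, 4)]


class TestEncodeUnit:
    @pytest.fixture(scope="class")
    def trials(self):
        return simulate_task(TaskConfig(n_blocks=16), AgentPolicy(), 3)

    def test_latency_of_planted_check_tuning_recovered(self, trials):
        spec = TuningSpec(
            "u", "MCC", 6.0, 2.0, (EffectSpec("CHECKWORK", 10.0, 0.3, 0.6),)
        )
        (unit,) = simulate_spikes(trials, [spec], 0)
        prof = encode_unit(
            unit, trials, FEEDBACK_MODEL, AlignmentSpec("next_lever_touch", -1.0, 1.5)
        )
        from checkdyn.encoding import classify_profile

        cls = classify_profile(prof, epoch=(-1.0, 1.5))
        assert cls["checkwork_significant"]
        assert cls["checkwork_sign"] == 1
        # first significant bin center within 300 +/- 100 ms of the planted
        # onset (bin centers lag the boxcar edge by up to half a width)
        assert cls["checkwork_first_sig_s"] == pytest.approx(0.3, abs=0.1)

    def test_profile_grid_matches_alignment(self, trials):
        spec = TuningSpec("u", "MCC", 5.0, np.inf)
        (unit,) = simulate_spikes(trials, [spec], 1)
        align = AlignmentSpec("feedback_onset", -0.5, 1.5)
        prof = encode_unit(unit, trials, FEEDBACK_MODEL, align)
        np.testing.assert_allclose(
            prof.records["bin_center_s"].to_numpy(), align.bin_centers_s
        )

    def test_untuned_unit_rarely_classified(self, trials):
        """Family-wise rate of the run rule on null units stays modest."""
        from checkdyn.encoding import classify_profile

        sig = 0
        n_units = 25
        specs = [TuningSpec(f"u{i}", "MCC", 6.0, np.inf) for i in range(n_units)]
        units = simulate_spikes(trials, specs, 2)
        for unit in units:
            prof = encode_unit(
                unit, trials, FEEDBACK_MODEL, AlignmentSpec("feedback_onset", -0.5, 1.5)
            )
            cls = classify_profile(prof, epoch=(0.0, 1.5))
            sig += cls["feedback_significant"]
        assert sig <= 3


class TestClassifyUnits:
    @pytest.fixture(scope="class")
    def planted(self):
        """60 units, 30% CHECK-tuned in MCC-weighted proportions."""
        trials = simulate_task(TaskConfig(n_blocks=16), AgentPolicy(), 5)
        specs = []
        rng = np.random.default_rng(0)
        for i in range(60):
            area = "MCC" if i < 30 else "LPFC"
            effects = ()
            if i % 10 < 3:  # 30% tuned
                effects = (EffectSpec("CHECKWORK", 9.0, 0.2, 0.6),)
            specs.append(
                TuningSpec(f"{area}_{i}", area, float(rng.uniform(3, 9)), 2.0, effects)
            )
        units = simulate_spikes(trials, specs, 1)
        profiles = [
            encode_unit(u, trials, FEEDBACK_MODEL, AlignmentSpec("next_lever_touch", -1.0, 1.0))
            for u in units
        ]
        return classify_units(profiles, {"FEEDBACK_MODEL": (-1.0, 1.0)})

    def test_planted_proportion_recovered(self, planted):
        props = planted["proportions"]
        cw = props[props["term"] == "checkwork"]
        for _, row in cw.iterrows():
            assert row["proportion"] == pytest.approx(0.30, abs=0.12)

    def test_area_chi2_emitted_for_each_term(self, planted):
        assert "checkwork" in planted["area_chi2"]
        chi2, p = planted["area_chi2"]["checkwork"]
        assert chi2 >= 0 and 0 < p <= 1


class TestFeatureCorrelation:
    @staticmethod
    def _table(zs_a, zs_b):
        n = len(zs_a)
        return pd.DataFrame(
            {
                "unit_id": [f"u{i}" for i in range(n)],
                "area": ["MCC"] * n,
                "feedback_max_abs_z": zs_a,
                "checkwork_max_abs_z": zs_b,
            }
        )

    def test_shared_tuning_gives_high_r(self):
        rng = np.random.default_rng(0)
        base = np.r_[np.zeros(30), rng.uniform(2, 8, 30)]
        table = self._table(base, base * 1.5 + rng.normal(0, 0.3, 60))
        res = feature_correlation(table, "feedback", "checkwork")
        assert res["MCC"][0] > 0.5

    def test_independent_tuning_gives_near_zero_r(self):
        rng = np.random.default_rng(1)
        a = np.r_[rng.uniform(2, 8, 30), np.zeros(30)]
        b = rng.permutation(a)
        res = feature_correlation(self._table(a, b), "feedback", "checkwork")
        assert abs(res["MCC"][0]) < 0.35

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        a, b = rng.uniform(0, 5, 40), rng.uniform(0, 5, 40)
        res = feature_correlation(self._table(a, b), "feedback", "checkwork")
        direct = np.corrcoef(a, b)[0, 1]
        assert res["MCC"][0] == pytest.approx(direct, rel=1e-9)

    def test_small_samples_reported_na(self):
        res = feature_correlation(self._table(np.ones(5), np.ones(5)), "feedback", "checkwork")
        assert np.isnan(res["MCC"][0])
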