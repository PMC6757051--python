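"""Logistic modelling: closed-form oracles, stepwise selection, per-SD ORs."""

import itertools

import numpy as np
import pandas as pd
import pytest

import ptbmetab as p
from ptbmetab.models import _fit_terms


def expand_2x2(a, b, c, d):
    """Subject-level data for a 2x2 (exposed/unexposed x case/control)."""
    y = np.r_[np.ones(a + b), np.zeros(c + d)]
    x = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    return y, pd.DataFrame({"x": x})


class TestFitLogistic:
    def test_two_by_two_equals_cross_product_ratio(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(2, 25, size=4)
            y, X = expand_2x2(a, b, c, d)
            fit = p.fit_logistic(y, X)
            assert np.exp(fit.params["x"]) == pytest.approx(
                (a * d) / (b * c), rel=1e-6)

    def test_intercept_only_probability_is_case_fraction(self):
        y = np.r_[np.ones(12), np.zeros(30)]
        X = pd.DataFrame(index=range(42))
        fit = p.fit_logistic(y, X)
        prob = 1 / (1 + np.exp(-fit.params["const"]))
        assert prob == pytest.approx(12 / 42, rel=1e-7)
        assert fit.aic == pytest.approx(2 - 2 * fit.llf)

    def test_rescaling_predictor_rescales_coefficient_only(self, rng):
        y = (rng.random(80) < 0.4).astype(float)
        x = rng.normal(size=80)
        f1 = p.fit_logistic(y, pd.DataFrame({"x": x}))
        f2 = p.fit_logistic(y, pd.DataFrame({"x": 10 * x}))
        assert f1.params["x"] == pytest.approx(10 * f2.params["x"], rel=1e-6)
        assert f1.aic == pytest.approx(f2.aic, abs=1e-8)
        assert f1.llf == pytest.approx(f2.llf, abs=1e-8)
        assert np.allclose(f1.linear_predictor, f2.linear_predictor, atol=1e-8)

    def test_single_class_rejected_and_collinear_rejected(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=10)})
        with pytest.raises(ValueError, match="both classes"):
            p.fit_logistic(np.ones(10), X)
        y = (rng.random(20) < 0.5).astype(float)
        x = rng.normal(size=20)
        X2 = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            p.fit_logistic(y, X2)

    def test_perfect_separation_is_flagged_not_silent(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        X = pd.DataFrame({"x": np.r_[np.ones(10) + np.arange(10) * 0.1,
                                     -np.ones(10) - np.arange(10) * 0.1]})
        fit = p.fit_logistic(y, X)
        assert not fit.converged
        assert "separation" in fit.flags or "non-convergence" in fit.flags

    def test_smoking_three_level_fit_matches_counts(self):
        rows = (
            [("current", 1)] * 7 + [("quit", 1)] * 4 + [("no smoking", 1)] * 44
            + [("current", 0)] * 3 + [("quit", 0)] * 7 + [("no smoking", 0)] * 92
        )
        df = pd.DataFrame(rows, columns=["smoking", "y"])
        fit = _fit_terms(df["y"].astype(float), df, ["smoking"])
        assert np.exp(fit.params["smoking[current]"]) == pytest.approx(
            7 * 92 / (3 * 44), rel=1e-6)


class TestStepwise:
    def test_pure_noise_candidates_yield_intercept_only(self, rng):
        n = 150
        df = pd.DataFrame({
            "height": rng.normal(165, 6, n),
            "vaginal_bleeding_15w": (rng.random(n) < 0.2).astype(int),
            "infection_15w": (rng.random(n) < 0.3).astype(int),
        })
        y = (rng.random(n) < 0.33).astype(float)
        fit = p.stepwise_select(y, df, ["height", "vaginal_bleeding_15w",
                                        "infection_15w"])
        assert fit.terms == []

    def test_single_strong_predictor_selected_alone(self, cork_cohort):
        cfg, clinical, _, _ = cork_cohort
        frame = p.clinical_model_frame(clinical, 37.0)
        fit = p.stepwise_select(frame["case"], frame)
        # the planted covariate is picked first and survives elimination
        first = next(s for s in fit.trace if s.get("phase") == 1 and s["chosen"])
        assert first["chosen"]["term"] == "vaginal_bleeding_15w"
        assert "vaginal_bleeding_15w" in fit.terms
        assert fit.pvalues["vaginal_bleeding_15w"] < 0.05

    def test_greedy_path_is_locally_optimal_vs_exhaustive(self, rng):
        """With <= 4 candidates, every greedy step must have chosen the
        AIC-minimizing move; where the final AIC differs from the best of
        all subsets, the trace must prove greedy local optimality."""
        n = 120
        df = pd.DataFrame({
            "a": rng.normal(size=n),
            "b": (rng.random(n) < 0.3).astype(int),
            "c": rng.normal(size=n),
            "d": (rng.random(n) < 0.5).astype(int),
        })
        logit = -0.5 + 0.9 * df["a"] + 0.8 * df["b"]
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        fit = p.stepwise_select(y, df, list("abcd"))
        # trace: each phase-1 chosen move was the minimum of evaluated moves
        for step in fit.trace:
            if step.get("phase") == 1 and step.get("chosen"):
                best = min(m["aic"] for m in step["moves"])
                assert step["chosen"]["aic"] == pytest.approx(best)
        # exhaustive all-subsets AIC
        best_aic = min(
            _fit_terms(y, df, list(sub)).aic
            for k in range(5) for sub in itertools.combinations("abcd", k)
        )
        # greedy cannot beat the exhaustive optimum
        greedy_phase1_aic = min(
            step["current_aic"] for step in fit.trace if step.get("phase") == 1
        )
        assert greedy_phase1_aic >= best_aic - 1e-9


class TestAddMetabolite:
    def test_per_sd_scaling(self, cork_cohort, normalized):
        _, clinical, _, _ = cork_cohort
        _, n20 = normalized
        log20 = p.log_transform(n20)
        frame = p.clinical_model_frame(clinical, 37.0)
        base = p.stepwise_select(frame["case"], frame)
        aug = p.add_metabolite(base, "undecane", log20)
        col = aug.X["log(undecane)"]
        assert col.mean() == pytest.approx(0.0, abs=1e-12)
        assert col.std(ddof=1) == pytest.approx(1.0, rel=1e-12)
        assert "log(undecane)" in aug.params.index

    def test_constant_compound_refused(self, cork_cohort, normalized):
        _, clinical, _, _ = cork_cohort
        _, n20 = normalized
        log20 = p.log_transform(n20)
        const = p.IntensityMatrix(
            log20.values.assign(flat=1.0), log20.sample_meta, None,
            list(log20.provenance))
        frame = p.clinical_model_frame(clinical, 37.0)
        base = p.stepwise_select(frame["case"], frame)
        with pytest.raises(ValueError, match="zero variance"):
            p.add_metabolite(base, "flat", const)

    def test_highly_correlated_second_metabolite_flagged(self, cork_cohort, normalized):
        _, clinical, _, _ = cork_cohort
        _, n20 = normalized
        log20 = p.log_transform(n20)
        frame = p.clinical_model_frame(clinical, 37.0)
        base = p.stepwise_select(frame["case"], frame)
        one = p.add_metabolite(base, "undecane", log20)
        two = p.add_metabolite(one, "dodecane", log20)
        assert "collinear-metabolite" in two.flags
        # the pair need not improve discrimination
        assert "log(dodecane)" in two.params.index


class TestThresholdSensitivity:
    def test_threshold_37_reproduces_base_augmented_fit(self, cork_cohort, normalized):
        _, clinical, _, _ = cork_cohort
        _, n20 = normalized
        log20 = p.log_transform(n20)
        frame = p.clinical_model_frame(clinical, 37.0)
        base = p.stepwise_select(frame["case"], frame)
        aug = p.add_metabolite(base, "undecane", log20)
        table = p.threshold_sensitivity(
            clinical, log20, "undecane", base.terms, [37.0])
        name = "log(undecane)"
        assert table.loc[0, "or"] == pytest.approx(
            float(np.exp(aug.params[name])), rel=1e-9)
        assert table.loc[0, "p"] == pytest.approx(float(aug.pvalues[name]), rel=1e-6)

    def test_small_case_groups_flagged_and_ci_widens(self, cork_cohort, normalized):
        _, clinical, _, _ = cork_cohort
        _, n20 = normalized
        log20 = p.log_transform(n20)
        table = p.threshold_sensitivity(
            clinical, log20, "undecane", ["vaginal_bleeding_15w"],
            [36.0, 34.0, 25.0])
        assert table.set_index("threshold").loc[25.0, "flag"] == "too few cases"
        width = np.log(table["or_hi"]) - np.log(table["or_lo"])
        # fewer cases -> wider CI
        assert width.iloc[1] > width.iloc[0]
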