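"""Tests for mixed models, stepwise simplification, group stats, FDR and mediation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lapsefit.reading_analysis import (
    CollinearityError,
    ModelSpec,
    cohens_d,
    correlation_screen_fdr,
    endpoint_accuracy_model,
    endpoint_accuracy_table,
    fit_shape_model,
    loo_discriminant_accuracy,
    mediation_analysis,
    stepwise_simplify,
)


def _toy_mixed_table(rng, n_subjects=40, beta_reading=0.02, beta_paradigm=0.0,
                     subject_sd=0.05, noise_sd=0.05):
    """Four observations (2 continua x 2 paradigms) per subject."""
    rows = []
    for i in range(n_subjects):
        wj = rng.normal(100, 15)
        u = rng.normal(0, subject_sd)
        for cont in (-0.5, 0.5):
            for par in (-0.5, 0.5):
                y = 0.5 + beta_reading * (wj - 100) + beta_paradigm * par + u + rng.normal(0, noise_sd)
                rows.append({"subject_id": f"S{i}", "wj_brs_c": wj - 100,
                             "continuum_dev": cont, "paradigm_dev": par, "y": y})
    return pd.DataFrame(rows)


class TestFitShapeModel:
    def test_recovers_reading_coefficient(self):
        rng = np.random.default_rng(0)
        table = _toy_mixed_table(rng, beta_reading=0.02)
        ct = fit_shape_model(table, ModelSpec("y", ["wj_brs_c", "continuum_dev", "paradigm_dev"]))
        assert ct.coef("wj_brs_c") == pytest.approx(0.02, abs=2 * ct.se("wj_brs_c"))

    def test_intercept_is_grand_mean_under_balanced_deviation_coding(self):
        rng = np.random.default_rng(1)
        table = _toy_mixed_table(rng, beta_paradigm=0.3)
        ct = fit_shape_model(table, ModelSpec("y", ["continuum_dev", "paradigm_dev"]))
        cell_means = table.groupby(["continuum_dev", "paradigm_dev"])["y"].mean()
        assert ct.coef("Intercept") == pytest.approx(cell_means.mean(), abs=1e-6)

    def test_null_coverage(self):
        """With a pure-noise response the reading CI covers 0 in >= 90% of replicates."""
        rng = np.random.default_rng(2)
        covered = 0
        n_rep = 40
        for _ in range(n_rep):
            table = _toy_mixed_table(rng, n_subjects=25, beta_reading=0.0)
            ct = fit_shape_model(table, ModelSpec("y", ["wj_brs_c"]))
            covered += abs(ct.coef("wj_brs_c")) <= 1.96 * ct.se("wj_brs_c")
        assert covered >= 0.9 * n_rep

    def test_collinear_design_names_term(self):
        rng = np.random.default_rng(3)
        table = _toy_mixed_table(rng)
        table["dup"] = table["wj_brs_c"] * 2.0
        with pytest.raises(CollinearityError, match="dup|wj_brs_c"):
            fit_shape_model(table, ModelSpec("y", ["wj_brs_c", "dup"]))


class TestStepwise:
    def test_keeps_only_true_predictor(self):
        rng = np.random.default_rng(4)
        table = _toy_mixed_table(rng, n_subjects=60, beta_reading=0.02, beta_paradigm=0.0)
        final = stepwise_simplify(
            table, ModelSpec("y", ["wj_brs_c", "continuum_dev", "paradigm_dev"])
        )
        assert set(final.terms["name"]) == {"Intercept", "wj_brs_c"}
        dropped = {t["dropped"] for t in final.trace}
        assert dropped == {"continuum_dev", "paradigm_dev"}

    def test_interactions_dropped_before_main_effects(self):
        rng = np.random.default_rng(5)
        table = _toy_mixed_table(rng, n_subjects=60, beta_reading=0.02)
        final = stepwise_simplify(
            table,
            ModelSpec("y", ["wj_brs_c", "paradigm_dev", "wj_brs_c:paradigm_dev"]),
        )
        names = list(t["dropped"] for t in final.trace)
        assert names[0] == "wj_brs_c:paradigm_dev"
        assert "wj_brs_c" in set(final.terms["name"])

    def test_all_significant_terms_retained(self):
        rng = np.random.default_rng(6)
        table = _toy_mixed_table(rng, n_subjects=80, beta_reading=0.02, beta_paradigm=0.4)
        final = stepwise_simplify(
            table, ModelSpec("y", ["wj_brs_c", "paradigm_dev"])
        )
        assert set(final.terms["name"]) == {"Intercept", "wj_brs_c", "paradigm_dev"}
        assert final.trace == []


class TestCohensD:
    def test_identical_groups_zero(self):
        x = np.array([1.0, 2, 3, 4])
        assert cohens_d(x, x) == 0.0

    def test_unit_definition(self):
        rng = np.random.default_rng(7)
        a = rng.normal(1.0, 1.0, 4000)
        b = rng.normal(0.0, 1.0, 4000)
        assert cohens_d(a, b) == pytest.approx(1.0, abs=0.06)

    @given(shift=st.floats(-5, 5), scale=st.floats(0.1, 10))
    @settings(max_examples=30, derandomize=True)
    def test_antisymmetric_and_affine_invariant(self, shift, scale):
        a = np.array([0.2, 0.5, 0.9, 1.4])
        b = np.array([1.1, 1.7, 2.3])
        d = cohens_d(a, b)
        assert cohens_d(b, a) == pytest.approx(-d, rel=1e-12)
        assert cohens_d(a * scale + shift, b * scale + shift) == pytest.approx(d, rel=1e-9)

    def test_degenerate_pooled_sd(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [1.0, 1.0])


class TestLooDiscriminant:
    def test_separable_classes_perfect(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, (20, 2))
        b = rng.normal(20, 1, (20, 2))
        x = np.vstack([a, b])
        y = np.array([0] * 20 + [1] * 20)
        assert loo_discriminant_accuracy(x, y, "linear") == 1.0
        assert loo_discriminant_accuracy(x, y, "quadratic") == 1.0

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(200, 2))
        y = rng.permutation([0] * 100 + [1] * 100)
        acc = loo_discriminant_accuracy(x, y, "linear")
        assert abs(acc - 0.5) < 3 * np.sqrt(0.25 / 200) + 0.05

    def test_interleaved_1d_classes_near_chance(self):
        x = np.arange(40, dtype=float)
        y = x.astype(int) % 2
        acc = loo_discriminant_accuracy(x, y, "linear")
        assert acc <= 0.6

    def test_affine_invariance_linear(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(30, 2))
        y = (x[:, 0] + x[:, 1] > 0).astype(int)
        a1 = loo_discriminant_accuracy(x, y, "linear")
        a2 = loo_discriminant_accuracy(x * 7.0 + 3.0, y, "linear")
        assert a1 == a2


class TestCorrelationScreen:
    def test_self_correlation_significant(self):
        rng = np.random.default_rng(11)
        base = rng.normal(size=40)
        params = pd.DataFrame({"slope": base})
        battery = pd.DataFrame({"wj": base + rng.normal(0, 0.01, 40),
                                "noise": rng.normal(size=40)})
        r, mask = correlation_screen_fdr(params, battery)
        assert r.loc["slope", "wj"] > 0.99
        assert bool(mask.loc["slope", "wj"]) is True
        assert bool(mask.loc["slope", "noise"]) is False

    def test_bh_ties_adjust_identically(self):
        """Identical raw p-values get identical BH decisions."""
        rng = np.random.default_rng(12)
        x = rng.normal(size=30)
        params = pd.DataFrame({"a": x, "b": x.copy()})
        battery = pd.DataFrame({"m": x + rng.normal(0, 0.5, 30)})
        _, mask = correlation_screen_fdr(params, battery)
        assert mask.loc["a", "m"] == mask.loc["b", "m"]

    def test_constant_column_flagged_nan(self):
        params = pd.DataFrame({"slope": [0.5] * 10})
        battery = pd.DataFrame({"m": np.arange(10.0)})
        r, mask = correlation_screen_fdr(params, battery)
        assert np.isnan(r.loc["slope", "m"])
        assert bool(mask.loc["slope", "m"]) is False

    def test_fdr_calibration_under_null(self):
        """Independent measures: expected false-discovery proportion <= ~alpha."""
        rng = np.random.default_rng(13)
        fdp = []
        for _ in range(20):
            params = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
            battery = pd.DataFrame(rng.normal(size=(30, 20)))
            _, mask = correlation_screen_fdr(params, battery)
            fdp.append(mask.to_numpy().mean())
        assert np.mean(fdp) <= 0.05 + 0.02


class TestMediation:
    def _data(self, rng, n=200, full=False):
        x = rng.normal(size=n)
        if full:
            m = 2.0 * x + rng.normal(0, 0.2, n)
            y = 1.5 * m + rng.normal(0, 0.2, n)
        else:
            m = rng.normal(size=n)
            y = 0.8 * x + rng.normal(0, 0.5, n)
        return x, m, y

    def test_product_identity_exact(self):
        """a*b == c - c' to numerical precision on arbitrary data."""
        rng = np.random.default_rng(14)
        x, m, y = self._data(rng)
        res = mediation_analysis(x, m, y, n_boot=10, seed=0)
        assert res.indirect_effect == pytest.approx(res.total_effect - res.direct_effect, abs=1e-10)

    def test_product_identity_with_covariates(self):
        rng = np.random.default_rng(15)
        x, m, y = self._data(rng)
        cov = rng.normal(size=len(x))
        res = mediation_analysis(x, m, y, covariates=cov, n_boot=10, seed=0)
        assert res.indirect_effect == pytest.approx(res.total_effect - res.direct_effect, abs=1e-10)

    def test_independent_mediator_no_indirect_effect(self):
        rng = np.random.default_rng(16)
        x, m, y = self._data(rng, full=False)
        res = mediation_analysis(x, m, y, n_boot=500, seed=1)
        assert res.ci[0] <= 0 <= res.ci[1]
        assert abs(res.indirect_effect) < 0.1

    def test_full_mediation_approaches_100_percent(self):
        rng = np.random.default_rng(17)
        x, m, y = self._data(rng, n=1000, full=True)
        res = mediation_analysis(x, m, y, n_boot=500, seed=2)
        assert res.percent_mediation == pytest.approx(100.0, abs=3.0)
        assert res.p_value < 0.05

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(18)
        x, m, y = self._data(rng)
        r1 = mediation_analysis(x, m, y, n_boot=200, seed=5)
        r2 = mediation_analysis(x, m, y, n_boot=200, seed=5)
        assert r1 == r2


class TestEndpointAccuracy:
    def _trials(self, rng, n_subjects=25, decay=0.0):
        """Endpoint-only trial records with controllable accuracy drift."""
        rows = []
        for i in range(n_subjects):
            sid = f"S{i}"
            for block in range(1, 7):
                cont = "dynamic_ba_da" if block % 2 else "static_sha_sa"
                par = "abx" if block <= 4 else "single"
                for t in range(1, 71):
                    step = rng.choice([1, 7]) if t % 3 else rng.integers(2, 7)
                    if step in (1, 7):
                        p = np.clip(0.92 + decay * (t - 35), 0.05, 1.0)
                        correct = rng.random() < p
                        resp = int(correct) if step == 7 else int(not correct)
                    else:
                        resp = rng.integers(0, 2)
                    rows.append({"subject_id": sid, "continuum": cont, "paradigm": par,
                                 "block_index": block, "trial_number": t, "step": int(step),
                                 "response": resp, "rt_ms": 700.0})
        return pd.DataFrame(rows)

    def _subjects(self, rng, n_subjects=25):
        return pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(n_subjects)],
                "wj_brs": rng.normal(100, 15, n_subjects),
                "age": rng.uniform(8, 12, n_subjects),
                "adhd": rng.integers(0, 2, n_subjects),
                "nonverbal_iq": rng.normal(50, 9, n_subjects),
            }
        )

    def test_stationary_accuracy_trial_coefficient_near_zero(self):
        rng = np.random.default_rng(19)
        ct = endpoint_accuracy_model(self._trials(rng), self._subjects(rng), simplify=False)
        assert abs(ct.coef("trial_number_c")) <= 2 * ct.se("trial_number_c")

    def test_decaying_accuracy_recovers_negative_trend(self):
        rng = np.random.default_rng(20)
        ct = endpoint_accuracy_model(
            self._trials(rng, decay=-0.004), self._subjects(rng), simplify=False
        )
        assert ct.coef("trial_number_c") < 0
        assert ct.pvalue("trial_number_c") < 0.05

    def test_simulated_blocks_have_twenty_endpoint_trials(self, small_cohort):
        ends = endpoint_accuracy_table(small_cohort.trials, small_cohort.subjects)
        per_block = ends.groupby(["subject_id", "block_index"]).size()
        assert (per_block == 20).all()

    def test_no_endpoint_trials_raises(self):
        rng = np.random.default_rng(21)
        trials = self._trials(rng, n_subjects=2)
        trials = trials[~trials["step"].isin([1, 7])]
        with pytest.raises(ValueError):
            endpoint_accuracy_table(trials, self._subjects(rng, 2))
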