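"""Long-table assembly, REML random-intercept fit, effect translation."""

import math
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from scmnet import (
    assemble_long_table,
    fit_random_intercept,
    predicted_accuracy_difference,
)
from scmnet.longitudinal import ModelFit, SingularDesignError
from scmnet.metrics import AccuracyRecord, TransitivityRecord
from scmnet.synthetic import simulate_model_table


def acc_record(perceiver, cid, wid, accuracy):
    return AccuracyRecord(
        perceiver=perceiver, classroom_id=cid, wave_id=wid,
        n_depicted=10, n_correct=5, n_true=10,
        precision=0.5, coverage=0.5, accuracy=accuracy,
    )


def trans_record(cid, wid, value):
    return TransitivityRecord(
        classroom_id=cid, wave_id=wid, n_transitive_triads=1, n_two_paths=1,
        transitivity=value,
    )


class TestAssembleLongTable:
    def test_baseline_and_deviations(self):
        acc = [acc_record("p1", "c", w, 0.5) for w in (0, 1, 2)]
        trans = [trans_record("c", 0, 0.50), trans_record("c", 1, 0.60), trans_record("c", 2, 0.55)]
        acc += [acc_record("p2", "c", w, 0.4) for w in (0, 1, 2)]
        table = assemble_long_table(acc, trans, min_waves=2)
        p1 = table[table.participant == "p1"].sort_values("wave_id")
        assert p1.transitivity_t0.tolist() == [0.50, 0.50, 0.50]
        assert p1.transitivity_change.tolist() == pytest.approx([0.00, 0.10, 0.05])
        assert p1.time.tolist() == [0, 1, 2]

    def test_single_wave_participant_dropped(self):
        acc = [acc_record("p1", "c", 1, 0.5)]
        acc += [acc_record("p2", "c", w, 0.4) for w in (0, 1)]
        trans = [trans_record("c", 0, 0.5), trans_record("c", 1, 0.6)]
        table = assemble_long_table(acc, trans, min_waves=2)
        assert set(table.participant) == {"p2"}

    def test_classroom_switcher_uses_each_waves_classroom(self):
        acc = [acc_record("p1", "cA", 0, 0.5), acc_record("p1", "cB", 1, 0.5),
               acc_record("p2", "cA", 0, 0.4), acc_record("p2", "cA", 1, 0.4)]
        trans = [trans_record("cA", 0, 0.30), trans_record("cA", 1, 0.50),
                 trans_record("cB", 1, 0.80)]
        table = assemble_long_table(acc, trans, min_waves=2)
        p1 = table[table.participant == "p1"].sort_values("wave_id")
        assert p1.transitivity.tolist() == pytest.approx([0.30, 0.80])
        assert p1.transitivity_change.tolist() == pytest.approx([0.0, 0.50])

    def test_baseline_is_first_observed_wave_not_wave_zero(self):
        acc = [acc_record("p1", "c", w, 0.5) for w in (1, 2)]
        acc += [acc_record("p2", "c", w, 0.4) for w in (0, 1, 2)]
        trans = [trans_record("c", 0, 0.3), trans_record("c", 1, 0.6), trans_record("c", 2, 0.7)]
        table = assemble_long_table(acc, trans, min_waves=2)
        p1 = table[table.participant == "p1"]
        assert p1.transitivity_t0.tolist() == pytest.approx([0.6, 0.6])

    def test_undefined_transitivity_rows_excluded(self):
        acc = [acc_record("p1", "c", w, 0.5) for w in (0, 1, 2)]
        trans = [trans_record("c", 0, 0.5), trans_record("c", 1, math.nan), trans_record("c", 2, 0.6)]
        table = assemble_long_table(acc, trans, min_waves=2)
        assert table.wave_id.tolist() == [0, 2]

    def test_dangling_classroom_wave_errors(self):
        acc = [acc_record("p1", "c", 0, 0.5)]
        with pytest.raises(KeyError, match="no transitivity record"):
            assemble_long_table(acc, [], min_waves=1)

    def test_disaggregation_identity(self):
        table = simulate_model_table(n_participants=30, seed=5)
        np.testing.assert_allclose(
            table.transitivity_t0 + table.transitivity_change,
            table.transitivity,
            rtol=0, atol=1e-12,
        )


class TestFitRandomIntercept:
    def test_matches_ols_when_no_between_person_variance(self):
        """With the intercept variance at zero, GLS collapses to OLS."""
        table = simulate_model_table(
            n_participants=60, sigma2_intercept=0.0, sigma2_residual=0.02, seed=7
        )
        fit = fit_random_intercept(table)
        X = np.column_stack([
            np.ones(len(table)), table.time, table.transitivity_t0, table.transitivity_change,
        ])
        beta_ols, *_ = np.linalg.lstsq(X, table.accuracy.to_numpy(), rcond=None)
        for fe, b in zip(fit.fixed_effects, beta_ols):
            assert fe.estimate == pytest.approx(b, abs=1e-4)

    def test_matches_lmertest_oracle(self, tmp_path):
        """Estimates, SEs, Satterthwaite dfs and p-values against lmerTest."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        table = simulate_model_table(n_participants=40, sigma2_intercept=0.02, seed=11)
        csv = tmp_path / "table.csv"
        table.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lmerTest))
            d <- read.csv('{csv}')
            m <- lmer(accuracy ~ time + transitivity_t0 + transitivity_change
                      + (1|participant), data=d, REML=TRUE)
            write.csv(coef(summary(m)), '{tmp_path}/out.csv')
        """))
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        oracle = pd.read_csv(tmp_path / "out.csv", index_col=0)
        fit = fit_random_intercept(table)
        for fe, (_, row) in zip(fit.fixed_effects, oracle.iterrows()):
            assert fe.estimate == pytest.approx(row["Estimate"], abs=1e-5)
            assert fe.se == pytest.approx(row["Std. Error"], abs=1e-5)
            assert fe.df == pytest.approx(row["df"], rel=1e-3)
            assert fe.p_value == pytest.approx(row["Pr(>|t|)"], abs=1e-5)

    def test_constant_transitivity_change_is_singular(self):
        table = simulate_model_table(n_participants=40, change_sd=0.0, seed=3)
        table["transitivity_change"] = 0.0
        with pytest.raises(SingularDesignError, match="transitivity_change"):
            fit_random_intercept(table)

    def test_constant_outcome_is_singular(self):
        table = simulate_model_table(n_participants=40, seed=3)
        table["accuracy"] = 1.0
        with pytest.raises(SingularDesignError, match="accuracy"):
            fit_random_intercept(table)

    def test_too_few_participants(self):
        table = simulate_model_table(n_participants=20, seed=3)
        with pytest.raises(ValueError, match="participants"):
            fit_random_intercept(table[table.participant == "p0000"])

    def test_variance_components_nonnegative_and_counts(self):
        table = simulate_model_table(n_participants=50, seed=9)
        fit = fit_random_intercept(table)
        assert fit.sigma2_intercept >= 0 and fit.sigma2_residual > 0
        assert fit.n_participants == 50
        assert fit.n_observations == 150
        assert fit.df_method == "satterthwaite"

    def test_centering_invariance(self):
        """Shifting all transitivity values by a constant leaves the slopes
        essentially unchanged and moves only the intercept."""
        table = simulate_model_table(n_participants=50, sigma2_intercept=0.02, seed=13)
        shifted = table.copy()
        shifted["transitivity_t0"] = shifted["transitivity_t0"] + 0.25
        shifted["transitivity"] = shifted["transitivity"] + 0.25
        f1, f2 = fit_random_intercept(table), fit_random_intercept(shifted)
        b2a = f1.coefficient("transitivity_t0").estimate
        b2b = f2.coefficient("transitivity_t0").estimate
        b3a = f1.coefficient("transitivity_change").estimate
        b3b = f2.coefficient("transitivity_change").estimate
        assert b3a == pytest.approx(b3b, abs=1e-6)
        assert b2a == pytest.approx(b2b, abs=1e-6)
        db0 = f2.coefficient("intercept").estimate - f1.coefficient("intercept").estimate
        assert db0 == pytest.approx(-0.25 * b2a, abs=1e-5)


class TestEffectTranslation:
    def test_between_person_coefficient_times_delta(self):
        fit = ModelFit.from_coefficients({"transitivity_t0": 0.67})
        assert predicted_accuracy_difference(fit, "transitivity_t0", 0.10) == pytest.approx(0.067)

    def test_within_person_coefficient_times_delta(self):
        fit = ModelFit.from_coefficients({"transitivity_change": 0.62})
        assert predicted_accuracy_difference(fit, "transitivity_change", 0.10) == pytest.approx(0.062)

    def test_zero_delta(self):
        fit = ModelFit.from_coefficients({"transitivity_t0": 0.5})
        assert predicted_accuracy_difference(fit, "transitivity_t0", 0.0) == 0.0

    def test_unknown_predictor(self):
        fit = ModelFit.from_coefficients({})
        with pytest.raises(KeyError, match="unknown predictor"):
            predicted_accuracy_difference(fit, "time", 0.1)
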