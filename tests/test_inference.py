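import numpy as np
import pytest
from scipy import stats

import muacglm as mg
from muacglm.inference import EliminationError, glm_screen_refit

import reference_tables as ref


class TestWaldTable:
    def test_t_is_estimate_over_se_exactly(self):
        table = mg.wald_table([1.5, -0.2], [0.5, 0.1], ["a", "b"])
        np.testing.assert_array_equal(table["t"], [3.0, -2.0])

    @pytest.mark.parametrize(
        "est,se,expected,dp",
        [
            (-2.44933, 0.706229, -3.4682, 4),
            (3.514933, 0.699909, 5.022, 3),
            (1.194023, 0.127182, 9.388, 3),
            (0.2719, 0.065510, 4.1505, 4),
            (-0.04087, 0.017389, -2.3503, 4),
        ],
    )
    def test_reference_t_values(self, est, se, expected, dp):
        t = float(mg.wald_table([est], [se], ["x"])["t"].iloc[0])
        assert round(t, dp) == pytest.approx(expected, abs=1.01 * 10**-dp)

    def test_null_coefficient(self):
        row = mg.wald_table([0.0], [2.0], ["x"]).iloc[0]
        assert row["t"] == 0.0
        assert row["p"] == 1.0
        assert row["stars"] == ""

    def test_star_rule_thresholds(self):
        # z-values straddling the 0.05 / 0.01 / 0.001 two-sided cutoffs
        z = [1.0, 2.0, 2.7, 3.5]
        table = mg.wald_table(z, [1.0] * 4, list("abcd"))
        assert list(table["stars"]) == ["", "*", "**", "***"]

    def test_p_from_standard_normal(self):
        table = mg.wald_table([1.2], [0.6], ["x"])
        assert table["p"].iloc[0] == pytest.approx(2 * stats.norm.sf(2.0))

    def test_t_distribution_option(self):
        table = mg.wald_table([1.2], [0.6], ["x"], dist="t", df=10)
        assert table["p"].iloc[0] == pytest.approx(2 * stats.t.sf(2.0, 10))

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            mg.wald_table([1.0], [0.0], ["x"])


class TestReferenceTableFixture:
    def test_reproduces_all_printed_t_values(self):
        """All 30 reference coefficient rows: the computed Wald statistic
        matches the printed t within the precision the printed inputs
        support (one ulp of t plus first-order propagation of one-ulp
        rounding of estimate and se)."""
        rows = [r for tab in ref.ALL_TABLES.values() for r in tab]
        assert len(rows) == 30
        for term, est_s, se_s, t_s in rows:
            est, se, t_printed = float(est_s), float(se_s), float(t_s)
            t = float(mg.wald_table([est], [se], [term])["t"].iloc[0])
            tol = ref.ulp(t_s) + (ref.ulp(est_s) + abs(t) * ref.ulp(se_s)) / se
            assert abs(t - t_printed) <= tol, (term, t, t_printed)

    def test_stars_match_printed_significance(self):
        # every |t| > 3.3 row is flagged ***; |t| < 1.96 rows unflagged
        for tab in ref.ALL_TABLES.values():
            frame = mg.wald_table(
                [float(e) for _, e, _, _ in tab],
                [float(s) for _, _, s, _ in tab],
                [term for term, _, _, _ in tab],
            )
            for _, row in frame.iterrows():
                if abs(row["t"]) > 3.3:
                    assert row["stars"] == "***"
                if abs(row["t"]) < 1.96:
                    assert row["stars"] == ""


class TestBackwardEliminate:
    def test_noop_when_all_below_threshold(self, cohort163):
        terms = mg.TermList(("age", "weight"))
        result = mg.backward_eliminate(cohort163, terms, threshold=0.999999)
        assert result == terms

    def test_intercept_only_unchanged(self, cohort163):
        assert (
            mg.backward_eliminate(cohort163, mg.INTERCEPT_ONLY)
            == mg.INTERCEPT_ONLY
        )

    def test_order_independence(self, cohort163):
        a = mg.TermList(("age", "weight", "height", "hemoglobin"))
        b = mg.TermList(("hemoglobin", "height", "weight", "age"))
        ra = mg.backward_eliminate(cohort163, a, threshold=0.2)
        rb = mg.backward_eliminate(cohort163, b, threshold=0.2)
        assert set(ra.terms) == set(rb.terms)

    def test_main_effect_protected_by_interaction(self):
        """A main effect whose p-value is large survives while one of its
        interactions is still in the model."""
        calls = []

        def fake_refit(table, terms):
            import pandas as pd

            calls.append(terms.terms)
            pmap = {"age": 0.9, "weight": 0.01, "age:weight": 0.01}
            return pd.DataFrame(
                {
                    "term": terms.labels,
                    "p": [0.0] + [pmap[t] for t in terms.terms],
                }
            )

        table = mg.generate(mg.default_config(100, seed=1))
        result = mg.backward_eliminate(
            table,
            mg.TermList(("age", "weight", "age:weight")),
            refit=fake_refit,
        )
        assert "age" in result.terms  # protected despite p = 0.9

    def test_noise_covariate_usually_eliminated(self):
        """With a pure-noise candidate appended, the screen keeps every
        true determinant and drops the noise term at roughly the null rate
        1 - threshold (binomial bound over replicates)."""
        eliminated = 0
        all_true_kept = 0
        n_rep = 40
        for rep in range(n_rep):
            table = mg.generate(mg.default_config(2000, seed=5000 + rep))
            rng = np.random.default_rng(9000 + rep)
            table = table.with_column("noise", rng.uniform(1.0, 2.0, table.n))
            candidates = mg.TermList(mg.DEFAULT_TERMS.terms + ("noise",))
            kept = mg.backward_eliminate(table, candidates, threshold=0.2)
            # interaction parents are protected by the hierarchy guard
            assert {"age", "weight", "height"} <= set(kept.terms)
            all_true_kept += set(mg.DEFAULT_TERMS.terms) <= set(kept.terms)
            eliminated += "noise" not in kept.terms
        # null retention prob ~ 0.2; 3-sigma lower bound on 0.8 * 40
        assert eliminated >= 0.8 * n_rep - 3 * np.sqrt(n_rep * 0.8 * 0.2)
        assert all_true_kept >= 0.9 * n_rep

    def test_refit_failure_carries_survivors(self, cohort163):
        def broken(table, terms):
            raise RuntimeError("boom")

        with pytest.raises(EliminationError) as err:
            mg.backward_eliminate(
                cohort163, mg.TermList(("age",)), refit=broken
            )
        assert err.value.surviving.terms == ("age",)

    def test_bad_threshold_rejected(self, cohort163):
        with pytest.raises(ValueError, match="threshold"):
            mg.backward_eliminate(cohort163, mg.TermList(("age",)), threshold=1.5)


class TestCompareModels:
    def _two_fits(self, table):
        glm = mg.fit_joint(table, mg.DEFAULT_TERMS, mg.INTERCEPT_ONLY, "ml")
        joint = mg.fit_joint(table, mg.DEFAULT_TERMS, mg.DEFAULT_TERMS, "reml")
        return glm, joint

    def test_rows_and_winner(self, cohort163):
        glm, joint = self._two_fits(cohort163)
        cmp = mg.compare_models([glm, joint], names=("glm", "joint"))
        assert {r.criterion for r in cmp.rows} == {
            "-2ML (-2 h)",
            "-2RL (-2 p_beta(h))",
            "cAIC",
            "AIC",
            "BIC",
        }
        aic_row = cmp.row("AIC")
        assert cmp.winner == int(np.argmin(aic_row.values))

    def test_identical_criteria_reported_as_tie(self, cohort163):
        glm, _ = self._two_fits(cohort163)
        cmp = mg.compare_models([glm, glm])
        assert cmp.winner is None
        assert all(r.best is None for r in cmp.rows)

    def test_single_fit_rejected(self, cohort163):
        glm, _ = self._two_fits(cohort163)
        with pytest.raises(ValueError, match="two"):
            mg.compare_models([glm])

    def test_different_n_rejected(self, cohort163):
        glm, _ = self._two_fits(cohort163)
        other = mg.generate(mg.default_config(200, seed=77))
        glm2, _ = self._two_fits(other)
        with pytest.raises(ValueError, match="sample sizes"):
            mg.compare_models([glm, glm2])

    def test_joint_model_wins_on_heteroscedastic_cohorts(self):
        """On dispersion-structured synthetic cohorts the joint model
        should essentially always beat the constant-dispersion GLM on
        AIC (a 20-replicate version of the full comparison)."""
        wins = 0
        for rep in range(20):
            table = mg.generate(mg.default_config(1000, seed=40_000 + rep))
            glm, joint = self._two_fits(table)
            wins += joint.criteria.aic < glm.criteria.aic
        assert wins >= 19
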