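"""Conditional-logistic estimator against closed-form, grid-search and
established-implementation oracles."""

import numpy as np
import pandas as pd
import pytest

from medscreen.conditional_logit import (
    CLogitFit,
    SeparationError,
    build_design,
    clogit_loglik,
    discordant_pair_or,
    estimate_effects,
    fit_conditional_logistic,
)
from medscreen.synthetic import simulate_matched_cohort


def paired_design(n10: int, n01: int, n_concordant: int = 5):
    """1:1 pairs: n10 case-exposed-only, n01 control-exposed-only, plus
    concordant-exposed pairs (uninformative)."""
    x, y, s = [], [], []
    i = 0
    for _ in range(n10):
        x += [1, 0]; y += [1, 0]; s += [i, i]; i += 1
    for _ in range(n01):
        x += [0, 1]; y += [1, 0]; s += [i, i]; i += 1
    for _ in range(n_concordant):
        x += [1, 1]; y += [1, 0]; s += [i, i]; i += 1
    return np.array(x, float), np.array(y), np.array(s)


class TestDiscordantPairs:
    def test_definition(self):
        x, y, s = paired_design(20, 10)
        assert discordant_pair_or(x, y, s) == 2.0

    def test_symmetry(self):
        x, y, s = paired_design(7, 7)
        assert discordant_pair_or(x, y, s) == 1.0

    def test_no_discordant_pairs_undefined(self):
        x, y, s = paired_design(0, 0, n_concordant=4)
        with pytest.raises(ValueError, match="discordant"):
            discordant_pair_or(x, y, s)

    def test_infinite_or(self):
        x, y, s = paired_design(3, 0)
        assert discordant_pair_or(x, y, s) == float("inf")


class TestOracleEquivalence:
    def test_matched_pairs_equal_closed_form(self):
        """On 1:1 binary designs the conditional MLE is n10/n01 exactly."""
        for n10, n01 in [(20, 10), (15, 15), (8, 24)]:
            x, y, s = paired_design(n10, n01)
            fit = fit_conditional_logistic(x, y, s)
            assert fit.beta[0] == pytest.approx(np.log(n10 / n01), abs=1e-6)

    def test_three_set_grid_search(self):
        """Tiny 1:2 fixture: Newton maximum matches a brute-force grid over
        beta to 1e-4."""
        x = np.array([1.0, 0.0, 0.0, 1.0, 1.0, 0.0, 0.0, 0.0, 1.0])
        y = np.array([1, 0, 0, 1, 0, 0, 1, 0, 0])
        s = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        fit = fit_conditional_logistic(x, y, s)
        order = np.argsort(s, kind="stable")
        starts = np.array([0, 3, 6])
        grid = np.arange(-3, 3, 1e-4)
        lls = [clogit_loglik(np.array([b]), x[order][:, None], y[order], starts)
               for b in grid]
        assert fit.beta[0] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-4)

    def test_agrees_with_statsmodels(self):
        """Cross-check against an independent established implementation on a
        random 1:3 design with binary and continuous covariates."""
        from statsmodels.discrete.conditional_models import ConditionalLogit

        rng = np.random.default_rng(8)
        n_sets, m = 120, 4
        s = np.repeat(np.arange(n_sets), m)
        y = np.tile([1, 0, 0, 0], n_sets)
        X = np.column_stack(
            [
                rng.random(n_sets * m) < 0.3,
                rng.random(n_sets * m) < 0.1,
                rng.normal(size=n_sets * m),
            ]
        ).astype(float)
        # induce signal so coefficients are away from 0
        X[y == 1, 0] = rng.random(n_sets) < 0.5
        fit = fit_conditional_logistic(X, y, s)
        sm = ConditionalLogit(y, X, groups=s).fit(
            disp=False, method="newton", tol=1e-10
        )
        np.testing.assert_allclose(fit.beta, sm.params, atol=1e-5)
        np.testing.assert_allclose(fit.se, sm.bse, atol=1e-5)


class TestModelBehaviour:
    def test_null_data_estimates_near_zero(self):
        hits = 0
        for seed in range(10):
            coh = simulate_matched_cohort(
                n_sets=300, ratio=3, prevalences=np.array([0.2]), seed=seed
            )
            fit = fit_conditional_logistic(coh.X, coh.y, coh.set_id)
            hits += abs(fit.beta[0]) < 3 * fit.se[0]
        assert hits >= 9

    def test_set_constant_covariate_leaves_estimates_unchanged(self):
        coh = simulate_matched_cohort(
            n_sets=200, ratio=2, prevalences=np.array([0.3]),
            planted={0: 2.0}, seed=4,
        )
        base = fit_conditional_logistic(coh.X, coh.y, coh.set_id)
        # a covariate constant within each set is absorbed by the likelihood
        const = coh.set_id.astype(float) % 5
        X2 = np.column_stack([coh.X[:, 0], const])
        aug = fit_conditional_logistic(X2, coh.y, coh.set_id)
        assert aug.beta[0] == pytest.approx(base.beta[0], abs=1e-8)

    def test_separation_detected(self):
        x, y, s = paired_design(25, 0, n_concordant=0)
        with pytest.raises(SeparationError):
            fit_conditional_logistic(x, y, s)

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError, match="exactly one case"):
            fit_conditional_logistic(
                np.ones((4, 1)), [1, 1, 0, 0], [0, 0, 1, 1]
            )
        with pytest.raises(ValueError, match="2 members"):
            fit_conditional_logistic(np.ones((3, 1)), [1, 1, 0], [0, 1, 1])

    def test_wald_summary_shape(self):
        x, y, s = paired_design(20, 10)
        fit = fit_conditional_logistic(x, y, s, feature_names=["drug"])
        tab = fit.summary()
        assert list(tab.columns) == ["feature", "beta", "se", "or", "ci_low",
                                     "ci_high", "p"]
        assert tab["ci_low"].iloc[0] < tab["or"].iloc[0] < tab["ci_high"].iloc[0]
        assert isinstance(fit, CLogitFit)


class TestDesignAssembly:
    def _frames(self):
        coh = simulate_matched_cohort(
            n_sets=50, ratio=2, prevalences=np.array([0.3, 0.2]), seed=6
        )
        matrix = coh.frame()
        matrix.insert(1, "subject_id", np.arange(len(matrix)))
        cov = matrix[["set_id", "subject_id", "is_case"]].copy()
        cov["visit_rate"] = 0.5
        cov["diabetes"] = 0
        cov["cardiovascular"] = 0
        cov["excess_weight"] = 0
        return matrix, cov

    def test_missing_visit_rate_drops_member_and_degenerate_sets(self):
        matrix, cov = self._frames()
        feats = [c for c in matrix.columns
                 if c not in ("set_id", "subject_id", "is_case")]
        cov.loc[cov["subject_id"] == 1, "visit_rate"] = np.nan  # a control
        case_row = (cov["set_id"] == 3) & (cov["is_case"] == 1)
        cov.loc[case_row, "visit_rate"] = np.nan  # kills set 3
        design = build_design(matrix, cov, feats)
        assert 1 not in set(design["subject_id"])
        assert 3 not in set(design["set_id"])
        assert design.groupby("set_id")["is_case"].sum().eq(1).all()

    def test_joint_and_per_medication_modes(self):
        coh = simulate_matched_cohort(
            n_sets=400, ratio=3, prevalences=np.array([0.25, 0.25]),
            planted={0: 2.2}, seed=9,
        )
        matrix = coh.frame()
        matrix.insert(1, "subject_id", np.arange(len(matrix)))
        cov = matrix[["set_id", "subject_id", "is_case"]].copy()
        for c in ("visit_rate", "diabetes", "cardiovascular", "excess_weight"):
            cov[c] = 0.0
        cov["visit_rate"] = np.random.default_rng(0).random(len(cov))
        feats = coh.feature_names
        design = build_design(matrix, cov, feats)
        joint = estimate_effects(design, feats, joint=True)
        single = estimate_effects(design, feats, joint=False)
        assert set(joint["feature"]) == set(feats)
        assert set(single["feature"]) == set(feats)
        # both modes place the planted class on top, sorted descending
        assert joint["or"].is_monotonic_decreasing
        planted_code = feats[0]
        assert joint.iloc[0]["feature"] == planted_code
        assert single.iloc[0]["feature"] == planted_code
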