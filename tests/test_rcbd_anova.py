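import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from crescreen.plate_model import BASELINE, FORSKOLIN, ScreenDesign
from crescreen.rcbd_anova import rcbd_anova, treatment_p_for_receptor
from crescreen.simulate import SimulationConfig, archetype_profiles, simulate_screen

from _oracles import anova_projection_oracle, random_balanced_layout

# A fixed 2-treatment x 3-block x 2-replicate table; the expected
# decomposition below was computed once with the least-squares projection
# oracle (sequential sums of squares) and frozen.
FIXED_TABLE = np.array(
    [
        [[13.975, 11.919], [9.867, 5.210], [9.260, 11.344]],
        [[9.770, 12.584], [10.046, 11.309], [11.921, 11.803]],
    ]
)
FIXED_EXPECTED = {
    "ss": {
        "treatment": 2.85968033333333,
        "block": 18.110922666666667,
        "interaction": 12.560140666666666,
        "residual": 19.892765,
        "total": 53.42350866666666,
    },
    "F": {
        "treatment": 0.8625287635982217,
        "block": 2.7312828558523665,
        "interaction": 1.894177204626908,
    },
    "p": {
        "treatment": 0.3888673416659744,
        "block": 0.14341951054398314,
        "interaction": 0.23031631029116434,
    },
}


class TestDecomposition:
    def test_fixed_table_matches_frozen_oracle_values(self):
        res = rcbd_anova(FIXED_TABLE)
        for source, ss in FIXED_EXPECTED["ss"].items():
            assert res[source]["sum_sq"] == pytest.approx(ss, rel=1e-8)
        for source in ("treatment", "block", "interaction"):
            assert res[source]["F"] == pytest.approx(FIXED_EXPECTED["F"][source], rel=1e-8)
            assert res[source]["p"] == pytest.approx(FIXED_EXPECTED["p"][source], rel=1e-8)

    @pytest.mark.parametrize("error_term", ["residual", "interaction"])
    def test_random_layouts_match_projection_oracle(self, error_term):
        rng = np.random.default_rng(99)
        for _ in range(10):
            y = random_balanced_layout(rng)
            res = rcbd_anova(y, error_term=error_term)
            oracle = anova_projection_oracle(y, error_term=error_term)
            for source in ("treatment", "block", "interaction", "residual", "total"):
                assert res[source]["sum_sq"] == pytest.approx(
                    oracle["ss"][source], rel=1e-8, abs=1e-10
                )
                assert res[source]["df"] == oracle["df"][source]
            for source in ("treatment", "block", "interaction"):
                assert res[source]["F"] == pytest.approx(oracle["F"][source], rel=1e-8)
                assert res[source]["p"] == pytest.approx(oracle["p"][source], rel=1e-8)

    def test_statsmodels_cross_check(self):
        """Independent route: statsmodels OLS with sequential ANOVA."""
        import pandas as pd
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        y = FIXED_TABLE
        t, b, r = y.shape
        frame = pd.DataFrame(
            {
                "y": y.reshape(-1),
                "t": np.repeat(np.arange(t), b * r),
                "b": np.tile(np.repeat(np.arange(b), r), t),
            }
        )
        fit = smf.ols("y ~ C(t) * C(b)", data=frame).fit()
        table = sm.stats.anova_lm(fit, typ=1)
        res = rcbd_anova(y)
        assert res["treatment"]["sum_sq"] == pytest.approx(
            table.loc["C(t)", "sum_sq"], rel=1e-10
        )
        assert res["block"]["sum_sq"] == pytest.approx(
            table.loc["C(b)", "sum_sq"], rel=1e-10
        )
        assert res["interaction"]["sum_sq"] == pytest.approx(
            table.loc["C(t):C(b)", "sum_sq"], rel=1e-10
        )
        assert res["treatment"]["p"] == pytest.approx(
            table.loc["C(t)", "PR(>F)"], rel=1e-10
        )

    def test_sums_of_squares_add_up_and_dfs_partition(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(3, 4, 2))
        res = rcbd_anova(y)
        parts = sum(
            res[s]["sum_sq"] for s in ("treatment", "block", "interaction", "residual")
        )
        assert parts == pytest.approx(res["total"]["sum_sq"], rel=1e-12)
        dfs = sum(
            int(res[s]["df"]) for s in ("treatment", "block", "interaction", "residual")
        )
        assert dfs == int(res["total"]["df"]) == y.size - 1


class TestInvariances:
    @settings(max_examples=20, deadline=None)
    @given(
        shift=st.floats(-1e3, 1e3, allow_nan=False),
        scale=st.floats(0.01, 1e3, allow_nan=False),
        seed=st.integers(0, 2**16),
    )
    def test_affine_invariance_of_f_and_p(self, shift, scale, seed):
        y = np.random.default_rng(seed).normal(10, 2, size=(2, 4, 4))
        base = rcbd_anova(y)
        moved = rcbd_anova(y * scale + shift)
        for source in ("treatment", "block", "interaction"):
            assert moved[source]["F"] == pytest.approx(base[source]["F"], rel=1e-6)
            assert moved[source]["p"] == pytest.approx(base[source]["p"], rel=1e-6)

    def test_block_permutation_leaves_all_ss_unchanged(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=(3, 5, 2))
        perm = y[:, rng.permutation(5), :]
        a, b = rcbd_anova(y), rcbd_anova(perm)
        for source in ("treatment", "block", "interaction", "residual", "total"):
            assert b[source]["sum_sq"] == pytest.approx(a[source]["sum_sq"], rel=1e-12)


class TestDegenerateAndErrors:
    def test_all_equal_observations_report_p_one_with_flag(self):
        res = rcbd_anova(np.full((2, 3, 2), 7.0))
        assert res.degenerate
        for source in ("treatment", "block", "interaction", "residual", "total"):
            assert res[source]["sum_sq"] == 0.0
        for source in ("treatment", "block", "interaction"):
            assert res[source]["p"] == 1.0

    def test_zero_residual_with_real_effect_is_degenerate_significant(self):
        y = np.zeros((2, 3, 2))
        y[1] = 1.0  # pure treatment effect, no within-cell variance
        res = rcbd_anova(y)
        assert res.degenerate
        assert res["treatment"]["p"] == 0.0
        assert res["block"]["p"] == 1.0

    def test_unbalanced_input_is_rejected(self):
        with pytest.raises(ValueError, match="validator"):
            rcbd_anova(np.zeros((2, 3)))

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            rcbd_anova(np.zeros((1, 3, 2)))


class TestNullCalibration:
    def test_null_treatment_pvalues_are_uniform(self):
        """No treatment effect, real block effects, Gaussian errors: the
        treatment p-value must be exactly U(0,1); checked by KS over 2000
        independent layouts."""
        rng = np.random.default_rng(314)
        pvals = np.empty(2000)
        for i in range(2000):
            blocks = rng.normal(0, 1, (1, 4, 1))
            y = 10 + blocks + rng.normal(0, 0.5, (2, 4, 4))
            pvals[i] = rcbd_anova(y).treatment_p
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestTreatmentPForReceptor:
    def test_noise_free_effect_is_degenerate_significant(self, design, noise_free_screen):
        p, res = treatment_p_for_receptor(noise_free_screen, "R_A", BASELINE, design)
        assert res.degenerate
        assert p == 0.0
        assert res["treatment"]["sum_sq"] > 0
        assert res["residual"]["sum_sq"] == pytest.approx(0.0, abs=1e-12)

    def test_strong_effect_is_significant_in_both_conditions(self, design, default_screen):
        for condition in (BASELINE, FORSKOLIN):
            p, _ = treatment_p_for_receptor(default_screen, "R_A", condition, design)
            assert p < 0.01

    def test_null_receptor_is_typically_not_significant(self, design, default_screen):
        p, _ = treatment_p_for_receptor(default_screen, "R_E", BASELINE, design)
        assert p > 0.001  # seed-pinned null comparison

    def test_error_term_switch_changes_denominator(self, design, default_screen):
        _, res_r = treatment_p_for_receptor(
            default_screen, "R_A", BASELINE, design, error_term="residual"
        )
        _, res_i = treatment_p_for_receptor(
            default_screen, "R_A", BASELINE, design, error_term="interaction"
        )
        expected_f = res_i["treatment"]["mean_sq"] / res_i["interaction"]["mean_sq"]
        assert res_i["treatment"]["F"] == pytest.approx(expected_f, rel=1e-12)
        assert res_r["treatment"]["F"] != pytest.approx(res_i["treatment"]["F"], rel=1e-6)

    def test_requires_two_complete_plates(self, design, default_screen):
        one_plate = default_screen[default_screen["plate_id"] == "B1_P1"]
        with pytest.raises(ValueError, match=">= 2"):
            treatment_p_for_receptor(one_plate, "R_A", BASELINE, design)


class TestBenjaminiHochberg:
    def test_known_adjustments(self):
        from crescreen.rcbd_anova import benjamini_hochberg

        adj = benjamini_hochberg(np.array([0.005, 0.03, 0.1]))
        np.testing.assert_allclose(adj, [0.015, 0.045, 0.1])
        # ties through the step-up rule collapse to the largest q
        adj = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        from crescreen.rcbd_anova import benjamini_hochberg

        rng = np.random.default_rng(4)
        p = rng.uniform(size=25)
        _, expected, *_ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(benjamini_hochberg(p), expected, rtol=1e-12)

    def test_classify_screen_fdr_option_never_lowers_pvalues(
        self, design, default_screen
    ):
        from crescreen.classify import classify_screen

        raw = {c.receptor: c for c in classify_screen(default_screen, design)}
        adj = {
            c.receptor: c
            for c in classify_screen(default_screen, design, fdr_adjust=True)
        }
        for name in raw:
            assert adj[name].baseline_p >= raw[name].baseline_p - 1e-15
            assert adj[name].forskolin_p >= raw[name].forskolin_p - 1e-15
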