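"""Random-model ANOVA: sums of squares, quasi-F, variance components."""

import numpy as np
import pandas as pd
import pytest

from mudswim.anova import (DesignConstants, DesignError, RandomEffectsAnova,
                           SOURCES, f_ratios, mean_squares, quasi_f_p,
                           satterthwaite_df, variance_components)
from mudswim.simulate import simulate_anova_responses

# Mean squares of the published total-density analysis, used as a worked
# arithmetic example throughout.
MS_TOTAL = {"round": 7.282, "site": 11.666, "round_x_site": 1.112,
            "night": 0.969, "site_x_night": 0.248, "error": 0.047}


def balanced_frame(rng, a=3, b=2, c=2, n=2):
    rows = []
    for i in range(a):
        for j in range(b):
            for k in range(c):
                for _ in range(n):
                    rows.append({"site": f"S{i}", "round": f"R{j}",
                                 "night": f"N{k}", "y": rng.normal()})
    return pd.DataFrame(rows)


class TestMeanSquares:
    def test_constant_response_gives_zero_mean_squares(self):
        df = balanced_frame(np.random.default_rng(0))
        df["y"] = 3.14
        _, ms, _ = mean_squares(df)
        assert np.allclose(ms.values, 0.0, atol=1e-20)

    def test_balanced_toy_matches_hand_oracle(self):
        """Brute-force SS decomposition on a 2x2x2x2 layout, computed
        directly from marginal means in the test."""
        rng = np.random.default_rng(5)
        df = balanced_frame(rng, a=2, b=2, c=2, n=2)
        dof, ms, const = mean_squares(df)

        y = df.set_index(["site", "round", "night"]).sort_index()["y"]
        cube = y.groupby(level=[0, 1, 2]).mean().to_numpy().reshape(2, 2, 2)
        grand = cube.mean()
        ms_site = 2 * 2 * 2 * ((cube.mean(axis=(1, 2)) - grand) ** 2).sum() / 1
        ms_round = 2 * 2 * 2 * ((cube.mean(axis=(0, 2)) - grand) ** 2).sum() / 1
        m_sr = cube.mean(axis=2)
        ms_rs = 2 * 2 * ((m_sr - cube.mean(axis=(1, 2))[:, None]
                          - cube.mean(axis=(0, 2))[None, :] + grand) ** 2).sum() / 1
        m_rn = cube.mean(axis=0)
        ms_night = 2 * 2 * ((m_rn - cube.mean(axis=(0, 2))[:, None]) ** 2).sum() / 2
        resid = (cube - m_sr[:, :, None] - m_rn[None, :, :]
                 + cube.mean(axis=(0, 2))[None, :, None])
        ms_sn = 2 * (resid ** 2).sum() / 2
        ms_err = ((y - y.groupby(level=[0, 1, 2]).transform("mean")) ** 2
                  ).sum() / 8

        assert ms["site"] == pytest.approx(ms_site, rel=1e-12)
        assert ms["round"] == pytest.approx(ms_round, rel=1e-12)
        assert ms["round_x_site"] == pytest.approx(ms_rs, rel=1e-12)
        assert ms["night"] == pytest.approx(ms_night, rel=1e-12)
        assert ms["site_x_night"] == pytest.approx(ms_sn, rel=1e-12)
        assert ms["error"] == pytest.approx(ms_err, rel=1e-12)
        assert const.n == 2

    def test_balanced_decomposition_is_exact(self, rng):
        df = balanced_frame(rng, a=4, b=3, c=2, n=3)
        dof, ms, _ = mean_squares(df)
        total_ss = ((df["y"] - df["y"].mean()) ** 2).sum()
        assert (ms * dof).sum() == pytest.approx(total_ss, rel=1e-10)

    def test_matches_statsmodels_on_balanced_data(self, rng):
        """Type-I SS from a general linear model fit agree to 1e-10."""
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        df = balanced_frame(rng, a=3, b=2, c=3, n=2)
        model = ols("y ~ C(round) + C(site) + C(round):C(site)"
                    " + C(round):C(night) + C(round):C(night):C(site)",
                    data=df).fit()
        tab = sm.stats.anova_lm(model, typ=1)
        _, ms, _ = mean_squares(df)
        sm_ms = tab["sum_sq"] / tab["df"]
        assert ms["round"] == pytest.approx(sm_ms["C(round)"], rel=1e-10)
        assert ms["site"] == pytest.approx(sm_ms["C(site)"], rel=1e-10)
        assert ms["round_x_site"] == pytest.approx(
            sm_ms["C(round):C(site)"], rel=1e-10)
        # round:night after round carries the nested Night(Round) SS
        assert ms["night"] == pytest.approx(
            sm_ms["C(round):C(night)"], rel=1e-10)
        assert ms["site_x_night"] == pytest.approx(
            sm_ms["C(round):C(night):C(site)"], rel=1e-10)
        assert ms["error"] == pytest.approx(sm_ms["Residual"], rel=1e-10)

    def test_unbalanced_uses_harmonic_mean(self, rng):
        df = balanced_frame(rng, a=2, b=2, c=2, n=3)
        df = df.drop(df.index[0])  # one cell now has 2 replicates
        _, _, const = mean_squares(df)
        sizes = [2] + [3] * 7
        assert const.n == pytest.approx(len(sizes) / sum(1 / s for s in sizes))

    def test_empty_cell_is_named(self, rng):
        df = balanced_frame(rng, a=2, b=2, c=2, n=1)
        df = df[~((df["site"] == "S0") & (df["round"] == "R1")
                  & (df["night"] == "N0"))]
        with pytest.raises(DesignError, match="S0"):
            mean_squares(df)

    def test_unequal_nights_per_round_rejected(self, rng):
        df = balanced_frame(rng, a=2, b=2, c=2, n=2)
        df.loc[(df["round"] == "R1") & (df["night"] == "N1"), "night"] = "N2"
        df2 = balanced_frame(rng, a=2, b=2, c=2, n=2)
        df = pd.concat([df, df2[(df2["round"] == "R1") & (df2["night"] == "N1")]])
        with pytest.raises(DesignError, match="nights"):
            mean_squares(df)


class TestFRatios:
    def test_published_arithmetic_example(self):
        f = f_ratios(MS_TOTAL)
        assert f["site"] == pytest.approx(11.666 / 1.112)
        assert f["round"] == pytest.approx((7.282 + 0.248) / (0.969 + 1.112))
        assert f["night"] == pytest.approx(0.969 / 0.248)

    def test_equal_mean_squares_give_unit_ratios(self):
        f = f_ratios({k: 2.5 for k in SOURCES})
        assert np.allclose(f.drop("error").values, 1.0)

    def test_zero_denominator_flags_undefined_not_raises(self):
        ms = dict(MS_TOTAL)
        ms["error"] = 0.0
        f = f_ratios(ms)
        assert np.isnan(f["site_x_night"])

    def test_negative_mean_square_rejected(self):
        ms = dict(MS_TOTAL)
        ms["site"] = -1.0
        with pytest.raises(ValueError):
            f_ratios(ms)


class TestVarianceComponents:
    CONST = DesignConstants(a=9, b=3, c=3, n=81 / (79 / 3 + 2 / 2))

    def test_error_component_passes_through(self):
        comp, pct = variance_components(MS_TOTAL, self.CONST)
        assert comp["error"] == pytest.approx(0.047)
        assert pct["error"] == pytest.approx(6.7, abs=0.05)
        assert comp["site"] == pytest.approx(0.396, abs=5e-4)
        assert pct["site"] == pytest.approx(56.3, abs=0.05)

    def test_equal_mean_squares_put_everything_in_error(self):
        comp, pct = variance_components({k: 1.0 for k in SOURCES}, self.CONST)
        assert np.allclose(comp.drop("error").values, 0.0)
        assert pct["error"] == pytest.approx(100.0)

    def test_truncation_clips_negative_estimates(self):
        ms = {"round": 0.1, "site": 0.1, "round_x_site": 2.0,
              "night": 0.1, "site_x_night": 0.5, "error": 0.4}
        raw, _ = variance_components(ms, self.CONST, truncate=False)
        clipped, _ = variance_components(ms, self.CONST)
        assert raw["site"] < 0
        assert clipped["site"] == 0.0

    def test_percentages_sum_to_100(self, rng):
        for _ in range(20):
            ms = {k: float(rng.uniform(0.01, 10)) for k in SOURCES}
            _, pct = variance_components(ms, self.CONST)
            assert pct.sum() == pytest.approx(100.0, abs=0.15)


class TestQuasiFP:
    def test_unit_ratio_of_equal_composites_not_significant(self):
        p, _, _ = quasi_f_p(1.0, [(1.0, 4), (1.0, 10)], [(1.0, 6), (1.0, 8)])
        assert p > 0.3

    def test_df_shrinks_toward_dominant_component(self):
        # one MS dominates the composite -> synthesised df approach its df
        assert satterthwaite_df([(100.0, 4), (0.001, 50)]) == pytest.approx(4, rel=0.01)
        assert satterthwaite_df([(1.0, 4), (1.0, 4)]) == pytest.approx(8, rel=1e-9)

    def test_p_monotone_decreasing_in_f(self):
        ps = [quasi_f_p(f, [(1.0, 4), (1.0, 10)], [(1.0, 6), (1.0, 8)])[0]
              for f in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestCalibration:
    def test_site_type_one_error_rate_near_nominal(self):
        """With no true non-error variance, Site is declared significant at
        alpha=0.05 in about 5% of simulated surveys."""
        rng = np.random.default_rng(314)
        hits = 0
        runs = 500
        for _ in range(runs):
            df = simulate_anova_responses({"error": 1.0}, a=5, b=3, c=3, n=2,
                                          rng=rng)
            res = RandomEffectsAnova(df, "y").fit()
            hits += res.pvalues["site"] < 0.05
        assert 0.025 <= hits / runs <= 0.075


class TestResultsObject:
    def test_summary_mentions_design_and_sources(self, rng):
        df = balanced_frame(rng, a=3, b=2, c=2, n=2)
        res = RandomEffectsAnova(df, "y").fit()
        text = res.summary()
        assert "Site" in text and "quasi" in text.lower()
        assert res.anova_table.shape == (6, 7)
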