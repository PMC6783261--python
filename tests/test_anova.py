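"""Coverage residualisation and permutation ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tedyn.anova import (PermutationAnova, residualize,
                         tes_lost_from_residual_slope)
from tedyn.synth import GeneratorConfig, gen_count_table


def design_table(rng, n_strains=4, gens=range(0, 991, 90), effects=None):
    """Balanced two-mode table with optional programmed effects."""
    effects = effects or {}
    rows = []
    for mode in ("sexual", "asexual"):
        for s in range(n_strains):
            strain = f"{mode[0].upper()}{s+1}"
            for g in gens:
                cov = rng.uniform(5, 50)
                y = 24.0
                y += effects.get("coverage", 0.0) * cov
                y += effects.get("generation", 0.0) * g
                if mode == "asexual":
                    y += effects.get("mode", 0.0)
                    y += effects.get("interaction", 0.0) * g
                y += rng.normal(0, effects.get("sd", 1.0))
                rows.append((strain, mode, g, cov, y))
    return pd.DataFrame(rows, columns=["strain", "mode", "generation",
                                       "coverage", "count"])


class TestResidualize:
    def test_counts_linear_in_coverage_residualise_to_zero(self):
        df = pd.DataFrame({
            "strain": "A1", "mode": "asexual", "generation": 0,
            "coverage": np.linspace(1, 30, 12),
        })
        df["count"] = 3.0 + 0.7 * df["coverage"]
        np.testing.assert_allclose(residualize(df), 0.0, atol=1e-9)

    def test_constant_coverage_falls_back_to_centring(self):
        df = pd.DataFrame({"strain": "A1", "mode": "asexual",
                           "generation": [0, 90, 180],
                           "coverage": 10.0, "count": [10.0, 20.0, 30.0]})
        np.testing.assert_allclose(residualize(df), [-10.0, 0.0, 10.0])

    def test_residuals_centred(self, rng):
        df = design_table(rng, effects={"coverage": 0.3, "sd": 2.0})
        r = residualize(df)
        assert abs(r.mean()) < 1e-9


class TestPermAnova:
    def test_programmed_interaction_detected(self, rng):
        df = design_table(rng, effects={"interaction": -0.009, "sd": 0.5})
        res = PermutationAnova(df).fit(n_permutations=999, seed=1)
        assert res.p_interaction < 0.01

    def test_null_interaction_not_systematically_rejected(self, rng):
        # a handful of null tables should not all reject at alpha=0.05
        ps = []
        for i in range(10):
            df = design_table(rng)
            res = PermutationAnova(df).fit(n_permutations=199, seed=i)
            ps.append(res.p_interaction)
        assert np.mean(np.asarray(ps) < 0.05) < 0.5

    def test_constant_response_gives_p_one(self, rng):
        df = design_table(rng, effects={"sd": 0.0})
        df["count"] = 7.0
        res = PermutationAnova(df).fit(n_permutations=99, seed=0)
        assert np.all(res.pvalues == 1.0)

    def test_p_values_bounded_below(self, rng):
        df = design_table(rng, effects={"interaction": -0.05, "sd": 0.01})
        B = 99
        res = PermutationAnova(df).fit(n_permutations=B, seed=0)
        assert np.all(res.pvalues >= 1.0 / (B + 1) - 1e-12)

    def test_invariance_to_row_order_and_affine_rescaling(self, rng):
        df = design_table(rng, effects={"generation": -0.005, "sd": 1.0})
        res = PermutationAnova(df).fit(n_permutations=299, seed=9)
        shuffled = df.sample(frac=1.0, random_state=4).reset_index(drop=True)
        res_shuffled = PermutationAnova(shuffled).fit(n_permutations=299, seed=9)
        rescaled = df.assign(count=3.0 * df["count"] + 10.0)
        res_rescaled = PermutationAnova(rescaled).fit(n_permutations=299, seed=9)
        np.testing.assert_allclose(res_rescaled.f_obs, res.f_obs, rtol=1e-9)
        np.testing.assert_allclose(res_rescaled.pvalues, res.pvalues)
        # permuting rows changes the permutation stream, not the law:
        # observed F statistics are identical, p-values nearly so
        np.testing.assert_allclose(res_shuffled.f_obs, res.f_obs, rtol=1e-9)
        np.testing.assert_allclose(res_shuffled.pvalues, res.pvalues, atol=0.05)

    @pytest.mark.parametrize("scheme", ["freedman-lane", "raw"])
    def test_converges_to_classical_f_test_under_gaussian_errors(self, rng, scheme):
        df = design_table(rng, effects={"coverage": 0.1, "generation": -0.004,
                                        "sd": 1.5})
        res = PermutationAnova(df).fit(n_permutations=10_000, seed=2,
                                       scheme=scheme)
        n, p = len(df), 5
        classical = stats.f.sf(res.f_obs, 1, n - p)
        np.testing.assert_allclose(res.pvalues, classical, atol=0.02)

    def test_rank_deficient_design_names_term(self, rng):
        df = design_table(rng)
        df["generation"] = 90.0  # single generation value
        with pytest.raises(ValueError):
            PermutationAnova(df)
        df2 = design_table(rng)
        df2["coverage"] = df2["generation"] + 1.0
        with pytest.raises(ValueError, match="generation"):
            PermutationAnova(df2)

    def test_seed_required(self, rng):
        df = design_table(rng)
        with pytest.raises(ValueError, match="seed"):
            PermutationAnova(df).fit(n_permutations=99)

    def test_summary_table_shape(self, rng):
        df = design_table(rng)
        res = PermutationAnova(df).fit(n_permutations=99, seed=0)
        tab = res.summary()
        assert list(tab.index) == ["coverage", "generation", "mode",
                                   "generation:mode"]
        assert {"coef", "F", "p_perm"} <= set(tab.columns)


class TestResidualSlopeLoss:
    def test_zero_slope_means_no_loss(self):
        gens = np.repeat(np.arange(0, 991, 90), 4)
        res = tes_lost_from_residual_slope(np.zeros_like(gens, dtype=float),
                                           gens)
        assert res.tes_lost_1000 == pytest.approx(0.0, abs=1e-9)
        assert res.implied_final_count == pytest.approx(50.0)

    def test_programmed_decline_recovered(self, rng):
        gens = np.repeat(np.arange(0, 991, 90, dtype=float), 4)
        residuals = -0.009 * (gens - gens.mean()) + rng.normal(0, 0.3, gens.size)
        res = tes_lost_from_residual_slope(residuals, gens)
        assert res.tes_lost_1000 == pytest.approx(9.0, abs=1.0)
        assert res.implied_final_count == pytest.approx(41.0, abs=1.0)

    def test_positive_slope_reported_as_gain(self):
        gens = np.array([0.0, 90.0, 180.0, 270.0])
        res = tes_lost_from_residual_slope(0.01 * gens, gens)
        assert res.tes_lost_1000 == pytest.approx(-10.0)
        assert res.implied_final_count == pytest.approx(60.0)

    def test_single_generation_rejected(self):
        with pytest.raises(ValueError):
            tes_lost_from_residual_slope([1.0, 2.0], [90.0, 90.0])


class TestPipelineOnGeneratedTables:
    def test_coverage_corrected_decline_recovered_from_generator(self):
        cfg = GeneratorConfig(seed=123)
        table, truth = gen_count_table(cfg)
        asex = table[table["mode"] == "asexual"]
        res = tes_lost_from_residual_slope(
            residualize(asex), asex["generation"].to_numpy(float))
        assert res.tes_lost_1000 == pytest.approx(9.0, abs=1.5)
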