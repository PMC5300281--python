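"""Mixed-model fitting, term tests, and backward AIC elimination."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hippomesh.mixedmodel import (
    ModelSpec,
    VOLUME_FULL_TERMS,
    backward_select,
    fit_model,
    parse_terms,
    predict_cells,
    term_name,
    term_pvalues,
    transform_response,
)
from hippomesh.phantom import DEFAULT_LEVELS, DesignSpec, simulate_observations


def _nonref(factor):
    return sorted(DEFAULT_LEVELS[factor])[1:]


def _strong_coefficients(scale=0.3):
    """Treatment-coded truth for G+M+H+T+R+G:R+M:R with |effects| >= scale."""
    co = {"intercept": 1.2}
    for f in ("G", "M", "H", "T", "R"):
        co[f] = {lev: (scale + 0.05 * i) * (-1) ** i for i, lev in enumerate(_nonref(f))}
    for t in ("G:R", "M:R"):
        f1, f2 = t.split(":")
        co[t] = {
            (a, b): (scale + 0.03 * i) * (-1) ** (i % 3 == 0)
            for i, (a, b) in enumerate(itertools.product(_nonref(f1), _nonref(f2)))
        }
    return co


class TestTransformResponse:
    def test_endpoints_fixed(self):
        assert transform_response(1.0) == 1.0
        assert transform_response(0.0) == 0.0

    def test_ninth_power(self):
        assert transform_response(0.829) == pytest.approx(0.1849229338, abs=1e-9)

    def test_monotone_on_unit_interval(self):
        j = np.linspace(0, 1, 101)
        assert np.all(np.diff(transform_response(j)) >= 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            transform_response(1.2)
        with pytest.raises(ValueError):
            transform_response(np.array([0.5, -0.1]))


class TestModelSpec:
    def test_marginality_enforced(self):
        with pytest.raises(ValueError, match="marginality"):
            ModelSpec(fixed_terms=frozenset({("G", "M")}))

    def test_formula_round_trip(self):
        spec = ModelSpec.from_formula("response ~ G + M + R + M:R + (1|subject)")
        assert spec.fixed_terms == parse_terms("G+M+R+M:R")
        assert ModelSpec.from_formula(spec.formula) == spec

    def test_maximal_droppable_respects_marginality(self):
        spec = ModelSpec(fixed_terms=parse_terms("G+M+R+M:R"))
        names = {term_name(t) for t in spec.maximal_droppable()}
        assert names == {"G", "M:R"}


class TestFit:
    def test_noiseless_data_recovers_every_coefficient_to_1e8(self):
        ds = DesignSpec(n_subjects_per_group=3, coefficients=_strong_coefficients())
        df = simulate_observations(ds)
        fit = fit_model(df, ModelSpec(fixed_terms=parse_terms("G+M+H+T+R+G:R+M:R")))
        co = ds.coefficients
        p = fit.params
        assert p["Intercept"] == pytest.approx(1.2, abs=1e-8)
        for f in ("G", "M", "H", "T", "R"):
            for lev, val in co[f].items():
                assert p[f"{f}[{lev}]"] == pytest.approx(val, abs=1e-8), (f, lev)
        for (a, b), val in co["G:R"].items():
            assert p[f"G[{a}]:R[{b}]"] == pytest.approx(val, abs=1e-8)

    def test_matches_r_lmertest_oracle(self):
        # deterministic fixture; reference values computed once with
        # lme4/lmerTest (ML fit, Satterthwaite anova) on the identical CSV
        ds = DesignSpec(
            n_subjects_per_group=5, sd_subject=0.3, sd_residual=0.2, seed=11,
            coefficients={"intercept": 2.0, "G": {"CTRL": 0.4},
                          "M": {"Manual": 0.25}, "R": {"Middle": 0.3}},
        )
        df = simulate_observations(ds)
        fit = fit_model(df, ModelSpec(fixed_terms=parse_terms("G+M+H+T+R")))
        assert fit.llf == pytest.approx(107.041647, abs=2e-4)
        assert fit.aic == pytest.approx(-190.083295, abs=4e-4)
        assert fit.sigma2_subject == pytest.approx(0.05345938, rel=1e-4)
        assert fit.sigma2_residual == pytest.approx(0.03900478, rel=1e-4)
        an = fit.anova()
        expected = {
            # term: (F, num df, den df, p)
            "G": (5.28114013, 3, 20.0, 0.0075907026),
            "M": (98.16382154, 2, 700.0, 2.6360e-38),
            "H": (1.57199753, 1, 700.0, 0.2103357202),
            "T": (0.79699760, 1, 700.0, 0.3722993529),
            "R": (212.78037295, 2, 700.0, 6.385e-73),
        }
        for term, (F, ndf, ddf, p) in expected.items():
            row = an.loc[term]
            assert row.F == pytest.approx(F, rel=1e-4)
            assert row.df_num == ndf
            assert row.df_den == pytest.approx(ddf, abs=0.1)
            assert row.p_value == pytest.approx(p, rel=1e-2)

    def test_matches_statsmodels_mixedlm(self):
        statsmodels = pytest.importorskip("statsmodels.formula.api")
        ds = DesignSpec(n_subjects_per_group=6, sd_subject=0.25, sd_residual=0.15, seed=3,
                        coefficients=_strong_coefficients())
        df = simulate_observations(ds)
        fit = fit_model(df, ModelSpec(fixed_terms=parse_terms("G+M+R+M:R")))
        md = statsmodels.mixedlm(
            "response ~ C(group) + C(method) + C(region) + C(method):C(region)",
            df, groups=df["subject"],
        ).fit(reml=False)
        assert fit.llf == pytest.approx(md.llf, abs=1e-4)
        assert fit.sigma2_residual == pytest.approx(md.scale, rel=1e-4)
        assert np.sort(fit.params.to_numpy()) == pytest.approx(np.sort(md.fe_params.to_numpy()), abs=1e-6)

    def test_aic_identity(self):
        ds = DesignSpec(n_subjects_per_group=4, sd_residual=0.5, seed=8)
        df = simulate_observations(ds)
        fit = fit_model(df, ModelSpec(fixed_terms=parse_terms("G+M")))
        assert fit.aic == pytest.approx(2 * fit.k_params - 2 * fit.llf, abs=1e-10)

    def test_nested_model_never_has_higher_loglik(self):
        ds = DesignSpec(n_subjects_per_group=5, sd_subject=0.2, sd_residual=0.3, seed=21,
                        coefficients={"intercept": 1.0, "G": {"CTRL": 0.5}})
        df = simulate_observations(ds)
        small = fit_model(df, ModelSpec(fixed_terms=parse_terms("G")))
        big = fit_model(df, ModelSpec(fixed_terms=parse_terms("G+M+H")))
        assert big.llf >= small.llf - 1e-8

    def test_variance_components_recovered_on_intercept_model(self):
        ds = DesignSpec(n_subjects_per_group=25, sd_subject=0.0, sd_residual=1.0, seed=17)
        df = simulate_observations(ds)
        fit = fit_model(df, ModelSpec(fixed_terms=frozenset()))
        assert fit.sigma2_residual == pytest.approx(1.0, rel=0.2)
        assert fit.sigma2_subject < 0.05

    def test_duplicated_cells_rejected(self):
        ds = DesignSpec(n_subjects_per_group=2, sd_residual=0.1, seed=0)
        df = simulate_observations(ds)
        dup = pd.concat([df, df.iloc[:5]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicated"):
            fit_model(dup, ModelSpec(fixed_terms=parse_terms("G")))

    def test_missing_responses_dropped_listwise(self):
        ds = DesignSpec(n_subjects_per_group=4, sd_residual=0.2, seed=5,
                        coefficients={"intercept": 1.0})
        df = simulate_observations(ds)
        df.loc[df.sample(frac=0.1, random_state=0).index, "response"] = np.nan
        fit = fit_model(df, ModelSpec(fixed_terms=parse_terms("G+M")))
        assert fit.nobs == df["response"].notna().sum()

    def test_inestimable_term_named(self):
        ds = DesignSpec(n_subjects_per_group=3, sd_residual=0.1, seed=2)
        df = simulate_observations(ds)
        df = df[~((df.method == "Manual") & (df.region == "Middle"))]
        # M:R has an empty cell -> its block is fine, but a collapsed factor is not;
        # drop every Manual row of one region entirely to break estimability
        df = df[~((df.method == "Manual") & (df.region != "Anterior"))]
        with pytest.raises(ValueError, match="M:R"):
            fit_model(df, ModelSpec(fixed_terms=parse_terms("G+M+R+M:R")))


class TestPvalues:
    def test_huge_effect_is_tiny_p(self):
        ds = DesignSpec(n_subjects_per_group=10, sd_subject=0.1, sd_residual=0.1, seed=9,
                        coefficients={"intercept": 1.0, "M": {"Manual": 2.0, "FreeSurfer": -2.0}})
        df = simulate_observations(ds)
        fit = fit_model(df, ModelSpec(fixed_terms=parse_terms("G+M")))
        pv = term_pvalues(fit)
        assert pv["M"] < 1e-6
        assert pv["G"] > 0.01

    def test_doubling_data_shrinks_pvalues(self):
        ds = DesignSpec(n_subjects_per_group=6, sd_subject=0.1, sd_residual=0.4, seed=14,
                        coefficients={"intercept": 1.0, "H": {"Right": 0.08}})
        df = simulate_observations(ds)
        ds2 = DesignSpec(n_subjects_per_group=12, sd_subject=0.1, sd_residual=0.4, seed=14,
                         coefficients={"intercept": 1.0, "H": {"Right": 0.08}})
        df2 = simulate_observations(ds2)
        p1 = term_pvalues(fit_model(df, ModelSpec(fixed_terms=parse_terms("H"))))["H"]
        p2 = term_pvalues(fit_model(df2, ModelSpec(fixed_terms=parse_terms("H"))))["H"]
        assert p2 < p1

    def test_null_term_pvalues_roughly_uniform(self):
        # calibration: p-values of a null between-subject factor over replicates
        from scipy import stats

        pvals = []
        for seed in range(60):
            ds = DesignSpec(
                n_subjects_per_group=5, sd_subject=0.2, sd_residual=0.3, seed=700 + seed,
                levels={"G": DEFAULT_LEVELS["G"], "M": DEFAULT_LEVELS["M"], "H": DEFAULT_LEVELS["H"]},
                coefficients={"intercept": 1.0},
            )
            df = simulate_observations(ds)
            pvals.append(term_pvalues(fit_model(df, ModelSpec(fixed_terms=parse_terms("G+M"))))["G"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestPredictCells:
    def test_noiseless_predictions_equal_cell_means(self):
        ds = DesignSpec(n_subjects_per_group=2, coefficients=_strong_coefficients())
        df = simulate_observations(ds)
        fit = fit_model(df, ModelSpec(fixed_terms=parse_terms("G+M+H+T+R+G:R+M:R")))
        cells = df[["group", "method", "hemisphere", "timepoint", "region"]].drop_duplicates()
        pred = predict_cells(fit, cells)
        merged = df.merge(pred, on=list(cells.columns))
        assert np.allclose(merged["response"], merged["predicted"], atol=1e-8)

    def test_additive_hemisphere_offset_is_constant(self):
        ds = DesignSpec(n_subjects_per_group=4, sd_subject=0.1, sd_residual=0.1, seed=31,
                        coefficients={"intercept": 1.0, "H": {"Right": 0.0332},
                                      "M": {"Manual": 0.2}})
        df = simulate_observations(ds)
        fit = fit_model(df, ModelSpec(fixed_terms=parse_terms("G+M+H")))
        cells = df[["group", "method", "hemisphere"]].drop_duplicates()
        pred = predict_cells(fit, cells)
        wide = pred.pivot_table(index=["group", "method"], columns="hemisphere", values="predicted")
        offsets = wide["Right"] - wide["Left"]
        assert np.allclose(offsets, offsets.iloc[0], atol=1e-9)

    def test_interaction_makes_group_differences_region_dependent(self):
        ds = DesignSpec(n_subjects_per_group=3,
                        coefficients={"intercept": 1.0, "G": {"CTRL": 0.3},
                                      "R": {"Middle": 0.1}, "G:R": {("CTRL", "Middle"): 0.5}})
        df = simulate_observations(ds)
        fit = fit_model(df, ModelSpec(fixed_terms=parse_terms("G+R+G:R")))
        cells = df[["group", "region"]].drop_duplicates()
        pred = predict_cells(fit, cells).pivot_table(index="group", columns="region", values="predicted")
        diff_mid = pred.loc["CTRL", "Middle"] - pred.loc["AD", "Middle"]
        diff_ant = pred.loc["CTRL", "Anterior"] - pred.loc["AD", "Anterior"]
        assert diff_mid == pytest.approx(diff_ant + 0.5, abs=1e-8)

    def test_unknown_level_rejected(self):
        ds = DesignSpec(n_subjects_per_group=2, coefficients={"intercept": 1.0})
        fit = fit_model(simulate_observations(ds), ModelSpec(fixed_terms=parse_terms("G")))
        with pytest.raises(ValueError, match="unknown level"):
            predict_cells(fit, pd.DataFrame({"group": ["XXL"]}))


class TestBackwardSelect:
    def test_true_model_with_huge_effects_drops_nothing(self):
        ds = DesignSpec(n_subjects_per_group=8, sd_subject=0.05, sd_residual=0.05, seed=77,
                        coefficients=_strong_coefficients(scale=1.0))
        df = simulate_observations(ds)
        true_spec = ModelSpec(fixed_terms=parse_terms("G+M+H+T+R+G:R+M:R"))
        sel = backward_select(df, true_spec)
        assert sel.selected.fixed_terms == true_spec.fixed_terms
        assert not sel.trace["accepted"].any()

    def test_null_interactions_eliminated_from_full_model(self):
        # strong true structure + a favourable seed: the six null terms go
        ds = DesignSpec(n_subjects_per_group=20, sd_subject=0.15, sd_residual=0.1, seed=1000,
                        coefficients=_strong_coefficients())
        df = simulate_observations(ds)
        sel = backward_select(df, ModelSpec(fixed_terms=VOLUME_FULL_TERMS))
        assert sel.selected.fixed_terms == parse_terms("G+M+H+T+R+G:R+M:R")
        dropped = set(sel.trace.loc[sel.trace.accepted, "term"])
        assert dropped == {"G:M", "M:H", "G:T", "T:R", "G:T:R", "G:M:R"}
        # AIC never increased along accepted drops
        acc = sel.trace[sel.trace.accepted]
        assert (acc["aic_after"] <= acc["aic_before"] + 1e-9).all()

    def test_selection_invariant_to_row_order(self):
        ds = DesignSpec(n_subjects_per_group=6, sd_subject=0.1, sd_residual=0.2, seed=55,
                        coefficients=_strong_coefficients())
        df = simulate_observations(ds)
        shuffled = df.sample(frac=1.0, random_state=4).reset_index(drop=True)
        full = ModelSpec(fixed_terms=parse_terms("G+M+H+T+R+G:R+M:R"))
        a = backward_select(df, full)
        b = backward_select(shuffled, full)
        assert a.selected.fixed_terms == b.selected.fixed_terms
        assert np.allclose(a.fit.aic, b.fit.aic, atol=1e-6)

    def test_jaccard_rank_preserved_through_transform(self):
        # mean Jacc^9 orders methods the same way as mean Jaccard when the
        # per-method distributions do not cross
        rng = np.random.default_rng(12)
        j = {
            "FIRST": rng.uniform(0.80, 0.86, 200),
            "Manual": rng.uniform(0.70, 0.78, 200),
            "FreeSurfer": rng.uniform(0.60, 0.68, 200),
        }
        means_raw = {m: v.mean() for m, v in j.items()}
        means_t = {m: transform_response(v).mean() for m, v in j.items()}
        order = lambda d: sorted(d, key=d.get)
        assert order(means_raw) == order(means_t)
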