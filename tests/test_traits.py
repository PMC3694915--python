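import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from platydate import traits
from platydate.traits import (
    DegenerateInputError,
    em_impute,
    fit_linear,
    fit_quadratic,
    impute_generation_times,
    load_traits,
    pearson_r,
    select_subset,
)

from oracles import normal_equations_quadratic


class TestPearson:
    def test_exact_linearity_gives_one(self):
        assert pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_extant_platyrrhine_correlation(self, trait_table):
        sub = select_subset(trait_table, "platyrrhini")
        assert len(sub) == 15
        r = pearson_r(sub["body_mass_g"], sub["generation_time_yr"])
        assert r == pytest.approx(0.89, abs=0.01)

    def test_study_primate_correlation(self, trait_table):
        # extant set minus Gorilla reproduces the published 0.907
        sub = select_subset(trait_table, "study")
        r = pearson_r(sub["body_mass_g"], sub["generation_time_yr"])
        assert r == pytest.approx(0.907, abs=0.005)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson_r([1.0, 1.0, 1.0], [2.0, 4.0, 6.0])

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.floats(0.1, 100),
        b=st.floats(-50, 50),
        c=st.floats(0.1, 100),
        d=st.floats(-50, 50),
    )
    def test_invariant_under_positive_affine_maps(self, a, b, c, d):
        x = np.array([1.0, 3.0, 4.0, 8.0, 9.5])
        y = np.array([2.0, 1.0, 5.0, 4.0, 7.0])
        r0 = pearson_r(x, y)
        r1 = pearson_r(a * x + b, c * y + d)
        assert r1 == pytest.approx(r0, abs=1e-9)
        assert -1.0 <= r1 <= 1.0


class TestPolynomialFits:
    def test_noiseless_linear_recovered_by_both(self, trait_table):
        tbl = trait_table.copy()
        tbl["generation_time_yr"] = 6 + 0.001 * tbl["body_mass_g"]
        for fit in (fit_linear(tbl), fit_quadratic(tbl)):
            pred = fit.predict(tbl["body_mass_g"].to_numpy())
            np.testing.assert_allclose(pred, tbl["generation_time_yr"], rtol=1e-8)
        quad = fit_quadratic(tbl)
        assert quad.coefficients[2] == pytest.approx(0.0, abs=1e-12)

    def test_quadratic_matches_normal_equations_oracle(self, trait_table, quad_fit):
        sub = select_subset(trait_table, "platyrrhini")
        coef = normal_equations_quadratic(
            sub["body_mass_g"], sub["generation_time_yr"]
        )
        np.testing.assert_allclose(quad_fit.coefficients, coef, rtol=1e-8)
        # the 2700 g fossil (Dolichocebus) rounds to the tabulated 10 yr
        pred = float(quad_fit.predict(2700.0))
        assert pred == pytest.approx(coef @ [1, 2700, 2700**2], rel=1e-8)
        assert round(pred) == 10

    def test_linear_recovers_truth_within_three_se(self):
        rng = np.random.default_rng(123)
        a, b, sd, n = 5.0, 0.002, 1.5, 200
        mass = rng.uniform(300, 10000, n)
        g = a + b * mass + rng.normal(0, sd, n)
        tbl = pd.DataFrame(
            {
                "genus": [f"g{i}" for i in range(n)],
                "clade": "Cebinae",
                "body_mass_g": mass,
                "generation_time_yr": np.clip(g, 0.5, None),
                "is_fossil": False,
            }
        )
        fit = fit_linear(tbl)
        X = np.column_stack([np.ones(n), mass])
        cov = sd**2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        assert abs(fit.coefficients[0] - a) < 3 * se[0]
        assert abs(fit.coefficients[1] - b) < 3 * se[1]

    def test_quadratic_never_fits_worse_than_linear(self, trait_table):
        sub = select_subset(trait_table, "platyrrhini")
        m = sub["body_mass_g"].to_numpy()
        g = sub["generation_time_yr"].to_numpy()
        rss = {
            f.kind: ((g - f.predict(m)) ** 2).sum()
            for f in (fit_linear(trait_table), fit_quadratic(trait_table))
        }
        assert rss["quadratic"] <= rss["linear"] + 1e-9

    def test_too_few_records_rejected(self):
        tbl = pd.DataFrame(
            {
                "genus": ["a", "b"],
                "clade": "Cebinae",
                "body_mass_g": [100.0, 200.0],
                "generation_time_yr": [5.0, 6.0],
                "is_fossil": False,
            }
        )
        with pytest.raises(DegenerateInputError):
            fit_quadratic(tbl)

    def test_constant_mass_rejected(self):
        tbl = pd.DataFrame(
            {
                "genus": list("abcde"),
                "clade": "Cebinae",
                "body_mass_g": 500.0,
                "generation_time_yr": [5, 6, 7, 8, 9.0],
                "is_fossil": False,
            }
        )
        with pytest.raises(DegenerateInputError):
            fit_linear(tbl)


class TestEMImputation:
    def test_complete_table_returns_sample_moments(self, trait_table):
        completed, fit = em_impute(trait_table)
        pd.testing.assert_frame_equal(completed, trait_table)
        m = trait_table["body_mass_g"].to_numpy()
        g = trait_table["generation_time_yr"].to_numpy()
        np.testing.assert_allclose(fit.mean, [m.mean(), g.mean()], rtol=1e-6)
        np.testing.assert_allclose(
            fit.cov, np.cov(np.vstack([m, g]), bias=True), rtol=1e-5
        )

    def test_loglik_monotone_nondecreasing(self, trait_table):
        tbl = trait_table.copy()
        tbl.loc[tbl["is_fossil"], "generation_time_yr"] = np.nan
        _, fit = em_impute(tbl)
        steps = np.diff(fit.loglik_trace)
        assert (steps >= -1e-7 * np.abs(fit.loglik_trace[:-1])).all()
        assert fit.converged

    def test_recovers_bivariate_normal_parameters(self):
        rng = np.random.default_rng(99)
        mu = np.array([2000.0, 10.0])
        S = np.array([[500.0**2, 500.0 * 2.0 * 0.8], [500.0 * 2.0 * 0.8, 2.0**2]])
        n = 500
        xy = rng.multivariate_normal(mu, S, size=n)
        g = xy[:, 1].copy()
        g[rng.random(n) < 0.3] = np.nan  # 30% missing at random
        tbl = pd.DataFrame(
            {
                "genus": [f"g{i}" for i in range(n)],
                "clade": "Synthetic",
                "body_mass_g": np.abs(xy[:, 0]) + 1,
                "generation_time_yr": g,
                "is_fossil": False,
            }
        )
        tbl["body_mass_g"] = xy[:, 0]  # keep exact draws for the check
        _, fit = em_impute(tbl)
        np.testing.assert_allclose(fit.mean, mu, rtol=0.05)
        np.testing.assert_allclose(np.diag(fit.cov), np.diag(S), rtol=0.05 * 3)
        assert fit.cov[0, 1] == pytest.approx(S[0, 1], rel=0.15)

    def test_all_missing_rejected(self, trait_table):
        tbl = trait_table.copy()
        tbl["generation_time_yr"] = np.nan
        with pytest.raises(DegenerateInputError):
            em_impute(tbl)


class TestImputation:
    def test_fossil_predictions_match_reference_column(self, trait_table, quad_fit):
        # tabulated fossil generation times were derived from inferred body
        # mass; the quadratic fit reproduces all fossils <= 3000 g to +-1.5 yr
        imputed = impute_generation_times(trait_table, quad_fit, rounding="none")
        fossil = imputed[imputed["is_fossil"]]
        small = fossil[fossil["body_mass_g"] <= 3000]
        assert len(small) == 16
        reference = trait_table.set_index("genus")["generation_time_yr"]
        for _, row in small.iterrows():
            assert row["generation_time_yr"] == pytest.approx(
                reference[row["genus"]], abs=1.5
            )

    def test_identical_masses_get_identical_times(self, trait_table, quad_fit):
        imputed = impute_generation_times(trait_table, quad_fit)
        by_mass = imputed[imputed["is_fossil"]].groupby("body_mass_g")
        assert (by_mass["generation_time_yr"].nunique() == 1).all()

    def test_monotone_fit_gives_nondecreasing_times(self, trait_table):
        tbl = trait_table.copy()
        tbl.loc[~tbl["is_fossil"], "generation_time_yr"] = (
            4 + 0.0005 * tbl.loc[~tbl["is_fossil"], "body_mass_g"]
        )
        fit = fit_linear(tbl, subset="all_extant")
        imputed = impute_generation_times(tbl, fit, rounding="none")
        fossil = imputed[imputed["is_fossil"]].sort_values("body_mass_g")
        assert fossil["generation_time_yr"].is_monotonic_increasing

    def test_negative_prediction_names_genus(self, trait_table):
        from platydate.traits import AllometricFit

        bad = AllometricFit(
            kind="linear", coefficients=(1.0, -0.01), residual_sd=0.0,
            fitted_r=0.0, n_used=5,
        )
        with pytest.raises(ValueError, match="Protopithecus"):
            impute_generation_times(trait_table, bad)

    def test_hide_and_impute_roundtrip_correlation(self, trait_table):
        # hide each extant genus's generation time in turn, refit on the
        # rest, impute; out-of-sample predictions must track the truth
        sub = select_subset(trait_table, "study").reset_index(drop=True)
        imputed, true = [], []
        for i in range(len(sub)):
            tbl = sub.copy()
            tbl.loc[i, "is_fossil"] = True  # treat as unknown
            hidden = tbl.loc[i, "generation_time_yr"]
            tbl.loc[i, "generation_time_yr"] = np.nan
            fit = fit_quadratic(tbl, subset="study")
            out = impute_generation_times(tbl, fit, rounding="none")
            imputed.append(out.loc[i, "generation_time_yr"])
            true.append(hidden)
        assert pearson_r(imputed, true) > 0.8


class TestLoading:
    def test_duplicate_genus_rejected(self):
        csv = io.StringIO(
            "genus,clade,body_mass_g,generation_time_yr,is_fossil\n"
            "A,Cebinae,100,5,0\nA,Cebinae,200,6,0\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            load_traits(csv)

    def test_packaged_table_composition(self, trait_table):
        extant = trait_table[~trait_table["is_fossil"]]
        plat = extant[extant["clade"].isin(traits.PLATYRRHINE_CLADES)]
        assert len(plat) == 15
        assert len(extant) - len(plat) == 4
        assert trait_table["is_fossil"].sum() == 20
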