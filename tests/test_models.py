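"""Model-family builders: constraints, worked examples and recovery."""

import dataclasses

import numpy as np
import pytest

import twinpath as tp


class TestSaturatedCorrelations:
    def test_one_trait_has_two_free_parameters(self):
        spec = tp.build_saturated_correlation_model(["x"])
        assert spec.n_free == 2

    def test_two_traits_have_seven_free_parameters(self):
        # 1 within-person + per group (2 cross-twin within-trait + 1
        # cross-twin cross-trait) = 7 unique constrained moments
        spec = tp.build_saturated_correlation_model(["x", "y"])
        assert spec.n_free == 7

    def test_recovers_generating_correlations(self):
        spec = tp.build_saturated_correlation_model(["x"])
        truth = {"rmz_x": 0.9, "rdz_x": 0.6}
        df = tp.simulate_from_model(spec, truth, 5000, 5000, seed=14)
        res = tp.fit(spec.copy(), df)
        for name, true in truth.items():
            assert abs(res.estimates[name] - true) < 3 * res.std_errors[name]


class TestUnivariateACE:
    # printed Table-2 style worked examples: unit-variance inputs whose
    # three-moment solution is exact, so ML equals the Falconer estimators
    CASES = [
        (0.96, 0.76, {"h2": 0.40, "c2": 0.56, "e2": 0.04}),  # playing with books
        (0.94, 0.79, {"h2": 0.30, "e2": 0.06}),              # talking and rhymes
        (0.95, 0.78, {"c2": 0.61, "e2": 0.05}),              # playing games
        (0.99, 0.86, {"e2": 0.01}),                          # cognitive development
        (0.50, 0.50, {"h2": 0.00, "c2": 0.50, "e2": 0.50}),  # no MZ excess
    ]

    @pytest.mark.parametrize("rmz,rdz,expected", CASES)
    def test_worked_examples_from_printed_correlations(self, rmz, rdz, expected):
        spec = tp.build_ace_univariate("t")
        covs = {
            "MZ": np.array([[1.0, rmz], [rmz, 1.0]]),
            "DZ": np.array([[1.0, rdz], [rdz, 1.0]]),
        }
        res = tp.fit_covariances(spec, covs, {"MZ": 1000, "DZ": 1000})
        comp = tp.standardized_ace(res, "t")
        got = {"h2": comp.h2, "c2": comp.c2, "e2": comp.e2}
        for key, val in expected.items():
            assert round(got[key], 2) == val
        # exact three-moment solution == Falconer's formulas
        assert np.allclose(
            comp.as_tuple(), tp.falconer(rmz, rdz), atol=1e-4
        )

    @pytest.mark.parametrize("rmz,rdz", [(0.83, 0.52), (0.71, 0.48), (0.9, 0.7)])
    def test_ml_solution_matches_grid_search(self, rmz, rdz):
        """Brute-force grid over the (a2, c2) simplex as an independent oracle."""
        spec = tp.build_ace_univariate("t")
        covs = {
            "MZ": np.array([[1.0, rmz], [rmz, 1.0]]),
            "DZ": np.array([[1.0, rdz], [rdz, 1.0]]),
        }
        res = tp.fit_covariances(spec, covs, {"MZ": 500, "DZ": 500})
        comp = tp.standardized_ace(res, "t")

        # two-stage vectorized grid over (a2, c2), refined to a 1e-4 step;
        # closed-form 2x2 multivariate-normal deviance per group
        best = None
        for step in (0.01, 0.0001):
            if best is None:
                a_vals = c_vals = np.arange(0.0, 1.0001, step)
            else:
                a_vals = np.arange(max(best[0] - 0.02, 0), min(best[0] + 0.02, 1), step)
                c_vals = np.arange(max(best[1] - 0.02, 0), min(best[1] + 0.02, 1), step)
            A, C = np.meshgrid(a_vals, c_vals, indexing="ij")
            mask = A + C <= 0.9999
            dev = np.full_like(A, np.inf)
            for coef, s in ((1.0, rmz), (0.5, rdz)):
                r = np.where(mask, coef * A + C, 0.0)
                dev = np.where(
                    mask,
                    np.where(np.isinf(dev), 0.0, dev)
                    + np.log(1 - r**2) + 2 * (1 - s * r) / (1 - r**2),
                    np.inf,
                )
            i, j = np.unravel_index(np.argmin(dev), dev.shape)
            best = (A[i, j], C[i, j])
        assert abs(comp.h2 - best[0]) < 2e-4
        assert abs(comp.c2 - best[1]) < 2e-4

    def test_latent_factor_requires_two_indicators(self):
        with pytest.raises(ValueError, match="two indicators"):
            tp.build_ace_univariate("cd", indicators=["cd_t1"])

    def test_latent_factor_model_recovers_measurement_and_shares(self):
        spec = tp.build_ace_univariate("cd", indicators=["cd_t1", "cd_t2"])
        truth = {
            "a_cd": 0.55, "c_cd": 0.75, "e_cd": 0.25,
            "lambda_cd": 0.85, "res_cd": 0.3,
        }
        df = tp.simulate_from_model(spec, truth, 3000, 3000, seed=61)
        res = tp.fit(spec.copy(), df)
        assert res.converged
        assert abs(res.estimates["lambda_cd"] - 0.85) < 3 * res.std_errors["lambda_cd"]
        comp = tp.standardized_ace(res, "cd")
        total = sum(v**2 for v in (0.55, 0.75, 0.25))
        assert abs(comp.h2 - 0.55**2 / total) < 3 * comp.se_h2


class TestCholesky:
    def test_zero_cross_loadings_imply_zero_cross_covariance(self):
        spec = tp.build_cholesky_bivariate("x", "y")
        params = {n: p.start for n, p in spec.parameters.items()}
        params.update({"a21": 0.0, "c21": 0.0, "e21": 0.0})
        cov = tp.implied_moments(spec, params)["MZ"][1]
        obs = spec.observed
        assert cov[obs.index("x_1"), obs.index("y_1")] == pytest.approx(0.0, abs=1e-12)

    def test_covariance_shares_sum_to_one(self):
        spec = tp.build_cholesky_bivariate("x", "y")
        truth = {"a11": 0.6, "a21": 0.25, "a22": 0.5,
                 "c11": 0.5, "c21": 0.35, "c22": 0.5,
                 "e11": 0.45, "e21": 0.1, "e22": 0.4}
        df = tp.simulate_from_model(spec, truth, 1500, 1500, seed=33)
        res = tp.fit(spec.copy(), df, compute_se=False)
        shares = tp.cross_trait_covariance_shares(res, "x", "y")
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-10)
        # dominant share should reflect the generating structure (C largest)
        hand = {comp: truth[f"{comp.lower()}11"] * truth[f"{comp.lower()}21"]
                for comp in ("A", "C", "E")}
        hand_total = sum(hand.values())
        for comp in ("A", "C", "E"):
            assert abs(shares[comp] - hand[comp] / hand_total) < 0.15


class TestDoC:
    def test_direction_none_with_independent_traits(self):
        spec = tp.build_doc("x", "y", direction="none")
        cov = tp.implied_moments(spec)["DZ"][1]
        obs = spec.observed
        assert cov[obs.index("x_1"), obs.index("y_1")] == pytest.approx(0.0, abs=1e-12)

    def test_invalid_direction_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            tp.build_doc("x", "y", direction="sideways")

    def test_direction_recovered_when_modes_of_inheritance_differ(self):
        gen = tp.build_doc("x", "y", direction="xtoy")
        truth = {
            "a_x": np.sqrt(0.7), "c_x": np.sqrt(0.1), "e_x": np.sqrt(0.2),
            "a_y": np.sqrt(0.1), "c_y": np.sqrt(0.7), "e_y": np.sqrt(0.2),
            "causal_x_to_y": 0.4,
        }
        wins = 0
        n_rep = 20
        for rep in range(n_rep):
            df = tp.simulate_from_model(gen, truth, 1500, 1500, seed=300 + rep)
            fx = tp.fit(tp.build_doc("x", "y", "xtoy"), df, compute_se=False)
            fy = tp.fit(tp.build_doc("x", "y", "ytox"), df, compute_se=False)
            wins += fx.aic < fy.aic
        assert wins >= 0.9 * n_rep

    def test_identical_ace_shares_leave_directions_indistinguishable(self):
        """With matching modes of inheritance the two unidirectional models
        fit near-identically — the design's known blind spot."""
        gen = tp.build_doc("x", "y", direction="xtoy")
        v = np.sqrt(1 / 3)
        truth = {"a_x": v, "c_x": v, "e_x": v, "a_y": v, "c_y": v, "e_y": v,
                 "causal_x_to_y": 0.4}
        gaps = []
        for rep in range(10):
            df = tp.simulate_from_model(gen, truth, 1000, 1000, seed=400 + rep)
            fx = tp.fit(tp.build_doc("x", "y", "xtoy"), df, compute_se=False)
            fy = tp.fit(tp.build_doc("x", "y", "ytox"), df, compute_se=False)
            gaps.append(abs(fx.aic - fy.aic))
        assert np.median(gaps) < 2.0


class TestMRDoC:
    def test_wald_test_calibration_under_null_causal_path(self):
        spec = tp.build_mrdoc("x", "y")
        truth = {n: p.start for n, p in spec.parameters.items()}
        truth.update({
            "instrument_strength": 0.3, "pleiotropy": 0.1, "causal_x_to_y": 0.0,
            "a_x": 0.6, "c_x": 0.55, "e_x": 0.45,
            "a_y": 0.6, "c_y": 0.55, "e_y": 0.45,
            "ra_residual": 0.25, "rc_residual": 0.3, "v_pgs": 1.0,
        })
        rejections = 0
        n_rep = 60
        for rep in range(n_rep):
            df = tp.mask_duplicate_instrument(
                tp.simulate_from_model(spec, truth, 800, 800, seed=500 + rep)
            )
            res = tp.fit(spec.copy(), df)
            if res.wald_p("causal_x_to_y") < 0.05:
                rejections += 1
        # nominal 5% two-sided test: expect ~3/60, allow binomial slack
        assert 0 <= rejections <= 8


class TestCrosslag:
    def test_nesting_identity_with_crosstime_fixed_at_zero(self):
        cfg = dataclasses.replace(tp.SimConfig(), n_mz=100, n_dz=100,
                                  missing_rate=0.0, sex_effect=0.0,
                                  age_effect=0.0, seed=71)
        cohort = tp.simulate_structural(cfg)
        plain = tp.build_crosslag("cd", "cs")
        ext = tp.build_extended_crosslag("cd", "cs")
        theta = {n: p.start for n, p in plain.parameters.items()}
        theta_ext = dict(theta)
        for name in ext.meta["crosstime"].values():
            theta_ext[name] = 0.0
        a = tp.fiml_minus2ll(plain, theta, cohort)
        b = tp.fiml_minus2ll(ext, theta_ext, cohort)
        assert a == pytest.approx(b, abs=1e-9)

    def test_null_crosslags_recovered_as_zero(self):
        cfg = dataclasses.replace(
            tp.SimConfig(), lag_y_to_x=0.0, lag_x_to_y=0.0,
            ra_cross=0.0, rc_cross=0.0, p1=0.0, p2=0.0,
            n_mz=1000, n_dz=1000, missing_rate=0.0,
            sex_effect=0.0, age_effect=0.0, seed=81,
        )
        cohort = tp.simulate_structural(cfg)
        res = tp.fit(tp.build_crosslag("cd", "cs"), cohort)
        for lag in ("lag_cs_to_cd", "lag_cd_to_cs"):
            assert abs(res.estimates[lag]) < 3 * res.std_errors[lag]


def test_build_model_dispatch():
    spec = tp.build_model("ace_univariate", trait="cd_t1")
    assert spec.name == "ace_cd_t1"
    with pytest.raises(ValueError, match="unknown model family"):
        tp.build_model("nope")


def test_every_family_identified_at_start_values():
    specs = [
        tp.build_saturated_correlation_model(["x", "y"]),
        tp.build_ace_univariate("x"),
        tp.build_ace_univariate("cd", indicators=["cd_t1", "cd_t2"]),
        tp.build_cholesky_bivariate("x", "y"),
        tp.build_doc("x", "y", "xtoy"),
        tp.build_mrdoc("x", "y"),
        tp.build_crosslag("cd", "cs"),
        tp.build_extended_crosslag("cd", "cs"),
    ]
    for spec in specs:
        assert tp.check_identification(spec).identified, spec.name
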