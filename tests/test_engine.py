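"""Implied moments, FIML likelihood, optimization and identification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import twinpath as tp
from twinpath.engine import GROUPS


def _univariate_cohort(rmz, rdz, n, seed):
    spec = tp.build_ace_univariate("x")
    # solve exact paths from the target correlations (Falconer moments)
    a2 = 2 * (rmz - rdz)
    c2 = 2 * rdz - rmz
    e2 = 1 - rmz
    params = {"a_x": np.sqrt(a2), "c_x": np.sqrt(c2), "e_x": np.sqrt(e2)}
    return spec, tp.simulate_from_model(spec, params, n, n, seed)


class TestImpliedMoments:
    def test_univariate_ace_hand_algebra(self):
        spec = tp.build_ace_univariate("x")
        v = np.sqrt(1 / 3)
        mom = tp.implied_moments(spec, {"a_x": v, "c_x": v, "e_x": v})
        assert np.allclose(mom["MZ"][1], [[1, 2 / 3], [2 / 3, 1]], atol=1e-12)
        assert np.allclose(mom["DZ"][1], [[1, 0.5], [0.5, 1]], atol=1e-12)

    def test_doc_without_causal_paths_reduces_to_independent_ace(self):
        doc = tp.build_doc("x", "y", direction="both")
        params = {n: p.start for n, p in doc.parameters.items()}
        params["causal_x_to_y"] = 0.0
        params["causal_y_to_x"] = 0.0
        mom_doc = tp.implied_moments(doc, params)
        none = tp.build_doc("x", "y", direction="none")
        mom_none = tp.implied_moments(none, {k: v for k, v in params.items()
                                             if k in none.parameters})
        for g in GROUPS:
            assert np.allclose(mom_doc[g][1], mom_none[g][1], atol=1e-12)

    def test_symmetric_and_deterministic(self):
        spec = tp.build_extended_crosslag("cd", "cs")
        cov1 = tp.implied_moments(spec)["DZ"][1]
        cov2 = tp.implied_moments(spec)["DZ"][1]
        assert np.array_equal(cov1, cov2)
        assert np.abs(cov1 - cov1.T).max() < 1e-12

    def test_mz_dz_differ_only_through_genetic_cells(self):
        # every cell whose treks avoid A factors must agree across groups:
        # kill the A paths and the two implied matrices must coincide
        spec = tp.build_extended_crosslag("cd", "cs")
        params = {n: p.start for n, p in spec.parameters.items()}
        for n in list(params):
            if n.startswith("a_") or n.startswith("ra"):
                params[n] = 0.0
        mom = tp.implied_moments(spec, params)
        assert np.allclose(mom["MZ"][1], mom["DZ"][1], atol=1e-12)

    def test_monte_carlo_covariance_matches_implied(self, quiet_config):
        import dataclasses

        cfg = dataclasses.replace(quiet_config, n_mz=20000, n_dz=20000, seed=31)
        cohort = tp.simulate_structural(cfg)
        spec = tp.config_to_modelspec(cfg)
        mom = tp.implied_moments(spec)
        for g in GROUPS:
            sub = cohort.data.loc[cohort.data.zygosity == g, spec.observed].to_numpy()
            emp = sub.T @ sub / len(sub)
            n = len(sub)
            imp = mom[g][1]
            # family-wise Monte-Carlo bound: the max over ~110 unique
            # entries needs 4 SE for a <1% false-alarm rate
            se = np.sqrt(
                (np.outer(np.diag(imp), np.diag(imp)) + imp**2) / n
            )
            assert np.all(np.abs(emp - imp) < 4.0 * se)


class TestFIML:
    def _tiny_spec(self):
        spec = tp.build_ace_univariate("x")
        params = {"a_x": 0.6, "c_x": 0.5, "e_x": 0.4}
        return spec, params

    def test_complete_data_equals_closed_form(self):
        spec, params = self._tiny_spec()
        df = tp.simulate_from_model(spec, params, 40, 40, seed=3)
        got = tp.fiml_minus2ll(spec, params, df)
        mom = tp.implied_moments(spec, params)
        expected = 0.0
        for g in GROUPS:
            X = df.loc[df.zygosity == g, spec.observed].to_numpy()
            expected += -2.0 * stats.multivariate_normal(
                mean=mom[g][0], cov=mom[g][1]
            ).logpdf(X).sum()
        assert got == pytest.approx(expected, abs=1e-8)

    def test_single_observed_value_contribution(self):
        # one row, one observed variable x under a unit-variance model:
        # -2 lnL = log(2 pi) + x^2
        spec = tp.build_ace_univariate("x")
        params = {"a_x": 0.0, "c_x": 0.0, "e_x": 1.0}
        x = 1.37
        df = pd.DataFrame(
            {"pair_id": ["p0"], "zygosity": ["MZ"], "x_1": [x], "x_2": [np.nan]}
        )
        got = tp.fiml_minus2ll(spec, params, df)
        assert got == pytest.approx(np.log(2 * np.pi) + x**2, abs=1e-12)

    def test_mixed_missingness_matches_rowwise_subsetting_oracle(self):
        """Five rows with mixed patterns vs explicit per-row marginalization."""
        spec = tp.build_ace_univariate("x")
        params = {"a_x": 0.55, "c_x": 0.6, "e_x": 0.5}
        df = pd.DataFrame({
            "pair_id": [f"p{i}" for i in range(5)],
            "zygosity": ["MZ", "MZ", "DZ", "DZ", "DZ"],
            "x_1": [0.3, np.nan, -1.2, np.nan, 0.9],
            "x_2": [-0.5, 0.8, 0.4, np.nan, np.nan],
        })
        mom = tp.implied_moments(spec, params)
        expected = 0.0
        for _, row in df.iterrows():
            obs = [c for c in ("x_1", "x_2") if not np.isnan(row[c])]
            if not obs:
                continue
            idx = [("x_1", "x_2").index(c) for c in obs]
            cov = mom[row.zygosity][1][np.ix_(idx, idx)]
            expected += -2.0 * stats.multivariate_normal(
                mean=np.zeros(len(idx)), cov=cov
            ).logpdf(np.array([row[c] for c in obs]))
        got = tp.fiml_minus2ll(spec, params, df)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_empty_rows_contribute_zero(self):
        spec = tp.build_ace_univariate("x")
        params = {"a_x": 0.5, "c_x": 0.5, "e_x": 0.5}
        base = pd.DataFrame({
            "pair_id": ["p0"], "zygosity": ["MZ"], "x_1": [0.2], "x_2": [0.1]
        })
        extra = pd.DataFrame({
            "pair_id": ["p1"], "zygosity": ["DZ"], "x_1": [np.nan], "x_2": [np.nan]
        })
        both = pd.concat([base, extra], ignore_index=True)
        assert tp.fiml_minus2ll(spec, params, both) == pytest.approx(
            tp.fiml_minus2ll(spec, params, base), abs=1e-12
        )

    def test_non_positive_definite_pattern_is_reported(self):
        spec = tp.build_ace_univariate("x")
        df = pd.DataFrame({
            "pair_id": ["p0"], "zygosity": ["MZ"], "x_1": [0.2], "x_2": [0.1]
        })
        with pytest.raises(ValueError, match="positive definite"):
            tp.fiml_minus2ll(spec, {"a_x": 0.0, "c_x": 0.0, "e_x": 0.0}, df)


class TestFit:
    def test_parameter_recovery_univariate(self):
        spec, _ = tp.build_ace_univariate("x"), None
        truth = {"a_x": np.sqrt(0.4), "c_x": np.sqrt(0.4), "e_x": np.sqrt(0.2)}
        df = tp.simulate_from_model(spec, truth, 4000, 4000, seed=8)
        res = tp.fit(spec.copy(), df)
        assert res.converged
        comp = tp.standardized_ace(res, "x")
        for share, true in zip(comp.as_tuple(), (0.4, 0.4, 0.2)):
            assert abs(share - true) < 3 * max(comp.se_h2, comp.se_c2, comp.se_e2)

    def test_refit_from_optimum_is_fixed_point(self):
        spec, _ = _univariate_cohort(0.8, 0.5, 500, 21)[0], None
        truth = {"a_x": 0.7, "c_x": 0.4, "e_x": 0.5}
        df = tp.simulate_from_model(spec, truth, 500, 500, seed=21)
        first = tp.fit(spec.copy(), df, compute_se=False)
        warm = spec.copy()
        for n, v in first.estimates.items():
            warm.parameters[n].start = v
        second = tp.fit(warm, df, compute_se=False)
        assert second.minus2ll == pytest.approx(first.minus2ll, abs=1e-8)

    def test_twin_order_swap_leaves_likelihood_unchanged(self):
        spec = tp.build_ace_univariate("x")
        truth = {"a_x": 0.6, "c_x": 0.5, "e_x": 0.4}
        df = tp.simulate_from_model(spec, truth, 200, 200, seed=5)
        swapped = df.rename(columns={"x_1": "x_2", "x_2": "x_1"})
        assert tp.fiml_minus2ll(spec, truth, df) == pytest.approx(
            tp.fiml_minus2ll(spec, truth, swapped), abs=1e-9
        )

    def test_nested_restriction_never_fits_better(self):
        spec = tp.build_ace_univariate("x")
        truth = {"a_x": 0.6, "c_x": 0.5, "e_x": 0.4}
        df = tp.simulate_from_model(spec, truth, 800, 800, seed=13)
        full = tp.fit(spec.copy(), df, compute_se=False)
        ce_only = spec.copy()
        ce_only.fix("a_x", 0.0)
        restricted = tp.fit(ce_only, df, compute_se=False)
        assert restricted.minus2ll >= full.minus2ll - 1e-6

    def test_aic_consistency(self):
        spec = tp.build_ace_univariate("x")
        df = tp.simulate_from_model(
            spec, {"a_x": 0.6, "c_x": 0.5, "e_x": 0.4}, 300, 300, seed=2
        )
        res = tp.fit(spec.copy(), df, compute_se=False)
        assert res.aic == pytest.approx(res.minus2ll + 2 * res.n_free)


class TestIdentification:
    def test_interchangeable_shared_factors_flagged(self):
        # two shared factors with identical cross-twin structure load on the
        # same phenotype: only c1^2 + c2^2 reaches the moments, so the rank
        # check must fail and name both loadings
        variables = ["x_1", "x_2", "L1_1", "L1_2", "L2_1", "L2_2"]
        spec = tp.ModelSpec(variables, ["x_1", "x_2"])
        spec.add_parameter("c1", 0.5)
        spec.add_parameter("c2", 0.4)
        for fac in ("L1", "L2"):
            for t in (1, 2):
                spec.set_cov(f"{fac}_{t}", f"{fac}_{t}", 1.0)
            spec.set_cov(f"{fac}_1", f"{fac}_2", 1.0)
        for t in (1, 2):
            spec.set_path(f"L1_{t}", f"x_{t}", "c1")
            spec.set_path(f"L2_{t}", f"x_{t}", "c2")
            spec.set_cov(f"x_{t}", f"x_{t}", 0.3)
        res = tp.check_identification(spec)
        assert not res.identified
        named = set().union(*(set(c) for c in res.deficient))
        assert {"c1", "c2"} <= named

    def test_extended_crosslag_identified_with_e_crosstime_fixed(self):
        spec = tp.build_extended_crosslag("cd", "cs")
        assert tp.check_identification(spec).identified

    def test_extended_crosslag_unidentified_with_e_crosstime_free(self):
        spec = tp.build_extended_crosslag("cd", "cs", free_e_crosstime=True)
        res = tp.check_identification(spec)
        assert not res.identified
        assert res.rank < res.n_free

    def test_mrdoc_causal_path_needs_instrument_or_e_contrast(self):
        """With a pleiotropy path, the causal path stays identified at zero
        instrument strength through the within- vs cross-twin E contrast;
        when both routes vanish the rank check names the causal path."""
        spec = tp.build_mrdoc("x", "y")
        values = {n: p.start for n, p in spec.parameters.items()}
        weak = dict(values, instrument_strength=0.0)
        assert tp.check_identification(spec, weak).identified
        degenerate = dict(weak, e_x=0.0)
        res = tp.check_identification(spec, degenerate)
        assert not res.identified
        named = set().union(*(set(c) for c in res.deficient))
        assert "causal_x_to_y" in named
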