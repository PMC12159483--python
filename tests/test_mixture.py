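"""Scheffé mixture models: pseudo coding, fitting, statistics, D-optimality."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mixkin
from mixkin.errors import BoundsError, SingularityError, SizeError, ValidationError
from mixkin.mixture import (
    DesignTable,
    MixtureDesignSpec,
    ScheffeMixture,
    d_optimal_select,
    from_pseudo,
    scheffe_term_labels,
    scheffe_terms,
    to_pseudo,
    _design_matrix,
)

from conftest import random_feasible_amounts


class TestPseudoCoding:
    def test_optimum_maps_to_known_pseudo_point(self, spec):
        p = to_pseudo([9.189, 60.0, 15.311], spec)
        assert p == pytest.approx([0.93089, 0.0, 0.06911], abs=5e-6)

    def test_vertex_maps_to_unit_vertex(self, spec):
        assert to_pseudo([9.5, 60.0, 15.0], spec) == pytest.approx([1, 0, 0])

    def test_inverse_of_known_point(self, spec):
        x = from_pseudo([0.93088889, 0.0, 0.06911111], spec)
        assert x == pytest.approx([9.189, 60.0, 15.311], abs=1e-6)

    def test_round_trip_identity_on_random_points(self, spec, rng):
        for x in random_feasible_amounts(spec, rng, 1000):
            back = from_pseudo(to_pseudo(x, spec), spec)
            np.testing.assert_allclose(back, x, atol=1e-9)

    def test_proportions_sum_to_one(self, spec, rng):
        for x in random_feasible_amounts(spec, rng, 50):
            assert to_pseudo(x, spec).sum() == pytest.approx(1.0, abs=1e-12)

    def test_bad_total_raises_naming_problem(self, spec):
        with pytest.raises(BoundsError, match="total"):
            to_pseudo([9.5, 60.0, 16.0], spec)

    def test_below_lower_bound_names_component(self, spec):
        with pytest.raises(BoundsError, match="juice"):
            to_pseudo([4.0, 62.0, 18.5], spec)

    def test_invalid_pseudo_rejected(self, spec):
        with pytest.raises(ValidationError):
            from_pseudo([0.5, 0.2, 0.2], spec)


class TestScheffeTerms:
    def test_vertex(self):
        np.testing.assert_allclose(
            scheffe_terms([1, 0, 0], "special_cubic"), [1, 0, 0, 0, 0, 0, 0]
        )

    def test_centroid(self):
        t = scheffe_terms([1 / 3] * 3, "special_cubic")
        np.testing.assert_allclose(
            t, [1 / 3] * 3 + [1 / 9] * 3 + [1 / 27], atol=1e-15
        )

    def test_binary_blend_products(self):
        t = scheffe_terms([0.93089, 0.0, 0.06911], "special_cubic")
        assert t[4] == pytest.approx(0.93089 * 0.06911, abs=1e-12)  # AC
        assert t[3] == t[5] == t[6] == 0  # every B-containing term

    @pytest.mark.parametrize("degree,n", [("linear", 3), ("quadratic", 6),
                                          ("special_cubic", 7)])
    def test_term_counts(self, degree, n):
        assert len(scheffe_term_labels(degree)) == n
        assert scheffe_terms([0.2, 0.3, 0.5], degree).size == n

    def test_unknown_degree(self):
        from mixkin.errors import ConfigurationError

        with pytest.raises(ConfigurationError):
            scheffe_terms([1, 0, 0], "cubic")


class TestFitting:
    @pytest.mark.parametrize("degree", ["linear", "quadratic", "special_cubic"])
    def test_zero_noise_recovery_all_degrees(self, fixtures, spec, degree, rng):
        """OLS on noiseless synthetic responses recovers the truth to 1e-8."""
        amounts = fixtures.design.amounts()
        labels = scheffe_term_labels(degree)
        truth = rng.uniform(-5, 25, len(labels))
        y = np.array([
            scheffe_terms(to_pseudo(a, spec), degree) @ truth for a in amounts
        ])
        df = pd.DataFrame(amounts, columns=list(spec.components))
        df["y"] = y
        res = ScheffeMixture(DesignTable(df, spec), "y", degree=degree).fit()
        np.testing.assert_allclose(res.params.to_numpy(), truth, atol=1e-8)
        assert res.stats.r2 == pytest.approx(1.0)
        assert res.stats.root_mse == pytest.approx(0.0, abs=1e-8)

    def test_matches_normal_equations_oracle(self, fixtures):
        """lstsq solution equals the brute-force (X'X)^-1 X'y solve."""
        for resp in ("total_flavonoid", "ph", "whc"):
            res = ScheffeMixture(fixtures.design, resp).fit()
            X = res.model_obj.exog
            y = res.model_obj.endog
            oracle = np.linalg.solve(X.T @ X, X.T @ y)
            np.testing.assert_allclose(res.params.to_numpy(), oracle, atol=1e-8)

    def test_flavonoid_refit_matches_published_scale(self, fixtures):
        """Refitting TFC reproduces the published grand mean and residual SD."""
        res = ScheffeMixture(fixtures.design, "total_flavonoid").fit()
        assert res.stats.grand_mean == pytest.approx(15.39, rel=0.05)
        assert res.stats.root_mse == pytest.approx(0.31, rel=0.05)
        assert res.stats.r2 >= 0.98

    def test_constant_response_degenerates_gracefully(self, fixtures, spec):
        df = pd.DataFrame(fixtures.design.amounts(), columns=list(spec.components))
        df["flat"] = 4.2
        with pytest.warns(UserWarning, match="constant"):
            res = ScheffeMixture(DesignTable(df, spec), "flat").fit()
        # a+b+c=1 makes (kappa, kappa, kappa, 0...) the minimum-norm solution
        np.testing.assert_allclose(res.params.to_numpy()[:3], 4.2, atol=1e-6)
        assert res.stats.r2 == 0.0

    def test_run_order_permutation_invariance(self, fixtures, spec, rng):
        df = fixtures.design.data
        perm = df.sample(frac=1.0, random_state=7).reset_index(drop=True)
        a = ScheffeMixture(DesignTable(df, spec), "dpph").fit().stats
        b = ScheffeMixture(DesignTable(perm, spec), "dpph").fit().stats
        for field in ("r2", "adjusted_r2", "predicted_r2", "cv_percent",
                      "adequate_precision", "model_f", "grand_mean", "root_mse"):
            assert getattr(a, field) == pytest.approx(getattr(b, field), rel=1e-9)

    def test_cv_identity_and_r2_ordering(self, fixtures):
        for resp in fixtures.design.response_names:
            s = ScheffeMixture(fixtures.design, resp).fit().stats
            assert s.cv_percent == pytest.approx(
                100 * s.root_mse / s.grand_mean, abs=1e-9
            )
            assert s.adjusted_r2 <= s.r2
            assert 0 <= s.r2 <= 1

    def test_too_few_runs(self, fixtures, spec):
        df = fixtures.design.data.iloc[:5]
        with pytest.raises(SizeError):
            ScheffeMixture(DesignTable(df, spec), "ph").fit()

    def test_rank_deficiency_names_terms(self, spec):
        # 7 identical rows at one vertex: wildly collinear
        df = pd.DataFrame([[9.5, 60.0, 15.0]] * 8, columns=list(spec.components))
        df["y"] = 1.0
        with pytest.raises(SingularityError, match="collinear"):
            ScheffeMixture(DesignTable(df, spec), "y").fit()

    def test_lack_of_fit_reported_with_replicates(self, fixtures):
        """The 17-run design has replicated runs, so pure error is available."""
        s = ScheffeMixture(fixtures.design, "overall_acceptability").fit().stats
        assert s.pure_error_df > 0
        assert s.lack_of_fit_f is None or s.lack_of_fit_f >= 0


class TestPrediction:
    def test_vertex_returns_first_coefficient(self, fixtures):
        m = fixtures.scheffe_models["total_flavonoid"]
        assert mixkin.predict_response(m, [1, 0, 0]) == pytest.approx(23.43)

    def test_term_count_mismatch(self, fixtures):
        from mixkin.errors import ModelError

        m = fixtures.scheffe_models["ph"]
        with pytest.raises(ModelError):
            mixkin.predict_response(m, [1, 0, 0, 0])


class TestDOptimal:
    def test_three_vertices_unique_choice(self):
        sel = d_optimal_select(np.eye(3), 3, "linear")
        assert sorted(sel) == [0, 1, 2]

    def test_full_rank_on_constrained_grid(self):
        g = [(a, b, 1 - a - b)
             for a in np.linspace(0, 1, 9)
             for b in np.linspace(0, 1, 9) if a + b <= 1 + 1e-12]
        g = np.array([(a, b, max(c, 0.0)) for a, b, c in g])
        sel = d_optimal_select(g, 17, "special_cubic", seed=11)
        X = _design_matrix(g[sel], "special_cubic")
        assert np.linalg.matrix_rank(X) == 7

    def test_beats_random_subsets(self, rng):
        g = np.array([(a, b, 1 - a - b)
                      for a in np.linspace(0, 1, 8)
                      for b in np.linspace(0, 1 - a, 8)])
        sel = d_optimal_select(g, 10, "special_cubic", seed=5)
        X = _design_matrix(g[sel], "special_cubic")
        best = np.linalg.slogdet(X.T @ X)[1]
        for _ in range(20):
            idx = rng.choice(len(g), 10, replace=False)
            Xr = _design_matrix(g[idx], "special_cubic")
            sign, ld = np.linalg.slogdet(Xr.T @ Xr)
            assert sign <= 0 or ld <= best + 1e-9

    def test_deterministic_under_seed(self):
        g = np.array([(a, b, 1 - a - b)
                      for a in np.linspace(0, 1, 7)
                      for b in np.linspace(0, 1 - a, 7)])
        a = d_optimal_select(g, 9, "special_cubic", seed=42)
        b = d_optimal_select(g, 9, "special_cubic", seed=42)
        np.testing.assert_array_equal(a, b)

    def test_infeasible_n_runs(self):
        with pytest.raises(SizeError):
            d_optimal_select(np.eye(3), 2, "special_cubic")


class TestSpecValidation:
    def test_degenerate_region_rejected(self):
        with pytest.raises(ValidationError):
            MixtureDesignSpec(("a", "b"), (50.0, 50.0), (60.0, 60.0), 100.0)

    def test_design_table_rejects_off_total_run(self, spec):
        df = pd.DataFrame([[9.5, 60.0, 15.5]], columns=list(spec.components))
        with pytest.raises(BoundsError):
            DesignTable(df, spec)

    def test_fixture_runs_all_sum_to_total(self, fixtures, spec):
        sums = fixtures.design.amounts().sum(axis=1)
        np.testing.assert_allclose(sums, spec.total, atol=1e-6)


@settings(max_examples=50, deadline=None)
@given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
def test_pseudo_round_trip_property(u, v):
    """Barycentric round trip holds across the whole simplex."""
    spec = mixkin.datasets.lassi_spec()
    # fold (u, v) onto the simplex
    a, b = (u, v) if u + v <= 1 else (1 - u, 1 - v)
    p = np.array([a, b, 1 - a - b])
    x = from_pseudo(p, spec)
    np.testing.assert_allclose(to_pseudo(x, spec), p, atol=1e-9)
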