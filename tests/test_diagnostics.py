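"""Information functions, item fit, reliability, culling, balanced selection."""

import numpy as np
import pandas as pd
import pytest

from emometrics.data import GradedMatrix, MISSING
from emometrics.diagnostics import (
    BalancedSelection,
    CullThresholds,
    ItemDiagnostics,
    chisq_df_ratio,
    compare_tifs,
    compute_diagnostics,
    cronbach_alpha,
    cull_items,
    item_fit_chisq,
    item_information,
    mcdonald_omega,
    reliability,
    scalar_item_information,
    select_balanced_final,
    test_information as total_information,
    tif_area,
)
from emometrics.grm import (
    FitControls,
    GRMFit,
    GRMItemParams,
    boundary_prob,
    category_probs,
    default_quadrature,
    fit_grm,
    loading_from_a,
)
from emometrics import simulate as sim


def _fit_of(items, quad=None):
    quad = quad or default_quadrature()
    return GRMFit(
        items=items,
        loadings=np.array([loading_from_a(it.a) for it in items]),
        loglik_trace=[0.0],
        converged=True,
        quadrature=quad,
        n_respondents=0,
    )


class TestItemInformation:
    def test_two_category_closed_form(self):
        # I(theta) = a^2 P (1-P); at theta = b, P = 1/2 -> a^2/4 = 1 for a=2
        p = GRMItemParams("d", 2.0, np.array([0.7]), 2)
        assert item_information(0.7, p) == pytest.approx(1.0, abs=1e-12)
        for th in (-1.0, 0.3, 2.2):
            P = boundary_prob(th, 2.0, 0.7)
            assert item_information(th, p) == pytest.approx(4 * P * (1 - P), rel=1e-10)

    def test_nonnegative_everywhere(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            m = rng.integers(2, 5)
            b = np.sort(rng.uniform(-3, 3, size=m - 1))
            b += np.arange(m - 1) * 1e-3
            p = GRMItemParams("r", rng.uniform(0.2, 4), b, m)
            th = rng.uniform(-5, 5, size=5)
            assert np.all(item_information(th, p) >= 0)

    def test_matches_finite_difference_definition(self, item3):
        # I = Sum_k (P_k')^2 / P_k with P_k' from central differences
        h = 1e-6
        for th in (-1.5, 0.0, 0.8):
            P = category_probs(th, item3)
            dP = (category_probs(th + h, item3) - category_probs(th - h, item3)) / (2 * h)
            assert item_information(th, item3) == pytest.approx(
                float((dP**2 / P).sum()), abs=1e-6
            )


class TestScalarInformation:
    def test_uninformative_item_scores_zero(self, quad):
        p = GRMItemParams("z", 1e-8, np.array([0.0]), 2)
        assert scalar_item_information(p, quad) < 1e-10

    def test_monotone_in_discrimination(self, quad):
        vals = [
            scalar_item_information(GRMItemParams("g", a, np.array([-0.5, 0.5]), 3), quad)
            for a in np.linspace(0.3, 3.0, 10)
        ]
        assert np.all(np.diff(vals) > 0)

    def test_identical_items_identical_scalars(self, quad, item3):
        twin = GRMItemParams("y", item3.a, item3.b.copy(), item3.m)
        assert scalar_item_information(item3, quad) == scalar_item_information(twin, quad)


class TestTestInformation:
    def test_additivity_pointwise(self, quad):
        items = sim.simulate_item_params(4, 3, seed=55)
        fit = _fit_of(items, quad)
        grid = np.linspace(-3, 3, 13)
        total = total_information(grid, fit)
        summed = sum(item_information(grid, it) for it in items)
        np.testing.assert_allclose(total, summed, rtol=1e-12)
        # the TIF pointwise dominates every single item's curve
        best_single = np.max([item_information(grid, it) for it in items], axis=0)
        assert np.all(total >= best_single - 1e-12)

    def test_duplicated_item_set_doubles(self, quad, item3):
        single = _fit_of([item3], quad)
        double = _fit_of([item3, item3], quad)
        grid = np.linspace(-3, 3, 7)
        np.testing.assert_allclose(
            total_information(grid, double), 2 * total_information(grid, single)
        )


class TestTIFArea:
    def test_rectangle_oracle_via_flat_duplication(self, quad):
        # a near-flat TIF: area over [-3, 3] approximates width * height
        p = GRMItemParams("f", 0.01, np.array([0.0]), 2)
        fit = _fit_of([p], quad)
        height = total_information(0.0, fit)
        assert tif_area(fit) == pytest.approx(6 * height, rel=1e-3)

    def test_grid_refinement_converges(self, fitted_toy):
        _, _, fit = fitted_toy
        a1 = tif_area(fit, grid_size=301)
        a2 = tif_area(fit, grid_size=601)
        assert abs(a1 - a2) < 1e-3

    def test_agrees_with_adaptive_quadrature(self, fitted_toy):
        from scipy.integrate import quad as adaptive_quad

        _, _, fit = fitted_toy
        oracle, _ = adaptive_quad(lambda t: total_information(t, fit), -3, 3, limit=200)
        assert tif_area(fit, grid_size=2001) == pytest.approx(oracle, abs=1e-3)


class TestCompareTIFs:
    def test_identical_fits_degenerate(self, fitted_toy):
        _, _, fit = fitted_toy
        res = compare_tifs(fit, fit)
        assert res.degenerate and res.t is None

    def test_default_grid_gives_df_59(self, fitted_toy, quad):
        _, _, fit = fitted_toy
        other = _fit_of(sim.simulate_item_params(5, 3, seed=77), quad)
        res = compare_tifs(fit, other)
        assert res.df == 59

    def test_d_matches_independent_two_pass_computation(self, quad, fitted_toy):
        _, _, fit_a = fitted_toy
        fit_b = _fit_of(sim.simulate_item_params(5, 3, seed=78), quad)
        res = compare_tifs(fit_a, fit_b, grid_size=60)
        grid = np.linspace(-3, 3, 60)
        diff = [total_information(t, fit_a) - total_information(t, fit_b) for t in grid]
        mean = sum(diff) / len(diff)
        sd = (sum((d - mean) ** 2 for d in diff) / (len(diff) - 1)) ** 0.5
        assert res.cohens_d == pytest.approx(mean / sd, rel=1e-12)
        assert res.t == pytest.approx(mean / (sd / np.sqrt(60)), rel=1e-12)


class TestChisqRatio:
    @pytest.mark.parametrize(
        "chisq,df,ratio,verdict",
        [
            (160.27, 141, 1.14, "adequate"),
            (153.81, 76, 2.02, "adequate"),
            (300.0, 100, 3.00, "poor"),  # boundary is inclusive for poor fit
        ],
    )
    def test_table_cells(self, chisq, df, ratio, verdict):
        r, v = chisq_df_ratio(chisq, df)
        assert round(r, 2) == ratio
        assert v == verdict

    def test_df_floor(self):
        with pytest.raises(ValueError):
            chisq_df_ratio(10.0, 0)


class TestItemFit:
    def test_model_true_data_not_rejected_wholesale(self, fitted_toy):
        _, matrix, fit = fitted_toy
        rejections = 0
        for iid in fit.item_ids:
            chisq, df, p = item_fit_chisq(matrix, fit, iid)
            assert df >= 1 and 0 <= p <= 1
            rejections += p < 0.05
        assert rejections <= 3  # ~5% expected among 10 model-true items

    def test_gross_misspecification_detected(self, quad):
        # simulate from a steep item but evaluate fit under a flat one
        items = sim.simulate_item_params(4, 3, seed=91)
        steep = GRMItemParams(items[0].item_id, 3.5, items[0].b, 3)
        rng = np.random.default_rng(14)
        theta = rng.normal(size=1500)
        matrix = sim.simulate_graded_responses(
            theta, [steep] + items[1:], np.ones((1500, 4), bool), 15
        )
        flat = GRMItemParams(items[0].item_id, 0.4, items[0].b, 3)
        fit = _fit_of([flat] + items[1:], quad)
        _, _, p_bad = item_fit_chisq(matrix, fit, items[0].item_id)
        assert p_bad < 1e-4

    def test_insufficient_data_is_reported(self, fitted_toy):
        _, matrix, fit = fitted_toy
        tiny = matrix.subset_participants(np.arange(matrix.n_participants) < 10)
        with pytest.raises(ValueError):
            item_fit_chisq(tiny, fit, fit.item_ids[0])


class TestReliability:
    def test_alpha_closed_form_construction(self):
        # 3 items, unit variances, pairwise covariances 0.5 -> alpha = 0.75
        cov = np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.5], [0.5, 0.5, 1.0]])
        rng = np.random.default_rng(3)
        X = rng.multivariate_normal(np.zeros(3), cov, size=200_000)
        k = 3
        sample_cov = np.cov(X, rowvar=False)
        alpha = k / (k - 1) * (1 - np.trace(sample_cov) / sample_cov.sum())
        assert alpha == pytest.approx(0.75, abs=0.01)
        # the implementation applies the same formula to a graded matrix
        scores = (X > 0).astype(int)
        m = GradedMatrix(
            [f"p{i}" for i in range(len(scores))], ["a", "b", "c"], scores, np.array([2, 2, 2])
        )
        got = cronbach_alpha(m)
        binary_cov = np.cov(scores, rowvar=False)
        expected = k / (k - 1) * (1 - np.trace(binary_cov) / binary_cov.sum())
        assert got == pytest.approx(expected, abs=1e-9)

    def test_independent_items_alpha_zero(self):
        rng = np.random.default_rng(4)
        scores = rng.integers(0, 3, size=(50_000, 4))
        m = GradedMatrix(
            [f"p{i}" for i in range(len(scores))], list("abcd"), scores, np.full(4, 3)
        )
        assert cronbach_alpha(m) == pytest.approx(0.0, abs=0.02)

    def test_duplicated_item_alpha_one(self):
        rng = np.random.default_rng(5)
        col = rng.integers(0, 3, size=(500, 1))
        m = GradedMatrix(
            [f"p{i}" for i in range(500)], list("abc"), np.hstack([col] * 3), np.full(3, 3)
        )
        assert cronbach_alpha(m) == pytest.approx(1.0, abs=1e-12)

    def test_omega_closed_form(self):
        # ten loadings of 0.5: (5)^2 / (25 + 10 * 0.75) = 25/32.5
        assert mcdonald_omega([0.5] * 10) == pytest.approx(25 / 32.5, abs=1e-12)

    def test_omega_limits_and_invariance(self):
        assert mcdonald_omega([0.999] * 5) > 0.99
        rng = np.random.default_rng(6)
        lams = rng.uniform(0.2, 0.8, size=8)
        assert mcdonald_omega(lams) == mcdonald_omega(lams[::-1])

    def test_alpha_le_omega_congeneric(self, quad):
        # unequal loadings: alpha underestimates, omega targets, reliability
        rng = np.random.default_rng(7)
        lams = np.array([0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
        theta = rng.normal(size=20_000)
        X = lams * theta[:, None] + np.sqrt(1 - lams**2) * rng.normal(size=(20_000, 6))
        scores = (X > 0).astype(int) + (X > 1).astype(int)
        m = GradedMatrix(
            [f"p{i}" for i in range(len(scores))],
            [f"i{j}" for j in range(6)], scores, np.full(6, 3),
        )
        assert cronbach_alpha(m) <= mcdonald_omega(lams) + 0.02


class TestCulling:
    def _diag(self, item_id, info, loading, p):
        return ItemDiagnostics(
            item_id=item_id, scalar_information=info, loading=loading,
            fit_chisq=10.0, fit_df=10, fit_p=p, chisq_df_ratio=1.0,
        )

    def test_two_flags_cull_one_flag_retains(self):
        diags = [
            self._diag("keep_misfit_only", info=1.0, loading=0.5, p=0.001),
            self._diag("cull_low_load_low_info", info=0.1, loading=0.25, p=0.5),
            self._diag("anchor_high", info=1.5, loading=0.6, p=0.5),
        ]
        res = cull_items(diags)
        assert "keep_misfit_only" in res.retained
        assert "cull_low_load_low_info" in res.culled
        assert set(res.reasons["cull_low_load_low_info"]) == {"low_loading", "low_information"}

    def test_any_rule_is_stricter(self):
        diags = [
            self._diag("misfit_only", info=1.5, loading=0.5, p=0.001),
            self._diag("clean", info=1.0, loading=0.6, p=0.5),
        ]
        assert "misfit_only" in cull_items(diags, rule="any").culled
        assert "misfit_only" in cull_items(diags, rule="two_of_three").retained

    def test_idempotent_with_frozen_reference(self):
        diags = [
            self._diag("a", 0.2, 0.25, 0.01),
            self._diag("b", 0.8, 0.5, 0.5),
            self._diag("c", 1.2, 0.6, 0.5),
        ]
        first = cull_items(diags)
        frozen = CullThresholds(info_reference=first.info_reference)
        survivors = [d for d in diags if d.item_id in first.retained]
        second = cull_items(survivors, frozen)
        assert second.retained == first.retained
        assert second.culled == []


class TestBalancedSelection:
    def _candidates(self):
        rows = []
        rng = np.random.default_rng(12)
        cells = [
            ("positive_high", g, r)
            for g in ("men", "women") for r in ("asian", "black")
        ]
        for i in range(20):
            cell = cells[i % 4]
            rows.append(
                {
                    "item_id": f"i{i:02d}", "scalar_information": float(rng.uniform(0.1, 2)),
                    "valence_activation": cell[0], "actor_gender": cell[1], "actor_race": cell[2],
                }
            )
        return pd.DataFrame(rows).set_index("item_id")

    def test_forced_single_candidates(self):
        df = self._candidates().iloc[:4]
        quotas = {tuple(r): 1 for r in df[["valence_activation", "actor_gender", "actor_race"]].to_numpy()}
        res = select_balanced_final(df, quotas, n_final=4)
        assert sorted(res.selected) == sorted(df.index)
        assert res.unmet_quotas == {}

    def test_no_quotas_returns_top_k_by_information(self):
        df = self._candidates()
        res = select_balanced_final(df, None, n_final=5)
        top5 = df.sort_values("scalar_information", ascending=False).index[:5]
        assert set(res.selected) == set(top5)

    def test_quotas_satisfied_verified_exhaustively(self):
        df = self._candidates()
        quotas = {
            ("positive_high", "men", "asian"): 2,
            ("positive_high", "women", "black"): 2,
        }
        res = select_balanced_final(df, dict(quotas), n_final=8)
        assert len(res.selected) == 8
        assert res.unmet_quotas == {}
        chosen = df.loc[res.selected]
        for cell, need in quotas.items():
            got = (
                (chosen["valence_activation"] == cell[0])
                & (chosen["actor_gender"] == cell[1])
                & (chosen["actor_race"] == cell[2])
            ).sum()
            assert got >= need

    def test_infeasible_quota_reported(self):
        df = self._candidates()
        quotas = {("neutral", "men", "asian"): 1}  # no such candidates
        res = select_balanced_final(df, quotas, n_final=3)
        assert res.unmet_quotas == {("neutral", "men", "asian"): 1}
        assert len(res.selected) == 3


def test_reliability_report_same_item_set(fitted_toy):
    _, matrix, fit = fitted_toy
    rep = reliability(matrix, fit)
    assert rep.n_items == matrix.n_items
    assert 0 < rep.alpha <= 1 and 0 < rep.omega < 1


def test_diagnostics_table_complete(fitted_toy):
    _, matrix, fit = fitted_toy
    diags = compute_diagnostics(matrix, fit)
    assert len(diags) == matrix.n_items
    for d in diags:
        assert d.scalar_information > 0
        assert 0 < d.loading < 1
        assert d.chisq_df_ratio == pytest.approx(d.fit_chisq / d.fit_df)
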