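"""Synthetic-control design, simplex weight optimization and ATT."""

import numpy as np
import pytest

from panelcf import (
    SyntheticControl,
    build_design,
    choose_v,
    fit_synth,
    generate_panel,
    scenario_presets,
    solve_weights,
)
from panelcf.synth import SynthDesign, _mspe

from .conftest import make_panel


def random_design(rng, K=4, n_controls=6):
    """Generic standardized design with no exact ties."""
    x0 = rng.standard_normal((K, n_controls))
    x1 = rng.standard_normal(K)
    T0 = K  # treat all predictors as outcome rows for simplicity
    return SynthDesign(
        x1=x1, x0=x0, scale=np.ones(K),
        outcome_mask=np.ones(K, bool),
        predictor_names=tuple(f"p{i}" for i in range(K)),
        control_units=np.array([f"c{j}" for j in range(n_controls)]),
        y_treated_path=np.concatenate([x1, [0.0]]),
        y_controls=np.vstack([x0, np.zeros(n_controls)]).T,
        T0=T0,
    )


def grid_min_objective(design, V, step=0.005):
    """Brute-force oracle: dense grid over the 3-control simplex."""
    assert design.n_controls == 3
    w1 = np.arange(0.0, 1.0 + step / 2, step)
    grid = [
        np.array([a, b, 1.0 - a - b])
        for a in w1
        for b in np.arange(0.0, 1.0 - a + step / 2, step)
    ]
    W = np.array(grid)
    sv = np.sqrt(V)
    R = (design.x0 * sv[:, None]) @ W.T - (design.x1 * sv)[:, None]
    return float((R**2).sum(axis=0).min())


class TestBuildDesign:
    def test_single_treated_unit_is_own_predictors(self):
        y = np.array([[1.0, 2, 9], [0, 1, 2], [3, 2, 1]])
        panel = make_panel(y, [True, False, False], T0=2)
        design = build_design(panel)
        np.testing.assert_allclose(design.x1 * design.scale, [1.0, 2.0])

    def test_equal_weight_treated_pair_averages_to_midpoint(self):
        y = np.array([[1.0, 2, 9], [3, 6, 9], [0, 1, 2], [3, 2, 1]])
        panel = make_panel(y, [True, True, False, False], T0=2)
        design = build_design(panel)
        np.testing.assert_allclose(design.x1 * design.scale, [2.0, 4.0])

    def test_admission_weighted_treated_aggregate_hand_checked(self):
        # treated weights 1 and 3 per period: aggregate = (1*a + 3*b) / 4
        y = np.array([[4.0, 8, 0], [0, 4, 0], [1, 1, 1]])
        w = np.array([[1.0, 1, 1], [3, 3, 3], [1, 1, 1]])
        panel = make_panel(y, [True, True, False], T0=2, weights=w)
        design = build_design(panel)
        np.testing.assert_allclose(design.x1 * design.scale, [1.0, 5.0])

    def test_predictor_count_is_T0_plus_p(self):
        panel, _ = generate_panel(scenario_presets("A", 5), 1)
        design = build_design(panel)
        assert design.n_predictors == panel.T0 + panel.n_covariates


class TestSolveWeights:
    def test_identical_control_gets_full_weight(self):
        rng = np.random.default_rng(0)
        design = random_design(rng, K=3, n_controls=4)
        design = SynthDesign(
            x1=design.x0[:, 2].copy(), x0=design.x0, scale=design.scale,
            outcome_mask=design.outcome_mask,
            predictor_names=design.predictor_names,
            control_units=design.control_units,
            y_treated_path=design.y_treated_path,
            y_controls=design.y_controls, T0=design.T0,
        )
        w = solve_weights(design, np.ones(3))
        assert w[2] == pytest.approx(1.0, abs=1e-6)
        r = design.x0 @ w - design.x1
        assert r @ r < 1e-10

    def test_midpoint_between_two_controls_splits_evenly(self):
        x0 = np.array([[0.0, 2.0, 50.0], [0.0, 2.0, 80.0]])
        x1 = np.array([1.0, 1.0])
        design = SynthDesign(
            x1=x1, x0=x0, scale=np.ones(2), outcome_mask=np.ones(2, bool),
            predictor_names=("p0", "p1"),
            control_units=np.array(["c0", "c1", "c2"]),
            y_treated_path=np.array([1.0, 1.0, 0.0]),
            y_controls=np.vstack([x0, np.zeros(3)]).T, T0=2,
        )
        w = solve_weights(design, np.ones(2))
        np.testing.assert_allclose(w, [0.5, 0.5, 0.0], atol=1e-7)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_objective_matches_simplex_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        design = random_design(rng, K=4, n_controls=3)
        V = rng.uniform(0.2, 1.0, 4)
        w = solve_weights(design, V)
        sv = np.sqrt(V)
        ours = float((((design.x0 * sv[:, None]) @ w - design.x1 * sv) ** 2).sum())
        oracle = grid_min_objective(design, V)
        assert ours <= oracle + 1e-12        # grid can never beat the optimum
        assert oracle - ours <= 1e-4         # and must agree to grid resolution

    @pytest.mark.parametrize("seed", range(6, 14))
    def test_simplex_and_vertex_necessary_condition(self, seed):
        rng = np.random.default_rng(seed)
        design = random_design(rng, K=5, n_controls=8)
        V = rng.uniform(0.1, 1.0, 5)
        w = solve_weights(design, V)
        assert np.all(w >= -1e-12) and np.all(w <= 1 + 1e-12)
        assert w.sum() == pytest.approx(1.0, abs=1e-8)
        sv = np.sqrt(V)
        A = design.x0 * sv[:, None]
        b = design.x1 * sv
        obj = ((A @ w - b) ** 2).sum()
        vertex_best = (((A - b[:, None]) ** 2).sum(axis=0)).min()
        assert obj <= vertex_best + 1e-8

    def test_sparsity_support_bounded_by_predictors(self):
        rng = np.random.default_rng(21)
        design = random_design(rng, K=4, n_controls=40)
        w = solve_weights(design, np.ones(4))
        assert (w > 1e-6).sum() <= 5  # K + 1

    def test_all_zero_v_rejected(self):
        design = random_design(np.random.default_rng(1), K=3, n_controls=4)
        with pytest.raises(ValueError):
            solve_weights(design, np.zeros(3))


class TestChooseV:
    def test_single_predictor_is_trivial(self):
        y = np.array([[1.0, 9], [0, 2], [3, 1]])
        panel = make_panel(y, [True, False, False], T0=1)
        np.testing.assert_array_equal(choose_v(panel), [1.0])

    @pytest.mark.parametrize("seed", [31, 32, 33])
    def test_nested_mspe_never_worse_than_equal(self, seed):
        cfg = scenario_presets("B", 4).replace(n_units=20, n_treated=8)
        panel, _ = generate_panel(cfg, seed)
        design = build_design(panel)
        v_eq = choose_v(design, mode="equal")
        v_nested = choose_v(design, mode="nested", maxiter=40)
        mspe_eq = _mspe(design, solve_weights(design, v_eq))
        mspe_nested = _mspe(design, solve_weights(design, v_nested))
        assert mspe_nested <= mspe_eq + 1e-10

    def test_outcome_priority_mass_share(self):
        panel, _ = generate_panel(scenario_presets("A", 4), 1)
        design = build_design(panel)
        v = choose_v(design, mode="outcome-priority", outcome_share=0.8)
        assert v[design.outcome_mask].sum() == pytest.approx(0.8)
        assert v.sum() == pytest.approx(1.0)


class TestFitSynth:
    def test_duplicating_control_recovers_added_effect(self):
        # one control replicates the treated average pre AND post; tau added post
        tau = 7.0
        base = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.vstack([
            base + tau * np.array([0, 0, 0, 1.0]),  # treated
            base,                                    # perfect control
            base + 5.0,
            base - 3.0,
        ])
        panel = make_panel(y, [True, False, False, False], T0=3)
        res = fit_synth(panel, v_mode="equal")
        assert res.att == pytest.approx(tau, abs=1e-6)
        assert res.fit_diagnostics.pre_mspe < 1e-12

    def test_convex_hull_reconstruction_gives_zero_att(self):
        # treated average is the midpoint of two controls in every period
        c1 = np.array([0.0, 1.0, 2.0, 3.0])
        c2 = np.array([4.0, 3.0, 6.0, 5.0])
        y = np.vstack([(c1 + c2) / 2, c1, c2, c2 + 40.0])
        panel = make_panel(y, [True, False, False, False], T0=3)
        res = fit_synth(panel, v_mode="equal")
        assert res.att == pytest.approx(0.0, abs=1e-6)

    def test_invariant_to_control_relabeling(self):
        cfg = scenario_presets("B", 4).replace(n_units=16, n_treated=6)
        panel, _ = generate_panel(cfg, 41)
        res = fit_synth(panel, v_mode="equal")
        perm = np.concatenate([
            np.arange(6), 6 + np.random.default_rng(0).permutation(10)
        ])
        shuffled = make_panel(
            panel.y[perm], panel.treated[perm], panel.T0, X=panel.X[perm],
            covariate_names=panel.covariate_names,
        )
        res2 = fit_synth(shuffled, v_mode="equal")
        assert res2.att == pytest.approx(res.att, abs=1e-6)
        # weight multiset is preserved under relabeling
        assert sorted(res.weights.values()) == pytest.approx(
            sorted(res2.weights.values()), abs=1e-6
        )

    def test_invariant_to_covariate_rescaling(self):
        cfg = scenario_presets("B", 4).replace(n_units=16, n_treated=6)
        panel, _ = generate_panel(cfg, 43)
        res = fit_synth(panel, v_mode="equal")
        X = panel.X.copy()
        X[:, :, 0] = X[:, :, 0] * 100.0 - 7.0
        rescaled = make_panel(
            panel.y, panel.treated, panel.T0, X=X,
            covariate_names=panel.covariate_names,
        )
        res2 = fit_synth(rescaled, v_mode="equal")
        assert res2.att == pytest.approx(res.att, abs=1e-6)

    def test_results_expose_simplex_weights(self):
        panel, _ = generate_panel(
            scenario_presets("A", 3).replace(n_units=12, n_treated=5), 47
        )
        res = SyntheticControl(panel, v_mode="outcome-priority").fit()
        w = np.array(list(res.weights.values()))
        assert w.sum() == pytest.approx(1.0, abs=1e-8)
        assert res.se is None and len(res.weights) == panel.n_control
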