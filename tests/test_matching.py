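"""Weighted-Mahalanobis matching, balance scoring and the evolutionary search."""

import itertools

import numpy as np
import pytest

from panelcf import (
    GeneticMatchingDiD,
    MatchSpec,
    balance_loss,
    fit_did,
    fit_match_did,
    generate_panel,
    genetic_search,
    scenario_presets,
    weighted_mahalanobis,
)
from panelcf.matching import _inv_sqrt

from .conftest import make_panel


def duplicate_panel(tau=0.0, rng_seed=8, n_decoys=2):
    """4 treated units whose controls 0-3 are exact pre/post duplicates,
    plus far-away decoy controls; optional post-period effect on treated."""
    rng = np.random.default_rng(rng_seed)
    yt = rng.normal(1.0, 1.0, (4, 3))
    decoys = rng.normal(4.0, 0.5, (n_decoys, 3))
    y = np.vstack([yt, yt.copy(), decoys])
    y[:4, 2] += tau
    return make_panel(y, [True] * 4 + [False] * (4 + n_decoys), T0=2)


class TestWeightedMahalanobis:
    def test_zero_for_identical_vectors(self):
        u = np.array([1.0, 2.0, 3.0])
        assert weighted_mahalanobis(u, u, np.eye(3), np.ones(3)) == 0.0

    def test_identity_metric_is_euclidean(self):
        u, v = np.array([1.0, 4.0]), np.array([4.0, 0.0])
        assert weighted_mahalanobis(u, v, np.eye(2), np.ones(2)) == pytest.approx(5.0)

    def test_random_case_against_dense_oracle(self):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((3, 3))
        S = A @ A.T + 0.5 * np.eye(3)
        u, v = rng.standard_normal(3), rng.standard_normal(3)
        M = rng.uniform(0.2, 2.0, 3)
        # oracle: explicit matrix product d' S^-1/2' M S^-1/2 d
        vals, vecs = np.linalg.eigh(S)
        Si = vecs @ np.diag(vals**-0.5) @ vecs.T
        z = Si @ (u - v)
        expected = np.sqrt(z @ np.diag(M) @ z)
        assert weighted_mahalanobis(u, v, S, M) == pytest.approx(expected, abs=1e-12)

    def test_singular_covariance_collapsed_with_warning(self):
        S = np.outer([1.0, 1.0], [1.0, 1.0])  # rank 1
        with pytest.warns(UserWarning, match="singular"):
            d = weighted_mahalanobis([1.0, 0.0], [0.0, 1.0], S, np.ones(2))
        assert np.isfinite(d)

    def test_negative_metric_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_mahalanobis([0.0], [1.0], np.eye(1), np.array([-1.0]))


class TestBalanceLoss:
    def test_identical_matched_controls_are_optimal(self):
        panel = duplicate_panel()
        key = balance_loss(panel, np.arange(4))
        assert np.allclose(key, 1.0)

    def test_variable_order_leaves_sorted_loss_unchanged(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal((8, 4))
        X = rng.standard_normal((8, 4, 2))
        p1 = make_panel(y, [True] * 3 + [False] * 5, T0=3, X=X,
                        covariate_names=("a", "b"))
        p2 = make_panel(y, [True] * 3 + [False] * 5, T0=3, X=X[:, :, ::-1],
                        covariate_names=("b", "a"))
        idx = np.array([0, 1, 2])
        assert balance_loss(p1, idx, outcome_priority=False) == pytest.approx(
            balance_loss(p2, idx, outcome_priority=False)
        )

    def test_five_unit_enumeration_identifies_duplicates(self):
        # 2 treated x 3 controls: all 9 assignments enumerated; the
        # duplicate-matching assignment is the lexicographic optimum
        rng = np.random.default_rng(9)
        yt = rng.normal(0, 1, (2, 3))
        y = np.vstack([yt, yt.copy(), rng.normal(5, 1, (1, 3))])
        panel = make_panel(y, [True, True, False, False, False], T0=2)
        keys = {
            assign: balance_loss(panel, np.array(assign))
            for assign in itertools.product(range(3), repeat=2)
        }
        assert max(keys, key=keys.get) == (0, 1)


class TestGeneticSearch:
    def test_exact_duplicates_found_with_perfect_balance(self):
        panel = duplicate_panel()
        res = genetic_search(panel, MatchSpec(population=10, generations=3, seed=0))
        np.testing.assert_array_equal(res.match_idx, np.arange(4))
        assert np.allclose(res.loss_key, 1.0)

    def test_matches_exhaustive_enumeration_optimum(self):
        panel = duplicate_panel()
        best = max(
            (balance_loss(panel, np.array(a))
             for a in itertools.product(range(6), repeat=4)),
        )
        res = genetic_search(panel, MatchSpec(population=10, generations=3, seed=1))
        assert tuple(res.loss_key) == pytest.approx(tuple(best))

    def test_never_worse_than_identity_metric_baseline(self):
        cfg = scenario_presets("B", 4).replace(n_units=20, n_treated=8)
        panel, _ = generate_panel(cfg, 51)
        spec = MatchSpec(population=12, generations=6, seed=3)
        res = genetic_search(panel, spec)
        from panelcf.matching import _balance_matrix

        B, _ = _balance_matrix(panel)
        Z = _inv_sqrt(np.cov(B, rowvar=False))
        Bt, Bc = B[panel.treated] @ Z.T, B[~panel.treated] @ Z.T
        d2 = ((Bt[:, None, :] - Bc[None, :, :]) ** 2).sum(axis=2)
        baseline = balance_loss(panel, np.argmin(d2, axis=1))
        assert tuple(res.loss_key) >= tuple(baseline)

    def test_elitism_trace_monotone(self):
        cfg = scenario_presets("B", 4).replace(n_units=20, n_treated=8)
        panel, _ = generate_panel(cfg, 53)
        res = genetic_search(panel, MatchSpec(population=8, generations=8, seed=5))
        for earlier, later in zip(res.trace, res.trace[1:]):
            assert tuple(later) >= tuple(earlier)

    def test_reproducible_under_fixed_seed(self):
        cfg = scenario_presets("A", 3).replace(n_units=16, n_treated=6)
        panel, _ = generate_panel(cfg, 57)
        spec = MatchSpec(population=10, generations=4, seed=11)
        a = genetic_search(panel, spec)
        b = genetic_search(panel, spec)
        np.testing.assert_array_equal(a.match_idx, b.match_idx)
        assert a.loss_key == b.loss_key

    def test_outcome_priority_at_least_identity_on_outcomes(self):
        cfg = scenario_presets("B", 4).replace(n_units=24, n_treated=8)
        panel, _ = generate_panel(cfg, 59)
        spec = MatchSpec(population=15, generations=8, seed=13, outcome_priority=True)
        res = genetic_search(panel, spec)
        from panelcf.matching import _balance_matrix

        B, n_out = _balance_matrix(panel)
        Z = _inv_sqrt(np.cov(B, rowvar=False))
        Bt, Bc = B[panel.treated] @ Z.T, B[~panel.treated] @ Z.T
        d2 = ((Bt[:, None, :] - Bc[None, :, :]) ** 2).sum(axis=2)
        base_key = balance_loss(panel, np.argmin(d2, axis=1), outcome_priority=True)
        # with priority on, the outcome block (key head) cannot regress
        n_head = 2 * n_out
        assert tuple(res.loss_key[:n_head]) >= tuple(base_key[:n_head])


class TestMatchedDiD:
    def test_duplicate_controls_recover_added_effect(self):
        panel = duplicate_panel(tau=6.0)
        res, match = fit_match_did(
            panel, MatchSpec(population=10, generations=3, seed=0)
        )
        assert res.att == pytest.approx(6.0, abs=1e-8)
        assert sum(match.multiplicity.values()) == panel.n_treated

    def test_equals_row_expansion_oracle(self):
        cfg = scenario_presets("B", 4).replace(n_units=18, n_treated=8)
        panel, _ = generate_panel(cfg, 61)
        spec = MatchSpec(population=10, generations=4, seed=7)
        res, match = fit_match_did(panel, spec)
        # oracle: physically replicate each matched control as its own unit
        ctrl = np.where(~panel.treated)[0]
        rows = list(np.where(panel.treated)[0])
        rows += [ctrl[j] for j in match.match_idx]
        y = panel.y[rows]
        X = panel.X[rows]
        treated = np.concatenate(
            [np.ones(panel.n_treated, bool), np.zeros(len(match.match_idx), bool)]
        )
        units = np.array([f"r{i}" for i in range(len(rows))])
        from panelcf import PanelDataset

        expanded = PanelDataset(
            units=units, y=y, treated=treated, T0=panel.T0, X=X,
            covariate_names=panel.covariate_names,
        )
        assert res.att == pytest.approx(fit_did(expanded).att, abs=1e-8)

    def test_control_order_invariance_up_to_tie_breaks(self):
        cfg = scenario_presets("A", 3).replace(n_units=14, n_treated=6)
        panel, _ = generate_panel(cfg, 63)
        spec = MatchSpec(population=12, generations=5, seed=17)
        res1 = GeneticMatchingDiD(panel, spec).fit()
        perm = np.concatenate(
            [np.arange(6), 6 + np.random.default_rng(1).permutation(8)]
        )
        shuffled = make_panel(
            panel.y[perm], panel.treated[perm], panel.T0, X=panel.X[perm],
            covariate_names=panel.covariate_names,
        )
        res2 = GeneticMatchingDiD(shuffled, spec).fit()
        assert res2.att == pytest.approx(res1.att, abs=1e-8)
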