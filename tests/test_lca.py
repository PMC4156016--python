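"""Tests for the latent class engine: likelihood, EM, fit statistics,
model selection, classification and label alignment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from engage.lca import (
    FitConfig,
    IndicatorSpec,
    LcaModel,
    align_classes,
    compute_fit_stats,
    engagement_spec,
    lca_fit,
    lca_log_likelihood,
    n_parameters,
    posterior_classify,
    select_model,
)
from engage.synthetic import simulate_profiles

BINARY2 = IndicatorSpec(items=("a", "b"), levels={"a": ("x", "y"), "b": ("x", "y")})

#: a well-separated two-class model over two binary items
SEP2 = LcaModel(
    gamma=np.array([0.6, 0.4]),
    rho={
        "a": np.array([[0.9, 0.1], [0.15, 0.85]]),
        "b": np.array([[0.85, 0.15], [0.1, 0.9]]),
    },
)


def brute_force_loglik(df, model, spec):
    """Independent oracle: explicit sum over classes and items per record."""
    total = 0.0
    for _, row in df.iterrows():
        p = 0.0
        for c in range(model.n_classes):
            term = model.gamma[c]
            for item in spec.items:
                k = spec.levels[item].index(row[item])
                term *= model.rho[item][c, k]
            p += term
        total += np.log(p)
    return total


class TestLogLikelihood:
    def test_one_class_closed_form_under_independence(self):
        df = pd.DataFrame({"a": ["x", "x", "y", "x"], "b": ["y", "x", "y", "y"]})
        marg_a = np.array([3 / 4, 1 / 4])
        marg_b = np.array([1 / 4, 3 / 4])
        model = LcaModel(gamma=np.array([1.0]),
                         rho={"a": marg_a[None, :], "b": marg_b[None, :]})
        expected = 3 * np.log(3 / 4) + np.log(1 / 4) + np.log(1 / 4) + 3 * np.log(3 / 4)
        assert lca_log_likelihood(df, model, BINARY2) == pytest.approx(expected)

    def test_matches_brute_force_enumeration_on_toy_model(self):
        df = pd.DataFrame({"a": ["x", "y", "y", "x"], "b": ["x", "x", "y", "y"]})
        assert lca_log_likelihood(df, SEP2, BINARY2) == pytest.approx(
            brute_force_loglik(df, SEP2, BINARY2)
        )

    def test_invariant_under_class_relabeling(self):
        df = pd.DataFrame({"a": ["x", "y", "y"], "b": ["x", "x", "y"]})
        swapped = SEP2.permute([1, 0])
        assert lca_log_likelihood(df, SEP2, BINARY2) == pytest.approx(
            lca_log_likelihood(df, swapped, BINARY2)
        )

    def test_dimension_mismatch_rejected(self):
        df = pd.DataFrame({"a": ["x"], "b": ["x"]})
        bad = LcaModel(gamma=np.array([1.0]), rho={"a": np.array([[0.5, 0.5]])})
        with pytest.raises(ValueError):
            lca_log_likelihood(df, bad, BINARY2)

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_oracle_equivalence_on_random_small_instances(self, data):
        rng_seed = data.draw(st.integers(0, 10_000))
        n_items = data.draw(st.integers(1, 3))
        n_levels = data.draw(st.integers(2, 3))
        K = data.draw(st.integers(1, 3))
        rng = np.random.default_rng(rng_seed)
        items = tuple(f"i{j}" for j in range(n_items))
        levels = {i: tuple(f"l{k}" for k in range(n_levels)) for i in items}
        spec = IndicatorSpec(items=items, levels=levels)
        model = LcaModel(
            gamma=rng.dirichlet(np.ones(K)),
            rho={i: rng.dirichlet(np.ones(n_levels), size=K) for i in items},
        )
        df = pd.DataFrame(
            {i: rng.choice(levels[i], size=8) for i in items}
        )
        assert lca_log_likelihood(df, model, spec) == pytest.approx(
            brute_force_loglik(df, model, spec)
        )


class TestFit:
    def test_one_class_model_is_observed_marginals(self):
        df = pd.DataFrame({"a": ["x"] * 6 + ["y"] * 2, "b": ["x", "y"] * 4})
        model = lca_fit(df, 1, BINARY2, FitConfig(n_starts=2, seed=0))
        assert model.gamma == pytest.approx([1.0])
        assert model.rho["a"][0] == pytest.approx([0.75, 0.25], abs=1e-9)
        assert model.rho["b"][0] == pytest.approx([0.5, 0.5], abs=1e-9)

    def test_recovers_well_separated_two_class_model(self, rng):
        # four binary items: 9 parameters against 15 free cells, identified
        spec = IndicatorSpec(
            items=tuple("abcd"), levels={i: ("x", "y") for i in "abcd"}
        )
        truth = LcaModel(
            gamma=np.array([0.6, 0.4]),
            rho={i: np.array([[0.9, 0.1], [0.15, 0.85]]) for i in "abcd"},
        )
        df, _ = simulate_profiles(spec, truth.gamma, truth.rho, 2000, rng)
        model = lca_fit(df, 2, spec, FitConfig(n_starts=10, seed=1))
        aligned = model.permute(align_classes(truth, model))
        assert np.abs(aligned.gamma - truth.gamma).max() <= 0.03
        for item in spec.items:
            assert np.abs(aligned.rho[item] - truth.rho[item]).max() <= 0.05

    def test_item_order_does_not_change_the_maximum(self, rng):
        df, _ = simulate_profiles(BINARY2, SEP2.gamma, SEP2.rho, 400, rng)
        reordered = IndicatorSpec(items=("b", "a"), levels=dict(BINARY2.levels))
        cfg = FitConfig(n_starts=8, seed=5)
        m1 = lca_fit(df, 2, BINARY2, cfg)
        m2 = lca_fit(df[["b", "a"]], 2, reordered, cfg)
        assert m1.log_likelihood == pytest.approx(m2.log_likelihood, abs=1e-5)

    def test_seed_determinism_is_bitwise(self, rng):
        df, _ = simulate_profiles(BINARY2, SEP2.gamma, SEP2.rho, 300, rng)
        cfg = FitConfig(n_starts=4, seed=77)
        m1 = lca_fit(df, 2, BINARY2, cfg)
        m2 = lca_fit(df, 2, BINARY2, cfg)
        assert np.array_equal(m1.gamma, m2.gamma)
        for item in BINARY2.items:
            assert np.array_equal(m1.rho[item], m2.rho[item])

    def test_fit_rejects_more_classes_than_rows(self):
        df = pd.DataFrame({"a": ["x", "y"], "b": ["x", "y"]})
        with pytest.raises(ValueError):
            lca_fit(df, 3, BINARY2)

    def test_em_monotonic_and_normalized(self, rng):
        df, _ = simulate_profiles(BINARY2, SEP2.gamma, SEP2.rho, 500, rng)
        model = lca_fit(df, 2, BINARY2, FitConfig(n_starts=3, seed=3))
        diffs = np.diff(model.ll_history)
        assert (diffs >= -1e-9).all()
        assert model.gamma.sum() == pytest.approx(1.0, abs=1e-12)
        for item in BINARY2.items:
            assert model.rho[item].sum(axis=1) == pytest.approx(
                np.ones(2), abs=1e-12
            )


class TestFitStats:
    def test_g2_zero_when_model_reproduces_cell_proportions(self):
        # two independent items: the one-class model is saturated for them
        df = pd.DataFrame(
            {"a": ["x", "x", "y", "y"], "b": ["x", "y", "x", "y"]}
        )
        model = lca_fit(df, 1, BINARY2, FitConfig(n_starts=1, seed=0))
        stats = compute_fit_stats(model, df, BINARY2)
        assert stats.G2 == pytest.approx(0.0, abs=1e-9)

    def test_g2_equals_classical_independence_statistic(self, rng):
        df, _ = simulate_profiles(BINARY2, SEP2.gamma, SEP2.rho, 200, rng)
        model = lca_fit(df, 1, BINARY2, FitConfig(n_starts=1, seed=0))
        stats = compute_fit_stats(model, df, BINARY2)
        # direct 2x2 oracle: G2 = 2 sum O ln(O/E), E from the margins
        table = pd.crosstab(df["a"], df["b"]).to_numpy().astype(float)
        n = table.sum()
        expected = np.outer(table.sum(1), table.sum(0)) / n
        mask = table > 0
        oracle = 2.0 * (table[mask] * np.log(table[mask] / expected[mask])).sum()
        assert stats.G2 == pytest.approx(oracle, abs=1e-8)

    def test_engagement_spec_parameter_and_df_arithmetic(self):
        spec = engagement_spec()
        assert n_parameters(6, spec) == 101
        gamma = np.full(6, 1 / 6)
        rho = {
            item: np.full((6, len(spec.levels[item])), 1 / len(spec.levels[item]))
            for item in spec.items
        }
        model = LcaModel(gamma=gamma, rho=rho)
        df = pd.DataFrame(
            {item: [spec.levels[item][0]] * 10 for item in spec.items}
        )
        stats = compute_fit_stats(model, df, spec)
        assert stats.n_params == 101
        assert stats.df == (4**2 * 3**5 - 1) - 101 == 3786
        assert stats.AIC == pytest.approx(stats.G2 + 2 * 101)
        assert stats.BIC == pytest.approx(stats.G2 + np.log(10) * 101)


class TestSelectModel:
    def test_recovers_three_class_order_with_strong_separation(self, rng):
        spec = IndicatorSpec(
            items=("a", "b", "c"),
            levels={i: ("x", "y", "z") for i in ("a", "b", "c")},
        )
        truth = LcaModel(
            gamma=np.array([0.4, 0.35, 0.25]),
            rho={
                i: np.array(
                    [[0.9, 0.05, 0.05], [0.05, 0.9, 0.05], [0.05, 0.05, 0.9]]
                )
                for i in ("a", "b", "c")
            },
        )
        df, _ = simulate_profiles(spec, truth.gamma, truth.rho, 1500, rng)
        sweep = select_model(df, spec, range(1, 5), FitConfig(n_starts=8, seed=0))
        assert sweep.selected_k == 3

    def test_loglik_non_decreasing_in_k(self, rng):
        df, _ = simulate_profiles(BINARY2, SEP2.gamma, SEP2.rho, 600, rng)
        sweep = select_model(df, BINARY2, range(1, 4), FitConfig(n_starts=8, seed=2))
        ll = sweep.table["log_likelihood"].to_numpy()
        assert (np.diff(ll) >= -1e-6).all()

    def test_degenerate_single_k_sweep(self, rng):
        df, _ = simulate_profiles(BINARY2, SEP2.gamma, SEP2.rho, 100, rng)
        sweep = select_model(df, BINARY2, [1], FitConfig(n_starts=2, seed=0))
        assert sweep.selected_k == 1

    def test_k1_row_matches_direct_fit_stats(self, rng):
        df, _ = simulate_profiles(BINARY2, SEP2.gamma, SEP2.rho, 300, rng)
        sweep = select_model(df, BINARY2, range(1, 3), FitConfig(n_starts=2, seed=4))
        direct = compute_fit_stats(sweep.models[1], df, BINARY2)
        row = sweep.table.set_index("K").loc[1]
        assert row["G2"] == pytest.approx(direct.G2)
        assert row["BIC"] == pytest.approx(direct.BIC)

    def test_unidentified_models_are_flagged_not_dropped(self, rng):
        df, _ = simulate_profiles(BINARY2, SEP2.gamma, SEP2.rho, 50, rng)
        # 2 binary items have 3 free cells; K=2 needs 5 params -> df < 0
        sweep = select_model(df, BINARY2, range(1, 3), FitConfig(n_starts=2, seed=0))
        row = sweep.table.set_index("K").loc[2]
        assert not row["identified"]
        assert row["df"] < 0


class TestPosterior:
    def test_bayes_rule_closed_form(self):
        spec = IndicatorSpec(items=("a",), levels={"a": ("x", "y")})
        model = LcaModel(
            gamma=np.array([0.5, 0.5]),
            rho={"a": np.array([[0.9, 0.1], [0.2, 0.8]])},
        )
        out = posterior_classify(model, pd.DataFrame({"a": ["x"]}), spec)
        assert out.posterior[0, 0] == pytest.approx(0.9 / 1.1)
        assert out.modal_class[0] == 0

    def test_one_class_posterior_is_one(self):
        df = pd.DataFrame({"a": ["x", "y"], "b": ["y", "x"]})
        model = lca_fit(df, 1, BINARY2, FitConfig(n_starts=1, seed=0))
        out = posterior_classify(model, df, BINARY2)
        assert np.allclose(out.posterior, 1.0)

    def test_rows_sum_to_one(self, rng):
        df, _ = simulate_profiles(BINARY2, SEP2.gamma, SEP2.rho, 200, rng)
        out = posterior_classify(SEP2, df, BINARY2)
        assert np.allclose(out.posterior.sum(axis=1), 1.0)

    def test_modal_shares_approach_prevalences_when_separated(self, rng):
        spec = IndicatorSpec(
            items=tuple("abcd"), levels={i: ("x", "y") for i in "abcd"}
        )
        truth = LcaModel(
            gamma=np.array([0.7, 0.3]),
            rho={i: np.array([[0.95, 0.05], [0.05, 0.95]]) for i in "abcd"},
        )
        df, _ = simulate_profiles(spec, truth.gamma, truth.rho, 10_000, rng)
        out = posterior_classify(truth, df, spec)
        shares = out.modal_shares()
        assert np.abs(shares - truth.gamma).max() <= 0.02


class TestAlignment:
    def test_identity_for_identical_models(self):
        assert list(align_classes(SEP2, SEP2)) == [0, 1]

    def test_recovers_an_explicit_swap(self):
        swapped = SEP2.permute([1, 0])
        perm = align_classes(SEP2, swapped)
        assert list(perm) == [1, 0]
        realigned = swapped.permute(perm)
        assert np.allclose(realigned.gamma, SEP2.gamma)

    def test_k_mismatch_rejected(self):
        one = LcaModel(gamma=np.array([1.0]),
                       rho={"a": np.array([[0.5, 0.5]]),
                            "b": np.array([[0.5, 0.5]])})
        with pytest.raises(ValueError):
            align_classes(SEP2, one)

    def test_matches_exhaustive_permutation_search(self, rng):
        """On a noisy refit of a 4-class model, optimal assignment equals
        the best of all 4! permutations."""
        spec = IndicatorSpec(
            items=tuple("abc"), levels={i: ("x", "y", "z") for i in "abc"}
        )
        base = np.array([
            [0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8], [1 / 3, 1 / 3, 1 / 3],
        ])
        truth = LcaModel(
            gamma=np.array([0.3, 0.3, 0.2, 0.2]),
            rho={i: base.copy() for i in "abc"},
        )
        df, _ = simulate_profiles(spec, truth.gamma, truth.rho, 1200, rng)
        fitted = lca_fit(df, 4, spec, FitConfig(n_starts=10, seed=6))
        perm = align_classes(truth, fitted)

        def cost(p):
            return sum(
                np.abs(truth.rho[i] - fitted.rho[i][list(p)]).sum() for i in "abc"
            )

        best = min(itertools.permutations(range(4)), key=cost)
        assert cost(tuple(perm)) == pytest.approx(cost(best))


class TestModelContainer:
    def test_prevalence_sorting_preserves_likelihood(self, rng):
        df, _ = simulate_profiles(BINARY2, SEP2.gamma, SEP2.rho, 100, rng)
        model = lca_fit(df, 2, BINARY2, FitConfig(n_starts=3, seed=0))
        assert (np.diff(model.gamma) <= 0).all()

    def test_json_round_trip(self, tmp_path):
        path = tmp_path / "model.json"
        SEP2.to_json(path)
        back = LcaModel.from_json(path)
        assert np.allclose(back.gamma, SEP2.gamma)
        for item in SEP2.rho:
            assert np.allclose(back.rho[item], SEP2.rho[item])

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            LcaModel(gamma=np.array([0.7, 0.7]), rho={})
        with pytest.raises(ValueError):
            LcaModel(gamma=np.array([1.0]), rho={"a": np.array([[0.7, 0.7]])})
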