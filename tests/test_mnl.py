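"""Multinomial response mapping and Monte-Carlo level assignment."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sf36map import (
    assign_level,
    expected_utility,
    fit_mnl_dimension,
    korea_tariff,
    predict_mnl_utility,
    simulate_states,
)
from sf36map.mnl import MNLFit


def degenerate_fit(dimension, level):
    """An MNLFit that puts (almost) all mass on one level."""
    big = 60.0
    coef = {
        2: np.array([big if level == 2 else -big, 0.0]),
        3: np.array([big if level == 3 else -big, 0.0]),
    }
    if level == 3:
        coef[2] = np.array([-big, 0.0])
    return MNLFit(
        dimension=dimension, labels=["const", "x"], coef=coef,
        se={k: np.zeros(2) for k in coef}, levels_present=(1, 2, 3),
        pseudo_r2={"mcfadden": 0.0}, llf=0.0, llnull=0.0,
    )


class TestAssignLevel:
    def test_degenerate_corner(self):
        for u in (0.0, 0.3, 1.0):
            assert assign_level(1.0, 0.0, u) == 1

    def test_level3_region(self):
        assert assign_level(0.2, 0.3, 0.75) == 3  # 0.75 > 1 - 0.3

    def test_inclusive_level1_boundary(self):
        assert assign_level(0.2, 0.3, 0.2) == 1  # u == P1 maps to level 1

    def test_inclusive_level2_boundary(self):
        assert assign_level(0.2, 0.3, 0.7) == 2  # u == 1 - P3 maps to level 2

    def test_outside_simplex_rejected(self):
        with pytest.raises(ValueError, match="simplex"):
            assign_level(0.8, 0.5, 0.5)
        with pytest.raises(ValueError, match="u must"):
            assign_level(0.5, 0.2, 1.5)

    @given(
        st.tuples(st.floats(0, 1), st.floats(0, 1)).filter(lambda t: t[0] + t[1] <= 1.0)
    )
    def test_partition_measures(self, p):
        """Level-set grid measures approximate (P1, P2, P3)."""
        p1, p3 = p
        u = (np.arange(20000) + 0.5) / 20000
        lev = assign_level(np.full_like(u, p1), np.full_like(u, p3), u)
        freq = np.array([(lev == k).mean() for k in (1, 2, 3)])
        np.testing.assert_allclose(freq, [p1, 1 - p1 - p3, p3], atol=1e-3)


class TestFitMNL:
    def test_saturated_two_cell_model(self):
        """With one binary covariate, fitted probabilities equal cell proportions."""
        rng = np.random.default_rng(21)
        x = np.repeat([0, 1], 300)
        probs = {0: [0.7, 0.2, 0.1], 1: [0.2, 0.5, 0.3]}
        levels = np.concatenate(
            [rng.choice([1, 2, 3], size=300, p=probs[v]) for v in (0, 1)]
        )
        X = np.column_stack([np.ones(600), x])
        fit = fit_mnl_dimension(X, levels, labels=["const", "x"], dimension="MO")
        pred = fit.predict_proba(np.array([[1.0, 0.0], [1.0, 1.0]]))
        for row, v in zip(pred, (0, 1)):
            observed = [(levels[x == v] == k).mean() for k in (1, 2, 3)]
            np.testing.assert_allclose(row, observed, atol=1e-5)

    def test_probabilities_sum_to_one(self, mixed_design):
        prof, X, labels, _, _ = mixed_design
        fit = fit_mnl_dimension(X, prof["PD"].to_numpy(int), labels, dimension="PD")
        p = fit.predict_proba(X)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-10)
        assert (p >= 0).all()

    def test_null_covariate_pseudo_r2_near_zero(self):
        rng = np.random.default_rng(33)
        n = 5000
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        levels = rng.choice([1, 2, 3], size=n, p=[0.5, 0.3, 0.2])  # independent of x
        fit = fit_mnl_dimension(X, levels, dimension="AD")
        assert fit.pseudo_r2["mcfadden"] < 0.01

    def test_absent_level_collapses_to_binary(self):
        rng = np.random.default_rng(44)
        n = 400
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        levels = rng.choice([1, 2], size=n)
        with pytest.warns(UserWarning, match="collapsing to binary"):
            fit = fit_mnl_dimension(X, levels, dimension="SC")
        p = fit.predict_proba(X)
        np.testing.assert_allclose(p[:, 2], 0.0, atol=1e-12)
        np.testing.assert_allclose(p.sum(axis=1), 1.0)

    def test_single_level_rejected(self):
        X = np.ones((50, 1))
        with pytest.raises(ValueError, match="only one level"):
            fit_mnl_dimension(X, np.ones(50, dtype=int), dimension="UA")

    def test_coefficient_recovery(self):
        """Known two-equation MNL coefficients recovered at moderate n."""
        rng = np.random.default_rng(55)
        n = 4000
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        b2, b3 = np.array([-0.5, 0.8]), np.array([-1.0, 1.5])
        e2, e3 = np.exp(X @ b2), np.exp(X @ b3)
        p1 = 1 / (1 + e2 + e3)
        u = rng.random(n)
        levels = 1 + (u > p1).astype(int) + (u > p1 + p1 * e2).astype(int)
        fit = fit_mnl_dimension(X, levels, dimension="MO")
        np.testing.assert_allclose(fit.coef[2], b2, atol=0.15)
        np.testing.assert_allclose(fit.coef[3], b3, atol=0.15)


class TestSimulation:
    def test_degenerate_level1_gives_full_health(self, korea):
        fits = [degenerate_fit(d, 1) for d in ("MO", "SC", "UA", "PD", "AD")]
        X = np.column_stack([np.ones(4), np.zeros(4)])
        states = simulate_states(fits, X, seed=1)
        assert (states == 1).all()
        util = predict_mnl_utility(fits, X, korea, seed=1)
        np.testing.assert_allclose(util, 1.0)

    def test_degenerate_level3_gives_floor(self, korea):
        fits = [degenerate_fit(d, 3) for d in ("MO", "SC", "UA", "PD", "AD")]
        X = np.column_stack([np.ones(4), np.zeros(4)])
        util = predict_mnl_utility(fits, X, korea, seed=1)
        np.testing.assert_allclose(util, -0.171, atol=1e-12)

    def test_seed_determinism(self, mixed_design):
        prof, X, labels, _, _ = mixed_design
        fits = {
            d: fit_mnl_dimension(X, prof[d].to_numpy(int), labels, dimension=d)
            for d in ("MO", "SC", "UA", "PD", "AD")
        }
        a = simulate_states(fits, X[:100], seed=7, n_draws=3)
        b = simulate_states(fits, X[:100], seed=7, n_draws=3)
        c = simulate_states(fits, X[:100], seed=8, n_draws=3)
        assert (a == b).all()
        assert (a != c).any()
        assert not (a[0] == a[1]).all()  # draws differ within a seed

    def test_missing_dimension_rejected(self):
        fits = {d: degenerate_fit(d, 1) for d in ("MO", "SC", "UA", "PD")}
        with pytest.raises(ValueError, match="AD"):
            simulate_states(fits, np.ones((1, 2)), seed=0)

    def test_draw_frequencies_match_probabilities(self):
        """Empirical level frequencies converge to the fitted (P1,P2,P3)."""
        p1, p3 = 0.55, 0.15
        big = np.log  # build a fit with those exact probabilities
        p2 = 1 - p1 - p3
        fit = MNLFit(
            dimension="MO", labels=["const"],
            coef={2: np.array([np.log(p2 / p1)]), 3: np.array([np.log(p3 / p1)])},
            se={2: np.zeros(1), 3: np.zeros(1)}, levels_present=(1, 2, 3),
            pseudo_r2={"mcfadden": 0.0}, llf=0.0, llnull=0.0,
        )
        fits = [fit] * 5
        states = simulate_states(fits, np.ones((1, 1)), seed=3, n_draws=10000)
        draws = states[:, 0, 0]
        for k, p in zip((1, 2, 3), (p1, p2, p3)):
            se = np.sqrt(p * (1 - p) / 10000)
            assert abs((draws == k).mean() - p) < 3 * se + 1e-9

    def test_mean_utility_approaches_exact_expectation(self, korea):
        p1, p2, p3 = 0.5, 0.3, 0.2
        fit = MNLFit(
            dimension="MO", labels=["const"],
            coef={2: np.array([np.log(p2 / p1)]), 3: np.array([np.log(p3 / p1)])},
            se={2: np.zeros(1), 3: np.zeros(1)}, levels_present=(1, 2, 3),
            pseudo_r2={"mcfadden": 0.0}, llf=0.0, llnull=0.0,
        )
        fits = [fit] * 5
        X = np.ones((1, 1))
        exact = expected_utility(fits, X, korea)[0]
        mean_util, _, util = predict_mnl_utility(
            fits, X, korea, seed=11, n_draws=5000, return_states=True
        )
        mc_se = util[:, 0].std(ddof=1) / np.sqrt(5000)
        assert abs(mean_util[0] - exact) < 3 * mc_se

    def test_utilities_stay_in_tariff_range(self, korea, mixed_design):
        prof, X, labels, _, _ = mixed_design
        fits = {
            d: fit_mnl_dimension(X, prof[d].to_numpy(int), labels, dimension=d)
            for d in ("MO", "SC", "UA", "PD", "AD")
        }
        util = predict_mnl_utility(fits, X, korea, seed=5)
        assert util.min() >= -0.171 - 1e-12
        assert util.max() <= 1.0 + 1e-12

    def test_dimensions_independent_in_simulation(self):
        """Joint frequency of a level pair factorizes into the marginals."""
        def flat_fit(dim, p1, p3):
            p2 = 1 - p1 - p3
            return MNLFit(
                dimension=dim, labels=["const"],
                coef={2: np.array([np.log(p2 / p1)]), 3: np.array([np.log(p3 / p1)])},
                se={2: np.zeros(1), 3: np.zeros(1)}, levels_present=(1, 2, 3),
                pseudo_r2={"mcfadden": 0.0}, llf=0.0, llnull=0.0,
            )

        fits = [flat_fit(d, 0.5, 0.2) for d in ("MO", "SC", "UA", "PD", "AD")]
        states = simulate_states(fits, np.ones((1, 1)), seed=19, n_draws=20000)
        mo = states[:, 0, 0]
        sc = states[:, 0, 1]
        joint = ((mo == 1) & (sc == 1)).mean()
        prod = (mo == 1).mean() * (sc == 1).mean()
        assert abs(joint - prod) < 0.015
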