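"""Fair game B construction, invariant measures, mixture and pattern profits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import flashratchet as fr

COPRIME_SHAPES = [(1, 2), (1, 3), (2, 3), (1, 4), (3, 4), (2, 5), (3, 5), (1, 5)]


class TestProbsFromRho:
    def test_parrondo_special_case(self):
        # rho = 1/3 at shape 1/3 gives the classic game
        p0, p1 = fr.probs_from_rho(1 / 3, 1, 3)
        assert p0 == pytest.approx(1 / 10, abs=1e-15)
        assert p1 == pytest.approx(3 / 4, abs=1e-15)

    def test_symmetric_limit(self):
        assert fr.probs_from_rho(1.0, 1, 3) == pytest.approx((0.5, 0.5))

    def test_quarter_shape(self):
        # (1-alpha)/alpha = 3 at alpha = 1/4
        p0, p1 = fr.probs_from_rho(0.95, 1, 4)
        assert p0 == pytest.approx(0.95**3 / (1 + 0.95**3), abs=1e-15)
        assert p0 == pytest.approx(0.4616058, abs=1e-7)
        assert p1 == pytest.approx(1 / 1.95, abs=1e-15)
        assert p1 == pytest.approx(0.5128205, abs=1e-7)

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
    def test_rho_out_of_range(self, bad):
        with pytest.raises(ValueError, match="rho"):
            fr.probs_from_rho(bad, 1, 3)

    def test_non_coprime_rejected(self):
        with pytest.raises(ValueError):
            fr.probs_from_rho(0.5, 2, 4)


@settings(deadline=None, max_examples=60)
@given(
    rho=st.floats(0.02, 0.999),
    shape=st.sampled_from(COPRIME_SHAPES),
)
def test_detailed_balance_identity(rho, shape):
    """(1-p0)^l (1-p1)^(L-l) = p0^l p1^(L-l): the solvability condition of
    the detailed-balance equations."""
    l, L = shape
    p0, p1 = fr.probs_from_rho(rho, l, L)
    assert 0 < p0 <= 0.5 <= p1 < 1
    lhs = (1 - p0) ** l * (1 - p1) ** (L - l)
    rhs = p0**l * p1 ** (L - l)
    assert lhs == pytest.approx(rhs, rel=1e-12)


class TestInvariantProfile:
    def test_printed_formula_shape_third(self):
        # (pi(0), pi(1), pi(2)) = (1+rho^2, rho(1+rho), 1+rho) / (2(1+rho+rho^2))
        for rho in (0.1, 1 / 3, 0.7, 0.95):
            spec = fr.GameBSpec(l=1, L_int=3, rho=rho)
            expected = np.array(
                [1 + rho**2, rho * (1 + rho), 1 + rho]
            ) / (2 * (1 + rho + rho**2))
            np.testing.assert_allclose(
                fr.game_b_invariant_profile(spec), expected, atol=1e-14
            )

    def test_rho_third_values(self):
        spec = fr.GameBSpec(l=1, L_int=3, rho=1 / 3)
        np.testing.assert_allclose(
            fr.game_b_invariant_profile(spec),
            [5 / 13, 2 / 13, 6 / 13],
            atol=1e-15,
        )

    @pytest.mark.parametrize("shape", COPRIME_SHAPES)
    @pytest.mark.parametrize("rho", [0.2, 0.5, 0.9])
    def test_detailed_balance_conditions(self, shape, rho):
        """pi satisfies every wrap-around detailed-balance edge condition."""
        l, L = shape
        spec = fr.GameBSpec(l=l, L_int=L, rho=rho)
        pi = fr.game_b_invariant_profile(spec)
        u = spec.chain.up_probs
        assert pi.sum() == pytest.approx(1.0, abs=1e-13)
        for j in range(L):
            k = (j + 1) % L
            assert pi[j] * u[j] == pytest.approx(
                pi[k] * (1 - u[k]), rel=1e-12
            ), f"edge {j}->{k}"

    def test_matches_linear_solve(self):
        """Closed-form profile equals the independent cycle stationary solve."""
        for l, L in COPRIME_SHAPES:
            spec = fr.GameBSpec(l=l, L_int=L, rho=0.4)
            np.testing.assert_allclose(
                fr.game_b_invariant_profile(spec),
                fr.cycle_stationary(spec.chain),
                atol=1e-13,
            )


class TestCycleStationary:
    def test_uniform_for_fair_coin(self):
        pi = fr.cycle_stationary(np.full(5, 0.5))
        np.testing.assert_allclose(pi, 0.2, atol=1e-14)

    def test_two_state_closed_form(self):
        # on a 2-cycle both moves from j land on 1-j, so the chain alternates
        # deterministically and the stationary law is uniform
        pi = fr.cycle_stationary(np.array([0.3, 0.8]))
        np.testing.assert_allclose(pi, [0.5, 0.5], atol=1e-14)

    def test_matches_eigenvector_solve(self):
        rng = np.random.default_rng(11)
        for L in (3, 4, 5, 7):
            u = rng.uniform(0.1, 0.9, size=L)
            P = np.zeros((L, L))
            idx = np.arange(L)
            np.add.at(P, (idx, (idx + 1) % L), u)
            np.add.at(P, (idx, (idx - 1) % L), 1 - u)
            w, v = np.linalg.eig(P.T)
            vec = np.real(v[:, np.argmin(np.abs(w - 1))])
            vec = np.abs(vec) / np.abs(vec).sum()
            np.testing.assert_allclose(
                fr.cycle_stationary(u), vec, atol=1e-10
            )


class TestProfits:
    def test_fair_coin_profit_zero(self):
        assert fr.mean_profit(np.full(3, 0.5)) == pytest.approx(0.0, abs=1e-15)

    def test_biased_chain_profit(self):
        assert fr.mean_profit(np.full(4, 0.6)) == pytest.approx(0.2, abs=1e-13)

    @pytest.mark.parametrize("shape", COPRIME_SHAPES)
    @pytest.mark.parametrize("rho", [0.1, 1 / 3, 0.6, 0.9, 0.99])
    def test_game_b_is_fair(self, shape, rho):
        """Game B has zero stationary mean profit for every rho and shape."""
        spec = fr.GameBSpec(l=shape[0], L_int=shape[1], rho=rho)
        assert abs(fr.mean_profit(spec.chain)) < 1e-12

    def test_mixture_endpoints_fair(self):
        spec = fr.GameBSpec(l=1, L_int=3, rho=1 / 3)
        assert abs(fr.mixture_mean_profit(0.0, spec)) < 1e-12
        assert abs(fr.mixture_mean_profit(1.0, spec)) < 1e-15

    def test_parrondo_effect_alpha_below_half(self):
        """Mixing two fair games wins when alpha < 1/2 (strict convexity)."""
        spec = fr.GameBSpec(l=1, L_int=3, rho=1 / 3)
        for c in (0.1, 0.25, 0.5, 0.75, 0.9):
            assert fr.mixture_mean_profit(c, spec) > 0

    def test_anti_parrondo_alpha_above_half(self):
        """alpha = 2/3 > 1/2: the same mixture loses (concavity flips)."""
        spec = fr.GameBSpec(l=2, L_int=3, rho=1 / 3)
        for c in (0.1, 0.5, 0.9):
            assert fr.mixture_mean_profit(c, spec) < 0

    def test_pattern_ab_fair(self):
        spec = fr.GameBSpec(l=1, L_int=3, rho=1 / 3)
        assert abs(fr.pattern_mean_profit(1, 1, spec)) < 1e-10

    def test_pattern_ab_fair_symmetric_boundary(self):
        with pytest.warns(UserWarning):
            spec = fr.GameBSpec(l=1, L_int=3, rho=1.0)
        assert abs(fr.pattern_mean_profit(1, 1, spec)) < 1e-12

    @pytest.mark.parametrize("r, s", [(2, 2), (1, 2), (2, 1), (3, 2)])
    def test_patterns_win_at_classic_parameters(self, r, s):
        spec = fr.GameBSpec(l=1, L_int=3, rho=1 / 3)
        assert fr.pattern_mean_profit(r, s, spec) > 0

    def test_pattern_validates_exponents(self):
        spec = fr.GameBSpec(l=1, L_int=3, rho=1 / 3)
        with pytest.raises(ValueError):
            fr.pattern_mean_profit(0, 1, spec)
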