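import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from moralcomp import ParamSet, choice_probabilities, log_likelihood, utility
from moralcomp.models import (
    MODEL_IDS,
    MODELS,
    _log_softmax,
    attributed_harm,
    get_model,
    utility_matrix,
)
from conftest import softmax_oracle


class TestModelRegistry:
    def test_eight_models(self):
        assert len(MODELS) == 8
        assert set(MODEL_IDS) == {f"{f}.{v}" for f in "12" for v in "1234"}

    @pytest.mark.parametrize(
        "mid, family, self_int, base, k",
        [
            ("1.1", "diffusion", True, True, 4),
            ("1.2", "diffusion", True, False, 3),
            ("1.3", "diffusion", False, True, 3),
            ("1.4", "diffusion", False, False, 2),
            ("2.1", "amplification", True, True, 4),
            ("2.4", "amplification", False, False, 2),
        ],
    )
    def test_variant_structure(self, mid, family, self_int, base, k):
        m = get_model(mid)
        assert (m.family, m.self_interest, m.baseline, m.k) == (family, self_int, base, k)
        assert "lam" in m.free_params
        assert ("theta" in m.free_params) == self_int
        assert ("eta" in m.free_params) == base

    def test_unknown_id_raises(self):
        with pytest.raises(KeyError):
            get_model("3.1")


class TestUtility:
    @pytest.mark.parametrize(
        "mid, params, H, W, D, expected",
        [
            # diffusion ideal point kappa*H/W + eta = 5
            ("1.3", dict(kappa=2, eta=1, lam=1), 4, 2, 5, 0.0),
            ("1.3", dict(kappa=2, eta=1, lam=1), 4, 2, 3, -2.0),
            # amplification ideal point kappa*H*R = 0.5*3*4 = 6
            ("2.3", dict(kappa=0.5, eta=0, lam=1), 3, 1, 6, 0.0),
            ("1.4", dict(kappa=1, lam=1), 2, 2, 1, 0.0),
        ],
    )
    def test_point_values(self, mid, params, H, W, D, expected):
        assert utility(mid, ParamSet(**params), H, W, D) == pytest.approx(expected)

    def test_pure_greed_limit(self):
        # theta = 1 removes the aversion term entirely: U(D) = 10 - D
        p = ParamSet(kappa=3.7, eta=2.2, theta=1.0, lam=1)
        U = utility("1.1", p, 3, 2)
        assert np.allclose(U, 10 - np.arange(11))

    def test_decision_outside_options_raises(self):
        with pytest.raises(ValueError):
            utility("1.3", ParamSet(kappa=1, eta=0, lam=1), 2, 2, 11)

    def test_families_have_distinct_ideal_points(self):
        # model discriminability: for kappa > 0 the two integration rules
        # disagree on at least one cell
        for kappa in (0.5, 1.0, 2.0):
            a1 = attributed_harm(get_model("1.3"), [1, 2, 3, 4], [4, 3, 2, 1])
            a2 = attributed_harm(get_model("2.3"), [1, 2, 3, 4], [4, 3, 2, 1])
            assert np.any(kappa * a1 != kappa * a2)


class TestChoiceProbabilities:
    def test_zero_temperature_uniform(self):
        p = ParamSet(kappa=2, eta=1, lam=0.0)
        probs = choice_probabilities("1.3", p, 3, 2)
        assert np.allclose(probs, 1 / 11)

    def test_low_temperature_concentrates(self):
        p = ParamSet(kappa=2, eta=1, lam=50.0)
        probs = choice_probabilities("1.3", p, 4, 2)
        assert probs[5] > 0.999

    def test_brute_force_oracle_model_14(self):
        p = ParamSet(kappa=1, lam=1)
        probs = choice_probabilities("1.4", p, 2, 2)
        expected = softmax_oracle(-np.abs(1.0 - np.arange(11)), 1.0)
        assert np.allclose(probs, expected, atol=1e-14)

    def test_large_lambda_no_overflow(self):
        # stabilised softmax must stay finite where naive exponentials blow up
        p = ParamSet(kappa=2.5, eta=10, theta=0.9, lam=20.0)
        probs = choice_probabilities("2.1", p, 4, 1)
        assert np.isfinite(probs).all() and probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_deterministic_limit_splits_ties(self):
        # ideal point 1.5 at (H=1, W=4): options 1 and 2 tie exactly
        p = ParamSet(kappa=2, eta=1, lam=np.inf)
        probs = choice_probabilities("1.3", p, 1, 4)
        assert probs[1] == probs[2] == pytest.approx(0.5)
        assert probs.sum() == pytest.approx(1.0)

    @settings(deadline=None, max_examples=60)
    @given(
        mid=st.sampled_from(MODEL_IDS),
        kappa=st.floats(0, 2.5),
        eta=st.floats(0, 10),
        theta=st.floats(0, 1),
        lam=st.floats(0, 20),
        H=st.integers(1, 4),
        W=st.integers(1, 4),
    )
    def test_probability_axioms(self, mid, kappa, eta, theta, lam, H, W):
        p = ParamSet(kappa=kappa, eta=eta, theta=theta, lam=lam)
        probs = choice_probabilities(mid, p, H, W)
        assert (probs >= 0).all()
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(
        shift=st.floats(-50, 50),
        kappa=st.floats(0, 5),
        lam=st.floats(0, 10),
        H=st.integers(1, 4),
        W=st.integers(1, 4),
    )
    def test_softmax_shift_invariance(self, shift, kappa, lam, H, W):
        spec = get_model("1.3")
        U = utility_matrix(spec, kappa, 1.0, 0.0, np.array([H], float), np.array([W], float))
        a = np.exp(_log_softmax(lam, U))
        b = np.exp(_log_softmax(lam, U + shift))
        assert np.allclose(a, b, atol=1e-12)


class TestLogLikelihood:
    def test_zero_temperature_closed_form(self, factorial_hw):
        H, W = factorial_hw
        D = np.zeros(64, dtype=int)
        ll = log_likelihood("1.3", ParamSet(kappa=2, eta=1, lam=0.0), (H, W, D))
        assert ll == pytest.approx(64 * np.log(1 / 11))

    def test_deterministic_ideal_point_near_zero(self):
        # stabilised probability at the unique ideal point approaches 1
        p = ParamSet(kappa=2, eta=1, lam=20.0)
        ll = log_likelihood("1.3", p, (np.array([4.0]), np.array([2.0]), np.array([5])))
        assert -1e-8 < ll <= 0

    def test_three_trial_toy_oracle(self):
        # Model 1.4, kappa=1, lam=1; per-trial log probs from direct summation
        H = np.array([2.0, 4.0, 3.0])
        W = np.array([2.0, 1.0, 3.0])
        D = np.array([1, 4, 1])
        expected = 0.0
        for h, w, d in zip(H, W, D):
            probs = softmax_oracle(-np.abs(h / w - np.arange(11)), 1.0)
            expected += np.log(probs[d])
        ll = log_likelihood("1.4", ParamSet(kappa=1, lam=1), (H, W, D))
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_empty_trials_error(self):
        with pytest.raises(ValueError):
            log_likelihood("1.3", ParamSet(kappa=1, eta=0, lam=1),
                           (np.array([]), np.array([]), np.array([], dtype=int)))


def test_oracle_equivalence_random_instances():
    """Softmax probabilities and log-likelihoods agree with the brute-force
    direct-summation oracle to 1e-10 over random model/parameter draws."""
    rng = np.random.default_rng(2024)
    for _ in range(100):
        mid = rng.choice(MODEL_IDS)
        spec = get_model(mid)
        kappa = rng.uniform(0, 2.5 if spec.family == "amplification" else 10)
        p = ParamSet(
            kappa=kappa,
            eta=rng.uniform(0, 10) if spec.baseline else 0.0,
            theta=rng.uniform(0, 1) if spec.self_interest else 0.0,
            lam=rng.uniform(0, 5),
        )
        H, W = int(rng.integers(1, 5)), int(rng.integers(1, 5))
        U = utility(mid, p, H, W)
        expected = softmax_oracle(U, p.lam)
        got = choice_probabilities(mid, p, H, W)
        assert np.allclose(got, expected, atol=1e-10)
        D = int(rng.integers(0, 11))
        ll = log_likelihood(mid, p, (np.array([H], float), np.array([W], float), np.array([D])))
        assert ll == pytest.approx(np.log(expected[D]), abs=1e-10)
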