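import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prodiff import (
    ProductionHistory,
    choose_behaviour,
    frequency_weights,
    generate_ring_lattice,
    individual_probabilities,
    production_probabilities,
    social_frequencies,
    update_expected_value,
)


class TestValueUpdate:
    @pytest.mark.parametrize(
        "e_prev,reward,rho,expected",
        [(1.0, 1.0, 0.1, 1.0), (0.0, 1.0, 0.1, 0.1), (1.0, 0.0, 0.1, 0.9)],
    )
    def test_direct_evaluation(self, e_prev, reward, rho, expected):
        assert update_expected_value(e_prev, reward, rho) == pytest.approx(expected)

    @pytest.mark.parametrize("rho", [0.0, 1.0, -0.1, 1.5])
    def test_rho_domain(self, rho):
        with pytest.raises(ValueError):
            update_expected_value(0.5, 1.0, rho)

    @given(
        rho=st.floats(0.01, 0.99),
        n=st.integers(1, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_geometric_growth_closed_form(self, rho, n):
        """Producing every step from E=0 with unit reward gives
        E_n = 1 - (1-rho)^n (geometric approach to the true reward)."""
        e = 0.0
        for _ in range(n):
            e = update_expected_value(e, 1.0, rho)
        assert e == pytest.approx(1.0 - (1.0 - rho) ** n, abs=1e-12)
        assert e <= 1.0

    @given(
        e=st.floats(0.0, 1.0),
        reward=st.sampled_from([0.0, 1.0]),
        rho=st.floats(0.01, 0.99),
    )
    @settings(max_examples=100, deadline=None)
    def test_value_never_exceeds_reward_bound(self, e, reward, rho):
        assert 0.0 <= update_expected_value(e, reward, rho) <= 1.0


class TestIndividualProbabilities:
    def test_singleton_repertoire(self):
        assert individual_probabilities({"a": 1.0}, alpha=3.0) == {"a": 1.0}

    def test_softmax_values(self):
        p = individual_probabilities({"a": 1.0, "b": 0.0}, alpha=1.0)
        assert p["a"] == pytest.approx(math.e / (1 + math.e), abs=1e-4)
        assert p["b"] == pytest.approx(0.2689, abs=1e-4)

    def test_higher_alpha_flattens_choice(self):
        p = individual_probabilities({"a": 1.0, "b": 0.0}, alpha=2.0)
        assert p["a"] == pytest.approx(0.6225, abs=1e-4)
        assert p["b"] > 0  # production without prior experience stays possible

    def test_empty_repertoire_rejected(self):
        with pytest.raises(ValueError):
            individual_probabilities({})


class TestFrequencyWeights:
    def test_linear_normalization(self):
        assert frequency_weights({"a": 6, "b": 2}, f=1.0) == pytest.approx(
            {"a": 0.75, "b": 0.25}
        )

    def test_conformist_amplification(self):
        w = frequency_weights({"a": 6, "b": 2}, f=3.0)
        assert w["a"] == pytest.approx(216 / 224, abs=1e-6)

    def test_anticonformist_damping(self):
        w = frequency_weights({"a": 8, "b": 1}, f=0.33)
        expected_a = 8**0.33 / (8**0.33 + 1)
        assert w["a"] == pytest.approx(expected_a, abs=1e-9)
        assert 0.66 < w["a"] < 0.67

    def test_all_zero_counts_fall_back_to_uniform(self):
        assert frequency_weights({"a": 0, "b": 0}, f=2.0) == pytest.approx(
            {"a": 0.5, "b": 0.5}
        )

    def test_unobserved_behaviour_gets_zero_weight(self):
        w = frequency_weights({"a": 5, "b": 0}, f=0.33)
        assert w == pytest.approx({"a": 1.0, "b": 0.0})


class TestMixing:
    def test_sigma_zero_returns_individual(self):
        ind = {"a": 0.7, "b": 0.3}
        assert production_probabilities(ind, {"a": 0.1, "b": 0.9}, 0.0) == pytest.approx(ind)

    def test_sigma_one_returns_social(self):
        soc = {"a": 0.1, "b": 0.9}
        assert production_probabilities({"a": 0.7, "b": 0.3}, soc, 1.0) == pytest.approx(soc)

    def test_even_mixture(self):
        p = production_probabilities(
            {"a": 0.7311, "b": 0.2689}, {"a": 0.75, "b": 0.25}, 0.5
        )
        assert p["a"] == pytest.approx(0.74055, abs=1e-6)

    def test_mismatched_behaviour_sets_rejected(self):
        with pytest.raises(ValueError):
            production_probabilities({"a": 1.0}, {"a": 0.5, "b": 0.5}, 0.5)

    @given(
        e_b=st.floats(0.0, 1.0),
        alpha=st.floats(0.1, 5.0),
        ca=st.integers(0, 60),
        cb=st.integers(0, 60),
        f=st.floats(0.2, 4.0),
        sigma=st.floats(0.0, 1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_probabilities_normalized(self, e_b, alpha, ca, cb, f, sigma):
        ind = individual_probabilities({"a": 1.0, "b": e_b}, alpha)
        soc = frequency_weights({"a": ca, "b": cb}, f)
        p = production_probabilities(ind, soc, sigma)
        assert sum(p.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(v >= 0 for v in p.values())


class TestChoice:
    def test_certain_choice(self, rng):
        assert choose_behaviour({"a": 1.0}, rng) == "a"

    def test_unbiased_frequency(self, rng):
        draws = [choose_behaviour({"a": 0.5, "b": 0.5}, rng) for _ in range(10_000)]
        freq_b = draws.count("b") / len(draws)
        assert freq_b == pytest.approx(0.5, abs=0.015)

    def test_seeded_reproducibility(self):
        seqs = []
        for _ in range(2):
            r = np.random.default_rng(7)
            seqs.append([choose_behaviour({"a": 0.3, "b": 0.7}, r) for _ in range(50)])
        assert seqs[0] == seqs[1]


def test_social_frequencies_counts_neighbours_only():
    net = generate_ring_lattice(6, 2)  # agent 0 sees agents 1 and 5
    codes = np.zeros((4, 6), dtype=np.int8)
    codes[:, 1] = 1  # neighbour 1 produced b every step
    codes[:, 3] = 1  # agent 3 is not a neighbour of 0; must be invisible
    hist = ProductionHistory(codes)
    w = social_frequencies(0, net, hist, t=5, m=10, f=1.0, repertoire={"a", "b"})
    # neighbours 1 and 5 produced 4 b and 4 a in the window
    assert w == pytest.approx({"a": 0.5, "b": 0.5})
    w_naive = social_frequencies(0, net, hist, t=5, m=10, f=1.0, repertoire={"a"})
    assert w_naive == pytest.approx({"a": 1.0})


def test_history_long_format_roundtrip(tmp_path):
    codes = np.array([[0, 1], [1, 1], [0, 0]], dtype=np.int8)
    hist = ProductionHistory(codes)
    path = tmp_path / "hist.csv"
    hist.to_csv(path)
    assert np.array_equal(ProductionHistory.from_csv(path).codes, codes)
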