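import math

import numpy as np
import pytest

from prodiff import (
    NBDAData,
    ctada_loglik,
    delta_aicc,
    fit_tadac,
    generate_ideal_data,
    generate_random_regular,
    generate_realistic_data,
    reference_constellation,
)
from prodiff.nbda import NBDAFit, _aicc
from prodiff.network import SocialNetwork


def _path_3():
    return SocialNetwork(np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.int8))


def _toy_data():
    """3-agent path 0-1-2; demonstrator 0; events: agent 1 at 1.3, agent 2 at 2.7."""
    return NBDAData(
        event_times=np.array([np.nan, 1.3, 2.7]),
        net=_path_3(),
        demonstrators=frozenset({0}),
        weights=np.array([0.5, 0.8, 0.3]),
    )


def _toy_loglik_brute(lam, s):
    """Independent hand computation: explicit survival x event-hazard product."""
    # interval (0, 1.3]: naive {1, 2}; exposures R1 = w0 = 0.5 (adjacent), R2 = 0
    h1 = lam * (s * 0.5 + 1.0)
    h2 = lam * 1.0
    log_l = -(h1 + h2) * 1.3 + math.log(h1)
    # interval (1.3, 2.7]: naive {2}; exposure R2 = w1 = 0.8
    h2b = lam * (s * 0.8 + 1.0)
    log_l += -h2b * 1.4 + math.log(h2b)
    return log_l


class TestLikelihood:
    @pytest.mark.parametrize("lam,s", [(0.04, 2.0), (0.1, 0.5), (0.5, 10.0)])
    def test_brute_force_oracle(self, lam, s):
        assert ctada_loglik(_toy_data(), lam, s, "social") == pytest.approx(
            _toy_loglik_brute(lam, s), abs=1e-10
        )

    def test_asocial_equals_social_at_s_zero(self):
        data = _toy_data()
        for lam in (0.01, 0.1, 1.0):
            assert ctada_loglik(data, lam, 0.0, "social") == pytest.approx(
                ctada_loglik(data, lam, 123.0, "asocial")
            )

    def test_weight_rate_scale_invariance(self):
        data = _toy_data()
        doubled = NBDAData(
            data.event_times, data.net, data.demonstrators, data.weights * 2
        )
        assert ctada_loglik(data, 0.05, 4.0, "social") == pytest.approx(
            ctada_loglik(doubled, 0.05, 2.0, "social"), abs=1e-10
        )

    def test_zero_rate_gives_minus_infinity(self):
        assert ctada_loglik(_toy_data(), 0.0, 1.0) == -np.inf


class TestFitting:
    def test_aicc_arithmetic(self):
        assert _aicc(-50.0, 1, 23) == pytest.approx(102 + 4 / 21)
        with pytest.raises(ValueError):
            _aicc(-50.0, 2, 3)

    def test_asocial_mle_matches_exponential_closed_form(self):
        """All-event data at unit spacing: lambda0_hat = n / total exposure
        time, the exponential waiting-time MLE."""
        net = SocialNetwork(np.zeros((3, 3), dtype=np.int8))
        data = NBDAData(np.array([1.0, 2.0, 3.0]), net, frozenset(), np.ones(3))
        fit = fit_tadac(data, "asocial")
        # exposure: 3 naive for 1 unit, 2 for 1 unit, 1 for 1 unit
        assert fit.lambda0_hat == pytest.approx(3 / 6)
        assert fit.k_params == 1

    def test_social_fit_nests_asocial(self):
        cons = reference_constellation()
        for seed in range(5):
            rng = np.random.default_rng(seed)
            net = generate_random_regular(24, 6, rng_seed=seed)
            data = generate_ideal_data("social", cons, net, rng)
            social = fit_tadac(data, "social")
            asocial = fit_tadac(data, "asocial")
            assert social.log_likelihood >= asocial.log_likelihood - 1e-9

    def test_single_event_guard(self):
        net = _path_3()
        data = NBDAData(np.array([np.nan, 1.5, np.nan]), net, frozenset({0}), np.ones(3))
        with pytest.raises(ValueError):
            fit_tadac(data, "social")

    def test_recovers_social_transmission_on_ideal_data(self):
        """Ideal social batches: positive support and s_hat near truth."""
        cons = reference_constellation()
        deltas, s_hats = [], []
        for seed in range(40):
            rng = np.random.default_rng(1000 + seed)
            net = generate_random_regular(24, 6, rng_seed=seed)
            data = generate_ideal_data("social", cons, net, rng)
            social = fit_tadac(data, "social")
            asocial = fit_tadac(data, "asocial")
            deltas.append(delta_aicc(social, asocial)[0])
            s_hats.append(social.s_hat)
        assert np.median(deltas) > 5
        assert np.mean(np.array(deltas) > 0) > 0.9
        assert 5.0 / 2.5 < np.median(s_hats) < 5.0 * 2.5


class TestDeltaAicc:
    def test_positive_supports_social(self):
        soc = NBDAFit("social", 0.1, 1.0, -45.0, 2, 100.0)
        aso = NBDAFit("asocial", 0.1, None, -53.0, 1, 110.0)
        assert delta_aicc(soc, aso) == (10.0, "social")

    def test_tie_is_not_support(self):
        soc = NBDAFit("social", 0.1, 1.0, -49.0, 2, 105.0)
        aso = NBDAFit("asocial", 0.1, None, -51.0, 1, 105.0)
        assert delta_aicc(soc, aso)[1] == "asocial"


class TestDataGeneration:
    def test_ideal_social_neighbours_of_seed_acquire_sooner(self):
        cons = reference_constellation()
        nb_times, far_times = [], []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            net = generate_random_regular(24, 6, rng_seed=seed)
            data = generate_ideal_data("social", cons, net, rng)
            (seed_agent,) = data.demonstrators
            nbs = net.adjacency[seed_agent].astype(bool)
            times = data.event_times
            nb_times.extend(times[nbs & ~np.isnan(times)])
            far = ~nbs & ~np.isnan(times)
            far_times.extend(times[far])
        assert np.mean(nb_times) < np.mean(far_times)

    def test_ideal_asocial_all_agents_are_events(self):
        rng = np.random.default_rng(0)
        net = generate_random_regular(24, 6, rng_seed=0)
        data = generate_ideal_data("asocial", reference_constellation(), net, rng)
        assert data.n_events == 24
        assert data.demonstrators == frozenset()

    def test_realistic_weights_are_observed_production_rates(self):
        rng = np.random.default_rng(3)
        net = generate_random_regular(24, 6, rng_seed=3)
        data, rec = generate_realistic_data(
            "social", reference_constellation(), net, rng, return_record=True
        )
        T = rec.history.n_timesteps
        expected = rec.history.codes.sum(axis=0) / (T - np.maximum(rec.t_a, 1.0) + 1.0)
        assert np.allclose(data.weights, expected)
        assert ((0 <= data.weights) & (data.weights <= 1)).all()
        # events are first productions, which follow acquisition
        assert (rec.t_p >= rec.t_a + 1).all()
        assert np.isnan(data.event_times[rec.seed_agent])
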