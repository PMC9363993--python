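"""Behavioural acquisition: the social-transmission hazard sub-model.

Each timestep every naive agent (one that only knows the established
behaviour ``a``) may acquire the novel behaviour ``b``. The per-timestep
probability follows a network-based diffusion hazard,

    P(acquire at t) = 1 - exp(-lambda_b * (T_i(t) + A)),

where A in {0, 1} switches asocial innovation and the transmission function
T_i(t) = s * sum_j a_ij * w_bj(t) accumulates, over network neighbours j,
the proportion w_bj of the last m timesteps in which j produced ``b``.
Knowledge therefore spreads strictly along edges and only from agents who
actually perform the behaviour.
"""

from __future__ import annotations

import numpy as np

from .network import SocialNetwork
from .params import AcquisitionParams
from .production import ProductionHistory

__all__ = [
    "transmission_weight",
    "transmission_weights",
    "transmission_function",
    "acquisition_probability",
    "acquisition_step",
]


def transmission_weight(agent: int, history: ProductionHistory, t: int, m: int) -> float:
    """Proportion of the last ``m`` timesteps in which ``agent`` produced b."""
    if t < 1:
        raise ValueError("t must be >= 1")
    return float(history.b_counts(t, m)[agent]) / m


def transmission_weights(history: ProductionHistory, t: int, m: int) -> np.ndarray:
    """Vector of w_bj(t) for all agents (0 for agents that never produced b)."""
    return history.b_counts(t, m) / m


def transmission_function(
    agent: int, net: SocialNetwork, weights: np.ndarray, s: float
) -> float:
    """T_i(t) = s * sum over neighbours j of w_bj(t)."""
    if s < 0:
        raise ValueError("s must be >= 0")
    return float(s * net.adjacency[agent].astype(float) @ np.asarray(weights, float))


def acquisition_probability(T: float, lambda_b: float, asocial: int) -> float:
    """1 - exp(-lambda_b (T + A)); in [0, 1), increasing in T."""
    if T < 0:
        raise ValueError("T must be >= 0")
    if lambda_b <= 0:
        raise ValueError("lambda_b must be > 0")
    return float(-np.expm1(-lambda_b * (T + asocial)))


def acquisition_step(
    knows_b: np.ndarray,
    net: SocialNetwork,
    history: ProductionHistory,
    t: int,
    acq: AcquisitionParams,
    m: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One synchronous round of acquisition draws.

    Every naive agent makes an independent Bernoulli trial with its hazard
    computed from the production history strictly before ``t``. Returns the
    boolean mask of agents acquiring b at ``t`` (callers update repertoires,
    setting the novel behaviour's expected value to 0). One uniform is drawn
    per agent regardless of knowledge state so that the stream of random
    numbers does not depend on who is already knowledgeable.
    """
    knows_b = np.asarray(knows_b, dtype=bool)
    w = transmission_weights(history, t, m)
    T = acq.s * (net.adjacency @ w)
    p = -np.expm1(-acq.lambda_b * (T + acq.asocial))
    draws = rng.random(knows_b.shape[0]) < p
    return draws & ~knows_b
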