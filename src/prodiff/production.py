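"""Behavioural production: value updating, softmax choice and social influence.

Each timestep an agent produces exactly one behaviour from its repertoire
(the established behaviour ``a``, and ``b`` once acquired). The choice mixes

* an *individual* component: expected values learned by reinforcement
  (exponentially weighted by the recent-experience bias ``rho``) passed
  through a softmax with risk-appetite ``alpha``; and
* a *social* component: counts of each known behaviour produced by network
  neighbours within the last ``m`` timesteps, raised to the
  frequency-dependence exponent ``f`` and normalized,

combined with weight ``sigma`` on the social component.

The module exposes both the per-agent, dict-based operations (the documented
contract, convenient for small examples) and the array versions the
simulation engine uses for whole-population updates; the dict operations are
thin wrappers over the array code so there is a single source of truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import SocialNetwork

__all__ = [
    "BEHAVIOURS",
    "AgentState",
    "ProductionHistory",
    "update_expected_value",
    "individual_probabilities",
    "frequency_weights",
    "social_frequencies",
    "production_probabilities",
    "choose_behaviour",
    "softmax_array",
    "frequency_weights_array",
]

#: Behaviour labels: index 0 is the established behaviour, 1 the novel one.
BEHAVIOURS = ("a", "b")


@dataclass
class AgentState:
    """Repertoire, expected values and acquisition time of one agent.

    ``a`` is always in the repertoire; ``b`` enters at acquisition with an
    expected value of 0 (reward is only ever experienced personally).
    """

    repertoire: set = field(default_factory=lambda: {"a"})
    expected_value: dict = field(default_factory=lambda: {"a": 1.0})
    knowledgeable_since: int | None = None

    @property
    def knows_b(self) -> bool:
        return "b" in self.repertoire

    def acquire_b(self, t: int) -> None:
        self.repertoire.add("b")
        self.expected_value["b"] = 0.0
        self.knowledgeable_since = t


class ProductionHistory:
    """Timestep x agent record of produced behaviours.

    Stored as an int8 matrix of behaviour codes (0 = ``a``, 1 = ``b``); row
    ``t-1`` holds the productions of (1-based) timestep ``t``. Exactly one
    behaviour is recorded per agent per timestep.
    """

    def __init__(self, codes: np.ndarray):
        codes = np.asarray(codes, dtype=np.int8)
        if codes.ndim != 2:
            raise ValueError("history must be a (timesteps, agents) matrix")
        if not np.isin(codes, (0, 1)).all():
            raise ValueError("behaviour codes must be 0 (a) or 1 (b)")
        self.codes = codes

    @property
    def n_timesteps(self) -> int:
        return self.codes.shape[0]

    @property
    def n_agents(self) -> int:
        return self.codes.shape[1]

    def window(self, t: int, m: int) -> np.ndarray:
        """Rows for timesteps ``t-m .. t-1``: the last ``m`` completed steps
        strictly before the decision at ``t`` (truncated at the start)."""
        return self.codes[max(0, t - 1 - m) : max(0, t - 1)]

    def b_counts(self, t: int, m: int) -> np.ndarray:
        """Per-agent number of productions of ``b`` within the window."""
        return self.window(t, m).sum(axis=0, dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (timestep, agent, behaviour)."""
        t, i = np.indices(self.codes.shape)
        return pd.DataFrame(
            {
                "timestep": t.ravel() + 1,
                "agent": i.ravel(),
                "behaviour": np.take(BEHAVIOURS, self.codes.ravel()),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ProductionHistory":
        df = pd.read_csv(path)
        n_t, n_a = df["timestep"].max(), df["agent"].max() + 1
        codes = np.zeros((n_t, n_a), dtype=np.int8)
        codes[df["timestep"] - 1, df["agent"]] = (df["behaviour"] == "b").astype(np.int8)
        return cls(codes)


# -- array kernels (used by the engine) ---------------------------------


def softmax_array(expected: np.ndarray, alpha: float) -> np.ndarray:
    """Row-wise softmax of expected values at inverse temperature 1/alpha.

    ``expected`` rows may contain ``-inf`` for behaviours outside the
    repertoire, which receive probability 0.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    x = np.exp(np.asarray(expected, dtype=float) / alpha)
    return x / x.sum(axis=-1, keepdims=True)


def frequency_weights_array(
    counts: np.ndarray, f: float, in_repertoire: np.ndarray
) -> np.ndarray:
    """Frequency-dependent social weights from neighbour production counts.

    ``counts`` is (N, 2) observation counts; behaviours outside an agent's
    repertoire are invisible (their column is masked to 0 before weighting).
    0**f is taken as 0 for all f > 0; if every in-repertoire count is zero
    there is no social signal and the weights fall back to the uniform
    distribution over the repertoire.
    """
    if f <= 0:
        raise ValueError("f must be > 0")
    counts = np.asarray(counts, dtype=float) * in_repertoire
    w = counts**f
    tot = w.sum(axis=-1, keepdims=True)
    rep_size = in_repertoire.sum(axis=-1, keepdims=True)
    uniform = in_repertoire / rep_size
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(tot > 0, w / np.where(tot > 0, tot, 1.0), uniform)
    return out


# -- dict-based operations (per-agent contract) -------------------------


def update_expected_value(e_prev: float, reward: float, rho: float) -> float:
    """One step of the exponentially weighted value update.

    E(t) = rho * r(t-1) + (1 - rho) * E(t-1); the reward is the behaviour's
    payoff if it was produced last timestep and 0 otherwise, so values of
    unproduced behaviours decay geometrically (information loss over time).
    """
    if not 0.0 < rho < 1.0:
        raise ValueError("rho must lie in (0, 1)")
    return rho * reward + (1.0 - rho) * e_prev


def individual_probabilities(expected: dict, alpha: float = 1.0) -> dict:
    """Softmax over the repertoire's expected values.

    Strictly positive for every known behaviour, so a zero-valued behaviour
    can still be produced (production without prior experience).
    """
    if not expected:
        raise ValueError("repertoire must be non-empty")
    keys = list(expected)
    probs = softmax_array(np.array([expected[k] for k in keys]), alpha)
    return dict(zip(keys, probs.tolist()))


def frequency_weights(counts: dict, f: float) -> dict:
    """Normalize observation counts raised to the power ``f``."""
    keys = list(counts)
    arr = np.array([counts[k] for k in keys], dtype=float)
    w = frequency_weights_array(arr, f, np.ones_like(arr))
    return dict(zip(keys, w.tolist()))


def social_frequencies(
    agent: int,
    net: SocialNetwork,
    history: ProductionHistory,
    t: int,
    m: int,
    f: float,
    repertoire: set,
) -> dict:
    """Social weights for one agent from its neighbours' recent productions.

    Counts each in-repertoire behaviour produced by network neighbours in
    the ``m`` timesteps before ``t``, then applies the frequency bias.
    Behaviours the agent cannot produce are invisible to it.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    window = history.window(t, m)
    adj_row = net.adjacency[agent].astype(bool)
    counts = {}
    for code, label in enumerate(BEHAVIOURS):
        if label in repertoire:
            counts[label] = int((window[:, adj_row] == code).sum())
    return frequency_weights(counts, f)


def production_probabilities(individual: dict, social: dict, sigma: float) -> dict:
    """Mix individual and social components: P = (1-sigma) I + sigma S."""
    if set(individual) != set(social):
        raise ValueError("individual and social maps must share a behaviour set")
    if not 0.0 <= sigma <= 1.0:
        raise ValueError("sigma must lie in [0, 1]")
    return {k: (1.0 - sigma) * individual[k] + sigma * social[k] for k in individual}


def choose_behaviour(probabilities: dict, rng: np.random.Generator) -> str:
    """Single categorical draw from a production-probability map."""
    keys = list(probabilities)
    p = np.array([probabilities[k] for k in keys], dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("probabilities must sum to 1")
    return keys[rng.choice(len(keys), p=p / p.sum())]
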