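"""Simulation engine linking the acquisition and production sub-models.

Each (1-based) timestep:

1. every agent updates its expected values from the reward it received at
   ``t - 1`` (unproduced behaviours receive reward 0);
2. every agent produces one behaviour from its repertoire, mixing its
   softmaxed expected values with frequency-biased social observation of
   the last ``m`` completed timesteps;
3. every naive agent makes an acquisition draw, with a hazard driven by how
   often its neighbours produced the novel behaviour over those same ``m``
   completed timesteps. An agent acquiring at ``t`` enters with expected
   value 0 for the novel behaviour and can produce it from ``t + 1``
   (within-step productions are not observable until the following step).

The default run starts with all agents knowing only the established
behaviour ``a`` (expected value 1) plus one randomly chosen seed agent that
also knows ``b``, and stops once every agent has both acquired and produced
``b`` at least once.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .network import SocialNetwork, generate_random_regular
from .params import Constellation
from .production import ProductionHistory

__all__ = ["SimulationRecord", "run_simulation", "rank_events", "jitter_times"]

#: Hard cap on simulation length; runs hitting it are flagged, not raised.
MAX_TIMESTEPS = 10_000


@dataclass
class SimulationRecord:
    """Complete record of one simulated diffusion."""

    t_a: np.ndarray  # per-agent acquisition timestep (seed agent: 0; NaN if never)
    t_p: np.ndarray  # per-agent first-production timestep (NaN if never)
    o_a: np.ndarray | None  # acquisition ranks 1..N (None if not all acquired)
    o_p: np.ndarray | None  # first-production ranks 1..N (None if not all produced)
    history: ProductionHistory
    net: SocialNetwork
    seed_agent: int | None
    constellation: Constellation
    rng_seed: int | None
    ttd: float  # max acquisition time
    ttfp: float  # max first-production time
    converged: bool
    prob_b: np.ndarray | None = None  # (T, N) production probabilities of b, if recorded

    @property
    def n_agents(self) -> int:
        return self.t_a.shape[0]

    def acquisition_intervals(self) -> np.ndarray:
        """Gaps between successive acquisition events (sorted times)."""
        times = np.sort(self.t_a[~np.isnan(self.t_a)])
        return np.diff(times)

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "agent": np.arange(self.n_agents),
                "time_of_acquisition": self.t_a,
                "time_of_first_production": self.t_p,
                "order_of_acquisition": self.o_a if self.o_a is not None else np.nan,
                "order_of_first_production": self.o_p if self.o_p is not None else np.nan,
            }
        )

    def export(self, directory, prefix: str = "run") -> None:
        """Write events and production history as CSV files."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.events_frame().to_csv(directory / f"{prefix}_events.csv", index=False)
        self.history.to_csv(directory / f"{prefix}_history.csv")


def rank_events(times: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Ranks 1..N of event times; simultaneous events get distinct ranks by
    uniform random tie-breaking (deterministic under the supplied rng)."""
    times = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(times)):
        raise ValueError("all event times must be finite")
    order = np.lexsort((rng.random(times.shape[0]), times))
    ranks = np.empty_like(order)
    ranks[order] = np.arange(1, times.shape[0] + 1)
    return ranks


def jitter_times(
    times: np.ndarray, rng: np.random.Generator, scale: float = 1e-6
) -> np.ndarray:
    """Break event-time ties into distinct continuous times.

    Events recorded at the same integer timestep receive i.i.d. uniform
    offsets of negligible width ``scale``, so their relative order is
    uniformly random (matching the rank tie-breaking convention) while the
    times themselves stay at the recorded timestep: simultaneous events are
    separated by effectively zero-duration intervals rather than being
    smeared across the step.
    """
    times = np.asarray(times, dtype=float)
    return times + scale * rng.random(times.shape[0])


def run_simulation(
    constellation: Constellation,
    net: SocialNetwork | None = None,
    rng_seed: int | None = 0,
    stop: str = "complete",
    horizon: int | None = None,
    seed_agent: bool | int = True,
    homogeneous_start: bool = False,
    record_probs: bool = False,
    order: str = "produce_first",
    rng: np.random.Generator | None = None,
) -> SimulationRecord:
    """Run one linked acquisition-production simulation.

    Parameters
    ----------
    stop
        ``"complete"`` (default): run until every agent has acquired *and*
        produced the novel behaviour at least once. ``"horizon"``: run
        exactly ``horizon`` timesteps. ``"twice_ttd"``: run until twice the
        time-to-diffusion, so the record holds equal spans of during- and
        post-diffusion data.
    seed_agent
        ``True``: one uniformly chosen agent knows ``b`` from the start
        (acquisition time 0). ``False``: nobody does (requires asocial
        innovation, A=1, for the behaviour to ever appear). An integer pins
        the seed agent explicitly.
    homogeneous_start
        All agents start knowing both behaviours with expected values 1
        (stationary start for pure production dynamics; no acquisition
        happens). Used for production-only scenarios.

    order
        Within-timestep ordering. ``"produce_first"`` (default): all agents
        produce, then naive agents make acquisition draws, so an agent
        acquiring at ``t`` first produces the novel behaviour at ``t + 1``.
        ``"acquire_first"``: acquisition draws precede production, so an
        agent acquiring at ``t`` may already produce it at ``t``. In both
        orderings the acquisition hazard is driven by the ``m`` completed
        timesteps strictly before ``t``.

    Runs that fail to meet their stopping rule within ``MAX_TIMESTEPS`` are
    returned with ``converged=False`` rather than raising (e.g. A=0, s=0:
    the seed's knowledge can never spread).
    """
    if stop not in ("complete", "horizon", "twice_ttd"):
        raise ValueError(f"unknown stop rule {stop!r}")
    if order not in ("acquire_first", "produce_first"):
        raise ValueError(f"unknown within-timestep order {order!r}")
    if stop == "horizon" and not horizon:
        raise ValueError("stop='horizon' requires a horizon")
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    N = constellation.n_agents
    if net is None:
        net = generate_random_regular(N, constellation.degree, int(rng.integers(2**31)))
    if net.n_agents != N:
        raise ValueError("network size does not match the constellation")
    adj = net.adjacency.astype(float)
    prod = constellation.production
    acq = constellation.acquisition
    m, rho, alpha, sigma, f = prod.m, prod.rho, prod.alpha, prod.sigma, prod.f
    rewards = np.array([constellation.r_a, constellation.r_b])

    knows = np.zeros(N, dtype=bool)
    t_a = np.full(N, np.nan)
    t_p = np.full(N, np.nan)
    E = np.zeros((N, 2))
    E[:, 0] = constellation.r_a
    seed: int | None = None
    if homogeneous_start:
        knows[:] = True
        t_a[:] = 0.0
        E[:, 1] = constellation.r_b
    elif seed_agent is not False:
        seed = int(rng.integers(N)) if seed_agent is True else int(seed_agent)
        knows[seed] = True
        t_a[seed] = 0.0
        E[seed, 1] = 0.0

    cap = MAX_TIMESTEPS if stop != "horizon" else int(horizon)
    codes = np.zeros((min(cap, 512), N), dtype=np.int8)
    probs = np.zeros_like(codes, dtype=float) if record_probs else None
    ttd_seen: float | None = None
    converged = False
    t = 0
    while t < cap:
        t += 1
        if t - 1 >= codes.shape[0]:  # grow storage
            codes = np.vstack([codes, np.zeros_like(codes)])
            if probs is not None:
                probs = np.vstack([probs, np.zeros_like(probs)])
        # value update from rewards at t-1
        if t > 1:
            produced_b = codes[t - 2].astype(bool)
            r_now = np.where(produced_b[:, None], [[0.0, 1.0]], [[1.0, 0.0]]) * rewards
            newE = rho * r_now + (1.0 - rho) * E
            E[:, 0] = newE[:, 0]
            E[knows, 1] = newE[knows, 1]

        def do_acquisition(window_end: int) -> None:
            """Acquisition draws from the m timesteps ending at window_end."""
            u_acq = rng.random(N)
            if knows.all():
                return
            b_cnt = codes[max(0, window_end - m) : window_end].sum(axis=0, dtype=np.int64)
            w = b_cnt / m
            T_i = acq.s * (adj @ w)
            p_acq = -np.expm1(-acq.lambda_b * (T_i + acq.asocial))
            acquired = (u_acq < p_acq) & ~knows
            if acquired.any():
                knows[acquired] = True
                t_a[acquired] = t
                E[acquired, 1] = 0.0

        def do_production() -> None:
            window = codes[max(0, t - 1 - m) : t - 1]
            b_cnt = window.sum(axis=0, dtype=np.int64)
            x = np.exp(E / alpha)
            x[~knows, 1] = 0.0
            I_b = x[:, 1] / (x[:, 0] + x[:, 1])
            L = window.shape[0]
            Cb = adj @ b_cnt
            Ca = adj @ (L - b_cnt).astype(float)
            Cb = np.where(knows, Cb, 0.0)  # behaviour b invisible to naive agents
            Wa, Wb = Ca**f, Cb**f
            tot = Wa + Wb
            S_b = np.where(
                tot > 0, Wb / np.where(tot > 0, tot, 1.0), np.where(knows, 0.5, 0.0)
            )
            P_b = (1.0 - sigma) * I_b + sigma * S_b
            choose_b = rng.random(N) < P_b
            codes[t - 1] = choose_b
            if probs is not None:
                probs[t - 1] = P_b
            first = choose_b & np.isnan(t_p)
            t_p[first] = t

        if order == "acquire_first":
            do_acquisition(t - 1)
            do_production()
        else:
            do_production()
            do_acquisition(t - 1)

        # stopping rules
        if knows.all() and ttd_seen is None:
            ttd_seen = float(np.nanmax(t_a))
        if stop == "complete":
            if ttd_seen is not None and not np.isnan(t_p).any():
                converged = True
                break
        elif stop == "twice_ttd":
            if ttd_seen is not None and t >= 2 * ttd_seen:
                converged = True
                break
        elif stop == "horizon" and t == horizon:
            converged = True
            break

    history = ProductionHistory(codes[:t])
    all_acquired = not np.isnan(t_a).any()
    all_produced = not np.isnan(t_p).any()
    o_a = rank_events(t_a, rng) if all_acquired else None
    o_p = rank_events(t_p, rng) if all_produced else None
    return SimulationRecord(
        t_a=t_a,
        t_p=t_p,
        o_a=o_a,
        o_p=o_p,
        history=history,
        net=net,
        seed_agent=seed,
        constellation=constellation,
        rng_seed=rng_seed,
        ttd=float(np.nanmax(t_a)) if all_acquired else float("nan"),
        ttfp=float(np.nanmax(t_p)) if all_produced else float("nan"),
        converged=converged,
        prob_b=probs[:t] if probs is not None else None,
    )
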