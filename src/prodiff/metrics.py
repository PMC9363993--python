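"""Diffusion statistics: tempo, divergence and delay.

Tempo is summarized by time-to-diffusion (TTD, last acquisition) and
time-to-first-production (TTFP, last first-production). Divergence compares
the *order* in which agents acquired the novel behaviour with the order in
which they first produced it; delay compares the corresponding *times*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .engine import SimulationRecord

__all__ = [
    "DiffusionMetrics",
    "order_divergence",
    "time_delay",
    "pct_divergent",
    "r2_orders",
    "summarize",
    "compute_metrics",
]


def _check_permutation(o: np.ndarray) -> np.ndarray:
    o = np.asarray(o)
    n = o.shape[0]
    if not np.array_equal(np.sort(o), np.arange(1, n + 1)):
        raise ValueError("ranks must be a permutation of 1..N")
    return o


def order_divergence(
    o_a: np.ndarray, o_p: np.ndarray, seed_agent: int | None = None
) -> float:
    """Mean Manhattan distance between acquisition and first-production ranks.

    d_order = (1 / (N-1)) * sum_i |o_a(i) - o_p(i)|, excluding the seed
    agent's first production (rank 1 by construction under purely social
    diffusion, so its term is 0 there anyway); the divisor is N - 1.
    """
    o_a = _check_permutation(o_a)
    o_p = _check_permutation(o_p)
    if o_a.shape != o_p.shape:
        raise ValueError("rank vectors must have equal length")
    diff = np.abs(o_a - o_p).astype(float)
    if seed_agent is not None:
        diff[seed_agent] = 0.0
    return float(diff.sum() / (o_a.shape[0] - 1))


def time_delay(t_a: np.ndarray, t_p: np.ndarray) -> float:
    """Mean absolute delay between acquisition and first production,
    d_time = (1/N) * sum_i |t_a(i) - t_p(i)|."""
    t_a = np.asarray(t_a, float)
    t_p = np.asarray(t_p, float)
    if t_a.shape != t_p.shape:
        raise ValueError("time vectors must have equal length")
    return float(np.abs(t_a - t_p).mean())


def pct_divergent(o_a: np.ndarray, o_p: np.ndarray) -> float:
    """Fraction of agents whose first-production rank differs from their
    acquisition rank."""
    o_a = _check_permutation(o_a)
    o_p = _check_permutation(o_p)
    return float(np.mean(o_a != o_p))


def r2_orders(o_a: np.ndarray, o_p: np.ndarray) -> float:
    """Coefficient of determination of the least-squares fit of
    first-production rank on acquisition rank (agent-level pairs, typically
    pooled across replicate runs)."""
    o_a = np.asarray(o_a, float).ravel()
    o_p = np.asarray(o_p, float).ravel()
    if o_a.std() == 0 or o_p.std() == 0:
        raise ValueError("degenerate rank variance")
    res = stats.linregress(o_a, o_p)
    return float(res.rvalue**2)


def summarize(values, level: float = 0.92) -> dict:
    """Mean, standard error and central percentile interval of a sample.

    The interval takes the empirical (1-level)/2 and 1-(1-level)/2
    quantiles with linear interpolation (e.g. the 4th and 96th percentiles
    at the default 92% level).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty sample")
    tail = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(arr, [tail, 100.0 - tail])
    return {
        "mean": float(arr.mean()),
        "se": float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0,
        "pi_low": float(lo),
        "pi_high": float(hi),
    }


@dataclass(frozen=True)
class DiffusionMetrics:
    """Per-run diffusion statistics."""

    ttd: float
    ttfp: float
    d_order: float
    d_time: float
    pct_divergent: float
    acquisition_intervals: np.ndarray

    def as_dict(self) -> dict:
        return {
            "ttd": self.ttd,
            "ttfp": self.ttfp,
            "d_order": self.d_order,
            "d_time": self.d_time,
            "pct_divergent": self.pct_divergent,
        }


def compute_metrics(record: SimulationRecord) -> DiffusionMetrics:
    """Diffusion statistics of one completed simulation record."""
    if record.o_a is None or record.o_p is None:
        raise ValueError("record is incomplete; diffusion metrics undefined")
    return DiffusionMetrics(
        ttd=record.ttd,
        ttfp=record.ttfp,
        d_order=order_divergence(record.o_a, record.o_p, record.seed_agent),
        d_time=time_delay(record.t_a, record.t_p),
        pct_divergent=pct_divergent(record.o_a, record.o_p),
        acquisition_intervals=record.acquisition_intervals(),
    )
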