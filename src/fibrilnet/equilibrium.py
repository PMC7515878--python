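"""Equilibrium ERGM distribution over aggregation graphs.

Two routes to the Boltzmann distribution Pr(G=g) ∝ exp(theta . t(g)) h(g):

* :func:`brute_force_distribution` enumerates every labeled graph on a tiny
  vertex set (n <= 5) and normalizes exactly — the oracle.
* :func:`mcmc_sample` runs Metropolis–Hastings over uniform single-dyad
  toggles, whose stationary distribution is the same Boltzmann form.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .graph import AggregationGraph, Edge
from .model import ModelParams
from .stats import change_stats, hamiltonian

#: enumeration guard: 2^C(n,2) microstates
MAX_BRUTE_FORCE_N = 5

GraphState = frozenset  # frozenset of (u, v) edges with u < v


def all_dyads(n: int) -> list[Edge]:
    return [(u, v) for u in range(n) for v in range(u + 1, n)]


def enumerate_graphs(n: int):
    """Yield every labeled simple graph on n vertices as an edge frozenset."""
    dyads = all_dyads(n)
    for r in range(len(dyads) + 1):
        for combo in itertools.combinations(dyads, r):
            yield frozenset(combo)


@dataclass
class GraphDistribution:
    """Exact probability mass function over graph microstates on n vertices."""

    n: int
    states: list[GraphState]
    probs: np.ndarray

    def __post_init__(self):
        total = float(self.probs.sum())
        if not math.isclose(total, 1.0, abs_tol=1e-12):
            raise ValueError(f"probabilities sum to {total}, not 1")
        if (self.probs < 0).any():
            raise ValueError("negative probability")
        self._index = {s: i for i, s in enumerate(self.states)}

    def prob(self, state) -> float:
        """Probability of a microstate (edge frozenset or AggregationGraph)."""
        if isinstance(state, AggregationGraph):
            state = state.edge_set()
        return float(self.probs[self._index[frozenset(state)]])

    def total_variation(self, other_probs: dict) -> float:
        """TV distance to an empirical distribution {state: frequency}."""
        tv = 0.0
        for s, p in zip(self.states, self.probs):
            tv += abs(p - other_probs.get(s, 0.0))
        # states outside the support cannot occur here (support is complete)
        return 0.5 * tv


def brute_force_distribution(n: int, params: ModelParams) -> GraphDistribution:
    """Exact equilibrium distribution by full enumeration (n <= 5)."""
    if n > MAX_BRUTE_FORCE_N:
        raise ValueError(
            f"n={n} has 2^{n * (n - 1) // 2} microstates; brute force is "
            f"limited to n <= {MAX_BRUTE_FORCE_N}"
        )
    states = list(enumerate_graphs(n))
    beta = params.beta
    logw = np.empty(len(states))
    for i, s in enumerate(states):
        g = AggregationGraph(n, s)
        logw[i] = -beta * hamiltonian(g, params) + params.log_h(g)
    logw -= logw.max()
    w = np.exp(logw)
    return GraphDistribution(n, states, w / w.sum())


def mcmc_sample(
    n: int,
    params: ModelParams,
    steps: int,
    seed: int,
    thin: int = 1,
    burn_in: int | None = None,
) -> list[GraphState]:
    """Metropolis–Hastings sample of aggregation-graph microstates.

    Proposal: uniform random dyad toggle.  Acceptance:
    ``min(1, exp(-beta * dH + d log h))``.  Identical seeds give identical
    output sequences.

    Parameters
    ----------
    steps : total Markov-chain steps (>= 1).
    thin : record every ``thin``-th post-burn-in state.
    burn_in : steps discarded from the front; default 10% of ``steps``.

    Returns
    -------
    list of edge frozensets (use :class:`AggregationGraph` to materialize).
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if burn_in is None:
        burn_in = steps // 10
    rng = np.random.default_rng(seed)
    dyads = all_dyads(n)
    g = AggregationGraph(n)
    beta = params.beta
    coeffs = params.coeffs
    counting = params.counting_measure

    out: list[GraphState] = []
    for step in range(steps):
        u, v = dyads[rng.integers(len(dyads))]
        log_ratio = -beta * float(np.dot(coeffs, change_stats(g, u, v)))
        if not counting:
            lh0 = params.log_h(g)
            g.toggle_edge(u, v)
            log_ratio += params.log_h(g) - lh0
            g.toggle_edge(u, v)
        if log_ratio >= 0 or rng.random() < math.exp(log_ratio):
            g.toggle_edge(u, v)
        if step >= burn_in and (step - burn_in) % thin == 0:
            out.append(g.edge_set())
    return out


def empirical_distribution(samples: list[GraphState]) -> dict:
    """Relative frequency of each microstate in a sample sequence."""
    counts: dict = {}
    for s in samples:
        counts[s] = counts.get(s, 0) + 1
    total = len(samples)
    return {s: c / total for s, c in counts.items()}
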