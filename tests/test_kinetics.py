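"""Kinetic rates, transition distributions, and Gillespie simulation."""

import math

import numpy as np
import pytest

from fibrilnet import (
    AggregationGraph,
    ModelParams,
    brute_force_distribution,
    energy_delta,
    occupancy_by_state,
    simulate,
    transition_distribution,
    transition_rate,
)


def test_rate_is_half_collision_frequency_at_zero_barrier():
    """dH = 0, dS = 0 gives exactly A/2."""
    p = ModelParams(phi_e=-1.0, A=3.0)  # edge coefficient vanishes
    g = AggregationGraph(2)
    assert transition_rate(g, (0, 1), p) == pytest.approx(1.5)


def test_rate_quarter_when_exponent_is_ln3():
    """beta*dH = ln 3 gives r = A / (1 + 3) = A/4."""
    p = ModelParams(phi_e=math.log(3.0) - 1.0, A=1.0)
    g = AggregationGraph(2)
    assert transition_rate(g, (0, 1), p) == pytest.approx(0.25)


@pytest.mark.parametrize("barrier", [7.0, 9.0, 14.0])
def test_rate_reduces_to_arrhenius_for_uphill_barriers(barrier):
    """For beta*dH >= 7 the rate matches A*exp(-beta*Ea) within 1%."""
    p = ModelParams(phi_e=barrier - 1.0, A=2.0)
    g = AggregationGraph(2)
    r = transition_rate(g, (0, 1), p)
    arrhenius = p.A * math.exp(-p.beta * barrier)
    assert r == pytest.approx(arrhenius, rel=0.01)


def test_rate_ratio_identity(params, rng):
    """r_ij / r_ji = exp(-beta*dH) for every dyad toggle."""
    from oracles import random_graph

    for _ in range(25):
        g = random_graph(6, 0.4, rng)
        u, v = sorted(rng.choice(6, size=2, replace=False))
        r_fwd = transition_rate(g, (u, v), params)
        h = g.copy()
        h.toggle_edge(u, v)
        r_back = transition_rate(h, (u, v), params)
        expected = math.exp(-params.beta * energy_delta(g, int(u), int(v), params))
        assert r_fwd / r_back == pytest.approx(expected, rel=1e-12)


def test_rates_bounded_by_collision_frequency(params, rng):
    from oracles import random_graph

    for _ in range(10):
        g = random_graph(7, 0.5, rng)
        total, probs = transition_distribution(g, params)
        assert total > 0
        assert sum(probs.values()) == pytest.approx(1.0)
        for d, pr in probs.items():
            r = pr * total
            assert 0.0 < r < params.A


def test_transition_distribution_two_monomers(params):
    total, probs = transition_distribution(AggregationGraph(2), params)
    assert probs == {(0, 1): pytest.approx(1.0)}


def test_transition_distribution_symmetric_on_empty_graph(params):
    """From free monomers all C(n,2) bond formations are equiprobable."""
    n = 6
    _, probs = transition_distribution(AggregationGraph(n), params)
    expected = 1.0 / (n * (n - 1) / 2)
    assert all(pr == pytest.approx(expected) for pr in probs.values())


def test_transition_distribution_needs_two_vertices(params):
    with pytest.raises(ValueError):
        transition_distribution(AggregationGraph(1), params)


def test_trajectory_starts_empty_with_increasing_times(params):
    traj = simulate(5, params, seed=3, max_events=400, frame_interval=100)
    assert traj.frames[0].event_index == 0
    assert traj.frames[0].edges == frozenset()
    times = [ev.time for ev in traj.events]
    assert all(t2 > t1 for t1, t2 in zip(times, times[1:]))
    assert times[0] > 0


def test_waiting_times_have_mean_inverse_exit_rate(params):
    """Empirical sojourn mean in the empty two-monomer state ~ 1/R."""
    traj = simulate(2, params, seed=9, max_events=30000)
    total, _ = transition_distribution(AggregationGraph(2), params)
    waits = []
    t_prev = 0.0
    bonded = False
    for ev in traj.events:
        if not bonded:  # sojourn in the empty state just ended
            waits.append(ev.time - t_prev)
        t_prev = ev.time
        bonded = not bonded
    waits = np.array(waits)
    assert len(waits) >= 10_000
    se = waits.std(ddof=1) / math.sqrt(len(waits))
    assert abs(waits.mean() - 1.0 / total) < 3 * se


def test_two_state_occupancy_matches_boltzmann(params):
    """Time-weighted bond occupancy at n=2 equals the two-state equilibrium."""
    traj = simulate(2, params, seed=21, max_events=30000)
    occ = occupancy_by_state(traj)
    d = brute_force_distribution(2, params)
    bonded = frozenset([(0, 1)])
    p_hat = occ.get(bonded, 0.0)
    # batch-means standard error over 10 equal-time batches
    batches = _batched_occupancy(traj, bonded, 10)
    se = batches.std(ddof=1) / math.sqrt(len(batches))
    assert abs(p_hat - d.prob(bonded)) < 3 * se


def _batched_occupancy(traj, state, k):
    end = traj.duration
    edges = []
    t_prev = 0.0
    cur = frozenset()
    spans = []  # (start, end, state)
    g_edges = set()
    for ev in traj.events:
        spans.append((t_prev, ev.time, frozenset(g_edges)))
        e = (min(ev.u, ev.v), max(ev.u, ev.v))
        if e in g_edges:
            g_edges.discard(e)
        else:
            g_edges.add(e)
        t_prev = ev.time
    spans.append((t_prev, end, frozenset(g_edges)))
    out = []
    for i in range(k):
        lo, hi = end * i / k, end * (i + 1) / k
        occ = 0.0
        for s, e, st in spans:
            if st == state:
                occ += max(0.0, min(e, hi) - max(s, lo))
        out.append(occ / (hi - lo))
    return np.array(out)


def test_kinetic_chain_stationary_distribution_is_boltzmann(params):
    """Time-weighted occupancy on n=3 vs exact enumeration (TV < 0.03)."""
    traj = simulate(3, params, seed=14, max_events=40000)
    tv = brute_force_distribution(3, params).total_variation(
        occupancy_by_state(traj)
    )
    assert tv < 0.03


def test_incremental_and_naive_rates_agree_event_for_event(params):
    a = simulate(12, params, seed=8, max_events=600, method="incremental")
    b = simulate(12, params, seed=8, max_events=600, method="naive")
    assert a.events == b.events


def test_incremental_agrees_with_cycle_heavy_parameters():
    """Cycle terms reach farthest; the rate cache must still be exact."""
    p = ModelParams(phi_e=-1.2, phi_C5=-0.6, phi_C6=0.4, phi_C7=-0.3, phi_2s=0.5)
    a = simulate(10, p, seed=77, max_events=500, method="incremental")
    b = simulate(10, p, seed=77, max_events=500, method="naive")
    assert a.events == b.events


def test_max_time_stopping(params):
    traj = simulate(4, params, seed=2, max_time=5.0, max_events=10**6)
    assert traj.duration == pytest.approx(5.0)
    assert all(ev.time <= 5.0 for ev in traj.events)


def test_graph_reconstruction_from_snapshots(params):
    traj = simulate(6, params, seed=4, max_events=1000, frame_interval=300)
    g_direct = AggregationGraph(6)
    for ev in traj.events[:750]:
        g_direct.toggle_edge(ev.u, ev.v)
    assert traj.graph_at(750) == g_direct
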