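"""The nine bonding-motif statistics and the network Hamiltonian.

Builds three tiny aggregation graphs, prints their statistic vectors
t(g) = (t_e, t_2s, t_NSP1, t_NSP2, t_ESP0, t_ESP1, t_C5, t_C6, t_C7),
and evaluates the Hamiltonian
H(g) = (phi_e + k_B T) t_e + sum_s phi_s t_s under a small parameter set.
"""

from fibrilnet import (
    AggregationGraph,
    ModelParams,
    STAT_NAMES,
    hamiltonian,
    sufficient_stats,
)

graphs = {
    "triangle": AggregationGraph(3, [(0, 1), (1, 2), (0, 2)]),
    "path a-b-c": AggregationGraph(3, [(0, 1), (1, 2)]),
    "5-cycle": AggregationGraph(5, [(i, (i + 1) % 5) for i in range(5)]),
}
params = ModelParams(phi_e=-1.5, phi_2s=0.3, phi_ESP1=-0.4)

print("statistic order:", ", ".join(STAT_NAMES))
for name, g in graphs.items():
    t = sufficient_stats(g)
    print(f"{name:>11}: t(g) = {tuple(t)},  H(g) = {hamiltonian(g, params):+.2f}")

# Each t component counts one bonding motif: edges, two-stars (a monomer
# bound to two others), null/edgewise shared partners, and 5-7-cycles.
# Negative H means the configuration is energetically favored under these
# coefficients (phi_e = -1.5 with k_B T = 1 gives each bond -0.5).
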