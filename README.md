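# fibrilnet

Network-Hamiltonian (ERGM) modelling of amyloid fibril self-assembly:
equilibrium sampling, stochastic kinetics from free monomers, and
topological analysis of the resulting aggregation trajectories.

## The problem and the model

Amyloid fibrils — the locally ordered protein aggregates behind
Alzheimer's, prion and many other deposition diseases — self-assemble
from free monomers over timescales far beyond atomistic simulation.
`fibrilnet` implements a coarse-grained *aggregation graph* model of this
process: each vertex is a protein monomer, each edge a non-covalent
inter-monomer contact, and the energy of an aggregation state `g` is a
network Hamiltonian over nine bonding-motif counts

```
H(g) = (φ_e + k_B T)·t_e + φ_2s·t_2s + φ_NSP1·t_NSP1 + φ_NSP2·t_NSP2
     + φ_ESP0·t_ESP0 + φ_ESP1·t_ESP1 + φ_C5·t_C5 + φ_C6·t_C6 + φ_C7·t_C7
```

where `t_e` counts edges, `t_2s` two-stars (a monomer bound to two
others), `t_NSPk`/`t_ESPk` null/edgewise shared partners (non-adjacent /
adjacent monomer pairs with exactly *k* common bonding partners), and
`t_C5..t_C7` simple cycles of length 5–7.  In equilibrium the graph
follows the Boltzmann / exponential-family random graph (ERGM) form

```
Pr(G = g) ∝ exp(θᵀ t(g)) · h(g),     θ = −φ′/(k_B T)
```

with `h` a reference measure (counting measure by default).  Kinetics
are modelled as a continuous-time Markov chain over single bond toggles
(Hamming steps) with conditional rates

```
r_ij = A / (1 + exp(β ΔH_ij − ΔS_ij))
```

which reduce to the Arrhenius law `A·exp(−β E_a)` for uphill barriers
and saturate at the collision frequency `A` downhill.  Exit rates,
transition probabilities and exponential waiting times give a
Gillespie-style simulator started from the empty graph (free monomers),
with time reported in units of inverse collision rate.

On top of the dynamics sits the analysis layer used to characterize
fibrillization mechanisms:

* the five fibril topology classes observed in the PDB (1-ribbon,
  2-ribbon, 1,2 2-ribbon, double 1,2 2-ribbon, 3-prism) as declarative
  periodic templates;
* *induced fibrillar components* — maximal connected sets of locally
  fibrillar monomers forming at least two repeating subunits — and the
  per-frame metrics built on them (average component size, max fibril
  size, fibril count, fibril fraction, oligomer count);
* segmentation of trajectories into the epochs of self-assembly
  (Condensation, Local Ordering, Nucleation, Fibril Growth, Maturation,
  plus the two 1-ribbon pathway schemes);
* vertex roles (fibril end / center / defect / free) and the
  bonding-motif census (end–end, end–center, defect–center, ...),
  including defect-breakage event detection.

The model's φ coefficients are configuration input (YAML/JSON); the
files under `examples/params/` are illustrative parameter sets.

## A worked example

```python
from fibrilnet import (ideal_fibril, make_fixture,
                       induced_fibrillar_components)

single = ideal_fibril("1-ribbon", 10)
joined = make_fixture("two_fibrils_joined", template="1-ribbon", length=10)
before = induced_fibrillar_components(single, "1-ribbon")
after = induced_fibrillar_components(joined, "1-ribbon")
print(before.count, before.max_size)   # 1 10
print(after.count, after.max_size)     # 1 20
```

A single bond between two terminal monomers fuses two 10-monomer
1-ribbon components into one: the induced fibril component count drops
from 2 (for the disjoint pair) to 1 while the maximum component size
doubles from 10 to 20 — the elementary consolidation step of fibril
growth.  The scripts in `examples/` walk through each capability
(statistics and Hamiltonian, equilibrium sampling, kinetic trajectories,
topology classes, epochs and defects) and print annotated output; a thin
CLI (`fibrilnet simulate|metrics|epochs|defects|sample-equilibrium|
make-fixture`) wraps the same functions for shell pipelines.

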