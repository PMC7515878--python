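# Methods

## Model

An aggregation state on `n` monomers is a simple undirected graph `g`
(vertices 0..n−1, edges = non-covalent contacts).  Its energy is

H(g) = (φ_e + k_B T)·t_e + φ_2s·t_2s + φ_NSP1·t_NSP1 + φ_NSP2·t_NSP2
     + φ_ESP0·t_ESP0 + φ_ESP1·t_ESP1 + φ_C5·t_C5 + φ_C6·t_C6 + φ_C7·t_C7

The edge statistic carries `φ_e + k_B T`, not the bare `φ_e`; every
coefficient vector in the package (`ModelParams.coeffs`) uses this
convention, and `θ = −coeffs/(k_B T)` is the natural ERGM parameter.
Statistic definitions:

* `t_e` — edge count;
* `t_2s` — two-stars, Σ_v C(deg v, 2);
* `t_NSPk` — unordered non-adjacent pairs with exactly k common
  neighbours (k = 1, 2);
* `t_ESPk` — adjacent pairs with exactly k common neighbours (k = 0, 1);
* `t_Ck` — simple cycles of length k = 5, 6, 7, each cycle *subgraph*
  counted once (not per rotation/reflection; distinct Hamiltonian cycles
  on the same vertex subset count separately).

Change statistics for a single edge toggle are computed locally: degree
terms directly, shared-partner terms by bookkeeping over the dyad's
neighbourhoods, cycle terms by a depth-limited DFS counting simple
u–v paths of 4–6 edges, pruned with a BFS distance-to-target lower
bound.  All of this is validated component-wise against an independent
enumeration oracle (subset/permutation counting) in the test suite.

## Equilibrium sampling

`brute_force_distribution` enumerates all `2^C(n,2)` microstates for
n ≤ 5 and normalizes `exp(−βH + log h)` in a numerically stable way
(log-weights shifted by their maximum).  `mcmc_sample` is
Metropolis–Hastings with a uniform single-dyad toggle proposal and
acceptance `min(1, exp(−βΔH + Δlog h))`; burn-in defaults to 10% of the
chain and thinning to 1, both caller-controlled.  The proposal is the
simplest symmetric choice — distributional correctness, not mixing
speed, is the design goal, and it is tested by total-variation distance
against the exact distribution.

The reference measure `h` defaults to the counting measure
(`log h ≡ 0`); a callable `g → log h(g)` can be supplied for entropic
corrections.  Trajectory serialization requires the counting measure
(callables are not serializable).

## Kinetics

Transitions connect states one Hamming step (one edge toggle) apart with
rate `r_ij = A / (1 + exp(βΔH_ij − ΔS_ij))`, evaluated with a logistic
(`expit`) so extreme barriers neither overflow nor round to zero
prematurely.  The exit rate is `R_i+ = Σ_j r_ij`, the next transition is
chosen with probability `r_ij / R_i+`, and waiting times are exponential
with mean `1/R_i+`.  Simulations start from the empty graph; the waiting
time is always drawn before the neighbour choice from a single seeded
PCG64 generator, so runs are bit-reproducible.  `A = 1` by default and
times are reported in units of inverse collision rate.

Because `r_ij/r_ji = exp(−βΔH + ΔS)`, the chain satisfies detailed
balance with respect to the equilibrium ERGM distribution; the suite
checks this both algebraically (rate-ratio identity to 1e−12) and
empirically (time-weighted occupancy vs exact enumeration at n = 3).

Rate bookkeeping: after toggling {u,v}, rates are recomputed for all
dyads incident to u or v (their degrees changed) plus every dyad {a,b}
with `dist(a,{u,v}) + dist(b,{u,v}) ≤ 5`, distances taken in the graph
state that contains the toggled edge.  The bound comes from the motif
geometry: a changed motif spanning dyad {a,b} and edge {u,v} has at most
7 vertices, and once the (possibly virtual) edge {a,b} is excluded the
connecting path decomposes as `dist(a,·) + 1 + dist(b,·) ≤ 6`.  A
simple radius-3 ball around the toggle is *not* sufficient for the 6-
and 7-cycle terms, which is why the sum-form criterion is used.  The
incremental cache is required to reproduce naive full recomputation
event-for-event at the same seed, and is tested that way (including a
cycle-weighted parameter set).

Degenerate inputs: if every exit rate underflows double precision (all
escape barriers ≳ 700 k_B T), the state is effectively absorbing and
`simulate` raises rather than dividing by zero.

## Fibril topology and induced fibrillar components

The five topology classes are declarative periodic templates: a subunit
edge pattern plus inter-subunit patterns at offsets 1 and 2.

| class | subunit | pattern |
|---|---|---|
| 1-ribbon | 1 | path (offset-1 bonds) |
| 2-ribbon | 2 | ladder: rung within subunit, rails at offset 1 |
| 1,2 2-ribbon | 2 | ladder whose rails bond offsets 1 **and** 2 |
| double 1,2 2-ribbon | 4 | two laterally bonded 1,2 2-ribbons |
| 3-prism | 3 | bonded triangle stack (rails at offset 1) |

These shipped patterns are data (a YAML/JSON template file can replace
any of them without code changes).  The nucleation threshold is two full
subunits — 6 monomers for the 3-prism — except the 1-ribbon, where two
subunits would declare every bonded dimer fibrillar; there the threshold
is 4.

**Local fibrillarity** has two semantics.  In `exact` mode a monomer's
entire closed 1-neighbourhood must match the neighbourhood of some
template position (interior or terminal).  In `partial` mode — the
default — it suffices that *some subset* of its bonds realizes a
template position's neighbourhood as an induced subgraph, so bonds to
material outside the fibril (defects, bridging contacts) do not
disqualify a monomer.  The partial semantics is what makes
defect-to-center bonding motifs observable at all: under exact matching
any extra bond changes the degree pattern and would demote a fibril
center to a defect, structurally emptying that census category.  The
price is that the vertex-level test is permissive (for the 1-ribbon any
non-isolated monomer passes it); selectivity comes from the component
level.

**Induced fibrillar components** are connected sets of locally
fibrillar monomers whose *induced* subgraph is a contiguous run of whole
template subunits (≥ the nucleation threshold).  Clean sets are accepted
by direct isomorphism to the ideal fibril; mixed sets are mined: seeds
are induced embeddings of the two-subunit nucleus, extended
subunit-by-subunit in both directions subject to the induced-match
constraint, exploring branch choices up to a fixed budget (800 states
per seed) and keeping the longest segment per round, ties broken by
sorted vertex labels.  Longest-first extraction makes the decomposition
independent of vertex labeling except at genuine structural ties; the
greedy rounds make disjointness exact but maximality heuristic in
adversarial overlapping cases.  Partial terminal subunits are not
extracted (segments are whole-subunit runs).

One consequence worth knowing: under partial semantics a degree-2
monomer bridging two 1-ribbons at non-adjacent positions is
*topologically indistinguishable* from ribbon material — the merged
induced path is a legitimate longer fibril, and the extractor will
report it as one.  Defects in the 1-ribbon sense are monomers whose
bonding pattern cannot embed in any path (branch vertices, clustered
blobs, monomers with adjacent-pair attachments only).

## Metrics and epochs

Per-frame metrics: average component size `n / #components` (free
monomers count, so every run starts at 1); max induced fibril size,
fibril component count and fibril fraction from the component
extraction; oligomer count = connected components with 2 ≤ size < 8
(free monomers are not oligomers — an interpretive choice, since the
size bound alone would count them).

Epoch boundaries are computed on smoothed series (centered moving
average, default window 1% of frames, minimum 3; first occurrence wins
ties) and depend only on frame order and values, so they are invariant
under uniform time rescaling:

* Condensation ends at the argmax of smoothed average component size;
* Local Ordering ends (Nucleation starts) when smoothed max fibril size
  first reaches the nucleation threshold;
* Fibril Growth starts at the argmax of smoothed fibril component count;
* Maturation starts at the earliest frame from which both smoothed
  fibril fraction and max size stay within `conv_tol` (default 0.05)
  relative fluctuation through the end of the series.

Missing or out-of-order boundaries raise a diagnostic error listing the
boundaries that were found.  The two 1-ribbon pathway schemes
(condensate annealing: Dimerization → Condensation → Annealing →
Maturation; dendrite consolidation: Dimerization → Local Ordering →
Fibril Growth → Consolidation → Maturation) reuse the same boundary
machinery plus an initial dimerization epoch ending when average
component size first reaches 2; their exact boundary rules are explicit
approximations, since the narrative descriptions of these pathways do
not fully pin them down.

## Defects

Roles: fibrillar monomers in the first or last subunit of their segment
are *ends*, other fibrillar monomers *centers*; non-fibrillar monomers
are *defects* when their aggregate contains fibrillar material and
*free* otherwise.  Every edge not internal to a single fibrillar
component falls in exactly one role-pair census category (the closed
taxonomy {end, center, defect}² plus free–free), so the categories
partition those edges by construction.  A defect-breakage event is an
edge deletion incident to at least one defect (roles evaluated in the
pre-deletion state) that disconnects its aggregate; deletions that leave
the aggregate connected are not breakage.  Events are reported per
fixed event-count bin (default 10³).

## Synthetic data and what the tests show

Fixture generators produce ideal fibrils, joined-fibril and
fibril-with-defect constructions, deterministic sequential-growth
trajectories, and metric curves with planted epoch landmarks (tent
peaks, threshold jumps and convergence gaps sized so that the smoothed
boundary rules land exactly on the planted frames).  These emulate the
*topological* content of aggregation trajectories — they contain no
spatial information, no diffusion limits and no experimental noise, so
passing tests demonstrate correctness of the statistics, samplers and
analysis machinery, not agreement with any particular experimental
fibrillization assay.  The shipped parameter files are illustrative
(chain-favoring coefficients chosen so a small system visibly
aggregates into ribbons); they are not a published calibration, and the
epoch phenomenology they produce at the small problem sizes used in the
suite (tens of monomers, 10³–10⁴ events) is qualitative.

Problem sizes used by the test suite and acceptance script: exhaustive
oracle checks at n ≤ 4 plus 500 random graphs at n ≤ 7; MCMC 10⁶ steps
at n = 3; kinetic occupancy 10⁵ events at n = 3; incremental-vs-naive
equivalence at n = 30 over 10³ events; qualitative pipeline runs at
n = 30.

## Known limitations

* Cycle change statistics cost grows like the 5th power of local degree
  in dense condensates; the simulator is practical for hundreds of
  monomers, not (yet) thousands.
* Segment extraction is deterministic greedy longest-first: disjoint by
  construction, maximal only heuristically, and whole-subunit only.
* `classify_topology` matches whole graphs (or the largest connected
  component) against ideal fibrils; it does not search for embedded
  sub-fibrils.
* No spatial embedding, diffusion model, or fitting of `A`/φ to
  experimental kinetics data.
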