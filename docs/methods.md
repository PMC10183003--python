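# Methods

This note records the models, conventions and numerical choices behind
`dcnatools`, and what the synthetic benchmarks do and do not establish.

## Node model and input handling

Networks are residue-level: one node per residue, represented by its Cα
atom (any residue containing one) or its P atom (nucleotides). Residues
with neither — waters, ions, 5′-terminal nucleotides without a
phosphate — contribute no node and are logged. Residues are keyed by
(chain, author residue number, insertion code) and author numbering is
preserved in every report, because mutation positions are quoted in
author numbering. Internally nodes are 0-based and contiguous.

Topologies are parsed with Biopython (altloc '' or 'A' only);
trajectories (multi-model PDB, DCD, XTC) with mdtraj, converted to Å.
mdtraj does not carry insertion codes, so loading a trajectory against
a topology whose residues are distinguished *only* by insertion code is
refused rather than silently mis-mapped. Inputs are assumed imaged and
whole; no periodic-boundary handling is applied.

## Contact probabilities

P_ij is the fraction of frames in which the minimum inter-residue
distance is ≤ the cutoff (default 4.5 Å). The distance is measured
between heavy atoms by default — 4.5 Å is a heavy-atom-scale contact
criterion and Cα–Cα pairs rarely approach it — with representative-atom
distance as an explicit fallback mode. Pairs on the same chain within
sequence separation ≤ 1 are zeroed: contacts between covalently linked
neighbours carry no dynamic information. Inter-chain pairs are never
excluded. The binary contact map thresholds P_ij at an occupancy
fraction (default 0.75, inclusive: 0.75 itself qualifies).

dCNA edge weights are the raw occupancy fractions, not binarized maps:
ΔP is a probability change, and subtracting binary maps would discard
it. A binary mode remains available through `binary_contacts` for
sensitivity checks.

## Superposition, B-factors, correlations

`superpose` performs rigid-body least-squares fitting (Kabsch SVD, no
scaling, reflections excluded). The default fits every frame once onto
a reference frame; this map is exactly idempotent, because an optimally
aligned frame yields the identity transform. For flexibility and PCA
analysis the `reference='mean'` mode iterates fitting onto the evolving
ensemble average until convergence; for ensembles with a well-defined
average structure this converges in a few iterations and is likewise a
fixed point. (A ensemble of pure noise with no common structure has no
well-defined average orientation, and the mean-fit iteration converges
only slowly there; that case is irrelevant to trajectory data.)

B-factors use the isotropic crystallographic convention
B = (8π²/3)·⟨Δr²⟩ with ⟨Δr²⟩ the mean-square fluctuation of the
representative atom about its ensemble mean after superposition. The
estimator loses the 6 rigid-body degrees of freedom to the fit, a
relative bias of roughly 2/N; validation against the closed-form
Gaussian limit therefore uses N = 200 nodes, where the bias is ~1 %.

Cross-correlations are vector dot-product dynamic cross-correlations,
c_ij = ⟨Δr_i·Δr_j⟩/√(⟨Δr_i²⟩⟨Δr_j²⟩), the standard definition in
protein network analysis — not per-axis Pearson coefficients. A node
with zero variance makes c undefined and raises an error naming it.

## Networks, communities and differences

Per-state networks come in two modes: `dcna` (edges wherever P_ij > 0,
weighted by P_ij) and `covariance` (edges from the binary 4.5 Å/75 %
rule, weighted w_ij = −ln|c_ij|; |c_ij| = 0 on a qualifying edge is an
error, not an infinite weight).

The consensus network keeps an edge iff P_ij reaches the stability
threshold in every state. The threshold defaults to 0.75 — the only
occupancy threshold the underlying protocol fixes — and is
configurable; studies of planted probability *changes* that straddle
0.75 use a permissive threshold instead, since an edge must be in the
consensus for its ΔP to be observable. Nodes absent from any state
(e.g. DNA present only in one functional state) are dropped from the
consensus node set and reported.

Community detection is divisive Girvan–Newman: repeatedly delete the
edge of maximal betweenness (unweighted betweenness by default,
matching the non-weighted variant; edge weights can serve as shortest-
path lengths in the weighted variant). Ties in betweenness are broken
by deleting the lexicographically smallest node-index pair, making the
whole pipeline deterministic. Whenever a deletion splits a connected
component, the partition and its modularity Q — always evaluated on the
*original* graph, unweighted — are recorded. Subdivision stops when a
newly recorded partition improves Q by less than 0.001 over the
previous one, and the best-Q partition recorded so far is returned.
The full (partition, Q) trace is retained so that the alternative
"best-Q over the whole dendrogram" reading can be taken from the same
run. Q uses the Newman–Girvan form Σ_c [e_c/m − (d_c/2m)²]; a weighted
variant exists but is not the default.

Difference networks assign each consensus edge ΔP = P(state B) −
P(state A); the transition direction is later-state minus earlier-state
so that positive ΔP means contacts gained. The community ΔP matrix sums
edge ΔP over community pairs (diagonal = within-community), conserving
the total: upper triangle plus diagonal equals the sum over all edges.
Per-residue aggregates sum ΔP over a node's incident edges; ranking is
by |aggregate| with sign retained (gain vs loss), ties broken by
(chain, residue number).

## PCA

Plain Cartesian PCA on representative-atom coordinates (no mass
weighting), on the same superposed frames used for B-factors, so modes
exclude rigid-body motion. The covariance is the population (1/F)
estimator; eigendecomposition is dense (`scipy.linalg.eigh`), adequate
to a few thousand nodes. Modes are reported in descending variance
order — the dominant collective motions — and each mode's sign is fixed
by making its largest-magnitude component positive. Porcupine arrows
weight mode components by the mode's RMS amplitude (√eigenvalue), so a
rigid ensemble draws no arrows; per-community summaries report the mean
direction and mean arrow amplitude.

## Mutation interfaces

Mutations are mapped by (chain, author position) only; the mutant side
chain is never modelled. A mutation is *interfacial* in a state iff its
node has at least one network edge to a node of a different community,
with the crossed community pairs reported; otherwise *internal*. This
graph-adjacency criterion reuses the pipeline's only contact
definition. Classification depends only on the partition's equivalence
classes, so it is invariant under community relabelling. Wild-type
letters are cross-checked against the topology when resolvable;
mismatches are kept and logged. Phenotype vocabulary is closed to
{XP, TTD, XP/CS, XP/TTD}; compound-heterozygote details travel in a
free-text note column. Unresolvable positions are reported per run, not
fatal.

## Synthetic ensembles

The generator plants the statistical structure the analysis assumes,
with hard guarantees rather than soft tendencies:

* Communities are compact clusters (radius 1 Å, one chain each) whose
  centres sit 9 Å apart (regular simplex for K ≤ 4, cubic grid above),
  so every intra-community pair is always within the 4.5 Å cutoff and
  no cross-cluster pair can reach it by chance.
* Designated boundary-node pairs toggle per frame, with the planted
  Bernoulli probability, between home positions and a "near" geometry
  (3 Å separation at the inter-centroid midpoint, still within 4.5 Å of
  the own cluster). Random displacements are norm-clipped (rigid
  community translations at 2.34× their per-axis σ, per-node noise at
  3σ) so jitter can never cross the planted geometry: empirical
  occupancy equals the Bernoulli draw fraction exactly, converging to
  the planted probability at the binomial rate.
* Intra-community occupancies below 1 are realized by sending
  non-boundary nodes on excursions to distant parking spots at rate
  1 − √p, making eligible pairs jointly home with probability p.
  Boundary nodes never take excursions; their intra-pair occupancy is
  √p, a documented edge effect of the mechanism.
* Correlated intra-community motion is a shared per-frame Gaussian
  translation per community (default σ 0.15 Å/axis) plus independent
  per-node noise (σ 0.05 Å); per-state amplitude multipliers mark
  mobile communities. Non-boundary node offsets are confined to
  half-spaces facing away from every designated interface, keeping
  bystander nodes out of planted interfaces.
* The mutation fixture places interfacial mutations on boundary nodes
  of pairs with nonzero planted probability and internal ones on nodes
  with no inter-community edges, with the expected classification
  emitted alongside.

All randomness flows from one mandatory seed; static geometry depends
on the seed only (shared across states, as a consensus requires), while
frame randomness is keyed by (seed, state label).

What these benchmarks show: that every pipeline stage recovers known
ground truth exactly or at the expected statistical rate. What they do
not show: behaviour on real MD data, where contacts are not Bernoulli,
communities are unequal and nested, motions include rotations and
anharmonic transitions, and the contact graph is far from a union of
cliques. The mobile/rigid fixture also illustrates a physical caveat:
after least-squares superposition a two-module system splits relative
motion evenly between the modules, so mobile-module contrasts (B-factor
maxima, mode-1 amplitude ratios) are only meaningful when a majority of
the system anchors the fit — the validation fixture therefore uses five
communities with one mobile.

## Problem sizes used in validation

Planted-partition recovery uses K = 4 communities × 10 nodes, 500
frames, 20 replicate systems; ΔP sign recovery uses planted ±0.4
changes at 800–1,000 frames; estimator-limit checks use 10,000 frames
(B-factor) and 5,000 frames (occupancy); graph oracles enumerate all
partitions of ≤ 8-node graphs. These sizes give each check sharp
expectations (binomial error ≪ the asserted tolerances) while the whole
suite runs in seconds.

## Known limitations

* No mmCIF output, no trajectory writing, no PBC imaging.
* No hydrogen-bond/salt-bridge/energy-weighted contact definitions.
* Girvan–Newman recomputes betweenness after every edge removal
  (O(V·E) per removal); for consensus graphs beyond ~10⁴ edges expect
  minutes to hours. Louvain/Leiden alternatives are out of scope by
  design.
* The stability threshold interacts with ΔP observability: contacts
  that exist in only one state never enter the consensus and hence
  never contribute ΔP. This is inherent to consensus-based dCNA, not an
  implementation artifact.
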