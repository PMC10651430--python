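# Methods

This note documents the models and procedures implemented in
`petridyn`, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the numerical and design choices
a maintainer would want recorded.

## Pathway Petri Nets and their ODE semantics

A PPN is a bipartite directed graph of places (species) and transitions
(reactions) with arcs typed reactant/product/promoter/inhibitor and
weighted by integer stoichiometry, plus a mass-action rate constant per
transition and an initial concentration per place. Structural
invariants (disjoint nonempty node sets, referential integrity,
positive weights, weight-1 modifier arcs, complete kinetics and
marking) are enforced by `core.validate`, which reports *all*
violations as data rather than failing on the first.

The ODE semantics assign each transition the rate

    rate(t) = k_t · Π_reactants [s]^w · Π_promoters [p] · Π_inhibitors 1/(1+[i])

and each species the stoichiometry-weighted sum of rates. The modifier
algebra is a package choice: SBML kinetic laws do not determine how a
generic "modifier" enters the rate, so promoters enter multiplicatively
and inhibitors through the smooth, bounded factor 1/(1+[i]). Both
reduce to plain mass action without modifiers, and the modes are fields
of `KineticLaw` so alternative algebras can be added without changing
callers.

### Steady-state simulation

`simulate_steady_state` integrates with LSODA (stiff-capable, adaptive)
and stops at the first time the residual max_s |d[s]/dt| falls to
`tol`; otherwise it returns the state at `t_max` flagged
non-converged. Defaults: `tol = 1e-6` (concentration units per time
unit), `t_max = 1e5` time units. These are explicit numbers for a
"simulate until steady state or a time cap" rule whose exact constants
are always somewhat arbitrary; both are arguments everywhere. Two
details matter numerically: concentrations are clipped at zero inside
the rate function (solver undershoot must not create negative masses or
NaN powers), and trajectories whose maximum concentration exceeds 1e9
are terminated early as divergent rather than left to overflow.

### SBML import

The importer covers the mass-action fragment: species, compartments
(sizes folded into rate constants), global/local parameters, reactions
with integer stoichiometry, and modifiers. Reversible reactions split
into a forward and an `_Reverse` transition, mirroring the usual
convention in curated model repositories. A rate law is accepted when
its MathML flattens to a product of one positive constant and the
reactant species raised to their stoichiometric powers (a difference of
two such terms for reversible reactions); anything else — and any model
with rules or events — is rejected with the offending feature named, so
batch conversions never silently mangle a model. Modifiers default to
promoter; a small SBO-term table classifies known inhibition terms, and
a per-model override map handles repositories with sparse SBO coverage.
An optional `fit` policy replaces rejection with a crude constant
(first local parameter) for exploratory use.

## Dynamical properties

**α-robustness.** The input's initial concentration is swept over
`n_grid` points across a relative interval of width ε around its
nominal value (absolute interval [0, ε] when the nominal is zero, so a
zero-concentration input can still be perturbed); all other species
start at their nominal marking. With α the absolute output range and ᾱ
its relative version, the score is 1 − min(1, ᾱ/ε). Defaults: ε = 0.2,
n_grid = 21, binarization threshold 0.5. The output scale for ᾱ is the
nominal steady-state output, falling back to the maximum observed
output whenever the nominal scale would push ᾱ above 1 — ᾱ must land in
[0, 1] for the score to be meaningful. A degenerate all-zero scale
yields ᾱ = 0 when α = 0 (nothing moved) and a saturated ᾱ = 1 with a
warning otherwise. Any non-converged simulation in the sweep flags the
result unreliable rather than silently biasing the range.

**Morris screening.** Factors are the initial concentrations of every
place except the output, each mapped from the unit interval to
[0.5·nominal, 1.5·nominal] (or [0, 1] for zero-nominal species). The
design is radial: r scrambled-Sobol base points, each with k companions
differing in exactly one coordinate by Δ = `delta_frac` of the factor's
range, reflected at the cube boundary. Each block contributes the
elementary effect of the designated input on the output's steady state.
The EE is the difference *quotient* (scale-invariant); the undivided
difference is available via `undivided=True` since the two conventions
coexist in the literature and coincide at Δ = 1. μ* is the mean
absolute EE, σ the sample standard deviation (ddof = 1); the pair is
sensitive when either exceeds its threshold (defaults r = 16,
delta_frac = 0.1, thresholds 0.1). Blocks with non-converged
simulations are dropped; losing more than half flags the result
unreliable.

**Monotonicity.** True iff every EE in the pool is strictly positive.
Near-zero EEs are genuinely ambiguous: the strict default treats
|EE| ≤ `zero_tol` (default 0) as breaking monotonicity; the `ignore`
policy drops them instead. An empty pool is an error, not a value.

## Graph preprocessing

Augmentation adds one reactant-labeled arc from each reaction to each
of its reactants, making the reaction's consumption of its reactants
visible to directed traversal. Extraction takes the forward-reachable
set of I intersected with the backward-reachable set of O — directed
reachability, since augmentation only makes sense under directed
semantics — and returns nothing when O is unreachable (the triple is
discarded). On acyclic graphs this equals the union of nodes on simple
I→O paths; on cyclic graphs (which augmentation routinely creates) the
reach/co-reach definition is strictly larger and is the definition
used, since "lies on a directed walk from I to O" is the property the
model should see. Features are the three indicators (Source, Dest,
NodeType); transitions are all-zero. Stoichiometric weights are dropped
at featurization — the network consumes labels, not weights — but
remain in the provenance PPN.

Edge labels: four labels {reactant, product, promoter, inhibitor} by
default, with augmentation arcs labeled reactant (they represent
consumption). A `scheme="three"` switch collapses product into
reactant for the minimal three-label alphabet; both schemes are tested
and the label ordering is stored in every checkpoint, keyed by name.

Dataset assembly drops subgraphs above `max_nodes` (default 200) and
logs every drop with its reason. Queries with I = O are rejected
upfront.

## The network and its variants

Layer update (layer ℓ ≥ 1, d-dimensional embeddings):

    h_{A,v}^ℓ = Σ_a E_a^ℓ · Σ_{u ∈ γ(v,a)} h_u^{ℓ-1}
    h_v^ℓ     = BN(ReLU(W^ℓ h_v^{ℓ-1} + h_{A,v}^ℓ))

γ(v, a) is the set of in-neighbors along label-a edges; messages flow
along edge direction. The self-term applies W^ℓ to the *previous*
layer's embedding — the composition ϕ(h_v^{ℓ-1}, h_γ^{ℓ-1}) standard
for graph convolutions. Batch normalization follows the ReLU; during
training it uses batch statistics over all nodes in the batch (and
updates running statistics with momentum 0.1), at inference the running
statistics, making prediction deterministic and single-graph-capable.
Readout is the mean over nodes per layer, concatenated across layers
(jumping-knowledge style, length d·L), followed by a linear map and a
sigmoid. No self-loops are added; an empty neighbor set contributes a
zero vector.

Variants: `baseline` zeroes the neighbor term entirely (structure
agnostic); `connectivity` uses constant node features and one shared
neighbor matrix U^ℓ; `source_dest` and `node_type` add the feature
columns back while keeping the shared U^ℓ; `edge_aware` is the full
model with per-label E_a^ℓ. Setting all E_a^ℓ equal reproduces the
shared-U forward exactly, which is asserted in the tests.

Training minimizes the mean binary cross-entropy (probabilities clamped
to [1e-7, 1−1e-7]) with Adam (the optimizer is a recorded choice; the
update is plain adaptive SGD) on batches drawn *with replacement* with
per-example weight inversely proportional to class frequency, so
expected batches are class-balanced under any imbalance. All gradients
are hand-derived (including through training-mode batch normalization)
and verified against central differences to 1e-4. Training is
deterministic given the config seed; single-class training data is
refused. When a validation set is supplied, the parameters of the
best-validation-AUROC epoch are returned.

The implementation is numpy throughout: graphs are batched as one
block-diagonal sparse adjacency per edge label, so an epoch over
thousands of small graphs costs a few hundred milliseconds on one CPU.

## Evaluation protocol

Stratified 5-fold cross-validation (per-fold class counts within one of
proportional) with, per outer fold, an inner stratified 80/20 split of
the training folds for grid-search model selection by validation AUROC.
Ties break toward smaller d, then fewer layers, then larger learning
rate — recorded in the report. The selected model predicts the
untouched test fold; AUROC is the Mann-Whitney rank statistic (ties
half credit, undefined — not zero — for single-class folds), the other
five metrics come from the confusion matrix at threshold 0.5 (a package
default; AUROC-based selection is threshold-free). WF1 is the
support-weighted mean of per-class F1; MCC uses the zero convention for
vanishing denominators. Reports carry per-fold index hashes so absence
of train/test leakage is auditable after the fact. Hyper-parameters are
re-selected per outer fold.

## Arc knock-out interpretation

For a trained model and a subgraph with prediction ŷ_g, each edge e is
deleted in turn (node set unchanged — no re-extraction, so each
contribution isolates one edge; `without_edge` composes if cascaded
analysis is wanted) and the contribution is ŷ_g − ŷ_{g\e}. An edge is
not removable when deleting it breaks every directed I→O path or leaves
some node unable either to be reached from I or to reach O; such edges
are reported with the violated condition. Knock-outs can be validated
against ground truth: the corresponding arc is removed from the PPN
(removed reactant arc ⇒ the species is no longer consumed and leaves
the rate law; removed product arc ⇒ no longer produced), transitions
stripped of their last arc are pruned and logged, and the property is
re-assessed by simulation. Augmentation back-arcs have no PPN
counterpart and are flagged instead. A DOT export renders contributions
(red: removal raises the prediction, blue: lowers, black:
non-removable).

## Synthetic generators

`generate_ppn` draws weakly connected mass-action nets: sizes uniform
over configurable ranges (default 5–10 places, 4–10 transitions), every
transition with at least one reactant and one product, optional second
reactants/products (probability 0.3), promoter/inhibitor attachment
probability 0.15 each, rate constants log-uniform on [0.1, 10], initial
concentrations uniform on [0.1, 2], occasional weight-2 arcs.
Disconnected components are stitched with extra reactant arcs so
generation always terminates. These ranges aim at small, mostly
convergent, structurally diverse nets — *not* at reproducing the degree
distributions or motif statistics of curated pathway repositories;
conclusions from synthetic experiments are about the method, not about
any real model corpus.

`generate_structural_task` emits chain-shaped I/O subgraphs (m ∈ {3, 4,
5} reactions, with back-arcs as graphprep would produce) whose label is
the predicate "every directed I→O path traverses an inhibitor arc",
computed by exhaustive simple-path enumeration. The generator is
engineered so the variant ladder is exercised: (i) node counts are
independent of the label, so the baseline cannot beat chance; (ii) a
latent regime couples the density of promoter skip arcs (pure topology)
with the probability of an inhibitor being present, giving
connectivity-only models partial signal (regime 1: inhibitor
probability 0.9, skip probability 0.15; regime 0: 0.2 and 0.5); (iii)
the label is a deterministic function of topology *plus* edge labels,
so only the edge-aware model can resolve it fully. Classes are balanced
to 50% by per-class rejection and the output is shuffled. These
constants were fixed at design time by computing the Bayes-optimal
AUROC of each information set (node counts ≈ 0.51, topology ≈ 0.86,
full graph = 1.0).

`generate_dynamics_task` is the end-to-end miniature: small random nets
(default 4–7 places), random path-connected (I, O) pairs, labels from
`assess_property` itself. Failed or divergent simulations drop the
triple. Random small mass-action nets are predominantly robust at
ε = 0.2 (roughly 85–90% positive labels in practice); the evaluation
pipeline handles this imbalance via the weighted sampler and
stratification, and it is a property of the generator's conditions, not
a bug.

## Problem sizes and runtime

The test suite and acceptance script run everything at desk scale on
one CPU: the structural-task experiments use 4000 graphs (d = 16,
L = 6, 30 epochs; under a minute for all five variants), the
end-to-end miniature 250–300 simulation-labeled triples with n_grid = 5
and t_max = 1e4 (a few minutes, dominated by ODE solves), and oracle
comparisons use graphs of at most 10–13 nodes where exhaustive
enumeration is exact. Larger runs only change constants, not code
paths.

## Known limitations

- Modifier kinetics beyond the multiplicative/saturating algebra are
  not implemented (the hooks exist on `KineticLaw`).
- The SBML reader covers the mass-action subset only: no function
  definitions, units, delayed events, or non-constant compartments.
- Steady-state detection is residual-based; oscillatory systems hit the
  time cap and are reported non-converged rather than classified as
  oscillating.
- σ-based Morris thresholds operate on the output's natural scale;
  comparing thresholds across outputs of very different magnitude
  requires setting `output` normalization by hand.
- The structural toy task is a chain family; it exercises the
  information ladder but not wide fan-in/fan-out topologies.
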