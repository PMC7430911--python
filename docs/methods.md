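# Methods

This note documents the model implemented by `funcprop`, its assumptions,
the parameters that matter, the numerical choices made where the design
was genuinely open, what the synthetic generator does and does not
emulate, and the known limitations.

## Model and assumptions

The method rests on guilt by association — interacting proteins tend to
share function — but corrects for two failure modes of naive neighbour
transfer: noisy/missing interactions, and the small-world property of
interaction networks that makes hop distance unspecific. It does so by
(1) re-weighting the interaction network with three independent evidence
channels, (2) diffusing similarity globally with a restart walk, and
(3) restricting the annotation vote to a cohesive module around the
target.

### Correlation networks

- **Co-neighbor.** Edge for every physically interacting pair sharing at
  least one partner; weight is the product of the two neighbourhood
  overlap ratios, `(2z/(|Ni|+z))·(2z/(|Nj|+z))` with `z = |Ni∩Nj|`. It is
  1 exactly when the neighbourhoods coincide, 0 when disjoint; the
  denominators mix each protein's own degree with the overlap, so the
  score is asymmetric in information but symmetric in value.
- **Co-domain.** Edge for every pair sharing at least one domain. The raw
  weight `−log(M^z (M−z)^(x−z) (M−x)^(y−z) / M^(x+y))` is a
  chance-overlap surprisal (x, y per-protein domain counts, z shared,
  M total domain categories), evaluated term-wise in log space. The
  printed formula is not symmetric under x↔y, so the builder fixes the
  convention x ≥ y; weights are then min–max normalized over exactly the
  scored pair set. Pairs with z = 0 carry no shared-domain evidence and
  get no edge; a min = max degenerate set maps to weight 1; the singular
  case x = M with y > z (a protein annotated with every domain category,
  unreachable in practice) is capped at the largest finite raw score.
  Because min–max normalization cancels constant factors, the weights are
  invariant to the logarithm base (natural log used).
- **Co-complex.** Edge for every pair sharing a complex, weighted
  `|Ci∩Cj|/(|Ci|·|Cj|)` — full weight for proteins whose single complex
  coincides, discounted as either membership list grows.

Each network's node set is the endpoints of its surviving edges, so the
three networks (and the propagation network) generally cover different
subsets of the proteome.

### Propagation

`H` row-normalizes the co-neighbor weights (all-zero rows for proteins
absent from it). For each seed protein, two n-vectors — structural scores
`VD` and modular scores `VC`, both initialized to 1/n — are iterated
synchronously:

    VD(t+1) = α·H·VC(t)  + (1−α)·RV_D
    VC(t+1) = α·Hᵀ·VD(t) + (1−α)·RV_C

with the seed's raw co-domain and co-complex rows as restart vectors
(deliberately unnormalized, so restart mass reflects evidence strength,
and converged vectors are not probability distributions). The updates are
cross-coupled — domain-derived and complex-derived evidence flow through
each other via the interaction topology. All seeds are iterated at once
as two dense n×n matrices against sparse `H`; this is exact because the
per-seed maps are independent and linear.

Convergence is declared when the L1 change of the concatenated (VD, VC)
pair drops below `tol = 1e-6` (a conventional threshold for restart
walks; the fixed point is the solution of a linear system, checked
against a direct solve in the tests), with `max_iter = 1000`.

**Convergence condition (limitation).** The iteration matrix
`[[0, αH], [αHᵀ, 0]]` has spectral radius `α·σ_max(H)`. For a
row-normalized matrix σ_max ≥ 1, and it grows with degree imbalance
(≈ 1.2–1.4 on typical co-neighbor networks, √k for a k-leaf star), so the
walk converges only when `α < 1/σ_max(H)`. The default α = 0.5 converges
comfortably on every network we generate; α near 1 (e.g. 0.9) diverges on
realistic networks. The implementation raises a `ConvergenceError`
carrying the residual rather than silently returning garbage.

The propagation network is `PN(i,j) = VD_i[j] + VC_i[j]`, then: per-row
sparsification (entries below `ε = 1e-4` of the row maximum dropped — a
scale-free rule, since converged rows differ in magnitude with restart
mass), diagonal removal, and symmetrization by averaging (i,j) with
(j,i), yielding an undirected weighted similarity network. Seeds with no
domain and no complex evidence have zero restart vectors, converge to
zero rows, and receive no predictions downstream.

### Module detection and annotation

Module cohesion is `f(M) = w_in/(w_in + w_out)^β` with `w_in` the total
PN edge weight inside M and `w_out` the boundary weight; `β = 1` (at
which f ∈ [0, 1], equal to 1 iff the module is boundary-free, and
invariant to rescaling all weights). For a target v the initial module is
all its PN neighbours; they are visited in descending PN-weight order
(ties lexicographic) and removed whenever the neighbour fitness
`f(M∪{u}) − f(M∖{u})` is ≤ 0, with the module updated after each removal
(a static variant that judges every neighbour against the full initial
module is available via `sequential=False`). The target itself anchors
the module: its edges count as internal weight during pruning — otherwise
a partner tied only to the target would always be dropped and
single-neighbour targets would be unpredictable — but the target is never
a candidate and does not vote.

Candidates vote on functions with weight PN(v, u); the top K functions by
score are predicted, K being the annotation count of the most similar
*annotated* neighbour (an unannotated nearest neighbour has no count to
copy). All ties — similarity ties in the K rule (larger annotation count,
then lexicographic id) and score ties at rank K (lexicographic id) — are
broken deterministically, so identical inputs give identical predictions.

## Evaluation protocol

GO terms annotating fewer than 10 or more than 200 proteins are removed
(inclusive bounds 10..200 kept), and proteins left termless drop out of
evaluation. Cross-validation masks only annotation knowledge: test
proteins keep their interactions, domains and complexes. Leave-one-out
masks one protein at a time; ten-fold CV partitions annotated proteins
into 10 seeded folds (sizes within 1), masks each fold jointly, and
reports mean ± standard deviation over folds × repeats (function default
100 repeats; smaller counts are used in the shipped scripts, stated where
used). Unpredictable proteins count TP = 0, FP = 0, FN = |known| and fall
in MMP, so MP + MMP always equals the number of evaluated proteins.

Because the field is ambiguous about averaging, the report carries both
macro-averages (per-protein mean of precision, recall, F — the headline
numbers), the harmonic mean of macro-P and macro-R (`f_of_means`), and
pooled micro-averages, labelled distinctly. PR and FP/TP curves re-truncate
every protein's ranking at each cutoff K; the FP/TP point is omitted when
TP = 0. The neighbour-counting baseline ranks functions by the number of
direct PIN neighbours carrying them and annotates with all of them.

## Synthetic data

The generator plants a partition: `n_modules` disjoint modules whose
within-module pairs interact with probability `p_in` and cross-module
pairs with `p_out`; each module owns `funcs_per_module` GO terms
annotated to all members, `domain_pool_per_module` domains sampled onto
members (1 to pool-size each), and a `complex_coverage` fraction of its
members recorded as one complex. Defaults — 10 modules × 20 proteins,
p_in = 0.3, p_out = 0.01, 3 terms/module, no annotation noise, 3-domain
pools, coverage 0.5 — give ~5.7 within-module partners per protein and
put every planted term inside the 10..200 evaluation window.
`annotation_noise` swaps a protein's whole function set for a random
other module's, emulating wrong (not merely missing) annotations. All
sampling flows from one seed; equal seeds give byte-identical files.

What this does **not** emulate: scale-free degree distributions, hubs and
date/party interactors, overlapping modules and moonlighting proteins,
the GO hierarchy (terms are independent symbols), correlated
domain–complex–interaction noise, and literature-driven annotation bias.
Perfect recovery on the default dataset therefore shows the pipeline is
internally consistent and signal-faithful, not that real-proteome
accuracy would be near 1; the noise and p_out/p_in knobs probe graceful
degradation only within the planted-partition world.

## Problem sizes in the shipped runs

The test suite exercises graphs up to 50 nodes for propagation oracles,
exhaustive 4-node (plus sampled 8-node) graphs for the fitness oracle,
and 200-protein planted datasets for end-to-end recovery (LOOCV over all
200 proteins, 5 seeds × 3 noise levels for the monotonicity check). The
acceptance script runs the 200-protein benchmark with 10 ten-fold
repeats. These sizes were chosen so a full run completes on one CPU in
minutes while keeping every estimate's sampling error far below the
asserted margins.

## Known limitations

- The cross-coupled walk's convergence bound (`α·σ_max(H) < 1`, above) is
  a property of the update equations as defined; there is no damping or
  renormalization fallback.
- Exact term matching only: no GO-hierarchy-aware partial credit, and no
  propagation of predictions up the ontology.
- The per-target module is a single non-overlapping set; proteins active
  in several processes get one merged candidate pool.
- Identifier harmonization is exact string matching after whitespace
  trimming; inputs must already share one labelling system.
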