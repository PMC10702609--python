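# Methods

This note documents the models, conventions and design choices behind
`strucnet`: what the pipeline computes, what the synthetic-data generator
does and does not emulate, and where genuinely open choices were settled.

## Data model

A subject's connectome is a symmetric 72×72 matrix of nonnegative integer
streamline counts with zero diagonal, indexed by a fixed bilateral atlas of
36 left and 36 right regions.  Region abbreviations are the external keys;
matrix order equals region-table order, which prevents silent index drift
between files and matrices.  Left/right homolog pairing is positional (the
i-th left region pairs with the i-th right region), because the packaged
region table lists the two hemispheres in matched order; this resolves
abbreviation pairs that no prefix rule could (IntC↔RIC, IC↔RInfC, RA↔RRN).

Four analysis scopes reflect where tracking seeds sit: `ipsi-L`/`ipsi-R`
restrict to one hemisphere's 36×36 block; `contra-L`/`contra-R` retain the
full 72×72 graph (seeding one hemisphere still tracks its within-hemisphere
connections) and expose the 36×36 cross-hemisphere block for pairwise
comparison and display.  Composite seed ROIs (hippocampus = CA1+CA2+CA3+DG,
amygdala = COA, caudate = CP, per side) restrict the graph to edges incident
to their members; by default members collapse to a single node whose edge
weights are member-row sums, while `collapse=False` keeps the full node set
(only non-incident edges are zeroed) — the convention under which seeded
tracts are still mapped onto all 36 ipsilateral regions, and under which a
composite of an entire hemisphere degenerates to the plain ipsilateral
graph.

## Graph construction

Weights are normalized so the maximum entry is 1, then every weight below
the extraction threshold (default 0.001, i.e. 0.1% of the maximum) is set
to zero.  The order normalize → threshold is a documented choice, not an
external fact: it is the only order under which a 0.001 threshold does
anything to integer counts, and applying normalize+threshold twice is
exactly a no-op (property-tested).

## Network metrics

All metrics use Brain Connectivity Toolbox weighted-undirected conventions
on weights in [0, 1]:

- **Clustering (Onnela)** per node:
  C_i = Σ_{j,k} (w_ij w_jk w_ki)^{1/3} / (k_i(k_i−1)), zero for degree < 2.
- **Distances**: Dijkstra on edge lengths 1/w; unreachable pairs are +∞.
- **Characteristic path length**: mean of finite off-diagonal distances;
  the count of unreachable pairs is reported rather than silently dropped.
- **Global efficiency**: mean over ordered pairs of 1/d with 1/∞ = 0.  The
  literal "inverse of the characteristic path length" variant is exposed as
  `variant="inverse_cpl"`; the two differ only on disconnected graphs, and
  the mean-inverse-distance form is the reference-toolbox definition.
- **Local efficiency**: per node, the global efficiency of the weighted
  subgraph induced on its neighbors (Latora–Marchiori convention).
- **Small-worldness**: σ = (C/C_rand)/(L/L_rand) over a null ensemble of
  degree-preserving double-edge-swap rewirings (default 20 graphs, ~10
  successful swaps per edge, seeded) with the original weight multiset
  shuffled onto the rewired edges.  Graphs admitting no valid swap (e.g.
  complete graphs) fall back to weight shuffling with a warning, so a unit
  complete graph yields σ = 1 exactly.  Note that σ here is the standard
  normalized ratio (≈1 for random graphs); tractography suites that report
  unnormalized small-worldness on very different magnitudes (e.g. 1e-4) are
  not comparable and no attempt is made to match such values.

Every metric is verified against exhaustive brute-force oracles (triangle
enumeration, all-simple-paths distances, literal neighborhood subgraphs) on
all fixture graphs of ≤ 8 nodes to 1e-10, and clustering additionally
against networkx.

## Statistics

**Edgewise comparison** (per scope): enumerate the scope's distinct pairs
(630 within a hemisphere, 36×36 across); exclude pairs whose pooled zero
fraction across all subjects exceeds 50% (exactly half stays in; pooling
rather than per-group counting is a documented reading of "their
observations"); transform x ↦ ln(x+1) — the log base is irrelevant to t and
p by affine invariance, and the pseudocount of 1 maps zeros to 0; pooled
(equal-variance) two-sample t with df = n₁+n₂−2 — the pooled test, not
Welch, is what a stated df of 17 at n = 9/10 implies; Benjamini–Hochberg
step-up across included pairs only, excluded pairs carrying missing adjusted
p.  The signed matrix holds ±p_adj with + where the KO log-mean exceeds WT.
Zero-pooled-variance pairs yield t = 0, p = 1 when means agree and p = 0
with a `degenerate` flag otherwise, so NaNs never enter the FDR step.

**Metric-level tests**: unpaired two-tailed t per network parameter at
α = 0.05, deliberately uncorrected across the four parameters (they are
reported individually, not as a family).

**Per-ROI diffusion comparisons**: unpaired t per ROI per scalar (volume,
FA, AD, MD, RD), with the Benjamini–Krieger–Yekutieli two-stage step-up
across ROIs within each scalar family: stage 1 is BH at q′ = q/(1+q); the
stage-1 rejection count r₁ estimates m₀ = m − r₁ true nulls; stage 2 reruns
BH at q′·m/m₀ (r₁ = 0 → reject nothing; m₀ = 0 → reject all).  The
q/(1+q) two-stage variant is implemented and named explicitly.  Both BH and
BKY are validated against independent literal step-up oracles and against
statsmodels on random p-vectors.

**Tensor scalars**: MD = (λ₁+λ₂+λ₃)/3, AD = λ₁, RD = (λ₂+λ₃)/2,
FA = √(3/2)·√Σ(λᵢ−MD)² / √Σλᵢ², with FA of the zero tensor defined as 0.
MD = (AD+2·RD)/3 holds identically and FA is scale-invariant
(property-tested over random triples).

## Synthetic cohorts

The generator produces the data structure the pipeline assumes — it is a
study-design emulator, not a tractography simulator.

- **Propensities**: log-normal edge strengths (log-sd 1) drawn once per
  cohort and shared by all subjects; anatomy is cohort-level, subjects
  differ by sampling noise.  Cross-hemisphere pairs are attenuated (×0.3),
  matching contralateral totals ≈ 1.3× ipsilateral ones.  A fixed list of
  backbone tracts (callosal/corticostriatal/thalamocortical projections,
  intra-hippocampal connections, the fimbria, the amygdalo-piriform
  pathway; ×20) anchors the maximum weight the way dominant bundles do in
  real tractography — without them the max-normalizing edge can be a
  deficit edge, and halving the maximum *raises* every other normalized
  weight in the deficit group, an artifact rather than a signal.
- **Structural zeros**: each edge is absent with probability
  π_ij = zero_prob^(p_ij/p̄) (default zero_prob 0.5; p̄ = mean
  within-hemisphere propensity), drawn once per cohort: weak long-range
  pairs are mostly absent, strong tracts essentially never, and — as in
  real data — the same pairs are zero in every subject.  Per-subject
  zeroing was rejected because it makes null t-test p-values visibly
  non-uniform (measured KS distance up to 0.11), breaking FDR calibration.
  Deficit and backbone edges have the absence exponent floored at 8 (a
  multiplicative deficit on an absent tract is undefined); zero_prob = 1
  still forces an all-zero matrix.
- **Counts**: negative-binomial with size 10 per edge, independent across
  subjects and edges.  Size 10 (per-edge CV ≈ 32%) reproduces the
  few-percent coefficient of variation of hemispheric totals and the
  ~15–30% CV of subnetwork totals and per-subject network metrics seen in
  data of this kind.  The scale s is set per hemisphere so the expected
  within-hemisphere WT total (given the realized absence mask) equals
  5·10⁵; cross-hemisphere edges use the geometric mean of the two scales —
  each hemisphere is tracked from a fixed seed budget, so totals calibrate
  per seeding.
- **Deficit**: KO subjects' means are multiplied by `effect_factor`
  (default 0.5) on ten designated left hippocampus/amygdala edges, which
  also carry a ×4 strength multiplier (affected limbic tracts are robust,
  measurable pathways at several times the typical pair count, but below
  the backbone maximum).
- **Diffusion tables**: per homolog pair, baseline FA ~ U(0.1, 0.4), MD
  around 5·10⁻⁴ mm²/s, log-normal volume around 4 mm³; subjects add noise
  and KO subjects an optional additive FA shift.  Axially symmetric
  eigenvalue triples are built from (FA, MD) via δ = FA/√(3−2FA²),
  λ₁ = MD(1+2δ), λ₂ = λ₃ = MD(1−δ), and the scalars recomputed from them,
  so FA ∈ [0,1] and AD ≥ MD ≥ RD hold by construction.  Homologs share
  baselines, making left-vs-right comparisons null at zero shift.
- **Reproducibility**: one cohort seed expands via SeedSequence spawning
  into substreams for propensities, the absence mask and each subject;
  identical configuration and seed give bit-identical cohorts.

**What the generator does not emulate**: streamline geometry (a seeded
subgraph therefore contains only edges incident to the seed regions,
whereas real seeded tractography also links region pairs traversed en
route); spatially correlated noise across edges; region-volume coupling of
counts; hemispheric asymmetries.  Consequently, passing tests demonstrate
the correctness and calibration of the *procedures* under a realistic count
model — not that any particular biological effect in real data would be
detected.

## Operating characteristics at the study design

At the emulated design (9 vs 10 subjects, 36 regions, FDR 5%), measured by
the test suite and `scripts/acceptance.py`:

- under exchangeable groups, the edgewise pipeline's raw p-values are
  uniform (pooled KS distance ≈ 0.003 over ~45,000 tests) and the mean
  false-discovery proportion over 200 null cohorts stays within Monte-Carlo
  error of the nominal 5%;
- with the 0.5× ten-edge deficit, ≥ 6 of 10 deficit edges are recovered at
  FDR 5% in ~90% of replicates;
- hemisphere-wide network parameters, by contrast, are insensitive to a
  ten-edge deficit: the systematic group gap is ~0–2% (clustering ≈ 0)
  against ~22% per-subject metric CV, so the direction of the group-mean
  difference is close to a coin flip.  This is a property of the design,
  not a defect of the code: whole-hemisphere summaries average over 630
  pairs, and a localized deficit must be caught edgewise (or with seeded
  pathway analyses whose weight is concentrated on the affected tracts).

## Numerical choices and degenerate inputs

Matrix files round-trip at 17 significant digits (read∘write exact to
1e-12); asymmetries ≤ 1e-9 are silently symmetrized, larger ones symmetrized
with a warning.  Edgeless graphs yield a flagged-missing path length rather
than an exception; single-node graphs have zero efficiency; disconnected
pairs contribute zero to efficiencies and are excluded, with a count, from
L.  FA clipping guards only roundoff just past 1.  All simulation sizes in
the test suite (200 null cohorts, 100 deficit cohorts) were chosen as the
smallest ensembles whose Monte-Carlo error is well below the margins being
checked.
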