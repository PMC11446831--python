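# Methods

This note documents the models and procedures implemented in `cotype`, the
defaults they ship with, and what the synthetic benchmark does and does not
establish about real data.

## Morphological similarity

Skeletons are conditioned before comparison: terminal twigs shorter than
5 µm are removed iteratively (the root-bearing segment is never deleted),
and branches are resampled to an even arc-length spacing.  Two presets
mirror common practice — 0.5 nodes/µm for coarse cross-dataset matching and
1 node/µm for co-clustering — and both are exposed; neither is asserted as
canonical for new data.

A neuron is then a *dotprops*: its points plus a unit tangent per point,
the first principal axis of the point's k-neighbourhood (k = 5).  Tangent
sign is meaningless, so only |dot| enters scoring.  The query→target score
is

    S(q→t) = Σ_i |u_i · v_{m(i)}| · exp(−d_i / σ),

summing over query points, with m(i) the nearest target point, d_i the
distance to it, and σ = 3 µm.  Published NBLAST work trains a tabulated
log-odds score matrix over (distance, |dot|) bins; that matrix is an input
artifact we do not re-derive, so the default kernel is the parametric form
above — monotone in the same two arguments — and a tabulated matrix can be
loaded from CSV where one is available.  Scores are self-normalized
(S(q→t)/S(q→q), so identity scores 1) and symmetrized as
min(forward, reverse), the conservative choice for matching.  The
clustering distance is `1 − min-normalized score`, clipped to [0, 2].

Left-side neurons are mirrored across the midline plane (x → 2x₀ − x,
tangent x-component negated) before any cross-side comparison; mirroring is
an exact involution.

## Connectivity profiles and distances

For each query neuron the profile row holds, for every cell type shared by
*all* datasets, the synapses received from (in) and sent to (out) members
of that type in the neuron's own dataset.  Restricting columns to
cross-identified types is essential: connectivity matching is only defined
relative to a corpus of shared labels, which in practice comes from a prior
morphological matching round.  Partners without a shared label contribute
nothing (they are counted, not bucketed into an "other" column, since the
method conditions on cross-identified types only).

Distances between rows are cosine distances.  Cosine is invariant to
positive per-row scaling, so a neuron whose entire profile is scaled by its
hemisphere's reconstruction completeness is unmoved; for this reason
profiles default to raw weights and per-row normalization is offered only
for reporting.  Whether per-column scaling would help is an open question;
columns are left raw.  Zero rows have no defined angle: they are set to
distance 1 from everything and flagged.  Combined distances are the
elementwise sum of connectivity and morphology distances (1:1 by default);
connectivity alone suits types that tile a neuropil, while the morphology
term prevents mixing of spatially overlapping types.

## Balanced-cluster typing

Pooled neurons are clustered with the Ward algorithm applied, via the
Lance–Williams recurrence, directly to the given (generally non-Euclidean)
distance matrix; distances are not squared first, and ties in merge height
resolve by scipy's deterministic ordering.  A dendrogram node is *balanced*
when (1) every dataset is represented and (2) max per-dataset count
≤ `max_ratio` · min + `abs_slack`.  "Approximately equal" is not quantified
in the underlying literature; the (2.0, 1) default is a first-class
parameter recorded in output metadata.

Extraction descends depth-first from the root: at a balanced node it
descends only if *every* child is balanced, otherwise it emits the node as
one cluster; at an unbalanced node it keeps searching its children.  Leaves
under subtrees that are never balanced stay unassigned — how such neurons
should be labelled is ultimately a manual-review question, so the package
reports them rather than forcing a label.  Requiring all children balanced
(instead of emitting balanced children and re-merging stragglers)
guarantees the output is the unique minimal antichain of balanced nodes and
keeps the procedure deterministic.  Manual overrides (neuron → type) can be
applied after extraction.  Tests verify the implementation against an
independent characterization: a node is emitted iff it is balanced, is a
leaf or has an unbalanced child, and every balanced ancestor has
all-balanced children.

Two typings are compared on their shared neurons through the bipartite
type-overlap graph; each connected component is 1:1, split (1:many), merge
(many:1) or recombination (many:many) by its type counts on either side.

Persistent morphology groups: given several clusterings of overlapping
neuron sets (e.g. one-, two- and three-hemisphere runs of a pluggable
density clustering such as HDBSCAN), a neuron keeps a group label only if
its cluster's member set — restricted to the common universe — is identical
in every run.  This is the strictest reading of "consistently
co-clustered": a neuron that gains or loses partners between runs is left
unlabelled, matching the observation that morphologically unique early-born
neurons often fail to participate.

## Technical-noise model

The model asks how much left/right edge-weight discrepancy reconstruction
artifacts alone would produce.  Observed weights are inflated to a fictive
"100%" table by dividing by the postsynaptic completion rate of each edge's
neuropil (52.5% → ×(100/52.5) ≈ 1.9).  The fictive weights stay fractional;
they are integerized only at draw time by expectation-preserving stochastic
rounding.  Each simulation round then

1. draws synapses without replacement per neuropil down to the completion
   rate (multivariate hypergeometric across edges),
2. deletes each drawn synapse with probability 1 − recall (default 0.77),
3. adds false positives with expected count TP·(1−p)/p (precision
   p = 0.72), allocated across edges proportionally to fictive weight —
   correlated detection noise; a configurable share lands on uniformly
   random pairs instead, and a uniform-allocation alternative exists behind
   a flag since the allocation is not specified by the source analyses.

The operation order (completion → false negatives → false positives) is
configurable and recorded.  Each round makes a second draw with left/right
completion rates swapped; per non-flipped weight 1–30 (heavier edges are
too rare to bin stably) the mean and 5–95% quantiles of the paired
difference form the envelope.  The fraction of observed left/right pairs
inside the envelope at their left weight is the technically explainable
variability; the per-weight excess of observed spread over envelope spread
is reported as biological.

Two caveats are inherent to the procedure and retained deliberately: the
fictive table is inflated from an *already noisy* observation (detection
errors are not inverted before inflation), and the identity limit
(completion = precision = recall = 1) reproduces the input exactly, which
the tests assert bitwise.

*Calibration and discreteness.*  When pseudo-observations are drawn from
the model itself, the fraction inside the 5–95% envelope should be 0.90.
On integer differences this is not achievable with plain empirical
quantiles: counting boundary atoms as inside over-covers (≈ 0.94 at the
default conditions) and excluding them under-covers (≈ 0.83), because the
atoms at weights 1–4 carry several percent of mass each.  The module
therefore offers a standard continuity correction — dither the integer
differences with U(−½, ½) before both quantile estimation and containment —
under which attained coverage matches the nominal mass (measured 0.899).
The correction is off by default (scoring real observations keeps the plain
inclusive semantics) and is switched on for the self-consistency check.

## Kenyon-cell rate model

KC activity is h = W·r with inputs zero-mean and unit-covariance, so
C = W·Wᵀ and

    dim(h) = (Tr C)² / Tr(C²).

Each of the M rows of W has K entries 1 − α and N − K entries −α at
uniformly random positions, α = A/M with A = 100, N = 58 channels.
`dimensionality` evaluates the trace identities on the N×N Gram matrix
WᵀW (same trace and Frobenius norm as C, O(MN²) instead of O(M²N)); the
Monte-Carlo route through sampled inputs exists only as a test oracle.
Sweeps over K use common random numbers across K (the same derived seed per
realization) to sharpen cross-K comparisons, and argmax ties break toward
smaller K.  The model's simplifications are retained, not repaired: binary
(two-level) weights, a single global inhibition value, a fixed K for every
cell, and a linear rate code.

Observed K counts, per KC, the distinct input channels (glomeruli) with
total weight ≥ a threshold (default 1, i.e. unthresholded; a sweep mode
shows how filtering weak connections lowers K).  The channel map is an
explicit input — glomerulus assignments are annotations, not something this
package infers.  The excitation/inhibition ratio divides each cell's share
of the excitatory population budget by its share of the inhibitory budget,
normalized to a population mean of 1; cells with zero inhibitory input are
flagged rather than silently dropped.

## Synthetic connectome generator

The generator defines the study conditions under which everything above is
validated.  Defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| datasets | a_left, a_right, b_right | two hemispheres of one brain plus a second brain's right, the three-hemisphere design used in practice |
| types × cells | 50 types, 2–8 cells/type | small-type regime where balance criteria bite |
| type-level weights | lognormal, µ=3.5, σ=1.2 | heavy tail; median ≈ 33 synapses per type edge, a minority of strong edges carries most synapses |
| edge density | 0.15 | ~7 in- and out-partners per type |
| count jitter (sd) | 0.3 within brain, 0.6 across | implies mean &#124;Δcount&#124; ≈ 0.34 / 0.68, matching reported within- / across-brain count differences of 0.3 / 0.8 |
| biological edge jitter | lognormal, CV 0.2, per *brain* | hemispheres of one brain share a biological realization; brains differ |
| completion | U(0.5, 0.9) per (dataset, neuropil) | realistic reconstruction range |
| precision / recall | 0.72 / 0.77 | reported synapse-detection rates |
| point jitter | 1 µm per neuron | within-type morphological variability |
| registration offset | 1 µm rigid shift per dataset | residual template-registration error shared by a dataset's neurons |

Left prototypes are exact mirror images of right prototypes; a mirrored
left neuron therefore NBLASTs its right twin at 1.0 when jitter is off,
which the tests assert.  Biological jitter is applied to the type-level
weights at brain level *before* the multinomial split across member pairs —
this is what makes within-brain similarity exceed across-brain similarity,
the defining contrast of the noise decomposition.  The registration offset
deserves emphasis: balanced-cluster extraction stops splitting inside a
true type only because within-type children are dataset-blocky, and in real
data that blockiness comes from shared per-dataset distortions (completion
rates on the connectivity side, registration residuals on the morphology
side).  A generator without the morphology analogue would be *less*
faithful and would over-split pure-noise subtrees.

What the generator does not emulate: neuropil geometry (synapses carry a
label, not a location — truncation boxes clip morphology only),
neurotransmitters, developmental lineages, continuous "daisy-chain"
morphology spectra, and segmentation merge/split errors.  Passing the
planted-recovery benchmark therefore shows the pipeline is correct and
well-calibrated under these conditions, not that real cell types are as
cleanly separable.

## Numerical choices and degenerate inputs

- All randomness flows through `numpy.random.default_rng` seeded via
  blake2-derived per-stage seeds (< 2³¹), so every stage is independently
  re-runnable and byte-deterministic.
- Quantiles use numpy's default linear interpolation everywhere; the
  continuity correction above addresses the one place discreteness matters.
- Zero-input targets, zero profiles, zero pooled variance and zero
  inhibitory budgets warn or flag rather than raise, so batch analyses
  survive degenerate rows; structural errors (cycles, duplicate ids,
  non-involutive flip maps, missing completion rates) raise immediately
  with the offending name.
- Writers emit sorted, deterministic row order; manifests record content
  hashes.

## Problem sizes used in validation

The shipped validation runs at sizes where every check is exact or has
negligible Monte-Carlo error on one CPU: 50-type/~700-neuron connectomes
for recovery, 200 random dendrograms (≤ 14 leaves) against exhaustive
enumeration, 550-edge tables × 500 rounds for the noise envelope, 600
edges per weight × weights 1–30 × three retention rates for the thinning
curve, and 20 realizations per K for the M = 1,920 vs 3,840 dimensionality
ordering.
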