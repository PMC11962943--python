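# Methods

This note documents the models implemented in `tmegraph`, the choices made
where the design was genuinely open, and what the synthetic cohorts do and
do not establish about behavior on real tissue.

## Cellular graphs

Cells are treated as points (segmentation centroids) in a per-image µm
frame; no coordinate normalization or registration is applied.  The graph
is complete within each image with Gaussian weights
w = exp(−α d²), α = 0.01 per µm² by default, and unit self-loops.  Patients
with several tissue cores contribute one graph per core, merged as
disconnected components, so multi-core patients need no special handling
downstream.  Patients with fewer than `min_cells` cells in total (default
500, summed over their images, strict `<`) are excluded before any
analysis: tiny cores produce unstable pattern histograms.

The default is the exact dense graph.  `sparsify_epsilon` zeroes weights
below a cutoff as an opt-in efficiency knob for very large images
(ε = 1e−6 is a reasonable choice above ~20k cells); each zeroed weight is
below ε, so a depth-h convolution changes by at most ε·N per hop.

For the classic WL comparator the graph is binarized: an edge is kept iff
w ≥ 0.01, equivalently a centroid distance of at most ~21.46 µm, so 21 µm
is the largest integer distance that keeps an edge.  The threshold
comparison is `≥` so that the 21 µm geometry holds exactly.

## Subtree embeddings

Depth-h subtree embeddings are the rows of A^h X(0) where X(0) one-hot
encodes phenotypes in a fixed vocabulary order (serialized with every
model).  The iterative sweep and the matrix-power form are algebraically
identical; both are implemented (dense and CSR) and agree to ~1e−12.
Because features start as one-hots, the total mass of row i equals the i-th
row sum of A^h — a conservation law the tests assert.  The neighborhood
threshold τ (default 0.01 on (A^h)_ij) affects only the reported
neighborhood sizes and radii, never the embedding values.

## Pattern discovery

Pooled embeddings from the whole discovery cohort are clustered
PhenoGraph-style: exact Euclidean k-NN (k = 100), each k-NN edge reweighted
by the Jaccard overlap of its endpoints' neighbor sets, then Louvain
modularity maximization (resolution 1.0) via igraph, seeded for
reproducibility.  Patterns are relabeled by descending size.  Embeddings
are clustered raw (unnormalized): signatures are arithmetic means of member
embeddings, which presumes no row scaling.  Neighbor ties are resolved by
index order; with continuous coordinates exact ties have measure zero.

A known behavior of this clustering — inherited from PhenoGraph and
modularity maximization generally — is over-partitioning of continuous
embedding clouds: a single "true" niche type whose local density or
composition varies smoothly is typically reported as several patterns
(e.g., a dense-core and a sparse-rim variant).  These splits are pure
(each sub-pattern belongs to one niche type); downstream analyses that
aggregate over patterns (histograms, kernel, subgroups, characteristic
patterns) are robust to them, but the number of patterns C should not be
read as the number of distinct biological niches.  C is emergent and
data-dependent; no attempt is made to force a particular C.

Pattern categories: signature mass is summed per phenotype category
(tumor / immune / stromal) and normalized; the pattern is the argmax
category when that share is ≥ 0.5 (ties and the boundary go to the
category), otherwise an *interface* niche.  The 0.5 cutoff is configurable;
it encodes "no single compartment dominates" as the definition of an
interface.

## Population level

Patient histograms are compared by cosine similarity (unit diagonal by
construction; the matrix is a normalized Gram matrix, hence PSD).  Before
community detection each patient's k★ = 30 most similar *other* patients
form its NN set — self-exclusion is our choice where the construction is
ambiguous; including self would add a constant to every IoU — and edges
carry the IoU of the two sets, zero-IoU pairs omitted.  Louvain (seeded,
modularity reported) yields subgroups labeled by descending size then
smallest patient index, so reports are stable across reruns.

## Characteristic patterns and survival

Histograms are normalized per patient to proportions.  For each (subgroup,
pattern), the Hodges-Lehmann statistic is the median of all |in|×|out|
pairwise differences of proportions (even grids: mean of the two central
order statistics).  A pattern is characteristic when its statistic strictly
exceeds 0.5 × the subgroup maximum; if the maximum is ≤ 0 nothing is
selected and a warning is emitted.  Selection is scale-invariant.

Survival machinery delegates to lifelines: Kaplan-Meier product-limit
curves, the G-sample log-rank test, and per-subgroup univariate Cox fits of
the binary in/out indicator with patients outside the subgroup as baseline.
Efron tie handling is used (a documented default, not a claim of
faithfulness to any particular convention); p-values come from the
log-likelihood-ratio test; CIs are normal-approximation on the
log-hazard scale.  Degenerate fits (a level with no events, separation)
are reported as non-estimable rather than raised.  Pattern positivity uses
proportion ≥ 1 % (boundary inclusive).  All p-values are two-sided and
**no multiple-testing correction is applied anywhere** — callers screening
many patterns should apply their own.

## Cohort mapping

All three mapping levels are nearest-centroid assignments with ties broken
to the lower index and logged: cells to per-phenotype mean expression over
the shared antigen list (expression used as provided; an optional
per-antigen z-scaling flag exists, default off, since no normalization
convention is implied by the construction), subtrees to pattern signatures,
and patients by a κ-weighted vote among the 3 most similar discovery
patients (vote ties fall back to the single most similar neighbor).

## Synthetic cohorts

`simulate_cohort` plants the structure the pipeline assumes: niche
archetypes (phenotype mixtures with spatial extent), patient subgroups as
archetype mixture profiles, and subgroup-linked survival.  Defaults: 60
patients in 3 balanced subgroups; 3 archetypes with distinct dominant
phenotypes whose mixtures spread over all six phenotypes
(0.5/0.2/0.1/0.1/0.05/0.05), radius 12 µm, 8 cells per niche placed
isotropic-Gaussian with σ = radius/2; 5 niches per patient with centers at
least 3 radii apart on a 700 µm image; ~8 uniform background cells per
patient; subgroup profiles 0.9/0.05/0.05; exponential survival with
subgroup hazards 0.08/0.03/0.01 per month and an independent exponential
censoring clock (rate 0.015).  Everything derives from one seed;
regeneration is byte-identical.

The mixture and geometry defaults were chosen so that within-archetype
embedding variation (local density and neighborhood composition noise) is
roughly isotropic across several phenotype dimensions rather than
concentrated along one axis: strongly anisotropic clouds are exactly the
regime where modularity clustering over-partitions hardest.  Even so, the
generator's archetype clouds are continuous, and the clustering typically
reports the three archetypes as ~3–4 patterns plus one low-mass pattern
per background phenotype; at the patient level the planted subgroups are
recovered cleanly (adjusted Rand index ≥ 0.85 in pilot runs) and held-out
cohorts map back to the correct subgroup with ≥ 0.9 accuracy.

What the synthetic cohorts do *not* emulate: segmentation error, antigen
spillover, per-image staining batch effects, spatially varying background,
non-exponential hazards, or niches with internal architecture.  Passing
planted-recovery tests therefore shows the pipeline's statistical machinery
is wired correctly, not that it resolves subtle niche biology in real
tissue.

The fixed `worked_example_cohort` (3 patients, ≤ 12 cells each) uses
distances chosen to make weights land on round values (10 µm → e⁻¹) so
embeddings, histograms, and kernel values can be verified by hand or by the
dense matrix-power oracle in the tests.

## Numerical choices and problem sizes

Kernel values are clipped to [0, 1] and the matrix symmetrized against
~1e−16 float drift; PSD is asserted to −1e−8.  Dense and sparse
convolution paths must agree to 1e−9.  Louvain runs (subtree- and
patient-level) are seeded; modularity is reported so near-ties are visible.
The test suite exercises cohorts of 12–60 patients (~0.5k–3k pooled
subtrees), 200 simulated Cox fits at n = 500 with ~20 % censoring, and 400
null log-rank simulations at n = 150 — sizes at which every oracle
comparison (brute-force IoU, difference-grid medians, exhaustive
subtree-isomorphism enumeration up to 6 nodes) runs exactly.

## Known limitations

- Pattern counts are resolution-dependent (see over-partitioning above);
  merging related patterns is left to the user via signatures and
  categories rather than automated.
- The Gaussian kernel fixes one spatial scale (~30 µm neighborhoods at
  h = 2); multi-scale structure needs multiple runs with different α or h.
- k-NN determinism across platforms depends on the tree-based search's
  handling of exact ties; with continuous data results are reproducible
  for a fixed seed and input order.
- The FEATHER-style graph-embedding comparator is not implemented; any
  per-patient embedding matrix can be fed into the same population-graph
  and survival stages instead.
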