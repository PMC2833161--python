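# Methods

This note documents the models, numerical choices, and defaults behind
envclust, and what the synthetic benchmarks do and do not demonstrate.

## Microenvironment vectors

A microenvironment is the spherical region of radius `radius_angstrom`
(default 7.5 Å) around a site's center atom, described by per-shell property
counts over `n_shells` (default 6) equal-width concentric shells.  Distance
bins are half-open [inner, outer) measured from the center atom, with the
outermost shell closed, so a point at exactly 7.5 Å is still counted.  For
cysteine-centered sites the center is the SG atom, falling back to CB then
CA (with a logged warning) when SG is absent.

The packaged property extractor (`simple_properties`) is a deliberately
simple **surrogate**: per shell it counts the 20 standard residue-type
presences (a residue counts once per shell in which it has at least one
atom), C/N/O/S atoms, aromatic-ring atoms (PHE/TYR/TRP/HIS ring systems),
and a signed charge sum (+1 for LYS NZ and ARG CZ, −1 for ASP CG and GLU CD
in the shell — the side-chain terminal heavy atoms standing in for the
formal charge).  It is *not* a full physicochemical description (no solvent
accessibility, secondary structure, hydrophobicity, or partial charges), and
no pipeline correctness claim rests on it: the clustering and selection
machinery is validated on synthetic vectors with planted structure.

Standardization divides each feature by its population (divisor n) standard
deviation over the entire set; features are scaled but not centered
(centering happens inside PCA, which is standard practice and makes the
reduction invariant to feature offsets).  Constant features keep divisor 1
so no NaNs propagate.  Standardization is idempotent up to 1e-9.

Disulfide exclusion uses an SG–SG distance threshold of 2.5 Å (the covalent
bond is ~2.05 Å); this geometric heuristic removes bonded pairs without
requiring connectivity records.

## Reduction

PCA is fitted on standardized vectors with a deterministic sign convention:
each component is flipped so its largest-magnitude loading is positive.
Explained variances use the population convention so they sum to the total
population variance.  Default `n_pc` = 80; cosine geometry enters only at
the clustering stage, mirroring the pipeline ordering (standardize → reduce
→ unit-normalize → cluster).

## Coarse phase: spherical k-means

Rows are unit-normalized (all-zero rows are rejected) and clustered under
the distance 1 − cosine; centroids are normalized member means, which is the
optimizer of summed cosine similarity.  Initialization is k-means++ seeding
adapted to cosine distance; iteration stops at an assignment fixed point,
objective improvement < `tol` (1e-6), or `max_iter` (300).  The objective is
asserted non-increasing every iteration.  Empty clusters are reseeded with
the point cosine-farthest from its centroid.  `restarts` (default 10 in the
CLI, 3 in the pipeline for speed) keeps the run with the lowest objective,
ties to the lowest seed.  k is a user parameter (study default 40); the
sweep harness in `evaluate` measures enrichment/silhouette/purity over a
(k, n_pc) grid when reference labels exist.

## Fine phase: merge trees

Single-linkage agglomeration under cosine distance is computed exactly with
an explicit tie-break: among minimum-distance candidate pairs, the pair
whose (smaller, larger) minimum-leaf-index key is lexicographically smallest
merges first.  This makes merge order fully deterministic, which scipy's
MST-based implementation does not guarantee under ties; the implementation
is verified against a brute-force O(n³) re-computation on random instances.
Trees are always built per coarse cluster, never globally.

Node correlation C is the cosine similarity between the unit-normalized mean
vectors of a node's two branches, clamped to [0, 1].  The branch mean of
unit vectors is the natural centroid under cosine geometry; clamping honors
the statistic's defined range (an anti-correlated pair is simply "not
coherent", C = 0).

## Functional coherence (F)

Documents (title + abstract) become weighted word vectors with weight
log(1 + tf) · ln(n_docs/df), unit-normalized, compared by cosine; each
document's m = 20 most similar documents are its semantic neighbors (never
itself; ties broken by document id; m capped at n_docs − 1).  Documents
flagged as large-scale surveys are dropped from the corpus at construction —
they reference so many proteins that they carry no cluster-specific signal.

For a candidate cluster, a document's *fractional reference* is the share of
its mapped proteins inside the cluster; a document's *score* is the sum of
fractional references over its semantic neighbors (bounded by m).  Per
protein, scores of its documents are floored into integer bins to form an
observed distribution, compared by KL divergence to a Poisson with rate λ =
the protein's mean score (floored at 1e-6); F is the mean KL over proteins
that have documents.  Proteins with no surviving documents are excluded from
the mean (not scored 0) so corpus sparsity does not silently deflate F; the
exclusion count is always reported.

Three constructions here are package decisions where the statistic's source
description leaves latitude: the tf-idf weighting scheme, integer-floor
binning, and λ = per-protein mean.  Each is a config knob with the defaults
above.  Two consequences worth knowing:

* On a perfectly clean synthetic corpus where every neighbor's fractional
  reference is 1, every document scores exactly m, and F saturates at
  −ln Poisson(m; m) ≈ 2.42 for m = 20.  Real corpora (and synthetic corpora
  with `shared_doc_rate` > 0, see below) disperse the scores and push
  coherent clusters well above this.
* F is scale-dependent on corpus structure, so the F > 3.0 default filter is
  an empirical cutoff appropriate to a realistically messy corpus; on clean
  synthetic corpora a lower cutoff (or the off-switch F ≡ 0) is appropriate.

## Scoring and selection

The combined node score is S = N^e · (w_C·C + w_F·min(F, F_cap)/F_cap) with
e = 1, w_C = w_F = 0.5, F_cap = 10 — linear in N, strictly increasing in C
and in F below the cap.  Capping and normalizing F onto [0, 1] is what makes
"approximately equal weighting" of a bounded and an unbounded statistic
meaningful; all four constants are configurable.  Nodes whose proteins have
no documents score with F = 0 (warning logged) so selection never aborts.

Selection is a bottom-up dynamic pass: best(node) = max(S(node),
best(left) + best(right)), displacing descendants only on *strict*
improvement.  The result is a disjoint antichain maximizing total score,
verified against exhaustive antichain enumeration on small random trees, and
asserted disjoint on every run.  Filters: N ≥ 5 (min_size) and F strictly
greater than 3.0 (fc_cutoff); the complementary high-C/low-F list is
available for inspecting physically tight but literature-poor clusters.

`recluster_stability` pools the member sites of several selected clusters,
re-runs tree + selection on the pooled set, and reports exact-recovery flags
plus a site accounting (recovered + changed + singletons = pooled size) —
the robustness check for coarse-phase boundaries.

## Annotation

The counting entity is the protein throughout: a protein carries a
categorical term if its table says so, and a literature term if any of its
documents contains it (this stops one heavily published protein from
inflating k).  p-values are upper-tail hypergeometric P(X ≥ k) via the
log-space survival function; Bonferroni multiplies by the number of distinct
terms observed in the cluster for that category (the hypotheses actually
tested), corrected cutoff 0.01.  Tokenization lowercases, splits on
whitespace/punctuation keeping intra-word hyphens, and removes packaged stop
words; unigrams and consecutive bigrams are terms.  The entropy score uses
H_t = −Σ_p D_tp ln D_tp over the cluster's per-protein document counts for
the term, normalized by the cluster's maximum raw entropy before weighting
by idf_t = ln(n_docs/df_t); cutoff 2.7.  A term confined to one protein's
documents always scores 0.

## Synthetic data

`gen_vectors` plants unit-sphere clusters: rejection-sampled centers with
pairwise angle ≥ `separation_deg` (default 60°), members perturbed by
isotropic Gaussian noise with expected norm `noise` (per-coordinate sigma
noise/√dim) and re-normalized, so expected cosine to center ≈ 1/√(1+noise²)
independent of dimension (noise 0.1 → ≈ 0.995).  Background points are
uniform on the sphere, labeled −1.

`gen_corpus` builds topic-structured corpora: each topic owns a vocabulary
block (a `cross_overlap` share of which is shared across topics, default
0.05), and a document of a topic protein draws each word from its topic
vocabulary with probability `within_overlap` (default 0.8), otherwise from
the background vocabulary.  Defaults: 5 documents per protein, 60 words per
document.  `shared_doc_rate` (default 0) additionally maps each document to
a Poisson number of uniformly chosen extra proteins, emulating publications
that reference several proteins; without it every fractional reference is 0
or 1 and document scores cannot disperse.  Implanted categorical terms and
topic assignments are returned as first-class ground truth.

What the synthetic benchmarks show: the numeric kernels are exact (oracle
agreement), the coherence statistic discriminates planted from random
protein sets and degrades monotonically under dilution, the two-phase
clustering recovers well-separated planted structure exactly and its
boundaries are stable under pooling and re-clustering, and the whole
pipeline is bit-deterministic.  What they do not show: behavior on real
corpora with bursty vocabulary, citation skew, or annotation bias, nor the
adequacy of any particular property set for real structures — the surrogate
extractor is exercised only for plumbing correctness.

## Problem sizes and determinism

The shipped tests and the acceptance script run at deliberately small sizes
chosen to exercise every code path with exact or tight statistical checks:
150–170 vectors in dim 264, corpora of 200 proteins × 5 documents, 20–100
replicate clusters, 20 pipeline seeds.  All randomness flows through
`numpy.random.default_rng` seeded from explicit parameters; identical
config + seed reproduces every artifact byte-for-byte, including HTML.

## Known limitations

* The coherence statistic's absolute scale depends on corpus structure; the
  3.0 cutoff transfers only qualitatively to other corpora.
* Single linkage chains on diffuse data; the average/complete options exist
  behind the linkage switch for sweeps but selection defaults assume the
  single-linkage monotone merge-distance property.
* Hierarchical clustering is O(n²) memory per coarse cluster; very large
  coarse clusters (≫10⁴ sites) would need a different fine-phase backend.
* Enrichment is upper-tail only (discovery use-case); depletion is not
  tested, and no term-graph (GO hierarchy) awareness is implemented.
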