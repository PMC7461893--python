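# Methods

This note records the models, conventions and numerical choices behind
`semkos`, and what the synthetic experiments do and do not demonstrate.

## Term harvesting and recognition

Keywords are counted as occurrences in keyword sections (an article listing
the same keyword twice contributes twice); method names are the immediate
(first-level) subsection titles of any section whose lowercased title
contains `method` or `procedure`. Deeper subsection nesting is ignored:
first-level subtitles are where method names live in practice, and nesting
conventions vary too much across journals to harvest reliably. A surface
appearing in both lists is kept only as a method, so the keyword and method
vocabularies are disjoint and a keyword×method matrix is well defined.

Frequency filters are strict inequalities: keywords need source count > 5
and corpus count > 10, methods source count > 2 and corpus count > 10.
Rank ids (`kwd<r>`, `mtd<r>`) are assigned before filtering and never
reassigned, so ids remain stable identifiers across filter settings. Rank
ties break lexicographically by surface for determinism.

Recognition is greedy longest-phrase-first over word boundaries: words are
alphanumeric runs with internal hyphens kept (`short-term` is one word);
matches never cross sentence boundaries (`.?!`); after a phrase is emitted
its words are consumed, so embedded shorter phrases are not counted and
spans never overlap. All words outside the lexicon are dropped from the
streams — including stop words. Leaving stop words in would only add
high-frequency noise tokens to every context window; dropping them keeps
the streams purely terminological.

## Embedding

The trainer optimizes the skip-gram negative-sampling objective in a
count-weighted full-batch form. Windowed co-occurrence counts X (window 7
either side, within one article's stream) are collected once; each epoch
then performs 50 full-batch gradient steps on

    L = Σ_ij P_ij log σ(u_i·v_j) + k q_j log σ(−u_i·v_j)

where P is the row-stochastic normalization of X, q the unigram^0.75
context distribution, and k = 5 negative samples per center. The batch of
50 steps per epoch stands in for one pass of pairwise stochastic updates;
the learning rate starts at 0.025, drops by 0.002 each epoch and is floored
at 1e-4. Document vectors are trained the same way
(distributed-bag-of-words style) against the frozen context matrix, 10
steps per epoch. Initialization is uniform in ±0.5/dimension from the
configured seed; training is single-threaded and bit-reproducible.

A second registered backend, `ppmi_svd`, factorizes the positive pointwise
mutual information of the same counts by dense SVD; it is deterministic,
ignores the epoch schedule, and serves as a fast spectral alternative and
cross-check. Both backends satisfy the same contract (vectors for every
term with total count ≥ min_count, one vector per article).

Term vectors are normalized to unit length before clustering; on unit
vectors the Euclidean distance is a monotone transform of cosine distance,
so the merge order is metric-choice independent.

## Tree construction

Average linkage (UPGMA) is used because single linkage chains through
outliers and complete linkage is hostage to them; the average is the
natural compromise. Node labels follow a fixed convention: leaves 1..n in
input order, the k-th merge creates node n+k, hence the root is 2n−1.
Merge height is the exact mean pairwise distance between the merged
clusters, recomputed from the original matrix (never chained through
Lance–Williams updates), with a fixed summation orientation so results are
bitwise reproducible. Ties on the minimal average are broken by the
lexicographically smallest (min label, max label) pair. Average linkage is
reducible, so heights are non-decreasing along the merge order; this is
asserted on every built tree.

Branch review samples representatives by splitting a branch at its highest
merges first until the budget is reached, then drawing one leaf per
frontier subtree (seeded). The rationale: the deepest splits are where a
branch is most likely to mix concepts, so they are inspected first.

Level-2 annotations must be disjoint on terms; several sibling branches may
share one name when a paraphyletic group reads as a single concept. A
cluster's representation is the plain componentwise mean of its member unit
vectors — not re-normalized, so incoherent clusters have short
representations and coherent ones long. Level-3 groups re-cluster these
representations with the same UPGMA procedure; the default group count is
one per three level-2 clusters (coarsening by about 3× per level), always
at least 2. The landscape layout projects representations with PCA by
default (deterministic; any 2-D projector can be plugged in), dot area
equals the cluster's summed citations (proportionality constant 1), and
color keys are the level-3 parents.

## Co-occurrence statistics

The per-article correlation index C_ij = W·K_i·M_j / (ΣK)(ΣM) distributes
exactly the article's citation weight W over the keyword×method cluster
pairs it combines; K and M count token occurrences, not distinct terms.
Articles lacking either keyword or method tokens contribute nothing.
Consequences used as tests: per-article cell sums equal W to rounding,
aggregation is linear, and doubling all weights doubles every cell.

Cell-value histograms run from 10 to 400 at step 10 (39 bins); values below
10 or above 400 are discarded, and the top bin is closed ([390, 400]) so
the inclusive end of the range is counted. The power-law fit is ordinary
least squares of log count on log bin center over positive-count bins,
reported with r²; the exponent is the slope magnitude. This estimator is
only consistent when the bins are well populated: if the sampled support
extends far beyond the binned window, the tail bins are Poisson-sparse and
the fitted slope biases low. The recovery experiments therefore either
draw on the binned support (α = 2, 5000 draws on 10..400) or use enough
draws (50,000 of the citation law) that every bin's expected count is well
above 1.

## Article groups

Affinity propagation is pinned to damping 0.5, preference = median
similarity, similarity = negative squared Euclidean distance, 200
iterations with 15-iteration convergence window, and a fixed internal
random state — reproducible across environments. Non-convergence returns
the last-iteration labels with a flag and a warning (singleton fallback if
the backend yields no exemplars). Multi-round clustering re-clusters the
exemplar vectors of the previous round — exemplars are the algorithm's
native representatives, so "applying the same algorithm again" composes
naturally; counts are weakly decreasing and a round that collapses to one
cluster stops the recursion early.

Coverage of a term cluster over a group is the fraction of the group's
articles containing at least one member term (an exact function of
retrieval: coverage × group size = |retrieved ∩ group|). Profiles rank the
top-k clusters by coverage for whole collections and by coverage
difference against a reference for subgroups; the retrieval cluster itself
is excluded from its own keyword ranking by default.

## Synthetic corpora: what they emulate, and what not

Each generated article has a topic drawn from the planted keyword groups;
its author keywords and body mentions come from the topic's group, and
context words are group-specific with probability `group_separation` (else
drawn from a shared pool). Methods subtitles and in-text method mentions
draw from the method groups, with one keyword-group×method-group pair
boosted by a multiplier when an affinity block is configured. Bodies are
sentence-wise (8–20 words) so sentence-boundary rules are exercised, and
nested phrase pairs ("visual short-term memory" containing "short-term
memory") are planted in group 1 to exercise longest-first matching.
Citations are Zipf, p(c) ∝ c^−α on 1..10,000, drawn by inverse CDF.

Reference conditions: 10 keyword groups × 8 terms, 5 method groups, 2,000
articles, context pools of 30, separation 0.9, citation exponent 2.0.
Under these conditions the full pipeline (embedding dimension 50, 10
epochs) recovers the planted groups at ARI ≥ 0.8 when the keyword tree is
cut at the group count, across ≥ 95% of seeds.

The block-model experiment uses 5×5 groups, 6 terms per group, 600
articles, multiplier 10, and citation exponent 3.0. The exponent matters:
with tail index 1 (α = 2), the single most-cited article holds a
non-vanishing fraction of the total citation mass at any corpus size, so no
block structure can dominate the weighted aggregate reliably — block
detectability requires finite-mean weights, which α = 3 provides.

What the generator does **not** emulate: real syntax or grammar, polysemy
and synonymy, abbreviations, section-layout variation beyond the
methods-title synonyms, citation-network dynamics (the Matthew effect is a
distributional assumption here, not a mechanism), or correlated topics.
Passing tests therefore show that the machinery is correct and that the
pipeline recovers structure when the corpus statistics match its
assumptions — not that real corpora satisfy those assumptions.

## Degenerate inputs and edge rules

Zero-norm term vectors abort normalization with the term named; clustering
requires ≥ 2 items; annotation of overlapping level-2 clusters fails
listing the conflicting terms; missing citation entries count as 0 (with a
warning in the layout); an affinity-propagation call needs ≥ 2 units;
power-law fitting needs ≥ 3 positive bins. Pipeline stages are cached by
the hash of their parameters and upstream artifact hashes, so re-runs of an
unchanged configuration reproduce identical manifests without recomputing.

## Known limitations

The binary tree cannot express poly-hierarchy (a term belonging to two
parents), so some cross-cutting concepts land in exactly one branch. The
longest-first tokenizer cannot recognize discontinuous or inflected
variants (no stemming or synonym merging). Curation is recorded and
replayable but inherently manual: the automatic tree-cut annotation is a
starting template, not a finished KOS. Problem sizes in the test suite and
acceptance script (hundreds to thousands of articles, tens of terms per
tree) are chosen so the whole suite runs on a laptop; the algorithms are
quadratic-to-cubic in term count and are not tuned for vocabularies of
tens of thousands of terms.
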