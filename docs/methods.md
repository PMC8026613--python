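# Methods

## Coordinate model and input resolution

All coordinates are 0-based half-open. BED input is taken as-is; washU
`chr:start-end` pair strings are interpreted the same way; conversion happens
only in `genome_io`. The fragment map must tile each chromosome without gaps
or overlaps, which makes base-to-fragment lookup total over covered bases and
implementable as a binary search. Interaction rows are resolved to fragments
by **exact** start/end match (an optional ±1 bp tolerance accommodates
off-by-one dialects); nearest-fragment snapping is deliberately refused
because it can silently rewire edges. Duplicate rows for the same fragment
pair and condition keep the maximum score and sum read counts — the maximum
preserves significance while the summed counts remain interpretable as
coverage. Promoters are the 1 kb immediately upstream of the TSS,
strand-relative; unstranded rows default to + with a warning.

## Merged network and specificity

An edge exists when the interaction score reaches `sig_threshold` (default
5.0, the conventional significance cutoff for CHiCAGO-type scores) in at
least one condition. Specificity: significant in one condition and above
`support_threshold` (default 3.0) in the other → shared; at or below the
support threshold (or absent) → condition-specific. The stored label is
always recomputable from the stored scores (`classify_edge` is the single
point of truth, and tests assert the idempotence). Nodes enter only through
edges, so there are no orphan nodes; node specificity derives from incident
edges.

Interaction distance is the absolute difference of fragment midpoints:
symmetric, order-free, and honest about fragment-level resolution (anchors
within a fragment are not localisable). Trans edges carry no distance and
are excluded from distance statistics. Distance bands: long is strictly
> 1 Mb; the short/mid breakpoint is a reporting convention with no canonical
value, so it defaults to 100 kb and is configurable and echoed in output
metadata. Box-plot outliers (1.5 × IQR beyond the quartiles) are flagged,
never removed from statistics.

## Communities

Components of ≤ 10 nodes are partitioned by exhaustive modularity
maximisation over all set partitions (Bell(10) ≈ 1.2 × 10⁵, negligible at
that size); larger components use networkx's seeded multilevel (Louvain)
optimisation. The exhaustive branch exists because greedy local moves can
miss the global optimum even on 7-node graphs, and at desk scale exactness
is affordable. A component is split into its communities only when the best
partition's modularity reaches 0.7; note that a two-community partition can
never exceed Q = 0.5, so the gate intentionally keeps small bipartitions
whole. The split threshold, like every threshold, is recorded in run
metadata.

## Chromatin-state reduction

Fragments typically overlap several segmentation intervals. The reduction
rules are: no informative overlap → background; exactly one informative
state → that state; bivalent + Polycomb only → bivalent (bivalency subsumes
the Polycomb mark); any other mixture → mixed. A state counts toward a
fragment at ≥ 1 bp of overlap by default; `min_state_bp` raises that floor
for robustness analyses. Uncovered bases count as background, since
segmentations are genome-wide and gaps only arise from upstream filtering.
Transition matrices between conditions are reported as counts plus
percentages normalised within each destination state.

For the longest-interaction state profile, the bait side of an edge is the
end with a gene annotation; edges baited at both ends contribute one row per
direction (documented, and the bivalent-bait edge fraction counts each edge
once).

## Enhancers and super-enhancers

Peaks merge transitively when their gap is ≤ the stitching distance
(1.5 kb default, following the bimodal nearest-peak-distance rationale);
element signal is the sum of constituent signals, so stitching is
idempotent. The super-enhancer cutoff scales ranks and signals to [0, 1]
with min–max normalisation — which makes the cutoff invariant to affine
rescaling of the signal vector, a property the tests exercise — and takes
argmax(x − y), the tangent point of a slope-1 line on the convex rank curve.
Signal ties are broken by genomic order so ranks and the cutoff are
deterministic; an all-equal signal vector yields no super-enhancers (flat
curve, warning).

Element-to-gene mapping goes exclusively through the network: element →
overlapped fragments → condition-supported edges → baited fragments → genes.
An element sitting on a bait fragment still maps through edges only (no
self-targets). Gene classes (A-only / B-only / shared) partition the target
genes, and genes contacted by a super-enhancer in either condition are
removed from the plain-enhancer gene list so the two lists are disjoint.
Cross-condition element matching uses ≥ 1 bp overlap and preserves
one-to-many pairs, so shared counts may legitimately differ per condition.

Methylation per region is the pooled ratio 100·Σmeth/Σtotal over covered
CpGs; regions without covered CpGs are missing, not zero. Histone gain is
per-region Δlog2 > 1.0 by default; the set-level statistic is the log2 ratio
of linear-scale medians, reported separately.

## OSN occupancy and contingency

Factor peaks are merged when the gap is strictly below 100 bp (touching
always merges) and kept only where the merged region overlaps at least one
original peak of each of the three factors. Signal filtering uses tiled,
non-sliding 500 bp windows aligned to position 0 (configurable offset);
missing windows count as below threshold. Per-peak chromatin state uses the
state at the peak centre. Control regions are fixed-width (1.2 kb) uniform
draws allocated across chromosomes proportionally to length,
seed-reproducible, with rejection sampling against an optional exclusion
list.

The contingency universe is every network fragment in the active state in
either condition. Interaction change per fragment: lost = carries A-specific
but no B-specific edges; gained = the converse; retained otherwise (including
fragments with both, i.e. rewired-but-present). OSN change comes from
overlap with condition-labelled OSN peaks; "never" marks active fragments
without OSN in either condition. Each cell of the 4×3 matrix is collapsed to
a 2×2 (cell vs rest) with the sample odds ratio (0.5 added to every cell
when any count is zero, flagged), tested by chi-squared without continuity
correction, with Fisher's exact test substituted automatically when any
expected cell is below 5.

## Statistics

Mann–Whitney U uses the exact null for min(n₁, n₂) ≤ 8 without ties and the
tie- and continuity-corrected normal approximation otherwise (scipy backend;
tests verify both branches against independent enumeration and an
independently coded normal formula). The permutation overlap test redraws
each query region uniformly within its chromosome, width-preserving
(circular shifting available as an alternative); the empirical p-value uses
the +1 pseudocount convention and can never be zero. The number of
permutations, seed and strategy are recorded in the result. BH correction is
available for lists of contingency results.

## Layouts

The force-directed layout is a simplified ForceAtlas2: linear attraction
along edges (edge weight raised to a configurable influence), repulsion
proportional to (deg+1)(deg+1)/d between all node pairs, central gravity,
geometric step decay with early stopping on total displacement. Repulsion is
computed exactly but vectorised rather than via Barnes–Hut approximation:
at the network sizes this package lays out, exactness is cheaper than the
approximation's complexity, and the reproducible contract is qualitative
anyway — connected nodes end up closer than disconnected ones, identical
seeds give byte-identical coordinates, and all parameters are logged.

MDS is initialised from the classical-scaling eigendecomposition and refined
by SMACOF majorisation (deterministic, no restarts), reporting Kruskal
stress-1 over **all** node pairs — all-pairs keeps stress well-defined for
sparse graphs. Dissimilarity is pairwise linear genomic distance; a
single-chromosome node set is therefore exactly 1-D embeddable and reaches
stress ≈ 0, while trans pairs are clamped to the maximum cis distance and
flagged, which generally leaves residual stress. Fewer than three nodes are
placed analytically.

## The synthetic study generator

The generator emulates the statistical structure of a two-condition
promoter-interactome study on a 2 × 20 Mb genome of 4 kb fragments:

- **Communities**: 8 blocks of 10–25 fragments, intra-block edge probability
  0.5 plus a guaranteed spanning path (so each planted community is surely
  connected), inter-block probability 0.02 applied between genomically
  *adjacent* blocks (with one guaranteed link). Adjacency-limited coupling
  reflects the distance decay of contact probability and keeps the chained
  component's best-partition modularity (~0.8) above the 0.7 split gate;
  all-pairs coupling at the same rate would push Q below the gate and make
  community recovery structurally impossible.
- **Bridges**: 15 condition-B-specific edges spanning 1.04–2.7 Mb, of which
  80% join fragments bivalent in condition B (their condition-A states cycle
  through Polycomb, mixed — an active patch inside a Polycomb block, which
  exercises the mixed-state rule — and active). All other generated edges
  stay under ~0.5 Mb, so the bridges are exactly the longest B-supported
  edges.
- **Scores**: significant edges draw 5 + Exponential(mean 4); the
  second-condition score of a shared edge is either significant again or a
  sub-threshold support score Uniform(3, 5), exercising both shared paths.
- **Enhancers**: 12 super-enhancer loci (three constituent peaks each,
  signals 25–40) and 18 plain loci (single peaks, signals 1–4), each wired
  to its own baited gene with edge support matching the locus's condition
  presence (4 A-only / 4 B-only / 4 shared per tier); two extra plain
  enhancers contact SE-target genes so the SE-exclusion rule is exercised.
  The signal tiers are separated enough that the rank-curve cutoff always
  lands between them.
- **OSN coupling**: 500 enhancer fragments on the second chromosome, each
  with one edge to the nearest of 20 promoter hubs (< 1 Mb away) whose
  specificity encodes the interaction change; occupancy change mirrors it
  with probability 0.9 (the coupling rate) and is otherwise uniform over the
  four classes. OSN presence is realised as three overlapping factor peaks
  inside the fragment.
- **Expression / methylation**: SE-target genes carry a +2 log2 expression
  shift in their condition; A-specific enhancer loci go from ~25% to ~90%
  methylation (background ~20% → ~70%), mirroring enhancer decommissioning
  by DNA methylation.

The manifest records every planted structure, so downstream statistics are
checkable exactly. The null variant removes bridges, planted shifts and the
occupancy/interaction coupling and makes intra-community edge patterns
exchangeable between conditions; it backs the calibration tests (null log2
odds ratio within ±1, symmetric census quadrants, uniform null p-values).
Bundles are byte-identical across runs with the same seed. The bait count
(~90 genes) follows from the planted wiring (community genes, bridge
anchors, SE/enhancer targets, hubs) rather than being a free parameter.

## Problem sizes and determinism

Tests and the acceptance script run the full study at the sizes above
(≈ 10,000 fragments, ≈ 2,700 interaction rows), 1,000-replicate permutation
and enumeration oracles, 10,000-replicate type-I-error calibration and 100
null-study replicates — sizes chosen so the whole suite exercises every
stage end-to-end in a few minutes on one CPU. All randomness flows through
explicit seeds: the study definition has its own fixed seed (it is part of
the experimental design), while analysis-side seeds (community detection,
permutations, control sampling, null replicates) derive from the caller's
seed. Derived seeds stay below 2³¹.

## Known limitations

- The generator plants clean block structure; real interactomes have
  overlapping scales (nested sub-TADs, baited-fragment biases, distance
  decay within communities) that it does not emulate, so passing recovery
  tests demonstrates correctness of the machinery, not power on real data.
- CHiCAGO scores are simulated only as threshold-respecting draws; nothing
  about the caller's background model is reproduced, and score magnitudes
  carry no information here beyond the 3/5 thresholds.
- Genomic-distance MDS of a single-chromosome node set is exactly
  embeddable, so its stress is near zero by construction; informative stress
  values require multi-chromosome sets or non-metric dissimilarities.
- The force-directed layout is a visual aid with a qualitative contract;
  exact node positions are not comparable across implementations.
- The ibed dialect is the ten-column tab-separated form described in
  `genome_io`; the washU dialect is the three-column pair form. Both are
  auto-detected, and other dialect versions must be converted first.
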