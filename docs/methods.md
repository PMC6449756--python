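# Methods

## Problem and model

Draft genome assemblies — especially large, repetitive plant genomes —
frequently annotate two fragments of one gene as two separate gene models.
Because the fragments share no (or almost no) residues, sequence comparison
alone cannot tell them apart from a pair of close paralogs.  `splitgene`
exploits the gene family context instead: the fragments are placed in a
phylogeny together with full-length homologs from reference genomes, and two
statistical tests ask whether the data are consistent with the fragments
occupying a *single* position in that tree.

Candidate pairs are same-family gene models of the target genome with at
least `min_len = 50` residues each whose aligned overlap satisfies the
strict rule `a12 < 0.1*l1 AND a12 < 0.1*l2`, where `l1`, `l2` are the
fragment lengths and `a12` the number of alignment columns in which both
hold a residue.  Ties (exactly 10%) are rejected.

**Test 1 — branch collapsing.**  Fragments of one gene are separated only by
sampling noise, so the internal branches between them should carry low
bootstrap support.  All internal branches with support strictly below a
threshold (default 0.95) are contracted, and the pair is called split when
the fragments end up as children of the same — possibly multifurcating —
node of the unrooted tree.  Support equal to the threshold survives; missing
supports default to 1.0 (never collapsed); an artificial degree-2 root is
contracted before testing.  Sisterhood inside a polytomy counts as a call:
collapsing is meant to erase insignificant resolution, so post-collapse
multifurcations are exactly the intended situation.

**Test 2 — likelihood ratio test.**  The null H_s says the fragments are one
gene: their rows are merged into a single sequence (n−1 genes); the
alternative H_p keeps them separate (n genes).  The statistic is
`T = 2 ln[L(H_p)/L(H_s)]` with `L()` the maximized likelihood.  H_s is the
more constrained model, and — unusually — *failing to reject it* produces
the split prediction.  The models are not nested, so the null distribution
is estimated by a non-parametric bootstrap: columns of the merged alignment
are resampled with replacement, each replicate is split back into two
fragments using per-column provenance labels (F1/F2/BOTH — robust to columns
being duplicated or dropped by the resampling, which a single cut index
would not be), and the statistic is recomputed.  The empirical p-value is
`p_B = #{T*_i >= T0}/n` with ties counted in the numerator; `p_B >= alpha`
(default 0.01, n = 100 replicates) yields the split call.  Negative T0 is
not clamped: it simply produces a large p_B, the conservative direction for
this null.

Because the bootstrap resamples the *observed* merged alignment, the
replicate distribution is centred near the observed statistic; the LRT
therefore rarely rejects on its own (high recall, modest precision) and the
intersection with the collapse test — the default combined mode — supplies
the precision.  This mirrors the behaviour of the published method family
this package implements.

To protect against a suboptimal tree search reporting T0 < 0, two searches
are run under H_p: one de novo and one started from the H_s tree with the
merged leaf expanded into a (fragment1, fragment2) cherry whose pendant
branches start at 1e-6.  With gaps treated as missing data the zero-length
cherry reproduces the H_s likelihood, so `T0 >= -2*tol` by construction.

**Combined decision.**  The default combined mode is the intersection of
the two tests (both must call split).  Union with an external call set —
e.g. a pairwise-method's predictions — is provided only as a post-hoc merge
utility over prediction tables (`pipeline.union_call_sets`), not as a
pipeline mode.

**Multi-way predictions.**  A gene appearing in several split calls is fine
if the partner fragments cover disjoint parts of the alignment (a gene split
into more than two pieces; reported as an ordered chain).  If two partners
overlap at >= 10% (the candidate rule applied to the partners), the
predictions claim the same stretch of sequence and the whole conflict
component is labelled *ambiguous*.

## Likelihood engine

A deliberately small ML engine backs both tests:

- **Model.**  LG exchangeabilities and stationary frequencies (shipped as a
  plain-text matrix), normalized to one expected substitution per site.
  Transition matrices come from a symmetric eigendecomposition, so each
  P(t) is three 20x20 products.  A single rate category is the default; a
  discrete-Gamma mixture (`LG+G4`, category medians, equal weights) exists
  as an option because among-site rate variation is a known failure mode of
  split-gene inference, but the default mirrors a simple baseline.
- **Likelihood.**  Felsenstein pruning over pattern-compressed columns with
  per-node max rescaling.  Gaps and X are missing data (partial likelihood
  of ones); an all-gap column contributes exactly zero.
- **Branch lengths.**  Each branch is maximized by bounded Brent search on
  [1e-8, 10] using the reversible-model edge decomposition (below-subtree
  message x P(t) x rest-of-tree message), swept in preorder until the round
  improvement drops below `tol = 1e-4` log-likelihood units.  Each 1-D step
  only ever accepts an improvement, so the sweep is a monotone ascent.
- **Search.**  Neighbor joining (on pairwise ML distances; near-disjoint
  pairs such as the two fragments get the smallest through-a-third-taxon
  path bound as an imputed distance) gives the start; nearest-neighbor
  interchanges are screened by re-optimizing the central branch only and
  accepted when the full re-fit improves the likelihood.
- **Supports.**  Felsenstein bootstrap proportions.  Replicate trees are
  re-built by NJ on re-estimated distances (the classical distance
  bootstrap) by default; a full NNI re-search per replicate is available
  (`support_rebuild: full`).  Note this differs from the SH-like local
  supports some fast tree builders emit; the threshold semantics are
  unchanged, and externally supplied trees may carry either kind.
- **Replicate fits.**  The default LRT replicate mode re-searches topologies
  per replicate ("full").  The "fast" mode freezes both topologies at the
  original fits and re-optimizes branch lengths only, warm-starting each
  branch in a narrow bracket and accepting a coarser convergence target
  (0.05 lnL units): replicate statistics are only ever compared against T0,
  so their third decimal is irrelevant.  Desk-scale suites use fast mode.

External tools can replace the built-in aligner and tree builder through
shell-template adapters (e.g. MAFFT, FastTree); adapter outputs are
validated against the same contracts (sequence set preserved, supports in
[0,1]).  The built-in progressive aligner (3-mer guide clustering +
profile-profile Needleman-Wunsch with BLOSUM62 expected scores and a linear
gap penalty) is a fallback for convenience, not a contribution.

## Synthetic data

The generator reproduces the evaluation design of the method's validation
studies at desk scale.  Families are evolved site-independently (no indels,
so the true alignment is columnwise trivial and test outcomes are isolated
from aligner error) along a balanced species tree of `n_refs = 8` reference
genomes plus the target, with branch lengths redrawn per family from
U(0.05, 0.3) substitutions/site to emulate among-family rate variation.
Genes are 400 aa by default (parents must be at least 100 aa).

- **Positives**: the target gene is cut at a position uniform on
  [50, L−50] and replaced by its two fragments.
- **Negatives**: a duplication is placed on the target's *ancestral* lineage
  `dup_depth` substitutions/site above the present (the ancestral state at
  a mid-branch point is bridge-sampled conditional on both realized branch
  ends; the point clamps at the root for very deep values).  The second
  copy re-evolves to the present, and the planted pair keeps the N-terminal
  piece of the original gene plus the C-terminal piece of the duplicate —
  complementary, hence non-overlapping.  Placing the duplication on the
  ancestral lineage (rather than evolving two copies forward from the
  extant gene) is essential: with site-independent evolution, a chimera of
  two tip-forward copies is *statistically identical* to a single sequence,
  leaving nothing for any homology-based method to detect at any depth.
  Duplications above the nearest reference divergences, by contrast, make
  the two copies attach at genuinely different tree positions, which is the
  situation in which real (non-species-specific) paralog fragments are
  detectable.  `dup_depth = 0` yields fragments of identical copies — the
  hardest negative, indistinguishable from a true split by construction,
  kept as a reported diagnostic of that inherent limitation.

Real data differ from these simulations in having indels and alignment
error, among-site rate variation, unbalanced taxon sampling and family
sizes, and paralogs whose duplication history interleaves with speciations
in more complex ways; passing the simulation suite shows the machinery and
its decision rules are correct under the model's assumptions, not that the
operating point is optimal for any particular genome.

## Numerical and design choices

- Branch-length bounds [1e-8, 10]; likelihood tolerance 1e-4; NNI accepted
  only above the same tolerance (monotone search, max 10 sweeps).
- p_B is an exact count ratio; its value is always a multiple of 1/n.
- Deterministic throughout: every stochastic operation takes a seed;
  bootstrap replicate r uses seed + r; family k of a run uses
  seed + 10007·(k+1) mod 2^31; identical configuration and seeds reproduce
  byte-identical prediction files.
- Families with fewer than 4 members are skipped (no informative unrooted
  topology question below four taxa); per-family failures are logged and
  reported, never fatal to a run.
- The ≥50 aa length filter is applied to ungapped residue counts before
  alignment-dependent filtering; the overlap rule uses strict inequalities.
- The merged H_s alignment reuses the family MSA rows without re-alignment;
  re-alignment of the concatenated sequence can be enabled via the aligner
  adapter but is off by default.
- At BOTH-labelled (overlap) columns the merged row takes the longer
  fragment's residue (ties: lexicographically smaller id); splitting a
  replicate routes BOTH columns to that fragment, so the shorter fragment
  loses its overlap residues — a documented lossy corner of partially
  overlapping pairs.

## Scale of the shipped studies

The recovery study run by `scripts/acceptance.py` and the acceptance tests
uses 30 positive and 30 deep-negative families (plus 15 identical-copy
negatives), 400-aa genes, 50 bootstrap replicates and fast replicate mode —
sizes chosen so the whole study completes in minutes on one core while
keeping the Monte-Carlo error of a recall/precision estimate near 0.05.

## Known limitations

- Identical or near-identical (species-specific) paralog fragments are
  inherently indistinguishable from true splits; the FP rate on
  `dup_depth = 0` negatives documents this.
- Rate heterogeneity along the sequence can make true fragments look like
  distinct genes; the Gamma option mitigates only among-site, not
  domain-structured, variation.
- The NNI search can stop in local optima; the dual H_p search protects the
  sign of T0 but not global optimality.
- No multiple-testing correction is applied across candidate pairs, by
  design: each pair is an independent prediction whose confidence is
  controlled by the two thresholds.
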