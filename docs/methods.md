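# Methods notes

## Trace model

The trace assumes the input alignment is a faithful sampling of one
homologous family and that a UPGMA tree on normalized Hamming distances
(gap = fifth symbol, T→U, anything else → N) is an adequate summary of its
phylogeny. UPGMA was chosen over ML/NJ because the ranking only consumes
the nested leaf partitions induced by cutting the tree level by level, and
UPGMA's ultrametric heights give those levels a canonical root-distance
order; the distance metric itself is the simplest one consistent with
treating gaps as informative states. Agglomeration ties are broken toward
the lowest pair of current cluster indices, and level order is a frontier
walk from the root (min root distance, then creation order, children only
after their parent), so traces are bit-reproducible and the partitions stay
nested even across zero-length branches. Consequence: the trace is
deterministic given the input row order, but re-ordering rows can change
the tree when distances tie exactly — the invariance tests therefore
permute rows *with* tree relabeling.

Integer ET adds 1 per level at which the column still varies inside some
group; rvET adds the mean in-group Shannon entropy (natural log, 0·ln 0 = 0).
The entropy alphabet is the observed symbols; `alphabet_size` (default 5:
A,C,G,U,gap; 6 with N) only sets the theoretical rank ceiling. A
conservation-only baseline (whole-column entropy, no tree) is provided for
comparison; its reported rank is 1 + H so that every method's ranks start
at 1. Coverage assigns tied ranks the largest sorted position, in percent.

## Structural statistics

Contacts default to minimum heavy-atom distance ≤ 4 Å. The atom set is
configurable to first-atom-only (`atoms="c1p"`) because "distance between
nucleotides" is genuinely ambiguous; both are tested. Immediate backbone
neighbors (|i−j| ≤ 1) are excluded from 3D contacts by default — they are
contacts of chemistry, not of fold — with `exclude_neighbors=0` to include
them. The 2D graph is base pairs ∪ backbone; 1D is backbone only.

The clustering z-score uses exact closed-form moments of the selection
clustering weight under sampling without replacement, parameterized by the
graph's edge count E and 2-path count T; both moments are validated against
full enumeration on all graphs up to L = 12 in the tests, and a
permutation-mode estimator (mandatory explicit seed) is provided as an
independent check. The overlap σ is the standard hypergeometric standard
deviation with divisor N−1. (The customary write-up of this σ is sometimes
garbled dimensionally; the enumeration oracle pins the implemented form.)

Per-coverage-bin profiles: bin b covers positions with coverage ≤ 100·b/L.
A bin is *valid* when its coverage value is attained (selection size = b)
and its z is defined. Degenerate selections — empty, singleton, edgeless
graph, or site-equal-to-universe — have σ = 0 and are flagged undefined,
with one deliberate convention: the full-universe bin has zero excess by
construction (w = ⟨w⟩, k = m) and is assigned z = 0 rather than flagged, so
even an all-tied trace yields a defined profile. Invalid bins inherit the
nearest valid bin's z by coverage distance, ties toward lower coverage.
zc35%/zo35% average the filled bins at coverage ≤ 35%; the 35% cutoff is a
convention inherited from protein work and is a parameter everywhere
(`threshold`). Smoothness uses coverage (not absolute rank) as x by
default, so SMT is comparable across molecules with different N; it is
translation-invariant and scales quadratically, which the property tests
pin.

Overlap evaluation with site-specific exclusion shrinks the universe:
excluded positions are neither positives nor negatives, and coverage is
recomputed on the remaining positions before binning, in both z and AUC.
AUC is Mann–Whitney pair counting with half-credit ties (equal to
trapezoidal ROC integration, cross-checked against scikit-learn).

## Column ↔ residue mapping

The ungapped query row is matched to the structure sequence by exact
substring containment (either direction) before falling back to global
pairwise alignment, keeping clean inputs deterministic. Mapping fails above
a 10% base-identity mismatch fraction (configurable). Residues are indexed
by chain ordinal; author numbering is reporting-only.

## Optimization

Rank entropy is RE = −Σ_r f_r ln f_r over distinct rank values (ranks
rounded at 1e−9 before grouping): 0 for an all-tied trace, ln L when all
ranks are distinct. The combined criterion multiplies min-max-normalized RE
by (1 − min-max-normalized SMT), normalization taken over the current
ensemble; smoothness enters inverted because it is a cost. A raw-smoothness
criterion is kept available because its failure mode — collapsing onto a
few near-invariant sequences — is itself a tested behavior. Ensemble
members remove a uniform-random 0 < n < N − min_keep sequences
(min_keep = 20 by default); the query is never removed so the structure
mapping survives. Scoring ties resolve to the lowest member id.

Degradation resamples a chosen fraction of non-gap characters uniformly
from {A,C,G,U} — giving the clean expectation of 25% residual per-site
identity at rate 1 — with within-column permutation available behind
`mode="permute"`. Gaps and column positions are never touched, so one
structure mapping serves all degraded copies.

## What the synthetic fixtures emulate — and what they do not

`synthfix` plants three column classes on a balanced binary tree
(default 16 leaves, 60 columns, fractions 0.2/0.2/0.6): conserved columns,
clade-specific columns fixed within each of the two top-level clades
(distinct between them — the signal that separates a trace from flat
conservation), and random columns whose per-column base frequencies come
from a symmetric Dirichlet (α = 0.6). The Dirichlet skew mirrors real
per-site base-usage bias; it matters because it lets some random columns
drift to low flat entropy, which confuses a tree-blind conservation score
but not the trace. The toy structure is a helix-like curve (radius 4 Å,
twist 90°, rise 0.9 Å per position) whose slot order is permuted so the
planted site — all conserved + clade columns — occupies a contiguous
spatial stretch; with this geometry the only 4 Å contacts are between
positions one helix turn apart, so contact density is uniform along the
curve and the site's clustering signal is purely positional.
Contamination decoys are cyclically shifted copies of member sequences
(register errors, the way mis-anchored homologs corrupt columns), with
i.i.d. random sequences as a milder alternative.

The fixtures have no substitution model, no indels, no rate variation, no
base-pair covariation, and a geometry far simpler than an RNA fold.
Passing tests therefore show that the statistics behave as designed under
their own null and signal models — calibrated z under no signal,
significant z under planted signal, class separation, degradation coupling,
contamination recovery — not that any particular biological family will
score significantly.

## Problem sizes in the test battery

Enumeration oracles run on all selection sizes of graphs up to L = 12;
null calibration uses 200 random-rank trials (bar: ≥95% within |z| ≤ 2);
degradation uses 6 rates × 12 replicates on the 16-leaf fixture; the
contamination-recovery experiment uses 25 seeds × 300-member ensembles on
32-leaf fixtures with 30% misaligned decoys. The ensemble size is a
scaled-down stand-in for the thousands of members one would use in
practice; smaller ensembles select in the right direction (clustering z
correlates with decoy removal) but win less reliably end-to-end.

## Known limitations

UPGMA only; user trees are importable as Newick but not constructed.
First NMR model only; no modified-nucleotide chemistry; no inter-chain
contact graphs; no weighted contacts or solvent-accessibility terms; raw
z-scores are reported without multiple-testing correction across sites.
The contingency-table helper implements the standard one-sided
hypergeometric tail; published p-values rounded from other conventions
(point probability, mid-p) can differ in the second decimal.
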