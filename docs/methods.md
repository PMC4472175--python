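# Methods

This note documents the models, rules and numerical choices behind
`csphylo`, in the order the pipeline applies them, together with what
the synthetic-data generator does and does not emulate.

## Consensus-site model

For each gene of the mapping reference and each 0-based position *p*,
the pileup holds counts of A/C/G/T calls from filtered alignments.
Read `N`s and positions outside an alignment's block carry no evidence
and are excluded from depth.  The site rule is a deterministic
three-way classification:

* **CS** — depth ≥ `min_depth` (default 10, inclusive) *and* the
  majority base carries ≥ `min_agree` (default 0.80, inclusive) of the
  depth; symbol = upper-case majority base.
* **UNS** — depth 0; symbol `-`.
* **AS** — everything else; symbol = lower-case majority base.

Ties for the majority base are broken alphabetically (A < C < G < T);
the paper of record for this design says only "the nucleotide with the
highest number", and a deterministic tie-break is required for
reproducible matrices.  The symbol case is a bijection with the
category, which downstream stages rely on.  Depth thresholds are
interpreted inclusively ("greater or equal to 10", "no less than
80%").  Human-readable output is 1-based; everything internal is
0-based.  Overlapping paired mates are counted as two observations —
no dedup rule is imposed, and the pooling operator (element-wise count
sums across libraries of one species) would interact badly with one.

A gene is *retained* when CS positions cover ≥ `min_cs_cover`
(default 0.10, inclusive) of its CDS length.  This filter absorbs
reference/sample ORF disagreements: genes whose reading frame does not
transfer across species simply never accumulate consensus.

## Reference preparation

Paralogy is decided on all-vs-all protein homology E-values.  The
cutoff is the **nearest-rank** upper 95th percentile (1-based rank
⌈0.95·n⌉ of the ascending E-values) of a known-paralog calibration
set — nearest-rank avoids interpolation conventions; with n = 1 it
degenerates to the single value, and repeated values are handled
naturally.  Directional asymmetry between the two hits of a pair is
resolved by taking the smaller E-value: a pair is paralogous if either
direction says so.  Groups are connected components of the thresholded
graph (networkx); raising the cutoff can only merge components, so the
group count is monotonically non-increasing in the cutoff.  The m-CDS
representative is the longest member, ties broken by smallest gene id.
CDS whose length is not a multiple of 3 are dropped with a warning —
the codon machinery downstream requires a clean frame.

## Translated mapping and its calibration

The built-in mapper is intentionally simple: exact 7-residue seed words
(protein space; reference indexed in its three forward frames with
stops kept as `*`, reads translated in six frames), candidate
(target, diagonal, strand) placements deduplicated, and each candidate
rescored ungapped in nucleotide space as matches − mismatches over the
read/target overlap.  A perfect read therefore scores its own length.
Only the unique best-scoring target is kept; exact score ties across
targets discard the read as ambiguous — the conservative reading of
"mapped reads", and the CS 80% rule tolerates the residual noise
either way.  Alignments under a floor score of 18 are discarded
(configurable).  The mapper stands in for BLAT dnax/dnax at desk
scale; it makes no claim of bit-compatibility, and 21-column PSL from a
real BLAT run can be ingested instead (`read_psl`; 0-based half-open
coordinates, `-`-strand qStarts on the reversed query per the PSL
specification).  One written-dialect note: read `N`s are tallied as
misMatches rather than nCount so the PSL score formula
(matches + repMatches − misMatches − qNumInsert − tNumInsert)
reproduces the internal score exactly.

The score cutoff is calibrated against a decoy: each reference sequence
is shuffled preserving its hexamer composition.  The shuffle is the
Euler-path construction on the (k−1)-mer De Bruijn multigraph — each
k-mer occurrence is an edge; a uniform random arborescence toward the
terminal (k−1)-mer (sampled with Wilson's loop-erased random walks)
fixes every vertex's last-exit edge, remaining out-edges are permuted
uniformly, and the Eulerian walk spells the decoy.  This conserves the
k-mer count vector exactly for all k ≤ 6 (and, on a long random
sequence, almost surely breaks it at k = 7); a homopolymer is its own
unique arrangement and shuffles to itself.  `choose_score_cutoff`
returns the smallest integer cutoff at which

    FDR(c) = #decoy reads with score ≥ c / #real reads with score ≥ c

is < `fdr_max` (default 0.01), subject to passing at least one real
read — the vacuous "pass nothing" solution is rejected, and an input
whose distributions cannot be separated raises an explicit error rather
than returning a degenerate cutoff.  The realized ratio at the chosen
cutoff is reported as *q*.

## Supermatrix

A reference codon (positions 3j, 3j+1, 3j+2) enters the matrix iff its
gene is retained in every sample and all three positions are CS in
every sample.  Codons step through the fixed reference reading frame
(step 3, no overlap): the reference frame is unambiguous, and
overlapping windows would duplicate columns.  Columns are ordered by
(gene id, codon index) for byte-stable output.  Intersection over
samples is monotone — adding a sample can only remove codons — and the
result is invariant to sample input order.  All taxa in the run,
out-groups included, participate in the intersection.  Export formats:
relaxed PHYLIP (`ntaxa nchar` header), FASTA, NEXUS with an optional
SETS block, and RAxML-style partition lines `DNA, codonN = N-L\3`;
labels are sanitized for format safety with a logged mapping.  The
matrices are meant for external partitioned inference (the motivating
analyses used GTR+GAMMA+I, 500 bootstrap replicates / 10⁶ MCMC
generations); the package itself stops at distance methods.

## Hybrid marker sites

Marker sites demand CS calls — not AS — in every group member: by the
encoding's own semantics an ambiguous call is untrustworthy lineage
evidence.  Classification fractions use the total site depth (other
bases included) as denominator, the conservative reading of "of mapping
reads".  Rule precedence is both-alleles (both marker bases ≥ 40%)
first, then single-allele (≥ 90%), then uncertain; since
0.40 + 0.40 ≤ 1 < 0.90 + 0.40 the categories only collide at degenerate
fractions, where hybrid evidence wins.  Sites whose reads show neither
marker base, and sites with no coverage, fall into *uncertain* with
separate flags (the "species-specific site" category of the original
analysis is a flagged subset of uncertain rather than a fourth
category).  Summary proportions are recomputed from counts and sum
to 1; the dominance split of both-allele sites (larger fraction wins,
exact tie → none) sums to the both-alleles proportion.

## Internal phylogenetics

Distances are Jukes–Cantor, d = −¾ ln(1 − 4p/3), with an explicit
saturation error at p ≥ 0.75; JC (not GTR) because the matrix contains
only unambiguous CS characters and the internal tree is a topology
smoke test, not an inference product.  Neighbor joining follows
Saitou–Nei with Studier–Keppler updates, deterministic tie-breaks on
the index pair, and negative branch estimates clamped to zero with a
log note.  Robinson–Foulds counts bipartitions present in exactly one
tree, with splits normalized to the side not containing a fixed anchor
leaf.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *structure* of a short-read transcriptome
experiment on a small clade: a frame-clean reference CDS set (ATG
start, no in-frame stops), species sequences evolved along a known
newick tree under per-site Jukes–Cantor (branch lengths in expected
substitutions/site; per-branch substitution probability
¾(1 − e^(−4b/3))), optional paralog families at a stated divergence,
uniform read starts, uniform per-base substitution errors, fixed-insert
paired ends, and 1:1 two-haplotype hybrids.  Codons mutated into stops
are redrawn to a different non-stop target, so substitution counts are
preserved while frames stay clean — the pipeline assumes intact ORFs
and has no indel handling, so no indels are simulated.

Defaults mirror the motivating experiments: 80 nt reads (between the
75–90 nt paired and 100 nt single-end libraries of the original data),
1% base error, mean depth 20 (comfortably above the CS depth rule).
Deliberately *not* emulated: expression-level variation (read depth is
uniform per gene, with optional per-gene multipliers for
retention-filter tests), alternative splicing, machine-specific error
profiles, base-quality variation, and real cross-species codon usage.
Passing tests therefore demonstrate the correctness of the rules and
the recoverability of known truth under the stated noise model — not
robustness to expression skew or to assembly-grade artifacts in real
libraries.

## Problem sizes used in the checks

The test-suite and acceptance-script problem sizes are chosen as the
smallest scales at which each property is statistically unambiguous:
rule boundaries are swept exhaustively (exact); decoy conservation uses
a 100 kb random sequence; FDR calibration uses 200 genes × 900 nt with
50,000 80-nt reads at 1% error; end-to-end recovery uses a 6-taxon tree
(12 genes × 300 nt, depth 40, error-free) plus a 1:1 hybrid of two
non-sister taxa.  At these scales the realized decoy/real ratio lands
in the 0.2–0.4% range (seed-dependent), the hexamer decoy conserves
k-mers exactly up to k = 6, neighbor joining recovers the generating
topology at Robinson–Foulds 0, and the hybrid's both-alleles fraction
exceeds every pure control's by far more than an order of magnitude.

## Known limitations

* The internal mapper's 7-residue exact seeds lose sensitivity beyond
  roughly 70–80% protein identity between sample and reference; for
  distant clades, run real BLAT and ingest the PSL.
* Paralog collapsing keeps one representative per family; reads from
  non-represented family members may still cross-map at low identity
  and are then absorbed (or rejected) by the 80% consensus rule rather
  than handled explicitly.
* Library pooling sums counts, which implicitly weights libraries by
  depth; a CS-level vote across libraries is a documented alternative
  that is not the default.
* No base-quality weighting, genotype likelihoods or indel calling —
  sites are counts of A/C/G/T over filtered alignments, nothing more.
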