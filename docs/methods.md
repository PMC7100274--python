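# Methods

`mitocompare` compares circular plant mitochondrial genomes between
cytoplasmic-male-sterile (CMS) lines and their fertile maintainer lines.
This note records the models, conventions, and numerical choices behind
each stage, what the synthetic data generator does and does not emulate,
and the design decisions taken where more than one reasonable choice
existed.

## Coordinate and sequence conventions

All coordinates are 0-based, half-open, on the forward strand. GenBank and
GFF3 (1-based, closed) are converted only at the I/O boundary. Circular
topology is handled by rotation: an ingested record whose feature spans
the origin is rotated so every feature is contiguous, and the offset is
retained (`rotation_offset`) so the original frame can be restored.
Ambiguity codes other than N are converted to N with a warning; N never
matches anything in alignment scoring and is excluded from the GC
denominator.

Gene labels are normalized into a base name plus an optional suffix:
trailing lowercase letters a–e mark trans-spliced exon groups (`nad2a`,
`cox2ab`), `-D<k>` marks an extra gene copy (`nad3-D2`). A label is split
only when the remainder is a plausible gene name (ends in a digit or an
uppercase letter), so `cob` or `trnM` are never mangled. Cross-genome
comparisons (clusters, homolog pairing, copy counting) use base names;
exon parts of one copy are concatenated in suffix order, `-D` labels count
as separate copies.

## Alignment engines

Two engines share one identity convention (BLAST-like: identical columns
divided by all alignment columns, gaps included).

* `local_align_dp` — exact Smith–Waterman with affine gaps (a gap of
  length L costs `gap_open + gap_extend·L`), implemented as a
  numba-compiled banded kernel with the band covering the whole matrix.
  It refuses inputs above a configurable cell cap (default 10^6) and is
  the oracle for small inputs. Its scores are cross-checked in the test
  suite against Biopython's independent `PairwiseAligner` implementation.
* `anchored_align` — the production engine: exact k-mer seeds (default
  k = 12, skipping k-mers with more than 64 occurrences, a standard
  low-complexity guard), greedy co-linear chaining (diagonal drift ≤ band,
  default 32; seed gap ≤ 500), and banded Smith–Waterman extension around
  each chain's diagonal range with 200 bp of padding. Both strands are
  searched; reverse hits report subject intervals in forward coordinates.
  Everything is deterministic: ties break leftmost-first.

Default scoring is BLASTN-like (+1/−2, gap −5/−2). The property suite
verifies on hundreds of random pairs that the anchored score never
exceeds the exact DP score and equals it whenever the optimal alignment
contains an exact 12-mer (i.e., whenever a seed exists).

Where a Levenshtein alignment is sufficient and speed matters — ORF
specificity screening against a whole genome, reciprocal ORF matching,
and region-to-region identity — edlib's bit-parallel infix/global
alignment is used, with identity computed as (columns − distance)/columns
from the extended CIGAR.

## Repeats

Dispersed repeats come from aligning a genome against itself and against
its own reverse complement; the trivial diagonal and mirror duplicates are
removed, pairs are canonicalized (left interval first) and de-duplicated
by containment. A pair counts as a repeat only above 90% identity
(strict), and is classed small (<50 bp), intermediate (50–500 bp,
inclusive) or large (>500 bp) by arm alignment length, and DR/IR by
orientation. A minimum arm of 20 bp (configurable) keeps chance k-mer
matches out of the open-ended "small" class. Forward self-hits whose arms
overlap (tandem self-similarity) are left to the SSR detector.

A reverse self-hit that crosses its own center is a palindrome: the hit is
split at the midpoint of its union span into two contiguous arms.
`find_palindromes` flags IR pairs with spacer ≤ `max_spacer` (default 0,
"continuous"); for arms shorter than the seed length an exhaustive
center-expansion scan is used instead.

SSRs are maximal tandem arrays of primitive 1–6 bp motifs, detected by a
vectorized periodicity scan (`seq[i] == seq[i+m]` run-length encoding),
with MISA-style per-size copy minimums (mono ≥ 12, di ≥ 6, tri ≥ 4,
tetra/penta/hexa ≥ 3) and a 12 bp overall floor — chosen because no copy
thresholds are stated in the source methods and these reproduce realistic
per-genome SSR counts (a few dozen). Overlapping calls resolve
longest-first, then leftmost; motifs are reported as their
lexicographically least rotation. The scan is linear; an SSR crossing the
linearization origin would be reported as two runs (none of the planted
ones do).

Repeat summaries count each genomic position at most once (interval union
over all arms and SSR spans).

## Synteny and rearrangement typing

Alignment hits ≥ 100 bp at ≥ 90% identity are chained into blocks:
co-oriented, monotone, with inter-hit gaps ≤ 3 kb on both genomes (so a
block tolerates internal indels up to that size, e.g. a deleted gene
copy). Blocks below `min_block` (default 3,000 bp, the granularity used
for CMS-region analysis; 1 kb gives a finer inventory) are dropped;
conflicting blocks resolve by score and residual overlaps are trimmed so
block spans are disjoint on both genomes.

Because both genomes are circles, "order" is evaluated after choosing the
rotation of genome B's block order — and, if needed, its overall strand —
that maximizes the number (then total length) of collinear blocks. Order
consistency is the longest increasing subsequence of B-ranks along A.
Each block then gets exactly one class: in-order + forward =
collinearity; in-order + reverse = inversion; out-of-order + forward =
translocation; out-of-order + reverse = translocation+inversion. This
makes classification invariant to where either circle was linearized.

Aligned fractions are the percentage of a genome's positions covered by
block alignment columns (union). Unique regions of a CMS genome are the
maximal complement intervals of block coverage ≥ `min_len` (3 kb), with a
200 bp slack absorbing alignment end-trimming; with several CMS genomes,
only regions aligning to a region of every other CMS genome at > 0.90
global identity are kept (the "shared CMS-specific regions" — the
threshold deliberately reuses the repeat-definition identity). Regions
are annotated with overlapping (≥ 1 bp) genes, ORFs and repeats in
region-relative coordinates.

## Gene clusters

Clusters are maximal runs of genes (tRNA and rRNA included) with
inter-gene gaps ≤ 2,000 bp, circular-aware. The 2 kb default is not stated
in the source methods; it is the spacing at which the expected
co-transcriptional units form while unrelated neighbors stay apart, and
it is recorded in run metadata. Signatures collapse adjacent identical
base names (exon parts), are orientation-normalized (a run equals its
reversal), and conservation is evaluated on maximal contiguous sub-runs:
a cluster conserved inside a larger cluster still counts, and is reported
once at its maximal shared extent. Cluster-to-block context uses the
majority-overlap rule against the CMS-side synteny blocks.

## ORF screen

ORFs are ATG-to-stop, all six frames, circular-aware (an ORF may span the
origin; the nucleotide length includes the stop, the amino-acid length
does not); for nested starts sharing a stop only the longest is kept. The
length filter is strictly greater than 300 nt. Names follow
`orf<aa_length>` with `b`, `c`… suffixes for collisions in genomic order.

Specificity: a CMS ORF is specific iff its best alignment against the
entire paired maintainer genome — coding or not, either strand, origin
wrap included — has identity strictly below 0.99. The screen is monotone
in the threshold. Cross-line intersection takes ORFs of the first CMS
line with a reciprocal best match ≥ 0.99 in every other line's specific
set.

## Candidate genes

Homologs pair by base name; multi-copy genes pair by reciprocal best
identity with unresolved ties reported, never silently chosen. CDSs are
compared by global alignment with affine penalties chosen to keep
biological indels contiguous (match 1, mismatch −1.5, open −6, extend
−0.2) — a unit-cost aligner fragments a 90 bp deletion into cost-equal
pieces, which is why edlib is not used here. Indels are left-normalized
to the lowest equivalent maintainer position. Substitutions are grouped
per maintainer codon and reported at the codon's first nucleotide
(1-based in the CDS), with changed bases uppercased, and classified under
the standard genetic code (plant-mitochondrial RNA editing is not
modeled — a documented simplification; a codon containing N is
"unclassified"). Per-cultivar polymorphic gene sets intersect on base
names to nominate candidates.

## Phylogenies

The SNP matrix is called through synteny blocks against a reference:
every reference position covered in all retained samples where at least
one state differs becomes a column (reference included as a taxon,
deletions as `-`, biallelism not required); samples below 10% alignable
fraction are excluded with a warning. A reference-only gap between two
block segments is called as a deletion when the sample side is contiguous.
The gene-concatenation matrix aligns each taxon's CDS to the first
taxon's copy and projects onto anchor columns with insertion padding —
adequate for the near-identical CDSs it is applied to, not a general MSA.

Maximum parsimony uses Fitch counting with `-`/`?` as missing (free)
states, over unique column patterns with multiplicities; the topology
search is exhaustive up to 9 taxa ((2n−5)!! enumeration) and NNI
hill-climbing from the NJ topology beyond. Ties are all recorded; the
canonically first topology is primary. Distance trees are p-distance
(mismatches over mutually unambiguous sites) + scikit-bio's
neighbor-joining, with negative branch lengths clamped to zero (logged).
Bootstrap supports resample columns with replacement (default 1,000
replicates, seeded) and report the percentage of replicate trees
containing each internal bipartition of the primary tree.

## The synthetic study system

`simulate.generate_quartet` builds two cultivars, each a maintainer and a
CMS derivative, plus an outgroup reference, with every planted element
recorded in a truth table. The defaults are the validation conditions:

* Maintainer scaffold: 430 kb circle, i.i.d. background at GC 0.40
  (coding codons are drawn from the same base composition with stops
  rejected, which keeps genome-wide GC within ±0.01). Thirty conserved
  protein-coding genes (realistic CDS lengths; nad1/nad2/nad5/rps3/cox2/
  rps10 trans-spliced into parts), three rRNAs and ten tRNAs, laid out as
  13 clusters plus spaced singletons; rpl16 starts 108 bp inside rps3b.
* Repeats: 80 small (20–40 bp, exact copies — a substitution would
  destroy every seed in so short an arm), 20 intermediate (60–400 bp) and
  3 large (600–2,500 bp) two-copy families at 1% per-copy substitution
  divergence, half inverted; 34 SSRs with the observed motif-size mix;
  2.6% of the genome copied from a simulated chloroplast donor in four
  disjoint tracts.
* Cultivars: intergenic background divergence of 0.001 (A) and 0.002 (B)
  from the common ancestor, an outgroup at 0.004 — intergenic only, so
  conserved genes stay conserved and the two trees show the two signals
  (SNP tree groups cultivars; candidate-gene tree separates CMS). Copy
  plan per the observed inventory (both maintainers carry nad3-D2, lost
  in CMS; cultivar-specific sdh3/cob/rpl5/rps14 copies; CMS-B gains
  atp9-D2/D3 and mat-R-D2).
* CMS derivation: 3 inversions, 6 translocations and 3 combined events
  (8–20 kb and 5–15 kb, breakpoints never inside genes, clusters or
  planted marks); three shared inserted regions (41,000 / 3,400 /
  3,300 bp — identical sequence in both CMS lines, the common-cytoplasm
  model), region 1 carrying the 16 specific ORFs (an adjacent
  orf100–orf115–orf115b trio plus 13 scattered, each framed by an
  in-frame upstream stop so no chance ATG can extend it) and its own
  repeat families; one private palindrome per CMS line (arms 5,778 and
  1,491 bp); per-line SSR gains (+8 with (CTTA)n, +5 with (CTCCAA)n);
  and the candidate-gene edit presets. Net CMS expansion lands inside
  30–60 kb by construction.
* Gene edits are expressed as one common CMS haplotype from which each
  maintainer differs: atp6 by six codon substitutions in cultivar A
  (tAt→tCt at 58, …, tcT→tcC at 766) and by the single shared synonymous
  766 event in cultivar B; nad2 by a 90 bp insertion at 456 (A) or 3 bp
  (B); sdh3 by +15 (A) or +3 (B); cox2 by two codon substitutions (A) or
  a 33 bp deletion (B); plus one random substitution in each of the other
  polymorphic genes (18 in A, 6 in B, overlapping exactly in the four
  candidates).
* Structural edits are executed by partitioning the maintainer at the
  planned breakpoints and re-emitting segments, so the truth table's
  block inventory (maintainer interval + expected class) is exact by
  construction; in-segment substitutions and splices remap features and
  marks deterministically.
* Cleaning: accidental background features that would blur the truth
  tables — chance SSR runs, chance ORFs inside inserted payloads, chance
  ~20 bp dispersed matches in the random background — are scrubbed by
  running the package's own detectors and disrupting hits outside planted
  spans. This guarantees truth-table completeness; planted-element
  *recovery* remains an independent check. Everything is byte-identical
  under a fixed seed.

What the generator does not emulate: real organelle base composition
(isochores, coding bias), recombination-mediated substoichiometric
molecules, indel noise inside repeat copies (available as an option, off
by default), RNA editing, and real intron structure (trans-spliced
"parts" are planted as separate exon features without splice signals).
Passing the planted-recovery suite therefore demonstrates detector
correctness under a faithful structural model, not performance on raw
field data with assembly artifacts.

## Problem sizes and runtime

Validation runs at full scale — 430 kb maintainers, ~490 kb CMS genomes —
because the detectors' hard cases (chance k-mer hits, block chaining
across real distances) only appear there; the numba kernels make
genome-scale banded alignment cheap. Oracle-equivalence checks run at
the scales where exhaustive enumeration is feasible (pairs ≤ 300 bp,
3 kb circles, ≤ 7 taxa). Bootstrap replicates default to 1,000 in the
analysis scripts; library tests use fewer replicates of the same seeded
procedure.

## Interface note

The package is organized as an analysis project: the numbered scripts
under `analysis/` are the narrative drivers, `pipeline.run_pipeline` is
the one-call orchestrator, and the library modules are the API. A shell
entry point would add nothing over `python analysis/<step>.py`, so none
is installed.

## Known limitations

* Rearrangement typing assumes a dominant collinear backbone; on genome
  pairs where most blocks moved, the rotation choice can become
  ambiguous (ties break deterministically but arbitrarily).
* The anchored aligner cannot see homology with no shared exact 12-mer
  (≳ 8–10% divergence in short windows); such pairs fall below the 90%
  identity rule anyway.
* `gene_concat_matrix` is anchor-projected, not a joint MSA; it is only
  used for near-identical CDS sets.
* The specificity screen's edlib distance bound (k = 5% of ORF length)
  means identities below ~0.95 are reported as "no match"; the decision
  threshold (0.99) is far inside the reliable range.
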