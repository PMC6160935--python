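# Methods

This note documents the models, algorithms, numerical choices and
limitations behind plastokit, in the order of the workflow.

## Read preparation

Paired-end FASTQ files are synchronized by the *ordered intersection* of
their read IDs: mate suffixes (`/1`, `/2`, and Casava `1:N:0:...` dialects)
are stripped, only IDs present in both files are kept, and output is sorted
lexicographically so `R1[i]` and `R2[i]` always pair. Duplicate IDs within
one mate file are an error, not silently collapsed.

Quality filtering is 3' trimming: each read is cut back to its last base
with Phred quality >= `min_q` (default 30), reads shorter than `min_len`
(default 50 bp) are dropped, and pairing is re-synchronized (both mates must
survive). This trimming interpretation (rather than whole-read filtering)
preserves pairing and the long mean pair lengths typical of 2x300 bp runs;
the operation is idempotent. Adapter removal cuts the longest read suffix
matching an adapter prefix over >= 12 bases with <= 1 mismatch, and cuts
from the start of any internal full-length adapter occurrence.

## Assembly finishing

**Contig positioning.** Contigs are seeded against the reference with exact
31-mers in both orientations; the modal seed offset places the contig. A
contig originating from an inverted repeat matches a complete reference
equally well at both IR copies (in opposite orientations); near-tied
candidates (within 80% of the best vote count) are resolved in a second
pass by preferring the placement most end-overlapping the unambiguously
placed contigs — the automated equivalent of the by-eye placement such
contigs otherwise need.

**Stitching.** Adjacent positioned contigs merge when their predicted end
overlap is >= 50 nt with < 10% mismatches (a +-10 bp shift search absorbs
small positioning error); the left contig's bases win mismatch ties.
Contained contigs are dropped with a warning; non-qualifying adjacencies
start a new segment and are reported rather than force-joined.

**Read placement.** Reads are placed by exact 31-mer probes (three per
read, both orientations) followed by ungapped comparison; all placements
tied at the minimal mismatch count are kept. Keeping ties is essential: on
a draft containing a single IR copy, reads from both physical copies place
at the one copy, which is exactly the 2x coverage signal used for IR
detection. The default mismatch budget is 10% of read length; IR detection
places reads at 2% because the reads come from the very sample being
assembled (post-QC identity >> 98%), and a looser budget lets reads with
small foreign overhangs smear coverage across region boundaries.

**IR detection from coverage.** On a one-copy draft the IR shows ~2x the
single-copy depth. Candidate regions are runs where 500 bp-windowed depth
exceeds 1.5x the genome-wide median, kept when the run mean is >= ratio x
(median outside) within tolerance. Boundaries are then refined in three
stages: (i) the 1.5x-baseline crossing located on 301 bp box-smoothed depth
(symmetric smoothing preserves the mid-ramp crossing of a linear ramp);
(ii) a least-squares fit of the box-smoothed ideal ramp (baseline and
amplitude absorbed by regression) scanned over candidate boundaries; (iii)
a matched-filter changepoint on *raw depth increments*: doubled-read starts
form a square pulse of known height (median depth / read length) and known
width (one read length) beginning exactly at the boundary, and the pulse
offset minimizing squared error is the boundary estimate. With 2x300 bp
reads at 200x, stage (iii) localizes boundaries with a median error of
~10 bp and worst cases of ~35 bp over sampled replicates: the residual
error is read-start sampling noise (a ~2 sigma local deficit of doubled
reads moves the likelihood optimum inward by tens of bp), not estimator
bias, so precision beyond this requires information outside the depth
profile. The `read_len` hint enables the pulse model; without it the ramp
width is estimated from threshold crossings and a two-free-mean changepoint
is used.

**Exact completion.** Exact IR boundaries come from matching the
coverage-identified region against an assembled contig: a contig occurring
verbatim (either orientation) in the draft with both ends within 200 bp of
the coverage candidate defines the IR at single-base precision; 100%
identity is required for this auto-complete path, otherwise the coverage
estimate is used and reported. The reverse complement of the confirmed IR
is appended after the SSC, giving the canonical LSC–IRb–SSC–IRa circle; the
result is self-checked by the sequence-level IR finder (31-mer seeding of
the sequence against its own reverse complement, ungapped extension that
steps over a mismatch only when >= 7 of the next 8 positions pair, never
ending on a mismatch, identity >= 99% over >= 1 kb).

**Ambiguity resolution.** IUPAC positions are replaced by the strict
majority base among covering read bases (depth >= 3); ties stay ambiguous
and are reported. Because completion duplicates the draft's IR, an IR
ambiguity exists at both mirror positions and reads from either physical
copy tie across both, so IR ambiguities resolve like single-copy ones.

**Partition and statistics.** The two single-copy stretches between the IRs
are labeled LSC (longer) and SSC (shorter); the four intervals always tile
the genome. N50 is the smallest contig length such that contigs at least
that long sum to half the total (over contigs >= 1 kb by default); L50 is
the size of that minimal set. Depth-threshold fractions (>= 20/50/100x) are
position-wise and monotone by construction.

## Annotation curation

Server tables are parsed under a configurable column dialect (default
`start end [strand] gene [kind]`, 1-based inclusive; reversed coordinates
mean minus strand). The union of two annotation sets deduplicates
coordinate-identical features (joining source tags) and retains both
versions of same-gene/kind coordinate disagreements, listing them as
conflicts for the validator — conflicts are arbitrated by validation, never
averaged.

CDS validation checks (a) a table-11 initiator {ATG, GTG, TTG} at position
1 and a stop {TAA, TAG, TGA} at the end, (b) no internal stops, (c) length
divisible by three. A missing start or stop triggers an in-frame scan up to
50 bp upstream/downstream for the nearest valid codon and the annotation is
extended (never shrunk; upstream extensions are multiples of 3, preserving
frame). An ACG initiator is recorded as a feature exception (RNA editing of
the start codon) rather than extended away; internal stops in multi-exon
genes flag the exon boundaries for re-evaluation instead of auto-moving
them.

Gene-content summaries count unique genes by name (IR copies collapse); a
gene is duplicated-in-IR when a whole copy — or, for trans-spliced genes,
an exon — lies wholly within each IR. The coding fraction is the fraction
of genome positions covered by any CDS/tRNA/rRNA feature, and gene density
counts gene copies (unique + IR duplicates) per kb — the convention that
reproduces how plastome papers tabulate ~0.85 genes/kb alongside 116 unique
genes. GC content excludes ambiguity codes from numerator and denominator
and is reported to one decimal as a percentage.

## Codon-aware alignment

CDSs are grouped by case-insensitive gene name; exons join in transcript
order with minus-strand parts reverse-complemented (the trans-spliced
*rps12* keeps exon order metadata, including per-exon strands for the IR
copy). Per gene, sequences are translated (terminal stop trimmed and later
restored as a final codon block; internal stops are an error), aligned at
the amino-acid level, and back-translated codon-by-codon, so every gap run
in the nucleotide alignment is a codon multiple and de-gapping any row
reproduces its input CDS exactly.

The built-in aligner is center-star progressive alignment: the center is
the sequence with the greatest summed k-mer similarity, others are aligned
to it pairwise (BLOSUM62, affine gaps −11/−1, global) in decreasing
similarity order and merged under "once a gap, always a gap" on center
coordinates. This is accurate for the near-identical congeneric CDSs the
tool targets; an external aligner executable (e.g. mafft) can be swapped in
through the `aligner` hook where exact replication of a third-party
program's columns matters.

Genes concatenate in lexicographic name order (order affects no statistic);
taxa missing a gene receive an all-gap block, and the partition table maps
gene boundaries before and after gap-column removal (every column holding a
gap or missing symbol in any row is dropped). Pairwise identity is computed
over columns where at least one member of the pair is non-gap, with
gap-versus-residue counting as non-identical — under this definition
removing gap columns can only raise identity, matching the reported
direction of change in published comparisons; difference counts use columns
where both members are non-gap. Other identity conventions exist
(gap-column exclusion per pair, per-alignment); agreement with third-party
statistics beyond ~3 decimals can depend on that choice.

## Phylogenetics

Site patterns are compressed with counts; gaps and IUPAC ambiguities enter
as partial likelihoods over their compatible states. GTR+I+G: the rate
matrix is scaled to one expected substitution per unit branch length; the
gamma distribution (shape `alpha`) is discretized into 4 equal-probability
bins represented by their category means (mean 1 overall), mixed with an
invariant class of weight `p_inv` whose per-site likelihood is the
stationary frequency of the constant state (zero for non-constant
patterns). Transition matrices come from the eigendecomposition of the
frequency-symmetrized rate matrix.

Fitting is joint bounded L-BFGS-B over log branch lengths (bounds 1e-9..5)
and transformed model parameters (log10 exchangeabilities in +-3, three
frequency logits in +-6, log10 alpha in +-1.7, p_inv in 0..0.95),
initialized from empirical base frequencies, restarted until the
log-likelihood improves by < 1e-6; refitting a converged result changes the
log-likelihood by less than that tolerance. Tree search is exhaustive over
unrooted topologies (3 for four taxa, 15 for five; refused above 8 taxa),
which favors exactness over scalability — appropriate for the intended
handful of genomes. Bootstrap resamples alignment columns with replacement
to the original length and reruns the search per replicate; supports are
the percentage of replicates containing each bipartition of the best tree.
By default every replicate refits all model parameters; the fast mode fixes
the model at the full-data estimates and refits only branch lengths. The
test suite and the acceptance script use the fast mode with ~100
replicates as their problem-size choice; on the low-divergence data here
the two modes give the same supports at the reported resolution.

## Synthetic ground truth

The generator builds a circular quadripartite plastome: random intergenic
sequence at the target GC; CDSs composed of an ATG, non-stop codons (codon
weights corrected so coding GC matches the target despite stop-codon
exclusion) and a stop; tRNA/rRNA features; genes packed into each region
with gene lengths rescaled so the covered fraction matches the coding
target (default 0.69); one trans-spliced three-exon gene (*rps12*) with
exon 1 in the LSC and exons 2–3 inside the IR, annotated for both IR
copies with per-exon strands. IRa is exactly the reverse complement of
IRb, and the first/last bases of each single-copy region are chosen not to
pair, so the constructed IR is the maximal inverted repeat and detector
exactness is well-defined. Full-scale defaults mirror published *Cabomba*
magnitudes (LSC 89 kb, SSC 19 kb, IR 25.4 kb, 82 CDS + 30 tRNA + 4 rRNA =
116 genes with 9/7/4 duplicated in the IR, GC 0.38); a 10x-scaled spec
drives routine tests.

Evolution is site-wise under GTR+I+G down a user tree with per-site rate
classes drawn once at the root; there are no indels, so annotations carry
over unchanged, and realized pairwise differences (genome-wide and over
coding positions) are recorded as ground truth. `frame_safe` rolls back
substitutions that would create internal stops; descendant IRa regions are
overwritten with the reverse complement of their IRb (concerted IR
evolution), keeping quadripartite invariants true in every descendant.
In-frame indel variation for alignment testing is generated at the CDS
level (`mutate_cds_family`) rather than genomically, which keeps
assembly-finishing truth exact.

Reads are simulated from uniformly placed circular fragments
(insert 550 +- 60 bp; 2 x 300 bp, matching ~594 bp mean pair length);
per-base errors at the configured rate with Phred scores
`max(2, round(-10 log10 p))` with lognormal jitter, capped at 41; adapter
read-through when the insert is shorter than the read plus an extra
contaminated fraction (default 5%); an orphan fraction (default 2%) loses
one mate. A truth table records fragment origin, insert length, adapter
length, orphan flags and error counts.

## Problem sizes and determinism

The default test suite runs on the 10x-scaled genome (15.9 kb) with 100–200x
reads; the acceptance script runs the full-scale genome (158.8 kb, ~53,000
pairs at 200x, error rate 0.001) with 100 fast-mode bootstrap replicates.
All randomness flows from explicit integer seeds; identical configuration
and seed give byte-identical outputs, and the workflow manifest records
each step's parameters and output checksums.

## Limitations

* No de-novo contig assembly: contigs are inputs (or synthesized).
* Read placement is ungapped; indel-bearing reads and structural variants
  are out of scope, as is SAM/BAM emission.
* The read simulator does not model quality-by-cycle decay or
  nuclear/organellar contaminant genomes beyond random decoy sequence.
* Exhaustive tree search only (<= 8 taxa); no heuristic search, model
  selection, dating or per-gene partitioned models.
* Accession-based comparisons require the GenBank records on disk; the
  package does not download.
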