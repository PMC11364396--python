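# Methods

## Scope and model

`editscan` quantifies adenosine-to-inosine (A-to-I) RNA editing from
stranded paired-end RNA-seq.  Inosine base-pairs like guanosine, so an
edited adenosine is sequenced as G: on the transcript strand an editing
event is an A→G mismatch, and for a gene encoded on the genomic minus
strand the same event appears as T→C against the plus-strand reference.
All counting is therefore done in *event-strand* space: each read's
transcript strand is resolved from the F2R1 library convention (read 2
carries the transcript-strand sequence), and base counts at each position
are complemented for minus-strand transcripts before any ratio is formed.

The per-site editing rate is the fraction of edited over informative
reads, `ratio = G / (A + G)` on the event strand.  Bases other than A or G
at an A site are sequencing errors or masked bases; they are excluded from
the denominator and reported in a separate `other` column.  (The
alternative denominator including all bases is recoverable from the output
columns; the A+G form is the robust default and is recorded in output
metadata.)

## Pipeline stages

**Primary alignment.**  The built-in aligner is an ungapped k-mer
seed-and-verify aligner (default seed 20 nt, up to 4 mismatches,
both orientations).  It is a deliberately small, fully deterministic
device for desk-scale genomes — not a reimplementation of a production
spliced aligner — and reads with several equally good placements are
discarded outright rather than assigned randomly.  Real alignments can be
supplied as SAM/BAM and bypass it; ingested records with base qualities
have bases below Q20 masked to N.

**Hyper-editing rescue.**  Reads left unaligned by the primary pass are
transformed (every A rewritten as G) and aligned against an equally
transformed reference, which collapses the A/G distinction and lets
edit-dense reads place uniquely.  Two transformed references are kept —
A→G and T→C of the plus strand — so both mates of a stranded library are
rescuable in both transcript orientations; which transform succeeds
implies the transcript strand, and is cross-checked against the mate flag.
Each placement is then verified against the *original* genome: the read is
accepted as hyper-edited only when edit-consistent mismatches (A→G on the
event strand) number at least `rescue_min_ag_sites` (default 3), make up
at least `rescue_min_ag_fraction` of all mismatches (default 0.6), and
non-consistent mismatches do not exceed `rescue_max_other_mismatches`
(default 2).  These thresholds are design choices exposed in the
configuration and echoed into output headers; the verification step is
what prevents e.g. C→T mutation clusters from masquerading as editing.
Mismatches of rescued reads are always recorded against the original
reference, never the pseudo-genome.

**Pileup and site calling.**  Base counts are accumulated per (contig,
position, event strand).  Overlapping mate bases are counted once per
fragment; where the mates disagree the base is dropped.  Candidate sites
are positions whose event-strand reference base is A with at least one G
read.  Sites supported by any rescued read are flagged `hyper`.

**High-confidence filter.**  Across the cohort, a site is kept iff at
least 3 samples *individually* show more than 5 edited reads and an
editing rate strictly between 0.1 and 0.9.  The thresholds are read
strictly: `edited > 5` means ≥ 6, and both ratio bounds are open.  The
lower cut removes low-editing loci; the upper cut removes homozygous
genomic variants that masquerade as ~100 % "editing".  Cohorts smaller
than 3 samples cannot satisfy the rule and produce an empty result with a
warning.

**Differential editing.**  At each filtered site, reads are pooled across
the samples of each group into a 2×2 table (edited/unedited ×
group1/group2) and tested with the two-sided Fisher exact test
(`scipy.stats.fisher_exact`; the test suite verifies it against full
hypergeometric enumeration to 1e-12).  Whether to pool reads or test a
per-sample statistic is a genuine design fork; pooling matches a
count-based exact test and is used here, with per-sample mean ratios
carried descriptively in the output.  P values are adjusted by
Benjamini–Hochberg within each comparison separately
(`statsmodels.stats.multitest`), and sites with adjusted p < 0.05 are
significant.  Direction is the sign of the pooled-ratio difference;
direction-0 sites are excluded from the stacked direction summary.
Top-k tables rank by adjusted p, then |Δratio|, then coordinate.

**Annotation.**  A site inside a same-strand gene receives its finest
containing feature with precedence CDS > 3′UTR > 5′UTR > intron (the usual
collapse when isoform features overlap — recorded in output metadata);
otherwise it is `proximal_intergenic` within ±10 kb of any gene's
transcription start/end and `distal_intergenic` beyond.  Region densities
divide site counts by the total annotated length of each class.  Repeat
classes come from a BED track; nested/overlapping repeat intervals resolve
to the smallest interval, ties alphabetically.  Codon consequences rebuild
the codon on the coding strand, substitute the edited A with G and
translate with the standard code (synonymous / nonsynonymous / stop_gain /
stop_loss); with multi-isoform GTFs the longest CDS per gene is used.
Splice proximity labels the first 2 and last 2 intronic nucleotides as
donor and acceptor, and positions 18–44 nt upstream of the 3′ splice site
as the branch-point window — a literature-standard window, since only the
branch-point adenosine itself is a fixed landmark.

**Sequence context.**  Motif profiles take the ±50 nt event-strand
neighbourhood of each site (clipped windows dropped; at least 10 required)
and test each position/base against the background composition with a
one-sided exact binomial test.  The background defaults to the genome-wide
composition rather than 0.25 per base to avoid composition bias; a uniform
or user-supplied background is selectable.  A-rich satellite detection
scans 10-nt windows starting 20–40 nt downstream (event strand) of each
hyper-edited site and flags sites with a window of A-fraction ≥ 0.7;
window width, offsets and threshold are exposed because only the ~30 nt
periodicity itself is established.  The inverted-repeat scanner reports
all maximal exact arm pairs (arm ≥ `min_arm`, loop ≤ `max_loop`,
contained hits removed), seeded by exact `min_arm`-mers at the inner arm
boundary and verified in the tests against an O(n²) brute-force oracle.
An optional mismatch budget extends arms greedily through mispairs; with a
non-zero budget, arms whose inner `min_arm` bases already mispair can be
missed (a documented approximation — the default budget is 0, i.e. exact
complementarity).

## Synthetic data: what it emulates and what it does not

The generator builds multi-gene contigs with
5′UTR–CDS–intron–CDS–3′UTR structure on both strands (second codon fixed
to AGC so a Ser→Gly recoding site is always plantable, including on a
minus-strand gene), SINE-like repeat copies at ~5 % divergence covering a
configurable fraction of introns and 3′UTRs, and inverted repeats of
specified arm/loop lengths planted into introns.  Editing plans draw
transcript-strand adenosines with per-group rates; hyper clusters are runs
of ≥ 3 nearby 3′UTR adenosines edited jointly — one Bernoulli draw per
fragment edits all covered cluster sites, reproducing the read-level
mismatch clustering that rescue relies on, while ordinary sites are edited
independently per fragment (no phasing across fragments).

Reads are 2×75 F2R1 pairs (read length, fragment length ~N(200, 30),
depth and error rate configurable) from uniform-expression transcripts,
with pre-mRNA fragments at a default 0.2 of exonic coverage to emulate
abundant intronic/nascent-transcript editing; tissue data do not pin this
ratio down, so it is an explicit free parameter rather than an inference.
Sequencing error is a flat substitution rate applied after editing.  The
simulator also emits truth alignments (each read's known placement,
spliced reads as multi-block records), which the statistical validation
uses so that pileup and testing are measured independently of aligner
losses.

Not emulated: indels, isoform diversity and alternative splicing, PCR
duplicates, coverage non-uniformity (GC or positional), quality-score
structure, and SNP contamination.  Passing tests therefore demonstrate
correctness of the counting, filtering and testing machinery under clean
conditions — not robustness to the full error structure of tissue
RNA-seq, where SNP masking and duplicate handling matter.

## Numerical and design choices

- Coordinates are 0-based half-open internally; GTF/SAM outputs are
  1-based, BED/bedGraph 0-based, and the VCF-like cohort file 1-based with
  REF=A/ALT=G on the event strand.
- Determinism: a single global seed derives stable per-stage, per-sample
  sub-seeds (SHA-256, < 2³¹); gzip streams are written with a pinned
  mtime, so identical configurations give byte-identical outputs and a
  reproducible checksum manifest.
- Empty Fisher margins return p = 1 with a warning (no information), and
  empty/degenerate inputs (zero-length region classes, < 10 motif windows,
  sub-8 k-mers or arms) raise or warn explicitly rather than silently.
- A site falling in overlapping genes on opposite strands is emitted once
  per strand whose reference base is A, with distinct strand keys.
- Validation problem sizes: statistical checks run on a 4-contig,
  16-gene genome (≈ 36 kb) with 500-site rate-recovery and 2,500-site
  differential cohorts at 50× exonic coverage, 6 samples; rescue checks
  use the default 2-contig, 6-gene genome with four 6-site hyper
  clusters at 40×.  These sizes give stable pass/fail behaviour across
  seeds while keeping the whole suite fast.

## Known limitations

- The primary aligner is ungapped: reads crossing exon–exon junctions
  fail the primary pass and, being spliced, cannot be rescued by the
  ungapped rescue either; they are simply lost from FASTQ-based runs
  (truth-SAM or external SAM/BAM input handles spliced reads fully).
- No SNP database masking: the upper ratio bound of the high-confidence
  filter is the only defence against genomic variants.
- Fisher on pooled counts ignores between-sample overdispersion; strongly
  sample-variable sites can reach significance on pooled counts alone.
- The inverted-repeat scanner measures sequence complementarity only; it
  does not fold RNA or estimate thermodynamic stability.
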