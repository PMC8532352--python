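# Methods

This note records the models, parameter choices and numerical decisions
behind `ectvar`, and what the simulated benchmark does and does not
establish.

## Model overview

The pipeline treats variant discovery as detection of over-expressed novel
sequence. Its unit of analysis is the equivalence class (EC): the set of
indexed sequences (assembled contigs plus reference transcripts) with which
a read end is equally compatible. A read's EC is the intersection of the
id-sets of its k-mers that are present in the index; k-mers absent from the
index are skipped so isolated sequencing errors shrink the evidence rather
than destroy it, but at least half of a read's k-mers must be present
(`min_frac` = 0.5) for the read to count. Reads are assigned single-end
even when sequenced paired, so that short contigs are quantified
correctly; the library size of a sample is its number of assigned read
ends, fixed before any filtering so CPM values keep a stable denominator.

ECs whose members are all contigs ("novel ECs") carry sequence that no
reference transcript explains — assembly junctions, inserts, retained
introns. Everything else is discarded as consistent with the reference.

### Orientation handling

The k-mer index is canonical: each k-mer is stored under the lexicographic
minimum of itself and its reverse complement, making assignment
orientation-agnostic, as in conventional pseudo-aligners. This matters for
inversions: a read from the inverted interior of a variant allele matches
the contig in one orientation and the wild-type transcript in the other.
An orientation-picking rule with a deterministic tie-break assigns
reverse-complement mates of wild-type junction reads to the contig-only
EC in *both* case and control samples, which cancels the differential
signal and makes inversions undetectable at the EC stage. Canonical k-mers
give those reads the joint EC {contig, wild-type} instead, leaving the
inversion-boundary reads — genuinely contig-specific — as the clean
case-only signal.

### Differential expression

Counts are modelled as negative binomial with fixed dispersion φ
(Var = μ + φμ²; default φ = 0.1, not estimated — single-case designs give
no replication to estimate from, and detection is insensitive to φ below
~0.6). The test is a likelihood-ratio test between a null with one shared
rate and an alternative with separate case and control rates, each rate a
mean per library-size offset. The case group has one sample, so its MLE is
the closed form y/L; group rates with several samples and unequal library
sizes are fitted by Newton iteration on log-rate (the log-likelihood is
concave in log-rate; the equal-library closed form Σy/ΣL is the starting
point, convergence tolerance 1e-12, step clamp ±5). The statistic is
floored at zero and referred to χ²(1); under a simulated null
(case and 3 controls from the same NB, μ = 100, φ = 0.1) the empirical
type-I error at p < 0.05 is ≈ 0.047, inside the 0.03–0.07 band expected of
the asymptotic approximation at these counts.

logFC uses a prior count of 0.5 on both groups to avoid infinities; the
significance rule is strict on both thresholds (FDR < 0.05, logFC > 2).
Over-expression (not under-) is the one-sided interest, enforced by the
logFC filter rather than by halving p-values. With zero controls the test
is skipped and ECs are selected on the case CPM filter alone; expect many
more background calls in that mode.

More controls suppress background: sporadically expressed unannotated
transcripts pass the test only when no control happens to express them.
With background ECs expressed in each control independently with
probability 0.5, mean significant counts fall from ≈ 100 to ≈ 40 of 200
going from 1 to 4 controls in our property test. Note this is *not* a
monotone property of the test itself — for genuinely case-enriched ECs,
more controls add power and can only help.

### Annotation

Raw evidence per contig: I/D CIGAR ops ≥ 7 bp, S/H clips ≥ 20 bp, N
junctions absent from the annotation, and aligned blocks ≥ 20 bp outside
every annotated exon. Consolidation rules, in order:

1. Gene-level segment analysis. Aligned segments hitting two genes, or one
   gene plus a ≥ 20 bp block outside every gene extent, give a fusion
   call; multiple segments confined to one gene that overlap on the
   reference, disagree in strand, or run against transcription order give
   an intra-genic rearrangement. Junctions whose two ends lie in different
   genes are fusion evidence and are excluded from the splice rules below.
2. Novel blocks flanked by at least one novel junction become
   novel/extended exon calls (requiring a valid donor or acceptor motif
   when motif checking is on); both flanking junctions are thereby
   consumed. Blocks contiguous with aligned sequence on both sides and
   contained within an annotated intron become retained introns. Blocks
   with no junction support are discarded as unsupported.
3. Remaining novel junctions joining two annotated exon boundaries, or
   truncating an annotated exon end by ≥ 20 bp, become novel exon
   junction calls (size = the larger truncated end). With motif checking
   on, a novel junction must show valid splice sites to be reported.
4. Insertions and deletions pass through as their own classes; a deletion
   whose gap shows valid motifs at both ends is flagged as a possible
   novel intron but keeps the deletion class (the output taxonomy has no
   separate class for it).
5. Clips whose query interval is not ≥ 50% covered by another aligned
   segment of the same contig are reported as class "unknown".

Motif validity means the intron's genomic-forward dinucleotides are within
`tolerance` (default 1) mismatches of {GT, CT} at the start and {AG, AC} at
the end — a set symmetric under strand, so one check covers genes on either
strand. Contigs enter annotation only if ≥ 30 bp *and* ≥ 30% of their
length is aligned and at least one block overlaps an annotated exon.

VAF is estimated from case EC counts as U/(U+W), with U the counts of
contig-only ECs containing the call's contig and W the counts of ECs
containing a reference transcript of the call's gene(s) and no contig. No
closed-form allele model stands behind this: it is an expressed-fraction
proxy using only data the pipeline already has. On heterozygous
simulations it centres near 0.5 for indels (slightly above for insertions,
whose contig-unique region is wider than the wild-type-unique region, and
slightly below for deletions, symmetrically); for fusions it is an
underestimate, since most of the partner genes' wild-type expression
counts towards W. ITDs give VAF ≈ 1 because every wild-type k-mer also
occurs in the duplication-bearing contig.

## The simulator

Fifteen variant classes, five per category:

* fusions — canonical (first two exons of gene A joined to last two of
  gene B), extended exon (plus 30–199 bp of A's downstream intron), novel
  exon (a 30–199 bp intronic block 30–199 bp downstream of A's second
  exon), boundary insertion (7–49 bp of random sequence between the
  partners), unpartnered (A's first two exons joined to a cryptic two-exon
  block, 30–199 bp exons, sampled ≥ 10 kb from any gene);
* transcribed structural variants — insertion, deletion and ITD of 7–49 bp
  within one exon with both endpoints ≥ 10 bp inside it; PTD and inversion
  of 1–3 whole exons (inversions of a *proper* subset, so the variant is
  not merely the whole transcript reverse-complemented);
* novel splice variants — extended exon (+30–199 bp of intron), novel exon
  (30–199 bp block, 30–199 bp into the intron, checked against all
  annotated exons for overlap), truncated exon pair (facing ends shortened
  30–199 bp each, capped to leave ≥ 20 bp of exon), skipped exon (novel
  junction between a non-adjacent exon pair, resampled if annotated),
  retained intron (> 30 bp).

Splice motifs are intentionally not created at variant junctions, so
benchmark runs disable motif checking. Each variant is represented as a
segment list (genomic blocks plus non-templated inserts) from which the
variant sequence, the truth table and a ground-truth spliced alignment are
all derived; in that alignment, gaps ≤ 50 bp contained in an exon become D
ops (deletions), all other gaps become N (introns), the second copy of an
ITD becomes an I op (as an optimal alignment would place it), and segment
runs that are not collinear within 200 kb split into supplementary records.

The case sample is heterozygous: variant and wild-type sequence of each
variant gene at equal coverage (default 50× each), unaltered background
genes at the doubled total (100×); the control holds wild-type sequence
only, for all source transcripts plus the same background genes, at the
doubled coverage. Reads are 100 bp paired-end from 300 bp fixed-length
fragments sampled uniformly (fragment jitter available but off by
default), with independent per-base substitution errors at 0.001 and a
constant quality string. Indel sequencing errors, PCR duplicates, optical
artefacts, coverage bias and strandedness are not modelled.

The synthetic genome provides the reference: non-overlapping genes (one
transcript each) of 4–8 exons of 150–300 bp with introns of 500–1200 bp,
2 kb intergenic gaps, and a 60 kb gene-free tail per chromosome. The exon
minimum keeps every variant transcript at or above the 300 bp fragment
length (a skipped-exon variant of a 4-exon gene retains two exons
≥ 150 bp each); the intron minimum keeps post-variant intron remnants well
above the 50 bp deletion/intron discrimination threshold; the tails supply
the ≥ 10 kb-from-genes intergenic sequence that unpartnered fusions need.
All introns carry GT..AG on the transcribed strand so motif checks can
pass on reference junctions.

## What the benchmark shows — and does not

With ground-truth contigs and alignments, the benchmark isolates the
quantification, testing and annotation stages: recall ≈ 100% per category
at 50× (20 variants per class), classification consistency ≈ 100%, and
≈ 1,400 of 1,500 variants still detected at 5× variant coverage, where the
losses are small indels and truncations near transcript ends with too few
junction-spanning reads to pass the test. Real-data performance is bounded
above by these numbers: de novo assembly failures, alignment ambiguity
(homologous sequence, pseudogenes), expression differences between case
and controls, and shared variants in controls all reduce sensitivity and
add background, and none of them is exercised here. Benchmark problem
sizes (20/class at 50×, 100/class at 5×) were chosen so the whole
acceptance run completes in a few minutes on one CPU while keeping ≥ 20
draws of every size distribution per class.

## Defaults

| parameter | default | meaning |
|---|---|---|
| k | 31 | k-mer length (odd, < read length) |
| min_frac | 0.5 | minimum fraction of read k-mers present |
| φ | 0.1 | fixed NB dispersion |
| CPM | > 0.1 | case-sample expression floor (strict) |
| FDR | < 0.05 | BH-adjusted significance (strict) |
| logFC | > 2 | case-vs-controls fold-change floor (strict) |
| prior count | 0.5 | logFC stabiliser, both groups |
| gap_min | 7 bp | smallest reported insertion/deletion |
| clip_min | 20 bp | smallest breakpoint-evidence clip |
| block_min | 20 bp | smallest novel block |
| trunc_min | 20 bp | smallest reported exon truncation |
| aligned | ≥ 30 bp and ≥ 30% | contig retention at annotation |
| motif tolerance | 1 | mismatches allowed per junction end |
| min_contig_len | 150 bp | contig length floor entering the pipeline |
| read/fragment | 100 / 300 bp | read simulation geometry |
| coverage | 50× | per-allele variant coverage |
| error rate | 0.001 | per-base substitution probability |

## Known limitations

* ECs cannot separate two variants assembled into one contig; a common
  secondary variant shared with controls can mask a rare one.
* The fixed-dispersion χ² LRT is approximate; at very low counts it is
  mildly conservative, and no exact small-sample correction is applied.
* Variant transcripts shorter than the fragment length receive no
  simulated reads and are undetectable within the benchmark.
* The fusion rule imposes no minimum distance: any second locus outside
  the gene's extent counts, so read-through-like proximal events are
  called fusions.
* VAF is a proxy, biased upward for insertions/ITDs and downward for
  fusions, as described above.
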