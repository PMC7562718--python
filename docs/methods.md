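# Methods

This note documents the models, conventions, and numerical choices behind
`phasiscan`: what each stage computes, which knobs matter, what the
synthetic benchmark does and does not emulate, and where the design was
genuinely open.

## Biological model

Reproductive phased siRNAs (phasiRNAs) in grasses are 21- or 24-nt
siRNAs produced in register from long non-coding precursor transcripts.
A trigger miRNA (miR2118 for 21-nt loci, miR2275 for 24-nt loci) directs
AGO cleavage of the precursor between the bases paired with trigger
positions 10 and 11; RDR6 copies the downstream fragment into dsRNA,
which DCL proteins dice processively into duplexes one period at a time.
Consequently siRNA 5' ends fall on a fixed residue class modulo the
period — the *phase register* — set by the cleavage site.  21-nt
phasiRNAs show a strong 5'-cytosine bias and are loaded into AGO5-clade
effectors, which can slice mRNA targets; a sliced target leaves a
degradome (PARE) tag whose 5' end marks the +1 position of the cut.

## Small-RNA processing

Reads are collapsed (unique sequence + count), filtered to 18–30 nt, and
placed on the reference by exact match on both strands — the contract of
a no-mismatch aligner in report-all mode, implemented with a
collision-free base-4 k-mer index (k = shortest read length) rather than
an external aligner.  The 5' position of a minus-strand placement is the
forward coordinate of its biological 5' end (leftmost + length − 1).
Multi-mapping policy is "count-all" by default (weight 1 at every
placement) with "fractional" (1/n) selectable; the reads-per-million
denominator is always the total mapped 18–30-nt read count with each
read copy counted once, so the two policies share a library size.

## Phase score and locus calling

Within a nine-cycle window (9 × period nt) at register r, let P be the
summed count of period-length reads whose (shifted) 5' ends sit on r,
U the summed count at off-register positions, and k the number of
occupied (position, strand) phase slots (≤ 18).  The score is

    score = ln[(1 + 10·P/(1 + U))^(k−2)]   for k ≥ 3, else 0.

The statistic is monotone increasing in P and k and decreasing in U.
Minus-strand reads are tested after shifting their 5' position by +2 nt,
the dicer-duplex 3'-overhang convention; the synthetic generator plants
minus-strand reads at register − 2 (mod p) so generator and detector
share one convention, which is the quantity actually asserted by the
register invariants.

The scan slides the window by 1 nt, takes the best register per window
(both strands pooled), and merges overlapping qualifying windows of
equal register into loci spanning from the first to the last in-register
read.  Defaults: score ≥ 15 and k ≥ 4, both configurable — values in
the range used by published phasing scanners; sensitivity to the score
threshold is reported by the pipeline's built-in sweep.  Loci are named
`<period>PHAS<number>` in (reference, start) order; member phasiRNAs are
named `<locus>_<offset><strand>` with offset the 5'-end distance from
the locus start on the forward strand.

## Mispair scoring and target prediction

Duplexes are scored with the plant target-prediction penalty scheme:
Watson–Crick pair 0; G:U wobble 0.5; mismatch or bulged nucleotide 1;
every penalty halved when its sRNA position (1-based from the 5' end)
lies outside the core region 2–17.  Candidate sites are duplexes with
total score ≤ 3.5 (inclusive).  The predicted cleavage (+1) coordinate
is the target base paired with sRNA position 10.

Conventions the scheme itself does not fix, chosen once and frozen:

* **Bulge cap** — at most 2 bulged nucleotides per duplex.  Each bulge
  costs ≥ 0.5 of the 3.5 budget, and the cap keeps the exhaustive
  enumeration oracle tractable.
* **Bulge attribution** — a bulged target nucleotide takes the sRNA
  index of its 5'-adjacent paired nucleotide (clamped to [1, n]); a
  bulged sRNA nucleotide takes its own index.  The halving rule then
  applies to bulges exactly as to mismatches.
* **Overlap resolution** — among overlapping qualifying sites the lower
  score wins, leftmost on ties.

Two engines implement the scheme: a small global dynamic program with
traceback per window, and a semi-global scan (vectorized over a whole
concatenated transcriptome, sentinel-separated) that scores every
possible site end in one pass and refines qualifying ends through the
global DP.  Their equality, and equality with brute-force enumeration
of all ≤ 2-bulge alignments, are property-tested.

## Degradome categories and target validation

Tag profiles record 5'-end counts per transcript position (1-based);
tags map by exact sense-strand match and are expected ~20 nt (MmeI
product length), any length ≥ 15 accepted.  The cleavage-site category
ranks the tag count c at the diagnostic position against the
transcript's profile:

| Category | rule |
|---|---|
| 0 | c > 1, equal to the maximum, unique maximum |
| 1 | c > 1, equal to the maximum, maximum shared |
| 2 | c > 1, above the average but not the maximum |
| 3 | c > 1, at most the average |
| 4 | c = 1 |

"Average" is computed over occupied positions (≥ 1 tag) by default —
the convention of the category scheme's originating tools; a per-
nucleotide average is selectable (`average="all"`) and flagged in the
output.  A candidate is **validated** iff its category is 0 or 1, the
site carries ≥ 4 tags, and those tags make up ≥ 10% of the transcript's
total — all bounds inclusive.  Degradome abundances are reported as
RP10M (reads per ten million mapped tags).

## Mutant-dependence classification

For each phasiRNA the wild-type and mutant replicate counts are
compared with a stand-in for a negative-binomial differential test: a
two-sided exact binomial test on pooled counts, with success
probability equal to the wild-type share of total library size,
followed by Benjamini–Hochberg correction.  A feature is *dependent*
iff its wild-type/mutant fold change of mean RPM is ≥ 2 and its FDR is
≤ 0.05.  The stand-in is exact under the generator's Poisson noise but
does not model overdispersion; externally computed p-values can be
supplied to replace it.  Normalization is by total mapped library size;
when a depleted class dominates the library this compresses apparent
fold changes (the usual composition effect), which is why the benchmark
reference includes a large non-phased background (below).

## Synthetic benchmark

The generator plants known truth and emulates the statistical structure
the analysis assumes:

* **Reference** — per 21-/24-nt locus one precursor embedding the exact
  reverse complement of its trigger miRNA, phased read positions on
  both strands downstream of the implied cleavage site; 60 transcripts
  of 900–1600 nt, at most one planted target site each (the exact
  reverse complement of a plus-strand 21-nt phasiRNA); ten 50-kb
  "intergenic" contigs that receive background reads and belong to the
  mapping reference but not to the target-prediction transcriptome,
  mirroring the genome-mapping versus cDNA-target distinction of real
  analyses.  The intergenic background also keeps phasiRNAs a minority
  (~20%) of each library so library-size normalization remains
  meaningful.
* **5'-C bias** — with probability 0.9 per 21-nt phased position the
  precursor base at the read 5' end is edited to C (G on the forward
  strand for minus-strand reads) at generation time, so biased reads
  remain exact reference matches and all replicates share one
  reference.  Positions inside the trigger site are never edited; the
  default trigger carries G at position 10 and C at position 12, so the
  cycle-0 duplex reads begin with C regardless.
* **Counts** — phased positions draw Poisson(20) per replicate
  (negative binomial optional via a dispersion parameter), divided by
  the depletion factor (default 4) in the mutant; background reads of
  18–30 nt fall uniformly over the whole reference at 0.05 reads/nt.
  Three replicates per condition.
* **Degradome** — background tag counts at position i are
  Poisson(1.0 × 0.995^i), a geometric decay from the 5' end
  approximating exonucleolytic background; planted cleavage coordinates
  receive an extra Poisson(50) spike.  Tags are 20-nt substrings;
  positions within 20 nt of the 3' end emit none, and a planted site
  falling there is marked unvalidatable.

All randomness derives from the configuration seed through fixed named
streams, so a fixed configuration reproduces byte-identical output
files.  Things the generator deliberately does **not** model:
sequencing error, adapters, quality scores, expression heterogeneity
across loci, overdispersion by default, transcript secondary structure,
and any biogenesis difference between 21- and 24-nt loci beyond the
period.  Passing recovery tests therefore demonstrates correctness of
the analysis logic under the stated statistical model, not performance
on real libraries.

## Problem sizes and measured error modes

The default benchmark (20 loci × 10 cycles, 50 planted targets, ~580 kb
reference, six libraries of ~37 k reads) runs in ~25 s; the test suite
executes it across ten seeds and the acceptance script across three.
Under these conditions locus and validated-target recovery are
complete, no period-24 locus is called at a 21-nt locus, and ~97% of
phasiRNAs are flagged RDR-dependent at depletion 4 versus 0% without
depletion.  One measured limitation: among 500 dinucleotide-shuffled
decoy sRNAs (ten seeds) a single decoy chanced to resemble another
planted phasiRNA closely enough to form a 3.5-score duplex over that
phasiRNA's site, placing its predicted cleavage on a genuine degradome
spike and validating — the classic degradome-coincidence false
positive.  The decoy false-validation rate of the validation chain is
therefore of order 0.2% per decoy–transcriptome test at this spike
density, not exactly zero.

## Known limitations

* The phase score uses the widely adopted closed form above; published
  scanners differ in constants and consensus rules, so absolute scores
  are not comparable across tools (thresholds are configurable).
* Exact-match mapping only; one mismatch tolerance (common for real
  reads) is out of scope.
* The dependence test ignores overdispersion and uses library-size
  normalization; on real data a dedicated count-model package should
  supply p-values through the override hook.
* Degradome mapping is sense-strand, full-tag exact match; no partial
  or antisense placement.
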