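# phasiscan

Detection of phased siRNA (*PHAS*) loci from small-RNA sequencing data
and degradome-based validation of phasiRNA-directed target cleavage.

In grass reproductive tissues, 21- and 24-nt phasiRNAs are produced in
fixed registers from long non-coding precursors after trigger-miRNA
cleavage (miR2118 / miR2275 families), and 21-nt phasiRNAs can direct
slicing of mRNA targets.  `phasiscan` re-implements the computational
chain used to characterize this pathway, for researchers who want a
tested, scriptable version of these analyses on transcript-scale
references — or a fully synthetic benchmark with planted ground truth:

* **sRNA processing** — collapse, 18–30 nt filtering, exact (no
  mismatch) mapping on both strands, 5'-end position profiles, size and
  5'-nucleotide summaries, RPM normalization.
* **PHAS detection** — nine-cycle sliding-window phase score
  `ln[(1 + 10·P/(1+U))^(k−2)]` (P in-register abundance, U off-register,
  k occupied phase slots, k ≥ 3), best-register scan, locus merging,
  phasiRNA naming (`21PHAS0007_165+`), trigger-site annotation.
* **Target scoring** — the plant mispair scheme: mismatch/gap/bulge +1,
  G:U wobble +0.5, penalties halved outside sRNA positions 2–17,
  candidates at score ≤ 3.5; predicted cleavage between the target bases
  paired with sRNA positions 10 and 11.
* **Degradome analysis** — tag 5'-end profiles, Category 0–4
  cleavage-site classification, target validation (category 0/1, ≥ 4
  tags at the site, ≥ 10% of the transcript's tags), RP10M.
* **Dependence classification** — wild-type vs mutant replicate counts,
  exact binomial stand-in test + BH-FDR, dependent ⇔ fold ≥ 2 ∧
  FDR ≤ 0.05.
* **Synthetic data** — generator planting loci, registers, 5'-C bias,
  background reads, degradome spikes, and replicate noise, with the
  ground truth emitted for recovery scoring.

See `docs/methods.md` for the full model description and conventions.

## Worked example

Run the whole synthetic pipeline at its default benchmark conditions
(20 planted 21-nt loci of 10 cycles, 50 planted targets, three
wild-type and three mutant replicates):

```bash
$ phasiscan run-all --seed 1 --out runs/demo
20 loci, 66 validated targets; locus recall 1.00, target recall 1.00
```

All 20 planted loci are recovered at their exact registers and every
planted cleavage site is validated from the degradome (66 validated
rows cover the 50 planted sites; some sites are hit by more than one
phasiRNA).  `runs/demo/loci.tsv` begins:

```
locus_id    reference_id  start  end  period  register  strand  phase_score  k   trigger       trigger_score  trigger_cleavage  trigger_register_consistent
21PHAS0001  PRE21_0001    17     248  21      17        -       116.67       18  miR2118-like  0.0            39                True
21PHAS0002  PRE21_0002    8      239  21      8         -       123.69       18  miR2118-like  0.0            30                True
```

Each locus carries a phase score far above the calling threshold (15),
all 18 phase slots of the nine-cycle window occupied, and an exact
(score 0.0) trigger site whose implied cleavage position is consistent
with the locus register.  The validated-target table pairs each
phasiRNA with its slicing evidence — here 63 degradome tags at the
diagnostic +1 position, 24% of all tags on that transcript, a unique
maximum (Category 0):

```
srna_id          transcript_id  site  duplex_score  tags_at_site  category  site_fraction  validated
21PHAS0014_169+  T0001          971   0.0           63.0          0.0       0.244          True
```

The same stages are available as `simulate`, `profile`, `phas`,
`predict`, `degradome`, `dependence`, and `evaluate` subcommands for
user-supplied FASTA/TSV inputs, and as plain library functions
(`phasiscan.scan_phas_loci`, `phasiscan.score_duplex`, ...).  Every
threshold can be overridden from a YAML config (`--config`).

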