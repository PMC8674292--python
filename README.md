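# psiexon

Junction-level splicing statistics and pseudoexon (psiExon) discovery for
studies of small-molecule splicing modifiers.

Splicing-modifier compounds (risdiplam-class molecules and their relatives)
can lower the expression of a target gene by promoting the inclusion of a
normally silent intronic *pseudoexon* carrying a premature termination
codon: the transcript is then destroyed by nonsense-mediated decay (NMD).
Detecting and characterising such events from RNA-seq or targeted amplicon
sequencing requires a chain of junction-level statistics that are usually
reimplemented ad hoc per study. `psiexon` packages that chain as a tested
library and CLI for bioinformaticians analysing splice-junction count
tables, together with a synthetic-data generator so every stage can be
validated end to end without external downloads.

## What it computes

**Junction expression index (JEI).** For an annotated intron with donor d
and acceptor a, in one sample:

    JEI = 100 · n(d→a) / Σ n(junctions using d or a)

JEI = 100% means the intron always splices exactly as annotated; lower
values reveal alternative paths such as a cryptic exon inside the intron.
Groups are compared per intron with a two-sided Student's t test, and
introns with >25% mean reduction at P < 0.05 are flagged as
compound-induced splicing events.

**Percent spliced in (PSI).** For a cassette exon with inclusion junctions
(counts I₁, I₂) and a skip junction (count S):

    PSI = 100 · mean(I₁, I₂) / (mean(I₁, I₂) + S),   NA if denominator < 20

ΔPSI between conditions is tested with a two-sided Fisher exact test on
replicate-pooled counts; events with ΔPSI > 20 (or < −20) and P < 0.001 are
called Inc (or Skp). Inc-called cassette exons with a splice site absent
from every supplied annotation source are psiExons.

**Splice-site strength.** 9-mer donor windows (3 exonic + 6 intronic bases)
and 23-mer acceptor windows (20 intronic + 3 exonic) are scored in log2
odds, either with user-supplied maximum-entropy score tables in their
published file layout, or with a trainable PWM fallback (uniform 0.25
background, additive pseudocount) so that nothing external is required.

**Genome-wide GA-psiExon scan.** Introns are scanned on their sense strand
for the noncanonical donor signature `AGA|gtaag`; every upstream AG is
scored as a candidate acceptor, and candidates pass when 6–200 nt long,
acceptor score > 2.3, and not already annotated.

**NMD classification.** An included exon is an NMD-psiExon when it causes a
frameshift (length not divisible by 3) and/or introduces a premature stop
codon, determined by splicing the exon into its host transcript and
translating from the annotated start.

**k-mer enrichment.** k-mer (k = 4–6) frequencies in fixed windows around
the 5'ss of two exon groups are compared with Fisher exact tests and
reported as signed significance scores SS = −S·log₁₀(P).

**Quantification arithmetic.** ECL protein-lowering normalisation
(ratio ×1000 vs the vehicle grand mean, % lowering = (1−fold)×100),
efficiency-corrected qPCR abundances (1+E)^(−Ct), transwell permeability
Papp = (dCr/dt)·Vr/(A·C0) with both efflux summaries, and the unbound brain
partition coefficient Kp,uu = C_brain·fu,b/(C_plasma·fu,p).

## Worked example

Generate a synthetic corpus with three planted psiExons, scan the genome,
and run the event analysis:

```bash
psiexon simulate --seed 7 --n-genes 6 --n-pass 3 --out demo/
psiexon scan --genome demo/genome.fa --annotation demo/annotation.gtf \
             --out demo/scan.tsv --bed demo/scan.bed
# -> 3 candidates, 3 passing, 3 primary
psiexon events --junctions demo/junctions.tsv --annotation demo/annotation.gtf \
               --genome demo/genome.fa --manifest demo/manifest.tsv \
               --out-prefix demo/ev
# -> 25 events, 3 psiExons
head -3 demo/ev/psiexons.tsv
```

```
event_id             contig strand start end  length basal_psi is_psiexon
CE:chr1:+:1391-1519  chr1   +      1391  1519 128    0.99      True
CE:chr2:-:2566-2628  chr2   -      2566  2628 62     0.88      True
```

The scan recovers exactly the three planted exons (each ending `AGA` with
`gtaag` following, acceptor scoring above 2.3). The event analysis finds the
same three intervals as Inc-called cassette exons: nearly silent in the
control group (basal PSI ≈ 1%) and strongly included after treatment, with
both splice sites absent from the annotation — the psiExon signature.

The full pipeline (`psiexon run --config run.yaml`) chains all stages and
writes per-stage TSVs plus a run manifest with config hash and input
checksums; rerunning a config reproduces byte-identical outputs.

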