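# Methods

## Coordinate and junction conventions

All coordinates are 0-based half-open internally. A junction is keyed by
`(contig, donor, acceptor, strand)` with `donor` the first intronic base and
`acceptor` one past the last, so the intron is `[donor, acceptor)`
irrespective of strand; 1-based inclusive dialects (GTF, the 9-column
spliced-aligner junction tab) are converted once at the IO boundary.
Junctions with undefined strand inherit the strand of the unique gene whose
intron span contains them; ambiguous or orphan junctions are dropped and the
count recorded on the table. Writing and re-reading any table or annotation
reproduces identical records, and internal→GTF→internal conversion is the
identity.

## JEI

The junction expression index of an intron in a sample is the percentage of
junction reads supporting the exact annotated intron among all reads using
either of its splice sites. Junctions wholly inside the intron but touching
neither site are excluded from the denominator — the definition names only
reads using the 5'ss or 3'ss. JEI is undefined (not zero) when no read uses
either site. Group comparison is per-sample-then-test: each replicate gets
its own JEI and the two groups are compared with a two-sided pooled-variance
Student's t test (Welch available via an option; pooled is the default
because the classical test is what "Student's t test" names). Percent
reduction is 100·(1 − mean_treated/mean_control) and an intron is flagged at
reduction > 25% and P < 0.05. Degenerate inputs are reported, not hidden:
fewer than two defined JEIs in a group makes the comparison untestable; two
constant equal groups give t = 0, P = 1; constant unequal groups report
P = 0 with a degeneracy status.

## Event catalogue and PSI

Discovery is junction-driven with annotation as scaffold. Cassette exons are
intervals between a flank pair (an annotated intron, or an observed junction
linking two annotated exon boundaries) supported by two inclusion junctions;
novel intervals additionally require the skip junction to be observed.
A5SS/A3SS events are pairs of observed junctions sharing one end (pairs that
belong to a cassette triad are not double-reported); the junction with the
shorter intron — retaining more exonic sequence — is the inclusion isoform.
Events with zero reads everywhere are dropped. Events spanning several genes
are assigned to the first containing gene and flagged ambiguous.

Per sample, inclusion support for a cassette exon is the arithmetic mean of
its two inclusion-junction counts (an inclusion isoform carries two
junctions, a skip isoform one; averaging corrects the double counting), and
PSI = 100·inc/(inc+exc), NA when inc+exc < 20 reads. NA is first-class and
excluded from group averages. The group test pools replicates by summing
per-sample supports and rounding half-up (Fisher needs integers; half-up is
the deterministic choice), then applies a two-sided Fisher exact test to the
2×2 inclusion/exclusion × group table; an all-zero row or column margin is
reported as P = 1 with a degeneracy flag. ΔPSI uses NA-excluded averaged
per-sample PSI, not pooled-count PSI. Calls: Inc iff ΔPSI > 20 and
P < 0.001, Skp iff ΔPSI < −20 and P < 0.001, else NC — boundaries exclusive.
Swapping group labels maps Inc↔Skp and leaves P unchanged.

psiExons are Inc-called cassette exons with at least one splice site present
in no supplied annotation source. Their 9-mer donor and 23-mer acceptor
windows are extracted strand-aware; windows running off a contig are kept
but marked unavailable.

## Splice-site models

Two backends score the same window geometries (donor 9-mer at −3..+6,
acceptor 23-mer at −20..+3; log2 odds). The maximum-entropy backend loads
user-supplied published score tables in their distributed layout (`me2x5`;
`me2x3acc1..9`) and applies the published combination formula — consensus
positions scored against a 0.27/0.23/0.23/0.27 background, the remaining
7-mers combined multiplicatively with the lower-order correction terms in
the denominator. The tables are not redistributable, so they are never
bundled; tests exercise the loader and formula on synthetic table files
whose expected scores are hand-computable. The PWM fallback scores
Σ log2((count+pc)/(n+4·pc)/0.25) per position (pseudocount pc = 1 by
default) and can be trained from any annotation + genome (≥50 sites) or
window list; a shipped synthetic PWM (canonical GT/AG consensus with a
pyrimidine-rich acceptor tract, not trained on any genome) makes the scan
and simulator fully self-contained. The scan threshold 2.3 applies to
whichever backend is configured and the backend is recorded in outputs —
the threshold is calibrated to the maximum-entropy scale, so fallback runs
are for self-contained testing, not biological inference.

## GA-psiExon scan

Each intron is scanned on its biological sense strand only (pseudoexon
inclusion requires the host pre-mRNA's orientation) for `AGAGTAAG`, read as
exon-final `AGA` plus intronic `gtaag`. For each occurrence, every upstream
AG whose implied exon is ≤ max_len + 23 bases is enumerated; the 23-mer
acceptor window ending 3 bases into the candidate exon is scored, and
candidates failing the 6–200 nt length filter or the > 2.3 score filter are
still reported with their failure reasons. Candidates whose acceptor window
would cross the intron boundary are skipped. Per motif occurrence the
best-scoring passing candidate is primary (ties to the shorter exon), so
both per-candidate and per-occurrence counts are available. "Annotated"
means the exon interval exactly matches an annotated exon or both splice
sites are annotated boundaries in one source; annotated candidates fail with
reason `annotated`. Candidates are deduplicated by (contig, strand,
interval) across overlapping transcripts. A census utility tabulates the
−2,−1 exon-terminal dinucleotide over internal exons (exons with a
downstream intron), strand-aware and deduplicated, with AG as the canonical
signature.

## NMD classification

An exon inserted between two exons of a CDS-bearing transcript causes a
frameshift iff its length mod 3 ≠ 0 — this is arithmetic and holds
regardless of sequence. A premature stop (PTC) is detected by splicing the
exon into the mature transcript and walking codons from the annotated start:
the first stop counts as introduced when it overlaps the inserted exon, or,
for frameshifted insertions, when it precedes the transcript's original stop
after removing the insertion offset. `is_nmd = frameshift OR ptc`.
Insertions upstream of the start codon or downstream of the stop return
`is_nmd = False` with reason "non-coding insertion". The 50-nucleotide
exon-junction rule is deliberately not applied by default — the definition
here is the literal PTC-or-frameshift one — and classification is strand
invariant. When several isoforms could host an exon, use the longest
CDS-bearing transcript.

Host-gene expression context is consumed from an externally computed
differential-expression table (`gene_id, log2fc, fdr, base_mean`);
dispersion modelling and shrinkage belong to the upstream tool. The shift
test is a two-sided Wilcoxon rank-sum of log2 fold changes, gene set vs all
other genes: exact null when the smaller group has ≤ 20 genes and no ties,
normal approximation with tie correction otherwise; the per-group empirical
CDF is emitted. The volcano classifier labels genes down/up at >1.5-fold and
FDR < 5%, NC otherwise (missing FDR → NC with reason).

## k-mer enrichment

Windows around the 5'ss are specified relative to the exon/intron boundary
with no position zero (−4..−1 exonic, +1..+6 intronic by default). Counting
is by overlapping occurrences across windows — with the short default
windows and k = 4 this coincides with per-window presence. Each observed
k-mer is tested one-vs-all-other-k-mers between groups with a two-sided
Fisher exact test (side chosen for consistency with the module's other
tests and recorded in output metadata), and SS = −S·log₁₀(P) with S = +1
when relatively enriched in group 1. P values are deliberately uncorrected:
SS is a ranking score. Degenerate tables give SS = 0. A position-frequency
matrix TSV supports logo-style summaries; rendering is out of scope.

## Quantification

ECL lowering: per animal, ratio = mean(duplicate target)/mean(duplicate
normaliser)×1000; fold = ratio / vehicle-group grand mean of ratios;
% lowering = (1 − fold)×100, which makes the vehicle group average exactly
0% by construction. The white-blood-cell variant omits the normaliser and
uses raw target means. Zero-normaliser animals are excluded with a reason.

qPCR: abundance = (1+E)^(−Ct) per amplicon; the target is normalised to the
housekeeping amplicon and expressed as percent of the vehicle-group mean
(efficiency-corrected ΔΔCt). When E is not supplied it is estimated from a
dilution series as E = 10^(−1/slope) − 1, the standard reading of
"calculated from the slope of the amplification curve". The result is
invariant to shifting all Cts by a constant when efficiencies are equal.

Permeability: Papp = (dCr/dt)·Vr/(A·C0) in cm/s with dCr/dt the
least-squares slope of receiver concentration vs time (difference quotient
for two points). The efflux summary is emitted in both published forms —
the difference Papp(B→A) − Papp(A→B) exactly as printed and the
conventional ratio Papp(B→A)/Papp(A→B), each labelled, with no silent
correction of either. Percent recovery is not computed (its formula is not
specified); the donor volume Vd is carried on the record for users who
supply their own. Kp,uu = C_brain·fu,b/(C_plasma·fu,p), dimensionless.

## Synthetic data

The generator emulates the statistical structure of the study inputs, not
sequencing reads. Defaults are the study conditions: two groups (DMSO
control vs compound) with three biological replicates; psiExons nearly
silent at baseline (PSI 1%) and strongly included under treatment (PSI 40%);
junction depths ~1000 per event and ~200 for constitutive junctions, typical
of the bulk and targeted designs emulated.

Genomes are one gene per contig, strands alternating, each with an annotated
CDS (random non-stop codons between ATG and TAA, 30-base UTRs) so NMD is
decidable. Planted psiExons have exact `AGA|GTAAG` boundaries; their
acceptors are rejection-sampled against the shipped fallback acceptor model
until the target score class is hit (pyrimidine tract for passing, AG-poor
purine mix for sub-threshold), then frozen into the FASTA with the realised
score recorded in the truth manifest. Intron filler is AG-free so each plant
yields exactly one scan candidate, and any unplanned occurrence of the donor
motif (either genomic orientation) is scrubbed by forcing its +3 position to
C — a substitution that can create neither a stop codon nor an AG. Decoys
violate exactly one filter each: length 5, length 201, weak acceptor, or an
annotated twin (the interval added to the annotation as an extra
transcript).

Junction counts per event and sample: with depth N and true PSI π,
M ~ Binomial(N, π/100) inclusion molecules each evidence both inclusion
junctions (counts M, M) and exclusion contributes N − M skip reads, so the
averaged-inclusion PSI estimator is unbiased for π — the averaging exists
precisely because the inclusion isoform carries two junctions. The
amplicon-panel mode is deterministic: one intron receives a cryptic junction
taking fraction f of donor-sharing reads, making its true JEI exactly
100·(1−f) up to count rounding. Threshold-straddling event fixtures use
fixed per-sample counts, with expected calls derived from hand arithmetic
plus an exact hypergeometric enumeration independent of the analysis path.
Quantification fixtures encode known lowering percentages, Ct values
consistent with stated efficiencies, and linear receiver series whose slope
encodes the true Papp. Identical config + seed reproduce byte-identical
outputs; all randomness flows through one seeded generator.

What the generator does **not** emulate: read-level noise (mapping errors,
overhang filters, positional bias), expression heterogeneity across genes,
correlated replicates, intron retention, or realistic splice-site sequence
diversity beyond the shipped PWM's consensus. Passing tests therefore
demonstrate the correctness of the statistics and the scan on their stated
models, not robustness to aligner artefacts.

## Problem sizes and numerical choices

The test suite and acceptance script run on deliberately small corpora —
4–26 genes (up to ~125 introns, ~120 kb of sequence), 100 planted intervals
in the scan check, 500 replicates for PSI recovery, 1000 sampled Fisher
tables — sizes at which every expected value is hand-checkable or
enumerable while still exercising both strands and every decoy class.
Fisher comparisons use the conventional 1+1e-7 relative tie tolerance;
replicate pooling rounds half-up; PWM training uses pseudocount 1 against a
uniform background; scan ties break toward the shorter exon. All thresholds
(ΔPSI 20, P 0.001, PSI denominator 20, JEI 25%/0.05, fold 1.5/FDR 0.05,
scan 6/200/2.3) live in one config block and are overridable.

## Known limitations

Intron-retention events are out of scope (not in the event taxonomy used).
No multiple-testing correction is applied to event calls (a fixed P < 0.001
operates as the selection rule) or to k-mer SS values. The maximum-entropy
backend's acceptor consensus constants follow the published scorer's
formula; exact agreement with a live third-party installation should be
spot-checked once when tables are supplied. The genome-wide counts reported
by the original study require the human genome and RefSeq-class annotation
and are not reproduced by the desk-scale synthetic corpora.
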