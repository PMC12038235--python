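# Methods

## The synthetic locus

All analyses run against a seeded generator (`synthetic_locus`) that
emulates the structural biology of the grapevine berry color locus rather
than its literal sequence. Sequences are pseudo-random with GC ≈ 0.45;
nothing in the package depends on real *Vitis* nucleotides, only on the
locus's structural features. Real FASTA/GFF3 input is accepted by every
downstream module, so the generator is a default, not a requirement.

### Gene templates

Every `VvMybA` paralog derives from one ancestral template: a 300-bp
promoter and a three-exon gene (240 + 130 + 383 bp of CDS = 753 bp,
translating to a 250-aa protein, the length of the functional MybA
regulators; introns of 150 and 500 bp). Paralogs are produced by seeded
substitution-only divergence that never creates an in-frame stop and never
touches the start/stop codons, so every template translates cleanly.
The divergence design is hierarchical so the gene family has the observed
group structure: `VvMybA1/2/3` share a close common ancestor (~94%
pairwise identity), `VvMybA4/11` a second group, `VvMybA9/10` are
intermediate, and `VvMybA13` (plus the schematic `VvMybA12`, see below) is
distant — 60–78% identity to the R2R3 probe, the range reported for the
real cluster. An outgroup sequence at ~55% probe identity stands in for
the Arabidopsis MYB75 anthocyanin regulator in tree building; it is
deliberately below the gene-discovery identity threshold.

Because paralog divergence is substitution-only, the probe regions of all
paralogs are equal-length and can be stacked into an ungapped alignment
(`paralog_probe_alignment`) without running an aligner. This is the one
place the generator departs from real data, where paralogs also differ by
indels and a multiple alignment would be required; the phylo module's
contract is a pre-aligned input either way.

### Haplotypes

Allelic differences are expressed as variant specs applied right-to-left
(so template coordinates never shift under earlier edits), with exon
intervals remapped across indels and an edit log retained in allele
coordinates — the log is what the diagnostics module uses to place
markers:

* HapA: *Gret1* in the `VvMybA1` promoter; `VvMybA2` with an R44L-style
  codon substitution and a CA dinucleotide deletion (frameshift, premature
  stop); `VvMybA3` with the 209-bp exon-3 deletion.
* HapC-N: functional `VvMybA1c`; `VvMybA2r` with the in-frame 282-bp
  C-terminal duplication; the same `VvMybA3` deletion.
* HapF1/F2: `VvMybA1_SUB` (intronic insertions of 44, 33 and 111 bp, a
  diagnostic SNP at position 99 of intron 2, and a few synonymous exonic
  substitutions that act as allele-private coding SNPs for the expression
  analyses — without them the SUB allele's cDNA would be indistinguishable
  from the reference allele, since its hallmark insertions are intronic);
  full-length `VvMybA3`; functional `VvMybA2` with the 282-bp duplication.
* HapF2 additionally duplicates the `VvMybA4` unit (gene + 4.2-kb
  downstream flank); the second copy is mutated to 90% identity, then the
  213-bp insertion goes into exon 3 of copy 1 (`VvMybA4a`) and an RLG
  retrotransposon into exon 1 of copy 2 (`VvMybA4b`) — the order of
  events proposed for the locus's evolution.
* HapF^DEL^ is literally HapF2 with the interval from 1.4 kb upstream of
  `VvMybA3` to 10.8 kb downstream of `VvMybA4b` excised, which removes six
  genes and leaves `VvMybA1`, `VvMybA9`, `VvMybA13`.

Gene counts are therefore 8 (HapA), 8 (HapC-N), 8 (HapF1), 9 (HapF2),
3 (HapF^DEL^). HapF1 has 8, not 9, genes: it lacks the tandem duplication
by definition, and the HapF1-like wild accessions carry eight MybA
sequences.

Two geometry choices are schematic and declared as such. (1) The eighth
HapA gene is named `VvMybA12`; the published locus maps only say HapA has
eight MybA genes and that `VvMybA13` has no close HapA homolog, so the
eighth slot needed a neutral name. (2) Gene order and orientation follow
the HapF map with all genes on the plus strand; exact intergenic
distances are not published, so two default spacer widths are used —
9,070 bp inside the deleted interval and 12,200 bp elsewhere — chosen so
that HapF2 spans ≈138 kb *and* the deletion spans ≈76 kb simultaneously
(a single uniform spacer cannot satisfy both numbers).

Intergenic spacers are haplotype-family specific (one set for HapA/C-N,
one for the HapF family). This mirrors the fact that the two haplotype
families are structurally divergent outside the genes themselves, and it
is what makes "confirmed absence" detectable: gene bodies attract reads
from every haplotype, F-specific spacers only from HapF carriers.

### Transposable elements

TEs are built as LTR–internal–LTR (600 + 3,000 + 600 bp by default) with
initially identical LTRs, then aged by giving each LTR independently
`Poisson(μ·age·L)` substitutions at uniform positions — exactly the
process the LTR clock `T = K/(2μ)` inverts. Default planted ages: *Gret1*
0.15 Myr (HapA promoter), and on HapF 0.19/0.45/1.19 Myr for the
intergenic elements plus 0.69 Myr for the RLG in `VvMybA4b`, the published
age range. μ defaults to 1.3×10⁻⁸ substitutions/site/year; the published
analysis's exact rate lives in supplementary material, so the value is an
explicit, configurable assumption.

### Read simulators

DNA reads are single-end, uniform-start, substitution-error-only
(configurable rate); a diploid input draws each read from either haplotype
with probability 1/2. RNA reads are multinomial across alleles with
probabilities ∝ TPM × transcript length, uniform within the transcript.
Both are bit-reproducible from their seed. No indel errors, no quality
model, no ONT error profile: the diagnostics depend on spanning and
matching, which substitution errors already stress. Consequently, passing
tests show the decision logic and estimators are correct under the stated
error model — not that the pipeline is robust to real instrument
artifacts (chimeric reads, indel-rich ends, mapping ambiguity in repeats).

## Haplotype diagnostics

Reads are mapped (minimap2 short-read preset; mapping itself is input,
the wrapper exists for the simulated data) against the HapF2 haplotype as
the single reference, on which the default marker panel lives:

* `hapf_ins33` — insertion-span over the 33-bp intron-2 insertion of
  `VvMybA1_SUB` (HapF presence), plus the corroborating intron-2
  position-99 SNP. Which F subhaplotype that SNP separates is not
  published, so the marker file carries the state→subhaplotype mapping
  and the default panel uses it only as HapF-level support.
* `f2_tandem_junction`, `f2_ins213`, `f2_rlg_junction` — the three HapF2
  criteria (tandem-copy junction, 213-bp insertion, RLG/gene junction).
* `fdel_absence_1/2` — absence regions over the two pure F-specific
  spacers inside the deleted interval (`A11–A10` and `A2–A4a` gaps,
  shrunk by a 50-bp margin against alignment-end bleed), with 1.5-kb
  flank windows that reach into the neighbouring gene bodies.

A junction/insertion read supports its marker iff one gapless aligned
block covers the breakpoint with ≥ 20 bp on each side. For inserts, the
window sits on *either* insert boundary: a read cannot physically span a
213-bp insert plus overhangs, but a block across a boundary is proof the
insert is present, while reads lacking it align with a deletion exactly
there. An absence region is confirmed only with zero interior coverage
and ≥ `min_reads` coverage on both flanks — flanking gene bodies are
covered by HapA-derived reads in the heterozygotes the assay is used on,
which is what separates deletion from missing data. The published
protocol inspected these alignments by eye; the thresholds
(`min_reads` = 3, `min_overhang` = 20) make that judgment explicit and
configurable.

Decision rule (a pure function of evidence + thresholds): no 33-bp
support → `no_HapF` (1–2 reads → `ambiguous`, never a hard negative);
confirmed absence with no F2-marker support → `HapF_DEL`; tandem-junction
support corroborated by at least one other F2 marker → `HapF2`; no
F2-marker support and absence not confirmed → `HapF1`; anything
conflicting → `ambiguous`. Round-trip tests run at 30× diploid depth (the
simulator's reference depth); at 20× the expected number of reads
spanning the 33-bp insertion windows leaves a non-negligible chance of
dropping below three supporting reads, i.e. the visual-inspection
protocol itself becomes underpowered.

In-silico PCR is exact-substring primer matching on both orientations
(product set provably invariant under reverse complement). The
`VvMybA3_HapF` assay anchors its forward primer in intron 2 (identical
across alleles) and its reverse primer in distal exon 3 past the 209-bp
deletion and clear of the allele-private SNPs, so both alleles amplify
and the 209-bp product-length difference is the diagnostic signal.

## Allele-specific expression

Private SNPs are alignment columns where exactly one allele differs and
the rest share one ungapped state. Per-allele proportion is the
unweighted arithmetic mean of the allele-state frequencies at those
columns (a depth-weighted mean exists behind a flag as an extension;
unweighted is the default because simple averaging is the described
procedure). Columns under `min_depth` = 10 are skipped and logged.
Proportions are renormalized per gene to sum to 1 before TPM splitting —
the per-allele TPM of a gene must add to the gene's total. A detection
floor of 0.01 reproduces the "n.d." semantics of per-allele expression
tables. Quantification is against one consensus per gene, then split —
matching the consensus-sequence protocol.

## Locus structure

Gene discovery aligns the conserved R2R3 probe (exon 1 + intron 1 +
exon 2 of `VvMybA1`, 520 bp) as an infix with edlib, iteratively taking
the best hit and masking it, on both strands; default `min_identity` 0.6
spans the `VvMybA13` divergence while excluding the outgroup. Structural
diffs are annotation-driven (runs of genes present in one model, absent
in the other) with breakpoints refined by the common prefix of the
inter-anchor sequences, so an exact substring deletion is recovered
base-precisely; flank offsets are reported relative to the first/last
deleted gene. Pairwise identity and LTR divergence use an affine-gap
global aligner (match +1, mismatch −1, open −3, extend −0.5): under unit
edit costs, co-optimal paths trade adjacent mismatch pairs for gap pairs
and systematically deflate the mismatch fraction — a ~2% downward bias in
LTR ages that the affine scoring removes. Allele-to-allele indel calling
merges gap runs separated by exact anchors < 15 bp, because optimal edit
paths split a long insertion wherever an inserted base coincidentally
matches the reference.

Divergence correction for dating is Jukes–Cantor by default with Kimura
2-parameter behind a flag; the published choice is in supplementary
material, and at the divergences involved (≤ 3%) the two differ by far
less than the clock's Poisson noise. LTR pairs below 60% identity
(gap-inclusive) are rejected as unreliable clocks rather than dated.

## Phylogenetics

TN93 distances use pairwise complete deletion (per-pair shared ungapped
columns; global complete-deletion is configurable) and pair-pooled base
frequencies; saturated pairs become +inf with a warning, never a clipped
value. UPGMA breaks ties by the lexicographically smallest pair of member
label tuples, making trees deterministic. Bootstrap support is computed
on the point-estimate tree's clades (majority-on-reference), replicates
resample columns with replacement, branches under 90% collapse into
polytomies with their length absorbed into the children (tip heights
preserved), and the tree is finally rooted on the outgroup edge. Whether
supports should be recomputed after collapsing is unspecified in the
protocol being mirrored; they are not recomputed here. The implementation
is cross-checked in the tests against an independent closed-form
evaluation from raw substitution counts and against `ape::dist.dna`
(model "TN93") through Rscript.

## Genetics statistics

The segregation χ² is Pearson's without continuity correction: the
uncorrected statistic for 151:36 against 3:1 is 3.296 (printed 3.29),
while Yates' correction would give ≈ 2.94 — the uncorrected form is
therefore what the published number used. Allele frequencies assume one
copy per carrier unless told otherwise (carrier tallies from typing
surveys don't distinguish homozygotes). The dosage comparison is Welch's
two-sample test; the published analysis does not name its test, and a
two-sample mean comparison is the standard choice producing p-values of
that magnitude. Percentages print half-up to integers (6.5 → 7, matching
printed tables; banker's rounding would not), statistics to two decimals.
The wild-grapevine survey table ships as a constant (printed tables are
inputs), and its aggregation reproduces every printed row.

## Problem sizes

The defaults keep everything desk-scale: ~138-kb haplotypes, 30× diploid
read sets (~50k reads), 50k-read RNA experiments, 20-replicate dating
experiments at 3-kb LTRs, 200–1000 bootstrap replicates on ≤ 10 taxa.
The full test suite runs in about a minute on one CPU.

## Known limitations

* The somatic-chimera case (distinct haplotypes in L1/L2 cell layers) is
  not modeled; diploid simulation mixes two haplotypes 50:50.
* Absence-region flanks rely on cross-haplotype coverage of shared gene
  bodies, so a HapF^DEL^/HapF^DEL^ homozygote would need absence markers
  with F-family flanks instead of the default panel.
* The generator's substitution-only divergence understates indel
  variation between real paralogs and alleles.
* `find_myba_genes` reports probe-sized hits (the R2R3 footprint), not
  full gene models; counts, order and strand are the contract.
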