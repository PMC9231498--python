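# Methods

`erv-census` studies endogenous retrovirus (ERV) lineage expansions in a
host genome the way a population-genomic screen would: structurally
annotate proviruses in a reference assembly, call presence/absence of each
ERV locus in resequenced individuals from short-read alignment signatures,
date lineages from LTR divergence under a molecular clock, and aggregate
calls into cohort-level sharing statistics. Because the real data for such
a study are a multi-gigabase assembly and terabytes of reads, the package
ships its own synthetic-study generator and treats it as a first-class,
tested component: every downstream claim is measured against the
generator's ground truth.

## The synthetic study

### Provirus templates

A lineage's ancestral provirus is a random-sequence template with the
canonical structure 5'LTR–gag–pro–pol–env–3'LTR (defaults: 500 bp LTRs,
~7.3 kb internal region, ~8.3 kb total — the size of a typical
betaretroviral provirus). Each gene is generated as a single open reading
frame (ATG, non-stop codons, stop), so premature stops and frameshifts in
descendant copies are unambiguously attributable to mutation. Templates of
different lineages are independent random sequences; real ERV lineages are
phylogenetically related, but inter-lineage homology plays no role in any
measured quantity here, and independence guarantees that clip-to-library
matching and k-mer repeat finding cannot cross lineages by construction.

### Molecular evolution of copies

`evolve_copy` applies a single-hit Jukes–Cantor substitution process: each
site of each LTR and of the internal region is substituted independently
with probability `mu * age` (substituted bases move to one of the other
three bases uniformly); the two LTRs evolve independently, which is what
makes the expected 5'–3' LTR divergence `2 * mu * age` — the clock used
for dating. Indels of length 1–3 bp are placed at `indel_rate * age` per
site (default `mu/10`) and drive frameshifts. No rate heterogeneity and no
multiple-hit correction are modelled: at the divergences involved (≤ ~7%)
the single-hit bias on the clock is ≈ d/2 relative (about 2% at d = 5%),
well inside the 15% recovery tolerance the package tests.

Every mutation is logged with template coordinates. Log-derived truth
counters (`pol_stop_count`, `pol_frameshift_count`) replay the log rather
than re-aligning, and the annotation module's alignment-based profiling is
required by test to agree with the log in ≥ 95% of copies (the residual
disagreement is real: later indels can restore frame or alignments can
place gaps differently).

### Lineage design

The default three-lineage configuration mirrors an old, an intermediate
and a very young expansion:

| lineage | target median LTR divergence | age (years, mu = 3e-9) | allele freq | population pool |
|---|---|---|---|---|
| phaCin-beta-like | 2.2% | 3.67e6 | Beta(1.2, 2.5) | 90 |
| phaCin-beta | 0.6% | 1.0e6 | Beta(0.5, 6.0) | 320 |
| KoRV | ~0% | 2.5e4 | Beta(0.3, 16.0) | 560 |

Copy ages are drawn uniformly over (0, 2·age] — a burst window centred on
the lineage age — so the median copy divergence hits the target while the
range extends down to 0, as observed ranges for young expansions do. The
clock rate is fixed at 3e-9 substitutions/site/year (the midpoint of the
human 2e-9 to mouse 4.5e-9 interval used for dating); dating always
reports the interval implied by both endpoint rates.

Allele-frequency distributions shift lower with lineage youth: an older
burst has had more drift time, so its surviving loci sit at higher
population frequencies. The Beta parameters were chosen once, by matching
the implied carrier statistics for an 11-individual cohort (mean carrier
counts of roughly 2.8 / 1.9 / 1.5 and singleton-dominated sharing for the
youngest lineage) to the kind of gradient a recent germline invasion
shows. Pool sizes are set so the loci detectable in 11 individuals number
roughly 80 / 170 / 145 at scale 1. The spec for this distribution is
deliberately configurable (`AlleleFreqDist`), since the true frequency
spectrum of ERV alleles in a wild population is not known.

Assembly membership is emergent by default: each locus is in the reference
assembly haplotype with probability equal to its allele frequency, because
the assembly is itself one sampled haplotype from the population. This
single assumption reproduces, without further tuning, the observed pattern
that younger lineages have both fewer assembly loci and a lower assembly
fraction among detected loci (the youngest lineage's low-frequency alleles
are rarely caught in one haplotype). A fixed `ref_fraction` mode
(frequency-weighted subset of exactly that size) is retained for
controlled experiments and is what most tests use when they need a
guaranteed number of reference loci.

### Planting and coordinates

Insertion sites are uniform over contigs subject to a minimum spacing of
2× the library insert size (default 800 bp; overlapping evidence clusters
are outside the modelled regime) and an edge margin of 2 kb. Each
integration duplicates a 4–6 bp target site: the planted block reads
TSD + element + TSD, with `pos` (0-based) the first base of the TSD in the
pre-insertion sequence. Elements land on either strand with probability
0.5 (minus-strand copies are reverse-complemented in the genome). All
internal and BED coordinates are 0-based half-open; SAM output is 1-based
via pysam. Infeasible spacing is a hard error, never silent truncation.

In population-only mode (`sequences=False`) the generator draws loci,
frequencies, assembly membership and genotypes but skips sequence
evolution and reference editing — used for population-scale Monte Carlo
over cohort statistics, where only the genotype layer matters.

### Read-alignment emulation

Rather than running a production mapper, the simulator places reads
against the reference directly from truth, which preserves exactly the
evidence classes the caller consumes while keeping runs seeded and
byte-reproducible. Each diploid individual is sequenced as paired-end
fragments (150 bp reads, insert 400 ± 50 bp, flat base quality, per-base
error default 0.002) drawn uniformly from each haplotype at half the
individual's depth. A haplotype is represented as a piecewise map onto the
reference: host segments map linearly; non-reference proviral copies map
to the lineage's library contig. Junction arithmetic then dictates each
read's placement:

- a read crossing a non-reference insertion junction anchors on the host
  side when at least 20 bp of host sequence are present (else it anchors
  in the element and maps to the library contig) and the remainder is
  soft-clipped — clips at the 5' junction end at the TSD's last base,
  clips at the 3' junction start at the TSD's first base, producing the
  double-clip overlap whose width is the TSD length;
- a pair straddling a junction deeply enough becomes a discordant
  host↔library pair;
- for a haplotype lacking a reference-assembly ERV, the empty site behaves
  as a deletion: pairs spanning it show an apparent insert stretched by
  the element length, and junction-crossing reads are clipped at the
  element's boundaries with the clipped tail matching the opposite flank.

Sequencing errors are applied to the read sequence after placement, so
clip tails carry errors but CIGARs do not drift — a deliberate
simplification (real aligners occasionally mis-place reads near junctions;
this simulator never does, which is part of why measured precision/recall
are upper bounds for real data).

## Annotation

`find_ltr_pairs` finds candidate proviruses as pairs of similar repeats at
proviral spacing: exact 12-mers shared at a consistent offset (±24 bp,
tolerating indels between the repeats) are chained (gaps ≤ 250 bp), and
chains are verified by global affine alignment (identity threshold 0.85 by
default, length and element-span windows applied). Candidates are
deterministic (leftmost, then longest; greedy non-overlap). The element
span window must be chosen below the minimum distance between planted
elements (the pipeline derives it from the template length); this excludes
chance chains between the LTRs of *different* nearby copies of the same
lineage.

Repeat boundaries are then refined against the integration-site geometry:
because the detected repeat pair is maximal, the true element can only be
a trim of it, and `refine_boundaries_by_tsd` picks the trim (≤ 6 bp per
side) that maximises the flanking exact duplication. `detect_tsd` itself
is an exact longest-duplication search (≤ 20 bp, truncated at contig
edges); exact matching keeps the contract unambiguous, and mismatch
tolerance is left as a configuration extension.

Gene profiling aligns the element globally (affine gaps: match 2,
mismatch −3, open −6, extend −1) to the full template; orientation comes
from an LTR match against the template library and minus-strand elements
are reverse-complemented first. Per gene, identity is matched columns over
the gene's template length; premature stops are read in the template frame
from codons aligned without gaps; each indel of length ≢ 0 (mod 3)
touching the gene counts as one frameshift. A gene under 40% identity —
far above random for nucleotides, far below intra-lineage identities — is
reported undetected rather than mutation-free. `full_length` requires both
LTRs and all four genes. Solo LTRs are found by iterative best-infix
search (edlib) of each library LTR outside annotated elements.

## Calling

`extract_evidence` collects, from a coordinate-sorted SAM: soft-clips
≥ 10 bp whose tails pass a low-complexity filter (Shannon entropy of the
overlapping dinucleotide composition ≥ 1 bit) and match a library LTR on
either strand at ≥ 80% identity with ≥ 10 matching bases (edlib infix
alignment); and discordant pairs (host-anchored reads with library-mapped
mates). Reads on library contigs never generate evidence, so no call can
fall inside the library.

`call_nonreference_insertions` single-linkage clusters evidence within
200 bp per contig and lineage. The breakpoint is the interval between the
modal left-clip and modal right-clip positions; its width estimates the
TSD length. Support semantics: the policy's `min_reads` threshold (5 for
high-coverage, 2 for low-coverage samples) counts discordant pairs — the
discovery signal — while clips drive the stringent per-side filters
(CLIP5 ≥ 2 and CLIP3 ≥ 2) and a support-vs-coverage sanity window on pair
support, cov/8 ≤ pairs ≤ 3·cov. The lower bound is set a factor ~3 below
the expected heterozygous junction support at that depth; the upper bound
rejects pile-ups no single germline locus can generate. The stringent call
set is a subset of the relaxed set for the same evidence, by construction
and by test.

`call_reference_absences` scores each annotated reference ERV locus per
individual: spanning pairs (one mate each side, apparent insert within
4 SD of insert + element length) plus split reads (clips at the element
boundaries whose tails match the opposite flank when the reference is
available). An absence needs combined support ≥ `min_reads`. The zygosity
hint is `hom_absent` unless concordant, unclipped coverage inside the
element reaches 20% of the heterozygous expectation (cov/2 scaled by
element length over read length, floor 3 reads).

`rescue_softclips` re-counts LTR-matching clips and discordant anchors
within ±300 bp of known cross-sample loci and upgrades a locus to present
when pooled support meets the relaxed threshold. This is where
low-coverage individuals gain: their pair support alone often falls below
2 at 6×, while junction clips are still there. Rescue is idempotent and,
because random clips do not match library LTRs, does not cost precision
in any measured configuration.

## Dating and distances

Distances are raw p-distances — mismatched over aligned, ungapped columns
of a global affine pairwise alignment, computed on a canonical ordering of
the pair so symmetry is exact. Pairwise alignment stands in for a
multiple-sequence alignment; at the divergences involved the column-wise
discrepancy is negligible and is covered by the clock-recovery property
test. The integration age is `t = d / (2·mu)` — the factor 2 because both
LTRs accumulate substitutions independently after integration — reported
as an interval over mu ∈ [2e-9, 4.5e-9]. Display rounding is two
significant figures in millions of years, capped at one decimal for ages
≥ ~0.1 My (5.5, 2.4, 1.5, 0.7). Inactivating-mutation summaries count pol
stops plus pol frameshifts per copy; copies without a detectable pol are
excluded and reported separately.

## Cohort aggregation

Cross-sample insertion calls merge by single-linkage clustering of
breakpoints within ±100 bp on the same contig and lineage (breakpoint
scatter after clip refinement is far smaller; clusters never mix
lineages). Locus ids are assigned in coordinate order, making merging
deterministic and idempotent, and every (individual, call) maps to exactly
one presence entry. The presence matrix holds loci × individuals in {0,1}
(reference loci default to present unless a hom_absent call exists; het
absences keep presence with genotype 1). "Frequency" in lineage summaries
is the carrier count — an integer number of individuals, formatted as
"N (lo-hi / mean)" — not an allele-frequency estimate. Sharing is the
percentage of a lineage's matrix rows present in ≥ 2 individuals.
Reference loci carried by no resequenced individual stay in the matrix
flagged reference-only. Heatmap rows order by carrier count over a focus
set, then by the binary presence pattern, then id — deterministic and
idempotent.

## Pipeline and reproducibility

`run_end_to_end` drives simulate → annotate → call (per individual) →
rescue → merge → date → summarise → evaluate from one YAML-serialisable
config. A single seed feeds every stage through fixed-offset
`SeedSequence` substreams, so stages are independently reproducible and
the whole run directory is byte-identical under re-run (asserted by test).
Outputs are plain text: FASTA, coordinate-sorted SAM, BED, TSV, YAML, and
a Markdown report carrying per-individual precision/recall against truth,
lineage summaries, sharing fractions and age intervals. Config validation
is an explicit key/type check rather than a JSON-schema engine — the
config surface is small and the error messages are better.

Truth evaluation matches calls to true loci greedily by breakpoint
distance (tolerance 25 bp). In the simulator's regime — loci spaced ≥ 800
bp, scatter ≤ a few bp — greedy matching attains the maximum matching,
which the tests verify against brute force on spaced point sets.

## Problem sizes used by the test and acceptance suites

Chosen as the package's own desk-scale defaults: clock Monte Carlo uses a
short-internal template with full-size 500 bp LTRs (the LTRs are what the
clock measures); age recovery uses 200 replicates per clock point; age
ordering and the cohort gradient use 100 replicate cohorts (the gradient
at 3× the default pools, population-only mode, where larger lineages make
the ordering statistic stable); caller performance uses one 40×
individual on a 1 Mb host with 30 planted loci; rescue and
detection-asymmetry experiments use 10 paired cohorts at 40× / 6× on
200–300 kb hosts.

## Known limitations

- Truth-guided alignment emulation has no mapping error, no duplicate
  reads, no mismapping between near-identical ERV copies; measured caller
  accuracy is therefore an upper bound on real-data performance.
  Low-complexity clip filtering is exercised by construction, not by a
  realistic repeat landscape.
- The substitution clock is single-hit and homogeneous; dating of old
  elements (d ≫ 10%) would need a multiple-hit correction the package
  does not apply by default.
- Independent random templates mean cross-lineage evidence confusion is
  structurally impossible, unlike truly related retroviral lineages.
- Genotype calls at non-reference loci are presence-only; no likelihood
  model distinguishes het from hom insertions.
- The sharing statistics of the default generator are truth-level
  (perfect detection) when computed from the genotype layer; the paper-
  style detection-limited values are lower, and only the ordering across
  lineage ages is treated as the reproducible claim.
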