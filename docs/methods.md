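# Methods

This note records the models, parameter choices and known limitations
behind `mhcasm`, in the order the pipeline runs. Nothing here reports a
number the test suite or `scripts/acceptance.py` does not itself compute.

## The assembly model

`mhcasm` produces *pseudo-haploid* MHC consensus sequences: one assembly
per best-matching guide haplotype (BMH) rather than a single diploid
assembly. The BMH stands in for a parental chromosome — a proxy for trio
binning — and is chosen from the guide panel by the individual's HLA-DRB1
first-field genotype (mapped through DRB1/DRB3/DRB4/DRB5 linkage to a DR
class) and C4 status. The guide is used three times, and only three
times: to bin reads (mapped vs unmapped), to localize assembly
(superblocks), and to order/orient scaffolds. Consensus *bases* always
come from the reads, never from the guide, so novel variation is captured
reference-free.

Assumptions inherited from this design:

* DR class and C4 capture the major structural variation; recombinant
  DR haplotypes are not modelled.
* Binning is per-guide and non-competitive: every read that aligns to a
  BMH end-to-end at score ≥ −0.6·L joins that BMH's bin. For a diploid
  individual both haplotypes' reads enter each bin wherever the two
  haplotypes are similar; see *Heterozygous inclusion* below for the
  consequence.

## Stage parameters

| stage | parameter | default | rationale |
|---|---|---|---|
| QC | min poly-G run | 20 | two-colour chemistry artifact signature |
| QC | lead/trail quality floor | Q3 / N | standard trimmer semantics |
| QC | sliding window | 4 bp, mean Q ≤ 15 truncates | standard trimmer semantics; truncation at window start |
| QC | min mate length | 40 bp | shorter mates carry little seed information |
| mapper | scoring | match 0, mismatch −6, gap open −5, extend −3 | end-to-end aligner defaults behind the published `L,0,−0.6` threshold |
| mapper | accept threshold | score ≥ −0.6·L | published threshold function |
| mapper | seed k | 15 | exact-seed sensitivity at 150 bp reads |
| superblocks | span / overlap | 50 kb / 5 kb | localized assembly windows; overlap lets adjacent windows' contigs merge |
| assembly | k | 51 (both pools) | the workflow's published operating point balancing accuracy and speed |
| assembly | coverage cutoff | max(2, ⌈median/10⌉) | removes singleton error k-mers at ≥ 20× without touching real sequence |
| assembly | tip length / bubble identity | 2k / 0.95 | standard de Bruijn cleaning |
| cross-filter | identity / coverage | 0.90 / 0.50 | published rule: unmapped-pool contigs mapping to the alternative BMH or off target are removed |
| merge | min overlap / identity | 40 bp / 0.95 | overlap-layout consensus defaults; joins must be **unambiguous** (see below) |
| polish | depth / majority | ≥ 5 reads, > 50% | conservative column edit; length-1 indels only |
| scaffold | min links | 3 consistent pairs | below this, spurious links dominate |
| placement filter | reject if loc < 0.1, or loc < 0.3 ∧ orient < 0.75 | — | published scaffold-orientation filter |
| depth advisory | hard < 25×, soft < 30× | — | published coverage recommendations |

Numerical tie-breaks are all deterministic: mapper ties go to the
leftmost target start then '+' strand; bubble ties to the
lexicographically smaller branch; contigs are emitted in (length,
sequence) order in canonical orientation; every random draw flows from
one integer seed through named per-stage streams.

Two engineering notes on fidelity. The mapper tries a mismatch-only
extension first and falls back to an affine-gap dynamic program over a
seed window; for targets ≤ 4 kb an exhaustive semi-global scan runs
before a read is declared unmapped, so accept/reject decisions are exact
there (the property the test suite verifies against an independent
aligner). The external variant-caller-based error-correction step of the
original workflow is replaced by pileup majority polishing with declared
thresholds — the cited caller was itself a substitution for a retired
tool, and a transparent majority rule is easier to reason about at desk
scale.

Supercontig merging requires an *unambiguous* partner: if a contig end
has two distinct qualifying overlap partners — the signature of ending
inside similar repeat copies — no merge happens and the pieces are left
to scaffolding and placement. Without this rule, repeat-dense simulations
produce chimeric supercontigs. Similarly, paired-end links whose gap
estimate is strongly negative (contigs that overlap but disagree too much
to merge) are dropped rather than clamped, because clamping duplicates
the overlap into a false insertion.

Junctions — scaffold-internal seams whose insert-model gap estimate is
below 10 bp, and consecutive placed scaffolds whose guide coordinates
overlap — are resolved by *sequence verification*: overlap lengths are
scanned around the estimate and accepted when the consensus suffix and
the incoming prefix agree at ≥ 90% over ≥ 25 bp, giving an exact,
indel-free cut (a verified seam is recorded with gap 0, the one place a
gap run may be shorter than the 10 N minimum). Without sequence support
the junction falls back to a coordinate trim under a 10 N spacer, or to a
plain spacer when the estimated overlap is within placement jitter.
Inter-scaffold gaps are otherwise sized from guide spacing (minimum
10 N). Getting these junctions right matters: a clamped or coordinate-
trimmed junction leaves a ±tens-of-bp duplication or deletion that the
error accounting classifies as a (usually repeat-associated) structural
event, and junctions concentrate exactly where contigs break — in
repeats.

## The synthetic data generator

The simulator emulates the features of the MHC that this method's design
answers to, at a scale a laptop handles:

* **Shared ancestor, class II cassettes.** All guides derive from one
  ancestor sequence; each DR class inserts a distinct cassette at a fixed
  locus (DR1 4 kb, DR3 6 kb, DR2 8 kb, DR4 14 kb, DR8 none — only the
  relative structure is meaningful, chosen so DR4 > DR2 > DR3 > DR8 and
  class II alignment breaks are visible at 300 kb scale). Each cassette
  begins with a 1 kb allele-group tag, which doubles as the exemplar for
  the naive genotyper.
* **C4.** A ~5 kb tandem unit with 1–3 copies, A/B isotype motifs, and a
  long/short form via an internal 1 kb insertion.
* **Interspersed repeats.** Three families (300/450/1000 bp) implanted at
  a configurable density; each copy is mutated at 12% from the family
  consensus, matching the lower end of real interspersed-element
  divergence (genomic Alu/L1 copies sit roughly 10–25% from consensus).
  Truth intervals are recorded per guide and lifted through the
  individual's indels to exact truth-haplotype coordinates.
* **Diploid individuals.** Each haplotype is its guide mutated at stated
  SNP and short-indel rates, with every change recorded; applying the
  recorded variants to the guide reconstructs the haplotype exactly (a
  tested invariant).
* **Reads.** 150 bp FR pairs drawn uniformly from both haplotypes at a
  per-haplotype depth, normal insert model (500 ± 50 bp), uniform
  substitution errors, Q37 baseline with occasional low-quality tails,
  and poly-G replacement artifacts.

What it does **not** emulate: real human MHC sequence content, empirical
Illumina error profiles (quality-dependent, context-dependent errors),
target-capture probe bias, segmental duplications beyond C4, and
population-level haplotype structure. Passing the synthetic benchmark
therefore demonstrates the pipeline's mechanics — binning, localized
assembly, repeat handling at realistic divergence, structural-haplotype
reconstruction, error accounting — not calibrated accuracy on real data.

## The benchmark scenario

The reference validation scenario (`mhcasm.benchmark`, also what
`scripts/acceptance.py` runs) fixes: two 300 kb DR3/DR4 guides, repeats
at 20% density, both guides carrying a single long-form C4 unit; one
diploid individual at 0.5% SNP divergence per haplotype (indels at
5×10⁻⁴/bp); 30× per-haplotype 150 bp pairs at 0.1% base error; full
pipeline per BMH; consensus scored against truth. At these sizes the
whole scenario runs in a few minutes on one CPU, which is also why the
test suite can execute it wholesale.

Multi-copy and heterozygous-form C4 are deliberately excluded from the
scenario. Near-identical tandem units collapse in any short-read de
Bruijn assembly — a known limitation of the approach, visible as C4
alignment gaps on real data — and one collapsed 5 kb unit is an
*absolute* artifact: at 4.7 Mb it costs ~0.1% error, at 300 kb the same
event costs ~1.7% and would swamp every rate-driven error source the
scaled-down scenario is meant to measure. C4-aware BMH matching and
copy-number handling are exercised by unit tests instead.

## Heterozygous inclusion

At a site where the two haplotypes differ, the BMH bin contains both
alleles at roughly equal depth (the −0.6·L mapping threshold admits ~10%
mismatch, so haplotypes do not separate at SNP scale). The resulting
graph bubble is collapsed to the higher-coverage branch — a coin flip at
balanced depth — so the consensus carries the *other* haplotype's allele
at about half of all heterozygous sites, regardless of read quality or
depth. Expected base-call mismatch rate against one truth haplotype is
therefore ≈ het-rate/2 plus a small true-error term; with 0.5%
per-haplotype divergence (≈ 1% het density) that is ≈ 0.5%. The
benchmark's `attribute_het_switch` output confirms the decomposition:
over 90% of consensus mismatches equal the homologous allele of the other
haplotype, and the residual true-error rate is a few hundredths of a
percent. This is an intrinsic cost of pseudo-haploid assembly from a
mixed diploid pool, not a defect of any particular stage; resolving it
would require competitive (haplotype-phasing) binning, which is outside
this method's design.

## Known limitations

* C4 and other near-identical tandem duplications collapse; the placed
  consensus represents them once, with guide-spaced N gaps absorbing the
  length difference where placement allows.
* The naive k-mer DRB1 genotyper exists to make self-contained runs
  possible. It keys on class-cassette tags, cannot call DR8 (no cassette
  to detect; DR8 genotypes must be provided), and is unsuitable for any
  clinical or even research-grade HLA typing.
* Base-call error against a single truth haplotype is dominated by
  heterozygous inclusion (above) whenever haplotype divergence exceeds
  the read error rate.
* No long-read integration, no iterative polishing rounds, no formal
  phasing of the two per-BMH consensi.
* Error percentages are computed over assembled (consensus) length, not
  the full region length, so fragmented low-coverage assemblies can look
  deceptively accurate; the depth advisories exist for this reason.
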