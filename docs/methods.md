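# Methods

This note records the models, conventions and numerical choices behind
each module, in the order data flows through the pipeline.

## Coordinates and containers

VCF and GFF3 are 1-based inclusive at the I/O boundary; BED is 0-based
half-open. Internally every interval is 0-based half-open, and the
conversion (start − 1, end unchanged) is bijective. A callset is a
`VariantSet`: one row per biallelic variant with chromosome, 1-based
position, ref/alt alleles, Phred quality, total depth, per-strand
alternative-allele read counts and a genotype in
{hom-ref, het, hom-alt, no-call}. Multiallelic VCF records are split
into biallelic rows on read, because allele matching (novelty,
cross-breed sharing, chip harmonization) and Ts/Tv are per-allele
concepts. Per-strand alt counts are read from a configurable INFO
field; the default is a samtools-style `DP4` (ref-fwd, ref-rev,
alt-fwd, alt-rev) taking the last two entries, since different callers
emit these counts under different tags.

## Hard-filter cascade

Six predicates, with defaults: quality < 20; depth < 10 or
depth > mean + 3·SD; fewer than one forward or one reverse
alt-supporting read; SNP within 5 bp of another SNP (both removed);
SNP within 5 bp of an InDel (the SNP removed — the rule's wording is
asymmetric and names only SNPs); InDel within 10 bp of another InDel
(both removed). Choices the rule text leaves open:

* **"Within k bp" is inclusive**: |Δpos| ≤ k triggers the rule. The
  most permissive reading, stated once and tested at the boundary
  (positions 100/105 fail, 100/106 pass).
* **Distances use the VCF anchor position** for InDels, not the span
  end; no span convention is implied by the rules themselves.
* **Joint-predicate semantics**: all six rules are evaluated against
  the raw input set, not against survivors of earlier rules, so the
  result is independent of any rule ordering and each removal can be
  attributed to every rule it violates. A variant failing several
  rules is counted once per rule but removed once.
* **Depth bounds are per callset**: the high bound is mean + 3·SD of
  the raw depths, with the population SD (ddof = 0). Because the
  bounds are estimated from the input, re-running the cascade on its
  own output would re-estimate them from a truncated distribution;
  `apply_filters` therefore accepts explicit bounds, and idempotence
  holds (and is tested) when the raw callset's bounds are re-used.
  Conceptually the bounds are part of the predicate, fixed once per
  sample.

The implementation uses sorted-neighbour searches; the test suite
checks exact equivalence against an all-pairs brute-force oracle on a
thousand random 500-variant callsets, plus idempotence and
quality-threshold monotonicity properties.

## Consequence classification

Interval containment against a transcript model decides the
non-coding classes; a variant overlapping several transcripts takes
the most severe class under a fixed Ensembl-like order (stop gained >
stop lost > frameshift > splice donor/acceptor > missense > generic
coding > inframe > splice region > UTRs > synonymous > intron >
upstream > downstream > non-coding exon > intergenic). Conventions:

* Up/downstream are measured from transcript (not gene) boundaries,
  strand-aware, within 5 kb (configurable).
* Splice donor/acceptor are the first/last 2 intronic bases; the
  splice region extends 8 bp into the intron and 3 bp into the exon
  (configurable; the class vocabulary fixes no definitions, so
  Ensembl-style values are used).
* Coding SNPs are classified by codon comparison under the standard
  genetic code when reference sequence is available (dict of strings
  or a pyfaidx `Fasta`); without sequence they report a generic
  "coding sequence" class.
* InDels overlapping CDS are frameshift when |signed length| mod 3 ≠ 0,
  else inframe insertion/deletion. A deletion's affected bases follow
  the VCF anchor; an insertion counts as coding when its insertion
  point lies strictly inside a CDS block.
* A variant on a chromosome absent from the gene model is intergenic
  (with a warning at the I/O layer rather than a hard error).

Correctness is checked against a brute-force per-base annotation map
of a toy genome and against hand-built codon fixtures on both strands;
a mirror test verifies that reflecting a gene to the minus strand
leaves every positional classification unchanged.

## Callset summaries

Transitions are A↔G and C↔T; Ts/Tv errors out when no transversions
exist rather than returning infinity. The hom:het ratio is reported in
the 1:x convention with x = het/hom rounded half-up to one decimal;
percentages are likewise rounded half-up (novelty to two decimals,
sharing to one), matching how such tables are conventionally printed.
Novelty and cross-breed matching require identity of
(chrom, pos, ref, alt), not position alone — stricter and unambiguous.
"Shorter than 4 bp" for InDels means |signed length| ≤ 3.

## CNVR calling

Best-hit read starts of a test and a reference sample are counted in
half-overlapping windows (stride = length/2) tiling each chromosome;
the last window is clipped at the chromosome end and its null mean
scaled accordingly. The per-window signal is the total-normalized
ratio r = (x/y)·(N_ref/N_test); its log₂ is the copy-number estimate
(0 at the null center).

Under the null both counts are Poisson with means λ_t, λ_r
proportional to the genome-wide totals. The default p-value is the
**exact conditional mid-p test**: given n = x + y,
x ~ Binomial(n, θ₀) with θ₀ = λ_t/(λ_t + λ_r), and
p = 2·min(P(X ≤ x), P(X ≥ x)) − P(X = x), capped at 1. The mid-p
correction removes the conservativeness that discrete count atoms
cause in the far tail: at λ = 100 the realized rate of p < 0.001 under
the null is ≈ 0.0010 (measured at 10⁶ windows in the test suite),
where the plain Gaussian ratio approximation yields ≈ 0.0008. That
approximation — the Geary–Hinkley transformation
z = (λ_r·T − λ_t)/√(λ_t + T²·λ_r) with T = x/y and the null means as
parameters — is retained as `method="gh"` for comparison with
read-depth tools built on it. Windows with a zero count get 0.5 added
to both counts for the ratio (a symmetric continuity correction that
keeps the log₂ finite) and are flagged.

A CNVR is a maximal run of at least 10 consecutive windows that each
satisfy p ≤ 0.001 and |log₂ r| ≥ 0.7 with a common sign; runs never
cross chromosomes, the CNVR spans the first window start to the last
window end, and gains are reported relative to the test sample. The
window length can be given explicitly or derived: the smallest length
whose implied null means make a true ratio at the log₂ threshold
detectable at the p threshold (solved from the Gaussian ratio
statistic in both directions, taking the larger), times a multiplier
(default 5). The X chromosome is processed exactly like the autosomes,
with no ploidy correction — X calls should be read with that in mind.

## ROH detection

Autosomes are divided into non-overlapping 400-kb bins on a grid
anchored at coordinate 0; the final partial bin keeps its true length.
Only hom-alt genotypes are observable as homozygous in a single-sample
callset (hom-ref sites produce no VCF record), so the homozygosity
ratio is hom-alt/(hom-alt + het) over the genotyped records per bin. A
variant whose 0-based coordinate falls exactly on a grid boundary
belongs to the right-hand bin. A bin qualifies when its ratio is
≥ 0.95 **and** it contains at least 20 informative genotypes (default,
configurable): a variant-free bin is evidence-free, not evidence of
homozygosity. Maximal runs of adjacent qualifying bins merge into one
ROH, summarized in half-open size classes <1, 1–5, 5–10, 10–15 and
>15 Mb. Cross-breed ROH comparison operates on 400-kb grid
coordinates.

## Chip-vs-WGS concordance

Markers are matched to WGS records by (chrom, pos). At a matched site
the chip allele pair must equal {ref, alt} directly or — for markers
that are not A/T or C/G, where the flip is ambiguous — after
complementing; otherwise the marker is excluded. When the chip's A
allele is the alternative allele, calls are recoded so that A always
denotes the reference. A chip site with no WGS record (and no basis
for exclusion) counts in the WGS hom-ref column, since a single-sample
callset only records non-reference sites. Duplicated marker positions
keep the first occurrence with a warning.

Genotype concordance at variant sites divides the concordant
non-reference cells (chip A/B × WGS het plus chip B/B × WGS hom-alt)
by, by default, those plus the two discordant non-ref × non-ref cells
— i.e. chip non-reference sites at which WGS also made a
non-reference call. The stricter reading that divides by *all*
included chip non-reference genotypes is implemented as
`denominator="all-chip-nonref"`; the default is the reading that
reproduces the published percentages exactly from the published
contingency cells. Non-reference sensitivity is the literal fraction
of chip non-reference genotypes that WGS also classifies
non-reference. Reported percentages round half-up to one decimal.

## Synthetic data

One global seed feeds named per-generator streams
(`numpy.random.SeedSequence(seed, spawn_key=...)`), so each fixture
can be regenerated independently and identical seeds give
byte-identical outputs. What the generator emulates, and with which
defaults:

* **Callsets** — per-breed SNP/InDel sites split into an all-breeds
  shared pool (fraction 0.355) and breed-specific remainders; alleles
  drawn with transition probability r/(1+r) for target Ts/Tv r = 2.24;
  genotypes hom-alt with probability 1/(1+1.6) for the 1:1.6 hom:het
  target; site-level catalog membership at 1 − 0.5412 so the novel
  fraction matches 54.12%; depth ~ round(Normal(29.5, 5)) truncated at
  0 (the ~30× coverage regime); alt reads Binomial(depth, ½) for hets,
  all reads for hom-alts, split Binomial(·, ½) across strands; quality
  a mixture putting 5% of variants below the Phred-20 filter line
  (uniform 5–20) and the rest uniform 20–60.
* **InDels** — sign insertion with probability 0.466 (the observed
  deletion excess), magnitude geometric with p = 0.383 (chosen so
  ~76.5% of InDels are shorter than 4 bp), truncated at +31/−49; 3n
  lengths get a ×4 weight boost inside CDS, qualitatively reproducing
  the coding 3n enrichment.
* **Depth tracks** — reference windows Poisson(λ), test windows
  Poisson(λ·ratio) inside truth segments (pro-rated by window
  overlap); the default read-start density 0.3/bp corresponds to ~30×
  coverage of 90-bp reads, i.e. λ = 3000 per 10-kb window. The default
  truth segment is a single copy-ratio-2 gain spanning 300
  half-overlapping windows.
* **Autozygous genomes** — genotyped positions uniform at 1/2 kb;
  heterozygote fraction 0.615 outside (consistent with 1:1.6) and 0.01
  inside the truth segments; defaults embed three grid-aligned
  segments of 0.8, 4 and 12 Mb.
* **Chip panels** — 50,000 markers, half at callset SNP sites
  (mirroring the WGS genotype) and half homozygous-reference; a fixed
  round(1% of panel) of markers made allele-incompatible; no-calls at
  0.3% and genotyping errors at 0.2% to a uniformly chosen other call.

What it does **not** emulate: linkage disequilibrium, pedigree
structure, mapping artifacts, GC or repeat-driven depth bias,
multi-nucleotide or overlapping variants, and sequence-context error
profiles. Passing the recovery suites therefore demonstrates that the
statistics and calling logic are implemented correctly under their own
stated models, not that the pipeline is robust to real-data artifacts.

## Problem sizes

The test and acceptance runs use a 52-Mb five-chromosome toy genome:
callsets of 10⁵ SNPs per breed (binomial error on Ts/Tv ≈ 0.015, well
inside the ±0.05 check), 10⁶ windows for null calibration of the
window test (3·SE band ±9.5·10⁻⁵ around 0.001), a 300-window embedded
CNV, three autozygous segments over 42 bins, and 5·10⁴-marker chip
panels (error-rate recovery to ±0.1 percentage points). These sizes
were chosen so every Monte-Carlo band quoted above is meaningfully
tight while the whole suite stays interactive.

## Known limitations

Severity resolution implements a fixed order; initiator-codon,
stop-retained and mature-miRNA classes are not distinguished and fall
to the nearest implemented class. The concordance module resolves
strand flips only for unambiguous markers and discards A/T–C/G flip
candidates. ROH detection is ratio-threshold based (no HMM, no LD
pruning, no inbreeding-coefficient estimation), CNVR calling has no
breakpoint refinement or within-sample segmentation, and the CNVR
direction convention (gain in test) must be kept in mind when the
deeper-sequenced sample is used as reference.
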