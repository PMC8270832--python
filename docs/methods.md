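# Methods

## The problem setting

In a diploid with per-site heterozygosity of several percent, a short-read
assembler cannot collapse the two haplotypes: the alleles of a single-copy
gene assemble as two separate contigs, k-mer spectra become bimodal (a
heterozygous peak at the per-haplotype coverage and a homozygous peak at
twice that), and any diversity statistic computed between "contigs" is
really a statistic between alleles. This package implements that whole
chain — simulation with known truth, k-mer genome sizing, split-allele
recovery, and the diversity statistics — so each step can be validated
against planted ground truth.

## Diversity statistics

**π** between two codon-aligned alleles is the uncorrected p-distance:
mismatches over sites comparable in both sequences. No multiple-hit
correction is applied to π; at the few-percent divergences in scope the
p-distance is the natural "fraction of heterozygous sites" reading, and
the Jukes–Cantor correction enters only inside the dN/dS distances.

**π4D** restricts π to fourfold-degenerate third codon positions. The
default rule is strict: a position counts only when *both* codons lie in a
fourfold family (32 of 64 codons: Leu-CTN, Val, Ser-TCN, Pro, Thr, Ala,
Arg-CGN, Gly) *and* agree at codon positions 1–2, so that any third-
position base leaves both amino acids unchanged and the site's degeneracy
is unambiguous. A lax variant (`strict=False`) drops the context
requirement. Pairs with no fourfold site report π4D as undefined rather
than zero.

**Nei–Gojobori (1986) dN/dS.** Per codon, the synonymous site count is the
sum over positions of (synonymous single-base changes)/3, with changes to
stop codons counted as nonsynonymous, so S + N = 3 × codons exactly; site
counts are averaged over the two sequences. Differences in codons that
differ at d positions are averaged with equal weight over the d! orderings
of the changes; orderings passing through a stop codon are excluded (if
all are, the exclusion is waived for that codon). Proportions pS = Sd/S and
pN = Nd/N are corrected by d = −(3/4)·ln(1 − (4/3)p), which is undefined at
p ≥ 3/4 and raises an explicit error there; ω = dN/dS is undefined when
dS = 0 and is reported at two significant figures in summaries. The
implementation agrees with Biopython's independent NG86 code to < 1e-9
and with an exhaustive pathway oracle on small alignments (both checked in
the test suite).

**Population statistics.** A column is valid when every sequence has an
unambiguous A/C/G/T; a valid column with ≥ 2 distinct bases is
segregating (multi-allelic columns count once toward S). θ_W = S/a₁ with
a₁ = Σ_{i<n} 1/i; k̄ is the mean pairwise difference count over all
n(n−1)/2 pairs (complete deletion by default; a pairwise-deletion flag and
per-sequence weights — e.g. 1/clones per individual — are available), and
Tajima's D uses the full 1989 constants with D undefined at S = 0.

## k-mer machinery

Canonical k-mers (lexicographic minimum of k-mer and reverse complement,
k ≤ 31) are packed into 64-bit integers by a Horner scheme over the
concatenated reads; windows containing non-ACGT characters are masked via
a cumulative invalid-count. Counting is exact (validated against a
string-hash brute force) and in-memory, sized for desk-scale read sets
(≲ 10⁷ reads).

Peak detection densifies the histogram, mirrors the (non-existent)
multiplicity-0 bin from m = 1 — without this the moving-average smoothing
(centered, window 3) carves a spurious maximum at m = 2 on decaying error
components — and takes the first local minimum after m = 1 as the error
trough. The tallest mode above the trough is primary; a secondary mode at
1.6–2.4× its coverage identifies (c_het, c_hom), one at the reciprocal
position identifies a taller homozygous peak, and an isolated peak is
reported as homozygous. Ties break toward lower multiplicity; secondary
modes below 2% of the primary height are ignored as noise.

Genome size is n·(L−k+1)/C with L the average read length of the input.
`coverage` in the read simulator is per-haplotype depth, so the homozygous
peak sits near 2×coverage×(L−k+1)/L and division by it yields the haploid
size; the heterozygous peak yields the diploid (2n) size. The repeat
fraction is the share of k-mer *occurrences* (multiplicity-weighted;
distinct-k-mer weighting behind a flag) above a multiplicity threshold,
with k-mers below the error trough excluded from the denominator by
default so sequencing errors do not dilute the estimate.

## Split-allele discovery

Conserved proteins are aligned to contigs in all six reading frames with
BLOSUM62 and affine gaps (open 11, extend 1) — the field's default
scoring, configurable. Scores are normalized by the protein self-score so
a full-length exact match is 1.0 independent of length or composition,
and hits require norm ≥ 0.50 on a single contig (no chaining across
contigs). Proteins shorter than 300 aa are excluded before alignment
(configurable; the synthetic recovery tests use 150 aa because their
planted CDS lengths are exponential around the configured mean and a 300
aa floor would discard most of them). A cheap shared-5-mer prescreen skips
the dynamic programming for unrelated frames.

Frameshift detection: when a second frame on the same strand aligns a
largely disjoint stretch of the protein (secondary score ≥ 10% of self,
protein-interval overlap ≤ 30%, coverage gain ≥ 15% of the protein), the
contig's CDS is interrupted by an indel of length not divisible by three;
the hit is flagged, carries the combined score, and any pair containing a
flagged hit is excluded from diversity statistics.

Classification: zero/one/two/many qualifying hits; with more than two, the
top two are accepted as a pair only when they outscore the third by ≥ 0.02
norm-score, otherwise the protein is conservatively labelled multi-hit.
Pair CDS extraction takes the in-frame nucleotide region under each
alignment, aligns the two translations globally and back-maps gaps to
whole codons, rejecting pairs below 50% nucleotide identity as
non-allelic. No intron modelling is attempted: contigs are assumed to
carry the CDS contiguously (single-exon or pre-spliced), a documented
limitation of the translated aligner.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes and
nothing more. Haplotype A is uniform random sequence with planted repeat
copies and gene models (exon/intron lengths exponential above a floor so
the configured means — defaults 202 bp exons, 706 bp introns — are exact
distribution means; genes are placed outside repeat tracts). Haplotype B
differs by independent per-site substitutions: a uniform rate outside CDS,
and inside CDS a codon-aware model with separate synonymous and
nonsynonymous per-site rates (both default to the genome-wide rate;
a per-gene uniform range such as 2–11% is available). Defaults mirror the
study conditions: ~5% genome-wide heterozygosity, 5.5% mean coding-pair
diversity with 20.1% on synonymous sites, a 3.6% population sample of
24 × 1473 bp, ~100 bp reads.

Coding substitutions are applied position by position, sequentially: the
substitution probability at a position is syn_rate·f + nonsyn_rate·(1−f)
with f the NG86 synonymous fraction of the *current* codon, the class is
drawn in proportion to its contribution, and changes creating stop codons
are rejected within their class (a site whose class has no viable
alternative stays unchanged; start codons are conserved). Sequential
classification guarantees that a purely synonymous history never changes
the amino acid — so nonsyn_rate = 0 yields pairs with zero amino-acid
mismatches but substantial π, the "silent divergence" regime. NG86 can
still assign small fractional nonsynonymous counts to multi-hit codons
whose alternative substitution orderings pass through other amino acids;
this is a property of the estimator, present on real data too. For
planting an exact dN/dS truth, `expected_ng86_omega` computes the
generator's NG86-expected ω analytically (exact enumeration of the
per-codon outcome distribution) and `calibrate_nonsyn_rate` inverts it by
bisection; the residual bias of the *mean of per-pair ratios* is ≈ +1%
(Jensen's inequality on the dS denominator).

The population sampler draws each site independently: a site segregates
with probability p, and the derived-allele count i is drawn ∝ 1/i under
the neutral spectrum (expected heterozygosity per segregating site is then
exactly 1/a₁, so p = π_target·a₁) or fixed at 1 under the all-singleton
spectrum (p = π_target·n/2). Targets above the reachable maximum raise an
error. This is a site-independence model, not a coalescent: it reproduces
the expected SFS and pairwise diversity but no linkage disequilibrium or
genealogical variance in D, which is what makes the neutral-D calibration
tight.

The fragmenter cuts each haplotype at uniform random breakpoints with
1 + Poisson(L/mean_len − 1) fragments, giving exponential-like lengths
with mean `mean_len` and, deterministically, one contig per haplotype when
mean_len ≥ L.

Mutations are substitutions only; no recombination, no realistic error
profiles, no indel-rich non-coding simulation. Consequently, passing tests
demonstrate correctness of the estimators under the stated generative
model, not robustness to assembly artifacts, alignment error or linked
selection in real data.

## Problem sizes and numerical choices

Simulated genomes in tests and drivers are 40–200 kb at 30× coverage —
large enough that k-mer peaks are well separated (relative error of the
genome-size recovery < 5%) while a full test run stays in minutes. Allele
pair cohorts use 66 pairs of 500 codons; population calibrations use 200
replicates. Recovery tests assert agreement within 3 standard errors of
the replicate mean; deterministic identities (site counts, oracle
equality) are asserted exactly. Coordinates are 0-based half-open
internally, GFF3 output is 1-based inclusive; every operation takes one
explicit integer seed and touches no global random state.

## Known limitations

* The translated aligner has no spliced-alignment mode; multi-exon genes
  in fragmented assemblies are out of its reach by design.
* π4D's strict site definition makes per-pair fourfold-site counts vary
  slightly between pairs; this matches the per-site reading of the
  statistic but differs from fixed-site-list conventions.
* The "manual inspection" step of real studies is approximated by the
  frameshift flag plus a nucleotide-identity floor; no other artifact
  classes are detected.
* Repeat-fraction estimates depend on the chosen multiplicity threshold;
  the package reports the estimate for a stated threshold rather than
  asserting a universal one.
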