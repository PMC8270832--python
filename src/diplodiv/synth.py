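"""Seeded generator of hyperdiverse diploid genomes with known truth.

Emulates the statistical structure of a highly heterozygous marine
invertebrate genome: a diploid with per-site heterozygosity up to ~10% in
coding regions and ~20% at fourfold-degenerate sites, high-copy repeat
families, intron/exon gene structure, short (~100 bp) reads, allelic CDS
pairs with controllable synonymous/nonsynonymous substitution rates, a
neutral-SFS population sampler, and a fragmenter that mimics a diploid
assembly in which the two alleles of a gene land on separate contigs.

Mutations are substitutions only; proposed coding changes that would create
a stop codon are rejected and resampled within their class. All generators
take one explicit integer seed and are bit-reproducible; no global random
state is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .divstats import AllelePairAlignment
from .genetics import (
    BASES,
    CODON_TO_AA,
    SENSE_CODONS,
    STOP_CODONS,
    reverse_complement,
    synonymous_fraction,
    translate_codon,
)
from .popstats import PopAlignment

_BASE_ARR = np.frombuffer(b"ACGT", dtype="S1")


class SizingError(ValueError):
    """Requested genes/repeats cannot be placed in a genome of this size."""


@dataclass
class GeneModel:
    """One protein-coding gene: strand plus ordered exon intervals.

    Exon intervals are 0-based half-open genome coordinates, sorted and
    non-overlapping; the spliced sequence is a valid CDS (starts ATG, total
    length divisible by 3, no internal stop).
    """

    gene_id: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not self.exons:
            raise ValueError("gene needs at least one exon")
        prev_end = -1
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty exon ({s}, {e})")
            if s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e
        if self.cds_length % 3:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def cds_positions(self) -> list[int]:
        """Genome positions of the CDS, in translation order (5'->3')."""
        pos = [i for s, e in self.exons for i in range(s, e)]
        return pos[::-1] if self.strand == "-" else pos

    def spliced(self, genome: str) -> str:
        """The CDS sequence read from ``genome`` respecting strand."""
        seq = "".join(genome[s:e] for s, e in self.exons)
        return reverse_complement(seq) if self.strand == "-" else seq

    def intron_lengths(self) -> list[int]:
        return [self.exons[i + 1][0] - self.exons[i][1] for i in range(len(self.exons) - 1)]


@dataclass
class RepeatFamily:
    family_id: str
    unit: str
    positions: list[int]

    @property
    def copy_number(self) -> int:
        return len(self.positions)


@dataclass
class DiploidTruth:
    """Two simulated haplotypes plus the complete generating truth."""

    haplotype_a: str
    haplotype_b: str
    variants: list[tuple[int, str, str]]
    genes: list[GeneModel]
    repeats: list[RepeatFamily]
    seed: int

    def __post_init__(self) -> None:
        if len(self.haplotype_a) != len(self.haplotype_b):
            raise ValueError("haplotypes differ in length")
        for g in self.genes:
            if g.span[1] > len(self.haplotype_a):
                raise ValueError(f"{g.gene_id}: exon beyond sequence bounds")

    @property
    def size(self) -> int:
        return len(self.haplotype_a)

    def variant_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.variants, columns=["position", "allele_a", "allele_b"])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASE_ARR[rng.integers(0, 4, n)].tobytes().decode()


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG followed by random sense (non-stop) codons."""
    if n_codons < 2:
        raise ValueError("need at least 2 codons")
    idx = rng.integers(0, len(SENSE_CODONS), n_codons - 1)
    return "ATG" + "".join(SENSE_CODONS[i] for i in idx)


def _mutate_codon(
    codon: str, syn_rate: float, nonsyn_rate: float, rng: np.random.Generator
) -> str:
    """Substitute positions of one codon at class-specific per-site rates.

    Positions are visited in order and substitutions applied sequentially:
    at each position the substitution probability is
    ``syn_rate * f_syn + nonsyn_rate * (1 - f_syn)`` where f_syn is the
    NG86 synonymous fraction of that position in the current codon, the
    class of the change is drawn in proportion to its contribution, and the
    change is classified against the current codon. A purely synonymous
    history therefore never alters the amino acid, even when several
    positions of one codon mutate. Alternatives creating a stop codon are
    rejected; if a class has no viable alternative the site is left
    unchanged.
    """
    current = codon
    for pos in range(3):
        f_syn = synonymous_fraction(current, pos)
        p = syn_rate * f_syn + nonsyn_rate * (1.0 - f_syn)
        if p <= 0 or rng.random() >= p:
            continue
        want_syn = rng.random() < (syn_rate * f_syn) / p
        aa = translate_codon(current)
        syn_alts, nonsyn_alts = [], []
        for b in BASES:
            if b == current[pos]:
                continue
            alt = current[:pos] + b + current[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            (syn_alts if translate_codon(alt) == aa else nonsyn_alts).append(b)
        alts = syn_alts if want_syn else nonsyn_alts
        if alts:
            b = alts[int(rng.integers(0, len(alts)))]
            current = current[:pos] + b + current[pos + 1 :]
    return current


def mutate_cds(
    cds: str,
    syn_rate: float,
    nonsyn_rate: float,
    rng: np.random.Generator,
    protect_start: bool = True,
) -> str:
    """Codon-aware mutation of a CDS; start codon conserved by default."""
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if protect_start and i == 0:
            out.append(codon)
        else:
            out.append(_mutate_codon(codon, syn_rate, nonsyn_rate, rng))
    return "".join(out)


def _codon_outcome_distribution(
    codon: str, syn_rate: float, nonsyn_rate: float
) -> dict[str, float]:
    """Exact distribution of _mutate_codon outcomes for one starting codon."""
    dist = {codon: 1.0}
    for pos in range(3):
        new: dict[str, float] = {}
        for cur, pr in dist.items():
            f_syn = synonymous_fraction(cur, pos)
            p = syn_rate * f_syn + nonsyn_rate * (1.0 - f_syn)
            aa = translate_codon(cur)
            syn_alts, nonsyn_alts = [], []
            for b in BASES:
                if b == cur[pos]:
                    continue
                alt = cur[:pos] + b + cur[pos + 1 :]
                if alt in STOP_CODONS:
                    continue
                (syn_alts if translate_codon(alt) == aa else nonsyn_alts).append(alt)
            p_syn = syn_rate * f_syn if syn_alts else 0.0
            p_non = nonsyn_rate * (1.0 - f_syn) if nonsyn_alts else 0.0
            stay = 1.0 - p_syn - p_non
            new[cur] = new.get(cur, 0.0) + pr * stay
            for alt in syn_alts:
                new[alt] = new.get(alt, 0.0) + pr * p_syn / len(syn_alts)
            for alt in nonsyn_alts:
                new[alt] = new.get(alt, 0.0) + pr * p_non / len(nonsyn_alts)
        dist = new
    return dist


def expected_ng86_omega(
    syn_rate: float, nonsyn_rate: float, n_codons: int = 500
) -> float:
    """Exact NG86-expected dN/dS of pairs from :func:`simulate_coding_pair`.

    Enumerates, for every starting codon, the exact outcome distribution of
    the codon mutation process and accumulates the expected NG86 site and
    pathway-difference counts (so multi-hit codons whose alternative
    substitution orderings pass through other amino acids are accounted
    for). The conserved ATG start codon enters the site counts with weight
    1/n_codons.
    """
    from .divstats import _pathway_counts, jukes_cantor
    from .genetics import codon_site_counts

    E_S = E_N = E_Sd = E_Nd = 0.0
    weights = {c: (1.0 - 1.0 / n_codons) / len(SENSE_CODONS) for c in SENSE_CODONS}
    weights["ATG"] = weights.get("ATG", 0.0) + 1.0 / n_codons  # protected start
    for codon, w in weights.items():
        dist = _codon_outcome_distribution(codon, syn_rate, nonsyn_rate)
        if codon == "ATG":
            # the start codon itself never mutates; other ATGs do
            w_start = 1.0 / n_codons
            w_free = w - w_start
            parts = [(w_start, {codon: 1.0}), (w_free, dist)]
        else:
            parts = [(w, dist)]
        sa, na = codon_site_counts(codon)
        for wt, d in parts:
            for out, pr in d.items():
                sb, nb = codon_site_counts(out)
                E_S += wt * pr * (sa + sb) / 2.0
                E_N += wt * pr * (na + nb) / 2.0
                sd, nd = _pathway_counts(codon, out)
                E_Sd += wt * pr * sd
                E_Nd += wt * pr * nd
    return jukes_cantor(E_Nd / E_N) / jukes_cantor(E_Sd / E_S)


def calibrate_nonsyn_rate(
    target_omega: float, syn_rate: float, n_codons: int = 500
) -> float:
    """Nonsynonymous rate whose exact NG86-expected omega equals the target.

    Solved by bisection on :func:`expected_ng86_omega`; this is the inverse
    map a study design needs when planting a known dN/dS truth.
    """
    lo, hi = 0.0, 0.5
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if expected_ng86_omega(syn_rate, mid, n_codons) < target_omega:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def simulate_coding_pair(
    n_codons: int,
    syn_rate: float,
    nonsyn_rate: float,
    seed: int,
    gene_id: str = "pair",
) -> AllelePairAlignment:
    """Allelic CDS pair with controlled synonymous/nonsynonymous divergence.

    ``syn_rate`` and ``nonsyn_rate`` are per-synonymous-site and
    per-nonsynonymous-site substitution probabilities (p-distance scale):
    the expected NG86 proportions pS and pN of the resulting pair equal the
    requested rates, and the expected overall p-distance is their
    site-weighted average.
    """
    if n_codons < 10:
        raise ValueError("need at least 10 codons")
    for name, r in (("syn_rate", syn_rate), ("nonsyn_rate", nonsyn_rate)):
        if not 0.0 <= r <= 0.5:
            raise ValueError(f"{name} must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    seq_a = random_cds(rng, n_codons)
    seq_b = mutate_cds(seq_a, syn_rate, nonsyn_rate, rng)
    return AllelePairAlignment(gene_id=gene_id, seq_a=seq_a, seq_b=seq_b)


def _place_intervals(
    rng: np.random.Generator,
    size: int,
    lengths: list[int],
    occupied: list[tuple[int, int]],
    gap: int = 10,
    max_tries: int = 200,
) -> list[int]:
    """Random non-overlapping placement of intervals; SizingError on failure."""
    starts = []
    occ = list(occupied)
    for L in lengths:
        if L + 2 * gap >= size:
            raise SizingError(f"interval of {L} bp does not fit in {size} bp")
        for attempt in range(max_tries):
            s = int(rng.integers(gap, size - L - gap))
            if all(s + L + gap <= os or s >= oe + gap for os, oe in occ):
                starts.append(s)
                occ.append((s, s + L))
                break
        else:
            raise SizingError(
                f"could not place {len(lengths)} intervals of ~{L} bp in {size} bp"
            )
    return starts


def _draw_gene_structure(
    rng: np.random.Generator,
    exon_bp_mean: float,
    intron_bp_mean: float,
    exons_per_gene: tuple[int, int],
) -> tuple[list[int], list[int]]:
    """(exon lengths, intron lengths); exponential above a floor, so the
    configured means are the distribution means."""
    n_exons = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
    min_exon, min_intron = 30, 60
    exons = [
        max(min_exon, int(round(min_exon + rng.exponential(exon_bp_mean - min_exon))))
        for _ in range(n_exons)
    ]
    # trim the last exon so the CDS is a whole number of codons (>= 2)
    total = sum(exons)
    exons[-1] -= total % 3
    if sum(exons) < 6:
        exons[-1] += 6
    introns = [
        max(min_intron, int(round(min_intron + rng.exponential(intron_bp_mean - min_intron))))
        for _ in range(n_exons - 1)
    ]
    return exons, introns


def simulate_diploid_genome(
    size: int,
    het_rate: float,
    n_genes: int = 0,
    repeat_spec: tuple[int, int, int] | None = None,
    seed: int = 0,
    *,
    gene_het_range: tuple[float, float] | None = None,
    coding_syn_rate: float | None = None,
    coding_nonsyn_rate: float | None = None,
    exon_bp_mean: float = 202.0,
    intron_bp_mean: float = 706.0,
    exons_per_gene: tuple[int, int] = (1, 1),
    strands: str = "+-",
) -> DiploidTruth:
    """Simulate a diploid genome with planted repeats, genes and SNVs.

    Haplotype A is a uniform random sequence with ``repeat_spec =
    (n_families, unit_len, copy_number)`` repeat copies and ``n_genes``
    protein-coding genes (placed outside repeat tracts) written into it.
    Haplotype B carries independent per-site substitutions: outside coding
    regions at ``het_rate`` per site; inside CDS via the codon-aware model
    at (``coding_syn_rate``, ``coding_nonsyn_rate``), both defaulting to
    ``het_rate`` so the genome-wide mismatch fraction matches ``het_rate``.
    ``gene_het_range`` instead draws one uniform rate per gene (used for
    both classes), emulating the observed 2-11% per-gene spread.
    """
    if size < 1000:
        raise ValueError("size must be >= 1000 bp")
    if not 0.0 <= het_rate <= 0.25:
        raise ValueError("het_rate must be in [0, 0.25]")
    rng = np.random.default_rng(seed)
    hap_a = np.frombuffer(_random_seq(rng, size).encode(), dtype="S1").copy()

    occupied: list[tuple[int, int]] = []
    repeats: list[RepeatFamily] = []
    if repeat_spec is not None:
        n_fam, unit_len, copy_number = repeat_spec
        for f in range(n_fam):
            unit = _random_seq(rng, unit_len)
            starts = _place_intervals(rng, size, [unit_len] * copy_number, occupied)
            for s in starts:
                hap_a[s : s + unit_len] = np.frombuffer(unit.encode(), dtype="S1")
                occupied.append((s, s + unit_len))
            repeats.append(RepeatFamily(f"rep{f}", unit, sorted(starts)))

    genes: list[GeneModel] = []
    for g in range(n_genes):
        exon_lens, intron_lens = _draw_gene_structure(
            rng, exon_bp_mean, intron_bp_mean, exons_per_gene
        )
        span = sum(exon_lens) + sum(intron_lens)
        start = _place_intervals(rng, size, [span], occupied)[0]
        occupied.append((start, start + span))
        exons = []
        pos = start
        for i, L in enumerate(exon_lens):
            exons.append((pos, pos + L))
            pos += L + (intron_lens[i] if i < len(intron_lens) else 0)
        strand = strands[int(rng.integers(0, len(strands)))]
        gene = GeneModel(f"gene{g}", strand, exons)
        cds = random_cds(rng, gene.cds_length // 3)
        write = reverse_complement(cds) if strand == "-" else cds
        arr = np.frombuffer(write.encode(), dtype="S1")
        off = 0
        for s, e in exons:
            hap_a[s:e] = arr[off : off + (e - s)]
            off += e - s
        genes.append(gene)

    genome_a = hap_a.tobytes().decode()
    hap_b = hap_a.copy()

    # non-coding substitutions, uniform at het_rate
    coding_mask = np.zeros(size, dtype=bool)
    for gene in genes:
        for s, e in gene.exons:
            coding_mask[s:e] = True
    if het_rate > 0:
        hit = (rng.random(size) < het_rate) & ~coding_mask
        idx = np.flatnonzero(hit)
        shift = rng.integers(1, 4, idx.size)
        codes = np.searchsorted(_BASE_ARR, hap_a[idx])
        hap_b[idx] = _BASE_ARR[(codes + shift) % 4]

    # coding substitutions, codon-aware per gene
    for gene in genes:
        if gene_het_range is not None:
            r = float(rng.uniform(*gene_het_range))
            syn, nonsyn = r, r
        else:
            syn = het_rate if coding_syn_rate is None else coding_syn_rate
            nonsyn = het_rate if coding_nonsyn_rate is None else coding_nonsyn_rate
        cds_a = gene.spliced(genome_a)
        cds_b = mutate_cds(cds_a, syn, nonsyn, rng)
        if gene.strand == "-":
            cds_b = reverse_complement(cds_b)
        arr = np.frombuffer(cds_b.encode(), dtype="S1")
        off = 0
        for s, e in gene.exons:
            hap_b[s:e] = arr[off : off + (e - s)]
            off += e - s

    genome_b = hap_b.tobytes().decode()
    variants = [
        (int(i), genome_a[i], genome_b[i])
        for i in np.flatnonzero(hap_a != hap_b)
    ]
    return DiploidTruth(genome_a, genome_b, variants, genes, repeats, seed)


@dataclass
class SimRead:
    name: str
    seq: str
    qual: str


def simulate_reads(
    truth: DiploidTruth,
    coverage: float,
    read_len: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[SimRead]:
    """Uniform single-end reads drawn equally from both haplotypes.

    ``coverage`` is per-haplotype depth: ceil(coverage * L / read_len)
    reads are drawn from each haplotype (so homozygous k-mers appear at
    about twice the per-haplotype read depth), with random strand and
    optional uniform substitution errors.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    L = truth.size
    if read_len > L:
        raise ValueError("read_len exceeds haplotype length")
    rng = np.random.default_rng(seed)
    n_per_hap = max(1, math.ceil(coverage * L / read_len))
    q = 40 if error_rate <= 0 else max(2, min(40, round(-10 * math.log10(error_rate))))
    qual = chr(33 + q) * read_len
    reads: list[SimRead] = []
    for hap_name, hap in (("A", truth.haplotype_a), ("B", truth.haplotype_b)):
        starts = rng.integers(0, L - read_len + 1, n_per_hap)
        rev = rng.integers(0, 2, n_per_hap).astype(bool)
        for i, (s, r) in enumerate(zip(starts, rev)):
            seq = hap[s : s + read_len]
            if r:
                seq = reverse_complement(seq)
            if error_rate > 0:
                arr = np.frombuffer(seq.encode(), dtype="S1").copy()
                hit = np.flatnonzero(rng.random(read_len) < error_rate)
                if hit.size:
                    codes = np.searchsorted(_BASE_ARR, arr[hit])
                    arr[hit] = _BASE_ARR[(codes + rng.integers(1, 4, hit.size)) % 4]
                    seq = arr.tobytes().decode()
            strand = "-" if r else "+"
            reads.append(SimRead(f"hap{hap_name}_{i}_{int(s)}_{strand}", seq, qual))
    return reads


def write_fastq(reads: list[SimRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{r.qual}\n")


def simulate_population_alignment(
    n_seqs: int,
    length: int,
    target_pi: float,
    sfs_model: str = "neutral",
    seed: int = 0,
) -> PopAlignment:
    """Population sample with independent sites and a chosen frequency spectrum.

    Each site segregates with probability p_seg; at a segregating site the
    derived-allele count i is drawn proportional to 1/i (``"neutral"``, the
    standard neutral site-frequency spectrum) or fixed at 1
    (``"singletons"``). The expected per-site pairwise diversity is exactly
    ``target_pi``: under the neutral SFS the expected heterozygosity of a
    segregating site is 1/a1, so p_seg = target_pi * a1; under singletons
    it is 2/n, so p_seg = target_pi * n / 2.
    """
    if n_seqs < 2:
        raise ValueError("need n_seqs >= 2")
    if not 0.0 <= target_pi <= 0.5:
        raise ValueError("target_pi must be in [0, 0.5]")
    a1 = float(sum(1.0 / i for i in range(1, n_seqs)))
    if sfs_model == "neutral":
        p_seg = target_pi * a1
        sfs_w = np.array([1.0 / i for i in range(1, n_seqs)])
        sfs_w /= sfs_w.sum()
    elif sfs_model == "singletons":
        p_seg = target_pi * n_seqs / 2.0
        sfs_w = None
    else:
        raise ValueError(f"unknown sfs_model {sfs_model!r}")
    if p_seg > 1.0:
        raise ValueError(
            f"target_pi={target_pi} unreachable with n_seqs={n_seqs} "
            f"(required per-site segregation probability {p_seg:.3f} > 1)"
        )
    rng = np.random.default_rng(seed)
    anc = rng.integers(0, 4, length)
    mat = np.tile(anc, (n_seqs, 1))
    seg_sites = np.flatnonzero(rng.random(length) < p_seg)
    for site in seg_sites:
        if sfs_w is None:
            i = 1
        else:
            i = 1 + int(rng.choice(len(sfs_w), p=sfs_w))
        carriers = rng.choice(n_seqs, size=i, replace=False)
        derived = (anc[site] + int(rng.integers(1, 4))) % 4
        mat[carriers, site] = derived
    seqs = [_BASE_ARR[row].tobytes().decode() for row in mat]
    return PopAlignment(seqs)


def fragment_assembly(
    truth: DiploidTruth, mean_len: float, seed: int = 0
) -> tuple[dict[str, str], pd.DataFrame]:
    """Fragment both haplotypes independently into assembly-like contigs.

    Each haplotype is cut at uniform random breakpoints; the number of
    fragments is 1 + Poisson(L/mean_len - 1), so fragment lengths average
    ``mean_len`` (with exponential-like spacing) and a mean_len >= genome
    size yields exactly one contig per haplotype. Returns the contigs and a
    truth table mapping contig_id -> (haplotype, start, end); concatenating
    a haplotype's fragments in order restores the haplotype.
    """
    if mean_len < 500:
        raise ValueError("mean_len must be >= 500")
    rng = np.random.default_rng(seed)
    L = truth.size
    contigs: dict[str, str] = {}
    rows = []
    for hap_name, hap in (("A", truth.haplotype_a), ("B", truth.haplotype_b)):
        lam = max(0.0, L / mean_len - 1.0)
        n_frag = 1 + int(rng.poisson(lam))
        cuts = sorted(set(rng.integers(1, L, n_frag - 1).tolist())) if n_frag > 1 else []
        bounds = [0, *cuts, L]
        for i in range(len(bounds) - 1):
            s, e = bounds[i], bounds[i + 1]
            cid = f"hap{hap_name}_ctg{i}"
            contigs[cid] = hap[s:e]
            rows.append({"contig_id": cid, "haplotype": hap_name, "start": s, "end": e})
    return contigs, pd.DataFrame(rows)
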