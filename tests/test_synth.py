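"""Synthetic diploid generator: truth consistency, rate recovery, determinism."""

import math

import numpy as np
import pytest

from diplodiv import divstats, synth
from diplodiv.genetics import reverse_complement, translate_cds


# ------------------------------------------------------------- diploid genome
def test_zero_heterozygosity_gives_identical_haplotypes():
    truth = synth.simulate_diploid_genome(2000, 0.0, seed=1)
    assert truth.haplotype_a == truth.haplotype_b
    assert truth.variants == []


def test_mismatch_fraction_matches_het_rate_within_binomial_bound():
    size, het = 100_000, 0.05
    truth = synth.simulate_diploid_genome(size, het, seed=1)
    mism = sum(a != b for a, b in zip(truth.haplotype_a, truth.haplotype_b))
    sd = math.sqrt(het * (1 - het) * size)
    assert abs(mism - het * size) < 3 * sd
    # the variant table is exactly the set of differing positions
    assert len(truth.variants) == mism
    for pos, a, b in truth.variants[:50]:
        assert truth.haplotype_a[pos] == a != b == truth.haplotype_b[pos]


def test_planted_repeats_are_retrievable():
    truth = synth.simulate_diploid_genome(
        80_000, 0.0, repeat_spec=(1, 300, 100), seed=4
    )
    (fam,) = truth.repeats
    assert fam.copy_number == 100
    for pos in fam.positions:
        assert truth.haplotype_a[pos : pos + 300] == fam.unit


def test_genes_valid_and_outside_repeats():
    truth = synth.simulate_diploid_genome(
        60_000, 0.05, n_genes=5, repeat_spec=(1, 300, 20), seed=8,
        exons_per_gene=(1, 3),
    )
    repeat_ivs = [(p, p + 300) for fam in truth.repeats for p in fam.positions]
    for g in truth.genes:
        cds = g.spliced(truth.haplotype_a)
        assert cds.startswith("ATG")
        aa = translate_cds(cds)
        assert "*" not in aa[:-1]
        s, e = g.span
        assert all(e <= rs or s >= re for rs, re in repeat_ivs)
    # haplotype B CDS also remains a valid open reading frame
    for g in truth.genes:
        aa_b = translate_cds(g.spliced(truth.haplotype_b))
        assert "*" not in aa_b[:-1]


def test_sizing_error_when_genome_too_small():
    with pytest.raises(synth.SizingError):
        synth.simulate_diploid_genome(1000, 0.0, repeat_spec=(1, 400, 10), seed=0)


# ------------------------------------------------------------- coding pairs
def test_zero_rates_give_identical_pair():
    pair = synth.simulate_coding_pair(50, 0.0, 0.0, seed=3)
    assert pair.seq_a == pair.seq_b


def test_nonsynonymous_rate_zero_means_dn_zero():
    for seed in range(5):
        pair = synth.simulate_coding_pair(200, 0.2, 0.0, seed=seed)
        ng = divstats.nei_gojobori(pair)
        assert ng.dN == 0.0
        assert divstats.aa_mismatches(pair) == 0


def test_ds_estimate_recovers_generating_rate():
    """NG86 pS over many replicate pairs averages to the generating
    synonymous per-site rate (dS averages to its JC correction)."""
    ps, ds = [], []
    for seed in range(50):
        pair = synth.simulate_coding_pair(491, 0.09, 0.0, seed=seed)
        ng = divstats.nei_gojobori(pair)
        ps.append(ng.pS)
        ds.append(ng.dS)
    se = np.std(ps, ddof=1) / math.sqrt(len(ps))
    assert abs(np.mean(ps) - 0.09) < 3 * se
    se_d = np.std(ds, ddof=1) / math.sqrt(len(ds))
    assert abs(np.mean(ds) - divstats.jukes_cantor(0.09)) < 3 * se_d


def test_no_stop_codons_ever_created():
    for seed in range(10):
        pair = synth.simulate_coding_pair(100, 0.5, 0.5, seed=seed)
        for seq in (pair.seq_a, pair.seq_b):
            assert "*" not in translate_cds(seq)


def test_rate_bounds_rejected():
    with pytest.raises(ValueError):
        synth.simulate_coding_pair(50, 0.6, 0.0, seed=0)
    with pytest.raises(ValueError):
        synth.simulate_coding_pair(5, 0.1, 0.0, seed=0)


# ------------------------------------------------------------- reads
def test_error_free_reads_are_exact_substrings():
    truth = synth.simulate_diploid_genome(5000, 0.05, seed=2)
    reads = synth.simulate_reads(truth, coverage=2, read_len=80, seed=2)
    haps = truth.haplotype_a + "#" + truth.haplotype_b
    for r in reads[:200]:
        assert r.seq in haps or reverse_complement(r.seq) in haps


def test_read_count_arithmetic():
    truth = synth.simulate_diploid_genome(100_000, 0.0, seed=1)
    reads = synth.simulate_reads(truth, coverage=30, read_len=100, seed=1)
    assert abs(len(reads) - 60_000) <= 0.01 * 60_000
    total_bases = sum(len(r.seq) for r in reads)
    assert total_bases == pytest.approx(2 * 30 * 100_000, rel=0.01)


def test_minimum_one_read_per_haplotype():
    truth = synth.simulate_diploid_genome(2000, 0.0, seed=1)
    reads = synth.simulate_reads(truth, coverage=0.001, read_len=100, seed=1)
    assert len(reads) == 2  # ceiling rule: one per haplotype


def test_reads_with_errors_differ():
    truth = synth.simulate_diploid_genome(5000, 0.0, seed=3)
    reads = synth.simulate_reads(truth, coverage=5, read_len=100, error_rate=0.05, seed=3)
    n_mut = sum(
        1 for r in reads
        if r.seq not in truth.haplotype_a
        and reverse_complement(r.seq) not in truth.haplotype_a
    )
    assert n_mut > 0.9 * len(reads)  # P(read untouched) = 0.95^100 ~ 0.6%


# ------------------------------------------------------------- population
def test_population_zero_pi_identical():
    aln = synth.simulate_population_alignment(8, 500, 0.0, "neutral", seed=1)
    assert len(set(aln.seqs)) == 1


def test_population_unreachable_pi_errors():
    with pytest.raises(ValueError, match="unreachable"):
        synth.simulate_population_alignment(30, 100, 0.3, "neutral", seed=1)


# ------------------------------------------------------------- fragmentation
def test_fragmentation_roundtrip_and_trivial_case():
    truth = synth.simulate_diploid_genome(20_000, 0.05, seed=6)
    contigs, cmap = synth.fragment_assembly(truth, mean_len=3000, seed=6)
    for hap, seq in (("A", truth.haplotype_a), ("B", truth.haplotype_b)):
        sub = cmap[cmap.haplotype == hap].sort_values("start")
        assert "".join(contigs[c] for c in sub.contig_id) == seq
    # mean_len >= genome size: exactly one contig per haplotype
    contigs2, _ = synth.fragment_assembly(truth, mean_len=50_000, seed=6)
    assert len(contigs2) == 2


# ------------------------------------------------------------- determinism
def test_generators_bit_reproducible():
    a = synth.simulate_diploid_genome(5000, 0.1, n_genes=2, seed=9)
    b = synth.simulate_diploid_genome(5000, 0.1, n_genes=2, seed=9)
    assert a.haplotype_a == b.haplotype_a and a.haplotype_b == b.haplotype_b
    assert a.variants == b.variants

    ra = synth.simulate_reads(a, 2, 50, 0.01, seed=4)
    rb = synth.simulate_reads(b, 2, 50, 0.01, seed=4)
    assert [r.seq for r in ra] == [r.seq for r in rb]

    pa = synth.simulate_coding_pair(100, 0.2, 0.05, seed=12)
    pb = synth.simulate_coding_pair(100, 0.2, 0.05, seed=12)
    assert (pa.seq_a, pa.seq_b) == (pb.seq_a, pb.seq_b)

    na = synth.simulate_population_alignment(6, 300, 0.05, "neutral", seed=13)
    nb = synth.simulate_population_alignment(6, 300, 0.05, "neutral", seed=13)
    assert na.seqs == nb.seqs
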