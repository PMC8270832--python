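"""Shared fixtures: session-scoped simulations reused across test modules."""

from __future__ import annotations

import pytest

from diplodiv import kmers, pairs, synth
from diplodiv.genetics import translate_cds


@pytest.fixture(scope="session")
def hom_genome_spectrum():
    """Homozygous 50 kb genome, 30x error-free reads, k=17 spectrum."""
    truth = synth.simulate_diploid_genome(50_000, 0.0, seed=5)
    reads = synth.simulate_reads(truth, coverage=30, read_len=100, seed=5)
    spectrum = kmers.count_kmers([r.seq for r in reads], 17)
    return truth, reads, spectrum


@pytest.fixture(scope="session")
def planted_pair_sim():
    """Diploid genome with 20 single-exon genes (het 2-11% per gene),
    fragmented into contigs, with split-allele classification run."""
    truth = synth.simulate_diploid_genome(
        100_000,
        0.05,
        n_genes=20,
        seed=11,
        gene_het_range=(0.02, 0.11),
        exon_bp_mean=1000.0,
        exons_per_gene=(1, 1),
    )
    contigs, cmap = synth.fragment_assembly(truth, mean_len=12_000, seed=3)
    proteins = {
        g.gene_id: translate_cds(g.spliced(truth.haplotype_a)).rstrip("*")
        for g in truth.genes
    }
    table, hits = pairs.find_allele_pairs(proteins, contigs, min_len=150)

    def unfragmented(gene):
        s, e = gene.span
        return all(
            ((cmap.haplotype == hap) & (cmap.start <= s) & (cmap.end >= e)).any()
            for hap in "AB"
        )

    eligible = {
        g.gene_id
        for g in truth.genes
        if unfragmented(g) and len(proteins[g.gene_id]) >= 150
    }
    return {
        "truth": truth,
        "contigs": contigs,
        "contig_map": cmap,
        "proteins": proteins,
        "table": table,
        "hits": hits,
        "eligible": eligible,
    }
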