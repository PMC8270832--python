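"""End-to-end "characterize" workflow on synthetic or user data.

Runs, in the order a genome-characterization study would: simulate a
diploid genome and reads -> k-mer spectrum, peaks, genome-size and repeat
estimates -> fragment into a diploid assembly and recover split-allele
pairs -> per-pair and set-level diversity statistics -> population-sample
statistics (pi, Tajima's D). Every number in the report is written from an
intermediate artifact, and the whole run is a pure function of the
configuration and its single seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, divstats, kmers, pairs, popstats, synth
from .genetics import translate_cds


@dataclass
class RunConfig:
    """Parameters of one characterize run; defaults emulate the study regime:
    ~5% genome-wide heterozygosity, ~5.5% mean coding-pair diversity with
    ~20% at fourfold-degenerate sites, and a population sample at 3.6% pi."""

    seed: int = 1
    # genome + reads
    genome_size: int = 100_000
    het_rate: float = 0.05
    n_genes: int = 8
    repeat_spec: tuple[int, int, int] | None = (1, 300, 50)
    coverage: float = 30.0
    read_len: int = 100
    error_rate: float = 0.0
    k: int = 17
    repeat_threshold_x_hom: float = 4.0  # repeat cutoff, multiples of the hom peak
    # assembly + allele pairs
    fragment_mean_len: int = 6000
    min_protein_len: int = 300
    min_score: float = 0.50
    # coding allele pairs
    n_pairs: int = 66
    pair_codons: int = 500
    pair_syn_rate: float = 0.201
    pair_nonsyn_rate: float = 0.0113
    # population sample
    pop_n_seqs: int = 24
    pop_length: int = 1473
    pop_target_pi: float = 0.036
    pop_replicates: int = 20


def _seed_for(base: int, stage: str) -> int:
    """Stable per-stage child seed below 2**31."""
    h = 0
    for ch in stage:
        h = (h * 131 + ord(ch)) % 1_000_003
    return (base * 1_000_003 + h) % (2**31 - 1)


def run_characterize(config: RunConfig, outdir: str | Path) -> dict:
    """Run the full synthetic characterization; returns the report dict.

    Writes spectrum.tsv, pair_classification.tsv, diversity.tsv and
    report.json under ``outdir``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": {k: list(v) if isinstance(v, tuple) else v for k, v in asdict(config).items()},
    }

    # 1. diploid genome, reads, k-mer spectrum
    truth = synth.simulate_diploid_genome(
        config.genome_size,
        config.het_rate,
        n_genes=config.n_genes,
        repeat_spec=config.repeat_spec,
        seed=_seed_for(config.seed, "genome"),
        exon_bp_mean=1000.0,
        exons_per_gene=(1, 1),
    )
    reads = synth.simulate_reads(
        truth,
        coverage=config.coverage,
        read_len=config.read_len,
        error_rate=config.error_rate,
        seed=_seed_for(config.seed, "reads"),
    )
    spectrum = kmers.count_kmers([r.seq for r in reads], config.k)
    spectrum.to_tsv(out / "spectrum.tsv")
    peaks = kmers.detect_peaks(spectrum)
    size_est: dict = {"error_trough": peaks.error_trough, "c_het": peaks.c_het, "c_hom": peaks.c_hom}
    if peaks.c_hom is not None:
        size_est["haploid_bp_from_hom_peak"] = kmers.genome_size(spectrum, peaks.c_hom)
    if peaks.c_het is not None:
        size_est["diploid_bp_from_het_peak"] = kmers.genome_size(spectrum, peaks.c_het)
    ref_peak = peaks.c_hom or (2 * peaks.c_het if peaks.c_het else None)
    if ref_peak:
        threshold = int(config.repeat_threshold_x_hom * ref_peak)
        size_est["repeat_threshold"] = threshold
        size_est["repeat_fraction"] = kmers.repeat_fraction(
            spectrum, threshold, exclude_error_below=peaks.error_trough
        )
    report["genome_size"] = size_est
    report["truth"] = {
        "genome_size": truth.size,
        "n_variants": len(truth.variants),
        "het_rate_realized": len(truth.variants) / truth.size,
        "n_genes": len(truth.genes),
    }

    # 2. fragmented assembly -> split-allele discovery
    contigs, cmap = synth.fragment_assembly(
        truth, config.fragment_mean_len, seed=_seed_for(config.seed, "fragment")
    )
    proteins = {}
    for gene in truth.genes:
        aa = translate_cds(gene.spliced(truth.haplotype_a)).rstrip("*")
        if "*" not in aa:
            proteins[gene.gene_id] = aa
    if proteins:
        table, hits = pairs.find_allele_pairs(
            proteins,
            contigs,
            min_len=config.min_protein_len,
            min_score=config.min_score,
        )
        table.to_csv(out / "pair_classification.tsv", sep="\t", index=False)
        n_hits = table["n_hits"][table["label"] != "short"]
        report["allele_pairs"] = {
            "labels": table["label"].value_counts().to_dict(),
            "mean_alignments_per_gene": float(n_hits.mean()) if len(n_hits) else None,
        }
    else:
        (out / "pair_classification.tsv").write_text("protein_id\tlabel\tn_hits\n")
        report["allele_pairs"] = {"labels": {}, "mean_alignments_per_gene": None}

    # 3. coding allele pairs -> diversity statistics
    pair_set = [
        synth.simulate_coding_pair(
            config.pair_codons,
            config.pair_syn_rate,
            config.pair_nonsyn_rate,
            seed=_seed_for(config.seed, f"pair{i}"),
            gene_id=f"pair{i}",
        )
        for i in range(config.n_pairs)
    ]
    df, summary = divstats.analyze_pair_set(pair_set)
    df.to_csv(out / "diversity.tsv", sep="\t", index=False)
    report["coding_diversity"] = summary

    # 4. population sample -> pi, Tajima's D
    pis, Ds = [], []
    for i in range(config.pop_replicates):
        aln = synth.simulate_population_alignment(
            config.pop_n_seqs,
            config.pop_length,
            config.pop_target_pi,
            "neutral",
            seed=_seed_for(config.seed, f"pop{i}"),
        )
        res = popstats.tajimas_d(aln)
        _, pi = popstats.mean_pairwise_k(aln)
        pis.append(pi)
        if res.D is not None:
            Ds.append(res.D)
    report["population"] = {
        "replicates": config.pop_replicates,
        "mean_pi": float(np.mean(pis)),
        "mean_tajimas_d": float(np.mean(Ds)) if Ds else None,
    }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
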