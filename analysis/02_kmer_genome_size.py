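#!/usr/bin/env python
"""k-mer spectrum of the simulated reads: peaks, genome size, repeats.

Counts canonical 17-mers in the reads from 01, locates the heterozygous
and homozygous coverage peaks, estimates genome size from each (the
heterozygous peak reads out the diploid 2n size, the homozygous peak the
haploid size), and reports the k-mer occurrence fraction above a repeat
threshold. Run 01_simulate_genome.py first.
"""

import json
from pathlib import Path

from Bio import SeqIO

from diplodiv import kmers

K = 17
RESULTS = Path("results")
SCRATCH = Path("scratch")


def main() -> None:
    reads = [str(r.seq) for r in SeqIO.parse(SCRATCH / "reads.fastq", "fastq")]
    spectrum = kmers.count_kmers(reads, K)
    spectrum.to_tsv(RESULTS / "kmer_spectrum.tsv")
    peaks = kmers.detect_peaks(spectrum)

    sim = json.loads((RESULTS / "simulation.json").read_text())
    true_size = sim["params"]["size"]
    report = {
        "k": K,
        "error_trough": peaks.error_trough,
        "c_het": peaks.c_het,
        "c_hom": peaks.c_hom,
        "haploid_size_from_hom_peak": kmers.genome_size(spectrum, peaks.c_hom),
        "diploid_size_from_het_peak": kmers.genome_size(spectrum, peaks.c_het),
        "true_haploid_size": true_size,
        "repeat_threshold": 4 * peaks.c_hom,
        "repeat_fraction_occurrences": kmers.repeat_fraction(
            spectrum, 4 * peaks.c_hom, exclude_error_below=peaks.error_trough
        ),
        "repeat_fraction_distinct": kmers.repeat_fraction(
            spectrum, 4 * peaks.c_hom, weight="distinct",
            exclude_error_below=peaks.error_trough,
        ),
    }
    with open(RESULTS / "genome_size.json", "w") as fh:
        json.dump(report, fh, indent=2)
    print(
        f"peaks: het {peaks.c_het}x, hom {peaks.c_hom}x | "
        f"haploid estimate {report['haploid_size_from_hom_peak']/1e3:.1f} kb "
        f"(truth {true_size/1e3:.0f} kb), diploid estimate "
        f"{report['diploid_size_from_het_peak']/1e3:.1f} kb | repeat fraction "
        f"{report['repeat_fraction_occurrences']:.3f} above {4*peaks.c_hom}x"
    )


if __name__ == "__main__":
    main()
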