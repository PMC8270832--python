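"""k-mer counting, spectrum peaks, genome size and repeat fraction."""

import math
from collections import Counter

import numpy as np
import pytest

from diplodiv import kmers, synth


# ------------------------------------------------------------- counting
def test_palindromic_and_canonical_examples():
    spec = kmers.count_kmers(["ACGT"], 4)
    assert spec.hist == {1: 1}  # ACGT is its own reverse complement
    spec = kmers.count_kmers(["AAAA", "TTTT"], 4)
    assert spec.hist == {2: 1}
    assert spec.total_kmers == 2


def test_total_kmer_arithmetic():
    rng = np.random.default_rng(1)
    reads = ["".join(rng.choice(list("ACGT"), 100)) for _ in range(50)]
    spec = kmers.count_kmers(reads, 15)
    assert spec.total_kmers == 50 * (100 - 15 + 1)
    assert spec.total_kmers == sum(m * c for m, c in spec.hist.items())


def test_counts_match_brute_force_with_ambiguous_bases():
    rng = np.random.default_rng(2)
    reads = [
        "".join(rng.choice(list("ACGTN"), p=[0.24] * 4 + [0.04], size=60))
        for _ in range(40)
    ]
    k = 11
    comp = str.maketrans("ACGT", "TGCA")
    counter = Counter()
    for r in reads:
        for i in range(len(r) - k + 1):
            km = r[i : i + k]
            if "N" not in km:
                counter[min(km, km.translate(comp)[::-1])] += 1
    expected = Counter(counter.values())
    spec = kmers.count_kmers(reads, k)
    assert spec.hist == dict(expected)


def test_spectrum_invariant_under_reverse_complement():
    rng = np.random.default_rng(3)
    reads = ["".join(rng.choice(list("ACGT"), 80)) for _ in range(30)]
    from diplodiv.genetics import reverse_complement

    fwd = kmers.count_kmers(reads, 13)
    rev = kmers.count_kmers([reverse_complement(r) for r in reads], 13)
    assert fwd.hist == rev.hist


def test_input_validation():
    with pytest.raises(ValueError):
        kmers.count_kmers([], 15)
    with pytest.raises(ValueError):
        kmers.count_kmers(["ACGT"], 35)
    with pytest.raises(ValueError):
        kmers.count_kmers(["ACG"], 4)  # k longer than every read


# ------------------------------------------------------------- peaks
def _bump(center, mass, width):
    """Binomial-like histogram bump around a center multiplicity."""
    hist = {}
    for m in range(max(2, center - width), center + width + 1):
        hist[m] = int(mass * math.exp(-((m - center) ** 2) / (2 * (width / 2) ** 2)))
    return hist


def test_peak_detection_on_constructed_mixture():
    hist = {1: 5000, 2: 1200, 3: 300}  # error component
    for m, c in _bump(25, 2000, 10).items():
        hist[m] = hist.get(m, 0) + c
    for m, c in _bump(50, 800, 10).items():
        hist[m] = hist.get(m, 0) + c
    spec = kmers.KmerSpectrum(k=15, hist=hist, n_reads=1000, read_len=100)
    peaks = kmers.detect_peaks(spec)
    assert peaks.error_trough > 1
    assert abs(peaks.c_het - 25) <= 2
    assert abs(peaks.c_hom - 50) <= 2


def test_unimodal_spectrum_reports_homozygous_peak():
    spec = kmers.KmerSpectrum(k=15, hist=_bump(40, 1000, 12), n_reads=1000, read_len=100)
    peaks = kmers.detect_peaks(spec)
    assert peaks.c_het is None
    assert abs(peaks.c_hom - 40) <= 2


def test_diploid_simulation_shows_two_peaks(hom_genome_spectrum):
    truth = synth.simulate_diploid_genome(60_000, 0.05, seed=21)
    reads = synth.simulate_reads(truth, coverage=30, read_len=100, seed=21)
    spec = kmers.count_kmers([r.seq for r in reads], 17)
    peaks = kmers.detect_peaks(spec)
    assert peaks.c_het is not None and peaks.c_hom is not None
    assert 1.6 <= peaks.c_hom / peaks.c_het <= 2.4


def test_heterozygous_peak_mass_grows_with_het_rate():
    ratios = []
    for het in (0.0, 0.02, 0.05):
        truth = synth.simulate_diploid_genome(40_000, het, seed=31)
        reads = synth.simulate_reads(truth, coverage=30, read_len=100, seed=31)
        spec = kmers.count_kmers([r.seq for r in reads], 17)
        c_hom = kmers.detect_peaks(spec).c_hom or (
            2 * kmers.detect_peaks(spec).c_het
        )
        het_mass = sum(
            m * c for m, c in spec.hist.items() if 0.35 * c_hom <= m <= 0.65 * c_hom
        )
        hom_mass = sum(
            m * c for m, c in spec.hist.items() if 0.8 * c_hom <= m <= 1.2 * c_hom
        )
        ratios.append(het_mass / hom_mass)
    assert ratios[0] <= ratios[1] <= ratios[2]


# ------------------------------------------------------------- genome size
def test_genome_size_formula_examples():
    spec = kmers.KmerSpectrum(k=15, hist={86: 1000}, n_reads=1000, read_len=100)
    assert kmers.genome_size(spec, 86) == pytest.approx(1000.0)
    assert kmers.genome_size(spec, 43) == pytest.approx(2 * kmers.genome_size(spec, 86))
    with pytest.raises(ValueError):
        kmers.genome_size(spec, 0)


@pytest.mark.parametrize("size", [50_000, 100_000, 200_000])
def test_genome_size_recovery_homozygous(size):
    """Error-free 30x reads from a homozygous genome recover its size
    within 5% using the homozygous-peak coverage."""
    truth = synth.simulate_diploid_genome(size, 0.0, seed=size)
    reads = synth.simulate_reads(truth, coverage=30, read_len=100, seed=size)
    spec = kmers.count_kmers([r.seq for r in reads], 17)
    peaks = kmers.detect_peaks(spec)
    est = kmers.genome_size(spec, peaks.c_hom)
    assert abs(est - size) / size < 0.05


def test_het_peak_gives_diploid_scale(hom_genome_spectrum):
    """On a heterozygous diploid the het-peak estimate is about twice the
    haploid genome size."""
    truth = synth.simulate_diploid_genome(60_000, 0.05, seed=21)
    reads = synth.simulate_reads(truth, coverage=30, read_len=100, seed=21)
    spec = kmers.count_kmers([r.seq for r in reads], 17)
    peaks = kmers.detect_peaks(spec)
    diploid_est = kmers.genome_size(spec, peaks.c_het)
    assert abs(diploid_est - 2 * 60_000) / (2 * 60_000) < 0.15


# ------------------------------------------------------------- repeats
def test_repeat_fraction_threshold_zero_is_one(hom_genome_spectrum):
    _, _, spec = hom_genome_spectrum
    assert kmers.repeat_fraction(spec, 0) == pytest.approx(1.0)


def test_unique_genome_has_no_high_coverage_kmers(hom_genome_spectrum):
    _, _, spec = hom_genome_spectrum
    assert kmers.repeat_fraction(spec, 400) < 0.01


def test_planted_repeat_occupancy_recovered():
    """A genome that is ~35% one 100-copy repeat family shows that share of
    k-mer occurrences above a high multiplicity threshold."""
    size, unit_len, copies = 85_000, 300, 100
    truth = synth.simulate_diploid_genome(
        size, 0.0, repeat_spec=(1, unit_len, copies), seed=17
    )
    reads = synth.simulate_reads(truth, coverage=20, read_len=100, seed=17)
    spec = kmers.count_kmers([r.seq for r in reads], 17)
    occupancy = unit_len * copies / size
    # threshold 10x the unique-sequence coverage separates repeat k-mers
    frac = kmers.repeat_fraction(spec, 400)
    assert frac == pytest.approx(occupancy, rel=0.15)
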