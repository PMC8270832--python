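"""k-mer spectrum construction, peak detection and genome-size estimation.

Counts canonical k-mers (lexicographic minimum of a k-mer and its reverse
complement, k <= 31, packed into 64-bit integers) in memory, builds the
multiplicity spectrum, locates the heterozygous and homozygous coverage
peaks, and estimates genome size as

    genome size = n * (L - k + 1) / C

with n reads of average length L and C the coverage at a spectrum peak:
the homozygous peak gives the haploid-scale estimate, the heterozygous
peak (at about half that coverage) the diploid-scale one. The repeat
fraction is the share of k-mer occurrences above a coverage threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
    _LUT[_b + 32] = _i  # lowercase


@dataclass
class KmerSpectrum:
    """Histogram of k-mer multiplicity -> number of distinct canonical k-mers.

    When built by :func:`count_kmers` with ``keep_counts=True`` the sorted
    per-k-mer count table is retained so per-sequence coverage can be looked
    up later (e.g. for contig screening).
    """

    k: int
    hist: dict[int, int]
    n_reads: int
    read_len: float
    kmer_ids: np.ndarray | None = field(default=None, repr=False)
    kmer_counts: np.ndarray | None = field(default=None, repr=False)

    @property
    def total_kmers(self) -> int:
        return int(sum(m * c for m, c in self.hist.items()))

    @property
    def distinct_kmers(self) -> int:
        return int(sum(self.hist.values()))

    def lookup(self, seq: str) -> np.ndarray:
        """Multiplicity of each canonical k-mer of ``seq`` (0 if unseen)."""
        if self.kmer_ids is None:
            raise ValueError("spectrum was built without a retained count table")
        kmers = _canonical_kmers(seq, self.k)
        if kmers.size == 0:
            return np.zeros(0, dtype=np.int64)
        pos = np.searchsorted(self.kmer_ids, kmers)
        pos = np.clip(pos, 0, self.kmer_ids.size - 1)
        found = self.kmer_ids[pos] == kmers
        out = np.where(found, self.kmer_counts[pos], 0)
        return out.astype(np.int64)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("multiplicity\tdistinct_count\n")
            for m in sorted(self.hist):
                fh.write(f"{m}\t{self.hist[m]}\n")

    @classmethod
    def from_tsv(cls, path, k: int, n_reads: int = 0, read_len: float = 0.0):
        hist = {}
        with open(path) as fh:
            next(fh)
            for line in fh:
                m, c = line.split()
                hist[int(m)] = int(c)
        return cls(k=k, hist=hist, n_reads=n_reads, read_len=read_len)


@dataclass
class PeakEstimate:
    """Coverage peaks of a diploid k-mer spectrum.

    ``c_het`` is the heterozygous-peak multiplicity, ``c_hom`` the
    homozygous one (about twice c_het); for an effectively homozygous
    spectrum only ``c_hom`` is reported. ``error_trough`` is the first
    local minimum after multiplicity 1, separating sequencing-error k-mers
    from genomic ones.
    """

    error_trough: int
    c_het: int | None
    c_hom: int | None


def _encode(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _window_kmers(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(forward kmer ints, validity mask) for every window of ``codes``.

    Horner scheme over k shifted views, so no (n, k) matrix is ever built;
    windows containing a non-ACGT byte are flagged invalid via a cumulative
    count (their packed values are garbage and must be masked out).
    """
    n = codes.size
    if n < k:
        return np.zeros(0, dtype=np.uint64), np.zeros(0, dtype=bool)
    w = n - k + 1
    c = codes.astype(np.uint64)
    fwd = c[:w].copy()
    four = np.uint64(4)
    for j in range(1, k):
        fwd *= four
        fwd += c[j : j + w]
    bad = np.concatenate(([0], np.cumsum(codes == 255)))
    valid = (bad[k:] - bad[:-k]) == 0
    return fwd, valid


def _canonical_kmers(seq: str, k: int) -> np.ndarray:
    codes = _encode(seq)
    fwd, valid = _window_kmers(codes, k)
    # uint8 wraparound makes invalid bytes garbage here, but every window
    # touching one is dropped by the forward validity mask
    rc_codes = 3 - codes[::-1]
    rev, _ = _window_kmers(rc_codes, k)
    rev = rev[::-1]
    canon = np.minimum(fwd, rev)
    return canon[valid]


def count_kmers(
    reads: Iterable[str] | str | Path,
    k: int,
    keep_counts: bool = True,
) -> KmerSpectrum:
    """Count canonical k-mers from reads (sequences, or a FASTA/FASTQ path).

    k-mers containing non-ACGT characters are skipped; reads shorter than k
    contribute nothing. Raises on empty input, k outside 1..31, or when no
    read is long enough to yield a k-mer.
    """
    if not 1 <= k <= 31:
        raise ValueError("k must be in 1..31")
    if isinstance(reads, (str, Path)):
        reads = list(_read_seqs(reads))
    else:
        reads = [str(r) for r in reads]
    if not reads:
        raise ValueError("no reads supplied")
    # concatenate with a sentinel so one sliding-window pass covers all reads
    sep = "N"
    blob = sep.join(reads)
    kmers = _canonical_kmers(blob, k)
    if kmers.size == 0:
        raise ValueError("no valid k-mers (is k larger than the read length?)")
    ids, counts = np.unique(kmers, return_counts=True)
    mult, n_distinct = np.unique(counts, return_counts=True)
    hist = {int(m): int(c) for m, c in zip(mult, n_distinct)}
    read_len = float(np.mean([len(r) for r in reads]))
    return KmerSpectrum(
        k=k,
        hist=hist,
        n_reads=len(reads),
        read_len=read_len,
        kmer_ids=ids if keep_counts else None,
        kmer_counts=counts.astype(np.int64) if keep_counts else None,
    )


def _read_seqs(path) -> Iterable[str]:
    from Bio import SeqIO

    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    for rec in SeqIO.parse(str(path), fmt):
        yield str(rec.seq)


def _smooth(dense: np.ndarray, window: int = 3) -> np.ndarray:
    kernel = np.ones(window) / window
    return np.convolve(dense, kernel, mode="same")


def detect_peaks(
    spectrum: KmerSpectrum, smooth_window: int = 3, min_rel_height: float = 0.02
) -> PeakEstimate:
    """Locate the error trough and the het/hom coverage peaks.

    The dense histogram is smoothed by a centered moving average before the
    extremum search; ties break toward lower multiplicity. The tallest mode
    above the trough is taken as primary; a secondary mode at 1.6-2.4x its
    coverage identifies (het, hom), one at the reciprocal position
    identifies (hom taller than het), and with no companion the single peak
    is reported as homozygous.
    """
    max_m = max(spectrum.hist)
    dense = np.zeros(max_m + 2)
    for m, c in spectrum.hist.items():
        dense[m] = c
    # multiplicity 0 does not exist; mirror m=1 so smoothing cannot carve a
    # spurious extremum at the boundary of a decaying error component
    dense[0] = dense[1]
    s = _smooth(dense, smooth_window)

    # first local minimum after multiplicity 1 (error/genomic boundary)
    trough = 1
    for m in range(2, max_m):
        if s[m] < s[m - 1] and s[m] <= s[m + 1]:
            trough = m
            break
        if s[m] > s[m - 1]:  # histogram rising from the start: no error bulk
            break

    modes = [
        m
        for m in range(max(2, trough + 1), max_m + 1)
        if s[m] >= s[m - 1] and s[m] > s[m + 1]
    ]
    if not modes:
        raise ValueError("spectrum uninformative: no mode above the error trough")
    tallest = max(modes, key=lambda m: (s[m], -m))
    floor = min_rel_height * s[tallest]
    modes = [m for m in modes if s[m] >= floor]

    hom_cands = [m for m in modes if 1.6 * tallest <= m <= 2.4 * tallest]
    if hom_cands:
        c_hom = max(hom_cands, key=lambda m: (s[m], -m))
        return PeakEstimate(error_trough=trough, c_het=tallest, c_hom=c_hom)
    het_cands = [m for m in modes if tallest / 2.4 <= m <= tallest / 1.6]
    if het_cands:
        c_het = max(het_cands, key=lambda m: (s[m], -m))
        return PeakEstimate(error_trough=trough, c_het=c_het, c_hom=tallest)
    return PeakEstimate(error_trough=trough, c_het=None, c_hom=tallest)


def genome_size(spectrum: KmerSpectrum, C: float) -> float:
    """Genome size = n * (L - k + 1) / C.

    With C at the homozygous peak this is the haploid-scale estimate; at
    the heterozygous peak, the diploid-scale (2n) estimate.
    """
    if C <= 0:
        raise ValueError("peak coverage C must be positive")
    return spectrum.n_reads * (spectrum.read_len - spectrum.k + 1) / C


def repeat_fraction(
    spectrum: KmerSpectrum,
    threshold: int,
    weight: str = "occurrences",
    exclude_error_below: int | None = None,
) -> float:
    """Fraction of the k-mer content above a multiplicity threshold.

    ``weight="occurrences"`` (default) weights each distinct k-mer by its
    multiplicity; ``"distinct"`` counts distinct k-mers once. K-mers below
    ``exclude_error_below`` (e.g. the detected error trough) are dropped
    from the denominator so sequencing-error k-mers do not dilute the
    estimate.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if weight not in ("occurrences", "distinct"):
        raise ValueError("weight must be 'occurrences' or 'distinct'")
    lo = exclude_error_below or 1
    num = den = 0
    for m, c in spectrum.hist.items():
        if m < lo:
            continue
        w = m * c if weight == "occurrences" else c
        den += w
        if m > threshold:
            num += w
    return num / den if den else 0.0
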