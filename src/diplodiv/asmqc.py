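"""Contig screening and gene-structure statistics.

GC content and mean k-mer coverage per contig (coverage looked up in a
k-mer count table, so no read aligner is needed), the low-coverage
exclusion rule (strictly below the cutoff), and exon/intron length
distributions binned for histograms.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .kmers import KmerSpectrum
from .synth import GeneModel


def gc_content(seq: str) -> float:
    """(G+C) / (A+C+G+T); ambiguous characters are ignored."""
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence has no unambiguous bases")
    return (counts["G"] + counts["C"]) / total


def contig_stats(
    contigs: dict[str, str],
    spectrum: KmerSpectrum | None = None,
    coverage_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-contig length, GC and mean coverage.

    Coverage is the mean multiplicity of the contig's constituent k-mers in
    ``spectrum`` (which must retain its count table); alternatively a
    precomputed ``coverage_table`` with columns (contig_id, mean_cov) can
    be supplied. Contigs shorter than k have undefined coverage and are
    flagged.
    """
    if spectrum is None and coverage_table is None:
        raise ValueError("need a k-mer spectrum or a coverage table")
    cov_map = None
    if coverage_table is not None:
        cov_map = dict(
            zip(coverage_table["contig_id"], coverage_table["mean_cov"].astype(float))
        )
    rows = []
    for cid, seq in contigs.items():
        flagged, reason = False, ""
        mean_cov = np.nan
        if cov_map is not None:
            if cid in cov_map:
                mean_cov = cov_map[cid]
            else:
                flagged, reason = True, "no coverage entry"
        else:
            mults = spectrum.lookup(seq)
            if mults.size == 0:
                flagged, reason = True, f"shorter than k={spectrum.k}"
            else:
                mean_cov = float(mults.mean())
        rows.append(
            {
                "contig_id": cid,
                "length": len(seq),
                "gc": gc_content(seq),
                "mean_cov": mean_cov,
                "flagged": flagged,
                "reason": reason,
            }
        )
    return pd.DataFrame(rows)


def filter_low_coverage(
    stats: pd.DataFrame, min_cov: float = 10.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition contigs into (retained, removed) by mean coverage.

    Removal uses strict inequality (mean_cov < min_cov), so a contig at
    exactly the cutoff is retained; contigs with undefined coverage are
    removed.
    """
    if stats.empty:
        raise ValueError("empty stats table")
    low = stats["mean_cov"].isna() | (stats["mean_cov"] < min_cov)
    return stats[~low].copy(), stats[low].copy()


def gene_structure_stats(
    genes: Iterable[GeneModel], bin_size: int = 20
) -> dict:
    """Exon and intron length distributions with histogram bins.

    Returns per-feature length arrays, means/medians, and fixed-width
    histogram bins (default 20 bp) whose counts sum to the number of
    measured lengths.
    """
    exon_lengths: list[int] = []
    intron_lengths: list[int] = []
    for g in genes:
        # GeneModel validates exon ordering/overlap on construction
        exon_lengths.extend(e - s for s, e in g.exons)
        intron_lengths.extend(g.intron_lengths())

    def _hist(lengths: Sequence[int]) -> pd.DataFrame:
        if not lengths:
            return pd.DataFrame(columns=["bin_start", "bin_end", "count"])
        arr = np.asarray(lengths)
        top = (int(arr.max()) // bin_size + 1) * bin_size
        edges = np.arange(0, top + bin_size, bin_size)
        counts, _ = np.histogram(arr, bins=edges)
        return pd.DataFrame(
            {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
        )

    def _summary(lengths: Sequence[int]) -> dict:
        if not lengths:
            return {"n": 0, "mean": None, "median": None}
        arr = np.asarray(lengths, dtype=float)
        return {"n": len(arr), "mean": float(arr.mean()), "median": float(np.median(arr))}

    return {
        "exon_lengths": exon_lengths,
        "intron_lengths": intron_lengths,
        "exon_summary": _summary(exon_lengths),
        "intron_summary": _summary(intron_lengths),
        "exon_hist": _hist(exon_lengths),
        "intron_hist": _hist(intron_lengths),
        "bin_size": bin_size,
    }
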