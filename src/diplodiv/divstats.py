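"""Diversity statistics between two allelic coding sequences.

Implements, for a codon-aligned pair of alleles of one gene:

* ``pairwise_pi`` -- uncorrected per-site p-distance (pi),
* ``pi4d`` -- pi restricted to fourfold-degenerate third codon positions,
* ``nei_gojobori`` -- NG86 synonymous/nonsynonymous site and difference
  counting with equal-weight pathway averaging and Jukes-Cantor correction,
  giving dN, dS and omega = dN/dS,
* ``analyze_pair`` / ``analyze_pair_set`` -- per-gene results and summary
  tables over a collection of allele pairs.

pi is deliberately an uncorrected proportion; the Jukes-Cantor correction
is applied only inside the NG86 distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genetics import (
    CODON_TO_AA,
    FOURFOLD_CODONS,
    STOP_CODONS,
    codon_site_counts,
    translate_codon,
)

GAP_CODON = "---"


@dataclass
class AllelePairAlignment:
    """Codon-aware alignment of the two alleles of one gene.

    Sequences are equal-length nucleotide strings whose length is divisible
    by three; gaps occupy whole codons (``---``), so every aligned triplet is
    either a gap codon or gap-free. Neither ungapped sequence may contain an
    internal stop codon.
    """

    gene_id: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        self.seq_a = self.seq_a.upper()
        self.seq_b = self.seq_b.upper()
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(f"{self.gene_id}: aligned sequences differ in length")
        if len(self.seq_a) % 3:
            raise ValueError(f"{self.gene_id}: alignment length not divisible by 3")
        for name, seq in (("seq_a", self.seq_a), ("seq_b", self.seq_b)):
            codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
            for c in codons:
                if "-" in c and c != GAP_CODON:
                    raise ValueError(
                        f"{self.gene_id}/{name}: gap not codon-sized at codon {c!r}"
                    )
            sense = [c for c in codons if c != GAP_CODON]
            if any(c in STOP_CODONS for c in sense[:-1]):
                raise ValueError(f"{self.gene_id}/{name}: internal stop codon")

    def codon_pairs(self) -> list[tuple[str, str]]:
        """Aligned codon pairs, in alignment order (gap codons included)."""
        return [
            (self.seq_a[i : i + 3], self.seq_b[i : i + 3])
            for i in range(0, len(self.seq_a), 3)
        ]

    def compared_codons(self) -> list[tuple[str, str]]:
        """Codon pairs with no gap on either side and no stop codon."""
        return [
            (a, b)
            for a, b in self.codon_pairs()
            if GAP_CODON not in (a, b)
            and a not in STOP_CODONS
            and b not in STOP_CODONS
        ]


@dataclass
class DiversityResult:
    """All per-pair diversity statistics for one gene's allele pair."""

    gene_id: str
    pi: float
    pi4d: float | None
    n_4d_sites: int
    n_het_4d: int
    dN: float
    dS: float
    omega: float | None
    N_sites: float
    S_sites: float
    aa_mismatches: int


@dataclass
class NG86Result:
    """Raw Nei-Gojobori counts and corrected distances for one pair."""

    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float | None


def jukes_cantor(p: float) -> float:
    """JC69 distance d = -(3/4) ln(1 - (4/3) p); undefined for p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        raise ValueError(f"proportion {p:.4f} >= 3/4: Jukes-Cantor correction undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def fourfold_sites(pair: AllelePairAlignment, strict: bool = True) -> list[int]:
    """Alignment positions (0-based, third codon positions) that are
    fourfold-degenerate in this pair.

    Strict rule (default): the position counts only if both codons belong
    to a fourfold family and agree at codon positions 1-2, so that any base
    at the third position leaves both amino acids unchanged. The lax
    variant (``strict=False``) drops the codon-context agreement and only
    requires both codons to sit in fourfold families. Gap codons are
    skipped.
    """
    out = []
    for idx, (a, b) in enumerate(pair.codon_pairs()):
        if GAP_CODON in (a, b) or "-" in a or "-" in b:
            continue
        if a in FOURFOLD_CODONS and b in FOURFOLD_CODONS and (
            not strict or a[:2] == b[:2]
        ):
            out.append(3 * idx + 2)
    return out


def pairwise_pi(pair: AllelePairAlignment) -> float:
    """Uncorrected p-distance: mismatches / sites comparable in both alleles."""
    comparable = 0
    mismatch = 0
    for x, y in zip(pair.seq_a, pair.seq_b):
        if x == "-" or y == "-":
            continue
        comparable += 1
        if x != y:
            mismatch += 1
    if comparable == 0:
        raise ValueError(f"{pair.gene_id}: no comparable sites")
    return mismatch / comparable


def pi4d(pair: AllelePairAlignment) -> tuple[float | None, int, int]:
    """(pi4D, n fourfold sites, n mismatching fourfold sites).

    pi4D is None when the pair has no fourfold-degenerate site; it is
    reported as undefined rather than fabricated.
    """
    sites = fourfold_sites(pair)
    n_het = sum(1 for i in sites if pair.seq_a[i] != pair.seq_b[i])
    if not sites:
        return None, 0, 0
    return n_het / len(sites), len(sites), n_het


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous difference counts between two codons.

    Differences are classified by enumerating all orderings of the differing
    positions; each single-base step is synonymous iff it preserves the
    amino acid. Pathways passing through a stop codon are excluded and the
    remainder averaged with equal weight; if every pathway is blocked the
    stop exclusion is waived for that codon (vanishingly rare in real data).
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        syn = nonsyn = 0
        current = codon_a
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if translate_codon(nxt) == translate_codon(current):
                syn += 1
            else:
                nonsyn += 1
            if nxt in STOP_CODONS and nxt != codon_b:
                through_stop = True
            current = nxt
        (blocked if through_stop else paths).append((syn, nonsyn))
    if not paths:
        paths = blocked
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def count_sites_and_differences(
    pair: AllelePairAlignment,
) -> tuple[float, float, float, float]:
    """(S_sites, N_sites, Sd, Nd): raw NG86 counts before any correction."""
    codons = pair.compared_codons()
    if not codons:
        raise ValueError(f"{pair.gene_id}: no comparable codons")
    S_sites = N_sites = 0.0
    Sd = Nd = 0.0
    for a, b in codons:
        sa, na = codon_site_counts(a)
        sb, nb = codon_site_counts(b)
        S_sites += (sa + sb) / 2.0
        N_sites += (na + nb) / 2.0
        sd, nd = _pathway_counts(a, b)
        Sd += sd
        Nd += nd
    return S_sites, N_sites, Sd, Nd


def nei_gojobori(pair: AllelePairAlignment) -> NG86Result:
    """Nei-Gojobori (1986) dN and dS for one codon-aligned allele pair.

    Fractional synonymous site counts are computed per codon and averaged
    over the two sequences; differences use equal-weight pathway averaging
    (stop-codon pathways excluded); proportions are Jukes-Cantor corrected
    (an explicit error when a proportion reaches the 3/4 saturation bound).
    omega is None when dS = 0.
    """
    S_sites, N_sites, Sd, Nd = count_sites_and_differences(pair)
    pS = Sd / S_sites if S_sites > 0 else 0.0
    pN = Nd / N_sites if N_sites > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    omega = (dN / dS) if dS > 0 else None
    return NG86Result(S_sites, N_sites, Sd, Nd, pS, pN, dS, dN, omega)


def aa_mismatches(pair: AllelePairAlignment) -> int:
    """Number of compared codons whose translations differ."""
    return sum(
        1 for a, b in pair.compared_codons() if translate_codon(a) != translate_codon(b)
    )


def analyze_pair(pair: AllelePairAlignment) -> DiversityResult:
    """Full per-pair diversity report: pi, pi4D, NG86 dN/dS, site counts."""
    p4, n4, nhet = pi4d(pair)
    ng = nei_gojobori(pair)
    return DiversityResult(
        gene_id=pair.gene_id,
        pi=pairwise_pi(pair),
        pi4d=p4,
        n_4d_sites=n4,
        n_het_4d=nhet,
        dN=ng.dN,
        dS=ng.dS,
        omega=ng.omega,
        N_sites=ng.N_sites,
        S_sites=ng.S_sites,
        aa_mismatches=aa_mismatches(pair),
    )


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (report convention for omega)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def analyze_pair_set(
    pairs: Iterable[AllelePairAlignment],
) -> tuple[pd.DataFrame, dict]:
    """Per-gene table plus summary statistics over a set of allele pairs.

    The summary gives mean/SD/median/range for pi and pi4D, the mean omega
    over pairs where it is defined, and a subgroup summary restricted to
    pairs with no amino-acid mismatch between the alleles (where nucleotide
    diversity is purely synonymous).
    """
    results = [analyze_pair(p) for p in pairs]
    if not results:
        raise ValueError("no pairs supplied")
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "pi": [r.pi for r in results],
            "pi4d": [r.pi4d for r in results],
            "n_4d_sites": [r.n_4d_sites for r in results],
            "n_het_4d": [r.n_het_4d for r in results],
            "dN": [r.dN for r in results],
            "dS": [r.dS for r in results],
            "omega": [r.omega for r in results],
            "N_sites": [r.N_sites for r in results],
            "S_sites": [r.S_sites for r in results],
            "aa_mismatches": [r.aa_mismatches for r in results],
        }
    )

    def _stats(series: pd.Series) -> dict:
        s = series.dropna().astype(float)
        if s.empty:
            return {"mean": None, "sd": None, "median": None, "min": None, "max": None}
        return {
            "mean": float(s.mean()),
            "sd": float(s.std(ddof=1)) if len(s) > 1 else 0.0,
            "median": float(s.median()),
            "min": float(s.min()),
            "max": float(s.max()),
        }

    no_aa = df[df["aa_mismatches"] == 0]
    summary = {
        "n_pairs": len(df),
        "pi": _stats(df["pi"]),
        "pi4d": _stats(df["pi4d"]),
        "omega_mean": float(df["omega"].dropna().astype(float).mean())
        if df["omega"].notna().any()
        else None,
        "no_aa_mismatch": {
            "n_pairs": int(len(no_aa)),
            "pi": _stats(no_aa["pi"]) if len(no_aa) else None,
        },
    }
    return df, summary
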