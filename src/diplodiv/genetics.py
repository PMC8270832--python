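"""Standard genetic code helpers used throughout the package.

Derives, from the standard (NCBI table 1) genetic code, the per-codon
quantities the diversity statistics need: synonymous/nonsynonymous site
fractions in the Nei-Gojobori sense and the fourfold-degenerate codon set.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable
from Bio.Seq import Seq

BASES = "ACGT"

_standard = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, with '*' for the three stop codons
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_standard.stop_codons)
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"

SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in CODON_TO_AA if c not in STOP_CODONS)
)


def translate_codon(codon: str) -> str:
    """Amino acid for one codon ('*' for stops)."""
    return CODON_TO_AA[codon.upper()]


def is_stop(codon: str) -> bool:
    return codon.upper() in STOP_CODONS


def _fourfold_codons() -> frozenset[str]:
    """Codons whose third position is fully degenerate.

    Brute force over the code: a codon belongs to a fourfold family iff all
    four third-position variants encode the same amino acid. This yields the
    8 families (Leu-CTN, Val, Ser-TCN, Pro, Thr, Ala, Arg-CGN, Gly),
    32 codons in total.
    """
    out = set()
    for c1 in BASES:
        for c2 in BASES:
            aas = {CODON_TO_AA[c1 + c2 + c3] for c3 in BASES}
            if len(aas) == 1 and "*" not in aas:
                out.update(c1 + c2 + c3 for c3 in BASES)
    return frozenset(out)


FOURFOLD_CODONS: frozenset[str] = _fourfold_codons()


@lru_cache(maxsize=None)
def synonymous_fraction(codon: str, pos: int) -> float:
    """Fraction of the three single-base changes at ``pos`` that are synonymous.

    Changes to stop codons count as nonsynonymous, so the nonsynonymous
    fraction is always ``1 - synonymous_fraction`` and per-codon site counts
    sum to 3 (the NG86 identity).
    """
    codon = codon.upper()
    aa = CODON_TO_AA[codon]
    syn = 0
    for b in BASES:
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if CODON_TO_AA[alt] == aa:
            syn += 1
    return syn / 3.0


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon; sums to 3."""
    s = sum(synonymous_fraction(codon, pos) for pos in range(3))
    return s, 3.0 - s


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS (length divisible by 3); stops as '*'."""
    if len(cds) % 3:
        raise ValueError("CDS length must be divisible by 3")
    return "".join(CODON_TO_AA[cds[i : i + 3].upper()] for i in range(0, len(cds), 3))
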