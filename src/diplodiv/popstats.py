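"""Population statistics on a multiple alignment of allele sequences.

Valid/segregating site counts, Watterson's theta, mean pairwise differences
(k-bar, per-site pi) and Tajima's (1989) D, following the usual convention
that a valid column has an unambiguous base (A/C/G/T) in every sequence and
a segregating column is a valid column with at least two distinct bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

_VALID_BASES = frozenset(b"ACGT")


@dataclass
class PopAlignment:
    """n >= 2 aligned nucleotide sequences of equal length."""

    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.seqs) < 2:
            raise ValueError("need at least two sequences")
        self.seqs = [s.upper() for s in self.seqs]
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValueError("sequences differ in length")

    @property
    def n(self) -> int:
        return len(self.seqs)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def matrix(self) -> np.ndarray:
        """(n, L) byte matrix of the alignment."""
        return np.frombuffer("".join(self.seqs).encode(), dtype="S1").reshape(
            self.n, self.length
        )

    def valid_mask(self) -> np.ndarray:
        """Columns with an unambiguous A/C/G/T in every sequence."""
        m = self.matrix()
        ok = np.zeros(m.shape, dtype=bool)
        for b in _VALID_BASES:
            ok |= m == bytes([b])
        return ok.all(axis=0)


@dataclass
class TajimaResult:
    n: int
    S: int
    valid_sites: int
    theta_w: float
    k_bar: float
    D: float | None  # None iff S == 0


def valid_and_segregating(aln: PopAlignment) -> tuple[int, int]:
    """(number of valid columns, number of segregating columns)."""
    mask = aln.valid_mask()
    m = aln.matrix()[:, mask]
    seg = (m != m[0]).any(axis=0)
    return int(mask.sum()), int(seg.sum())


def harmonic_a1(n: int) -> float:
    """a1 = sum_{i=1}^{n-1} 1/i."""
    return float(sum(1.0 / i for i in range(1, n)))


def watterson_theta(S: int, n: int) -> float:
    """Per-alignment Watterson estimator theta_W = S / a1."""
    if n < 2:
        raise ValueError("need n >= 2")
    return S / harmonic_a1(n)


def mean_pairwise_k(
    aln: PopAlignment,
    weights: Sequence[float] | None = None,
    pairwise_deletion: bool = False,
) -> tuple[float, float]:
    """(k_bar, per-site pi) over valid columns.

    k_bar is the mean number of differences over all sequence pairs;
    pi = k_bar / valid_sites. With complete deletion (default) a column
    with a gap or ambiguity anywhere is dropped for every pair; with
    ``pairwise_deletion`` each pair uses the columns valid in that pair
    only and per-pair pi values are averaged. Optional per-sequence
    ``weights`` (e.g. 1/c for c clones from the same individual) give a
    weighted mean over pairs.
    """
    n = aln.n
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError("weights must have one entry per sequence")
    mat = aln.matrix()
    if pairwise_deletion:
        ok = np.zeros(mat.shape, dtype=bool)
        for b in _VALID_BASES:
            ok |= mat == bytes([b])
        tot_k = tot_pi = wsum = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                both = ok[i] & ok[j]
                valid_ij = int(both.sum())
                if valid_ij == 0:
                    raise ValueError(f"no valid columns for pair ({i}, {j})")
                diffs = float((mat[i][both] != mat[j][both]).sum())
                pw = w[i] * w[j]
                tot_k += pw * diffs
                tot_pi += pw * diffs / valid_ij
                wsum += pw
        return tot_k / wsum, tot_pi / wsum
    mask = aln.valid_mask()
    valid = int(mask.sum())
    if valid == 0:
        raise ValueError("no valid columns")
    m = mat[:, mask]
    total = 0.0
    wsum = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            pw = w[i] * w[j]
            total += pw * float((m[i] != m[j]).sum())
            wsum += pw
    k_bar = total / wsum
    return k_bar, k_bar / valid


def tajimas_d(aln: PopAlignment) -> TajimaResult:
    """Tajima's D with the standard 1989 constants.

    D = (k_bar - S/a1) / sqrt(e1*S + e2*S*(S-1)); undefined (None) when
    there are no segregating sites.
    """
    valid, S = valid_and_segregating(aln)
    n = aln.n
    k_bar, _ = mean_pairwise_k(aln)
    theta_w = watterson_theta(S, n)
    if S == 0:
        return TajimaResult(n=n, S=0, valid_sites=valid, theta_w=0.0, k_bar=k_bar, D=None)
    a1 = harmonic_a1(n)
    a2 = float(sum(1.0 / i**2 for i in range(1, n)))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    D = (k_bar - S / a1) / np.sqrt(var)
    return TajimaResult(n=n, S=S, valid_sites=valid, theta_w=theta_w, k_bar=k_bar, D=float(D))
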