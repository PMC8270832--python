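"""Discovery of split-allele gene pairs in a fragmented diploid assembly.

In a highly heterozygous diploid assembled from short reads, the two
alleles of a single-copy gene frequently assemble as separate contigs. The
operations here find such pairs: conserved proteins are aligned to every
contig in all six reading frames (local alignment, BLOSUM62, affine gaps),
scores are normalized by the protein self-score, and each protein is
classified by how many contigs carry a high-scoring hit -- exactly two
being the split-allele signature. A frameshift heuristic flags hits whose
alignment is split across two reading frames on the same strand, and
flagged pairs are excluded from downstream diversity statistics.

No intron modeling is attempted: contigs are assumed to carry the CDS
contiguously (single-exon or pre-spliced), which is the regime the
synthetic data generates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .divstats import AllelePairAlignment
from .genetics import reverse_complement, translate_cds

_VALID_DNA = set("ACGTN")


def default_aligner(mode: str = "local") -> Align.PairwiseAligner:
    """BLOSUM62 with affine gap penalties (open 11, extend 1)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def translate_six_frames(dna: str) -> dict[str, str]:
    """All six reading-frame translations, keyed '+1'..'+3', '-1'..'-3'.

    Standard genetic code; stops rendered as '*', N-containing codons as
    'X'. Non-ACGTN characters are rejected.
    """
    dna = dna.upper()
    if len(dna) < 3:
        raise ValueError("sequence shorter than one codon")
    bad = set(dna) - _VALID_DNA
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    out: dict[str, str] = {}
    rc = reverse_complement(dna)
    for strand, seq in (("+", dna), ("-", rc)):
        for f in (1, 2, 3):
            sub = seq[f - 1 :]
            sub = sub[: len(sub) - len(sub) % 3]
            out[f"{strand}{f}"] = str(Seq(sub).translate())
    return out


@dataclass
class ContigHit:
    """Best translated alignment of one protein against one contig."""

    protein_id: str
    contig_id: str
    frame: int  # +-1..3; for frameshifted hits, the frame of the stronger part
    raw_score: float
    norm_score: float  # raw_score / protein self-alignment score
    aligned_fraction: float
    frameshift_flag: bool
    protein_interval: tuple[int, int] = (0, 0)
    contig_interval: tuple[int, int] = (0, 0)  # nt, forward-strand coordinates
    strand: str = "+"


def _frame_to_nt(frame: int, aa_start: int, aa_end: int, contig_len: int) -> tuple[int, int]:
    """Map an amino-acid interval in a reading frame to forward-strand nt coords."""
    f = abs(frame)
    nt_start = (f - 1) + 3 * aa_start
    nt_end = (f - 1) + 3 * aa_end
    if frame > 0:
        return nt_start, nt_end
    return contig_len - nt_end, contig_len - nt_start


def _merge_interval(a: tuple[int, int], b: tuple[int, int]) -> tuple[int, int]:
    return min(a[0], b[0]), max(a[1], b[1])


def _share_words(protein: str, frame_aa: str, word: int = 5, min_hits: int = 2) -> bool:
    """Cheap seed filter: do protein and frame share >= min_hits exact words?

    Allelic matches share hundreds of 5-aa words even at ~10% amino-acid
    divergence, while unrelated frames share essentially none, so frames
    failing this test skip the dynamic-programming alignment entirely.
    """
    if len(protein) < word or len(frame_aa) < word:
        return False
    words = {protein[i : i + word] for i in range(len(protein) - word + 1)}
    hits = 0
    for i in range(len(frame_aa) - word + 1):
        if frame_aa[i : i + word] in words:
            hits += 1
            if hits >= min_hits:
                return True
    return False


def align_protein_to_contig(
    protein_id: str,
    protein: str,
    contig_id: str,
    contig: str,
    aligner: Align.PairwiseAligner | None = None,
    frameshift_min_gain: float = 0.15,
    frames: dict[str, str] | None = None,
    self_score: float | None = None,
) -> ContigHit:
    """Best local alignment of a protein over all six frames of a contig.

    ``norm_score`` is the alignment score divided by the protein's
    self-alignment score, so a perfect full-length match scores 1.0
    regardless of length or composition (and is invariant to padding the
    contig with unrelated sequence).

    Frameshift detection: if a second reading frame on the same strand
    aligns a largely disjoint stretch of the protein and adds at least
    ``frameshift_min_gain`` of the protein length beyond the best single
    frame, the CDS in the contig is interrupted by an indel of length not
    divisible by 3; the hit is flagged and its score is the sum of the two
    part scores.
    """
    if len(protein) < 20:
        raise ValueError("protein must be at least 20 aa")
    if not contig:
        raise ValueError("empty contig")
    if aligner is None:
        aligner = default_aligner()
    if self_score is None:
        self_score = aligner.score(protein, protein)
    if frames is None:
        frames = translate_six_frames(contig)
    # cheap pass first: scores only, traceback alignments just where needed
    scores: dict[str, float] = {}
    for name, aa in frames.items():
        if len(aa) == 0 or not _share_words(protein, aa):
            continue
        score = aligner.score(protein, aa)
        if score > 0:
            scores[name] = score
    if not scores:
        return ContigHit(protein_id, contig_id, 1, 0.0, 0.0, 0.0, False)
    best_name = max(scores, key=scores.get)
    results: dict[str, tuple[float, object]] = {}
    for name, score in scores.items():
        if name == best_name or (
            name[0] == best_name[0] and score >= 0.10 * self_score
        ):
            results[name] = (score, aligner.align(protein, frames[name])[0])

    best_score, best_aln = results[best_name]
    strand = best_name[0]
    frame = int(best_name) if strand == "-" else int(best_name[1])
    p_blocks = best_aln.aligned[0]
    p_start, p_end = int(p_blocks[0][0]), int(p_blocks[-1][1])
    covered = sum(int(e - s) for s, e in p_blocks)
    a_blocks = best_aln.aligned[1]
    aa_start, aa_end = int(a_blocks[0][0]), int(a_blocks[-1][1])
    nt_iv = _frame_to_nt(frame, aa_start, aa_end, len(contig))

    # frameshift scan: complementary alignment in a sibling frame, same strand
    frameshift = False
    total_score, total_cov = best_score, covered
    p_iv = (p_start, p_end)
    for name, (score, aln) in results.items():
        if name == best_name or name[0] != strand:
            continue
        blocks = aln.aligned[0]
        s2, e2 = int(blocks[0][0]), int(blocks[-1][1])
        cov2 = sum(int(e - s) for s, e in blocks)
        overlap = max(0, min(p_end, e2) - max(p_start, s2))
        if (
            score >= 0.10 * self_score
            and overlap <= 0.3 * min(p_end - p_start, e2 - s2)
            and cov2 - overlap >= frameshift_min_gain * len(protein)
        ):
            frameshift = True
            total_score += score
            total_cov += cov2 - overlap
            p_iv = _merge_interval(p_iv, (s2, e2))
            ab = aln.aligned[1]
            f2 = int(name) if strand == "-" else int(name[1])
            nt_iv = _merge_interval(
                nt_iv, _frame_to_nt(f2, int(ab[0][0]), int(ab[-1][1]), len(contig))
            )
    return ContigHit(
        protein_id=protein_id,
        contig_id=contig_id,
        frame=frame,
        raw_score=float(total_score),
        norm_score=float(total_score / self_score),
        aligned_fraction=min(1.0, total_cov / len(protein)),
        frameshift_flag=frameshift,
        protein_interval=p_iv,
        contig_interval=nt_iv,
        strand=strand,
    )


#: classification labels for find_allele_pairs
LABELS = ("short", "zero_hit", "single_hit", "pair", "multi_hit", "excluded_frameshift")


def find_allele_pairs(
    proteins: dict[str, str],
    contigs: dict[str, str],
    min_len: int = 300,
    min_score: float = 0.50,
    tie_margin: float = 0.02,
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[pd.DataFrame, dict[str, list[ContigHit]]]:
    """Classify each conserved protein by its high-scoring contig hits.

    Proteins shorter than ``min_len`` aa are excluded before alignment.
    Hits with ``norm_score >= min_score`` are kept (one hit per contig; no
    split-gene chaining across contigs). Labels: ``zero_hit``,
    ``single_hit``, ``pair`` (exactly two hits, the split-allele
    signature), ``multi_hit``, and ``excluded_frameshift`` for pairs with
    any frameshift-flagged member. With more than two passing hits, the
    top two are still taken as a pair only when they outscore the third by
    at least ``tie_margin``; closer ranks are conservatively multi_hit.
    """
    if not proteins or not contigs:
        raise ValueError("proteins and contigs must be non-empty")
    if aligner is None:
        aligner = default_aligner()
    frames_by_contig = {cid: translate_six_frames(seq) for cid, seq in contigs.items()}
    rows = []
    hits_by_protein: dict[str, list[ContigHit]] = {}
    for pid, prot in proteins.items():
        if len(prot) < min_len:
            rows.append({"protein_id": pid, "label": "short", "n_hits": 0})
            continue
        self_score = aligner.score(prot, prot)
        hits = []
        for cid, contig in contigs.items():
            hit = align_protein_to_contig(
                pid, prot, cid, contig, aligner=aligner,
                frames=frames_by_contig[cid], self_score=self_score,
            )
            if hit.norm_score >= min_score:
                hits.append(hit)
        hits.sort(key=lambda h: -h.norm_score)
        hits_by_protein[pid] = hits
        if len(hits) == 0:
            label = "zero_hit"
        elif len(hits) == 1:
            label = "single_hit"
        elif len(hits) == 2 or hits[1].norm_score - hits[2].norm_score >= tie_margin:
            label = "pair"
            if any(h.frameshift_flag for h in hits[:2]):
                label = "excluded_frameshift"
        else:
            label = "multi_hit"
        rows.append({"protein_id": pid, "label": label, "n_hits": len(hits)})
    return pd.DataFrame(rows), hits_by_protein


def _hit_cds(hit: ContigHit, contigs: dict[str, str]) -> str:
    """In-frame nucleotide sequence under a hit's aligned region."""
    s, e = hit.contig_interval
    nt = contigs[hit.contig_id][s:e]
    if hit.strand == "-":
        nt = reverse_complement(nt)
    return nt[: len(nt) - len(nt) % 3]


def extract_pair_cds(
    hit_a: ContigHit,
    hit_b: ContigHit,
    contigs: dict[str, str],
    gene_id: str | None = None,
    min_identity: float = 0.5,
) -> AllelePairAlignment:
    """Codon-aligned CDS pair for two allelic hits of one protein.

    The in-frame nucleotide regions under the two alignments are extracted,
    their translations aligned globally, and the amino-acid alignment
    back-mapped to codons, so gaps only ever appear in multiples of three.
    Pairs whose aligned nucleotide identity falls below ``min_identity``
    are rejected as non-allelic.
    """
    if hit_a.frameshift_flag or hit_b.frameshift_flag:
        raise ValueError("cannot extract CDS from a frameshift-flagged hit")
    nt_a = _hit_cds(hit_a, contigs)
    nt_b = _hit_cds(hit_b, contigs)
    aa_a = translate_cds(nt_a).rstrip("*")
    aa_b = translate_cds(nt_b).rstrip("*")
    nt_a = nt_a[: 3 * len(aa_a)]
    nt_b = nt_b[: 3 * len(aa_b)]
    aligner = default_aligner(mode="global")
    aln = aligner.align(aa_a, aa_b)[0]
    out_a, out_b = [], []
    ia = ib = 0
    for col_a, col_b in zip(*aln.indices):
        if col_a >= 0 and col_b >= 0:
            out_a.append(nt_a[3 * ia : 3 * ia + 3])
            out_b.append(nt_b[3 * ib : 3 * ib + 3])
            ia += 1
            ib += 1
        elif col_a >= 0:
            out_a.append(nt_a[3 * ia : 3 * ia + 3])
            out_b.append("---")
            ia += 1
        else:
            out_a.append("---")
            out_b.append(nt_b[3 * ib : 3 * ib + 3])
            ib += 1
    seq_a, seq_b = "".join(out_a), "".join(out_b)
    comparable = [(x, y) for x, y in zip(seq_a, seq_b) if x != "-" and y != "-"]
    if comparable:
        ident = sum(1 for x, y in comparable if x == y) / len(comparable)
        if ident < min_identity:
            raise ValueError(
                f"pair identity {ident:.2f} below {min_identity}: not allelic"
            )
    gid = gene_id or hit_a.protein_id
    return AllelePairAlignment(gene_id=gid, seq_a=seq_a, seq_b=seq_b)
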