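"""Allele-pair diversity statistics: examples, oracles, properties."""

import math
import warnings
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diplodiv import divstats, synth
from diplodiv.divstats import AllelePairAlignment
from diplodiv.genetics import CODON_TO_AA, STOP_CODONS, translate_codon


def pair_of(codons_a, codons_b, gene_id="t"):
    return AllelePairAlignment(gene_id, "".join(codons_a), "".join(codons_b))


# ------------------------------------------------------------- validation
def test_alignment_validation():
    with pytest.raises(ValueError):
        AllelePairAlignment("t", "ATGAAA", "ATG")  # unequal
    with pytest.raises(ValueError):
        AllelePairAlignment("t", "ATGA", "ATGA")  # not codons
    with pytest.raises(ValueError):
        AllelePairAlignment("t", "ATGA--AAA", "ATGAAAAAA")  # ragged gap
    with pytest.raises(ValueError):
        AllelePairAlignment("t", "ATGTAAAAA", "ATGTAAAAA")  # internal stop
    # terminal stop and whole-codon gaps are fine
    AllelePairAlignment("t", "ATG---TGA", "ATGAAATGA")


# ------------------------------------------------------------- fourfold sites
def test_fourfold_sites_examples():
    assert divstats.fourfold_sites(pair_of(["ATG"], ["ATG"])) == []
    sites = divstats.fourfold_sites(pair_of(["GGA"], ["GGT"]))
    assert sites == [2]
    # context disagreement at positions 1-2 disqualifies the site
    assert divstats.fourfold_sites(pair_of(["GGA"], ["CGA"])) == []
    # ... unless the lax variant is requested (both are fourfold-family codons)
    assert divstats.fourfold_sites(pair_of(["GGA"], ["CGA"]), strict=False) == [2]
    # gap codons are skipped
    assert divstats.fourfold_sites(pair_of(["GGA", "---"], ["GGT", "GGC"])) == [2]


def test_pi4d_examples():
    p4, n4, nhet = divstats.pi4d(pair_of(["GGA"], ["GGT"]))
    assert (p4, n4, nhet) == (1.0, 1, 1)
    # 100 Gly codons, 20 third-position mismatches -> 0.20
    a = ["GGA"] * 100
    b = ["GGT"] * 20 + ["GGA"] * 80
    p4, n4, nhet = divstats.pi4d(pair_of(a, b))
    assert n4 == 100 and nhet == 20 and p4 == pytest.approx(0.20)
    # no fourfold sites -> undefined, not fabricated
    p4, n4, nhet = divstats.pi4d(pair_of(["ATG"], ["ATG"]))
    assert p4 is None and n4 == 0


# ------------------------------------------------------------- pi
def test_pairwise_pi_counts_match_direct_enumeration():
    a = ["ATG", "AAA", "CCC", "GGG", "---"]
    b = ["ATG", "AAG", "CCC", "GAG", "TTT"]
    pair = pair_of(a, b)
    # direct count: gap codon excluded -> 12 comparable sites, 2 mismatches
    assert divstats.pairwise_pi(pair) == pytest.approx(2 / 12)
    assert divstats.pairwise_pi(pair_of(["ATG"] * 491, ["ATG"] * 491)) == 0.0


# ------------------------------------------------------------- NG86
def test_ng86_identical_pair():
    ng = divstats.nei_gojobori(pair_of(["ATG", "GGA"], ["ATG", "GGA"]))
    assert ng.dN == 0.0 and ng.dS == 0.0 and ng.omega is None


def test_ng86_single_synonymous_change_site_count_oracle():
    """One synonymous third-position change in 20 codons: dS = JC(1/S) with
    S recomputed here by brute-force enumeration over all single-base
    changes of every codon."""
    codons_a = ["ATG", "GGA", "CCT", "AAA", "TTT", "GAT", "CAT", "AGA", "GTA", "TGG"] * 2
    codons_b = list(codons_a)
    codons_b[1] = "GGT"  # Gly GGA -> GGT, synonymous
    pair = pair_of(codons_a, codons_b)

    def site_count(codon):
        aa = CODON_TO_AA[codon]
        syn = 0
        for pos in range(3):
            for b in "ACGT":
                if b != codon[pos]:
                    alt = codon[:pos] + b + codon[pos + 1 :]
                    if CODON_TO_AA[alt] == aa:
                        syn += 1
        return syn / 3

    S = sum((site_count(a) + site_count(b)) / 2 for a, b in zip(codons_a, codons_b))
    ng = divstats.nei_gojobori(pair)
    assert ng.S_sites == pytest.approx(S)
    assert ng.dS == pytest.approx(divstats.jukes_cantor(1 / S))
    assert ng.dN == 0.0


def test_omega_report_rounding_matches_ratio():
    """omega reported at 2 significant figures equals the ratio of dN and dS."""
    assert divstats.round_sig(0.0057 / 0.069) == 0.083
    assert divstats.round_sig(0.0067 / 0.061) == 0.11


def exhaustive_pathway_oracle(codons_a, codons_b):
    """Independent NG86 difference counter: depth-first enumeration over
    orderings of differing positions, written without the package's helper."""
    Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        diffs = [i for i in range(3) if ca[i] != cb[i]]
        if not diffs:
            continue
        kept = []
        for order in permutations(diffs):
            cur, syn, nonsyn, ok = ca, 0, 0, True
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                if nxt in STOP_CODONS and nxt != cb:
                    ok = False
                syn += translate_codon(nxt) == translate_codon(cur)
                nonsyn += translate_codon(nxt) != translate_codon(cur)
                cur = nxt
            if ok:
                kept.append((syn, nonsyn))
        if not kept:
            kept = [(0, 0)]
        Sd += sum(k[0] for k in kept) / len(kept)
        Nd += sum(k[1] for k in kept) / len(kept)
    return Sd, Nd


def test_ng86_matches_exhaustive_oracle_on_small_alignments():
    rng = np.random.default_rng(42)
    sense = [c for c in CODON_TO_AA if c not in STOP_CODONS]
    for _ in range(300):
        n = int(rng.integers(1, 6))
        a = [sense[i] for i in rng.integers(0, len(sense), n)]
        b = [sense[i] for i in rng.integers(0, len(sense), n)]
        pair = pair_of(a, b)
        _, _, got_sd, got_nd = divstats.count_sites_and_differences(pair)
        Sd, Nd = exhaustive_pathway_oracle(a, b)
        assert got_sd == pytest.approx(Sd)
        assert got_nd == pytest.approx(Nd)


def test_ng86_matches_biopython_reference():
    """Cross-check dN/dS against Biopython's independent NG86 implementation."""
    from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

    for seed in range(1, 6):
        pair = synth.simulate_coding_pair(150, 0.15, 0.02, seed=seed)
        ng = divstats.nei_gojobori(pair)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dn, ds = cal_dn_ds(CodonSeq(pair.seq_a), CodonSeq(pair.seq_b), method="NG86")
        assert ng.dN == pytest.approx(dn, abs=1e-9)
        assert ng.dS == pytest.approx(ds, abs=1e-9)


def test_jukes_cantor_domain():
    assert divstats.jukes_cantor(0.0) == 0.0
    with pytest.raises(ValueError):
        divstats.jukes_cantor(0.75)


# ------------------------------------------------------------- properties
@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_statistics_symmetric_under_allele_swap(seed):
    pair = synth.simulate_coding_pair(60, 0.2, 0.05, seed=seed)
    swapped = AllelePairAlignment(pair.gene_id, pair.seq_b, pair.seq_a)
    r1, r2 = divstats.analyze_pair(pair), divstats.analyze_pair(swapped)
    assert r1.pi == r2.pi
    assert r1.pi4d == r2.pi4d
    assert r1.dN == pytest.approx(r2.dN)
    assert r1.dS == pytest.approx(r2.dS)
    assert r1.S_sites == pytest.approx(r2.S_sites)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_site_counts_conserve_total(seed):
    pair = synth.simulate_coding_pair(40, 0.3, 0.1, seed=seed)
    ng = divstats.nei_gojobori(pair)
    n_codons = len(pair.compared_codons())
    assert ng.S_sites + ng.N_sites == pytest.approx(3 * n_codons)


def test_ds_monotone_in_synonymous_rate():
    """Mean dS does not decrease as the generating synonymous rate rises."""
    means = []
    for rate in (0.05, 0.15, 0.30):
        ds = [
            divstats.nei_gojobori(
                synth.simulate_coding_pair(150, rate, 0.01, seed=s)
            ).dS
            for s in range(50)
        ]
        means.append(np.mean(ds))
    assert means[0] < means[1] < means[2]


# ------------------------------------------------------------- pair sets
def test_analyze_pair_set_recovers_generating_diversity():
    pairs = [
        synth.simulate_coding_pair(500, 0.055, 0.055, seed=s, gene_id=f"g{s}")
        for s in range(1, 40)
    ]
    df, summary = divstats.analyze_pair_set(pairs)
    se = summary["pi"]["sd"] / math.sqrt(len(df))
    assert abs(summary["pi"]["mean"] - 0.055) < 3 * se


def test_analyze_pair_set_degenerate_and_subgroup():
    identical = [
        synth.simulate_coding_pair(100, 0.0, 0.0, seed=s, gene_id=f"g{s}")
        for s in range(5)
    ]
    df, summary = divstats.analyze_pair_set(identical)
    assert summary["pi"]["mean"] == 0.0 and summary["pi"]["max"] == 0.0

    # synonymous-only pairs: no amino-acid mismatch yet pi > 0
    syn_only = [
        synth.simulate_coding_pair(300, 0.2, 0.0, seed=s, gene_id=f"g{s}")
        for s in range(5)
    ]
    df, summary = divstats.analyze_pair_set(syn_only)
    assert (df["aa_mismatches"] == 0).all()
    assert (df["pi"] > 0).all()
    assert summary["no_aa_mismatch"]["n_pairs"] == 5
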