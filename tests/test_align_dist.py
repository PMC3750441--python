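import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from organphylo.align_dist import (
    Alignment,
    SnpSummary,
    anchored_align,
    classify_snps,
    p_distance,
    pairwise_align,
    percent_difference,
    progressive_align,
)
from organphylo.genome_io import RegionSet

from conftest import random_dna

SCORING = dict(match=1.0, mismatch=-1.0, gap_open=-4.0, gap_extend=-1.0)


# -- independent affine-scoring oracle ---------------------------------------

def _score_pair(r1, r2, match, mismatch, gap_open, gap_extend):
    score = 0.0
    prev = None
    for a, b in zip(r1, r2):
        if a == "-" or b == "-":
            state = "g1" if a == "-" else "g2"
            score += gap_extend if prev == state else gap_open
            prev = state
        else:
            score += match if a == b else mismatch
            prev = "m"
    return score


def _brute_best_score(a, b, **sc):
    best = [-np.inf]

    def rec(i, j, score, prev):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + (sc["match"] if a[i] == b[j] else sc["mismatch"]), "m")
        if i < len(a):
            rec(i + 1, j, score + (sc["gap_extend"] if prev == "g1" else sc["gap_open"]), "g1")
        if j < len(b):
            rec(i, j + 1, score + (sc["gap_extend"] if prev == "g2" else sc["gap_open"]), "g2")

    rec(0, 0, 0.0, None)
    return best[0]


def test_pairwise_identity():
    r1, r2 = pairwise_align("ACGT", "ACGT")
    assert r1 == r2 == "ACGT"


def test_pairwise_single_gap():
    r1, r2 = pairwise_align("ACGT", "ACT")
    assert (r1, r2) == ("ACGT", "AC-T")


@pytest.mark.parametrize("a,b", [
    ("ACGT", "ACT"), ("AAAA", "AA"), ("ACGTAC", "AGTAC"),
    ("GATTAC", "GCATTA"), ("TTT", "GGG"),
])
def test_pairwise_is_score_optimal(a, b):
    r1, r2 = pairwise_align(a, b, **SCORING)
    assert r1.replace("-", "") == a and r2.replace("-", "") == b
    assert _score_pair(r1, r2, **SCORING) == pytest.approx(_brute_best_score(a, b, **SCORING))


def test_pairwise_empty_input_errors():
    with pytest.raises(ValueError):
        pairwise_align("", "A")


# -- anchored whole-genome alignment -----------------------------------------

def test_anchored_identity(rng):
    g = random_dna(rng, 5000)
    aln = anchored_align(g, g)
    assert aln.length == 5000
    assert aln.rows[0] == aln.rows[1]


def test_anchored_recovers_planted_substitutions(rng):
    g1 = random_dna(rng, 20000)
    pos = rng.choice(20000, size=100, replace=False)
    g2 = list(g1)
    rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
    for p in pos:
        g2[p] = rot[g2[p]]
    aln = anchored_align(g1, "".join(g2))
    mismatch_cols = sum(
        a != b and a != "-" and b != "-" for a, b in zip(*aln.rows)
    )
    assert mismatch_cols == 100
    assert "-" not in aln.rows[0] and "-" not in aln.rows[1]


def test_anchored_noncollinear_errors(rng):
    g1 = random_dna(rng, 60000)
    with pytest.raises(ValueError, match="anchor"):
        anchored_align(g1, g1[::-1])


# -- progressive multiple alignment ------------------------------------------

def test_progressive_identical_members():
    r = RegionSet("x", "genic", {"a": "ACGTAC", "b": "ACGTAC", "c": "ACGTAC"})
    aln = progressive_align(r)
    assert aln.rows == ["ACGTAC"] * 3
    assert aln.order == ["a", "b", "c"]


def test_progressive_single_deletion_member():
    r = RegionSet("x", "genic", {"a": "ACGT", "b": "ACT", "c": "ACGT"})
    aln = progressive_align(r)
    assert aln.length == 4
    assert aln.row("b").count("-") == 1
    assert aln.row("a") == aln.row("c") == "ACGT"


def test_progressive_substitutions_preserved(rng):
    base = random_dna(rng, 300)
    members = {}
    for i, s in enumerate("abcd"):
        seq = list(base)
        seq[10 + 50 * i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[10 + 50 * i]]
        members[s] = "".join(seq)
    aln = progressive_align(RegionSet("x", "genic", members))
    assert aln.length == 300
    n_poly = sum(len({r[c] for r in aln.rows}) > 1 for c in range(aln.length))
    assert n_poly == 4


# -- p-distance ---------------------------------------------------------------

def test_p_distance_simple():
    dm = p_distance(Alignment("x", ["a", "b"], ["AAAA", "AAAT"]))
    assert dm.value("a", "b") == pytest.approx(0.25)


def test_p_distance_gap_excluded_pairwise():
    dm = p_distance(Alignment("x", ["a", "b"], ["AA-A", "AAAA"]), "pairwise")
    assert dm.value("a", "b") == 0.0


def test_p_distance_complete_deletion():
    aln = Alignment("x", ["a", "b", "c"], ["AA-A", "AATA", "TATA"])
    dm = p_distance(aln, "complete")
    # only columns 1,2,4 survive; a vs c differ at column 1
    assert dm.value("a", "c") == pytest.approx(1 / 3)


def test_p_distance_matches_bruteforce_recount(rng):
    n, L = 6, 1000
    rows = []
    base = random_dna(rng, L)
    for _ in range(n):
        row = list(base)
        for p in rng.choice(L, size=40, replace=False):
            row[p] = rng.choice(list("ACGT-"))
        rows.append("".join(row))
    aln = Alignment("x", [f"s{i}" for i in range(n)], rows)
    dm = p_distance(aln)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            comp = [(a, b) for a, b in zip(rows[i], rows[j]) if a not in "-N" and b not in "-N"]
            expect = sum(a != b for a, b in comp) / len(comp)
            assert dm.d[i, j] == pytest.approx(expect)


def test_p_distance_no_comparable_sites_errors():
    with pytest.raises(ValueError, match="a.*b|b.*a"):
        p_distance(Alignment("x", ["a", "b"], ["A-", "-A"]))


@given(st.integers(0, 2 ** 31 - 1))
@settings(max_examples=20, deadline=None)
def test_p_distance_invariants_property(seed):
    r = np.random.default_rng(seed)
    n, L = int(r.integers(2, 6)), int(r.integers(10, 60))
    rows = ["".join(r.choice(list("ACGT"), size=L)) for _ in range(n)]
    dm = p_distance(Alignment("x", [f"s{i}" for i in range(n)], rows))
    assert np.allclose(dm.d, dm.d.T)
    assert np.all(np.diag(dm.d) == 0)
    assert np.all((dm.d >= 0) & (dm.d <= 1))


# -- percent difference --------------------------------------------------------

def test_percent_difference_by_definition():
    rows = ["A" * 100, "A" * 90 + "C" * 10]
    assert percent_difference(Alignment("x", ["a", "b"], rows)) == pytest.approx(10.0)


def test_percent_difference_identical_rows():
    assert percent_difference(Alignment("x", ["a", "b"], ["ACGT", "ACGT"])) == 0.0


def test_percent_difference_row_order_invariant(rng):
    rows = [random_dna(rng, 80) for _ in range(4)]
    labels = list("abcd")
    vals = set()
    for perm in itertools.permutations(range(4)):
        aln = Alignment("x", [labels[i] for i in perm], [rows[i] for i in perm])
        vals.add(percent_difference(aln))
    assert len(vals) == 1


def test_percent_difference_mean_pairwise_mode():
    aln = Alignment("x", ["a", "b"], ["AAAA", "AATT"])
    assert percent_difference(aln, mode="mean_pairwise") == pytest.approx(50.0)


# -- SNP classification --------------------------------------------------------

def test_transition_vs_transversion_columns():
    aln = Alignment("x", ["a", "b"], ["AG", "GT"])
    records, summary = classify_snps(aln)
    assert [r.klass for r in records] == ["transition", "transversion"]
    assert summary.n_transition == summary.n_transversion == 1


def test_triplet_indel_vs_frameshift():
    a = "ATGAAACCCTAA"
    b = "ATGAAA---TAA"  # 3-base gap: in-frame
    _, s1 = classify_snps(Alignment("g", ["a", "b"], [a, b], frame=0))
    assert s1.n_indel == 3
    recs, _ = classify_snps(Alignment("g", ["a", "b"], [a, b], frame=0))
    assert all(r.coding_effect == "triplet_indel" for r in recs)
    b2 = "ATGAAAC--TAA"  # 2-base gap: frameshift
    recs2, _ = classify_snps(Alignment("g", ["a", "b"], [a, b2], frame=0))
    indels = [r for r in recs2 if r.klass == "indel"]
    assert indels and all(r.coding_effect == "frameshift" for r in indels)


def test_synonymous_vs_nonsynonymous_annotation():
    # TTT->TTC is synonymous (Phe); TTT->GTT nonsynonymous (Phe->Val)
    aln = Alignment("g", ["a", "b"], ["TTTAAA", "TTCAAA"], frame=0)
    recs, s = classify_snps(aln)
    assert recs[0].coding_effect == "synonymous" and s.n_syn == 1
    aln2 = Alignment("g", ["a", "b"], ["TTTAAA", "GTTAAA"], frame=0)
    recs2, s2 = classify_snps(aln2)
    assert recs2[0].coding_effect == "nonsynonymous" and s2.n_nonsyn == 1


def test_snp_summary_counts_are_exact_partition(rng):
    for _ in range(10):
        L = 120
        rows = []
        base = random_dna(rng, L)
        for _ in range(5):
            row = list(base)
            for p in rng.choice(L, size=15, replace=False):
                row[p] = rng.choice(list("ACGTN-"))
            rows.append("".join(row))
        aln = Alignment("x", [f"s{i}" for i in range(5)], rows)
        records, s = classify_snps(aln)
        n_variant_cols = sum(
            len({r[c] for r in rows} - {"N"}) >= 2 for c in range(L)
        )
        assert s.n_variant == n_variant_cols == len(records)


def test_n_treated_as_missing():
    _, s = classify_snps(Alignment("x", ["a", "b"], ["AN", "AC"]))
    assert s.n_variant == 0


def test_summary_from_counts_ratio():
    s = SnpSummary.from_counts(300, 200, 5)
    assert s.n_variant == 505
    assert s.ts_tv_ratio == pytest.approx(1.5)
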