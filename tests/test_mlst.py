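import numpy as np
import pytest

from organphylo.align_dist import Alignment
from organphylo.examples import MLST_STRAINS, mlst_example_loci
from organphylo.mlst import (
    MlstLocus,
    call_variable_regions,
    find_mlst_loci,
    genotype_mlst,
    locus_difference_counts,
    read_allele_table,
    window_scan,
    write_allele_table,
)
from organphylo.simulate import build_fixture, conspecific_pair_config, replay

from conftest import random_dna


def _pair(a, b):
    return Alignment("x", ["r", "s"], [a, b])


# -- window scan ----------------------------------------------------------------

def test_identical_pair_all_windows_zero():
    sc = window_scan(_pair("A" * 2000, "A" * 2000))
    assert all(s == 0 for _, _, s in sc.windows)


def test_planted_cluster_counts():
    r2 = list("A" * 2000)
    for p in range(900, 940, 5):  # 8 substitutions in a 40 bp stretch
        r2[p] = "C"
    sc = window_scan(_pair("A" * 2000, "".join(r2)))
    full = [w for w in sc.windows if w[0] <= 901 and w[1] >= 936]
    assert full and all(s == 8 for _, _, s in full)


def test_window_s_matches_direct_recount(rng):
    a = random_dna(rng, 3000)
    b = list(a)
    for p in rng.choice(3000, size=120, replace=False):
        b[p] = rng.choice(list("ACGT-"))
    b = "".join(b)
    sc = window_scan(_pair(a, b), window_len=500, step=25)
    for start, end, S in sc.windows:
        expect = sum(
            1 for x, y in zip(a[start - 1:end], b[start - 1:end])
            if x != y and "-" not in (x, y) and "N" not in (x, y)
        )
        assert S == expect


def test_tiling_windows_conserve_total(rng):
    a = random_dna(rng, 4000)
    b = list(a)
    for p in rng.choice(4000, size=200, replace=False):
        b[p] = rng.choice(list("ACGT"))
    b = "".join(b)
    sc = window_scan(_pair(a, b), window_len=500, step=500)
    total = sum(1 for x, y in zip(a, b) if x != y)
    assert sum(s for _, _, s in sc.windows) == total


def test_short_alignment_single_window_warns():
    with pytest.warns(UserWarning):
        sc = window_scan(_pair("ACGT" * 20, "ACGT" * 20))
    assert len(sc.windows) == 1 and sc.windows[0][1] == 80


def test_gap_columns_excluded_from_s():
    a = "A" * 600
    b = "-" * 10 + "A" * 590
    sc = window_scan(_pair(a, b))
    assert all(s == 0 for _, _, s in sc.windows)
    assert sc.gap_counts[0] == 10


# -- variable region calling -------------------------------------------------------

def test_no_window_reaches_threshold():
    sc = window_scan(_pair("A" * 2000, "A" * 2000))
    assert call_variable_regions(sc, threshold=6) == []


def test_two_disjoint_clusters_give_two_intervals(rng):
    a = random_dna(rng, 6000)
    b = list(a)
    rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
    for p in list(range(1000, 1100, 10)) + list(range(4500, 4600, 10)):
        b[p] = rot[b[p]]
    sc = window_scan(_pair(a, "".join(b)))
    iv = call_variable_regions(sc, threshold=6)
    assert len(iv) == 2
    assert iv[0][0] <= 1001 and iv[0][1] >= 1091
    assert iv[1][0] <= 4501 and iv[1][1] >= 4591


def test_threshold_zero_spans_alignment():
    sc = window_scan(_pair("A" * 2000, "A" * 2000))
    iv = call_variable_regions(sc, threshold=0)
    assert iv == [(1, 2000, 0)]


def test_interval_calls_stable_under_step_refinement(rng):
    a = random_dna(rng, 5000)
    b = list(a)
    rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
    for p in range(2000, 2300, 12):
        b[p] = rot[b[p]]
    b = "".join(b)
    coarse = call_variable_regions(window_scan(_pair(a, b), step=25), 6)
    fine = call_variable_regions(window_scan(_pair(a, b), step=5), 6)
    for cs, ce, _ in coarse:
        assert any(fs <= cs and ce <= fe for fs, fe, _ in fine)


# -- genotyping ---------------------------------------------------------------------

def test_example_allele_table_roundtrip(tmp_path):
    loci = mlst_example_loci()
    path = tmp_path / "alleles.tsv"
    write_allele_table(loci, MLST_STRAINS, path)
    back = read_allele_table(path)
    assert [(l.locus_id, l.interval) for l in back] == [(l.locus_id, l.interval) for l in loci]


def test_identical_strains_zero_differences():
    loci = [MlstLocus("L", (10, 20), [(10, {"a": "A", "b": "A"}), (20, {"a": "T", "b": "T"})])]
    profile, _ = genotype_mlst(loci)
    assert profile.difference_count("a", "b") == 0


def test_missing_allele_warns_and_is_excluded():
    loci = [MlstLocus("L", (10, 10), [(10, {"a": "A", "b": "C"})])]
    with pytest.warns(UserWarning):
        profile, _ = genotype_mlst(loci, ["a", "b", "c"])
    assert profile.vectors["c"] == ["?"]
    assert profile.difference_count("a", "c") == 0


def test_difference_counts_satisfy_triangle_inequality(rng):
    strains = ["s1", "s2", "s3", "s4"]
    variants = []
    for i in range(30):
        variants.append((i + 1, {s: rng.choice(list("ACGT-")) for s in strains}))
    loci = [MlstLocus("L", (1, 30), variants)]
    profile, _ = genotype_mlst(loci, strains)
    for a in strains:
        for b in strains:
            for c in strains:
                assert profile.difference_count(a, c) <= (
                    profile.difference_count(a, b) + profile.difference_count(b, c)
                )


def test_mlst_tree_separates_divergent_strain():
    loci = mlst_example_loci()
    profile, tree = genotype_mlst(loci, MLST_STRAINS)
    assert tree is not None
    # CCMP531 carries nearly all differences; IMET1 and CCMP1779 are nearly identical
    assert profile.difference_count("IMET1", "CCMP1779") < profile.difference_count(
        "CCMP531", "IMET1")


# -- end-to-end discovery on the conspecific-pair fixture ----------------------------

@pytest.fixture(scope="module")
def pair_fixture():
    cfg = conspecific_pair_config(seed=11)
    genomes, feats, truth, _ = build_fixture(cfg)
    return cfg, genomes, feats, truth


def test_hotspot_intervals_recovered(pair_fixture):
    cfg, genomes, feats, truth = pair_fixture
    loci, scan, aln = find_mlst_loci(
        genomes["REF"].sequence, genomes["ALT"].sequence, feats["REF"],
        ref_strain="REF", alt_strain="ALT",
    )
    # true hotspot spans on the REF genome
    ref_regions = replay(truth, "REF")
    spans, pos = [], 0
    for spec in cfg.blueprint:
        L = len(ref_regions[spec.name])
        if spec.rate_multiplier > 1:
            spans.append((pos + 1, pos + L))
        pos += L
    assert len(loci) == len(spans)
    for locus, (ts, te) in zip(loci, spans):
        ls, le = locus.interval
        inter = max(0, min(le, te) - max(ls, ts) + 1)
        union = max(le, te) - min(ls, ts) + 1
        assert inter / union >= 0.8


def test_genotype_matches_alignment_differences(pair_fixture):
    cfg, genomes, feats, truth = pair_fixture
    loci, _, aln = find_mlst_loci(
        genomes["REF"].sequence, genomes["ALT"].sequence, feats["REF"],
        ref_strain="REF", alt_strain="ALT",
    )
    profile, _ = genotype_mlst(loci)
    per_locus = locus_difference_counts(profile, "REF", "ALT")
    assert sum(per_locus.values()) == profile.difference_count("REF", "ALT")
    assert all(v > 0 for v in per_locus.values())
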