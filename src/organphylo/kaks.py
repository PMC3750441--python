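"""Nei-Gojobori (1986) synonymous/nonsynonymous substitution rates.

Counting method with equal-weight averaging over all minimal mutational
pathways between differing codons and Jukes-Cantor multiple-hit correction:

    ps = Sd / S,  pn = Nd / N,  d = -(3/4) * ln(1 - (4/3) * p)

Site counts S and N are averaged over the two sequences; mutations to stop
codons are excluded from the per-position site denominators and pathways
passing through a stop codon are discarded (each codon position still
contributes exactly one site, so S + N = 3 per codon).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from ._util import BASES, GAP, codon_table, translate_codon


@dataclass
class KaKsResult:
    gene_id: str
    pair: tuple[str, str]
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ks: float | None  # None when the JC correction is undefined (p >= 3/4)
    Ka: float | None
    ratio: float | None  # None when Ks is 0 or undefined
    n_codons: int


@lru_cache(maxsize=None)
def codon_sites(codon: str, table_id: int = 1) -> tuple[tuple[float, float, float], float, float]:
    """Per-position synonymous site fractions and the codon's (S, N) totals.

    The fraction at a position is (# of the 3 point mutations preserving the
    amino acid) / (# of the 3 that do not create a stop codon); positions where
    every mutation creates a stop count as fully nonsynonymous.
    """
    codon = codon.upper()
    tbl = codon_table(table_id)
    if codon in tbl.stop_codons:
        raise ValueError(f"codon_sites: stop codon {codon}")
    aa = translate_codon(codon, table_id)
    fracs = []
    for pos in range(3):
        syn = 0
        counted = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if mut in tbl.stop_codons:
                continue
            counted += 1
            if translate_codon(mut, table_id) == aa:
                syn += 1
        fracs.append(syn / counted if counted else 0.0)
    S = sum(fracs)
    return tuple(fracs), S, 3.0 - S


@lru_cache(maxsize=None)
def _pathway_counts(c1: str, c2: str, table_id: int = 1) -> tuple[float, float] | None:
    """(Sd, Nd) contribution of one differing codon pair, averaged over all
    minimal pathways not passing through stop codons; None if all pathways do."""
    tbl = codon_table(table_id)
    diff = [i for i in range(3) if c1[i] != c2[i]]
    paths = []
    for order in permutations(diff):
        cur = c1
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in tbl.stop_codons:
                ok = False
                break
            if translate_codon(cur, table_id) == translate_codon(nxt, table_id):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            paths.append((syn, nonsyn))
    if not paths:
        return None
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def _clean_codon_pairs(row_a: str, row_b: str) -> list[tuple[str, str]]:
    """Codon pairs after dropping codons containing gaps or N in either row."""
    if len(row_a) != len(row_b):
        raise ValueError("rows must be aligned (equal length)")
    pairs = []
    for i in range(0, len(row_a) - len(row_a) % 3, 3):
        ca, cb = row_a[i:i + 3], row_b[i:i + 3]
        if len(ca) < 3:
            break
        if any(ch not in BASES for ch in ca + cb):
            continue
        pairs.append((ca, cb))
    return pairs


def ng86(row_a: str, row_b: str, gene_id: str = "", pair: tuple[str, str] = ("a", "b"),
         table_id: int = 1) -> KaKsResult:
    """NG86 Ka/Ks for one aligned coding sequence pair.

    Rows must be codon-aligned; the alignment length is truncated to a codon
    multiple, codons containing gaps or N in either row are dropped pairwise,
    and codons that are stops in either sequence are skipped.
    """
    tbl = codon_table(table_id)
    pairs = [
        (ca, cb) for ca, cb in _clean_codon_pairs(row_a.upper(), row_b.upper())
        if ca not in tbl.stop_codons and cb not in tbl.stop_codons
    ]
    if not pairs:
        raise ValueError(f"{gene_id or 'ng86'}: zero comparable codons")

    S_a = N_a = S_b = N_b = 0.0
    Sd = Nd = 0.0
    used = 0
    for ca, cb in pairs:
        _, sa, na = codon_sites(ca, table_id)
        _, sb, nb = codon_sites(cb, table_id)
        contrib = _pathway_counts(ca, cb, table_id) if ca != cb else (0.0, 0.0)
        if contrib is None:
            warnings.warn(f"{gene_id or 'ng86'}: all pathways {ca}->{cb} hit stops; codon skipped")
            continue
        S_a += sa
        N_a += na
        S_b += sb
        N_b += nb
        Sd += contrib[0]
        Nd += contrib[1]
        used += 1
    if used == 0:
        raise ValueError(f"{gene_id or 'ng86'}: zero comparable codons")

    S_sites = (S_a + S_b) / 2.0
    N_sites = (N_a + N_b) / 2.0
    ps = Sd / S_sites if S_sites else 0.0
    pn = Nd / N_sites if N_sites else 0.0
    Ks = _jc_correct(ps)
    Ka = _jc_correct(pn)
    if Ks is None:
        warnings.warn(f"{gene_id or 'ng86'}: ps >= 3/4, Ks correction undefined")
    if Ka is None:
        warnings.warn(f"{gene_id or 'ng86'}: pn >= 3/4, Ka correction undefined")
    ratio = None
    if Ka is not None and Ks is not None and Ks > 0:
        ratio = Ka / Ks
    return KaKsResult(gene_id, pair, S_sites, N_sites, Sd, Nd, ps, pn, Ks, Ka, ratio, used)


def rate_summary(groups: dict[str, list[float]], round_pct: bool = True) -> dict:
    """Mean per-gene rate per group and all pairwise percentage ratios.

    ``groups`` maps a group name (e.g. compartment "pt", "mt", or "nuclear"
    from an external table) to per-gene rates. Ratios are reported as
    100 * mean(a) / mean(b), rounded to a whole percent by default.
    """
    means: dict[str, float] = {}
    for name, rates in groups.items():
        if not rates:
            warnings.warn(f"rate_summary: empty group {name!r} omitted")
            continue
        means[name] = sum(rates) / len(rates)
    ratios: dict[str, float] = {}
    for a in means:
        for b in means:
            if a == b or means[b] == 0:
                continue
            pct = 100.0 * means[a] / means[b]
            ratios[f"{a}/{b}"] = round(pct) if round_pct else pct
    return {"means": means, "ratios_pct": ratios}


def write_kaks_tsv(results: list[KaKsResult], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["gene", "strain_a", "strain_b", "S", "N", "Sd", "Nd", "Ka", "Ks", "ratio"])
        for r in results:
            w.writerow([
                r.gene_id, r.pair[0], r.pair[1],
                f"{r.S_sites:.3f}", f"{r.N_sites:.3f}", f"{r.Sd:.3f}", f"{r.Nd:.3f}",
                "" if r.Ka is None else f"{r.Ka:.6f}",
                "" if r.Ks is None else f"{r.Ks:.6f}",
                "" if r.ratio is None else f"{r.ratio:.4f}",
            ])
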