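"""Alignment of closely related sequences, p-distances and SNP classification.

Organelle genomes within a genus are nearly collinear and only a few percent
divergent, so global affine alignment (for regions) and unique-k-mer anchoring
(for whole genomes) are adequate; no local or rearrangement-aware alignment is
attempted. Multiple alignment is a deterministic center-star merge, which is
exact enough at these divergences and keeps once-a-gap-always-a-gap semantics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from ._util import GAP, MISSING, is_transition, translate_codon
from .genome_io import RegionSet

DEFAULT_SCORING = dict(match=1.0, mismatch=-1.0, gap_open=-4.0, gap_extend=-1.0)


@dataclass
class Alignment:
    """A gapped multiple alignment over {A,C,G,T,N,-}."""

    region_id: str
    order: list[str]
    rows: list[str]
    frame: int | None = None

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError(f"{self.region_id}: alignment needs >=2 rows")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise ValueError(f"{self.region_id}: unequal row lengths")
        if L == 0:
            raise ValueError(f"{self.region_id}: zero-length alignment")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def row(self, strain: str) -> str:
        return self.rows[self.order.index(strain)]

    def matrix(self) -> np.ndarray:
        """Rows as a (n, L) array of single characters."""
        return np.array([list(r) for r in self.rows])

    def subset(self, strains: list[str]) -> "Alignment":
        rows = [self.row(s) for s in strains]
        # drop columns that are all-gap in the subset
        arr = np.array([list(r) for r in rows])
        keep = ~(arr == GAP).all(axis=0)
        rows = ["".join(r) for r in arr[:, keep]]
        return Alignment(self.region_id, list(strains), rows, self.frame)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])

    def subset(self, strains: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(s) for s in strains]
        return DistanceMatrix(list(strains), self.d[np.ix_(idx, idx)])


@dataclass
class SNPRecord:
    column: int  # 1-based alignment column
    alleles: dict[str, str]
    klass: str  # transition | transversion | indel | multiallelic
    coding_effect: str | None = None  # synonymous | nonsynonymous | frameshift | triplet_indel


@dataclass
class SnpSummary:
    """Exact partition of variant alignment columns plus derived ratios."""

    n_transition: int
    n_transversion: int
    n_indel: int
    n_multiallelic: int = 0
    n_syn: int = 0
    n_nonsyn: int = 0

    @property
    def n_variant(self) -> int:
        return self.n_transition + self.n_transversion + self.n_indel + self.n_multiallelic

    @property
    def ts_tv_ratio(self) -> float:
        if self.n_transversion == 0:
            return float("nan")
        return self.n_transition / self.n_transversion

    @classmethod
    def from_counts(cls, n_transition: int, n_transversion: int, n_indel: int = 0,
                    n_multiallelic: int = 0, n_syn: int = 0, n_nonsyn: int = 0) -> "SnpSummary":
        return cls(n_transition, n_transversion, n_indel, n_multiallelic, n_syn, n_nonsyn)


def _aligner(match: float, mismatch: float, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = gap_open
    a.extend_gap_score = gap_extend
    return a


def pairwise_align(
    a: str,
    b: str,
    match: float = DEFAULT_SCORING["match"],
    mismatch: float = DEFAULT_SCORING["mismatch"],
    gap_open: float = DEFAULT_SCORING["gap_open"],
    gap_extend: float = DEFAULT_SCORING["gap_extend"],
) -> tuple[str, str]:
    """Global affine-gap alignment of two sequences; deterministic first optimum.

    Gap cost for a run of length L is gap_open + (L-1)*gap_extend.
    """
    if not a or not b:
        raise ValueError("pairwise_align: empty input sequence")
    aligner = _aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(a.upper(), b.upper())[0]
    return str(aln[0]), str(aln[1])


def anchored_align(g1: str, g2: str, k: int = 21, **scoring) -> Alignment:
    """Whole-genome pairwise alignment via unique shared k-mer anchor chaining.

    Anchors must be unique in both genomes; they are chained by longest
    increasing subsequence on the second genome's coordinates and the
    inter-anchor gaps are closed with :func:`pairwise_align`.
    """
    g1, g2 = g1.upper(), g2.upper()

    def unique_kmers(s: str) -> dict[str, int]:
        pos: dict[str, int] = {}
        dup: set[str] = set()
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if km in dup:
                continue
            if km in pos:
                del pos[km]
                dup.add(km)
            else:
                pos[km] = i
        return pos

    k1, k2 = unique_kmers(g1), unique_kmers(g2)
    shared = sorted((k1[m], k2[m]) for m in k1.keys() & k2.keys())

    # longest increasing subsequence on g2 coordinates (patience sorting)
    chain: list[tuple[int, int]] = []
    if shared:
        import bisect

        tails: list[int] = []
        back: list[int] = [0] * len(shared)
        tidx: list[int] = []
        for i, (_, y) in enumerate(shared):
            j = bisect.bisect_left(tails, y)
            if j == len(tails):
                tails.append(y)
                tidx.append(i)
            else:
                tails[j] = y
                tidx[j] = i
            back[i] = tidx[j - 1] if j > 0 else -1
        i = tidx[len(tails) - 1]
        while i != -1:
            chain.append(shared[i])
            i = back[i]
        chain.reverse()
        # enforce non-overlap of anchors in both genomes
        filtered: list[tuple[int, int]] = []
        for x, y in chain:
            if filtered and (x < filtered[-1][0] + k or y < filtered[-1][1] + k):
                continue
            filtered.append((x, y))
        chain = filtered

    if not chain:
        if max(len(g1), len(g2)) <= 50_000:
            r1, r2 = pairwise_align(g1, g2, **scoring)
            return Alignment("anchored", ["seq1", "seq2"], [r1, r2])
        raise ValueError("anchored_align: no unique shared anchors (non-collinear input?)")

    out1: list[str] = []
    out2: list[str] = []
    p1 = p2 = 0
    for x, y in chain:
        s1, s2 = g1[p1:x], g2[p2:y]
        if s1 and s2:
            r1, r2 = pairwise_align(s1, s2, **scoring)
            out1.append(r1)
            out2.append(r2)
        elif s1 or s2:
            out1.append(s1 + GAP * len(s2))
            out2.append(GAP * len(s1) + s2)
        out1.append(g1[x : x + k])
        out2.append(g2[y : y + k])
        p1, p2 = x + k, y + k
    s1, s2 = g1[p1:], g2[p2:]
    if s1 and s2:
        r1, r2 = pairwise_align(s1, s2, **scoring)
        out1.append(r1)
        out2.append(r2)
    elif s1 or s2:
        out1.append(s1 + GAP * len(s2))
        out2.append(GAP * len(s1) + s2)
    return Alignment("anchored", ["seq1", "seq2"], ["".join(out1), "".join(out2)])


def _merge_center_star(center: str, pairs: list[tuple[str, str]]) -> list[str]:
    """Merge pairwise (center, other) alignments on the center coordinate.

    Classic center-star: the master gap pattern of the center is the union of
    per-pair center gap patterns (once a gap, always a gap).
    """
    # per-pair: list of gap-run lengths inserted after each center residue
    # index i in [0, len(center)] = gaps before residue i (i == len -> trailing)
    n = len(center)
    ins = [[0] * (n + 1) for _ in pairs]
    for pi, (c_aln, _) in enumerate(pairs):
        ci = 0
        for ch in c_aln:
            if ch == GAP:
                ins[pi][ci] += 1
            else:
                ci += 1
    master = [max(col) for col in zip(*ins)] if pairs else [0] * (n + 1)

    rows: list[str] = []
    # center row under the master pattern
    out = []
    for i in range(n):
        out.append(GAP * master[i])
        out.append(center[i])
    out.append(GAP * master[n])
    rows.append("".join(out))

    for pi, (c_aln, s_aln) in enumerate(pairs):
        out = []
        ci = 0  # center residue index
        run = 0  # gap chars of s already emitted before residue ci in this pair
        for cch, sch in zip(c_aln, s_aln):
            if cch == GAP:
                out.append(sch)
                run += 1
            else:
                out.append(GAP * (master[ci] - run))
                out.append(sch)
                ci += 1
                run = 0
        out.append(GAP * (master[n] - run))
        # pad leading for residue positions where this pair had no insertions:
        # handled inline above via (master[ci] - run)
        rows.append("".join(out))
    return rows


def progressive_align(region: RegionSet, **scoring) -> Alignment:
    """Center-star multiple alignment of one orthologous region set.

    The center is the member minimizing summed pairwise p-distance (ties: input
    order). Output row order equals input strain order.
    """
    strains = region.strains
    seqs = [region.members[s] for s in strains]
    n = len(seqs)
    if n < 2:
        raise ValueError(f"{region.region_id}: need >=2 members")
    if len(set(seqs)) == 1:
        return Alignment(region.region_id, strains, list(seqs), region.frame)

    pair_aln: dict[tuple[int, int], tuple[str, str]] = {}
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r1, r2 = pairwise_align(seqs[i], seqs[j], **scoring)
            pair_aln[(i, j)] = (r1, r2)
            comp = [(a, b) for a, b in zip(r1, r2) if a != GAP and b != GAP]
            mism = sum(a != b for a, b in comp)
            dist[i, j] = dist[j, i] = mism / len(comp) if comp else 1.0

    center = int(np.argmin(dist.sum(axis=1)))
    others = [i for i in range(n) if i != center]
    pairs = []
    for j in others:
        a, b = (center, j) if center < j else (j, center)
        r1, r2 = pair_aln[(a, b)]
        if a != center:  # stored with center second
            r1, r2 = r2, r1
        pairs.append((r1, r2))
    merged = _merge_center_star(seqs[center], pairs)
    rows_by_index = {center: merged[0]}
    for j, row in zip(others, merged[1:]):
        rows_by_index[j] = row
    rows = [rows_by_index[i] for i in range(n)]
    return Alignment(region.region_id, strains, rows, region.frame)


def p_distance(aln: Alignment, deletion_mode: str = "pairwise") -> DistanceMatrix:
    """Proportion of differing sites per pair over comparable (non-gap, non-N) sites.

    deletion_mode "pairwise" excludes columns gapped/missing in either row of a
    pair; "complete" excludes columns gapped/missing in any row.
    """
    if deletion_mode not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion_mode {deletion_mode!r}")
    arr = aln.matrix()
    n = len(aln.order)
    ok = (arr != GAP) & (arr != MISSING)
    if deletion_mode == "complete":
        keep = ok.all(axis=0)
        arr = arr[:, keep]
        ok = ok[:, keep]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp = ok[i] & ok[j]
            nc = int(comp.sum())
            if nc == 0:
                raise ValueError(
                    f"{aln.region_id}: no comparable sites for pair "
                    f"({aln.order[i]}, {aln.order[j]})"
                )
            d[i, j] = d[j, i] = (arr[i, comp] != arr[j, comp]).sum() / nc
    return DistanceMatrix(list(aln.order), d)


def polymorphic_columns(aln: Alignment) -> np.ndarray:
    """Boolean mask of columns with >=2 distinct non-N characters (gaps contrast)."""
    arr = aln.matrix()
    L = aln.length
    mask = np.zeros(L, dtype=bool)
    for c in range(L):
        chars = {ch for ch in arr[:, c] if ch != MISSING}
        mask[c] = len(chars) >= 2
    return mask


def percent_difference(aln: Alignment, mode: str = "polymorphic") -> float:
    """Sensitivity index: % of variable columns (or mean pairwise p-distance x100).

    mode "polymorphic": 100 x (columns with >=2 distinct non-N characters,
    counting a gap/base contrast) / alignment length. mode "mean_pairwise":
    100 x mean off-diagonal p-distance.
    """
    if mode == "polymorphic":
        return 100.0 * polymorphic_columns(aln).mean()
    if mode == "mean_pairwise":
        dm = p_distance(aln)
        n = len(dm.labels)
        iu = np.triu_indices(n, 1)
        return 100.0 * float(dm.d[iu].mean())
    raise ValueError(f"unknown percent_difference mode {mode!r}")


def _column_codon_effect(aln: Alignment, col: int, ref_row: str, alt: str,
                         table_id: int = 1) -> str | None:
    """Effect of substituting `alt` at alignment column `col` in the reference row."""
    # map alignment column -> ungapped reference position
    ref_pos = sum(1 for ch in ref_row[:col] if ch != GAP)
    if ref_row[col] == GAP:
        return None
    ungapped = ref_row.replace(GAP, "")
    cstart = (ref_pos // 3) * 3
    codon = ungapped[cstart : cstart + 3]
    if len(codon) < 3 or any(ch not in "ACGT" for ch in codon):
        return None
    mutated = list(codon)
    mutated[ref_pos - cstart] = alt
    mutated = "".join(mutated)
    if any(ch not in "ACGT" for ch in mutated):
        return None
    try:
        return "synonymous" if translate_codon(codon, table_id) == translate_codon(mutated, table_id) else "nonsynonymous"
    except KeyError:
        return None


def classify_snps(
    aln: Alignment, frame: int | None = None, table_id: int = 1
) -> tuple[list[SNPRecord], SnpSummary]:
    """Classify variant alignment columns into the exact partition
    {transition, transversion, indel, multiallelic}; optionally annotate
    coding effects when a codon frame is known.

    Columns containing a gap are indels; biallelic base columns are transitions
    (purine<->purine, pyrimidine<->pyrimidine) or transversions; columns with
    >=3 distinct bases are tallied separately as multiallelic. N is missing and
    excluded from comparisons. Contiguous gap runs with length divisible by 3
    in a coding alignment are flagged triplet_indel, else frameshift.
    """
    frame = frame if frame is not None else aln.frame
    arr = aln.matrix()
    use_frame = frame is not None
    ref_row = aln.rows[0]
    if use_frame and len(ref_row.replace(GAP, "")) % 3 != 0:
        warnings.warn(f"{aln.region_id}: ungapped length not a codon multiple; coding effects omitted")
        use_frame = False

    # per-row gap runs (for triplet/frameshift calls)
    gap_run_len: dict[tuple[int, int], int] = {}  # (row, col) -> run length
    for ri, row in enumerate(aln.rows):
        c = 0
        while c < len(row):
            if row[c] == GAP:
                start = c
                while c < len(row) and row[c] == GAP:
                    c += 1
                for cc in range(start, c):
                    gap_run_len[(ri, cc)] = c - start
            else:
                c += 1

    records: list[SNPRecord] = []
    n_ts = n_tv = n_indel = n_multi = n_syn = n_nonsyn = 0
    for col in range(aln.length):
        column = arr[:, col]
        chars = {ch for ch in column if ch != MISSING}
        if len(chars) < 2:
            continue
        alleles = {s: arr[i, col] for i, s in enumerate(aln.order)}
        effect: str | None = None
        if GAP in chars:
            klass = "indel"
            n_indel += 1
            if use_frame:
                runs = {gap_run_len[(ri, col)] for ri in range(len(aln.rows)) if arr[ri, col] == GAP}
                effect = "triplet_indel" if all(r % 3 == 0 for r in runs) else "frameshift"
        elif len(chars) == 2:
            a, b = sorted(chars)
            if is_transition(a, b):
                klass = "transition"
                n_ts += 1
            else:
                klass = "transversion"
                n_tv += 1
            if use_frame:
                alt = b if ref_row[col] == a else a
                effect = _column_codon_effect(aln, col, ref_row, alt, table_id)
                if effect == "synonymous":
                    n_syn += 1
                elif effect == "nonsynonymous":
                    n_nonsyn += 1
        else:
            klass = "multiallelic"
            n_multi += 1
        records.append(SNPRecord(col + 1, alleles, klass, effect))
    return records, SnpSummary(n_ts, n_tv, n_indel, n_multi, n_syn, n_nonsyn)


def write_snp_tsv(records: list[SNPRecord], order: list[str], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["column", *order, "class", "effect"])
        for r in records:
            w.writerow([r.column, *[r.alleles[s] for s in order], r.klass, r.coding_effect or ""])
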