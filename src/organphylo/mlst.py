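"""Intraspecies typing: sliding-window discovery of variable regions between
two conspecific organelle genomes, and multi-locus sequence typing (MLST) of
additional strains at the discovered loci.

The window statistic S counts segregating columns (both characters non-gap and
differing); gap columns are excluded from S (segregating-site convention) and
tallied separately. Indel positions are retained as genotype characters ('-')
in allele tables. Report coordinates are 1-based positions on the designated
reference strain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._util import GAP, MISSING
from .align_dist import Alignment, DistanceMatrix, anchored_align, p_distance
from .genome_io import Feature


@dataclass
class WindowScan:
    windows: list[tuple[int, int, int]]  # (start, end, S), 1-based alignment coords
    window_len: int = 500
    step: int = 25
    gap_counts: list[int] = field(default_factory=list)


@dataclass
class MlstLocus:
    locus_id: str
    interval: tuple[int, int]  # 1-based reference coordinates, inclusive
    variant_positions: list[tuple[int, dict[str, str]]]  # (ref position, strain -> allele)

    def __post_init__(self) -> None:
        for pos, alleles in self.variant_positions:
            if not (self.interval[0] <= pos <= self.interval[1]):
                raise ValueError(f"{self.locus_id}: variant {pos} outside interval {self.interval}")
            bad = set(alleles.values()) - set("ACGT-")
            if bad:
                raise ValueError(f"{self.locus_id}: invalid alleles {sorted(bad)}")


@dataclass
class MlstProfile:
    strains: list[str]
    loci: list[str]
    vectors: dict[str, list[str]]  # strain -> allele vector across all variant positions
    positions: list[tuple[str, int]]  # (locus_id, ref position) per vector entry

    def difference_count(self, a: str, b: str) -> int:
        """Hamming distance between two strains' allele vectors (missing excluded)."""
        va, vb = self.vectors[a], self.vectors[b]
        return sum(1 for x, y in zip(va, vb) if x != "?" and y != "?" and x != y)

    def difference_matrix(self) -> DistanceMatrix:
        n = len(self.strains)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = self.difference_count(self.strains[i], self.strains[j])
        return DistanceMatrix(list(self.strains), d)


def window_scan(aln: Alignment, window_len: int = 500, step: int = 25) -> WindowScan:
    """Sliding-window count of segregating sites on a 2-row alignment."""
    if len(aln.rows) != 2:
        raise ValueError("window_scan expects a 2-row alignment")
    r1, r2 = aln.rows
    L = aln.length
    a = np.frombuffer(r1.encode(), dtype="S1")
    b = np.frombuffer(r2.encode(), dtype="S1")
    gapn = (a == b"-") | (b == b"-") | (a == b"N") | (b == b"N")
    seg = (a != b) & ~gapn
    gap = (a == b"-") | (b == b"-")

    if L < window_len:
        warnings.warn(f"alignment length {L} < window length {window_len}; single full window")
        return WindowScan([(1, L, int(seg.sum()))], window_len, step, [int(gap.sum())])

    cs = np.concatenate([[0], np.cumsum(seg)])
    cg = np.concatenate([[0], np.cumsum(gap)])
    windows = []
    gaps = []
    start = 0
    while True:
        end = start + window_len
        if end > L:
            break
        windows.append((start + 1, end, int(cs[end] - cs[start])))
        gaps.append(int(cg[end] - cg[start]))
        if end == L:
            break
        start += step
    # final partial window covering the tail if the step grid ran past the end
    last_end = windows[-1][1]
    if last_end < L:
        s0 = windows[-1][0] + step - 1
        windows.append((s0 + 1, L, int(cs[L] - cs[s0])))
        gaps.append(int(cg[L] - cg[s0]))
    return WindowScan(windows, window_len, step, gaps)


def call_variable_regions(scan: WindowScan, threshold: int = 6) -> list[tuple[int, int, int]]:
    """Merge windows with S >= threshold into maximal intervals.

    Overlapping or directly adjacent qualifying windows coalesce; each merged
    interval is reported with the maximum window S it contains.
    """
    hits = [(s, e, v) for s, e, v in scan.windows if v >= threshold]
    if not hits:
        return []
    merged: list[list[int]] = []
    for s, e, v in hits:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2] = max(merged[-1][2], v)
        else:
            merged.append([s, e, v])
    return [tuple(m) for m in merged]


def _alignment_to_ref_coords(ref_row: str) -> np.ndarray:
    """1-based reference-genome position per alignment column (0 where ref gapped)."""
    out = np.zeros(len(ref_row), dtype=int)
    p = 0
    for i, ch in enumerate(ref_row):
        if ch != GAP:
            p += 1
            out[i] = p
    return out


def name_interval(start_ref: int, end_ref: int, features: list[Feature]) -> str:
    """Locus name from annotation: the containing gene, or "left-right" flanks."""
    containing = [f for f in features if f.start <= start_ref and end_ref <= f.end]
    if containing:
        return containing[0].name
    overlapping = sorted(
        (f for f in features if f.start <= end_ref and f.end >= start_ref),
        key=lambda f: f.start,
    )
    if overlapping:
        return "-".join(dict.fromkeys(f.name for f in overlapping))
    left = max((f for f in features if f.end < start_ref), key=lambda f: f.end, default=None)
    right = min((f for f in features if f.start > end_ref), key=lambda f: f.start, default=None)
    lname = left.name if left else "start"
    rname = right.name if right else "end"
    return f"{lname}-{rname}"


def find_mlst_loci(
    ref_seq: str,
    alt_seq: str,
    ref_features: list[Feature] | None = None,
    ref_strain: str = "ref",
    alt_strain: str = "alt",
    window_len: int = 500,
    step: int = 25,
    threshold: int = 6,
    k: int = 21,
) -> tuple[list[MlstLocus], WindowScan, Alignment]:
    """Discover variable loci between two conspecific genomes.

    Aligns the genomes (unique-k-mer anchoring), scans windows, merges
    qualifying windows into intervals, and reports each interval's variant
    positions (substitutions and indel columns) on reference coordinates.
    """
    aln = anchored_align(ref_seq, alt_seq, k=k)
    aln = Alignment(aln.region_id, [ref_strain, alt_strain], aln.rows)
    scan = window_scan(aln, window_len, step)
    intervals = call_variable_regions(scan, threshold)
    ref_coords = _alignment_to_ref_coords(aln.rows[0])
    loci: list[MlstLocus] = []
    feats = ref_features or []
    for s, e, _ in intervals:
        variants: list[tuple[int, dict[str, str]]] = []
        last_ref = 0
        for c in range(s - 1, e):
            a, b = aln.rows[0][c], aln.rows[1][c]
            if a != GAP:
                last_ref = ref_coords[c]
            if a == b or MISSING in (a, b):
                continue
            pos = int(ref_coords[c]) if a != GAP else last_ref  # insertions map to prior ref base
            variants.append((pos, {ref_strain: a, alt_strain: b}))
        ref_positions = [p for p, _ in variants] or [int(ref_coords[s - 1]) or 1]
        lo, hi = min(ref_positions), max(ref_positions)
        name = name_interval(lo, hi, feats) if feats else f"region_{lo}-{hi}"
        loci.append(MlstLocus(name, (lo, hi), variants))
    return loci, scan, aln


def genotype_mlst(loci: list[MlstLocus], strains: list[str] | None = None):
    """Build per-strain allele vectors over all variant positions of the loci,
    pairwise difference counts and (for >=3 strains) an NJ tree on the
    concatenated allele vectors.

    Strains missing an allele at a position get "?" (excluded from counts) with
    a warning.
    """
    if strains is None:
        seen: dict[str, None] = {}
        for locus in loci:
            for _, alleles in locus.variant_positions:
                for s in alleles:
                    seen.setdefault(s)
        strains = list(seen)
    vectors: dict[str, list[str]] = {s: [] for s in strains}
    positions: list[tuple[str, int]] = []
    for locus in loci:
        for pos, alleles in locus.variant_positions:
            positions.append((locus.locus_id, pos))
            for s in strains:
                if s in alleles:
                    vectors[s].append(alleles[s])
                else:
                    warnings.warn(f"{locus.locus_id}@{pos}: no allele for strain {s}; set missing")
                    vectors[s].append("?")
    profile = MlstProfile(list(strains), [l.locus_id for l in loci], vectors, positions)

    tree = None
    if len(strains) >= 3 and positions:
        from .phylo import nj_tree

        n = len(strains)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = profile.difference_count(strains[i], strains[j]) / len(positions)
        tree = nj_tree(DistanceMatrix(list(strains), d))
    return profile, tree


def locus_difference_counts(profile: MlstProfile, a: str, b: str) -> dict[str, int]:
    """Per-locus allele difference counts between two strains."""
    out: dict[str, int] = {}
    for (locus, _), x, y in zip(profile.positions, profile.vectors[a], profile.vectors[b]):
        out.setdefault(locus, 0)
        if x != "?" and y != "?" and x != y:
            out[locus] += 1
    return out


def write_allele_table(loci: list[MlstLocus], strains: list[str], path) -> None:
    """Allele table, one row per variant position (1-based reference coords)."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["region", "location", *strains])
        for locus in loci:
            for pos, alleles in locus.variant_positions:
                w.writerow([locus.locus_id, pos, *[alleles.get(s, "?") for s in strains]])


def read_allele_table(text_or_path, from_string: bool = False) -> list[MlstLocus]:
    """Parse an allele table (TSV: region, location, one column per strain)."""
    import csv
    import io

    if from_string:
        fh = io.StringIO(text_or_path)
    else:
        fh = open(text_or_path)
    with fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    header = rows[0]
    strains = header[2:]
    by_locus: dict[str, list[tuple[int, dict[str, str]]]] = {}
    order: list[str] = []
    current = None
    for row in rows[1:]:
        if not row or not row[1].strip():
            continue
        region = row[0].strip() or current
        current = region
        if region not in by_locus:
            by_locus[region] = []
            order.append(region)
        pos = int(row[1])
        alleles = {s: v.strip() for s, v in zip(strains, row[2:])}
        by_locus[region].append((pos, alleles))
    loci = []
    for region in order:
        variants = by_locus[region]
        pos = [p for p, _ in variants]
        loci.append(MlstLocus(region, (min(pos), max(pos)), variants))
    return loci


def write_loci_bed(loci: list[MlstLocus], chrom: str, path) -> None:
    """Loci as BED (0-based half-open) on the reference strain."""
    with open(path, "w") as fh:
        for locus in loci:
            s, e = locus.interval
            fh.write(f"{chrom}\t{s - 1}\t{e}\t{locus.locus_id}\n")
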