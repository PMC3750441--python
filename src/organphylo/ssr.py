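"""Perfect microsatellite (SSR) detection and cross-strain comparison.

An SSR locus is a maximal perfect tandem repeat of a primitive 1-6 nt motif
meeting a per-unit-length minimum total length (defaults: mono and di >= 10 nt,
tri- through hexa- >= 12 nt). Motifs are canonicalized to their
lexicographically smallest rotation; a run is reported once, at the smallest
period consistent with primitivity (poly-A is mononucleotide, never (AA)).
Copy-number differences at orthologous loci distinguish strains within a
species.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._util import canonical_rotation, is_primitive
from .genome_io import Feature, GenomeRecord

DEFAULT_MIN_LEN = {1: 10, 2: 10, 3: 12, 4: 12, 5: 12, 6: 12}


@dataclass
class SsrLocus:
    genome: str
    organelle: str  # pt | mt
    motif: str  # canonical rotation
    unit_len: int
    copies: int
    total_len: int
    start: int  # 1-based inclusive
    end: int
    context: str  # genic | intergenic
    context_name: str

    def key(self) -> tuple[str, str, str]:
        """Orthology key for cross-strain comparison."""
        return (self.organelle, self.motif, self.context_name)


def _maximal_runs(seq: str, u: int) -> list[tuple[int, int]]:
    """Maximal periodic runs of period u: list of (start, repeat_region_len)."""
    n = len(seq)
    runs = []
    i = u
    while i < n:
        if seq[i] == seq[i - u]:
            j = i
            while j < n and seq[j] == seq[j - u]:
                j += 1
            runs.append((i - u, j - (i - u)))
            i = j + 1
        else:
            i += 1
    return runs


def _assign_context(start: int, end: int, features: list[Feature]) -> tuple[str, str]:
    containing = [f for f in features if f.start <= start and end <= f.end]
    if containing:
        return "genic", containing[0].name
    overlapping = [f for f in features if f.start <= end and f.end >= start]
    if overlapping:
        return "genic", overlapping[0].name
    left = max((f for f in features if f.end < start), key=lambda f: f.end, default=None)
    right = min((f for f in features if f.start > end), key=lambda f: f.start, default=None)
    lname = left.name if left else "start"
    rname = right.name if right else "end"
    return "intergenic", f"{lname}-{rname}"


def find_ssrs(
    genome: GenomeRecord,
    features: list[Feature] | None = None,
    min_len: dict[int, int] | None = None,
) -> list[SsrLocus]:
    """Scan one genome for perfect maximal SSRs (unit lengths 1-6).

    Circular genomes are scanned on the doubled sequence; loci crossing the
    origin are reported once with coordinates on the original sequence
    (end wraps past the genome length).
    """
    min_len = {**DEFAULT_MIN_LEN, **(min_len or {})}
    seq = genome.sequence.upper()
    n = len(seq)
    scan_seq = seq + seq if genome.circular else seq
    feats = features or []

    found: dict[tuple[int, int], SsrLocus] = {}
    for u in range(1, 7):
        thr = min_len.get(u)
        if thr is None:
            continue
        for run_start, run_len in _maximal_runs(scan_seq, u):
            copies = run_len // u
            total = copies * u
            if copies < 2 or total < thr:
                continue
            motif = scan_seq[run_start : run_start + u]
            if not is_primitive(motif):
                continue  # reported at its primitive period
            if any(ch not in "ACGT" for ch in motif):
                continue
            start0 = run_start
            if genome.circular:
                if start0 >= n:
                    continue  # duplicate of a locus already seen in the first copy
                if start0 + total > n and run_start == 0:
                    pass  # wrap locus anchored at origin is fine
            start = start0 + 1
            end = start0 + total  # may exceed n for origin-crossing loci
            ctx, ctx_name = _assign_context(start, min(end, n), feats)
            key = (start, u)
            prev = found.get(key)
            if prev is None or total > prev.total_len:
                found[key] = SsrLocus(
                    genome=genome.strain_id,
                    organelle=genome.compartment,
                    motif=canonical_rotation(motif),
                    unit_len=u,
                    copies=copies,
                    total_len=total,
                    start=start,
                    end=end,
                    context=ctx,
                    context_name=ctx_name,
                )
    # drop loci fully contained in the doubled-scan continuation of another locus
    loci = sorted(found.values(), key=lambda l: (l.start, l.unit_len))
    if genome.circular:
        uniq = []
        seen_keys = set()
        for l in loci:
            k = (l.motif, l.total_len, l.start % n)
            if k in seen_keys:
                continue
            seen_keys.add(k)
            uniq.append(l)
        loci = uniq
    return loci


def validate_locus(locus: SsrLocus, genome: GenomeRecord) -> bool:
    """Re-check a reported locus: exact integer motif copies, not extendable."""
    seq = genome.sequence
    n = len(seq)

    def at(i: int) -> str:
        return seq[i % n] if genome.circular else (seq[i] if 0 <= i < n else "")

    s0 = locus.start - 1
    region = "".join(at(s0 + i) for i in range(locus.total_len))
    unit = region[: locus.unit_len]
    if region != unit * locus.copies:
        return False
    if canonical_rotation(unit) != locus.motif:
        return False
    before = "".join(at(s0 - locus.unit_len + i) for i in range(locus.unit_len))
    after = "".join(at(s0 + locus.total_len + i) for i in range(locus.unit_len))
    if genome.circular or s0 - locus.unit_len >= 0:
        if before == unit:
            return False
    if genome.circular or s0 + locus.total_len + locus.unit_len <= n:
        if after == unit:
            return False
    return True


def compare_ssrs(per_strain: dict[str, list[SsrLocus]]):
    """Split SSR loci into shared (orthologous across all compared strains) and
    strain-specific sets; shared loci with differing lengths are flagged as
    copy-number polymorphic.

    Orthology key: (organelle, canonical motif, context locus name).
    Returns (shared, specific, polymorphic) where shared maps key -> per-strain
    loci, specific maps strain -> its private loci, and polymorphic is the
    subset of shared keys with length differences.
    """
    strains = list(per_strain)
    keyed = {
        s: {l.key(): l for l in loci} for s, loci in per_strain.items()
    }
    all_keys = set().union(*(set(k) for k in keyed.values())) if keyed else set()
    shared: dict[tuple, dict[str, SsrLocus]] = {}
    specific: dict[str, list[SsrLocus]] = {s: [] for s in strains}
    polymorphic: list[tuple] = []
    for key in sorted(all_keys):
        holders = [s for s in strains if key in keyed[s]]
        if len(holders) == len(strains):
            shared[key] = {s: keyed[s][key] for s in strains}
            lengths = {l.total_len for l in shared[key].values()}
            if len(lengths) > 1:
                polymorphic.append(key)
        else:
            for s in holders:
                specific[s].append(keyed[s][key])
    return shared, specific, polymorphic


def write_ssr_tsv(loci: list[SsrLocus], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["repeat", "length", "region", "locus", "organelle", "strain", "start", "end"])
        for l in loci:
            w.writerow([l.motif, l.total_len, l.context.capitalize(), l.context_name,
                        l.organelle, l.genome, l.start, l.end])


def write_ssr_bed(loci: list[SsrLocus], path) -> None:
    with open(path, "w") as fh:
        for l in loci:
            fh.write(f"{l.genome}\t{l.start - 1}\t{l.end}\t{l.motif}x{l.copies}\n")
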