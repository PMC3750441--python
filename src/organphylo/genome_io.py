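"""Genome and annotation I/O plus orthologous region extraction.

Circular organelle genomes are linearized at position 1 of their FASTA record;
features whose end coordinate is smaller than their start are interpreted as
wrapping the origin. Orthology between strains is keyed on exact feature-name
identity (organelle locus names are stable within a genus), so duplicated loci
must carry distinct names (e.g. ``psbV`` vs ``psbV_1``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import revcomp, to_internal

VALID_ALPHABET = frozenset("ACGTN")


@dataclass
class GenomeRecord:
    """One strain's organelle genome, linearized at FASTA position 1."""

    strain_id: str
    compartment: str  # "pt" or "mt"
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.strain_id}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValueError(f"{self.strain_id}: invalid characters {sorted(bad)}")
        if self.compartment not in ("pt", "mt"):
            raise ValueError(f"compartment must be 'pt' or 'mt', got {self.compartment!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def subsequence(self, start: int, end: int, wraps_origin: bool = False) -> str:
        """Extract by 1-based inclusive coordinates, honouring origin wrap."""
        s0, e0 = to_internal(start, end)
        if wraps_origin:
            if not self.circular:
                raise ValueError(f"{self.strain_id}: wrap requested on linear genome")
            return self.sequence[s0:] + self.sequence[:e0]
        return self.sequence[s0:e0]


@dataclass
class Feature:
    """An annotated locus on one genome (1-based inclusive, forward-strand coords)."""

    genome: str
    name: str
    ftype: str  # gene | tRNA | rRNA | orf
    start: int
    end: int
    strand: str = "+"
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("feature name must be nonempty")
        if self.start < 1:
            raise ValueError(f"{self.name}: start {self.start} < 1")
        if not self.wraps_origin and self.start > self.end:
            raise ValueError(f"{self.name}: start {self.start} > end {self.end} (not wrapping)")
        if self.strand not in "+-":
            raise ValueError(f"{self.name}: bad strand {self.strand!r}")

    def length(self, genome_len: int | None = None) -> int:
        if self.wraps_origin:
            if genome_len is None:
                raise ValueError("genome length needed for wrapped feature")
            return genome_len - self.start + 1 + self.end
        return self.end - self.start + 1

    def extract(self, genome: GenomeRecord) -> str:
        seq = genome.subsequence(self.start, self.end, self.wraps_origin)
        return revcomp(seq) if self.strand == "-" else seq


@dataclass
class RegionSet:
    """Orthologous sequences for one candidate marker region across strains."""

    region_id: str
    rtype: str  # genic | intergenic
    members: dict[str, str] = field(default_factory=dict)
    frame: int | None = None

    def __post_init__(self) -> None:
        if any(not s for s in self.members.values()):
            raise ValueError(f"{self.region_id}: empty member sequence")

    @property
    def strains(self) -> list[str]:
        return list(self.members)

    def __len__(self) -> int:
        return len(self.members)


_GFF_COLS = ["seqid", "source", "ftype", "start", "end", "score", "strand", "phase", "attributes"]
_FTYPE_MAP = {"gene": "gene", "trna": "tRNA", "rrna": "rRNA", "orf": "orf", "cds": "gene"}


def _parse_gff_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff(path: str | Path) -> list[Feature]:
    """Read the GFF3 subset used here (Name= attribute names the locus)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=_GFF_COLS,
        dtype={"start": int, "end": int}, na_filter=False,
    )
    feats = []
    for row in df.itertuples(index=False):
        attrs = _parse_gff_attributes(row.attributes)
        name = attrs.get("Name") or attrs.get("ID")
        if name is None:
            raise ValueError(f"{path}: feature without Name/ID attribute at {row.start}")
        ftype = _FTYPE_MAP.get(str(row.ftype).lower(), "gene")
        feats.append(
            Feature(
                genome=str(row.seqid), name=name, ftype=ftype,
                start=int(row.start), end=int(row.end),
                strand=row.strand if row.strand in "+-" else "+",
                # wraps_origin is re-derived against the genome in load_genomes;
                # a raw end < start in the file also flags a wrap
                wraps_origin=int(row.end) < int(row.start),
            )
        )
    return feats


def write_gff(features: Sequence[Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.genome}\t.\t{f.ftype}\t{f.start}\t{f.end}\t.\t{f.strand}\t.\tName={f.name}\n"
            )


def load_genomes(
    fasta_paths: Iterable[str | Path],
    gff_paths: Iterable[str | Path] = (),
    compartment: str = "pt",
    circular: bool = True,
) -> tuple[list[GenomeRecord], list[Feature]]:
    """Load FASTA genomes and GFF3 features, attaching features by sequence id.

    Raises on duplicate strain ids and on feature coordinates that exceed the
    genome length. ``wraps_origin`` is set whenever end < start on a circular
    genome.
    """
    genomes: list[GenomeRecord] = []
    seen: set[str] = set()
    for p in fasta_paths:
        for rec in SeqIO.parse(str(p), "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate strain_id {rec.id!r}")
            seen.add(rec.id)
            genomes.append(GenomeRecord(rec.id, compartment, str(rec.seq), circular))
    by_id = {g.strain_id: g for g in genomes}

    features: list[Feature] = []
    for p in gff_paths:
        for f in read_gff(p):
            g = by_id.get(f.genome)
            if g is None:
                raise ValueError(f"feature {f.name}: unknown genome {f.genome!r}")
            if f.start > len(g) or f.end > len(g):
                raise ValueError(
                    f"feature {f.name} on {f.genome}: coordinates "
                    f"{f.start}..{f.end} exceed genome length {len(g)}"
                )
            if f.wraps_origin and not g.circular:
                raise ValueError(f"feature {f.name}: wraps origin of linear genome {f.genome}")
            features.append(f)
    return genomes, features


def _sorted_features(features: Sequence[Feature], genome: str) -> list[Feature]:
    return sorted((f for f in features if f.genome == genome), key=lambda f: (f.start, f.end))


def extract_region_sets(
    genomes: Sequence[GenomeRecord],
    features: Sequence[Feature],
    min_members: int = 2,
) -> list[RegionSet]:
    """Build orthologous genic and intergenic region sets across strains.

    One genic set per feature name present in >= min_members strains
    (minus-strand members reverse-complemented); one intergenic set per
    ordered adjacent feature pair shared by >= min_members strains, named
    "<left>-<right>". Overlapping/adjacent features leave no spacer and the
    pair is omitted.
    """
    by_id = {g.strain_id: g for g in genomes}

    genic: dict[str, dict[str, str]] = {}
    spacers: dict[str, dict[str, str]] = {}
    for g in genomes:
        feats = _sorted_features(features, g.strain_id)
        for f in feats:
            genic.setdefault(f.name, {})[g.strain_id] = f.extract(g)
        # adjacent pairs on the linearized genome; wrapped features sort by start
        for left, right in zip(feats, feats[1:]):
            if left.wraps_origin:
                continue  # a wrapped feature has no well-defined right spacer here
            s, e = left.end + 1, right.start - 1
            if e < s:
                continue  # overlap or zero-length spacer
            spacers.setdefault(f"{left.name}-{right.name}", {})[g.strain_id] = g.subsequence(s, e)

    out: list[RegionSet] = []
    for name in sorted(genic):
        members = genic[name]
        if len(members) >= min_members:
            out.append(RegionSet(name, "genic", members, frame=0))
    for name in sorted(spacers):
        members = spacers[name]
        if len(members) >= min_members:
            out.append(RegionSet(name, "intergenic", members))
    if not out:
        warnings.warn("no shared features across strains; no region sets extracted")
    return out


def write_region_fasta(region: RegionSet, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=strain, description=region.region_id)
        for strain, seq in region.members.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_region_fasta(path: str | Path, region_id: str, rtype: str = "genic") -> RegionSet:
    members = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return RegionSet(region_id, rtype, members)
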