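"""Synthetic organelle-genome evolution along a known tree.

Generates an annotated ancestor (genes as valid ORFs, intergenic spacers at a
target GC, optional planted SSRs) and evolves it along a Newick tree with
per-region rate multipliers (hotspots), Kimura-style transition bias kappa,
purifying selection in coding regions (a proposed nonsynonymous change is
accepted with probability min(1, omega); synonymous changes always), and
indels that are forced to codon-length multiples inside genes. Every accepted
event is recorded in a machine-readable truth object so that each leaf can be
reproduced exactly by replay — the ground truth for all recovery tests.

Protein-altering events in genes (nonsynonymous substitutions and in-frame
indels, which insert or delete residues) are both gated by omega, so omega=0
leaves every gene's translation untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._util import BASES, translate_codon
from .genome_io import Feature, GenomeRecord, write_gff

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass
class RegionSpec:
    name: str
    rtype: str  # genic | intergenic
    length: int
    rate_multiplier: float = 1.0
    omega: float = 1.0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.name}: length must be positive")
        if self.rtype == "genic" and self.length % 3 != 0:
            raise ValueError(f"{self.name}: genic length must be a codon multiple")
        if self.omega < 0 or self.rate_multiplier < 0:
            raise ValueError(f"{self.name}: omega and rate_multiplier must be >= 0")


@dataclass
class PlantedSsr:
    motif: str
    copies: int
    region: str
    offset: int | None = None  # within-region 0-based; None = centered


@dataclass
class SimulationConfig:
    tree: str  # Newick with branch lengths in expected substitutions/site
    blueprint: list[RegionSpec]
    kappa: float = 1.5
    gc_target: float = 0.333
    indel_rate: float = 0.0  # per site per unit branch length
    triplet_only_in_genes: bool = True
    planted_ssrs: list[PlantedSsr] = field(default_factory=list)
    seed: int = 0
    compartment: str = "mt"
    table_id: int = 1

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        names = [r.name for r in self.blueprint]
        if len(names) != len(set(names)):
            raise ValueError("blueprint region names must be unique")


@dataclass
class MutationEvent:
    branch: str
    region: str
    kind: str  # sub | ins | del
    pos: int  # 0-based offset within the region at application time
    ref: str
    alt: str
    klass: str = ""  # transition | transversion | "" for indels


@dataclass
class SimTruth:
    topology: str
    leaf_paths: dict[str, list[str]]  # leaf -> ordered branch ids root->leaf
    events: list[MutationEvent]
    sub_counts: dict[str, dict[str, int]]  # branch -> region -> accepted substitutions
    planted_ssrs: list[dict]
    ancestor_regions: dict[str, str]
    blueprint: list[dict]


# ---------------------------------------------------------------------------
# ancestor construction
# ---------------------------------------------------------------------------

def _random_spacer(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def _random_orf(rng: np.random.Generator, length: int, table_id: int = 1) -> str:
    """A valid ORF: start codon, random sense codons, stop codon."""
    if length < 9:
        raise ValueError("genic region must be >= 9 nt (start + 1 codon + stop)")
    n_inner = length // 3 - 2
    codons = ["ATG"]
    while len(codons) < n_inner + 1:
        c = "".join(rng.choice(list(BASES), size=3))
        if translate_codon_safe(c, table_id) not in ("*", None):
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def translate_codon_safe(codon: str, table_id: int = 1) -> str | None:
    try:
        return translate_codon(codon, table_id)
    except KeyError:
        return None


def scrub_chance_ssrs(
    seq: str,
    rng: np.random.Generator,
    min_len: dict[int, int] | None = None,
    protected: list[tuple[int, int]] | None = None,
    max_iter: int = 100,
) -> str:
    """Break unintended perfect repeats so planted SSRs are the only loci
    at/above threshold (used by the SSR fixture; leaves protected intervals
    untouched)."""
    from .ssr import DEFAULT_MIN_LEN, find_ssrs

    min_len = {**DEFAULT_MIN_LEN, **(min_len or {})}
    protected = protected or []

    def in_protected(i: int) -> bool:
        return any(ps <= i < pe for ps, pe in protected)

    s = list(seq)
    for _ in range(max_iter):
        g = GenomeRecord("tmp", "mt", "".join(s), circular=False)
        hits = []
        for l in find_ssrs(g, [], min_len):
            span = range(l.start - 1, l.start - 1 + l.total_len)
            free = [i for i in span if not in_protected(i)]
            if free:  # anything not fully inside a protected plant gets broken
                hits.append((l, free))
        if not hits:
            return "".join(s)
        for l, free in hits:
            mid = free[len(free) // 2]
            cur = s[mid]
            s[mid] = rng.choice([b for b in BASES if b != cur])
    raise RuntimeError("scrub_chance_ssrs did not converge")


def generate_ancestor(config: SimulationConfig) -> tuple[dict[str, str], GenomeRecord, list[Feature]]:
    """Build the ancestral genome region-by-region, deterministically under seed.

    Returns (region sequences by name, concatenated GenomeRecord, gene Features).
    """
    rng = np.random.default_rng(config.seed)
    regions: dict[str, str] = {}
    for spec in config.blueprint:
        if spec.rtype == "genic":
            regions[spec.name] = _random_orf(rng, spec.length, config.table_id)
        else:
            regions[spec.name] = _random_spacer(rng, spec.length, config.gc_target)
    for plant in config.planted_ssrs:
        if plant.region not in regions:
            raise ValueError(f"planted SSR region {plant.region!r} not in blueprint")
        seq = regions[plant.region]
        ssr = plant.motif * plant.copies
        if len(ssr) + 2 > len(seq):
            raise ValueError(f"planted SSR {plant.motif}x{plant.copies} too long for {plant.region}")
        off = plant.offset if plant.offset is not None else (len(seq) - len(ssr)) // 2
        new = seq[:off] + ssr + seq[off + len(ssr):]
        # flank the plant with bases breaking the period so it stays maximal
        u = len(plant.motif)
        if off - 1 >= 0 and new[off - 1] == plant.motif[-1]:
            new = new[: off - 1] + _other_base(rng, plant.motif[-1]) + new[off:]
        j = off + len(ssr)
        if j < len(new) and new[j] == plant.motif[0]:
            new = new[:j] + _other_base(rng, plant.motif[0]) + new[j + 1:]
        regions[plant.region] = new
    genome, features = concat_regions(regions, config, strain_id="ancestor")
    return regions, genome, features


def _other_base(rng: np.random.Generator, base: str) -> str:
    return rng.choice([b for b in BASES if b != base])


def concat_regions(
    regions: dict[str, str], config: SimulationConfig, strain_id: str
) -> tuple[GenomeRecord, list[Feature]]:
    seq_parts: list[str] = []
    features: list[Feature] = []
    pos = 0
    for spec in config.blueprint:
        s = regions[spec.name]
        if spec.rtype == "genic":
            features.append(
                Feature(genome=strain_id, name=spec.name, ftype="gene",
                        start=pos + 1, end=pos + len(s), strand="+")
            )
        seq_parts.append(s)
        pos += len(s)
    return GenomeRecord(strain_id, config.compartment, "".join(seq_parts)), features


# ---------------------------------------------------------------------------
# evolution
# ---------------------------------------------------------------------------

def _propose_substitution(rng: np.random.Generator, base: str, kappa: float) -> tuple[str, str]:
    if rng.random() < kappa / (kappa + 2.0):
        return _TRANSITION[base], "transition"
    return rng.choice(list(_TRANSVERSIONS[base])), "transversion"


def _is_nonsynonymous(seq: str, pos: int, alt: str, table_id: int) -> bool:
    ci = pos // 3
    codon = seq[ci * 3 : ci * 3 + 3]
    if len(codon) < 3:
        return True
    mutated = codon[: pos % 3] + alt + codon[pos % 3 + 1 :]
    a = translate_codon_safe(codon, table_id)
    b = translate_codon_safe(mutated, table_id)
    return a != b


def _evolve_branch(
    regions: dict[str, str],
    branch_id: str,
    blen: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    events: list[MutationEvent],
    sub_counts: dict[str, dict[str, int]],
) -> dict[str, str]:
    out = dict(regions)
    counts: dict[str, int] = {}
    for spec in config.blueprint:
        seq = out[spec.name]
        L = len(seq)
        lam = blen * spec.rate_multiplier * L
        n_sub = int(rng.poisson(lam)) if lam > 0 else 0
        applied = 0
        for _ in range(n_sub):
            for _try in range(200):
                pos = int(rng.integers(L))
                base = seq[pos]
                if base not in _TRANSITION:
                    continue
                alt, klass = _propose_substitution(rng, base, config.kappa)
                if spec.rtype == "genic" and spec.omega < 1.0:
                    if _is_nonsynonymous(seq, pos, alt, config.table_id):
                        if rng.random() >= spec.omega:
                            continue  # rejected by selection; resample
                seq = seq[:pos] + alt + seq[pos + 1 :]
                events.append(MutationEvent(branch_id, spec.name, "sub", pos, base, alt, klass))
                applied += 1
                break
        counts[spec.name] = applied

        if config.indel_rate > 0:
            n_indel = int(rng.poisson(blen * config.indel_rate * len(seq)))
            for _ in range(n_indel):
                genic = spec.rtype == "genic"
                if genic and spec.omega < 1.0 and rng.random() >= spec.omega:
                    continue  # in-frame indels alter the protein; gated by omega
                ilen = 3 if (genic and config.triplet_only_in_genes) else int(rng.integers(1, 4))
                if rng.random() < 0.5 and len(seq) > ilen + 9:
                    # deletion; in genes keep it codon-aligned and clear of start/stop
                    if genic:
                        ncod = len(seq) // 3
                        ci = int(rng.integers(1, max(2, ncod - 2)))
                        pos = ci * 3
                    else:
                        pos = int(rng.integers(0, len(seq) - ilen + 1))
                    ref = seq[pos : pos + ilen]
                    seq = seq[:pos] + seq[pos + ilen :]
                    events.append(MutationEvent(branch_id, spec.name, "del", pos, ref, ""))
                else:
                    ins = "".join(rng.choice(list(BASES), size=ilen))
                    if genic:
                        ncod = len(seq) // 3
                        ci = int(rng.integers(1, max(2, ncod - 1)))
                        pos = ci * 3
                    else:
                        pos = int(rng.integers(0, len(seq) + 1))
                    seq = seq[:pos] + ins + seq[pos:]
                    events.append(MutationEvent(branch_id, spec.name, "ins", pos, "", ins))
        out[spec.name] = seq
    sub_counts[branch_id] = counts
    return out


def evolve(
    ancestor_regions: dict[str, str], config: SimulationConfig
) -> tuple[dict[str, GenomeRecord], dict[str, list[Feature]], SimTruth]:
    """Evolve the ancestor along the configured tree.

    Returns leaf genomes and features keyed by leaf label, plus the truth
    object (events, counts, topology, leaf paths) for replay and recovery
    checks. Randomness is independent of the ancestor draw (seed + 1).
    """
    import dendropy

    tree = dendropy.Tree.get(data=config.tree, schema="newick")
    leaves = [l.taxon.label.replace(" ", "_") for l in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("tree must have >= 2 leaves")

    rng = np.random.default_rng(config.seed + 1)
    events: list[MutationEvent] = []
    sub_counts: dict[str, dict[str, int]] = {}
    leaf_regions: dict[str, dict[str, str]] = {}
    leaf_paths: dict[str, list[str]] = {}

    counter = [0]

    def branch_id(node) -> str:
        if node.is_leaf():
            return node.taxon.label.replace(" ", "_")
        counter[0] += 1
        return f"node{counter[0]}"

    def rec(node, regions: dict[str, str], path: list[str]) -> None:
        for child in node.child_nodes():
            bid = branch_id(child)
            blen = child.edge.length or 0.0
            child_regions = _evolve_branch(regions, bid, blen, config, rng, events, sub_counts)
            if child.is_leaf():
                leaf_regions[bid] = child_regions
                leaf_paths[bid] = path + [bid]
            else:
                rec(child, child_regions, path + [bid])

    rec(tree.seed_node, dict(ancestor_regions), [])

    genomes: dict[str, GenomeRecord] = {}
    feats: dict[str, list[Feature]] = {}
    for leaf, regions in leaf_regions.items():
        g, f = concat_regions(regions, config, strain_id=leaf)
        genomes[leaf] = g
        feats[leaf] = f

    planted = []
    for p in config.planted_ssrs:
        off = p.offset if p.offset is not None else (len(ancestor_regions[p.region]) - len(p.motif) * p.copies) // 2
        planted.append({"motif": p.motif, "copies": p.copies, "region": p.region, "offset": off})
    truth = SimTruth(
        topology=config.tree,
        leaf_paths=leaf_paths,
        events=events,
        sub_counts=sub_counts,
        planted_ssrs=planted,
        ancestor_regions=dict(ancestor_regions),
        blueprint=[asdict(r) for r in config.blueprint],
    )
    return genomes, feats, truth


def replay(truth: SimTruth, leaf: str) -> dict[str, str]:
    """Reapply the recorded mutations along the leaf's root path; must
    reproduce the leaf's region sequences exactly."""
    regions = dict(truth.ancestor_regions)
    path = truth.leaf_paths[leaf]
    by_branch: dict[str, list[MutationEvent]] = {}
    for ev in truth.events:
        by_branch.setdefault(ev.branch, []).append(ev)
    for bid in path:
        for ev in by_branch.get(bid, []):
            seq = regions[ev.region]
            if ev.kind == "sub":
                if seq[ev.pos] != ev.ref:
                    raise AssertionError(f"replay mismatch at {ev.region}:{ev.pos}")
                seq = seq[: ev.pos] + ev.alt + seq[ev.pos + 1 :]
            elif ev.kind == "del":
                if seq[ev.pos : ev.pos + len(ev.ref)] != ev.ref:
                    raise AssertionError(f"replay del mismatch at {ev.region}:{ev.pos}")
                seq = seq[: ev.pos] + seq[ev.pos + len(ev.ref) :]
            else:
                seq = seq[: ev.pos] + ev.alt + seq[ev.pos :]
            regions[ev.region] = seq
    return regions


def write_fixture(
    genomes: dict[str, GenomeRecord],
    feats: dict[str, list[Feature]],
    truth: SimTruth,
    outdir: str | Path,
) -> dict[str, Path]:
    """FASTA + GFF3 per leaf, topology Newick and truth JSON, round-trip
    readable by genome_io."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for leaf, g in genomes.items():
        fa = outdir / f"{leaf}.fasta"
        with open(fa, "w") as fh:
            fh.write(f">{leaf}\n")
            for i in range(0, len(g.sequence), 70):
                fh.write(g.sequence[i : i + 70] + "\n")
        gff = outdir / f"{leaf}.gff3"
        write_gff(feats[leaf], gff)
        paths[f"{leaf}.fasta"] = fa
        paths[f"{leaf}.gff3"] = gff
    (outdir / "tree.nwk").write_text(truth.topology + "\n")
    tj = {
        "topology": truth.topology,
        "leaf_paths": truth.leaf_paths,
        "events": [asdict(e) for e in truth.events],
        "sub_counts": truth.sub_counts,
        "planted_ssrs": truth.planted_ssrs,
        "ancestor_regions": truth.ancestor_regions,
        "blueprint": truth.blueprint,
    }
    (outdir / "truth.json").write_text(json.dumps(tj, indent=1))
    paths["tree.nwk"] = outdir / "tree.nwk"
    paths["truth.json"] = outdir / "truth.json"
    return paths


def load_truth(path: str | Path) -> SimTruth:
    d = json.loads(Path(path).read_text())
    return SimTruth(
        topology=d["topology"],
        leaf_paths=d["leaf_paths"],
        events=[MutationEvent(**e) for e in d["events"]],
        sub_counts=d["sub_counts"],
        planted_ssrs=d["planted_ssrs"],
        ancestor_regions=d["ancestor_regions"],
        blueprint=d["blueprint"],
    )


# ---------------------------------------------------------------------------
# standard fixtures
# ---------------------------------------------------------------------------

HOTSPOT_REGIONS = ("gene04", "gene09", "spacer06")


def hotspot_config(seed: int = 0) -> SimulationConfig:
    """Six strains, three regions evolving at 5x the background rate: the
    marker-screen test bed (hotspots must top the sensitivity ranking)."""
    blueprint: list[RegionSpec] = []
    rng = np.random.default_rng(12345)  # fixed layout; seed only drives sequences
    for i in range(1, 13):
        glen = int(rng.integers(100, 200)) * 3
        blueprint.append(RegionSpec(f"gene{i:02d}", "genic", glen, omega=0.3))
        blueprint.append(RegionSpec(f"spacer{i:02d}", "intergenic", int(rng.integers(120, 240))))
    for r in blueprint:
        if r.name in HOTSPOT_REGIONS:
            r.rate_multiplier = 5.0
    tree = "((A:0.03,B:0.03):0.02,(C:0.03,D:0.03):0.02,(E:0.04,F:0.04):0.01);"
    return SimulationConfig(tree=tree, blueprint=blueprint, kappa=1.5,
                            indel_rate=0.0, seed=seed, compartment="mt")


def conspecific_pair_config(seed: int = 0) -> SimulationConfig:
    """Two conspecific strains (~0.1% background divergence) with three long
    high-rate regions: the MLST window-scan test bed."""
    blueprint: list[RegionSpec] = []
    rng = np.random.default_rng(54321)
    hot = {"hot1": 6000, "hot2": 6000, "hot3": 6000}
    layout = ["gene", "spacer"] * 6
    gi = si = 0
    hot_names = list(hot)
    for i, kind in enumerate(layout):
        if kind == "gene":
            gi += 1
            blueprint.append(RegionSpec(f"g{gi:02d}", "genic", int(rng.integers(200, 400)) * 3, omega=0.2))
        else:
            si += 1
            blueprint.append(RegionSpec(f"s{si:02d}", "intergenic", int(rng.integers(200, 500))))
        if i in (2, 6, 10):
            name = hot_names.pop(0)
            blueprint.append(RegionSpec(name, "intergenic", hot[name], rate_multiplier=25.0))
    tree = "(REF:0.0005,ALT:0.0005);"
    return SimulationConfig(tree=tree, blueprint=blueprint, kappa=1.5,
                            indel_rate=0.0, seed=seed, compartment="mt")


def ssr_panel_config(seed: int = 0) -> SimulationConfig:
    """Two strains with planted SSR loci (mono through tetra) at and above the
    detection thresholds; background scrubbed of chance repeats by the fixture
    builder."""
    blueprint = [
        RegionSpec("geneA", "genic", 600, omega=0.0),
        RegionSpec("spc1", "intergenic", 500),
        RegionSpec("geneB", "genic", 900, omega=0.0),
        RegionSpec("spc2", "intergenic", 700),
        RegionSpec("spc3", "intergenic", 600),
    ]
    plants = [
        PlantedSsr("A", 10, "spc1"),
        PlantedSsr("TA", 7, "spc2"),
        PlantedSsr("ACT", 5, "spc3", offset=60),
        PlantedSsr("T", 12, "spc3", offset=400),
        PlantedSsr("AGTC", 3, "spc2", offset=80),
    ]
    tree = "(S1:0.0,S2:0.0);"
    return SimulationConfig(tree=tree, blueprint=blueprint, kappa=1.5,
                            indel_rate=0.0, planted_ssrs=plants, seed=seed)


def build_fixture(config: SimulationConfig, scrub_ssr_background: bool = False):
    """Convenience: ancestor + evolve in one call. Returns
    (genomes, features, truth, ancestor_regions)."""
    regions, _, _ = generate_ancestor(config)
    if scrub_ssr_background:
        rng = np.random.default_rng(config.seed + 7)
        protected: dict[str, list[tuple[int, int]]] = {}
        for p in config.planted_ssrs:
            off = p.offset if p.offset is not None else (len(regions[p.region]) - len(p.motif) * p.copies) // 2
            protected.setdefault(p.region, []).append((off, off + len(p.motif) * p.copies))
        for name in list(regions):
            regions[name] = scrub_chance_ssrs(regions[name], rng, protected=protected.get(name, []))
        # scrub junctions too: check the concatenated genome and break leftovers
        cfg_names = [r.name for r in config.blueprint]
        for _ in range(20):
            genome, _ = concat_regions(regions, config, "tmp")
            from .ssr import find_ssrs

            leftovers = []
            n_tot = len(genome.sequence)
            g = GenomeRecord("tmp", config.compartment, genome.sequence, circular=True)
            offsets = {}
            pos = 0
            for nm in cfg_names:
                offsets[nm] = pos
                pos += len(regions[nm])
            prot_abs = [
                (offsets[nm] + s, offsets[nm] + e)
                for nm, spans in protected.items()
                for s, e in spans
            ]

            def in_prot(i: int) -> bool:
                return any(ps <= i < pe for ps, pe in prot_abs)

            for l in find_ssrs(g, []):
                free = [i % n_tot for i in range(l.start - 1, l.start - 1 + l.total_len)
                        if not in_prot(i % n_tot)]
                if free:
                    leftovers.append((l, free))
            if not leftovers:
                break
            for l, free in leftovers:
                mid = free[len(free) // 2]
                for nm in reversed(cfg_names):
                    if offsets[nm] <= mid:
                        rel = mid - offsets[nm]
                        s = regions[nm]
                        regions[nm] = s[:rel] + _other_base(rng, s[rel]) + s[rel + 1:]
                        break
    genomes, feats, truth = evolve(regions, config)
    return genomes, feats, truth, regions
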