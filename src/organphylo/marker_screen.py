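"""Interspecies marker discovery: evaluate every candidate genic/intergenic
region for phylogenetic consistency, sensitivity and specificity, and rank the
candidates against a baseline marker.

Definitions (per-region "Table 2 row"):
  sensitivity   = % nucleotide difference of the region's alignment
  specificity   = mean bootstrap support over the internal splits of the
                  region's own exhaustive-MP tree
  consistency   = the reference topology attains the minimum Fitch score among
                  all enumerated topologies for the region (ties allowed) —
                  exact under exhaustive search, so no tie-break heuristics
  distance      = Euclidean distance between the region's p-distance matrix and
                  the reference p-distance matrix (restricted to common strains)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .align_dist import (
    Alignment,
    DistanceMatrix,
    p_distance,
    percent_difference,
    progressive_align,
)
from .genome_io import RegionSet
from .phylo import ExhaustiveMP, Tree, matrix_euclidean, mp_bootstrap, nested_to_tree


@dataclass
class Reference:
    tree: Tree
    matrix: DistanceMatrix
    alignment: Alignment


@dataclass
class MarkerEvaluation:
    region_id: str
    origin: str  # pt | mt | nc
    size_range: tuple[int, int]
    pct_difference_interspecies: float
    pct_difference_intraspecies: float | None = None
    mean_bootstrap: float | None = None
    euclid_to_reference: float | None = None
    consistent: bool = False
    rank: int | None = None
    n_members: int = 0
    flags: list[str] = field(default_factory=list)


@dataclass
class ScreenReport:
    evaluations: list[MarkerEvaluation]
    baseline_id: str
    n_candidates: int
    n_above_baseline: int
    relative_gain_pct: dict[str, float]  # region_id -> 100*(marker - baseline)/baseline


def build_reference_tree(
    region_sets: list[RegionSet], compartment_strains: list[str] | None = None,
    bootstrap_B: int = 100, seed: int = 0,
) -> Reference:
    """Reference phylogeny from the concatenation of all genic regions.

    Each gene is aligned first, then the aligned genes are concatenated
    strain-wise; the reference tree is the exhaustive-MP tree of the
    concatenation and the reference matrix its p-distance matrix.
    """
    genic = [r for r in region_sets if r.rtype == "genic"]
    if not genic:
        raise ValueError("no genic regions supplied")
    shared = set(genic[0].strains)
    for r in genic[1:]:
        shared &= set(r.strains)
    if compartment_strains:
        shared &= set(compartment_strains)
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} strains share all genes; need >= 4")
    order = sorted(shared)
    parts: dict[str, list[str]] = {s: [] for s in order}
    for r in genic:
        sub = RegionSet(r.region_id, r.rtype, {s: r.members[s] for s in order}, r.frame)
        aln = progressive_align(sub)
        for s in order:
            parts[s].append(aln.row(s))
    rows = ["".join(parts[s]) for s in order]
    concat = Alignment("reference_concat", order, rows)
    tree, _ = mp_bootstrap(concat, B=bootstrap_B, seed=seed)
    return Reference(tree=tree, matrix=p_distance(concat), alignment=concat)


def evaluate_marker(
    region: RegionSet,
    reference: Reference,
    origin: str = "mt",
    conspecific_pairs: list[tuple[str, str]] | None = None,
    bootstrap_B: int = 100,
    seed: int = 0,
    pct_mode: str = "polymorphic",
) -> MarkerEvaluation:
    """One Table-2-style row for a candidate region.

    Regions with fewer than 4 members get sensitivity only (consistent=False).
    Markers covering fewer strains than the reference are compared on the
    common subset, and consistency requires the reference topology restricted
    to that subset to be MP-optimal for the marker.
    """
    sizes = [len(s) for s in region.members.values()]
    ev = MarkerEvaluation(
        region_id=region.region_id,
        origin=origin,
        size_range=(min(sizes), max(sizes)),
        pct_difference_interspecies=0.0,
        n_members=len(region),
    )
    aln = progressive_align(region)
    ev.pct_difference_interspecies = percent_difference(aln, mode=pct_mode)

    if conspecific_pairs:
        vals = []
        for a, b in conspecific_pairs:
            if a in region.members and b in region.members:
                pair = RegionSet(region.region_id, region.rtype,
                                 {a: region.members[a], b: region.members[b]})
                vals.append(percent_difference(progressive_align(pair), mode=pct_mode))
        if vals:
            ev.pct_difference_intraspecies = float(np.mean(vals))

    if len(region) < 4:
        ev.flags.append("too_few_members_for_tree")
        return ev

    common = sorted(set(region.strains) & set(reference.matrix.labels))
    if len(common) < 4:
        ev.flags.append("too_few_common_strains")
        return ev
    sub_aln = aln.subset(common) if set(common) != set(aln.order) else aln

    mp = ExhaustiveMP(sub_aln)
    tree, supports = mp_bootstrap(sub_aln, B=bootstrap_B, seed=seed, mp=mp)
    internal = list(supports.values())
    ev.mean_bootstrap = float(np.mean(internal)) if internal else 0.0

    marker_matrix = p_distance(sub_aln)
    ev.euclid_to_reference = matrix_euclidean(
        marker_matrix, reference.matrix.subset(common)
    )

    # consistency: the reference topology restricted to the common strains must
    # attain the minimal Fitch score among all topologies for this marker
    ref_splits = _restrict_splits(reference.tree.splits(), common)
    if not ref_splits:
        # reference is unresolved on this subset; an identical region cannot
        # support any split, so require the marker tree to be compatible
        ev.consistent = False
        ev.flags.append("reference_unresolved_on_subset")
        return ev
    best_score, _ = mp.best()
    ref_idx = _find_topology(mp, ref_splits)
    if ref_idx is None:
        ev.consistent = False
        ev.flags.append("reference_splits_incompatible")
    else:
        ref_score = float(mp.scores()[ref_idx])
        ev.consistent = bool(ref_score == best_score)
    if ev.pct_difference_interspecies == 0.0:
        # no signal: every topology ties; do not call such a region consistent
        ev.consistent = False
        ev.flags.append("invariant_region")
    return ev


def _restrict_splits(splits: frozenset, strains: list[str]) -> set[frozenset]:
    keep = set(strains)
    anchor = min(keep)
    out = set()
    n = len(keep)
    for sp in splits:
        side = frozenset(sp) & keep
        side = keep - side if anchor in side else side
        if 2 <= len(side) <= n - 2:
            out.add(frozenset(side))
    return out


def _find_topology(mp: ExhaustiveMP, ref_splits: set[frozenset]) -> int | None:
    for i, splits in enumerate(mp.topology_splits):
        if set(splits) == ref_splits:
            return i
    return None


def rank_markers(evaluations: list[MarkerEvaluation], baseline_id: str) -> ScreenReport:
    """Rank consistent markers by interspecies sensitivity (ties broken by mean
    bootstrap, then region id) and report each candidate's relative sensitivity
    gain over the baseline marker."""
    by_id = {e.region_id: e for e in evaluations}
    if baseline_id not in by_id:
        raise ValueError(f"baseline {baseline_id!r} not among evaluations")
    baseline = by_id[baseline_id]
    candidates = [e for e in evaluations if e.consistent]
    candidates.sort(
        key=lambda e: (
            -e.pct_difference_interspecies,
            -(e.mean_bootstrap if e.mean_bootstrap is not None else 0.0),
            e.region_id,
        )
    )
    for i, e in enumerate(candidates, start=1):
        e.rank = i
    base_pct = baseline.pct_difference_interspecies
    gains: dict[str, float] = {}
    if base_pct > 0:
        for e in candidates:
            gains[e.region_id] = 100.0 * (e.pct_difference_interspecies - base_pct) / base_pct
    n_above = sum(1 for e in candidates if e.pct_difference_interspecies > base_pct)
    ordered = candidates + [e for e in evaluations if not e.consistent]
    return ScreenReport(
        evaluations=ordered,
        baseline_id=baseline_id,
        n_candidates=len(candidates),
        n_above_baseline=n_above,
        relative_gain_pct=gains,
    )


def screen(
    region_sets: list[RegionSet],
    baseline: RegionSet,
    origins: dict[str, str] | None = None,
    conspecific_pairs: list[tuple[str, str]] | None = None,
    bootstrap_B: int = 100,
    seed: int = 0,
) -> ScreenReport:
    """Full marker screen: reference from all genic regions, one evaluation per
    region (plus the baseline), ranking against the baseline."""
    reference = build_reference_tree(region_sets, bootstrap_B=bootstrap_B, seed=seed)
    origins = origins or {}
    evals = []
    for r in region_sets:
        evals.append(
            evaluate_marker(
                r, reference, origin=origins.get(r.region_id, "mt"),
                conspecific_pairs=conspecific_pairs,
                bootstrap_B=bootstrap_B, seed=seed,
            )
        )
    evals.append(
        evaluate_marker(
            baseline, reference, origin=origins.get(baseline.region_id, "nc"),
            conspecific_pairs=conspecific_pairs,
            bootstrap_B=bootstrap_B, seed=seed,
        )
    )
    return rank_markers(evals, baseline.region_id)


def write_screen_tsv(report: ScreenReport, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["rank", "region", "origin", "size", "difference_pct",
                    "intraspecies_pct", "mean_bootstrap", "euclidean_distance",
                    "consistent", "gain_over_baseline_pct"])
        for e in report.evaluations:
            lo, hi = e.size_range
            w.writerow([
                e.rank if e.rank is not None else "",
                e.region_id, e.origin,
                f"{lo}" if lo == hi else f"{lo}-{hi}",
                f"{e.pct_difference_interspecies:.2f}",
                "" if e.pct_difference_intraspecies is None else f"{e.pct_difference_intraspecies:.2f}",
                "" if e.mean_bootstrap is None else f"{e.mean_bootstrap:.1f}",
                "" if e.euclid_to_reference is None else f"{e.euclid_to_reference:.3f}",
                int(e.consistent),
                f"{report.relative_gain_pct.get(e.region_id, float('nan')):.1f}"
                if e.region_id in report.relative_gain_pct else "",
            ])
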