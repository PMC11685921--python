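"""Genetic source assignment for rafts.

Filters a SNP genotype matrix, builds a neighbour-joining tree with
locus-bootstrap supports, and assigns query individuals to geographic
source zones by ascending the tree to the first well-supported node and
taking the geographic range of the reference samples in that clade.
NJ + bootstrap stands in for full ML phylogenetics: the assignment rule
only consumes topology and supports.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .drift import TargetZone, haversine_km

TIER_POPULATION = "population"
TIER_LOCALIZED = "localized_region"
TIER_BROAD = "broad_region"
TIER_UNASSIGNED = "unassigned"

__all__ = [
    "GenotypeMatrix",
    "SourceAssignment",
    "EmptyPanelError",
    "filter_genotypes",
    "genotype_distance",
    "build_support_tree",
    "assign_source",
    "assignment_to_zone",
]


class EmptyPanelError(ValueError):
    """All loci (or individuals) removed by filtering."""


@dataclasses.dataclass
class GenotypeMatrix:
    """Alt-allele dosage matrix (individuals x loci); NaN encodes missing.

    ``depths`` optionally holds per-cell read depths; ``coords`` maps
    reference individuals to (lat, lon) — query individuals are absent
    from ``coords``.
    """

    individuals: list[str]
    loci: list[str]
    genotypes: np.ndarray
    depths: np.ndarray | None = None
    coords: Mapping[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.shape != (len(self.individuals), len(self.loci)):
            raise ValueError("genotypes shape must be (individuals, loci)")
        called = self.genotypes[~np.isnan(self.genotypes)]
        if called.size and not np.all(np.isin(called, [0.0, 1.0, 2.0])):
            raise ValueError("genotypes must be 0, 1, 2 or missing (NaN)")
        if self.depths is not None:
            self.depths = np.asarray(self.depths, dtype=float)
            if self.depths.shape != self.genotypes.shape:
                raise ValueError("depths shape must match genotypes")
            if np.nanmin(self.depths) < 0:
                raise ValueError("depths must be >= 0")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def subset(self, ind_idx: np.ndarray, locus_idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            individuals=[self.individuals[i] for i in ind_idx],
            loci=[self.loci[j] for j in locus_idx],
            genotypes=self.genotypes[np.ix_(ind_idx, locus_idx)],
            depths=None if self.depths is None else self.depths[np.ix_(ind_idx, locus_idx)],
            coords=self.coords,
        )


@dataclasses.dataclass
class SourceAssignment:
    query: str
    tier: str
    locations: list[tuple[str, float, float]]  # (individual, lat, lon)
    anchor_support: float

    def __post_init__(self) -> None:
        if (self.tier == TIER_UNASSIGNED) != (len(self.locations) == 0):
            raise ValueError("unassigned iff empty locations")


def filter_genotypes(
    g: GenotypeMatrix,
    min_depth: int = 5,
    max_missing: float = 0.2,
    min_mac: int = 2,
    min_snps_per_ind: int = 5000,
) -> GenotypeMatrix:
    """Apply depth masking, then locus filters (missingness, MAC), then the
    per-individual minimum-SNP filter — in that order.
    """
    geno = g.genotypes.copy()
    if g.depths is not None and min_depth > 0:
        geno[g.depths < min_depth] = np.nan

    n_ind = geno.shape[0]
    missing_frac = np.isnan(geno).sum(axis=0) / n_ind
    with np.errstate(invalid="ignore"):
        alt = np.nansum(geno, axis=0)
        called = (~np.isnan(geno)).sum(axis=0)
    total_alleles = 2 * called
    mac = np.minimum(alt, total_alleles - alt)  # minor allele count
    keep_locus = (missing_frac <= max_missing) & (mac >= min_mac) & (called > 0)
    locus_idx = np.flatnonzero(keep_locus)
    if locus_idx.size == 0:
        raise EmptyPanelError("all loci removed by filtering")

    geno = geno[:, locus_idx]
    n_called_per_ind = (~np.isnan(geno)).sum(axis=1)
    ind_idx = np.flatnonzero(n_called_per_ind >= min_snps_per_ind)
    if ind_idx.size == 0:
        raise EmptyPanelError("all individuals removed by filtering")

    out = g.subset(ind_idx, locus_idx)
    out.genotypes = geno[ind_idx]
    return out


def genotype_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Mean |dosage_i - dosage_j| / 2 over co-called loci, per pair."""
    if g.n_individuals < 3:
        raise ValueError("need >= 3 individuals")
    geno = g.genotypes
    n = g.n_individuals
    called = ~np.isnan(geno)
    filled = np.where(called, geno, 0.0)
    dist = np.zeros((n, n))
    for i in range(n):
        co = called & called[i]  # (n, loci) co-called with i
        n_co = co.sum(axis=1)
        if (n_co[:i] == 0).any():
            j = int(np.flatnonzero(n_co[:i] == 0)[0])
            raise ValueError(
                f"individuals {g.individuals[i]!r} and {g.individuals[j]!r} "
                "share no co-called loci"
            )
        diff = np.abs(filled - filled[i])
        diff[~co] = 0.0
        with np.errstate(invalid="ignore"):
            row = diff.sum(axis=1) / (2.0 * np.maximum(n_co, 1))
        dist[i] = row
        dist[i, i] = 0.0
    dist = 0.5 * (dist + dist.T)  # exact symmetry against fp noise
    return DistanceMatrix(dist, ids=g.individuals)


def _bipartitions(tree: TreeNode, scope: frozenset) -> set[frozenset]:
    """Canonical non-trivial bipartitions projected onto ``scope`` tips."""
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips()) & scope
        canon = _canonical(side, scope)
        if canon is not None:
            out.add(canon)
    return out


def _canonical(side: frozenset, all_tips: frozenset) -> frozenset | None:
    other = all_tips - side
    if len(side) < 2 or len(other) < 2:
        return None
    if len(side) < len(other) or (
        len(side) == len(other) and tuple(sorted(side)) < tuple(sorted(other))
    ):
        return side
    return other


def build_support_tree(
    g: GenotypeMatrix,
    n_boot: int = 100,
    seed: int = 0,
    support_tips: Sequence[str] | None = None,
) -> TreeNode:
    """NJ tree on genotype distances with locus-bootstrap bipartition supports.

    Internal nodes carry a ``support`` attribute in percent (0-100); the
    result is deterministic given ``seed``.  With ``support_tips`` (e.g. the
    reference individuals), bipartitions are projected onto that tip subset
    before counting, so unstable placement of the remaining (query) tips
    does not erode support for reference structure.  Nodes whose
    (projected) bipartition is trivial get support ``None`` and are skipped
    by the assignment traversal.
    """
    if g.n_individuals < 4:
        raise ValueError("need >= 4 individuals")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    dm = genotype_distance(g)
    tree = nj(dm)
    try:
        tree = tree.root_at_midpoint()  # stable root so clade traversal grows gradually
    except Exception:
        pass
    scope = frozenset(support_tips) if support_tips is not None else frozenset(g.individuals)

    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(n_boot):
        idx = rng.integers(0, g.n_loci, size=g.n_loci)
        boot = GenotypeMatrix(
            individuals=g.individuals,
            loci=[g.loci[j] for j in idx],
            genotypes=g.genotypes[:, idx],
        )
        try:
            boot_tree = nj(genotype_distance(boot))
        except ValueError:
            continue  # a bootstrap replicate with an uncomputable pair
        for bp in _bipartitions(boot_tree, scope):
            counts[bp] = counts.get(bp, 0) + 1

    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips()) & scope
        canon = _canonical(side, scope)
        node.support = (
            None if canon is None else 100.0 * counts.get(canon, 0) / n_boot
        )
    tree.support = None  # root carries no bipartition
    return tree


def assign_source(
    tree: TreeNode,
    query: str,
    ref_coords: Mapping[str, tuple[float, float]],
    support_threshold: float = 80.0,
    pop_span_km: float = 25.0,
    regional_span_km: float = 250.0,
) -> SourceAssignment:
    """Ascend from ``query`` to the first node with support > threshold and
    return the geographic range of reference tips inside that clade.

    Tier is decided by the clade's spatial span: <= ``pop_span_km`` →
    population; <= ``regional_span_km`` → localized region; else broad.
    Reaching the root without a qualifying node → unassigned.
    """
    try:
        tip = tree.find(query)
    except Exception as exc:
        raise ValueError(f"query {query!r} not found in tree") from exc
    node = tip.parent
    while node is not None:
        support = getattr(node, "support", None)
        if support is not None and support > support_threshold:
            locs = [
                (t.name, *ref_coords[t.name])
                for t in node.tips()
                if t.name in ref_coords
            ]
            if locs:
                lats = np.array([l[1] for l in locs])
                lons = np.array([l[2] for l in locs])
                span = 0.0
                for i in range(len(locs)):
                    span = max(
                        span,
                        float(np.max(haversine_km(lats[i], lons[i], lats, lons))),
                    )
                if span <= pop_span_km:
                    tier = TIER_POPULATION
                elif span <= regional_span_km:
                    tier = TIER_LOCALIZED
                else:
                    tier = TIER_BROAD
                return SourceAssignment(
                    query=query, tier=tier, locations=locs, anchor_support=float(support)
                )
        node = node.parent
    return SourceAssignment(
        query=query, tier=TIER_UNASSIGNED, locations=[], anchor_support=0.0
    )


def assignment_to_zone(
    a: SourceAssignment,
    coastline: Sequence[tuple[float, float]],
    buffer_km: float = 2.0,
) -> TargetZone:
    """Coastline segment spanned by the two most distant assigned locations.

    The coastline is an ordered (lat, lon) point sequence; the zone is every
    coastline point between (inclusive) the nearest coastline points to the
    two most distant assigned locations, with ``buffer_km`` as hit radius.
    Ties in the distance are broken by first occurrence in tip order.
    """
    if a.tier == TIER_UNASSIGNED or not a.locations:
        raise ValueError(
            f"query {a.query!r} is unassigned; skip drift modelling for it"
        )
    coast = np.asarray(coastline, dtype=float)
    lats = np.array([l[1] for l in a.locations])
    lons = np.array([l[2] for l in a.locations])
    best = (0, 0)
    best_d = -1.0
    for i in range(len(lats)):
        for j in range(i, len(lats)):
            d = float(haversine_km(lats[i], lons[i], lats[j], lons[j]))
            if d > best_d:  # strict: ties keep earliest pair in tip order
                best_d = d
                best = (i, j)
    i, j = best

    def nearest_idx(lat, lon):
        return int(np.argmin(haversine_km(lat, lon, coast[:, 0], coast[:, 1])))

    a_idx = nearest_idx(lats[i], lons[i])
    b_idx = nearest_idx(lats[j], lons[j])
    lo, hi = min(a_idx, b_idx), max(a_idx, b_idx)
    seg = coast[lo : hi + 1]
    return TargetZone(lats=seg[:, 0], lons=seg[:, 1], hit_radius_km=buffer_km)
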