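"""Microbiome table analyses.

Rarefaction, alpha diversity (richness, Shannon, Pielou), Bray-Curtis
dissimilarity, PCoA-based dysbiosis scoring, core / abundant / rare
partitioning by incremental Bray-Curtis contribution, and the
community-weighted rRNA operon trait.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa

STATUS_RAFT = "raft"
STATUS_NON_RAFT = "non_raft"
STATUS_SEAWATER = "seawater"

CLASS_CORE = "core"
CLASS_ABUNDANT = "abundant"
CLASS_RARE = "rare"

__all__ = [
    "CommunityTable",
    "TaxonClassification",
    "rarefy",
    "alpha_diversity",
    "bray_curtis",
    "dysbiosis_score",
    "core_taxa",
    "classify_and_partition",
    "weighted_rrna_trait",
    "merge_replicates",
]


@dataclasses.dataclass
class CommunityTable:
    """ASV counts (samples x taxa) with per-sample metadata.

    ``counts``: DataFrame indexed by sample, columns = taxa, integer counts.
    ``metadata``: DataFrame indexed by sample with at least a ``status``
    column (raft | non_raft | seawater); raft covariates (raft_time, sst,
    sigma_sst) and ``population`` live here too.
    ``taxonomy``: optional Series taxon -> genus.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be >= 0")
        missing = set(self.counts.index) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)[:5]}")
        if "status" not in self.metadata.columns:
            raise ValueError("metadata must have a 'status' column")
        self.metadata = self.metadata.loc[self.counts.index]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    def select(self, sample_ids: Iterable[str]) -> "CommunityTable":
        ids = list(sample_ids)
        return CommunityTable(
            counts=self.counts.loc[ids].copy(),
            metadata=self.metadata.loc[ids].copy(),
            taxonomy=self.taxonomy,
        )

    def by_status(self, status: str) -> "CommunityTable":
        return self.select(self.metadata.index[self.metadata["status"] == status])


@dataclasses.dataclass
class TaxonClassification:
    classes: pd.Series  # taxon -> core | abundant | rare
    abundance_cutoff: float
    core_stop_fraction: float


def merge_replicates(t: CommunityTable, group_col: str) -> CommunityTable:
    """Sum counts of replicate samples sharing ``metadata[group_col]``."""
    groups = t.metadata[group_col]
    counts = t.counts.groupby(groups).sum()
    meta = t.metadata.groupby(groups).first()
    counts.index.name = None
    meta.index.name = None
    return CommunityTable(counts=counts, metadata=meta, taxonomy=t.taxonomy)


def rarefy(t: CommunityTable, depth: int = 4000, seed: int = 0) -> CommunityTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped.  Deterministic given
    ``seed``.
    """
    if depth <= 0:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    rows = {}
    for sample, row in t.counts.iterrows():
        vec = row.to_numpy(dtype=np.int64)
        total = int(vec.sum())
        if total < depth:
            continue
        if total == depth:
            rows[sample] = vec
        else:
            rows[sample] = rng.multivariate_hypergeometric(vec, depth)
    if not rows:
        raise ValueError(f"no sample has >= {depth} reads")
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=t.counts.columns)
    counts = counts.loc[[s for s in t.counts.index if s in rows]]
    return CommunityTable(
        counts=counts, metadata=t.metadata.loc[counts.index], taxonomy=t.taxonomy
    )


def alpha_diversity(t: CommunityTable) -> pd.DataFrame:
    """Per-sample richness, Shannon entropy (nats) and Pielou's evenness.

    Pielou is NaN (flagged undefined) when richness <= 1.
    """
    out = []
    for sample, row in t.counts.iterrows():
        vec = row.to_numpy(dtype=float)
        present = vec[vec > 0]
        richness = int(len(present))
        if richness == 0:
            out.append((sample, 0, np.nan, np.nan))
            continue
        p = present / present.sum()
        shannon = float(-(p * np.log(p)).sum())
        pielou = shannon / np.log(richness) if richness > 1 else np.nan
        out.append((sample, richness, shannon, pielou))
    return pd.DataFrame(
        out, columns=["sample", "richness", "shannon", "pielou"]
    ).set_index("sample")


def bray_curtis(t: CommunityTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples."""
    mat = t.counts.to_numpy(dtype=float)
    if (mat.sum(axis=1) == 0).any():
        empty = t.counts.index[mat.sum(axis=1) == 0]
        raise ValueError(f"empty sample(s): {list(empty)}")
    d = squareform(pdist(mat, metric="braycurtis"))
    return DistanceMatrix(d, ids=t.samples)


def _pcoa_embedding(d: DistanceMatrix) -> pd.DataFrame:
    """Principal-coordinates embedding keeping positive-eigenvalue axes."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # skbio dimensionality chatter
        res = pcoa(d, method="eigh")
    keep = res.eigvals.to_numpy() > 1e-10
    return res.samples.iloc[:, np.flatnonzero(keep)].set_axis(list(d.ids), axis=0)


def dysbiosis_score(
    d: DistanceMatrix,
    labels: Mapping[str, str] | pd.Series,
    reference_filter: Sequence[str] | None = None,
) -> pd.Series:
    """Signed distance difference in PCoA space: d(non-raft centroid) −
    d(raft centroid); values > 0 indicate departure from the non-raft state.

    ``reference_filter`` optionally restricts which non-raft samples define
    the reference centroid.
    """
    labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
    emb = _pcoa_embedding(d)
    nonraft_ids = [s for s in d.ids if labels.get(s) == STATUS_NON_RAFT]
    if reference_filter is not None:
        keep = set(reference_filter)
        nonraft_ids = [s for s in nonraft_ids if s in keep]
    raft_ids = [s for s in d.ids if labels.get(s) == STATUS_RAFT]
    if len(nonraft_ids) < 2 or len(raft_ids) < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {len(nonraft_ids)} non-raft "
            f"and {len(raft_ids)} raft"
        )
    c_non = emb.loc[nonraft_ids].mean(axis=0).to_numpy()
    c_raft = emb.loc[raft_ids].mean(axis=0).to_numpy()
    pts = emb.to_numpy()
    scores = np.linalg.norm(pts - c_non, axis=1) - np.linalg.norm(pts - c_raft, axis=1)
    return pd.Series(scores, index=list(d.ids), name="dysbiosis")


def _mean_partial_bc(mat: np.ndarray, cols: np.ndarray) -> float:
    """Mean over sample pairs of the Bray-Curtis numerator restricted to
    ``cols`` over the full-pair denominator: monotone in the column set and
    equal to full Bray-Curtis when all columns are included."""
    sub = mat[:, cols]
    num = pdist(sub, metric="cityblock")
    totals = mat.sum(axis=1)
    n = len(totals)
    iu = np.triu_indices(n, k=1)
    den = totals[iu[0]] + totals[iu[1]]
    return float(np.mean(num / den))


def occupancy_rank(
    t: CommunityTable, population_col: str = "population"
) -> pd.DataFrame:
    """Site-weighted occupancy ranking used to order candidate core taxa.

    Index = mean of overall occupancy and mean per-population occupancy;
    ties broken by mean relative abundance, then taxon label.
    """
    mat = t.counts.to_numpy(dtype=float)
    present = mat > 0
    overall_occ = present.mean(axis=0)
    if population_col in t.metadata.columns:
        pops = t.metadata[population_col]
        pop_occ = np.zeros(mat.shape[1])
        groups = list(pops.groupby(pops).groups.values())
        for idx in groups:
            rows = [t.counts.index.get_loc(s) for s in idx]
            pop_occ += present[rows].mean(axis=0)
        pop_occ /= len(groups)
    else:
        pop_occ = overall_occ
    rel = mat / mat.sum(axis=1, keepdims=True)
    mean_rel = rel.mean(axis=0)
    df = pd.DataFrame(
        {
            "rank_index": (overall_occ + pop_occ) / 2.0,
            "occupancy": overall_occ,
            "mean_rel_abundance": mean_rel,
        },
        index=t.counts.columns,
    )
    df["taxon"] = df.index
    df = df.sort_values(
        by=["rank_index", "mean_rel_abundance", "taxon"],
        ascending=[False, False, True],
    ).drop(columns="taxon")
    return df


def core_taxa(
    t_nonraft: CommunityTable,
    stop_fraction: float = 0.03,
    min_occupancy: float = 0.8,
    enforce_occupancy: bool = False,
    population_col: str = "population",
) -> pd.DataFrame:
    """Occupancy-ranked core set by incremental Bray-Curtis contribution.

    Taxa are ranked by :func:`occupancy_rank`; walking down the ranking,
    the explained proportion at rank i is mean pairwise Bray-Curtis on the
    top-i taxa divided by mean Bray-Curtis on the full table.  The core is
    the smallest prefix after which the marginal gain drops below
    ``stop_fraction``.  Returns the ranked core with occupancy; with
    ``enforce_occupancy`` taxa below ``min_occupancy`` are excluded,
    otherwise occupancy >= ``min_occupancy`` is reported for checking.
    """
    if t_nonraft.counts.shape[0] < 4:
        raise ValueError("need >= 4 samples for pairwise dissimilarity curve")
    ranking = occupancy_rank(t_nonraft, population_col=population_col)
    mat = t_nonraft.counts.to_numpy(dtype=float)
    col_index = {tx: i for i, tx in enumerate(t_nonraft.counts.columns)}
    full_bc = _mean_partial_bc(mat, np.arange(mat.shape[1]))
    if full_bc == 0:
        raise ValueError("all samples identical; core undefined")

    ranked = list(ranking.index)
    explained = []
    cols: list[int] = []
    core_size = 1
    for i, tx in enumerate(ranked):
        cols.append(col_index[tx])
        e = _mean_partial_bc(mat, np.array(cols)) / full_bc
        explained.append(e)
        if i >= 1:
            gain = explained[i] - explained[i - 1]
            if gain < stop_fraction:
                core_size = i  # prefix before this rank
                break
            core_size = i + 1
    core = ranking.iloc[:core_size].copy()
    core["explained"] = explained[:core_size]
    if enforce_occupancy:
        core = core[core["occupancy"] >= min_occupancy]
    return core


def classify_and_partition(
    t: CommunityTable,
    core: Iterable[str],
    abundance_cutoff: float = 0.001,
    reference_status: str = STATUS_NON_RAFT,
) -> tuple[TaxonClassification, pd.DataFrame]:
    """Three-way core/abundant/rare classification plus per-sample read
    fractions in each class.

    Mean relative abundances for the abundant/rare split are computed on the
    reference (non-raft) samples; fractions sum to 1 per sample.
    """
    core = set(core)
    unknown = core - set(t.counts.columns)
    if unknown:
        raise ValueError(f"core taxa absent from table: {sorted(unknown)[:5]}")
    ref = t.by_status(reference_status)
    rel = ref.counts.div(ref.counts.sum(axis=1), axis=0)
    mean_rel = rel.mean(axis=0)

    def classify(tx: str) -> str:
        if tx in core:
            return CLASS_CORE
        return CLASS_ABUNDANT if mean_rel[tx] > abundance_cutoff else CLASS_RARE

    classes = pd.Series({tx: classify(tx) for tx in t.counts.columns}, name="class")
    totals = t.counts.sum(axis=1)
    fracs = pd.DataFrame(index=t.counts.index)
    for cls in (CLASS_CORE, CLASS_ABUNDANT, CLASS_RARE):
        taxa = classes.index[classes == cls]
        fracs[cls] = t.counts[taxa].sum(axis=1) / totals
    return (
        TaxonClassification(
            classes=classes,
            abundance_cutoff=abundance_cutoff,
            core_stop_fraction=np.nan,
        ),
        fracs,
    )


def weighted_rrna_trait(
    t: CommunityTable, traits: Mapping[str, float] | pd.Series
) -> pd.Series:
    """Community-weighted mean rRNA operon count per sample.

    Counts are aggregated to genus; genera without a trait value are
    excluded and weights renormalized.  Samples with no known genus get NaN.
    Genus matching is case-insensitive exact.
    """
    if t.taxonomy is None:
        raise ValueError("genus annotations (taxonomy) required")
    traits = pd.Series(dict(traits) if not isinstance(traits, pd.Series) else traits)
    trait_lookup = {str(g).lower(): float(v) for g, v in traits.items()}
    genus = t.taxonomy.reindex(t.counts.columns)
    genus_counts = t.counts.T.groupby(genus.values).sum().T
    values = np.array(
        [trait_lookup.get(str(g).lower(), np.nan) for g in genus_counts.columns]
    )
    known = ~np.isnan(values)
    out = {}
    for sample, row in genus_counts.iterrows():
        w = row.to_numpy(dtype=float)[known]
        if w.sum() == 0:
            out[sample] = np.nan
        else:
            out[sample] = float(np.average(values[known], weights=w))
    return pd.Series(out, name="rrna_trait")
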