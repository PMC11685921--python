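"""Null-model partitioning of community assembly processes.

Taxa are grouped into phylogenetic bins; per sample pair and bin, the
abundance-weighted beta mean-nearest-taxon distance is standardized
against a within-bin taxon shuffle (βNTI) and paired with a Raup-Crick
metric on Bray-Curtis (RCbray).  A decision tree maps the two metrics to
five processes — heterogeneous / homogeneous selection, dispersal
limitation, homogenizing dispersal, drift — and pair-level calls are
aggregated to group fractions with abundance bin weights.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .community import STATUS_NON_RAFT, STATUS_RAFT, CommunityTable

P_HETERO_SEL = "heterogeneous_selection"
P_HOMO_SEL = "homogeneous_selection"
P_DISP_LIM = "dispersal_limitation"
P_HOMO_DISP = "homogenizing_dispersal"
P_DRIFT = "drift"
PROCESSES = (P_HETERO_SEL, P_HOMO_SEL, P_DISP_LIM, P_HOMO_DISP, P_DRIFT)

__all__ = [
    "PhyloBin",
    "PairProcess",
    "bin_tree",
    "bnti_pair",
    "rcbray_pair",
    "partition_processes",
    "PROCESSES",
]


@dataclasses.dataclass
class PhyloBin:
    bin_id: int
    taxa: list[str]
    dmat: np.ndarray  # cophenetic distances among member taxa (taxon order)

    @property
    def size(self) -> int:
        return len(self.taxa)

    def index_of(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.taxa)}


@dataclasses.dataclass
class PairProcess:
    sample_a: str
    sample_b: str
    bin_id: int
    bnti: float
    rcbray: float
    process: str
    weight: float


def _cophenetic(tree: TreeNode) -> tuple[np.ndarray, list[str]]:
    dm = tree.tip_tip_distances()
    return dm.data, list(dm.ids)


def bin_tree(tree: TreeNode, min_bin: int = 24) -> list[PhyloBin]:
    """Partition tree tips into phylogenetic bins of at least ``min_bin``.

    Clades are visited shallow-to-deep (postorder); a bin is emitted the
    first time a clade's un-binned tips reach ``min_bin``.  Taxa left over
    at the root are merged into the nearest bin by mean cophenetic
    distance.  Fewer tips than ``min_bin`` → single-bin fallback (warns).
    """
    full_d, tip_ids = _cophenetic(tree)
    tip_pos = {t: i for i, t in enumerate(tip_ids)}
    n_tips = len(tip_ids)
    if n_tips < min_bin:
        warnings.warn(
            f"only {n_tips} tips < min_bin {min_bin}; falling back to one bin"
        )
        return [PhyloBin(0, tip_ids, full_d)]

    binned: set[str] = set()
    bins_members: list[list[str]] = []
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            continue
        members = [t.name for t in node.tips() if t.name not in binned]
        if len(members) >= min_bin:
            bins_members.append(members)
            binned.update(members)
    leftovers = [t for t in tip_ids if t not in binned]
    if leftovers and not bins_members:
        bins_members.append(leftovers)
    elif leftovers:
        for t in leftovers:
            ti = tip_pos[t]
            means = [
                np.mean([full_d[ti, tip_pos[m]] for m in mem]) for mem in bins_members
            ]
            bins_members[int(np.argmin(means))].append(t)

    out = []
    for b, members in enumerate(bins_members):
        idx = [tip_pos[t] for t in members]
        out.append(PhyloBin(b, members, full_d[np.ix_(idx, idx)]))
    return out


def _bmntd(fa: np.ndarray, fb: np.ndarray, d: np.ndarray) -> float:
    """Abundance-weighted beta mean nearest taxon distance.

    ``fa``/``fb`` are relative abundances over the bin's taxa; ``d`` the
    cophenetic matrix in the same order.
    """
    ia = np.flatnonzero(fa > 0)
    ib = np.flatnonzero(fb > 0)
    wa = fa[ia] / fa[ia].sum()
    wb = fb[ib] / fb[ib].sum()
    min_a = d[np.ix_(ia, ib)].min(axis=1)  # nearest taxon in b for each taxon in a
    min_b = d[np.ix_(ib, ia)].min(axis=1)
    return 0.5 * (float(wa @ min_a) + float(wb @ min_b))


def bnti_pair(
    a: np.ndarray,
    b: np.ndarray,
    bin_: PhyloBin,
    n_null: int = 100,
    seed: int = 0,
    return_null: bool = False,
):
    """βNTI for one pair restricted to one bin's taxa.

    The null re-assigns each sample's occupied taxa independently across
    the bin's tips ``n_null`` times, so identical communities still face a
    non-degenerate null (observed 0 is the minimum of the null support).
    Degenerate nulls (sd = 0) yield βNTI 0 with a flag.  Returns
    (bnti, observed, null_array?) depending on ``return_null``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != (bin_.size,) or b.shape != (bin_.size,):
        raise ValueError("community vectors must align with bin taxa")
    if not (a > 0).any() or not (b > 0).any():
        raise ValueError("both samples need >= 1 bin member present")
    obs = _bmntd(a, b, bin_.dmat)
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_null)
    idx = np.arange(bin_.size)
    for k in range(n_null):
        pa = rng.permutation(idx)
        pb = rng.permutation(idx)
        nulls[k] = _bmntd(a[pa], b[pb], bin_.dmat)
    sd = nulls.std(ddof=1) if n_null > 1 else 0.0
    bnti = 0.0 if sd == 0 else (obs - nulls.mean()) / sd
    if return_null:
        return float(bnti), float(obs), nulls
    return float(bnti)


def _bray_curtis_vec(x: np.ndarray, y: np.ndarray) -> float:
    s = x.sum() + y.sum()
    return float(np.abs(x - y).sum() / s) if s > 0 else 0.0


def _null_community(
    richness: int, total: int, occ_w: np.ndarray, ab_w: np.ndarray, rng
) -> np.ndarray:
    """Null assembly: colonize ``richness`` taxa weighted by occupancy, then
    distribute remaining reads multinomially weighted by pool abundance."""
    n_taxa = len(occ_w)
    richness = min(richness, int((occ_w > 0).sum()))
    chosen = rng.choice(n_taxa, size=richness, replace=False, p=occ_w / occ_w.sum())
    vec = np.zeros(n_taxa)
    vec[chosen] = 1
    remaining = total - richness
    if remaining > 0:
        w = ab_w[chosen]
        w = w / w.sum() if w.sum() > 0 else np.full(richness, 1.0 / richness)
        vec[chosen] += rng.multinomial(remaining, w)
    return vec


def rcbray_pair(
    a: np.ndarray,
    b: np.ndarray,
    pool_occupancy: np.ndarray,
    pool_abundance: np.ndarray,
    n_null: int = 100,
    seed: int = 0,
) -> float:
    """Raup-Crick on Bray-Curtis, scaled to [-1, 1] with ties counted half.

    Null pairs preserve each observed sample's richness and total reads;
    colonists are drawn by pool occupancy then filled by pool abundance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    occ = np.asarray(pool_occupancy, dtype=float)
    ab = np.asarray(pool_abundance, dtype=float)
    if occ.sum() == 0:
        raise ValueError("empty pool")
    obs = _bray_curtis_vec(a, b)
    rng = np.random.default_rng(seed)
    ra, ta = int((a > 0).sum()), int(round(a.sum()))
    rb, tb = int((b > 0).sum()), int(round(b.sum()))
    less = ties = 0
    for _ in range(n_null):
        na = _null_community(ra, ta, occ, ab, rng)
        nb = _null_community(rb, tb, occ, ab, rng)
        d = _bray_curtis_vec(na, nb)
        if abs(d - obs) < 1e-12:
            ties += 1
        elif d < obs:
            less += 1
    return float(2.0 * ((less + 0.5 * ties) / n_null) - 1.0)


def _admissible_pairs(meta: pd.DataFrame, within_population: bool) -> list[tuple[str, str]]:
    ids = list(meta.index)
    pairs = []
    for sa, sb in itertools.combinations(ids, 2):
        if within_population and meta.loc[sa, "population"] != meta.loc[sb, "population"]:
            continue
        pairs.append((sa, sb))
    return pairs


def partition_processes(
    t: CommunityTable,
    tree: TreeNode,
    n_null: int = 100,
    min_bin: int = 24,
    bnti_threshold: float = 1.96,
    rc_threshold: float = 0.95,
    mode: str = "ses",
    within_population_for_nonrafts: bool = True,
    seed: int = 0,
    return_pairs: bool = False,
):
    """Five-way assembly-process fractions per group (raft / non-raft).

    For every admissible sample pair (non-raft pairs restricted within
    population when flagged) and every bin: selection when |βNTI| exceeds
    the threshold (``ses`` mode) or observed βMNTD falls outside the
    central 95% of its null (``confidence`` mode), signed heterogeneous
    (+) / homogeneous (−); otherwise RCbray decides dispersal limitation
    (> threshold), homogenizing dispersal (< −threshold), or drift.  Bin
    calls are aggregated with weights = mean relative abundance of the
    bin's taxa across the two samples.
    """
    if mode not in ("ses", "confidence"):
        raise ValueError("mode must be 'ses' or 'confidence'")
    bins = bin_tree(tree, min_bin=min_bin)
    taxa = list(t.counts.columns)
    missing = [tx for tx in taxa if tx not in {m for b in bins for m in b.taxa}]
    if missing:
        raise ValueError(f"table taxa absent from tree: {missing[:5]}")
    counts = t.counts
    totals = counts.sum(axis=1)
    rng = np.random.default_rng(seed)

    results: dict[str, list] = {}
    pair_rows: list[PairProcess] = []
    groups = {
        STATUS_RAFT: t.metadata.index[t.metadata["status"] == STATUS_RAFT],
        STATUS_NON_RAFT: t.metadata.index[t.metadata["status"] == STATUS_NON_RAFT],
    }
    fractions = {}
    for group, ids in groups.items():
        if len(ids) == 0:
            continue
        meta = t.metadata.loc[ids]
        within = within_population_for_nonrafts and group == STATUS_NON_RAFT
        if within and "population" not in meta.columns:
            raise ValueError("within-population rule needs a 'population' column")
        pairs = _admissible_pairs(meta, within)
        if len(pairs) < 2:
            raise ValueError(f"group {group!r} has {len(pairs)} admissible pairs (< 2)")

        # per-bin pool statistics from this group's samples
        proc_weight = dict.fromkeys(PROCESSES, 0.0)
        total_weight = 0.0
        for bin_ in bins:
            cols = [c for c in bin_.taxa if c in counts.columns]
            if not cols:
                continue
            sub = counts[cols].to_numpy(dtype=float)[
                [counts.index.get_loc(s) for s in ids]
            ]
            occ = (sub > 0).mean(axis=0)
            ab = sub.sum(axis=0)
            if occ.sum() == 0:
                continue
            col_order = [bin_.taxa.index(c) for c in cols]
            dmat = bin_.dmat[np.ix_(col_order, col_order)]
            sub_bin = PhyloBin(bin_.bin_id, cols, dmat)
            id_loc = {s: i for i, s in enumerate(ids)}
            rel_all = sub / np.maximum(
                totals.loc[ids].to_numpy(dtype=float)[:, None], 1.0
            )
            for sa, sb in pairs:
                va = sub[id_loc[sa]]
                vb = sub[id_loc[sb]]
                if not (va > 0).any() or not (vb > 0).any():
                    continue
                bnti, obs, nulls = bnti_pair(
                    va,
                    vb,
                    sub_bin,
                    n_null=n_null,
                    seed=int(rng.integers(2**31)),
                    return_null=True,
                )
                if mode == "ses":
                    hetero = bnti > bnti_threshold
                    homo = bnti < -bnti_threshold
                else:
                    lo, hi = np.quantile(nulls, [0.025, 0.975])
                    hetero = obs > hi
                    homo = obs < lo
                rc = np.nan
                if hetero:
                    proc = P_HETERO_SEL
                elif homo:
                    proc = P_HOMO_SEL
                else:
                    rc = rcbray_pair(
                        va, vb, occ, ab, n_null=n_null, seed=int(rng.integers(2**31))
                    )
                    if rc > rc_threshold:
                        proc = P_DISP_LIM
                    elif rc < -rc_threshold:
                        proc = P_HOMO_DISP
                    else:
                        proc = P_DRIFT
                w = 0.5 * (rel_all[id_loc[sa]].sum() + rel_all[id_loc[sb]].sum())
                proc_weight[proc] += w
                total_weight += w
                if return_pairs:
                    pair_rows.append(
                        PairProcess(sa, sb, bin_.bin_id, bnti, rc, proc, w)
                    )
        if total_weight == 0:
            raise ValueError(f"group {group!r}: no informative pair-bin combination")
        fractions[group] = {p: proc_weight[p] / total_weight for p in PROCESSES}

    frac_df = pd.DataFrame(fractions).T
    if return_pairs:
        return frac_df, pair_rows
    return frac_df
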