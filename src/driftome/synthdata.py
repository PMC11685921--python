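"""Synthetic, truth-annotated scenarios.

Generates a coastal domain (SST water masses with distinct variability,
a shore-parallel current jet, stochastic wind), genetically structured
host populations along the coast, surrogate drifter tracks, and microbial
communities with planted structure: a non-raft core under strong
homogeneous selection, raft richness humped in σ-SST, raft dispersion
increasing with perturbation, and faster-growing (higher rRNA operon
count) colonist genera.  Every generator is a pure function of
(config, seed).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from skbio import TreeNode

from .community import STATUS_NON_RAFT, STATUS_RAFT, CommunityTable
from .drift import ParticleState, Trajectory, advect_forward, DEFAULT_LEEWAY_CLASSES
from .envfields import GridField
from .hostassign import GenotypeMatrix

__all__ = [
    "ScenarioConfig",
    "gen_environment",
    "gen_host_populations",
    "gen_microbiomes",
    "gen_drifter_tracks",
    "make_raft_covariates",
]


@dataclasses.dataclass
class ScenarioConfig:
    # domain / environment
    lat_min: float = -47.0
    lat_max: float = -41.0
    lon_min: float = 166.0
    lon_max: float = 176.0
    grid_step: float = 0.25
    n_days: int = 60
    sst_band_means: tuple = (16.0, 13.0, 10.0)  # north -> south water masses
    sst_band_sds: tuple = (0.3, 1.2, 0.5)  # temporal AR(1) innovation sd
    sst_ar1: float = 0.6
    jet_speed: float = 0.4  # m/s shore-parallel
    offshore_speed: float = 0.02  # m/s uniform zonal component
    wind_sd: float = 4.0  # m/s AR(1) innovation
    wind_ar1: float = 0.8
    # host genetics
    n_populations: int = 6
    n_ind_per_pop: int = 8
    n_snps: int = 300
    divergence: float = 0.25  # per-step allele-frequency drift along coast
    n_queries: int = 20
    # microbiome
    n_taxa: int = 120
    core_size: int = 14
    depth_mean: int = 5000
    nonraft_concentration: float = 80.0
    raft_concentration: float = 60.0
    akp_slope: float = 1.5  # dispersion increase per degree sigma-SST
    ish_peak: float = 1.0  # sigma-SST of the richness hump (deg C)
    ish_width: float = 0.5
    richness_base: int = 25
    richness_amp: int = 50
    mixing_tau: float = 10.0  # days to e-fold toward the water pool
    taxa_per_genus: int = 5
    host_operon_count: float = 2.0
    colonist_operon_count: float = 6.0


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------

def gen_environment(cfg: ScenarioConfig, seed: int = 0) -> dict[str, GridField]:
    """SST with latitudinal water masses + AR(1) noise, a shore-parallel
    current jet near the western boundary, and spatially uniform AR(1) wind."""
    if cfg.lat_max <= cfg.lat_min or cfg.lon_max <= cfg.lon_min:
        raise ValueError("degenerate domain box")
    rng = np.random.default_rng(seed)
    lats = np.arange(cfg.lat_min, cfg.lat_max + 1e-9, cfg.grid_step)
    lons = np.arange(cfg.lon_min, cfg.lon_max + 1e-9, cfg.grid_step)
    times = np.arange(cfg.n_days, dtype=float)
    ny, nx, nt = len(lats), len(lons), len(times)

    # band membership by latitude (equal thirds, north = high mean)
    edges = np.linspace(cfg.lat_min, cfg.lat_max, len(cfg.sst_band_means) + 1)
    band = np.clip(np.searchsorted(edges, lats, side="right") - 1, 0, len(cfg.sst_band_means) - 1)
    band = band[::-1]  # northernmost latitude -> first band mean
    base = np.array([cfg.sst_band_means[b] for b in band])  # per-lat mean

    # AR(1) temporal anomaly per band
    anom = np.zeros((nt, len(cfg.sst_band_means)))
    for b, sd in enumerate(cfg.sst_band_sds):
        e = rng.normal(0, sd, size=nt)
        for k in range(1, nt):
            anom[k, b] = cfg.sst_ar1 * anom[k - 1, b] + e[k]
        anom[0, b] = e[0]
    sst = np.empty((nt, ny, nx))
    for k in range(nt):
        col = base + anom[k][band]
        sst[k] = col[:, None] + 0.05 * (lons - lons.mean())[None, :]

    # shore-parallel (northward) jet decaying away from the west coast
    dist = (lons - cfg.lon_min)  # degrees offshore
    jet = cfg.jet_speed * np.exp(-((dist - 0.5) ** 2) / (2 * 1.0**2))
    cur_v = np.tile(jet[None, None, :], (nt, ny, 1))
    cur_u = np.full((nt, ny, nx), cfg.offshore_speed)

    # spatially uniform AR(1) wind components
    wind = np.zeros((nt, 2))
    e = rng.normal(0, cfg.wind_sd, size=(nt, 2))
    wind[0] = e[0]
    for k in range(1, nt):
        wind[k] = cfg.wind_ar1 * wind[k - 1] + e[k]
    wind_u = np.tile(wind[:, 0][:, None, None], (1, ny, nx))
    wind_v = np.tile(wind[:, 1][:, None, None], (1, ny, nx))

    mk = lambda vals, kind: GridField(lats=lats, lons=lons, times=times, values=vals, kind=kind)
    return {
        "sst": mk(sst, "scalar"),
        "cur_u": mk(cur_u, "vector_u"),
        "cur_v": mk(cur_v, "vector_v"),
        "wind_u": mk(wind_u, "vector_u"),
        "wind_v": mk(wind_v, "vector_v"),
    }


# ---------------------------------------------------------------------------
# host populations
# ---------------------------------------------------------------------------

def gen_host_populations(cfg: ScenarioConfig, seed: int = 0):
    """Isolation-by-distance SNP panel along a synthetic coastline.

    Allele frequencies random-walk from population to population along the
    coast; individuals are binomial draws.  Returns (GenotypeMatrix with
    reference coords, query truth dict, population coordinate table,
    coastline point list).
    """
    if cfg.n_populations < 2:
        raise ValueError("need >= 2 populations")
    if cfg.divergence == 0 and cfg.n_queries > 0:
        import warnings

        warnings.warn("divergence 0: source assignment is unidentifiable")
    rng = np.random.default_rng(seed)
    # populations evenly spaced along the west coast (fixed lon)
    coast_lon = cfg.lon_min + 0.3
    pop_lats = np.linspace(cfg.lat_min + 0.5, cfg.lat_max - 0.5, cfg.n_populations)
    pop_coords = pd.DataFrame(
        {"population": [f"pop{p}" for p in range(cfg.n_populations)],
         "lat": pop_lats, "lon": coast_lon}
    ).set_index("population")

    # dense ordered coastline points spanning the populations
    coast_lats = np.arange(cfg.lat_min + 0.2, cfg.lat_max - 0.2, 0.02)
    coastline = [(la, coast_lon) for la in coast_lats]

    p0 = rng.uniform(0.1, 0.9, size=cfg.n_snps)
    freqs = np.empty((cfg.n_populations, cfg.n_snps))
    freqs[0] = p0
    for k in range(1, cfg.n_populations):
        freqs[k] = np.clip(freqs[k - 1] + rng.normal(0, cfg.divergence, cfg.n_snps), 0.01, 0.99)

    individuals, rows, coords = [], [], {}
    for k in range(cfg.n_populations):
        for i in range(cfg.n_ind_per_pop):
            name = f"pop{k}_ind{i}"
            individuals.append(name)
            rows.append(rng.binomial(2, freqs[k]))
            coords[name] = (float(pop_lats[k]), float(coast_lon))
    truth = {}
    for q in range(cfg.n_queries):
        k = int(rng.integers(cfg.n_populations))
        name = f"query{q}"
        individuals.append(name)
        rows.append(rng.binomial(2, freqs[k]))
        truth[name] = {"population": f"pop{k}", "lat": float(pop_lats[k]), "lon": float(coast_lon)}

    g = GenotypeMatrix(
        individuals=individuals,
        loci=[f"snp{j}" for j in range(cfg.n_snps)],
        genotypes=np.asarray(rows, dtype=float),
        coords=coords,
    )
    return g, truth, pop_coords, coastline


# ---------------------------------------------------------------------------
# microbiomes
# ---------------------------------------------------------------------------

def _yule_tree(n_tips: int, rng: np.random.Generator) -> TreeNode:
    """Pure-birth tree with exponential branch increments."""
    tips = [TreeNode(name=f"asv{i:04d}", length=0.0) for i in range(n_tips)]
    active = list(tips)
    rng.shuffle(active)
    while len(active) > 1:
        # extend all active branches by the waiting time, then join two
        wait = rng.exponential(1.0 / len(active))
        for node in active:
            node.length += wait
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[i], active[j]
        parent = TreeNode(length=0.0, children=[a, b])
        active = [x for x in active if x is not a and x is not b] + [parent]
    root = active[0]
    root.length = None
    return root


def _brownian_trait(tree: TreeNode, rng: np.random.Generator) -> dict[str, float]:
    values = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        parent_val = values[id(node.parent)]
        bl = node.length if node.length else 0.0
        values[id(node)] = parent_val + rng.normal(0, np.sqrt(max(bl, 1e-9)))
    return {t.name: values[id(t)] for t in tree.tips()}


def make_raft_covariates(cfg: ScenarioConfig, n_rafts: int, seed: int = 0) -> pd.DataFrame:
    """Stand-in raft drift summaries (raft_time, sst, sigma_sst) for running
    the community generator without a full drift simulation."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "raft_time": rng.uniform(2, 40, n_rafts),
            "sst": rng.uniform(10, 16, n_rafts),
            "sigma_sst": rng.uniform(0.05, cfg.ish_peak * 2.5, n_rafts),
        },
        index=[f"raft{r}" for r in range(n_rafts)],
    )


def gen_microbiomes(
    cfg: ScenarioConfig,
    raft_summaries: pd.DataFrame,
    seed: int = 0,
):
    """Communities with planted core, ISH hump, AKP dispersion, and
    fast-growing colonists.

    ``raft_summaries`` needs columns raft_time, sst, sigma_sst (one row per
    raft sample).  Returns (CommunityTable, ASV tree, trait Series, truth).
    """
    if cfg.core_size > cfg.n_taxa:
        raise ValueError("core size exceeds taxon count")
    rng = np.random.default_rng(seed)
    tree = _yule_tree(cfg.n_taxa, rng)
    trait = _brownian_trait(tree, rng)
    taxa = [t.name for t in tree.tips()]
    pref = np.array([trait[t] for t in taxa])

    # host-favoured clade = high-preference taxa; water pool = the rest
    order = np.argsort(-pref)
    host_rank = np.full(cfg.n_taxa, np.inf)
    host_rank[order] = np.arange(cfg.n_taxa)
    # planted core: flat-ish high shares so each core taxon contributes a
    # comparable slice of pairwise dissimilarity; non-core tail decays fast
    core_idx = order[: cfg.core_size]
    # non-rafts only ever occupy the host-favoured clade: a strong,
    # consistent phylogenetic filter (homogeneous selection); the planted
    # core is flat-ish and dominant so each member contributes a
    # comparable, > stop-rule slice of pairwise dissimilarity
    host_support = host_rank < max(3 * cfg.core_size, cfg.core_size + 10)
    noncore_host = host_support & ~np.isin(np.arange(cfg.n_taxa), core_idx)
    host_base = np.where(host_support, np.exp(-(host_rank - cfg.core_size) / 20.0), 0.0)
    host_base[core_idx] = 1.0 + 0.1 * rng.uniform(size=cfg.core_size)
    core_mass = 0.8
    host_base[core_idx] *= core_mass / host_base[core_idx].sum()
    host_base[noncore_host] *= (1 - core_mass) / host_base[noncore_host].sum()
    water_base = np.exp(host_rank / 8.0 - cfg.n_taxa / 8.0)
    water_base = water_base / water_base.sum()

    # genera: contiguous clades of ~taxa_per_genus tips (tree tip order)
    tip_order = [t.name for t in tree.tips()]
    genus_of = {}
    for i, name in enumerate(tip_order):
        genus_of[name] = f"genus{i // cfg.taxa_per_genus:03d}"
    taxonomy = pd.Series({t: genus_of[t] for t in taxa}, name="genus")
    # genus trait: colonist (water-dominated) genera grow faster
    genus_water = pd.Series(water_base, index=taxa).groupby(taxonomy).mean()
    genus_host = pd.Series(host_base, index=taxa).groupby(taxonomy).mean()
    traits = pd.Series(
        np.where(
            genus_water.to_numpy() > genus_host.to_numpy(),
            cfg.colonist_operon_count,
            cfg.host_operon_count,
        ),
        index=genus_water.index,
        name="mean_copies",
    ) + np.round(rng.uniform(0, 0.5, len(genus_water)), 3)

    counts = {}
    meta_rows = {}
    pops = [f"pop{k}" for k in range(cfg.n_populations)]
    for k, pop in enumerate(pops):
        for i in range(5):
            name = f"nonraft_{pop}_{i}"
            # per-sample dropout of non-core host taxa: turnover stays
            # inside the host clade (phylogenetically conserved)
            keep = host_base > 0
            drop = noncore_host & (rng.uniform(size=cfg.n_taxa) > 0.65)
            keep = keep & ~drop
            base = np.where(keep, host_base, 0.0)
            base /= base.sum()
            profile = rng.dirichlet(cfg.nonraft_concentration * np.maximum(base, 1e-8))
            profile = np.where(keep, profile, 0.0)
            profile /= profile.sum()
            depth = int(cfg.depth_mean + rng.integers(-500, 500))
            counts[name] = rng.multinomial(depth, profile)
            meta_rows[name] = {
                "status": STATUS_NON_RAFT,
                "population": pop,
                "raft_time": 0.0,
                "sst": np.nan,
                "sigma_sst": float(rng.uniform(0.1, 0.6)),
            }

    regimes = {}
    for raft_id, row in raft_summaries.iterrows():
        w = 1.0 - np.exp(-row["raft_time"] / cfg.mixing_tau)  # toward water pool
        sigma = float(row["sigma_sst"])
        mean_profile = (1 - w) * host_base + w * water_base
        # ISH: effective taxon support size humps at intermediate sigma
        hump = np.exp(-((sigma - cfg.ish_peak) ** 2) / (2 * cfg.ish_width**2))
        n_avail = int(round(cfg.richness_base + cfg.richness_amp * hump))
        support = rng.choice(
            cfg.n_taxa, size=min(n_avail, cfg.n_taxa), replace=False,
            p=mean_profile / mean_profile.sum(),
        )
        profile_mean = np.zeros(cfg.n_taxa)
        profile_mean[support] = mean_profile[support]
        profile_mean /= profile_mean.sum()
        # flatten within the support so every available taxon is actually
        # observable at sequencing depth (realized richness tracks n_avail)
        flat = np.zeros(cfg.n_taxa)
        flat[support] = 1.0 / len(support)
        profile_mean = 0.5 * profile_mean + 0.5 * flat
        # AKP: concentration shrinks (dispersion grows) with perturbation
        conc = cfg.raft_concentration / (1.0 + cfg.akp_slope * sigma)
        profile = rng.dirichlet(conc * np.maximum(profile_mean, 1e-8))
        depth = int(cfg.depth_mean + rng.integers(-500, 500))
        counts[raft_id] = rng.multinomial(depth, profile)
        meta_rows[raft_id] = {
            "status": STATUS_RAFT,
            "population": "raft",
            "raft_time": float(row["raft_time"]),
            "sst": float(row["sst"]),
            "sigma_sst": sigma,
        }
        regimes[raft_id] = "drift" if w > 0.5 else "selection"

    table = CommunityTable(
        counts=pd.DataFrame.from_dict(counts, orient="index", columns=taxa),
        metadata=pd.DataFrame.from_dict(meta_rows, orient="index"),
        taxonomy=taxonomy,
    )
    truth = {
        "core_taxa": [taxa[i] for i in core_idx],
        "ish_peak": cfg.ish_peak,
        "ish_width": cfg.ish_width,
        "akp_slope": cfg.akp_slope,
        "regimes": regimes,
        "colonist_genera": list(
            genus_water.index[genus_water.to_numpy() > genus_host.to_numpy()]
        ),
    }
    return table, tree, traits, truth


# ---------------------------------------------------------------------------
# drifter tracks
# ---------------------------------------------------------------------------

def gen_drifter_tracks(
    cfg: ScenarioConfig,
    fields: dict[str, GridField],
    n: int = 21,
    seed: int = 0,
    track_days: float = 14.0,
    dt_hours: float = 3.0,
    obs_noise_deg: float = 0.0,
) -> list[Trajectory]:
    """Forward-advected surrogate drifters with optional observation noise."""
    rng = np.random.default_rng(seed)
    domain = (cfg.lat_min, cfg.lat_max, cfg.lon_min, cfg.lon_max)
    cls = DEFAULT_LEEWAY_CLASSES[0]
    tracks = []
    t_hi = cfg.n_days - 1 - track_days
    for i in range(n):
        p = ParticleState(
            lon=float(rng.uniform(cfg.lon_min + 2, cfg.lon_max - 2)),
            lat=float(rng.uniform(cfg.lat_min + 1, cfg.lat_max - 1)),
            time=float(rng.uniform(0, max(t_hi, 1))),
            crosswind_sign=int(rng.choice([-1, 1])),
            leeway_class=cls,
            downwind_draw=max(0.0, rng.normal(cls.downwind_slope, cls.downwind_sd)),
            crosswind_draw=max(0.0, rng.normal(cls.crosswind_slope, cls.crosswind_sd)),
        )
        tr = advect_forward(
            p,
            (fields["cur_u"], fields["cur_v"]),
            (fields["wind_u"], fields["wind_v"]),
            domain,
            dt_hours=dt_hours,
            max_days=track_days,
        )
        if obs_noise_deg > 0:
            tr = Trajectory(
                tr.times,
                tr.lats + rng.normal(0, obs_noise_deg, len(tr)),
                tr.lons + rng.normal(0, obs_noise_deg, len(tr)),
                tr.status,
            )
        tracks.append(tr)
    return tracks
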