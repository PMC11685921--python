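"""Readers and writers for the plain-text artifact formats.

Count tables are TSV with taxa as rows and samples as columns plus a
sidecar metadata TSV; genotypes a TSV matrix (individuals x loci, dot for
missing) or a minimal VCF subset (GT/DP only); trees newick with supports
as internal node labels; trajectories CSV / GeoJSON; fields NetCDF or
long CSV (see :mod:`driftome.envfields`).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .community import CommunityTable
from .drift import TargetZone, Trajectory
from .hostassign import GenotypeMatrix

__all__ = [
    "write_community_tsv",
    "read_community_tsv",
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "read_genotypes_vcf",
    "write_coords_tsv",
    "read_coords_tsv",
    "write_tree_newick",
    "read_tree_newick",
    "write_trait_tsv",
    "read_trait_tsv",
    "write_trajectories_csv",
    "read_trajectories_csv",
    "trajectories_to_geojson",
    "target_zone_to_geojson",
    "write_json",
    "read_json",
]

MISSING_GT = "."


def write_community_tsv(t: CommunityTable, counts_path, metadata_path, taxonomy_path=None):
    t.counts.T.to_csv(counts_path, sep="\t", index_label="taxon")
    t.metadata.to_csv(metadata_path, sep="\t", index_label="sample")
    if taxonomy_path is not None and t.taxonomy is not None:
        t.taxonomy.rename("genus").to_csv(taxonomy_path, sep="\t", index_label="taxon")


def read_community_tsv(counts_path, metadata_path, taxonomy_path=None) -> CommunityTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col="taxon").T
    counts.index.name = None
    counts.columns.name = None
    metadata = pd.read_csv(metadata_path, sep="\t", index_col="sample")
    metadata.index.name = None
    taxonomy = None
    if taxonomy_path is not None:
        taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col="taxon")["genus"]
        taxonomy.index.name = None
    return CommunityTable(counts=counts, metadata=metadata, taxonomy=taxonomy)


def write_genotypes_tsv(g: GenotypeMatrix, path):
    df = pd.DataFrame(g.genotypes, index=g.individuals, columns=g.loci)
    df = df.map(lambda v: MISSING_GT if np.isnan(v) else str(int(v)))
    df.to_csv(path, sep="\t", index_label="individual")


def read_genotypes_tsv(path, coords=None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="individual", dtype=str)
    geno = df.replace(MISSING_GT, np.nan).astype(float).to_numpy()
    return GenotypeMatrix(
        individuals=list(df.index),
        loci=list(df.columns),
        genotypes=geno,
        coords=coords,
    )


def read_genotypes_vcf(path, coords=None) -> GenotypeMatrix:
    """Minimal VCF subset: uses only GT (and DP when present in FORMAT)."""
    loci, geno_rows, depth_rows = [], [], []
    samples = None
    has_dp = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            parts = line.split("\t")
            if line.startswith("#CHROM"):
                if len(parts) < 10:
                    raise ValueError(f"{path}:{lineno}: VCF header has no samples")
                samples = parts[9:]
                continue
            if samples is None:
                raise ValueError(f"{path}:{lineno}: data before #CHROM header")
            if len(parts) < 10:
                raise ValueError(f"{path}:{lineno}: truncated record")
            chrom, pos, vid = parts[0], parts[1], parts[2]
            fmt = parts[8].split(":")
            try:
                gt_i = fmt.index("GT")
            except ValueError:
                raise ValueError(f"{path}:{lineno}: record without GT field")
            dp_i = fmt.index("DP") if "DP" in fmt else None
            has_dp = has_dp or dp_i is not None
            loci.append(vid if vid != "." else f"{chrom}:{pos}")
            g_row, d_row = [], []
            for cell in parts[9:]:
                fields = cell.split(":")
                gt = fields[gt_i].replace("|", "/")
                if gt in (".", "./."):
                    g_row.append(np.nan)
                else:
                    g_row.append(float(sum(int(a) for a in gt.split("/"))))
                if dp_i is not None and dp_i < len(fields) and fields[dp_i] != ".":
                    d_row.append(float(fields[dp_i]))
                else:
                    d_row.append(np.nan)
            geno_rows.append(g_row)
            depth_rows.append(d_row)
    geno = np.asarray(geno_rows, dtype=float).T  # individuals x loci
    depths = np.asarray(depth_rows, dtype=float).T if has_dp else None
    if depths is not None:
        depths = np.nan_to_num(depths, nan=0.0)
    return GenotypeMatrix(
        individuals=samples, loci=loci, genotypes=geno, depths=depths, coords=coords
    )


def write_coords_tsv(coords: dict, path):
    rows = [(k, v[0], v[1]) for k, v in coords.items()]
    pd.DataFrame(rows, columns=["individual", "lat", "lon"]).to_csv(
        path, sep="\t", index=False
    )


def read_coords_tsv(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return {r.individual: (float(r.lat), float(r.lon)) for r in df.itertuples()}


def write_tree_newick(tree: TreeNode, path):
    t = tree.copy()
    for node in t.non_tips(include_self=False):
        if getattr(node, "support", None) is not None:
            node.name = None  # skbio writes the support attribute as the label
    t.write(str(path))


def read_tree_newick(path) -> TreeNode:
    tree = TreeNode.read(str(path))
    tree.assign_supports()  # parse internal labels into .support
    return tree


def write_trait_tsv(traits: pd.Series, path):
    traits.rename("mean_copies").to_csv(path, sep="\t", index_label="genus")


def read_trait_tsv(path) -> pd.Series:
    s = pd.read_csv(path, sep="\t", index_col="genus")["mean_copies"]
    s.index.name = None
    return s


def write_trajectories_csv(trajectories, path):
    rows = []
    for pid, tr in enumerate(trajectories):
        for step, (t, la, lo) in enumerate(zip(tr.times, tr.lats, tr.lons)):
            rows.append((pid, step, t, la, lo, tr.status))
    pd.DataFrame(
        rows, columns=["particle_id", "step", "time", "lat", "lon", "status"]
    ).to_csv(path, index=False)


def read_trajectories_csv(path) -> list[Trajectory]:
    df = pd.read_csv(path)
    out = []
    for pid, sub in df.groupby("particle_id", sort=True):
        sub = sub.sort_values("step")
        out.append(
            Trajectory(
                sub["time"].to_numpy(),
                sub["lat"].to_numpy(),
                sub["lon"].to_numpy(),
                sub["status"].iloc[0],
            )
        )
    return out


def trajectories_to_geojson(trajectories, path):
    features = []
    for pid, tr in enumerate(trajectories):
        features.append(
            {
                "type": "Feature",
                "properties": {"particle_id": pid, "status": tr.status},
                "geometry": {
                    "type": "LineString",
                    "coordinates": [
                        [float(lo), float(la)] for la, lo in zip(tr.lats, tr.lons)
                    ],
                },
            }
        )
    write_json({"type": "FeatureCollection", "features": features}, path)


def target_zone_to_geojson(zone: TargetZone, path):
    write_json(
        {
            "type": "Feature",
            "properties": {"hit_radius_km": zone.hit_radius_km},
            "geometry": {
                "type": "MultiPoint",
                "coordinates": [
                    [float(lo), float(la)] for la, lo in zip(zone.lats, zone.lons)
                ],
            },
        },
        path,
    )


def write_json(obj, path):
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))


def read_json(path):
    return json.loads(Path(path).read_text())
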