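"""Anatomical reporting of selected connectivity features.

Each selected feature index maps back (through the upper-triangle index
map) to an unordered pair of atlas regions, i.e. one edge of a brain
graph.  This module aggregates those edges into the summaries used to
interpret a selection anatomically — intra-/inter-lobe counts,
intra-/inter-hemisphere counts — and exports BrainNet Viewer ``.node`` /
``.edge`` files for 3-D rendering.

The packaged atlas table (``data/aal90_atlas_synthetic.csv``) carries the
standard 90 AAL region names with this package's own lobe taxonomy
(Frontal, Parietal, Temporal, Medial-Temporal, Occipital, Subcortical,
Insula, Limbic), hemisphere taken from the region-name suffix, and
approximate MNI centroid coordinates intended for visualisation export
only; it is a synthetic stand-in, not the atlas distribution itself.
Users may supply any CSV with the same columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import FeatureIndexMap

__all__ = [
    "AtlasInfo",
    "EdgeSet",
    "load_atlas",
    "load_site_counts",
    "features_to_edges",
    "lobe_counts",
    "hemisphere_counts",
    "export_brainnet",
    "read_brainnet",
]


@dataclass
class AtlasInfo:
    """Region table: 0-based index, name, lobe, hemisphere, MNI centroid."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"index", "name", "lobe", "hemisphere", "x", "y", "z"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"atlas table missing columns: {sorted(missing)}")
        idx = self.table["index"].to_numpy()
        if not np.array_equal(np.sort(idx), np.arange(len(idx))):
            raise ValueError("atlas indices must be 0..R-1, complete and unique")
        if self.table["lobe"].isna().any() or (self.table["lobe"] == "").any():
            raise ValueError("every region needs a lobe label")
        if not set(self.table["hemisphere"]) <= {"L", "R"}:
            raise ValueError("hemisphere labels must be 'L' or 'R'")
        self.table = self.table.sort_values("index").reset_index(drop=True)

    @property
    def R(self) -> int:
        return len(self.table)

    def lobe(self, region: int) -> str:
        return str(self.table.at[region, "lobe"])

    def hemisphere(self, region: int) -> str:
        return str(self.table.at[region, "hemisphere"])

    def name(self, region: int) -> str:
        return str(self.table.at[region, "name"])

    def coords(self, region: int) -> tuple[float, float, float]:
        row = self.table.loc[region]
        return float(row["x"]), float(row["y"]), float(row["z"])


@dataclass
class EdgeSet:
    """Unordered, de-duplicated region-pair edges with unit weights."""

    edges: list[tuple[int, int]]
    weights: list[float]

    def __len__(self) -> int:
        return len(self.edges)


def load_atlas(path: str | Path | None = None) -> AtlasInfo:
    """Load an atlas CSV; defaults to the packaged AAL-90 table."""
    if path is None:
        with resources.files("tsfs.data").joinpath("aal90_atlas_synthetic.csv").open() as f:
            table = pd.read_csv(f)
    else:
        table = pd.read_csv(path)
    return AtlasInfo(table=table)


def load_site_counts() -> pd.DataFrame:
    """Packaged per-site participant counts of the 17-site ABIDE-I cohort."""
    with resources.files("tsfs.data").joinpath("abide_site_counts.csv").open() as f:
        return pd.read_csv(f)


def features_to_edges(
    indices: Sequence[int], index_map: FeatureIndexMap
) -> EdgeSet:
    """One unit-weight edge per selected feature index (duplicates dropped)."""
    seen: dict[tuple[int, int], None] = {}
    n_dup = 0
    for p in indices:
        pair = index_map.pair_of(int(p))
        if pair in seen:
            n_dup += 1
        else:
            seen[pair] = None
    if n_dup:
        warnings.warn(f"dropped {n_dup} duplicate feature indices", UserWarning)
    edges = list(seen.keys())
    return EdgeSet(edges=edges, weights=[1.0] * len(edges))


def lobe_counts(
    edges: EdgeSet, atlas: AtlasInfo
) -> tuple[pd.Series, pd.Series]:
    """(intra-lobe counts, inter-lobe counts) over the edge set.

    Every edge lands in exactly one bucket: its lobe if both endpoints
    share one, otherwise the unordered lobe pair ``"A<->B"``; the two
    tables therefore sum to the number of edges.
    """
    intra: dict[str, int] = {}
    inter: dict[str, int] = {}
    for j, k in edges.edges:
        lj, lk = atlas.lobe(j), atlas.lobe(k)
        if lj == lk:
            intra[lj] = intra.get(lj, 0) + 1
        else:
            key = "<->".join(sorted((lj, lk)))
            inter[key] = inter.get(key, 0) + 1
    return (
        pd.Series(intra, dtype=int).sort_index(),
        pd.Series(inter, dtype=int).sort_index(),
    )


def hemisphere_counts(edges: EdgeSet, atlas: AtlasInfo) -> tuple[int, int, int]:
    """(intra-left, intra-right, inter-hemisphere) edge counts."""
    ll = rr = lr = 0
    for j, k in edges.edges:
        hj, hk = atlas.hemisphere(j), atlas.hemisphere(k)
        if hj == hk:
            if hj == "L":
                ll += 1
            else:
                rr += 1
        else:
            lr += 1
    return ll, rr, lr


def export_brainnet(
    edges: EdgeSet,
    atlas: AtlasInfo,
    node_path: str | Path,
    edge_path: str | Path,
    top_k: int | None = None,
) -> tuple[Path, Path]:
    """Write BrainNet Viewer ``.node`` and ``.edge`` files.

    Only the first ``top_k`` edges are exported (default all; the usual
    report keeps the top 50 ranked features to avoid visual clutter).
    The ``.node`` file lists, for every region touched by those edges,
    ``x y z color size label`` with unit color and size; the ``.edge``
    file is the matching symmetric 0/1 adjacency matrix.
    """
    if top_k is None:
        top_k = len(edges)
    if top_k > len(edges):
        raise ValueError(f"top_k={top_k} exceeds the {len(edges)} available edges")
    kept = edges.edges[:top_k]
    nodes = sorted({r for e in kept for r in e})
    pos = {r: i for i, r in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)), dtype=int)
    for j, k in kept:
        adj[pos[j], pos[k]] = 1
        adj[pos[k], pos[j]] = 1

    node_path, edge_path = Path(node_path), Path(edge_path)
    with node_path.open("w") as f:
        for r in nodes:
            x, y, z = atlas.coords(r)
            f.write(f"{x:g}\t{y:g}\t{z:g}\t1\t1\t{atlas.name(r)}\n")
    with edge_path.open("w") as f:
        for row in adj:
            f.write("\t".join(str(v) for v in row) + "\n")
    return node_path, edge_path


def read_brainnet(
    node_path: str | Path, edge_path: str | Path, atlas: AtlasInfo
) -> EdgeSet:
    """Re-parse exported BrainNet files back into an :class:`EdgeSet`."""
    names = []
    with Path(node_path).open() as f:
        for line in f:
            parts = line.split()
            if parts:
                names.append(parts[-1])
    name_to_idx = {atlas.name(r): r for r in range(atlas.R)}
    regions = [name_to_idx[n] for n in names]
    adj = np.loadtxt(edge_path, dtype=int, ndmin=2)
    if adj.shape != (len(regions), len(regions)):
        raise ValueError("edge matrix does not match the node list")
    if not np.array_equal(adj, adj.T) or np.any(np.diag(adj) != 0):
        raise ValueError("edge matrix must be symmetric with a zero diagonal")
    edges = []
    for a in range(len(regions)):
        for b in range(a + 1, len(regions)):
            if adj[a, b]:
                pair = (min(regions[a], regions[b]), max(regions[a], regions[b]))
                edges.append(pair)
    return EdgeSet(edges=edges, weights=[1.0] * len(edges))
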