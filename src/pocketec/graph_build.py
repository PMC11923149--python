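"""Typed 3D graphs over descriptor selections.

A node per kept residue (at its Cα, typed by amino acid) or per kept heavy
atom (typed by chemical environment).  Directed edges j→i connect nodes within
``neighbor_radius`` Å, capped to each receiver's ``max_neighbors`` nearest
senders (ties broken by node index).  Graphs carry no edge features: distances
and angles are recomputed from positions inside the networks, which keeps
jitter augmentation cheap.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import h5py
import numpy as np
from scipy.spatial import cKDTree

from .annotation import AnnotationScheme
from .descriptor import EmptyDescriptorError, Selection

__all__ = [
    "ProteinGraph",
    "GraphBatch",
    "build_graph",
    "build_pocket_graph",
    "build_edges",
    "compute_triplets",
    "save_graphs",
    "load_graphs",
]


@dataclasses.dataclass
class ProteinGraph:
    """Node positions + chemical types + radius-limited directed edges."""

    positions: np.ndarray          # (N, 3) Å
    node_types: np.ndarray         # (N,) int annotation indices
    edge_index: np.ndarray         # (2, E) int; row 0 = sender j, row 1 = receiver i
    resolution: str                # "residue" | "atom"
    label: Optional[int] = None    # class index into the model's vocabulary
    structure_id: str = ""
    site_rank: int = 1
    scheme_version: str = ""
    neighbor_radius: float = 0.0
    #: residue-resolution provenance: one residue key per node (optional)
    node_keys: Optional[tuple] = None

    @property
    def n_nodes(self) -> int:
        return len(self.node_types)

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[1]

    def edge_lengths(self) -> np.ndarray:
        j, i = self.edge_index
        return np.linalg.norm(self.positions[i] - self.positions[j], axis=1)

    def with_positions(self, positions: np.ndarray, rebuild_edges: bool = False,
                       max_neighbors: int = 32) -> "ProteinGraph":
        g = dataclasses.replace(self, positions=np.asarray(positions, dtype=np.float64))
        if rebuild_edges:
            g.edge_index = build_edges(g.positions, g.neighbor_radius, max_neighbors)
        return g


def build_edges(positions: np.ndarray, neighbor_radius: float, max_neighbors: int) -> np.ndarray:
    """Directed edge list j→i: within radius, capped per receiver, ties by index."""
    n = len(positions)
    if n == 0:
        return np.zeros((2, 0), dtype=np.intp)
    tree = cKDTree(positions)
    senders: list[int] = []
    receivers: list[int] = []
    neighbor_lists = tree.query_ball_point(positions, r=neighbor_radius)
    for i, neigh in enumerate(neighbor_lists):
        cand = [j for j in neigh if j != i]
        if not cand:
            continue
        # quantized so exact geometric ties break by index, not float noise
        d = np.round(np.linalg.norm(positions[cand] - positions[i], axis=1), 9)
        order = np.lexsort((np.array(cand), d))
        for k in order[:max_neighbors]:
            senders.append(cand[k])
            receivers.append(i)
    return np.array([senders, receivers], dtype=np.intp).reshape(2, -1)


def build_graph(
    sel: Selection,
    scheme: AnnotationScheme,
    neighbor_radius: float = 15.0,
    max_neighbors: int = 32,
    label: Optional[int] = None,
    site_rank: int = 1,
) -> ProteinGraph:
    """Turn a Selection into a ProteinGraph at the selection's resolution.

    Default ``neighbor_radius`` suits residue graphs (Cα contact scale); use
    ~6 Å for atom graphs.
    """
    if len(sel) == 0:
        raise EmptyDescriptorError("cannot build a graph from an empty selection")
    s = sel.structure
    node_keys = None
    if sel.resolution == "residue":
        residues = s.residues()
        positions, types, keys = [], [], []
        for key in sel.residue_keys:
            atoms = residues[key]
            ca = next(a for a in atoms if a.atom_name == "CA" and not a.is_hydrogen)
            positions.append(ca.coord)
            types.append(scheme.annotate_residue(ca.residue_name))
            keys.append(key)
        node_keys = tuple(keys)
    else:
        positions, types = [], []
        for idx in sel.atom_indices:
            a = s.atoms[idx]
            positions.append(a.coord)
            types.append(scheme.annotate_atom(a.residue_name, a.atom_name))
    positions = np.array(positions, dtype=np.float64)
    node_types = np.array(types, dtype=np.intp)
    edge_index = build_edges(positions, neighbor_radius, max_neighbors)
    return ProteinGraph(
        positions=positions,
        node_types=node_types,
        edge_index=edge_index,
        resolution=sel.resolution,
        label=label,
        structure_id=s.source_id,
        site_rank=site_rank,
        scheme_version=scheme.version,
        neighbor_radius=float(neighbor_radius),
        node_keys=node_keys,
    )


def build_pocket_graph(
    structure,
    site,
    scheme: AnnotationScheme,
    resolution: str = "residue",
    cut_mode: str = "count",
    cut_param: float = 100,
    neighbor_radius: float = 15.0,
    max_neighbors: int = 32,
    label: Optional[int] = None,
) -> ProteinGraph:
    """Descriptor extraction + graph construction in one call.

    ``cut_mode`` is "none", "radius" (param = r in Å) or "count" (param = n);
    defaults follow the plateau sizes (100 residues / 16 Å; use 150 for atom
    counts).
    """
    from . import descriptor as _desc

    if cut_mode == "none":
        sel = _desc.select_all(structure, resolution)
    elif cut_mode == "radius":
        sel = _desc.select_by_radius(structure, site, float(cut_param), resolution)
    elif cut_mode == "count":
        sel = _desc.select_by_count(structure, site, int(cut_param), resolution)
    else:
        sel = _desc.get_cut(cut_mode)(structure, site, cut_param, resolution)
    return build_graph(
        sel, scheme, neighbor_radius=neighbor_radius, max_neighbors=max_neighbors,
        label=label, site_rank=getattr(site, "rank", 1),
    )


def compute_triplets(g: ProteinGraph) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Edge pairs (k→j, j→i) with k ≠ i and the angle at j.

    Returns ``(kj_edge_ids, ji_edge_ids, angles)`` where the angle is between
    r_k − r_j and r_i − r_j, in [0, π].  Raises on coincident points.
    """
    j_arr, i_arr = g.edge_index
    n_edges = g.n_edges
    if n_edges == 0:
        return (np.zeros(0, dtype=np.intp), np.zeros(0, dtype=np.intp), np.zeros(0))
    incoming: dict[int, list[int]] = {}
    for e in range(n_edges):
        incoming.setdefault(int(i_arr[e]), []).append(e)
    kj_ids: list[int] = []
    ji_ids: list[int] = []
    for e in range(n_edges):
        j, i = int(j_arr[e]), int(i_arr[e])
        for f in incoming.get(j, ()):
            k = int(j_arr[f])
            if k == i:  # exclude the back-triplet i→j→i
                continue
            kj_ids.append(f)
            ji_ids.append(e)
    kj = np.array(kj_ids, dtype=np.intp)
    ji = np.array(ji_ids, dtype=np.intp)
    if len(kj) == 0:
        return kj, ji, np.zeros(0)
    pos = g.positions
    jj = j_arr[ji]          # central node j of each triplet
    kk = j_arr[kj]
    ii = i_arr[ji]
    v1 = pos[kk] - pos[jj]
    v2 = pos[ii] - pos[jj]
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    if np.any(n1 == 0) or np.any(n2 == 0):
        raise ValueError("degenerate geometry: coincident points make the angle undefined")
    cosang = np.clip((v1 * v2).sum(axis=1) / (n1 * n2), -1.0, 1.0)
    return kj, ji, np.arccos(cosang)


@dataclasses.dataclass
class GraphBatch:
    """Concatenated graphs with a node→graph assignment vector."""

    positions: np.ndarray      # (ΣN, 3)
    node_types: np.ndarray     # (ΣN,)
    edge_index: np.ndarray     # (2, ΣE), node ids offset per graph
    node2graph: np.ndarray     # (ΣN,) graph id per node
    n_graphs: int
    labels: Optional[np.ndarray] = None   # (n_graphs,) or None
    neighbor_radius: float = 0.0

    @classmethod
    def from_graphs(cls, graphs: Sequence[ProteinGraph]) -> "GraphBatch":
        if not graphs:
            raise ValueError("empty batch")
        positions, types, edges, assign = [], [], [], []
        offset = 0
        labels = []
        for gid, g in enumerate(graphs):
            positions.append(g.positions)
            types.append(g.node_types)
            edges.append(g.edge_index + offset)
            assign.append(np.full(g.n_nodes, gid, dtype=np.intp))
            labels.append(-1 if g.label is None else g.label)
            offset += g.n_nodes
        label_arr = np.array(labels, dtype=np.intp)
        return cls(
            positions=np.concatenate(positions, axis=0),
            node_types=np.concatenate(types, axis=0),
            edge_index=np.concatenate(edges, axis=1),
            node2graph=np.concatenate(assign),
            n_graphs=len(graphs),
            labels=None if np.all(label_arr < 0) else label_arr,
            neighbor_radius=max(g.neighbor_radius for g in graphs),
        )

    @property
    def n_nodes(self) -> int:
        return len(self.node_types)


# -- hierarchical container I/O ----------------------------------------------

def save_graphs(graphs: Sequence[ProteinGraph], path) -> None:
    """Store graphs in an HDF5 file under /<graph_id>/{positions,types,edges,label}."""
    with h5py.File(path, "w") as fh:
        for idx, g in enumerate(graphs):
            gid = g.structure_id or f"graph{idx}"
            grp = fh.create_group(f"{gid}#{g.site_rank}#{idx}")
            grp.create_dataset("positions", data=g.positions)
            grp.create_dataset("types", data=g.node_types.astype(np.int64))
            grp.create_dataset("edges", data=g.edge_index.astype(np.int64))
            grp.attrs["label"] = -1 if g.label is None else int(g.label)
            grp.attrs["resolution"] = g.resolution
            grp.attrs["structure_id"] = g.structure_id
            grp.attrs["site_rank"] = g.site_rank
            grp.attrs["scheme_version"] = g.scheme_version
            grp.attrs["neighbor_radius"] = g.neighbor_radius


def load_graphs(path) -> list[ProteinGraph]:
    out: list[ProteinGraph] = []
    with h5py.File(path, "r") as fh:
        for key in sorted(fh, key=lambda k: int(k.rsplit("#", 1)[1])):
            grp = fh[key]
            label = int(grp.attrs["label"])
            out.append(
                ProteinGraph(
                    positions=np.array(grp["positions"], dtype=np.float64),
                    node_types=np.array(grp["types"], dtype=np.intp),
                    edge_index=np.array(grp["edges"], dtype=np.intp),
                    resolution=str(grp.attrs["resolution"]),
                    label=None if label < 0 else label,
                    structure_id=str(grp.attrs["structure_id"]),
                    site_rank=int(grp.attrs["site_rank"]),
                    scheme_version=str(grp.attrs["scheme_version"]),
                    neighbor_radius=float(grp.attrs["neighbor_radius"]),
                )
            )
    return out
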