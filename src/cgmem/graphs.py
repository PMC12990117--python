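"""Molecule-level contact graphs and network centralities.

Two molecules of one kind (cation or lipid) are in contact when any pair
of their hydrophobic tail sites lies within the first coordination shell —
the first minimum of the tail–tail radial distribution function, 0.7 nm
for the Martini-like beads analyzed here.  Per-frame graphs over all
molecules of the kind (isolated ones retained) feed the two measures used
to characterize aggregation: degree (number of direct contacts, a local
property) and closeness centrality (a long-range one, near 0 for dispersed
molecules and rising toward 1 inside compact aggregates).

Closeness on disconnected graphs uses the reachable-set form with the
Wasserman–Faust scaling ((r−1)/(n−1)) · ((r−1)/Σd), which reduces to
(n−1)/Σd on connected graphs and assigns 0 to isolated nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .core_io import Frame, RoleMap, select

logger = logging.getLogger("cgmem")

DEFAULT_CUTOFF = 0.7  # nm, tail-tail RDF first minimum

_KIND_ROLES = {"cation": "cation_tail", "lipid": "lipid_tail"}


def build_contact_graph(
    frame: Frame,
    role_map: RoleMap,
    node_kind: str = "cation",
    cutoff: float = DEFAULT_CUTOFF,
) -> nx.Graph:
    """Per-frame contact graph over all molecules of one kind.

    Nodes are molecule ids; an edge joins A and B iff the minimum-image
    distance between some tail site of A and some tail site of B is
    ≤ `cutoff`.  Neighbor search uses a periodic KD-tree (cell-list
    equivalent), so construction is near-linear in bead count.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if node_kind not in _KIND_ROLES:
        raise ValueError(f"node_kind must be one of {sorted(_KIND_ROLES)}")
    groups = select(frame, role_map, _KIND_ROLES[node_kind])
    g = nx.Graph(kind=node_kind, time=frame.time, cutoff=cutoff)
    if not groups:
        logger.warning("contact graph: no %s molecules in frame", node_kind)
        return g
    g.add_nodes_from(groups.keys())

    idx = np.concatenate(list(groups.values()))
    owner = np.concatenate(
        [np.full(len(v), mol) for mol, v in groups.items()]
    )
    pos = np.mod(frame.positions[idx], frame.box.lengths)
    tree = cKDTree(pos, boxsize=frame.box.lengths)
    for i, j in tree.query_pairs(r=cutoff):
        a, b = int(owner[i]), int(owner[j])
        if a != b:
            g.add_edge(a, b)
    return g


def degree_values(graph: nx.Graph):
    """Per-node degrees and their mean over ALL nodes (isolated included)."""
    deg = {n: d for n, d in graph.degree()}
    mean = float(np.mean(list(deg.values()))) if deg else 0.0
    return deg, mean


def closeness_values(graph: nx.Graph):
    """Per-node closeness centrality (Wasserman–Faust scaled) and mean.

    For node v reaching r nodes (itself included) with shortest-path sum
    Σd: closeness = ((r−1)/(n−1))·((r−1)/Σd); isolated nodes score 0."""
    clo = nx.closeness_centrality(graph, wf_improved=True)
    mean = float(np.mean(list(clo.values()))) if clo else 0.0
    return clo, mean


@dataclass
class CentralitySummary:
    """Pooled per-node per-frame centrality values over a trajectory
    window."""

    mean_degree: float
    mean_closeness: float
    degrees: np.ndarray
    closenesses: np.ndarray
    n_frames: int

    def histogram(self, which: str = "closeness", bins=50):
        data = self.closenesses if which == "closeness" else self.degrees
        return np.histogram(data, bins=bins)


def centrality_time_average(
    frames,
    role_map: RoleMap,
    node_kind: str,
    window: slice | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> CentralitySummary:
    """Degree and closeness pooled over node–frame pairs in a window.

    `window` defaults to the final 20% of frames, the steady-state portion
    of a production run."""
    frames = list(frames)
    if window is None:
        window = slice(int(np.floor(0.8 * len(frames))), len(frames))
    selected = frames[window]
    if not selected:
        raise ValueError("empty analysis window")
    all_deg, all_clo = [], []
    for frame in selected:
        g = build_contact_graph(frame, role_map, node_kind, cutoff)
        deg, _ = degree_values(g)
        clo, _ = closeness_values(g)
        all_deg.extend(deg.values())
        all_clo.extend(clo.values())
    degrees = np.array(all_deg, dtype=float)
    closenesses = np.array(all_clo, dtype=float)
    return CentralitySummary(
        float(degrees.mean()) if degrees.size else 0.0,
        float(closenesses.mean()) if closenesses.size else 0.0,
        degrees,
        closenesses,
        len(selected),
    )


def connected_components(graph: nx.Graph):
    """Component partition, size distribution and largest-component
    fraction (aggregation diagnostics: a micelle or nanodroplet shows up
    as one dominant component)."""
    comps = [set(c) for c in nx.connected_components(graph)]
    comps.sort(key=len, reverse=True)
    sizes = np.array([len(c) for c in comps], dtype=int)
    n = graph.number_of_nodes()
    largest_fraction = float(sizes[0] / n) if n else 0.0
    return comps, sizes, largest_fraction


def write_edge_list(graph: nx.Graph, path) -> None:
    """One edge per line: 'node_a node_b'."""
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a} {b}\n")
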