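"""Residue contact networks and divisive community decomposition.

One node per amino-acid residue (CB atom, CA for glycine) plus one node
per ligand (configurable atom, default C2); an undirected, unweighted
edge joins two nodes whose node atoms lie within the cutoff (default
6.7 Å). Communities are found divisively: repeatedly remove the single
edge of highest shortest-path betweenness (ties broken by lexicographic
edge id) until the graph falls apart into at least ``omega`` connected
components.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .errors import SpecError, TopologyError
from .structures_io import Structure, Trajectory, is_ligand_candidate

__all__ = [
    "NetworkConfig",
    "ResidueGraph",
    "CommunityPartition",
    "node_labels",
    "build_residue_network",
    "edge_betweenness",
    "girvan_newman_partition",
    "partition_series",
    "edge_list_tsv",
    "partition_series_tsv",
]

_AA_131 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "HSD": "H", "HSE": "H", "HSP": "H",
    "ILE": "I", "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

Edge = tuple[str, str]


def _edge(u: str, v: str) -> Edge:
    return (u, v) if u < v else (v, u)


@dataclass(frozen=True)
class NetworkConfig:
    cutoff: float = 6.7                # Å
    ligand_node_atom: str = "C2"
    omega: int = 6
    n_select_frames: int = 10
    window_ns: float = 100.0
    include_ligands: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise SpecError("cutoff must be > 0")
        if self.omega < 1:
            raise SpecError("omega must be >= 1")


@dataclass
class ResidueGraph:
    """Undirected simple graph over residue/ligand node labels."""

    nodes: list[str]
    edges: set[Edge] = field(default_factory=set)

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise SpecError(f"self-loop on node {u!r}")

    def adjacency(self) -> dict[str, list[str]]:
        adj: dict[str, list[str]] = {n: [] for n in self.nodes}
        for u, v in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        return adj

    def connected_components(self) -> list[list[str]]:
        adj = self.adjacency()
        seen: set[str] = set()
        comps: list[list[str]] = []
        for start in self.nodes:
            if start in seen:
                continue
            comp, queue = [], deque([start])
            seen.add(start)
            while queue:
                u = queue.popleft()
                comp.append(u)
                for w in adj[u]:
                    if w not in seen:
                        seen.add(w)
                        queue.append(w)
            comps.append(comp)
        return comps


@dataclass
class CommunityPartition:
    assignment: dict[str, int]
    n_communities: int

    def labels(self, node_order: list[str]) -> np.ndarray:
        return np.array([self.assignment[n] for n in node_order], dtype=int)

    def community_of(self, node: str) -> int:
        return self.assignment[node]


# ---------------------------------------------------------------------------
# node labelling and graph construction
# ---------------------------------------------------------------------------

def node_labels(
    structure: Structure, config: NetworkConfig | None = None
) -> tuple[list[str], list[int]]:
    """Node labels and their node-atom indices, in topology order.

    Protein residues are labelled with one-letter code + printed residue
    number (chain-qualified when the structure has several chains);
    ligands are labelled by residue name. Raises :class:`TopologyError`
    listing every residue that lacks its node atom.
    """
    config = config or NetworkConfig()
    chains = {a.chain for a in structure.atoms}
    multichain = len(chains) > 1

    labels: list[str] = []
    indices: list[int] = []
    missing: list[str] = []
    seen_residues: dict[str, None] = {}
    by_residue: dict[str, list[int]] = structure.residue_atom_indices()
    for rid, atom_idx in by_residue.items():
        if rid in seen_residues:
            continue
        seen_residues[rid] = None
        first = structure.atoms[atom_idx[0]]
        if is_ligand_candidate(first):
            if not config.include_ligands:
                continue
            target = config.ligand_node_atom
            label = first.residue_name
        elif first.is_hetatm:
            continue  # solvent / ions are never nodes
        else:
            target = "CA" if first.residue_name == "GLY" else "CB"
            one = _AA_131.get(first.residue_name, first.residue_name)
            label = f"{one}{first.residue_seq}{first.icode}"
            if multichain:
                label = f"{first.chain}:{label}"
        hit = next(
            (i for i in atom_idx if structure.atoms[i].name == target), None
        )
        if hit is None:
            missing.append(f"{rid} ({first.residue_name}, wants {target})")
        else:
            labels.append(label)
            indices.append(hit)
    if missing:
        raise TopologyError(
            "residues missing their network-node atom: " + "; ".join(missing)
        )
    # disambiguate duplicate ligand labels
    if len(set(labels)) != len(labels):
        counts: dict[str, int] = {}
        for i, lab in enumerate(labels):
            counts[lab] = counts.get(lab, 0) + 1
        seen: dict[str, int] = {}
        for i, lab in enumerate(labels):
            if counts[lab] > 1:
                seen[lab] = seen.get(lab, 0) + 1
                labels[i] = f"{lab}#{seen[lab]}"
    return labels, indices


def build_residue_network(
    frame: np.ndarray,
    topology: Structure,
    config: NetworkConfig | None = None,
) -> ResidueGraph:
    """Contact graph of one frame: edge iff node-atom distance ≤ cutoff."""
    config = config or NetworkConfig()
    labels, indices = node_labels(topology, config)
    xyz = np.asarray(frame, dtype=float)[indices]
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    iu, ju = np.triu_indices(len(labels), k=1)
    within = dist[iu, ju] <= config.cutoff
    edges = {_edge(labels[i], labels[j])
             for i, j in zip(iu[within], ju[within])}
    return ResidueGraph(nodes=list(labels), edges=edges)


# ---------------------------------------------------------------------------
# betweenness and Girvan–Newman
# ---------------------------------------------------------------------------

def edge_betweenness(graph: ResidueGraph) -> dict[Edge, float]:
    """Shortest-path edge betweenness over unordered node pairs.

    Unit edge weights; pairs in different components contribute nothing;
    multiple shortest paths split their contribution equally (Brandes
    accumulation, halved to count each unordered pair once).
    """
    adj = graph.adjacency()
    scores: dict[Edge, float] = {e: 0.0 for e in graph.edges}
    for s in graph.nodes:
        # BFS from s with path counting
        sigma = {v: 0.0 for v in graph.nodes}
        dist = {v: -1 for v in graph.nodes}
        preds: dict[str, list[str]] = {v: [] for v in graph.nodes}
        sigma[s], dist[s] = 1.0, 0
        order: list[str] = []
        queue = deque([s])
        while queue:
            u = queue.popleft()
            order.append(u)
            for w in adj[u]:
                if dist[w] < 0:
                    dist[w] = dist[u] + 1
                    queue.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
                    preds[w].append(u)
        # dependency accumulation onto edges
        delta = {v: 0.0 for v in order}
        for w in reversed(order):
            for v in preds[w]:
                c = sigma[v] / sigma[w] * (1.0 + delta[w])
                scores[_edge(v, w)] += c
                delta[v] += c
    return {e: s / 2.0 for e, s in scores.items()}


def _components_partition(graph: ResidueGraph) -> CommunityPartition:
    comps = graph.connected_components()
    # label communities by first-node order for determinism
    first_pos = {i: min(graph.nodes.index(n) for n in c)
                 for i, c in enumerate(comps)}
    ranking = sorted(range(len(comps)), key=lambda i: first_pos[i])
    assignment: dict[str, int] = {}
    for new_label, old in enumerate(ranking):
        for n in comps[old]:
            assignment[n] = new_label
    return CommunityPartition(assignment=assignment, n_communities=len(comps))


def girvan_newman_partition(
    graph: ResidueGraph, omega: int
) -> CommunityPartition:
    """Divisive partition: cut the highest-betweenness edge until ≥ omega parts.

    Betweenness is recomputed from scratch after every removal; among
    equally central edges the lexicographically smallest edge id is cut.
    If the input graph already has at least omega components it is
    partitioned as-is with no removal.
    """
    if omega > len(graph.nodes):
        raise SpecError(
            f"omega={omega} exceeds node count {len(graph.nodes)}"
        )
    work = ResidueGraph(nodes=list(graph.nodes), edges=set(graph.edges))
    while len(work.connected_components()) < omega:
        scores = edge_betweenness(work)
        if not scores:
            break  # no edges left; components == node count >= omega
        top = max(scores.values())
        victim = min(e for e, s in scores.items() if s == top)
        work.edges.discard(victim)
    return _components_partition(work)


# ---------------------------------------------------------------------------
# frame selection and series
# ---------------------------------------------------------------------------

def select_frames(traj: Trajectory, config: NetworkConfig) -> list[int]:
    """Equally spaced analysis frames over the trailing window.

    With frame times: n frames at spacing window/n ending at the final
    frame (e.g. the default picks one frame per 10 ns over the last
    100 ns). Without times: n equally strided frame indices ending at the
    last frame.
    """
    n_sel = config.n_select_frames
    if n_sel < 1:
        raise SpecError("n_select_frames must be >= 1")
    if traj.frame_times is not None:
        times = np.asarray(traj.frame_times, dtype=float)
        t_end = times[-1]
        if t_end - times[0] < config.window_ns - 1e-9:
            raise SpecError(
                f"window of {config.window_ns} ns exceeds trajectory span "
                f"{t_end - times[0]:.3f} ns"
            )
        spacing = config.window_ns / n_sel
        targets = [t_end - config.window_ns + spacing * (i + 1)
                   for i in range(n_sel)]
        return [int(np.argmin(np.abs(times - t))) for t in targets]
    if traj.n_frames < n_sel:
        raise SpecError(
            f"cannot select {n_sel} frames from {traj.n_frames}-frame trajectory"
        )
    stride = max(1, traj.n_frames // n_sel)
    idx = [traj.n_frames - 1 - stride * (n_sel - 1 - i) for i in range(n_sel)]
    if idx[0] < 0:
        raise SpecError("selection window exceeds trajectory length")
    return idx


def partition_series(
    traj: Trajectory,
    config: NetworkConfig | None = None,
    frame_indices: list[int] | None = None,
) -> list[CommunityPartition]:
    """One community partition per selected frame, in frame order."""
    config = config or NetworkConfig()
    if frame_indices is None:
        frame_indices = select_frames(traj, config)
    out = []
    for i in frame_indices:
        g = build_residue_network(traj.frames[i], traj.topology, config)
        out.append(girvan_newman_partition(g, config.omega))
    return out


# ---------------------------------------------------------------------------
# TSV export
# ---------------------------------------------------------------------------

def edge_list_tsv(graph: ResidueGraph) -> str:
    lines = ["node_a\tnode_b"]
    lines.extend(f"{u}\t{v}" for u, v in sorted(graph.edges))
    return "\n".join(lines) + "\n"


def partition_series_tsv(
    partitions: list[CommunityPartition], frame_indices: list[int] | None = None
) -> str:
    frames = frame_indices or list(range(len(partitions)))
    lines = ["frame\tnode\tcommunity"]
    for f, part in zip(frames, partitions):
        for node in sorted(part.assignment):
            lines.append(f"{f}\t{node}\t{part.assignment[node]}")
    return "\n".join(lines) + "\n"
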