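"""Residue contacts, contact probabilities and difference contact networks.

A contact exists between two residues in a frame when any of their heavy
(non-hydrogen) atoms lie within a cutoff distance (default 4.5 A) and the
residues are separated by at least ``min_separation`` positions in
sequence (default 3), which removes trivially bonded neighbours.  Contact
probability is the per-pair occupancy over frames; the difference network
df = P(mutant) - P(wild type) quantifies contacts formed (df > 0) and
broken (df < 0) by a perturbation.  Communities of residues densely
connected through stable contacts are found by modularity maximization and
consolidated across trajectory blocks into a consensus partition; the net
df summed over a community interface gives the community-level contact
change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .trajectory import Structure, Trajectory

__all__ = [
    "ContactProbabilityMatrix",
    "DifferenceNetwork",
    "CommunityPartition",
    "CommunityDifferenceGraph",
    "frame_contacts",
    "frame_contacts_bruteforce",
    "contact_probabilities",
    "difference_network",
    "consensus_communities",
    "community_difference",
    "significant_edges",
]

DEFAULT_CUTOFF = 4.5          # A, heavy-atom contact distance (inclusive)
DEFAULT_MIN_SEPARATION = 3    # |i - j| >= 3 in sequence


@dataclass(frozen=True)
class ContactProbabilityMatrix:
    """Symmetric per-residue-pair contact occupancy in [0, 1]."""

    values: np.ndarray              # (R, R) symmetric, zero diagonal/band
    residue_labels: tuple           # (chain, resid) per compact index
    n_frames_used: int
    min_sequence_separation: int

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be a square matrix")
        if not np.allclose(v, v.T):
            raise ValueError("contact probability matrix must be symmetric")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("contact probabilities must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        labels = [f"{c}{r}" for c, r in self.residue_labels]
        return pd.DataFrame(self.values, index=labels, columns=labels)


@dataclass(frozen=True)
class DifferenceNetwork:
    """df = P(system B) - P(system A) per residue pair, in [-1, 1]."""

    df: np.ndarray
    residue_labels: tuple
    system_labels: tuple[str, str]   # (A, B)

    def __post_init__(self):
        d = np.asarray(self.df, float)
        if not np.allclose(d, d.T):
            raise ValueError("df matrix must be symmetric")
        if np.abs(d).max() > 1 + 1e-12:
            raise ValueError("|df| must be <= 1")
        object.__setattr__(self, "df", d)

    @property
    def n_residues(self) -> int:
        return self.df.shape[0]


@dataclass(frozen=True)
class CommunityPartition:
    """Residue -> community labels (ids contiguous from 1) with per-residue
    consensus stability in [0, 1]."""

    labels: np.ndarray              # (R,) int, community id per residue
    stability: np.ndarray           # (R,) float consensus fraction
    residue_labels: tuple
    singletons: tuple = ()          # residues with no stable contacts, flagged

    def __post_init__(self):
        lab = np.asarray(self.labels, int)
        ids = np.unique(lab)
        if lab.min() < 1 or not np.array_equal(ids, np.arange(1, len(ids) + 1)):
            raise ValueError("community ids must be contiguous from 1")
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "stability",
                           np.asarray(self.stability, float))

    @property
    def n_communities(self) -> int:
        return int(self.labels.max())

    def members(self, community: int) -> np.ndarray:
        return np.nonzero(self.labels == community)[0]


@dataclass(frozen=True)
class CommunityDifferenceGraph:
    """Community-level net contact changes.

    ``edges[(c1, c2)]`` with c1 < c2 is the sum of signed pair df across the
    interface; ``intra[c]`` sums pairs inside community c.
    """

    sizes: dict                     # community id -> residue count
    edges: dict                     # (c1, c2) -> net df
    intra: dict                     # c -> net df within the community

    def total_df(self) -> float:
        return float(sum(self.edges.values()) + sum(self.intra.values()))


# ---------------------------------------------------------------------------
# per-frame contact kernel
# ---------------------------------------------------------------------------

def _heavy_atom_info(topology: Structure):
    heavy = np.nonzero(
        np.char.upper(topology.elements.astype(str)) != "H")[0]
    if len(heavy) == 0:
        raise ValueError("topology has no heavy atoms")
    res_of_atom = topology.residue_index_per_atom()[heavy]
    # sequence separation only applies within a chain; cross-chain pairs are
    # always "far" in sequence
    keys = topology.residue_keys()
    chain_of_res = np.array([k[0] for k in keys])
    resid_of_res = np.array([k[1] for k in keys])
    return heavy, res_of_atom, chain_of_res, resid_of_res


def _pair_allowed(i, j, chain_of_res, resid_of_res, min_separation) -> bool:
    if i == j:
        return False
    if chain_of_res[i] != chain_of_res[j]:
        return True
    return abs(int(resid_of_res[i]) - int(resid_of_res[j])) >= min_separation


def frame_contacts(frame: np.ndarray, topology: Structure,
                   cutoff: float = DEFAULT_CUTOFF,
                   min_separation: int = DEFAULT_MIN_SEPARATION,
                   ) -> set[tuple[int, int]]:
    """Residue contact set of one frame (fast neighbor-search kernel).

    Returns compact residue-index pairs (i < j) for which the closest
    heavy-atom distance is <= ``cutoff`` (inclusive boundary) and the
    sequence separation is >= ``min_separation``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    heavy, res_of_atom, chain_of_res, resid_of_res = _heavy_atom_info(topology)
    tree = cKDTree(np.asarray(frame, float)[heavy])
    pairs = tree.query_pairs(r=cutoff)
    out: set[tuple[int, int]] = set()
    for a, b in pairs:
        ri, rj = int(res_of_atom[a]), int(res_of_atom[b])
        if ri > rj:
            ri, rj = rj, ri
        if _pair_allowed(ri, rj, chain_of_res, resid_of_res, min_separation):
            out.add((ri, rj))
    return out


def frame_contacts_bruteforce(frame: np.ndarray, topology: Structure,
                              cutoff: float = DEFAULT_CUTOFF,
                              min_separation: int = DEFAULT_MIN_SEPARATION,
                              ) -> set[tuple[int, int]]:
    """All-pairs O(N^2) reference kernel (used to validate the fast path)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    heavy, res_of_atom, chain_of_res, resid_of_res = _heavy_atom_info(topology)
    xyz = np.asarray(frame, float)[heavy]
    out: set[tuple[int, int]] = set()
    for a in range(len(heavy)):
        d = np.linalg.norm(xyz[a + 1:] - xyz[a], axis=1)
        for off in np.nonzero(d <= cutoff)[0]:
            b = a + 1 + int(off)
            ri, rj = int(res_of_atom[a]), int(res_of_atom[b])
            if ri > rj:
                ri, rj = rj, ri
            if _pair_allowed(ri, rj, chain_of_res, resid_of_res, min_separation):
                out.add((ri, rj))
    return out


def contact_probabilities(trajectory: Trajectory,
                          cutoff: float = DEFAULT_CUTOFF,
                          min_separation: int = DEFAULT_MIN_SEPARATION,
                          ) -> ContactProbabilityMatrix:
    """Per-pair occupancy: fraction of frames in which the pair is in contact."""
    if trajectory.n_frames < 1:
        raise ValueError("need at least one frame")
    top = trajectory.topology
    R = top.n_residues
    counts = np.zeros((R, R))
    for f in range(trajectory.n_frames):
        for i, j in frame_contacts(trajectory.xyz[f], top, cutoff,
                                   min_separation):
            counts[i, j] += 1
            counts[j, i] += 1
    return ContactProbabilityMatrix(
        values=counts / trajectory.n_frames,
        residue_labels=tuple(top.residue_keys()),
        n_frames_used=trajectory.n_frames,
        min_sequence_separation=min_separation)


def difference_network(p_wt: ContactProbabilityMatrix,
                       p_mut: ContactProbabilityMatrix,
                       labels: tuple[str, str] = ("WT", "mutant"),
                       ) -> DifferenceNetwork:
    """df = P(mutant) - P(wild type); formed where df > 0, broken where < 0."""
    if p_wt.residue_labels != p_mut.residue_labels:
        raise ValueError("contact matrices cover different residue universes")
    if p_wt.min_sequence_separation != p_mut.min_sequence_separation:
        raise ValueError("contact matrices use different sequence separations")
    return DifferenceNetwork(df=p_mut.values - p_wt.values,
                             residue_labels=p_wt.residue_labels,
                             system_labels=labels)


# ---------------------------------------------------------------------------
# communities
# ---------------------------------------------------------------------------

def _modularity_partition(graph: nx.Graph, n_nodes: int) -> np.ndarray:
    """Greedy modularity communities -> integer label per node (0-based).

    Nodes absent from the graph (no qualifying edges) each get their own
    label.  Deterministic: networkx's greedy CNM algorithm has no RNG, and
    ties are resolved by sorted community order.
    """
    labels = np.full(n_nodes, -1, dtype=int)
    next_label = 0
    if graph.number_of_edges() > 0:
        comms = nx.community.greedy_modularity_communities(graph,
                                                           weight="weight")
        for comm in sorted((sorted(c) for c in comms), key=lambda c: c[0]):
            for node in comm:
                labels[node] = next_label
            next_label += 1
    for node in range(n_nodes):
        if labels[node] < 0:
            labels[node] = next_label
            next_label += 1
    return labels


def consensus_communities(probability_matrices: Sequence[ContactProbabilityMatrix],
                          stable_threshold: float = 0.7,
                          seed: int = 0) -> CommunityPartition:
    """Consensus residue communities from stable contacts.

    Per block: residues are nodes; pairs whose contact probability is at
    least ``stable_threshold`` are edges weighted by that probability;
    communities maximize modularity.  Across blocks: the co-classification
    fraction (how often two residues share a community) is thresholded by
    majority vote (> 1/2) to form a consensus graph whose modularity
    partition is the consensus.  ``stability`` of a residue is the mean
    fraction of its consensus-community peers it is co-classified with
    across blocks.  Residues with no stable contact in any block become
    flagged singleton communities.

    ``seed`` is accepted for interface stability; the algorithm is fully
    deterministic.
    """
    if not probability_matrices:
        raise ValueError("need at least one probability matrix")
    if not 0.0 < stable_threshold <= 1.0:
        raise ValueError("stable_threshold must be in (0, 1]")
    first = probability_matrices[0]
    R = first.n_residues
    for m in probability_matrices[1:]:
        if m.residue_labels != first.residue_labels:
            raise ValueError("blocks cover different residue universes")

    block_labels = []
    for m in probability_matrices:
        g = nx.Graph()
        g.add_nodes_from(range(R))
        ii, jj = np.nonzero(np.triu(m.values >= stable_threshold, k=1))
        for i, j in zip(ii, jj):
            g.add_edge(int(i), int(j), weight=float(m.values[i, j]))
        block_labels.append(_modularity_partition(g, R))
    block_labels = np.array(block_labels)           # (n_blocks, R)

    co = np.zeros((R, R))
    for lab in block_labels:
        co += lab[:, None] == lab[None, :]
    co /= len(block_labels)

    consensus_graph = nx.Graph()
    consensus_graph.add_nodes_from(range(R))
    ii, jj = np.nonzero(np.triu(co > 0.5, k=1))
    for i, j in zip(ii, jj):
        consensus_graph.add_edge(int(i), int(j), weight=float(co[i, j]))
    labels0 = _modularity_partition(consensus_graph, R)

    # relabel contiguous from 1 in order of first appearance
    remap: dict[int, int] = {}
    labels = np.empty(R, dtype=int)
    for i, lab in enumerate(labels0):
        labels[i] = remap.setdefault(int(lab), len(remap) + 1)

    stability = np.ones(R)
    for i in range(R):
        peers = np.nonzero((labels == labels[i]) & (np.arange(R) != i))[0]
        if len(peers):
            stability[i] = float(np.mean(co[i, peers]))

    # residues never in a stable contact in any block
    any_stable = np.zeros(R, dtype=bool)
    for m in probability_matrices:
        v = m.values >= stable_threshold
        np.fill_diagonal(v, False)
        any_stable |= v.any(axis=1)
    singletons = tuple(int(i) for i in np.nonzero(~any_stable)[0])

    return CommunityPartition(labels=labels, stability=stability,
                              residue_labels=first.residue_labels,
                              singletons=singletons)


def community_difference(diff: DifferenceNetwork,
                         partition: CommunityPartition,
                         ) -> CommunityDifferenceGraph:
    """Sum signed pair df over every community interface and interior."""
    if len(partition.labels) != diff.n_residues:
        raise ValueError("partition does not cover the difference network")
    lab = partition.labels
    R = diff.n_residues
    sizes = {int(c): int(np.sum(lab == c))
             for c in range(1, partition.n_communities + 1)}
    edges: dict[tuple[int, int], float] = {}
    intra: dict[int, float] = {c: 0.0 for c in sizes}
    ii, jj = np.triu_indices(R, k=1)
    for i, j in zip(ii, jj):
        d = diff.df[i, j]
        ci, cj = int(lab[i]), int(lab[j])
        if ci == cj:
            intra[ci] += d
        else:
            key = (min(ci, cj), max(ci, cj))
            edges[key] = edges.get(key, 0.0) + d
    return CommunityDifferenceGraph(sizes=sizes, edges=edges, intra=intra)


def significant_edges(diff: DifferenceNetwork, threshold: float = 0.5):
    """Residue pairs with |df| >= threshold (inclusive), strongest first.

    Ties in |df| are broken by ascending pair index.  Returns a list of
    ((i, j), df) with compact residue indices i < j.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    ii, jj = np.triu_indices(diff.n_residues, k=1)
    out = []
    for i, j in zip(ii, jj):
        d = float(diff.df[i, j])
        if d != 0.0 and abs(d) >= threshold:
            out.append(((int(i), int(j)), d))
    out.sort(key=lambda e: (-abs(e[1]), e[0]))
    return out


def edges_to_frame(diff: DifferenceNetwork, edges) -> pd.DataFrame:
    """Tidy (res_i, res_j, df) table for export."""
    rows = [{"res_i": f"{diff.residue_labels[i][0]}{diff.residue_labels[i][1]}",
             "res_j": f"{diff.residue_labels[j][0]}{diff.residue_labels[j][1]}",
             "df": d} for (i, j), d in edges]
    return pd.DataFrame(rows, columns=["res_i", "res_j", "df"])
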