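"""Residue interaction networks from coordinates.

Nodes are residues, edges are typed physicochemical contacts: hydrogen
bonds, van der Waals packing, π–π stacking and π–cation pairs.  The
criteria are distance-based (crystal structures and coarse models carry no
hydrogens, so no donor-angle geometry is applied):

* hbond — donor/acceptor heavy atoms (N/O/S with a plausible role) within
  3.5 Å;
* vdw — side-chain heavy atoms within r_i + r_j + 0.5 Å (Bondi radii);
* pipi — aromatic ring centroids within 6.5 Å;
* pication — cationic-group center to ring centroid within 5.0 Å.

Each residue pair carries at most one edge per type (the closest
qualifying atom pair); sequence-adjacent residues of the same chain are
excluded by default.  Edges are stored with a canonical residue order, so
network differences are independent of atom ordering in the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import Structure
from .descriptors import BONDI_RADII, FALLBACK_RADIUS
from .errors import LookupError_

__all__ = [
    "ContactRules",
    "InteractionEdge",
    "InteractionNetwork",
    "NetworkDiff",
    "detect_interactions",
    "network_diff",
    "neighborhood",
    "edges_to_dataframe",
    "write_edges",
    "read_edges",
]

BACKBONE_NAMES = {"N", "CA", "C", "O"}

#: ring atom names of the aromatic residues
AROMATIC_RINGS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

#: atoms whose centroid defines the cationic group
CATION_GROUPS = {
    "ARG": ("CZ", "NH1", "NH2", "NE"),
    "LYS": ("NZ",),
}


@dataclass
class ContactRules:
    """Distance cutoffs of the contact criteria (Å), all configurable."""

    hbond_cutoff: float = 3.5
    vdw_margin: float = 0.5
    pipi_cutoff: float = 6.5
    pication_cutoff: float = 5.0
    exclude_adjacent: bool = True  # skip |Δresid| == 1 within a chain


@dataclass(frozen=True)
class ResidueKey:
    chain: str
    resid: int
    resname: str

    def sort_key(self):
        return (self.chain, self.resid)


@dataclass
class InteractionEdge:
    """A typed residue–residue contact (canonical residue order)."""

    res_i: ResidueKey
    res_j: ResidueKey
    type: str  # hbond | vdw | pipi | pication
    distance: float
    inter_chain: bool

    def key(self) -> tuple:
        return (
            (self.res_i.chain, self.res_i.resid),
            (self.res_j.chain, self.res_j.resid),
            self.type,
        )


@dataclass
class InteractionNetwork:
    """Residue nodes plus typed contact edges for one structure."""

    nodes: set[ResidueKey]
    edges: list[InteractionEdge]
    label: str = ""

    def edge_keys(self) -> set[tuple]:
        return {e.key() for e in self.edges}

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for n in self.nodes:
            g.add_node((n.chain, n.resid), resname=n.resname)
        for e in self.edges:
            g.add_edge(
                (e.res_i.chain, e.res_i.resid),
                (e.res_j.chain, e.res_j.resid),
                key=e.type,
                distance=e.distance,
                inter_chain=e.inter_chain,
            )
        return g


def _residue_atoms(structure: Structure) -> dict[ResidueKey, np.ndarray]:
    """Heavy protein atoms grouped per residue (indices into the structure)."""
    groups: dict[ResidueKey, list[int]] = {}
    for i in range(structure.natoms):
        if structure.het[i] or structure.element[i].upper() == "H":
            continue
        key = ResidueKey(structure.chain[i], int(structure.resid[i]), structure.resname[i])
        groups.setdefault(key, []).append(i)
    return {k: np.array(v) for k, v in groups.items()}


def _is_polar(structure: Structure, i: int) -> bool:
    return structure.element[i].upper() in ("N", "O", "S")


def _canonical(a: ResidueKey, b: ResidueKey):
    return (a, b) if a.sort_key() <= b.sort_key() else (b, a)


def detect_interactions(
    structure: Structure,
    rules: ContactRules | None = None,
    label: str = "",
) -> InteractionNetwork:
    """Detect typed residue–residue contacts in one structure."""
    rules = rules or ContactRules()
    residues = _residue_atoms(structure)
    keys = sorted(residues, key=ResidueKey.sort_key)
    coords = structure.coords

    # precompute per-residue feature atoms
    polar: dict[ResidueKey, np.ndarray] = {}
    sidechain: dict[ResidueKey, np.ndarray] = {}
    ring_centroid: dict[ResidueKey, np.ndarray] = {}
    cation_center: dict[ResidueKey, np.ndarray] = {}
    for k, idx in residues.items():
        polar[k] = idx[[_is_polar(structure, i) for i in idx]]
        sidechain[k] = idx[[structure.name[i] not in BACKBONE_NAMES for i in idx]]
        if k.resname in AROMATIC_RINGS:
            ring = [i for i in idx if structure.name[i] in AROMATIC_RINGS[k.resname]]
            if len(ring) >= 3:
                ring_centroid[k] = coords[ring].mean(axis=0)
        if k.resname in CATION_GROUPS:
            grp = [i for i in idx if structure.name[i] in CATION_GROUPS[k.resname]]
            if grp:
                cation_center[k] = coords[grp].mean(axis=0)

    edges: list[InteractionEdge] = []

    def add_edge(a: ResidueKey, b: ResidueKey, etype: str, dist: float):
        ra, rb = _canonical(a, b)
        edges.append(
            InteractionEdge(ra, rb, etype, float(dist), inter_chain=ra.chain != rb.chain)
        )

    for ai in range(len(keys)):
        for bi in range(ai + 1, len(keys)):
            a, b = keys[ai], keys[bi]
            if (
                rules.exclude_adjacent
                and a.chain == b.chain
                and abs(a.resid - b.resid) == 1
            ):
                continue
            # hydrogen bond: closest polar-polar pair
            if polar[a].size and polar[b].size:
                d = cdist(coords[polar[a]], coords[polar[b]])
                if d.min() <= rules.hbond_cutoff:
                    add_edge(a, b, "hbond", d.min())
            # van der Waals between side-chain heavy atoms
            if sidechain[a].size and sidechain[b].size:
                d = cdist(coords[sidechain[a]], coords[sidechain[b]])
                ra = np.array(
                    [BONDI_RADII.get(structure.element[i].upper(), FALLBACK_RADIUS) for i in sidechain[a]]
                )
                rb = np.array(
                    [BONDI_RADII.get(structure.element[i].upper(), FALLBACK_RADIUS) for i in sidechain[b]]
                )
                limit = ra[:, None] + rb[None, :] + rules.vdw_margin
                if np.any(d <= limit):
                    add_edge(a, b, "vdw", d[d <= limit].min())
            # pi-pi stacking
            if a in ring_centroid and b in ring_centroid:
                d = float(np.linalg.norm(ring_centroid[a] - ring_centroid[b]))
                if d <= rules.pipi_cutoff:
                    add_edge(a, b, "pipi", d)
            # pi-cation (either orientation)
            for cat, aro in ((a, b), (b, a)):
                if cat in cation_center and aro in ring_centroid:
                    d = float(np.linalg.norm(cation_center[cat] - ring_centroid[aro]))
                    if d <= rules.pication_cutoff:
                        add_edge(cat, aro, "pication", d)

    return InteractionNetwork(nodes=set(keys), edges=edges, label=label)


@dataclass
class NetworkDiff:
    """Edge sets exclusive to each network plus the shared set."""

    only_a: list[InteractionEdge]
    only_b: list[InteractionEdge]
    shared: list[InteractionEdge]


def network_diff(net_a: InteractionNetwork, net_b: InteractionNetwork) -> NetworkDiff:
    """Exact set difference / intersection on canonical (pair, type) keys."""
    keys_a, keys_b = net_a.edge_keys(), net_b.edge_keys()
    return NetworkDiff(
        only_a=[e for e in net_a.edges if e.key() not in keys_b],
        only_b=[e for e in net_b.edges if e.key() not in keys_a],
        shared=[e for e in net_a.edges if e.key() in keys_b],
    )


def neighborhood(
    net: InteractionNetwork, residue: tuple[str, int], depth: int = 1
) -> InteractionNetwork:
    """Induced subnetwork within graph distance ``depth`` of a residue."""
    by_id = {(n.chain, n.resid): n for n in net.nodes}
    if residue not in by_id:
        raise LookupError_(f"residue {residue} not in network")
    g = net.to_networkx()
    ego = nx.ego_graph(g, residue, radius=depth)
    keep = set(ego.nodes)
    nodes = {by_id[n] for n in keep}
    edges = [
        e
        for e in net.edges
        if (e.res_i.chain, e.res_i.resid) in keep and (e.res_j.chain, e.res_j.resid) in keep
    ]
    return InteractionNetwork(nodes=nodes, edges=edges, label=f"{net.label}|{residue}±{depth}")


# ---------------------------------------------------------------------------
# edge-list input/output
# ---------------------------------------------------------------------------

def edges_to_dataframe(net: InteractionNetwork) -> pd.DataFrame:
    rows = [
        {
            "chain_i": e.res_i.chain,
            "resid_i": e.res_i.resid,
            "resname_i": e.res_i.resname,
            "chain_j": e.res_j.chain,
            "resid_j": e.res_j.resid,
            "resname_j": e.res_j.resname,
            "type": e.type,
            "distance": round(e.distance, 3),
            "inter_chain": e.inter_chain,
        }
        for e in net.edges
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chain_i", "resid_i", "resname_i",
            "chain_j", "resid_j", "resname_j",
            "type", "distance", "inter_chain",
        ],
    )


def write_edges(net: InteractionNetwork, path: str | Path) -> None:
    edges_to_dataframe(net).to_csv(path, sep="\t", index=False)


def read_edges(path: str | Path, label: str = "") -> InteractionNetwork:
    df = pd.read_csv(path, sep="\t")
    edges, nodes = [], set()
    for _, r in df.iterrows():
        a = ResidueKey(str(r["chain_i"]), int(r["resid_i"]), str(r["resname_i"]))
        b = ResidueKey(str(r["chain_j"]), int(r["resid_j"]), str(r["resname_j"]))
        a, b = _canonical(a, b)
        nodes.update((a, b))
        edges.append(
            InteractionEdge(a, b, str(r["type"]), float(r["distance"]), bool(r["inter_chain"]))
        )
    return InteractionNetwork(nodes=nodes, edges=edges, label=label)
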