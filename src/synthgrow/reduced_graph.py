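"""Reduced feature-graph representation and its vertex-pair similarity.

A molecule collapses to an acyclic graph of features: every SSSR ring becomes
one vertex, fused ring systems in which some atom belongs to more than two
SSSR rings collapse to a single "amalgamated" vertex, and maximal connected
clusters of acyclic lipophilic/untyped atoms become one vertex; every other
acyclic atom is a vertex of its own. Ring vertices that share atoms (fused
rings) are joined by an order-2 edge, all other adjacencies by order-1 edges,
so naphthalene and biphenyl reduce to distinguishable graphs.

Vertices carry a 10-bit label (the eight pharmacophore types plus `ring` and
`amalgamated ring`) and the number of atoms they represent.  Vertex-pair
similarity is the product of a size-difference penalty on the atom counts and
the Tanimoto index of the bit vectors; when the atom counts are equal it
reduces to the Tanimoto index, and an atom-count difference above five forces
it to zero regardless of bit overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .chemgraph import TypedMolecularGraph

#: bit positions of the 10-bit vertex label
BIT_ORDER = ("A", "D", "E", "P", "N", "R", "L", "0", "ring", "amalgamated")
BIT_INDEX = {name: i for i, name in enumerate(BIT_ORDER)}

#: the kernel cannot process vertices with more than six neighbors
MAX_DEGREE = 6

#: atom-count differences above this force the similarity to zero
_SD_CUTOFF = 5


@dataclass
class ReducedGraphVertex:
    """One feature vertex: 10-bit label, atom count, and member atoms."""

    bv: int  # 10-bit vector packed into an int, see BIT_ORDER
    ac: int  # number of atoms represented
    member_atoms: frozenset[int]
    # full atom sets of the SSSR rings behind a ring vertex; used for the
    # fused-ring (order 2) test, may overlap between vertices
    ring_atoms: frozenset[int] = frozenset()

    @property
    def bits(self) -> frozenset[str]:
        return frozenset(n for n, i in BIT_INDEX.items() if self.bv >> i & 1)

    @property
    def is_ring(self) -> bool:
        return bool(self.bv >> BIT_INDEX["ring"] & 1)


@dataclass
class ReducedGraph:
    """Acyclic feature graph; edge order 2 marks fused-ring adjacency."""

    vertices: list[ReducedGraphVertex]
    edges: list[tuple[int, int, int]]  # (i, j, order in {1, 2})
    source_id: str = ""
    rejected: bool = False  # True when some vertex exceeds MAX_DEGREE
    _adj: dict[int, list[int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._adj = {i: [] for i in range(len(self.vertices))}
        for i, j, _ in self.edges:
            self._adj[i].append(j)
            self._adj[j].append(i)

    def neighbors(self, i: int) -> list[int]:
        return self._adj[i]

    @property
    def types(self) -> list[frozenset[str]]:
        return [v.bits for v in self.vertices]


def _pack(bits: set[str]) -> int:
    return sum(1 << BIT_INDEX[b] for b in bits)


def tanimoto_bits(bv_a: int, bv_b: int) -> float:
    """Tanimoto index c / (a + b - c) of two packed bit vectors."""
    a = bin(bv_a).count("1")
    b = bin(bv_b).count("1")
    c = bin(bv_a & bv_b).count("1")
    denom = a + b - c
    return c / denom if denom else 0.0


def sd_factor(ac_a: int, ac_b: int) -> float:
    """Size-difference penalty: 1 at equal counts, 0 for differences > 5.

    Decays linearly in between (the simplest curve meeting both endpoints).
    """
    diff = abs(ac_a - ac_b)
    if diff > _SD_CUTOFF:
        return 0.0
    return 1.0 - diff / (_SD_CUTOFF + 1)


def vertex_similarity(v_a: ReducedGraphVertex, v_b: ReducedGraphVertex) -> float:
    """Similarity of two reduced-graph vertices: sd_factor x Tanimoto."""
    return sd_factor(v_a.ac, v_b.ac) * tanimoto_bits(v_a.bv, v_b.bv)


def build_reduced_graph(graph: TypedMolecularGraph) -> ReducedGraph:
    """Collapse a typed molecular graph to its reduced feature graph.

    The member-atom sets partition the heavy atoms (atoms shared between
    fused SSSR rings are assigned to the lower-indexed ring, while the full
    ring atom sets still drive the order-2 fused-ring edges). Molecules whose
    reduced graph has a vertex with more than six neighbors are flagged
    ``rejected`` for the caller to discard.
    """
    mol = graph.mol
    n_atoms = mol.GetNumAtoms()
    types = graph.types
    ring_info = mol.GetRingInfo()
    sssr = [frozenset(r) for r in ring_info.AtomRings()]

    # group SSSR rings into fused systems (rings sharing >= 1 atom)
    ring_sys = nx.Graph()
    ring_sys.add_nodes_from(range(len(sssr)))
    for i in range(len(sssr)):
        for j in range(i + 1, len(sssr)):
            if sssr[i] & sssr[j]:
                ring_sys.add_edge(i, j)

    in_n_rings = [0] * n_atoms
    for ring in sssr:
        for a in ring:
            in_n_rings[a] += 1

    vertices: list[ReducedGraphVertex] = []
    atom_vertex = [-1] * n_atoms  # atom index -> vertex index (partition)

    def add_vertex(members: set[int], bits: set[str], ring_atoms: frozenset[int] = frozenset()) -> int:
        idx = len(vertices)
        vertices.append(
            ReducedGraphVertex(
                bv=_pack(bits), ac=len(members),
                member_atoms=frozenset(members), ring_atoms=ring_atoms,
            )
        )
        for a in members:
            atom_vertex[a] = idx
        return idx

    def atom_bits(members: set[int]) -> set[str]:
        return {types[a] for a in members}

    for comp in nx.connected_components(ring_sys):
        comp_rings = sorted(comp)
        system_atoms = frozenset().union(*(sssr[r] for r in comp_rings))
        amalgamated = any(in_n_rings[a] > 2 for a in system_atoms)
        if amalgamated:
            bits = atom_bits(set(system_atoms)) | {"ring", "amalgamated"}
            add_vertex(set(system_atoms), bits, ring_atoms=system_atoms)
        else:
            claimed: set[int] = set()
            for r in comp_rings:
                members = set(sssr[r]) - claimed
                claimed |= sssr[r]
                bits = atom_bits(set(sssr[r])) | {"ring"}
                add_vertex(members, bits, ring_atoms=sssr[r])

    # acyclic atoms: L/0 clusters collapse, everything else is a singleton
    acyclic = [a for a in range(n_atoms) if atom_vertex[a] == -1]
    cluster_graph = nx.Graph()
    for a in acyclic:
        if types[a] in ("L", "0"):
            cluster_graph.add_node(a)
    for i, j, _ in graph.edges:
        if i in cluster_graph and j in cluster_graph:
            cluster_graph.add_edge(i, j)
    for comp in nx.connected_components(cluster_graph):
        members = set(comp)
        add_vertex(members, atom_bits(members))
    for a in acyclic:
        if atom_vertex[a] == -1:
            add_vertex({a}, {types[a]})

    # edges between vertices whose member atoms are bonded
    edge_orders: dict[tuple[int, int], int] = {}
    for i, j, _ in graph.edges:
        vi, vj = atom_vertex[i], atom_vertex[j]
        if vi == vj:
            continue
        key = (min(vi, vj), max(vi, vj))
        edge_orders.setdefault(key, 1)
    for key in list(edge_orders):
        vi, vj = key
        va, vb = vertices[vi], vertices[vj]
        if va.is_ring and vb.is_ring and va.ring_atoms & vb.ring_atoms:
            edge_orders[key] = 2
    edges = sorted((i, j, o) for (i, j), o in edge_orders.items())

    rg = ReducedGraph(vertices=vertices, edges=edges, source_id=graph.source_id)
    rg.rejected = any(len(rg.neighbors(i)) > MAX_DEGREE for i in range(len(vertices)))
    return rg


# -- debug output -------------------------------------------------------------

def to_networkx(rg: ReducedGraph) -> nx.Graph:
    g = nx.Graph()
    for i, v in enumerate(rg.vertices):
        g.add_node(i, bits="|".join(sorted(v.bits)), ac=v.ac)
    for i, j, o in rg.edges:
        g.add_edge(i, j, order=o)
    return g


def write_graphml(rg: ReducedGraph, path: str | Path) -> None:
    nx.write_graphml(to_networkx(rg), str(path))


def format_table(rg: ReducedGraph) -> str:
    """Human-readable vertex table (index, bits, atom count)."""
    lines = ["vertex\tbits\tac"]
    for i, v in enumerate(rg.vertices):
        lines.append(f"{i}\t{','.join(sorted(v.bits))}\t{v.ac}")
    lines.append("edges\t" + " ".join(f"{i}-{j}({o})" for i, j, o in rg.edges))
    return "\n".join(lines)
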