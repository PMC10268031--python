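"""Molecular graphs and r-radius subgraph fingerprints.

A molecule is a labeled graph G = (V, E): atoms are vertices (element symbol
plus aromatic flag), chemical bonds are edges (single/double/triple/aromatic).
Because bare atom/bond types carry little information, each vertex is typed by
the *r-radius subgraph* rooted at it — the set of atoms within graph distance
r together with the bonds connecting consecutive shells:

    V_i^r = { v_j : d(i, j) <= r }
    E_i^r = { e_mn : d(i, m) <= r, d(i, n) <= r-1 }

(so shell-r/shell-r edges are excluded, shell-r/shell-(r-1) edges included).
An edge e_ij is typed by the pair subgraph
(V_i^{r-1} ∪ V_j^{r-1}, E_i^r ∩ E_j^r).

Each rooted subgraph is reduced to a canonical, atom-order-independent
signature (a Weisfeiler–Lehman hash of the extracted subgraph with the root
flagged), and a :class:`FingerprintVocab` maps signatures to dense integer IDs
used as embedding-table indices downstream.  ID 0 is reserved for signatures
never seen while the vocabulary was growing (the cold-start case).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from networkx.algorithms.graph_hashing import weisfeiler_lehman_graph_hash
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

UNKNOWN_ID = 0

_BOND_NAMES = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


@dataclass
class MolecularGraph:
    """Heavy-atom graph of one molecule, optionally fingerprinted.

    atoms:      per-vertex (element symbol, aromatic flag)
    bonds:      (i, j, bond_type) with i < j
    adjacency:  per-vertex sets of neighbor indices
    vertex_fp / edge_fp: integer fingerprint IDs (None until assigned)
    """

    atoms: list
    bonds: list
    adjacency: list
    vertex_fp: np.ndarray | None = None
    edge_fp: np.ndarray | None = None
    _directed: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def n_atoms(self):
        return len(self.atoms)

    @property
    def n_bonds(self):
        return len(self.bonds)

    def directed_edges(self):
        """(dst, src, bond_index) arrays listing each bond in both directions.

        Cached; used by the encoder's message passing.
        """
        if self._directed is None:
            dst, src, eidx = [], [], []
            for k, (i, j, _) in enumerate(self.bonds):
                dst += [i, j]
                src += [j, i]
                eidx += [k, k]
            self._directed = (
                np.asarray(dst, dtype=np.intp),
                np.asarray(src, dtype=np.intp),
                np.asarray(eidx, dtype=np.intp),
            )
        return self._directed


class FingerprintVocab:
    """Dense signature -> integer ID tables for vertices and edges.

    IDs start at 1; 0 is the reserved unknown ID.  While open, novel
    signatures get fresh IDs; once frozen, they map to the unknown ID.
    """

    VERSION = 1

    def __init__(self, r):
        if r < 0:
            raise ValueError("radius r must be non-negative")
        self.r = int(r)
        self.vertex_table = {}
        self.edge_table = {}
        self.frozen = False

    @property
    def n_vertex_ids(self):
        """Number of embedding rows needed (including the unknown row)."""
        return len(self.vertex_table) + 1

    @property
    def n_edge_ids(self):
        return len(self.edge_table) + 1

    def _lookup(self, table, signature):
        fp = table.get(signature)
        if fp is not None:
            return fp
        if self.frozen:
            return UNKNOWN_ID
        fp = len(table) + 1
        table[signature] = fp
        return fp

    def vertex_id(self, signature):
        return self._lookup(self.vertex_table, signature)

    def edge_id(self, signature):
        return self._lookup(self.edge_table, signature)

    def freeze(self):
        self.frozen = True
        return self

    def save(self, path):
        payload = {
            "format": "molmir-fingerprint-vocab",
            "version": self.VERSION,
            "r": self.r,
            "frozen": self.frozen,
            "vertex_table": self.vertex_table,
            "edge_table": self.edge_table,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path, expect_r=None):
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format") != "molmir-fingerprint-vocab":
            raise ValueError(f"{path}: not a fingerprint vocabulary file")
        if payload["version"] != cls.VERSION:
            raise ValueError(f"{path}: unsupported vocab version {payload['version']}")
        if expect_r is not None and payload["r"] != expect_r:
            raise ValueError(
                f"{path}: vocabulary was built with r={payload['r']}, expected r={expect_r}"
            )
        vocab = cls(payload["r"])
        vocab.vertex_table = {str(k): int(v) for k, v in payload["vertex_table"].items()}
        vocab.edge_table = {str(k): int(v) for k, v in payload["edge_table"].items()}
        vocab.frozen = bool(payload["frozen"])
        return vocab


def parse_smiles(smiles, strip_hydrogens=True):
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Aromaticity is perceived by RDKit; atom order is the parser's canonical
    order for the input string (deterministic).  With ``strip_hydrogens``
    (default) only heavy atoms are kept.
    """
    if not smiles or not smiles.strip():
        raise ValueError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    if not strip_hydrogens:
        mol = Chem.AddHs(mol)
    atoms = [(a.GetSymbol(), a.GetIsAromatic()) for a in mol.GetAtoms()]
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i > j:
            i, j = j, i
        btype = _BOND_NAMES.get(b.GetBondType(), str(b.GetBondType()).lower())
        bonds.append((i, j, btype))
    bonds.sort()
    adjacency = [set() for _ in atoms]
    for i, j, _ in bonds:
        adjacency[i].add(j)
        adjacency[j].add(i)
    return MolecularGraph(atoms=atoms, bonds=bonds, adjacency=adjacency)


def _distances_from(g, root, r):
    """Graph distances from ``root``, truncated at radius ``r`` (BFS)."""
    dist = {root: 0}
    frontier = [root]
    depth = 0
    while frontier and depth < r:
        depth += 1
        nxt = []
        for u in frontier:
            for v in g.adjacency[u]:
                if v not in dist:
                    dist[v] = depth
                    nxt.append(v)
        frontier = nxt
    return dist


def vertex_neighborhood(g, i, r):
    """(vertices, edges) of the radius-r subgraph rooted at vertex ``i``.

    Edges connect a vertex within radius r to one within radius r-1; edges
    with both endpoints on the outermost shell are not part of the subgraph.
    """
    dist = _distances_from(g, i, r)
    verts = set(dist)
    edges = [
        (a, b, t)
        for a, b, t in g.bonds
        if a in dist and b in dist and min(dist[a], dist[b]) <= r - 1
    ]
    return verts, edges


def edge_neighborhood(g, bond_index, r):
    """Radius-r subgraph of an edge: (V_i^{r-1} ∪ V_j^{r-1}, E_i^r ∩ E_j^r)."""
    i, j, _ = g.bonds[bond_index]
    vi, ei = vertex_neighborhood(g, i, r - 1)
    vj, ej = vertex_neighborhood(g, j, r - 1)
    _, ei_r = vertex_neighborhood(g, i, r)
    _, ej_r = vertex_neighborhood(g, j, r)
    verts = vi | vj
    edges = sorted(set(ei_r) & set(ej_r))
    return verts, edges


def _atom_label(g, v):
    symbol, aromatic = g.atoms[v]
    return f"{symbol}{'~' if aromatic else ''}"


def _subgraph_signature(g, verts, edges, roots):
    """Canonical signature of a rooted subgraph, invariant to atom order."""
    sub = nx.Graph()
    # the edge set may reference shell vertices outside the declared vertex
    # set (the pair subgraph's E_i^r ∩ E_j^r does); include their labels too
    touched = set(verts) | {v for a, b, _ in edges for v in (a, b)}
    for v in touched:
        sub.add_node(v, label=_atom_label(g, v) + ("|root" if v in roots else ""))
    for a, b, t in edges:
        sub.add_edge(a, b, label=t)
    iters = max(3, sub.number_of_nodes())
    h = weisfeiler_lehman_graph_hash(
        sub, edge_attr="label", node_attr="label", iterations=iters
    )
    return f"v{len(verts)}e{len(edges)}:{h}"


def vertex_signature(g, i, r):
    """Canonical signature of vertex ``i``'s radius-r rooted neighborhood."""
    if r == 0:
        return f"atom:{_atom_label(g, i)}"
    verts, edges = vertex_neighborhood(g, i, r)
    return _subgraph_signature(g, verts, edges, {i})


def edge_signature(g, bond_index, r):
    """Canonical signature of a bond's radius-r neighborhood.

    At r=0 the pair subgraph is undefined (it needs radius r-1 vertex sets),
    so the signature degenerates to the bond type with its endpoint labels.
    """
    i, j, t = g.bonds[bond_index]
    if r == 0:
        ends = sorted([_atom_label(g, i), _atom_label(g, j)])
        return f"bond:{t}:{ends[0]}:{ends[1]}"
    verts, edges = edge_neighborhood(g, bond_index, r)
    return _subgraph_signature(g, verts, edges, {i, j})


def fingerprint_graph(g, r, vocab):
    """Assign radius-r fingerprint IDs to every vertex and edge of ``g``.

    A growing vocabulary allocates fresh IDs for novel signatures; a frozen
    one maps them to the reserved unknown ID.  Returns a new graph.
    """
    if r < 0:
        raise ValueError("radius r must be non-negative")
    if vocab.r != r:
        raise ValueError(f"vocabulary was built with r={vocab.r}, got r={r}")
    vertex_fp = np.array(
        [vocab.vertex_id(vertex_signature(g, i, r)) for i in range(g.n_atoms)],
        dtype=np.intp,
    )
    edge_fp = np.array(
        [vocab.edge_id(edge_signature(g, k, r)) for k in range(g.n_bonds)],
        dtype=np.intp,
    )
    return replace(g, vertex_fp=vertex_fp, edge_fp=edge_fp, _directed=None)
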