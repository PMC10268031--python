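"""SMILES parsing and r-radius fingerprints against brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from molmir.chem_graph import (
    UNKNOWN_ID,
    FingerprintVocab,
    fingerprint_graph,
    parse_smiles,
)
from conftest import MOLECULE_POOL, random_relabel


# ---------------------------------------------------------------- parsing

@pytest.mark.parametrize(
    "smiles,n_atoms,n_bonds,bond_types",
    [
        ("C", 1, 0, set()),
        ("CCO", 3, 2, {"single"}),
        ("c1ccccc1", 6, 6, {"aromatic"}),
        ("C=C", 2, 1, {"double"}),
        ("C#N", 2, 1, {"triple"}),
    ],
)
def test_parse_smiles_counts_and_bond_types(smiles, n_atoms, n_bonds, bond_types):
    g = parse_smiles(smiles)
    assert g.n_atoms == n_atoms
    assert g.n_bonds == n_bonds
    assert {t for _, _, t in g.bonds} == bond_types


def test_parse_smiles_graph_invariants():
    for smiles in MOLECULE_POOL:
        g = parse_smiles(smiles)
        for i, j, _ in g.bonds:
            assert 0 <= i < j < g.n_atoms
            assert j in g.adjacency[i] and i in g.adjacency[j]
        for v, nbrs in enumerate(g.adjacency):
            assert v not in nbrs  # no self loops


@pytest.mark.parametrize("bad", ["", "   ", "not-a-molecule(", "C1CC"])
def test_parse_smiles_rejects_garbage(bad):
    with pytest.raises(ValueError):
        parse_smiles(bad)


def test_benzene_atoms_are_aromatic():
    g = parse_smiles("c1ccccc1")
    assert all(aromatic for _, aromatic in g.atoms)


# ---------------------------------------------------------------- fingerprints

def test_radius_zero_signature_is_atom_symbol_alone():
    vocab = FingerprintVocab(r=0)
    g = fingerprint_graph(parse_smiles("CCO"), 0, vocab)
    assert g.vertex_fp[0] == g.vertex_fp[1]  # both carbons
    assert g.vertex_fp[2] != g.vertex_fp[0]  # the oxygen differs


def test_benzene_radius_one_all_vertices_share_one_id():
    vocab = FingerprintVocab(r=1)
    g = fingerprint_graph(parse_smiles("c1ccccc1"), 1, vocab)
    assert len(set(g.vertex_fp.tolist())) == 1
    assert len(set(g.edge_fp.tolist())) == 1


def test_ethanol_radius_one_three_distinct_vertex_ids():
    vocab = FingerprintVocab(r=1)
    g = fingerprint_graph(parse_smiles("CCO"), 1, vocab)
    assert len(set(g.vertex_fp.tolist())) == 3


def test_fingerprint_lengths_match_graph():
    vocab = FingerprintVocab(r=2)
    for smiles in MOLECULE_POOL[:10]:
        g = fingerprint_graph(parse_smiles(smiles), 2, vocab)
        assert len(g.vertex_fp) == g.n_atoms
        assert len(g.edge_fp) == g.n_bonds


def test_negative_radius_rejected():
    with pytest.raises(ValueError):
        fingerprint_graph(parse_smiles("C"), -1, FingerprintVocab(r=0))
    with pytest.raises(ValueError):
        FingerprintVocab(r=-1)


def test_radius_mismatch_with_vocab_rejected():
    with pytest.raises(ValueError):
        fingerprint_graph(parse_smiles("C"), 1, FingerprintVocab(r=2))


def test_fingerprints_invariant_under_atom_relabeling():
    rng = np.random.default_rng(11)
    for smiles in ["CC(C)O", "c1ccncc1", "CC(N)C(=O)O", "C1CC1CC"]:
        g = parse_smiles(smiles)
        vocab = FingerprintVocab(r=2)
        base = sorted(fingerprint_graph(g, 2, vocab).vertex_fp.tolist())
        for _ in range(5):
            relabeled, _ = random_relabel(g, rng)
            fp = sorted(fingerprint_graph(relabeled, 2, vocab).vertex_fp.tolist())
            assert fp == base


def test_radius_refinement_partitions():
    """The radius-(r+1) vertex partition refines the radius-r partition."""
    for smiles in MOLECULE_POOL:
        g = parse_smiles(smiles)
        ids = {}
        for r in (0, 1, 2, 3):
            vocab = FingerprintVocab(r=r)
            ids[r] = fingerprint_graph(g, r, vocab).vertex_fp
        for r in (0, 1, 2):
            for i, j in itertools.combinations(range(g.n_atoms), 2):
                if ids[r + 1][i] == ids[r + 1][j]:
                    assert ids[r][i] == ids[r][j]


# ------------------------------------------------- brute-force oracle

def _neighborhood_oracle(g, root, r):
    """Independent BFS extraction of the rooted radius-r subgraph as an
    nx.Graph with labels (mirrors the subgraph definition; used to check the
    canonical hash against true rooted isomorphism)."""
    dist = {root: 0}
    frontier = [root]
    for depth in range(1, r + 1):
        nxt = []
        for u in frontier:
            for v in g.adjacency[u]:
                if v not in dist:
                    dist[v] = depth
                    nxt.append(v)
        frontier = nxt
    sub = nx.Graph()
    for v, dv in dist.items():
        sym, arom = g.atoms[v]
        sub.add_node(v, sym=sym, arom=arom, root=(v == root))
    for i, j, t in g.bonds:
        if i in dist and j in dist and min(dist[i], dist[j]) <= r - 1:
            sub.add_edge(i, j, bond=t)
    return sub


def _rooted_isomorphic(a, b):
    nm = nx.algorithms.isomorphism.categorical_node_match(
        ["sym", "arom", "root"], [None, None, None]
    )
    em = nx.algorithms.isomorphism.categorical_edge_match("bond", None)
    return nx.is_isomorphic(a, b, node_match=nm, edge_match=em)


@pytest.mark.parametrize("r", [0, 1, 2])
def test_fingerprint_ids_match_rooted_isomorphism_partition(r):
    """Same ID iff the rooted radius-r neighborhoods are isomorphic, across
    all vertices of a pool of small molecules sharing one vocabulary."""
    vocab = FingerprintVocab(r=r)
    vertices = []  # (fingerprint id, oracle neighborhood graph)
    for smiles in MOLECULE_POOL:
        g = parse_smiles(smiles)
        if g.n_atoms > 12:
            continue
        fg = fingerprint_graph(g, r, vocab)
        for v in range(g.n_atoms):
            vertices.append((int(fg.vertex_fp[v]), _neighborhood_oracle(g, v, r)))
    # oracle partition by rooted isomorphism (union by class representative)
    classes = []  # (representative neighborhood, class index)
    oracle_class = []
    for _, nb in vertices:
        key = (
            nb.number_of_nodes(),
            nb.number_of_edges(),
            tuple(sorted(d["sym"] for _, d in nb.nodes(data=True))),
        )
        for rep_key, rep_nb, cls in classes:
            if key == rep_key and _rooted_isomorphic(nb, rep_nb):
                oracle_class.append(cls)
                break
        else:
            classes.append((key, nb, len(classes)))
            oracle_class.append(len(classes) - 1)
    fp_ids = [fp for fp, _ in vertices]
    for a, b in itertools.combinations(range(len(vertices)), 2):
        assert (fp_ids[a] == fp_ids[b]) == (oracle_class[a] == oracle_class[b])


# ---------------------------------------------------------------- vocabulary

def test_frozen_vocab_maps_novel_signatures_to_unknown():
    vocab = FingerprintVocab(r=1)
    fingerprint_graph(parse_smiles("CC"), 1, vocab)
    vocab.freeze()
    size_before = vocab.n_vertex_ids
    g = fingerprint_graph(parse_smiles("CCO"), 1, vocab)
    assert UNKNOWN_ID in g.vertex_fp  # oxygen neighborhood unseen
    assert vocab.n_vertex_ids == size_before  # table did not grow


def test_vocab_roundtrip_and_radius_check(tmp_path):
    vocab = FingerprintVocab(r=2)
    g = fingerprint_graph(parse_smiles("CC(N)C(=O)O"), 2, vocab)
    path = tmp_path / "vocab.json"
    vocab.save(path)
    loaded = FingerprintVocab.load(path, expect_r=2)
    assert loaded.vertex_table == vocab.vertex_table
    assert loaded.edge_table == vocab.edge_table
    g2 = fingerprint_graph(parse_smiles("CC(N)C(=O)O"), 2, loaded)
    assert g2.vertex_fp.tolist() == g.vertex_fp.tolist()
    with pytest.raises(ValueError):
        FingerprintVocab.load(path, expect_r=1)


def test_vocab_ids_are_dense_and_injective():
    vocab = FingerprintVocab(r=1)
    for smiles in MOLECULE_POOL[:12]:
        fingerprint_graph(parse_smiles(smiles), 1, vocab)
    ids = sorted(vocab.vertex_table.values())
    assert ids == list(range(1, len(ids) + 1))
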