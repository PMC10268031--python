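import numpy as np
import pytest

from molmir.chem_graph import FingerprintVocab, fingerprint_graph, parse_smiles
from molmir.config import ModelConfig
from molmir.synthetic_data import SyntheticSpec, generate
from molmir.train_eval import build_dataset

# a varied pool of hand-picked SMILES: chains, branches, rings (incl. the
# 3-ring whose radius-2 neighborhood is a brute-force-isomorphism edge case),
# aromatics, heteroatoms
MOLECULE_POOL = [
    "C", "CC", "CCC", "CCCC", "CCCCC", "CCO", "OCC", "CC(C)C", "CC(C)O",
    "C1CC1", "C1CCC1", "C1CCCC1", "C1CCCCC1", "c1ccccc1", "c1ccncc1",
    "CCN", "CN(C)C", "CC(=O)O", "CC(=O)N", "C=CC", "C#N", "CC#CC",
    "c1ccccc1O", "c1ccccc1N", "OC1CCCC1", "NC1CC1", "CC(N)C(=O)O",
    "C1CC1CC", "CCCCO", "CCNCC",
]


@pytest.fixture(scope="session")
def small_synthetic():
    """A compact planted-signal dataset shared by the integration tests."""
    raw = generate(SyntheticSpec(n_molecules=12, n_mirnas=18, seed=5))
    return raw


@pytest.fixture(scope="session")
def small_dataset(small_synthetic):
    raw = small_synthetic
    return build_dataset(raw.molecules, raw.mirnas, raw.positives)


@pytest.fixture()
def tiny_config():
    """A d=4 configuration small enough for finite-difference checks."""
    return ModelConfig(r=1, d=4, T=1, w=2, L=2, seed=0)


@pytest.fixture()
def fingerprinted_benzene():
    vocab = FingerprintVocab(r=1)
    return fingerprint_graph(parse_smiles("c1ccccc1"), 1, vocab), vocab


def random_relabel(graph, rng):
    """Apply a random vertex permutation to a MolecularGraph (test helper)."""
    from dataclasses import replace

    n = graph.n_atoms
    perm = rng.permutation(n)  # perm[old] = new index
    atoms = [None] * n
    for old, new in enumerate(perm):
        atoms[new] = graph.atoms[old]
    bonds = []
    for i, j, t in graph.bonds:
        a, b = perm[i], perm[j]
        if a > b:
            a, b = b, a
        bonds.append((int(a), int(b), t))
    bonds.sort()
    adjacency = [set() for _ in range(n)]
    for i, j, _ in bonds:
        adjacency[i].add(j)
        adjacency[j].add(i)
    return replace(graph, atoms=atoms, bonds=bonds, adjacency=adjacency,
                   vertex_fp=None, edge_fp=None, _directed=None), perm
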