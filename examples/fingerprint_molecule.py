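"""Fingerprint a molecule at increasing radii.

Parses aspirin from SMILES and shows how the r-radius subgraph fingerprints
partition its atoms: at r=0 atoms are typed by element alone, at larger radii
by their whole chemical neighborhood, so chemically distinct positions
separate.
"""

from molmir import FingerprintVocab, fingerprint_graph, parse_smiles

ASPIRIN = "CC(=O)Oc1ccccc1C(=O)O"

graph = parse_smiles(ASPIRIN)
print(f"aspirin: {graph.n_atoms} heavy atoms, {graph.n_bonds} bonds")

for r in (0, 1, 2):
    vocab = FingerprintVocab(r=r)
    fg = fingerprint_graph(graph, r, vocab)
    n_types = len(set(fg.vertex_fp.tolist()))
    print(f"r={r}: {n_types} distinct atom environments -> IDs {fg.vertex_fp.tolist()}")

print(
    "\nEach ID names one canonical rooted neighborhood; equal IDs mean the"
    "\natoms sit in isomorphic radius-r chemical environments."
)
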