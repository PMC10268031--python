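"""Planted-signal toy datasets for offline testing of the full pipeline.

The generator emits a molecule table (SMILES composed from a small fragment
grammar), miRNA-like sequences (i.i.d. uniform bases with a motif planted in a
configurable fraction) and pair labels from a known decision rule — by default
a pair is associated iff the molecule contains at least one nitrogen atom AND
the sequence contains the motif ``AUGGC``.  Both halves of the rule are
recoverable by the model's representations: nitrogen presence shows up in
atom-type fingerprints, the motif in consecutive 3-mer windows.

``label_noise`` models the missingness of real association lists: a truly
associated pair is *dropped* from the positives with that probability
(annotation false negatives).  Truth labels are returned alongside so tests
can score against the clean rule.

The generated shape deliberately stays desk-sized (40 molecules x 60
sequences by default) so end-to-end training runs in seconds to minutes on
one core; a real association dataset differs in molecule diversity, sequence
composition and extreme label sparsity, which these fixtures do not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem_graph import parse_smiles
from .io import write_associations, write_mirna_fasta, write_molecule_table

# Fragments end on a plain atom so plain concatenation stays valid SMILES.
CARBON_FRAGMENTS = [
    "C", "CC", "CCC", "CCO", "CO", "C(C)C", "CC(C)O",
    "c1ccccc1", "C1CCCCC1", "C=CC", "C1CC1", "CC(=O)O",
]
NITROGEN_FRAGMENTS = [
    "N", "CN", "CCN", "NCC", "CNC", "c1ccncc1", "CC(N)C", "C(=O)N",
]

DEFAULT_MOTIF = "AUGGC"


def has_nitrogen(smiles):
    """Default molecule predicate: at least one nitrogen atom."""
    g = parse_smiles(smiles)
    return any(sym == "N" for sym, _ in g.atoms)


@dataclass
class SyntheticSpec:
    n_molecules: int = 40
    n_mirnas: int = 60
    seq_len_range: tuple = (20, 30)
    molecule_grammar: tuple = (tuple(CARBON_FRAGMENTS), tuple(NITROGEN_FRAGMENTS))
    motif: str = DEFAULT_MOTIF
    nitrogen_fraction: float = 0.5   # molecules carrying >=1 nitrogen fragment
    motif_fraction: float = 0.5      # sequences with the motif planted
    label_noise: float = 0.05        # P(drop a truly associated pair)
    seed: int = 0


@dataclass
class SyntheticDataset:
    molecules: dict          # molecule_id -> SMILES
    mirnas: dict             # mirna_id -> RNA sequence
    positives: set           # labeled associations after dropout noise
    truth: dict = field(repr=False)  # (mol_id, mirna_id) -> rule truth (0/1)
    spec: SyntheticSpec = None

    def write(self, directory):
        """Write molecules.tsv / mirnas.fasta / associations.tsv."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_molecule_table(self.molecules, directory / "molecules.tsv")
        write_mirna_fasta(self.mirnas, directory / "mirnas.fasta")
        write_associations(
            sorted(self.positives), directory / "associations.tsv", with_labels=False
        )
        return directory


def _random_molecule(rng, spec, with_nitrogen):
    carbon, nitrogen = spec.molecule_grammar
    n_frag = int(rng.integers(2, 5))
    frags = [carbon[rng.integers(len(carbon))] for _ in range(n_frag)]
    if with_nitrogen:
        pos = int(rng.integers(n_frag))
        frags[pos] = nitrogen[rng.integers(len(nitrogen))]
    smiles = "".join(frags)
    parse_smiles(smiles)  # every generated molecule must be parseable
    return smiles


def _random_sequence(rng, spec, with_motif):
    lo, hi = spec.seq_len_range
    length = int(rng.integers(lo, hi + 1))
    seq = "".join(rng.choice(list("ACGU"), size=length))
    if with_motif:
        pos = int(rng.integers(length - len(spec.motif) + 1))
        seq = seq[:pos] + spec.motif + seq[pos + len(spec.motif):]
    return seq


def generate(spec=None):
    """Build a :class:`SyntheticDataset` from a spec; reproducible under seed."""
    spec = spec or SyntheticSpec()
    lo, hi = spec.seq_len_range
    if not (0 < lo <= hi):
        raise ValueError(f"invalid sequence length range {spec.seq_len_range}")
    if len(spec.motif) > lo:
        raise ValueError(
            f"motif {spec.motif!r} longer than minimum sequence length {lo}"
        )
    if not 0.0 <= spec.label_noise <= 1.0:
        raise ValueError("label_noise must be in [0, 1]")
    rng = np.random.default_rng(spec.seed)

    width = max(3, len(str(max(spec.n_molecules, spec.n_mirnas))))
    molecules, mol_has_n = {}, {}
    for k in range(spec.n_molecules):
        mol_id = f"SM{k:0{width}d}"
        with_n = rng.random() < spec.nitrogen_fraction
        smiles = _random_molecule(rng, spec, with_n)
        molecules[mol_id] = smiles
        mol_has_n[mol_id] = has_nitrogen(smiles)

    mirnas, seq_has_motif = {}, {}
    for k in range(spec.n_mirnas):
        mirna_id = f"mir-{k:0{width}d}"
        with_motif = rng.random() < spec.motif_fraction
        seq = _random_sequence(rng, spec, with_motif)
        mirnas[mirna_id] = seq
        seq_has_motif[mirna_id] = spec.motif in seq  # background can hit by chance

    truth, positives = {}, set()
    for mol_id in molecules:
        for mirna_id in mirnas:
            t = int(mol_has_n[mol_id] and seq_has_motif[mirna_id])
            truth[(mol_id, mirna_id)] = t
            if t and rng.random() >= spec.label_noise:
                positives.add((mol_id, mirna_id))
    return SyntheticDataset(
        molecules=molecules,
        mirnas=mirnas,
        positives=positives,
        truth=truth,
        spec=spec,
    )
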