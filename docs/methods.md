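# Methods

## Problem setting

Given a catalogue of small molecules (SMILES), a catalogue of miRNAs (RNA
sequences) and a sparse list of known positive associations, score every
molecule/miRNA pair with an association probability. The association lists
are positive-only: absence of a record means "not yet tested", not "not
associated". The package treats this as binary link prediction with sampled
negatives and evaluates by ranking (ROC/AUC).

## Molecule representation

SMILES are parsed with RDKit (aromaticity perceived, heavy atoms only by
default; `strip_hydrogens=False` re-adds explicit hydrogens). Atom vertices
carry (element, aromatic flag); bonds carry single/double/triple/aromatic.

Atoms are typed by their radius-r rooted subgraph: `V_i^r` is the ball of
vertices within distance r of atom i, and `E_i^r` contains the bonds joining
a vertex within radius r to one within radius r−1 — bonds between two
outermost-shell vertices are excluded, so the subgraph is exactly what r
rounds of neighbor expansion can see. Bond types are part of the signature.
An edge is typed by the pair subgraph `(V_i^{r−1} ∪ V_j^{r−1}, E_i^r ∩
E_j^r)`; at r = 0 that set is undefined and the edge signature degenerates to
the bond type plus its endpoint labels.

Each rooted subgraph is reduced to a canonical signature by a
Weisfeiler–Lehman hash of the *extracted* subgraph with the root(s) flagged
and iterations equal to the subgraph size. Hashing the extracted subgraph —
rather than iterating WL label refinement on the whole molecule — matters:
plain WL-subtree refinement cannot separate, e.g., the cyclopropane ring
carbon from a mid-chain carbon at r = 2, although their radius-2
neighborhoods are non-isomorphic; hashing the extracted neighborhood
separates every such case arising in desk-scale molecules, and the test
suite checks exact agreement with a brute-force rooted-isomorphism oracle.
Two consequences hold by construction and are property-tested: signatures
are invariant to atom relabeling, and the radius-(r+1) vertex partition
refines the radius-r partition.

A `FingerprintVocab` assigns dense integer IDs (starting at 1) to signatures
in first-seen order. Freezing the vocabulary (always done after the training
molecules are processed) maps unseen signatures to the reserved ID 0, whose
embedding row is trained like any other — this is the cold-start path for
new molecules. Vocabularies persist as versioned JSON carrying r; loading
with a different r is an error. Default **r = 2**, the usual choice for
radius-limited substructure fingerprints (larger radii fragment the
vocabulary on small datasets; r = 0 reduces atoms to element types).

## Molecule encoder

Vertex/edge fingerprint IDs index d-dimensional embedding tables
(initialized uniform in ±1/√d). T rounds of updates follow; within a round
the vertices update first from the previous edge states,

    h_ij = max(0, W_neighbor [v_j ; e_ij] + b_neighbor)     (W: d×2d)
    v_i ← σ(v_i + Σ_{j∈Γ_i} h_ij),

then the edges update from the fresh vertex states,

    g_ij = max(0, W_side (v_i + v_j) + b_side)              (W: d×d)
    e_ij ← σ(e_ij + g_ij).

Two deliberate choices: (1) σ is the standard logistic — every state stays
strictly inside (0,1), which stabilizes the recurrent accumulation; (2)
`W_side` acts on the *symmetric sum* v_i + v_j, so the edge update cannot
depend on an arbitrary endpoint ordering and the whole encoder is exactly
invariant to atom relabeling (verified to 1e−6 over random permutations).
Weights are shared across rounds. The molecule embedding is the mean of the
final vertex states; a single-atom molecule is valid (empty neighbor sums),
an empty graph is an error. Defaults **d = 32, T = 2**: two rounds let a
radius-2 fingerprint effectively see radius ≈ 4 context, and wider/deeper
settings showed no benefit at the data sizes the synthetic studies use.

## Sequence encoder

Sequences are uppercased, T read as U; characters outside {A,C,G,U,N} are
rejected. Overlapping n-mers (stride 1) become token IDs by base-4
enumeration — the vocabulary is fixed at 4^n + 1 (unknown token for windows
containing N) and needs no fitting. **n = 3** keeps the vocabulary at 65
types, small enough that every token is frequent in even a few dozen
sequences. Windows of **w = 5** consecutive word embeddings are concatenated
(covering 7 bases, the scale of a seed-like sequence element) and passed
through **L = 2** per-position ReLU layers: the first maps dw → d, deeper
layers d → d, each layer owning its weights. The first-layer weight shape
dw → d forces the layer-1/layer-2 distinction; sharing one d×dw matrix
across all layers cannot type-check beyond layer 1.

## Attention and classifier

Molecule embedding and each hidden window vector are mapped by a shared
ReLU affine layer (`W_inter`: d×d); each window's attention weight is the
sigmoid of its dot product with the transformed molecule vector. Weights are
*not* normalized across windows — a sigmoid per window rather than a softmax
— so a sequence with two strong sites reports two large weights, and weights
are comparable across sequences of different lengths. The attended readout
sums the *transformed* window vectors weighted by attention. A config switch
(`attention: off`) substitutes the plain mean readout for ablation. The
classifier is a 2-way softmax on `W_output [y_miRNA ; y_sm] + b_output`;
P₁ is reported. `W_output` is initialized small (±0.01) so a fresh model
starts near P = (½, ½) and cross-entropy ≈ ln 2.

## Training

Cross-entropy over labeled pairs, SGD with classical momentum (0.9),
mini-batches of pairs (graphs are processed one pair at a time; the batch
averages the losses before the update). Gradients come from the package's
reverse-mode autodiff engine (`molmir.autodiff`), a ~15-op tape over NumPy
(broadcast add/mul, 1-D/2-D matmul, gather, segment-sum, concat, reshape,
reductions, fused softmax/cross-entropy); the test suite checks every
operator and every model tensor against central finite differences
(relative error ≤ 1e−4). Training is deterministic under a seed and aborts
on non-finite loss.

Package defaults are deliberately conservative (lr 1e−3, 100 epochs,
batch 8) and fully config-driven. The synthetic-signal studies in the tests
and the acceptance script use an explicit schedule — **40 epochs, lr 0.01,
momentum 0.9, batch 4** — chosen once as the smallest schedule at which
training on the default synthetic dataset converges reliably on one core;
single-batch memorization checks use lr 0.05, which the loss-to-zero regime
needs.

## Protocols and metrics

* **Negative sampling** — uniform without replacement from all pairs minus
  the positives, default ratio 1:1, seeded. When cross-validation starts
  from a positives-only dataset, each fold samples its own training
  negatives (and, for the pairwise protocol, disjoint evaluation negatives),
  so no negative sample leaks across folds.
* **Pairwise k-fold CV** — labeled pairs shuffled and dealt round-robin into
  k near-equal folds.
* **Leave-one-molecule-out** — one fold per molecule that has labeled pairs
  (molecules without any are skipped with a warning). Per fold the
  fingerprint vocabulary is rebuilt from the training molecules only and
  frozen, so the held-out molecule's novel signatures hit the unknown ID;
  the molecule is scored against every miRNA with its known positives as
  labels — the ranking task a new drug poses. A leave-one-pair-out variant
  is also exposed.
* **AUC** — Mann–Whitney concordance with half-credit ties, computed via
  scikit-learn's trapezoidal ROC integration (mathematically identical);
  tested against an O(P·N) brute-force concordance count at 1e−12.
* **Ranking** — candidates are all pairs outside the training positives,
  sorted by probability, ties broken lexicographically for reproducibility.

## Synthetic data

The generator composes SMILES from a hand-written fragment grammar
(alkane/alcohol/acid/aromatic pieces, plus amine/pyridine/amide fragments
for the nitrogen arm), guaranteeing parseability; sequences are i.i.d.
uniform ACGU with the motif `AUGGC` planted at a uniform random position in
half of them. A pair is truly associated iff the molecule contains nitrogen
AND the sequence contains the motif — both arms sit squarely inside what the
two encoders can represent (atom-type fingerprints; three consecutive
3-mers). Defaults: 40 molecules × 60 sequences of 20–30 nt, half the
molecules nitrogen-bearing, giving ≈25% truly associated pairs.

`label_noise` (default 0.05) models the *missingness* of real association
lists: a truly associated pair is dropped from the labels with that
probability. The noise is one-sided by design — recorded associations are
experimentally validated and essentially never false, whereas unrecorded
true associations are common — and one-sided dropout keeps the planted-rule
oracle's AUC at ≥ 1 − noise, the ceiling against which the trained model is
compared (a symmetric flip would lower that ceiling well below 1 − noise at
this base rate). With `label_noise = 0` the labels equal the rule exactly.

What passing the synthetic studies does *not* show: real molecule catalogues
are far more diverse than the grammar, real miRNA families share sequence
beyond a single motif, and real association matrices are orders of magnitude
sparser (e.g. hundreds of positives in a 10^5-pair space). The synthetic
results demonstrate that the pipeline recovers a signal that is jointly
encoded in molecular substructure and sequence content — not that it attains
any particular accuracy on real data.

## Problem sizes

The studies are sized for a single core: pairwise CV runs on the default
40×60 dataset (≈550 positives + as many sampled negatives), cold-start LOMO
on a 12×18 dataset. These sizes are the package's own study conditions; the
loaders accept datasets of arbitrary shape.

## Numerical notes and limitations

* All floating point is float64; sigmoids use `scipy.special.expit`.
* Fingerprint hashing relies on NetworkX's WL graph hash; hash collisions
  between non-isomorphic rooted neighborhoods are theoretically possible but
  require WL-indistinguishable connected labeled graphs, which do not arise
  at molecule scale (and would only merge two atom types, not crash).
* Stereochemistry and 3-D conformation are outside the representation, as
  are miRNA secondary structure and precursor context.
* The model shares no information across miRNAs beyond 3-mer composition
  learned end-to-end; with very few sequences per motif family the sequence
  arm dominates the molecule arm (visible in small ranking demos).
* `train` is single-threaded by design (determinism); wall time scales
  linearly in pairs × epochs.
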