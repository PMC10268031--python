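"""Training loop, cross-validation protocols, ROC/AUC and candidate ranking.

Only positive molecule/miRNA associations are recorded, so a binary
classifier needs sampled negatives: unlabeled pairs drawn uniformly without
replacement.  Two evaluation protocols mirror how the model is used:

* **pairwise k-fold CV** — labeled pairs are partitioned uniformly into k
  folds; measures link prediction between entities seen in training.
* **leave-one-molecule-out** (local LOOCV) — all pairs of one molecule are
  held out per round, the fingerprint vocabulary is built from the remaining
  molecules only, and the held-out molecule is scored against every miRNA.
  This simulates a genuinely new drug: its unseen substructure signatures map
  to the reserved unknown ID.

AUC is the Mann–Whitney concordance probability (ties half credit), computed
via scikit-learn's trapezoidal ROC integration, which is equivalent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .chem_graph import FingerprintVocab, fingerprint_graph, parse_smiles
from .cnn_encoder import tokenize
from .config import ModelConfig
from . import autodiff as ad
from . import model as model_mod

logger = logging.getLogger("molmir")

PAIRWISE = "pairwise"
LEAVE_ONE_MOLECULE_OUT = "molecule"
LEAVE_ONE_PAIR_OUT = "pair"


@dataclass
class AssociationDataset:
    """Aligned molecule graphs, token sequences, labeled pairs and folds."""

    molecules: dict            # molecule_id -> MolecularGraph (unfingerprinted)
    mirnas: dict               # mirna_id -> TokenSequence
    positives: set             # (molecule_id, mirna_id)
    negatives: set = field(default_factory=set)
    folds: dict = field(default_factory=dict)  # pair -> fold index

    def __post_init__(self):
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"{len(overlap)} pairs labeled both positive and negative")
        for mol_id, mirna_id in list(self.positives) + list(self.negatives):
            if mol_id not in self.molecules:
                raise KeyError(f"pair references unknown molecule {mol_id!r}")
            if mirna_id not in self.mirnas:
                raise KeyError(f"pair references unknown miRNA {mirna_id!r}")

    @property
    def labeled_pairs(self):
        """[(molecule_id, mirna_id, label)] in deterministic order."""
        return [(m, s, 1) for m, s in sorted(self.positives)] + [
            (m, s, 0) for m, s in sorted(self.negatives)
        ]


@dataclass
class TrainResult:
    params: object             # ModelParams (plain arrays)
    vocab: FingerprintVocab    # frozen fingerprint vocabulary
    losses: list               # per-epoch mean cross-entropy
    graphs: dict               # molecule_id -> fingerprinted MolecularGraph


@dataclass
class EvalResult:
    protocol: str
    fold_aucs: list
    mean_auc: float
    roc_points: list           # pooled held-out (FPR, TPR) curve
    seed: int


def build_dataset(molecules, mirnas, positive_pairs, n=3):
    """Parse SMILES / tokenize sequences and assemble an AssociationDataset."""
    graphs = {mid: parse_smiles(smi) for mid, smi in molecules.items()}
    tokens = {mid: tokenize(seq, n=n, mirna_id=mid) for mid, seq in mirnas.items()}
    positives = set()
    negatives = set()
    for entry in positive_pairs:
        if len(entry) == 3:
            mol_id, mirna_id, label = entry
        else:
            mol_id, mirna_id = entry
            label = 1
        (positives if label else negatives).add((mol_id, mirna_id))
    return AssociationDataset(
        molecules=graphs, mirnas=tokens, positives=positives, negatives=negatives
    )


def candidate_pair_count(n_molecules, n_mirnas, n_positives):
    """Size of the negative-sampling space: all pairs minus the positives."""
    return n_molecules * n_mirnas - n_positives


def _sample_unlabeled(dataset, count, seed, exclude=()):
    """Uniform sample without replacement from unlabeled pairs."""
    mol_ids = sorted(dataset.molecules)
    mirna_ids = sorted(dataset.mirnas)
    n_mirna = len(mirna_ids)
    forbidden = dataset.positives | set(exclude)
    forbidden_idx = {
        mol_ids.index(m) * n_mirna + mirna_ids.index(s)
        for m, s in forbidden
        if m in dataset.molecules and s in dataset.mirnas
    }
    space = len(mol_ids) * n_mirna - len(forbidden_idx)
    if count > space:
        raise ValueError(f"requested {count} negatives but only {space} unlabeled pairs")
    pool = np.setdiff1d(
        np.arange(len(mol_ids) * n_mirna), np.fromiter(forbidden_idx, dtype=np.int64, count=len(forbidden_idx))
    )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(pool, size=count, replace=False)
    return {(mol_ids[i // n_mirna], mirna_ids[i % n_mirna]) for i in chosen}


def sample_negatives(dataset, ratio=1.0, seed=0):
    """Populate ``dataset.negatives`` with ratio x |positives| unlabeled pairs."""
    if ratio <= 0:
        raise ValueError("negative sampling ratio must be positive")
    count = int(round(ratio * len(dataset.positives)))
    dataset.negatives = _sample_unlabeled(dataset, count, seed)
    return dataset


def make_folds(dataset, k=5, protocol=PAIRWISE, seed=0):
    """Assign every labeled pair to a fold; returns the pair -> fold mapping.

    ``pairwise`` splits pairs uniformly into k near-equal folds; ``molecule``
    gives each molecule with labeled pairs its own fold (leave-one-molecule-
    out); ``pair`` gives each pair its own fold.
    """
    pairs = [(m, s) for m, s, _ in dataset.labeled_pairs]
    folds = {}
    if protocol == PAIRWISE:
        if k < 2:
            raise ValueError("pairwise protocol requires k >= 2")
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(pairs))
        for rank, idx in enumerate(order):
            folds[pairs[idx]] = rank % k
    elif protocol == LEAVE_ONE_MOLECULE_OUT:
        paired_molecules = sorted({m for m, _ in pairs})
        for m in sorted(dataset.molecules):
            if m not in paired_molecules:
                logger.warning("molecule %s has no labeled pairs; skipped", m)
        index = {m: f for f, m in enumerate(paired_molecules)}
        for m, s in pairs:
            folds[(m, s)] = index[m]
    elif protocol == LEAVE_ONE_PAIR_OUT:
        for f, p in enumerate(sorted(pairs)):
            folds[p] = f
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    dataset.folds = folds
    return folds


def _fingerprint_for_training(dataset, train_pairs, r):
    """Grow a vocabulary on the training molecules, freeze it, fingerprint all."""
    vocab = FingerprintVocab(r)
    train_mols = sorted({m for m, _, _ in train_pairs})
    graphs = {}
    for mid in train_mols:
        graphs[mid] = fingerprint_graph(dataset.molecules[mid], r, vocab)
    vocab.freeze()
    for mid in sorted(dataset.molecules):
        if mid not in graphs:
            graphs[mid] = fingerprint_graph(dataset.molecules[mid], r, vocab)
    return vocab, graphs


def train(dataset, config=None, pairs=None, seed=None):
    """Fit the model on labeled pairs by SGD with momentum on cross-entropy.

    ``pairs`` defaults to the dataset's positives plus negatives.  Returns a
    :class:`TrainResult` with the fitted parameters, the frozen fingerprint
    vocabulary and the per-epoch loss log.  Deterministic under seed.
    """
    config = config or ModelConfig()
    if pairs is None:
        pairs = dataset.labeled_pairs
    if not pairs:
        raise ValueError("no labeled pairs to train on")
    if not any(lab == 1 for _, _, lab in pairs) or not any(lab == 0 for _, _, lab in pairs):
        raise ValueError("training needs both positive and negative pairs")
    seed = config.seed if seed is None else seed
    vocab, graphs = _fingerprint_for_training(dataset, pairs, config.r)
    params = model_mod.init_params(config, vocab.n_vertex_ids, vocab.n_edge_ids, seed=seed)
    tensor_params, leaves = model_mod.as_tensors(params)
    opt = ad.SGD(leaves, lr=config.lr, momentum=config.momentum)
    rng = np.random.default_rng(seed)
    indexed = list(pairs)
    losses = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(indexed))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            opt.zero_grad()
            batch_losses = []
            for idx in batch:
                mol_id, mirna_id, label = indexed[idx]
                loss = model_mod.pair_loss(
                    graphs[mol_id], dataset.mirnas[mirna_id], label, tensor_params
                )
                batch_losses.append(loss)
            total = batch_losses[0]
            for extra in batch_losses[1:]:
                total = ad.add(total, extra)
            total = ad.mul(total, 1.0 / len(batch))
            if not np.isfinite(total.value):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            total.backward()
            opt.step()
            epoch_loss += float(total.value) * len(batch)
        losses.append(epoch_loss / len(indexed))
        logger.info("epoch %d: loss %.4f", epoch, losses[-1])
    model_mod.sync_from_tensors(params, tensor_params)
    return TrainResult(params=params, vocab=vocab, losses=losses, graphs=graphs)


def predict_pairs(result, dataset, pairs):
    """Association probabilities for (molecule_id, mirna_id) pairs."""
    scores = []
    for mol_id, mirna_id in pairs:
        graph = result.graphs.get(mol_id)
        if graph is None:
            graph = fingerprint_graph(
                dataset.molecules[mol_id], result.vocab.r, result.vocab
            )
        prob, _ = model_mod.pair_probability(
            graph, dataset.mirnas[mirna_id], result.params
        )
        scores.append(prob)
    return np.asarray(scores)


def predict_pair(result, dataset, mol_id, mirna_id):
    """Single-pair prediction with the per-window attention weights exposed."""
    from .attention_classifier import PairPrediction

    graph = result.graphs.get(mol_id)
    if graph is None:
        graph = fingerprint_graph(
            dataset.molecules[mol_id], result.vocab.r, result.vocab
        )
    prob, alpha = model_mod.pair_probability(
        graph, dataset.mirnas[mirna_id], result.params
    )
    return PairPrediction(
        molecule_id=mol_id, mirna_id=mirna_id, prob_positive=prob, attention=alpha
    )


def roc_auc(scores, labels):
    """(AUC, ROC points).  AUC is the concordance probability, ties half credit."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(scores) != len(labels):
        raise ValueError("scores and labels differ in length")
    classes = set(labels.tolist())
    if classes != {0, 1}:
        raise ValueError(f"need both classes present, got labels {sorted(classes)}")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, _ = roc_curve(labels, scores)
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def cross_validate(dataset, config=None, protocol=PAIRWISE, k=5, seed=0,
                   score_all_for_held_out_molecule=True):
    """Run a full CV protocol and return per-fold and mean held-out AUC.

    With no pre-populated negatives, each fold samples its own (training
    negatives and, for the pairwise protocol, disjoint evaluation negatives)
    at the configured ratio.  For the molecule protocol the held-out molecule
    is by default scored against *every* miRNA, positives labeled 1 and all
    other pairs 0 — the ranking task a new drug actually poses.
    """
    config = config or ModelConfig()
    if not dataset.folds:
        make_folds(dataset, k=k, protocol=protocol, seed=seed)
    fold_ids = sorted(set(dataset.folds.values()))
    resample = not dataset.negatives
    fold_aucs = []
    pooled_scores, pooled_labels = [], []
    for f in fold_ids:
        test_pairs = sorted(p for p, fi in dataset.folds.items() if fi == f)
        train_pos = [
            (m, s, 1)
            for (m, s), fi in sorted(dataset.folds.items())
            if fi != f and (m, s) in dataset.positives
        ]
        train_neg = [
            (m, s, 0)
            for (m, s), fi in sorted(dataset.folds.items())
            if fi != f and (m, s) in dataset.negatives
        ]
        held_out_mols = {m for m, _ in test_pairs}
        if protocol in (LEAVE_ONE_MOLECULE_OUT,):
            # the held-out molecule must be completely unseen in training
            exclude = {(m, s) for m in held_out_mols for s in dataset.mirnas}
        else:
            exclude = set(test_pairs)
        if resample:
            n_train_neg = int(round(config.negative_ratio * len(train_pos)))
            sampled = _sample_unlabeled(
                dataset, n_train_neg, seed=(seed * 1009 + f) % (2**31), exclude=exclude
            )
            train_neg = [(m, s, 0) for m, s in sorted(sampled)]
        result = train(dataset, config, pairs=train_pos + train_neg,
                       seed=(seed * 9176 + f) % (2**31))
        if protocol == LEAVE_ONE_MOLECULE_OUT and score_all_for_held_out_molecule:
            eval_pairs = sorted((m, s) for m in held_out_mols for s in dataset.mirnas)
            labels = [int(p in dataset.positives) for p in eval_pairs]
        else:
            eval_pairs = list(test_pairs)
            labels = [int(p in dataset.positives) for p in eval_pairs]
            if resample and all(labels):
                n_eval_neg = max(1, int(round(config.negative_ratio * len(eval_pairs))))
                extra = _sample_unlabeled(
                    dataset,
                    n_eval_neg,
                    seed=(seed * 5077 + f) % (2**31),
                    exclude=exclude | {(m, s) for m, s, _ in train_neg},
                )
                eval_pairs += sorted(extra)
                labels += [0] * len(extra)
        scores = predict_pairs(result, dataset, eval_pairs)
        if len(set(labels)) < 2:
            logger.warning("fold %d has a single class; skipped from AUC", f)
            continue
        auc, _ = roc_auc(scores, labels)
        fold_aucs.append(auc)
        pooled_scores.extend(scores.tolist())
        pooled_labels.extend(labels)
    if not fold_aucs:
        raise ValueError("no fold produced a two-class evaluation set")
    _, points = roc_auc(pooled_scores, pooled_labels)
    return EvalResult(
        protocol=protocol,
        fold_aucs=fold_aucs,
        mean_auc=float(np.mean(fold_aucs)),
        roc_points=points,
        seed=seed,
    )


def rank_candidates(result, dataset, top_k=30):
    """Score all pairs outside the training positives and rank them.

    Descending by probability; ties broken by (molecule_id, mirna_id) so the
    ranking is reproducible.  Returns a DataFrame (rank, molecule, miRNA,
    score) shaped like a top-k candidate table.
    """
    import pandas as pd

    candidates = sorted(
        (m, s)
        for m in dataset.molecules
        for s in dataset.mirnas
        if (m, s) not in dataset.positives
    )
    scores = predict_pairs(result, dataset, candidates)
    order = sorted(range(len(candidates)), key=lambda i: (-scores[i], candidates[i]))
    top = order[: min(top_k, len(order))]
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(top) + 1),
            "molecule_id": [candidates[i][0] for i in top],
            "mirna_id": [candidates[i][1] for i in top],
            "score": [float(scores[i]) for i in top],
        }
    )
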