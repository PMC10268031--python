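"""Negative sampling, fold construction, training oracles, AUC, ranking."""

import itertools

import numpy as np
import pytest

from molmir.config import ModelConfig
from molmir.synthetic_data import CARBON_FRAGMENTS, SyntheticSpec, generate
from molmir.train_eval import (
    AssociationDataset,
    build_dataset,
    candidate_pair_count,
    cross_validate,
    make_folds,
    predict_pair,
    predict_pairs,
    rank_candidates,
    roc_auc,
    sample_negatives,
    train,
    _fingerprint_for_training,
)
from molmir import model as M


def brute_force_auc(scores, labels):
    """Concordant-pair probability with half credit for ties (O(P*N))."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def _light_dataset(n_mols=30, n_mirnas=30, n_pos=200, seed=0):
    """A dataset with real (tiny) molecules/sequences and random positives."""
    rng = np.random.default_rng(seed)
    mols = {f"SM{k:03d}": CARBON_FRAGMENTS[k % len(CARBON_FRAGMENTS)] for k in range(n_mols)}
    seqs = {
        f"mir-{k:03d}": "".join(rng.choice(list("ACGU"), size=24)) for k in range(n_mirnas)
    }
    all_pairs = [(m, s) for m in sorted(mols) for s in sorted(seqs)]
    chosen = rng.choice(len(all_pairs), size=n_pos, replace=False)
    positives = [all_pairs[i] for i in chosen]
    return build_dataset(mols, seqs, positives)


# ----------------------------------------------------------- negatives

def test_negative_sampling_count_and_determinism():
    ds = _light_dataset()
    sample_negatives(ds, ratio=1.0, seed=5)
    assert len(ds.negatives) == len(ds.positives)
    assert not (ds.negatives & ds.positives)
    first = set(ds.negatives)
    sample_negatives(ds, ratio=1.0, seed=5)
    assert ds.negatives == first
    sample_negatives(ds, ratio=0.5, seed=5)
    assert len(ds.negatives) == round(0.5 * len(ds.positives))


def test_negative_sampling_exhausts_candidate_space():
    ds = _light_dataset(n_mols=3, n_mirnas=3, n_pos=5)
    with pytest.raises(ValueError):
        sample_negatives(ds, ratio=1.0, seed=0)  # needs 5, only 4 unlabeled


def test_candidate_space_arithmetic():
    assert candidate_pair_count(831, 541, 664) == 448_907


# --------------------------------------------------------------- folds

def test_pairwise_fold_sizes_balanced():
    ds = _light_dataset(n_mols=30, n_mirnas=30, n_pos=664)
    folds = make_folds(ds, k=5, protocol="pairwise", seed=0)
    sizes = sorted(
        sum(1 for f in folds.values() if f == k) for k in range(5)
    )
    assert sizes == [132, 133, 133, 133, 133]
    assert set(folds) == ds.positives  # union of folds = all labeled pairs


def test_molecule_protocol_holds_out_whole_molecules():
    ds = _light_dataset(n_mols=10, n_mirnas=10, n_pos=40)
    folds = make_folds(ds, protocol="molecule", seed=0)
    for fold_id in set(folds.values()):
        held = {m for (m, _), f in folds.items() if f == fold_id}
        trained = {m for (m, _), f in folds.items() if f != fold_id}
        assert len(held) == 1
        assert not (held & trained)


def test_pair_protocol_gives_singleton_folds():
    ds = _light_dataset(n_pos=25)
    folds = make_folds(ds, protocol="pair", seed=0)
    assert sorted(folds.values()) == list(range(25))


def test_conflicting_labels_rejected():
    ds = _light_dataset(n_pos=10)
    pair = next(iter(ds.positives))
    with pytest.raises(ValueError):
        AssociationDataset(
            molecules=ds.molecules,
            mirnas=ds.mirnas,
            positives=ds.positives,
            negatives={pair},
        )


# ----------------------------------------------------------------- AUC

def test_auc_worked_examples():
    auc, _ = roc_auc([0.9, 0.4, 0.8, 0.2], [1, 1, 0, 0])
    assert auc == pytest.approx(0.75, abs=1e-12)  # 3 of 4 concordant pairs
    auc, _ = roc_auc([0.1, 0.9, 0.2, 0.8], [0, 1, 0, 1])
    assert auc == 1.0
    auc, _ = roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])
    assert auc == pytest.approx(0.5)


def test_auc_matches_brute_force_on_fuzzed_sets():
    rng = np.random.default_rng(2024)
    for _ in range(60):
        n = int(rng.integers(4, 40))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.random(n), 2)  # coarse grid forces ties
        auc, points = roc_auc(scores, labels)
        assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
        fpr = [p[0] for p in points]
        tpr = [p[1] for p in points]
        assert fpr[0] == 0.0 and tpr[0] == 0.0
        assert fpr[-1] == 1.0 and tpr[-1] == 1.0
        assert all(a <= b for a, b in zip(fpr, fpr[1:]))
        assert all(a <= b for a, b in zip(tpr, tpr[1:]))


def test_auc_rejects_single_class():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.2], [1, 1])


# ------------------------------------------------------------- training

@pytest.fixture(scope="module")
def tiny_labeled_dataset():
    raw = generate(SyntheticSpec(n_molecules=10, n_mirnas=12, seed=2))
    ds = build_dataset(raw.molecules, raw.mirnas, raw.positives)
    sample_negatives(ds, ratio=1.0, seed=0)
    return ds


def test_untrained_model_loss_is_ln2(tiny_labeled_dataset):
    """Balanced labels, fresh parameters: expected cross-entropy ~ ln 2."""
    ds = tiny_labeled_dataset
    pairs = ds.labeled_pairs
    vocab, graphs = _fingerprint_for_training(ds, pairs, 2)
    params = M.init_params(ModelConfig(seed=0), vocab.n_vertex_ids, vocab.n_edge_ids)
    losses = [float(M.pair_loss(graphs[m], ds.mirnas[s], l, params)) for m, s, l in pairs]
    assert np.mean(losses) == pytest.approx(np.log(2), abs=0.05)


def test_model_memorizes_a_single_batch(tiny_labeled_dataset):
    """500 epochs on one batch of 8 pairs drives the loss below 0.01."""
    ds = tiny_labeled_dataset
    pos = [p for p in ds.labeled_pairs if p[2] == 1][:4]
    neg = [p for p in ds.labeled_pairs if p[2] == 0][:4]
    cfg = ModelConfig(epochs=500, lr=0.05, momentum=0.9, batch_size=8, seed=0)
    result = train(ds, cfg, pairs=pos + neg)
    assert result.losses[-1] < 0.01


def test_training_is_seed_deterministic(tiny_labeled_dataset):
    ds = tiny_labeled_dataset
    cfg = ModelConfig(epochs=2, lr=0.01, batch_size=8, seed=4)
    a = train(ds, cfg)
    b = train(ds, cfg)
    assert a.losses == b.losses


def test_training_requires_both_classes(tiny_labeled_dataset):
    ds = tiny_labeled_dataset
    with pytest.raises(ValueError):
        train(ds, ModelConfig(epochs=1), pairs=[p for p in ds.labeled_pairs if p[2] == 1])


# -------------------------------------------------------------- ranking

@pytest.fixture(scope="module")
def trained_small(tiny_labeled_dataset):
    cfg = ModelConfig(epochs=5, lr=0.02, batch_size=8, seed=1)
    return train(tiny_labeled_dataset, cfg)


def test_rank_candidates_clamps_and_sorts(tiny_labeled_dataset, trained_small):
    ds = tiny_labeled_dataset
    n_candidates = len(ds.molecules) * len(ds.mirnas) - len(ds.positives)
    table = rank_candidates(trained_small, ds, top_k=10**9)
    assert len(table) == n_candidates  # top_k larger than pool returns all
    scores = table["score"].to_numpy()
    assert np.all(np.diff(scores) <= 0)  # descending
    assert table["rank"].tolist() == list(range(1, n_candidates + 1))


def test_ranking_matches_independent_sort(tiny_labeled_dataset, trained_small):
    ds = tiny_labeled_dataset
    candidates = sorted(
        (m, s) for m in ds.molecules for s in ds.mirnas if (m, s) not in ds.positives
    )
    scores = predict_pairs(trained_small, ds, candidates)
    expected = [
        c for c, _ in sorted(zip(candidates, scores), key=lambda t: (-t[1], t[0]))
    ]
    table = rank_candidates(trained_small, ds, top_k=len(candidates))
    got = list(zip(table["molecule_id"], table["mirna_id"]))
    assert got == expected


def test_predict_pair_exposes_window_aligned_attention(
    tiny_labeled_dataset, trained_small
):
    ds = tiny_labeled_dataset
    mol_id = sorted(ds.molecules)[0]
    mirna_id = sorted(ds.mirnas)[0]
    pred = predict_pair(trained_small, ds, mol_id, mirna_id)
    n_windows = len(ds.mirnas[mirna_id].tokens) - trained_small.params.config.w + 1
    assert pred.attention.shape == (n_windows,)
    assert 0.0 < pred.prob_positive < 1.0
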