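"""Learnable molecule encoder (message-passing graph neural network).

Fingerprint IDs index embedding tables giving initial vertex states v_i^0 and
edge states e_ij^0 in R^d.  T update rounds follow; within round t the
vertices update first from the round-(t-1) edge states,

    h_ij = max(0, W_neighbor [v_j ; e_ij] + b_neighbor)
    v_i^t = sigma(v_i^{t-1} + sum_{j in Gamma_i} h_ij),

then the edges update from the fresh vertex states,

    g_ij = max(0, W_side (v_i^t + v_j^t) + b_side)
    e_ij^t = sigma(e_ij^{t-1} + g_ij),

with sigma the logistic function, so every state stays in (0, 1).  The
molecule embedding y_sm is the mean of the final vertex states.  The symmetric
sum v_i + v_j (W_side is d x d) keeps the encoder exactly invariant to atom
relabeling.  Weights are shared across rounds.

All ops go through :mod:`molmir.autodiff`, so the same code serves inference
(NumPy arrays) and training (tensors with gradients).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad

DEFAULT_D = 32
DEFAULT_T = 2


@dataclass
class MoleculeEncoderParams:
    vertex_embedding: object  # (n_vertex_ids, d)
    edge_embedding: object    # (n_edge_ids, d)
    W_neighbor: object        # (d, 2d)
    b_neighbor: object        # (d,)
    W_side: object            # (d, d) — applied to the symmetric sum v_i + v_j
    b_side: object            # (d,)
    T: int = DEFAULT_T
    d: int = DEFAULT_D


def init_molecule_encoder(n_vertex_ids, n_edge_ids, d=DEFAULT_D, T=DEFAULT_T, rng=None):
    """Fresh parameters: zero-mean uniform embeddings scaled by 1/sqrt(d)."""
    rng = np.random.default_rng(rng)
    s = 1.0 / np.sqrt(d)
    return MoleculeEncoderParams(
        vertex_embedding=rng.uniform(-s, s, size=(n_vertex_ids, d)),
        edge_embedding=rng.uniform(-s, s, size=(n_edge_ids, d)),
        W_neighbor=rng.uniform(-s, s, size=(d, 2 * d)),
        b_neighbor=np.zeros(d),
        W_side=rng.uniform(-s, s, size=(d, d)),
        b_side=np.zeros(d),
        T=T,
        d=d,
    )


def _check_state(g, v_state, e_state, d):
    vs = v_state.value if isinstance(v_state, ad.Tensor) else np.asarray(v_state)
    es = e_state.value if isinstance(e_state, ad.Tensor) else np.asarray(e_state)
    if vs.shape != (g.n_atoms, d):
        raise ValueError(f"vertex state shape {vs.shape} != ({g.n_atoms}, {d})")
    if es.shape != (g.n_bonds, d):
        raise ValueError(f"edge state shape {es.shape} != ({g.n_bonds}, {d})")


def vertex_update(g, v_state, e_state, params):
    """One vertex round: sigmoid(v + aggregated ReLU neighbor messages)."""
    _check_state(g, v_state, e_state, params.d)
    if g.n_bonds == 0:
        return ad.sigmoid(v_state)  # empty neighbor sums
    dst, src, eidx = g.directed_edges()
    msg_in = ad.concat([ad.take(v_state, src), ad.take(e_state, eidx)], axis=1)
    h = ad.relu(ad.add(ad.matmul(msg_in, _transpose(params.W_neighbor)), params.b_neighbor))
    agg = ad.segment_sum(h, dst, g.n_atoms)
    return ad.sigmoid(ad.add(v_state, agg))


def edge_update(g, v_state, e_state, params):
    """One edge round: sigmoid(e + ReLU(W_side (v_i + v_j) + b_side))."""
    _check_state(g, v_state, e_state, params.d)
    if g.n_bonds == 0:
        return e_state
    bi = np.array([b[0] for b in g.bonds], dtype=np.intp)
    bj = np.array([b[1] for b in g.bonds], dtype=np.intp)
    vsum = ad.add(ad.take(v_state, bi), ad.take(v_state, bj))
    gate = ad.relu(ad.add(ad.matmul(vsum, _transpose(params.W_side)), params.b_side))
    return ad.sigmoid(ad.add(e_state, gate))


def _transpose(w):
    if isinstance(w, ad.Tensor):
        return ad.Tensor(w.value.T, [(w, lambda g: g.T)])
    return np.asarray(w).T


def encode_molecule(g, params):
    """Embed fingerprints, run T update rounds, mean-pool vertices -> y_sm."""
    if g.n_atoms == 0:
        raise ValueError("cannot encode an empty molecular graph")
    if g.vertex_fp is None:
        raise ValueError("graph has no fingerprints; call fingerprint_graph first")
    v = ad.take(params.vertex_embedding, g.vertex_fp)
    e = ad.take(params.edge_embedding, g.edge_fp)
    for _ in range(params.T):
        v = vertex_update(g, v, e, params)
        e = edge_update(g, v, e, params)
    return ad.mean(v, axis=0)
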