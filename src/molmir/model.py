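"""The full pair model: molecule GNN + sequence CNN + attention + softmax.

:class:`ModelParams` owns every learned tensor.  :func:`forward_pair` runs one
molecule/miRNA pair through both encoders and the classifier; with tensor
parameters the whole pass is differentiable end to end, with array parameters
it is a cheap inference pass.  Checkpoints are JSON (shape manifest + config)
so they survive text-only storage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .attention_classifier import (
    AttentionParams,
    attended_readout,
    attention_weights,
    init_attention,
    pair_logits,
    transform_hidden,
)
from .cnn_encoder import (
    SequenceEncoderParams,
    encode_sequence,
    init_sequence_encoder,
    sequence_readout,
)
from .config import ModelConfig
from .gnn_encoder import MoleculeEncoderParams, encode_molecule, init_molecule_encoder

CHECKPOINT_FORMAT = "molmir-checkpoint"
CHECKPOINT_VERSION = 1


@dataclass
class ModelParams:
    molecule: MoleculeEncoderParams
    sequence: SequenceEncoderParams
    attention: AttentionParams
    config: ModelConfig

    def named_arrays(self):
        """Flat name -> array view of every learned tensor."""
        m, s, a = self.molecule, self.sequence, self.attention
        out = {
            "vertex_embedding": m.vertex_embedding,
            "edge_embedding": m.edge_embedding,
            "W_neighbor": m.W_neighbor,
            "b_neighbor": m.b_neighbor,
            "W_side": m.W_side,
            "b_side": m.b_side,
            "word_embedding": s.word_embedding,
            "W_inter": a.W_inter,
            "b_inter": a.b_inter,
            "W_output": a.W_output,
            "b_output": a.b_output,
        }
        for k, (W, b) in enumerate(zip(s.conv_W, s.conv_b)):
            out[f"conv_W_{k}"] = W
            out[f"conv_b_{k}"] = b
        return out


def init_params(config, n_vertex_ids, n_edge_ids, seed=None):
    """Fresh parameters for given vocabulary sizes; deterministic under seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    mol = init_molecule_encoder(n_vertex_ids, n_edge_ids, d=config.d, T=config.T, rng=rng)
    seq = init_sequence_encoder(n=config.n, w=config.w, L=config.L, d=config.d, rng=rng)
    att = init_attention(config.d, rng=rng)
    return ModelParams(molecule=mol, sequence=seq, attention=att, config=config)


def as_tensors(params):
    """Wrap every learned array in a leaf Tensor (shared across steps) and
    return (tensor-backed ModelParams, name -> leaf dict for the optimizer)."""
    leaves = {k: ad.Tensor(v) for k, v in params.named_arrays().items()}
    m, s, a, c = params.molecule, params.sequence, params.attention, params.config
    mol = MoleculeEncoderParams(
        vertex_embedding=leaves["vertex_embedding"],
        edge_embedding=leaves["edge_embedding"],
        W_neighbor=leaves["W_neighbor"],
        b_neighbor=leaves["b_neighbor"],
        W_side=leaves["W_side"],
        b_side=leaves["b_side"],
        T=m.T,
        d=m.d,
    )
    seq = SequenceEncoderParams(
        word_embedding=leaves["word_embedding"],
        conv_W=[leaves[f"conv_W_{k}"] for k in range(len(s.conv_W))],
        conv_b=[leaves[f"conv_b_{k}"] for k in range(len(s.conv_b))],
        w=s.w,
        L=s.L,
        d=s.d,
    )
    att = AttentionParams(
        W_inter=leaves["W_inter"],
        b_inter=leaves["b_inter"],
        W_output=leaves["W_output"],
        b_output=leaves["b_output"],
    )
    return ModelParams(molecule=mol, sequence=seq, attention=att, config=c), leaves


def sync_from_tensors(params, tensor_params):
    """Copy tensor leaf values back into plain-array ModelParams."""
    src = tensor_params.named_arrays()
    dst = params.named_arrays()
    for k in dst:
        np.copyto(dst[k], src[k].value)


def forward_pair(graph, token_seq, params):
    """(logits, alpha, y_sm, C) for one pair; alpha is None with attention off."""
    y_sm = encode_molecule(graph, params.molecule)
    C = encode_sequence(token_seq, params.sequence)
    if params.config.attention:
        alpha = attention_weights(y_sm, C, params.attention)
        H = transform_hidden(C, params.attention)
        y_mirna = attended_readout(alpha, H)
    else:
        alpha = None
        y_mirna = sequence_readout(C)
    logits = pair_logits(y_mirna, y_sm, params.attention)
    return logits, alpha, y_sm, C


def pair_probability(graph, token_seq, params):
    """Association probability P_1 (and attention weights) for one pair."""
    logits, alpha, _, _ = forward_pair(graph, token_seq, params)
    z = logits.value if isinstance(logits, ad.Tensor) else np.asarray(logits)
    if not np.all(np.isfinite(z)):
        raise FloatingPointError("non-finite logits in forward pass")
    p = ad.softmax(z)
    a = None
    if alpha is not None:
        a = alpha.value if isinstance(alpha, ad.Tensor) else np.asarray(alpha)
    return float(p[1]), a


def pair_loss(graph, token_seq, label, params):
    """Cross-entropy of the softmax probabilities against a 0/1 label."""
    logits, _, _, _ = forward_pair(graph, token_seq, params)
    return ad.softmax_cross_entropy(logits, int(label))


def save_checkpoint(params, path):
    arrays = {k: np.asarray(v).tolist() for k, v in params.named_arrays().items()}
    cfg = params.config
    payload = {
        "format": CHECKPOINT_FORMAT,
        "version": CHECKPOINT_VERSION,
        "config": {f: getattr(cfg, f) for f in cfg.__dataclass_fields__},
        "shapes": {k: list(np.asarray(v).shape) for k, v in params.named_arrays().items()},
        "arrays": arrays,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_checkpoint(path):
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format") != CHECKPOINT_FORMAT:
        raise ValueError(f"{path}: not a molmir checkpoint")
    if payload["version"] != CHECKPOINT_VERSION:
        raise ValueError(f"{path}: unsupported checkpoint version")
    config = ModelConfig(**payload["config"])
    arrays = {k: np.asarray(v, dtype=np.float64) for k, v in payload["arrays"].items()}
    for k, shape in payload["shapes"].items():
        if list(arrays[k].shape) != shape:
            raise ValueError(f"{path}: shape mismatch for {k}")
    params = init_params(config, arrays["vertex_embedding"].shape[0], arrays["edge_embedding"].shape[0])
    dst = params.named_arrays()
    for k in dst:
        np.copyto(dst[k], arrays[k])
    return params
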