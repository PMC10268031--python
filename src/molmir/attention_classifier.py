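"""Neural attention coupling and the pair classifier.

The molecule embedding y_sm and each miRNA hidden vector c_i are mapped into a
shared space, h = ReLU(W_inter x + b_inter), and every sub-sequence receives
an (unnormalized) sigmoid attention weight

    alpha_i = sigmoid(h_sm . h_i),

the strength of interaction between the molecule and that sub-sequence.  The
attended miRNA readout is y_miRNA = sum_i alpha_i h_i (over the transformed
vectors).  The classifier is a softmax over two logits,

    Z = W_output [y_miRNA ; y_sm] + b_output,   P_t = exp(z_t) / sum exp(z),

and P_1 is reported as the association probability.  Because the weights are
sigmoids rather than a softmax over positions, they are comparable across
sequences of different lengths and expose which sub-sequences drive a
prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad


@dataclass
class AttentionParams:
    W_inter: object   # (d, d)
    b_inter: object   # (d,)
    W_output: object  # (2, 2d)
    b_output: object  # (2,)


@dataclass
class PairPrediction:
    molecule_id: str
    mirna_id: str
    prob_positive: float
    attention: np.ndarray  # one weight per token window, each in (0, 1)


def init_attention(d, rng=None):
    rng = np.random.default_rng(rng)
    s = 1.0 / np.sqrt(d)
    return AttentionParams(
        W_inter=rng.uniform(-s, s, size=(d, d)),
        b_inter=np.zeros(d),
        # small output weights keep the untrained classifier near P=(1/2, 1/2)
        W_output=rng.uniform(-0.01, 0.01, size=(2, 2 * d)),
        b_output=np.zeros(2),
    )


def _transpose(w):
    if isinstance(w, ad.Tensor):
        return ad.Tensor(w.value.T, [(w, lambda g: g.T)])
    return np.asarray(w).T


def transform_hidden(C, params):
    """h_i = ReLU(W_inter c_i + b_inter) for a stack of hidden vectors."""
    return ad.relu(ad.add(ad.matmul(C, _transpose(params.W_inter)), params.b_inter))


def transform_molecule(y_sm, params):
    """h_sm = ReLU(W_inter y_sm + b_inter)."""
    return ad.relu(ad.add(ad.matmul(params.W_inter, y_sm), params.b_inter))


def attention_weights(y_sm, C, params):
    """Per-sub-sequence weights alpha_i = sigmoid(h_sm . h_i), each in (0,1)."""
    vals = C.value if isinstance(C, ad.Tensor) else np.asarray(C)
    if vals.shape[0] == 0:
        raise ValueError("empty hidden set")
    h_sm = transform_molecule(y_sm, params)
    H = transform_hidden(C, params)
    return ad.sigmoid(ad.matmul(H, h_sm))


def attended_readout(alpha, H):
    """Attention-weighted sum y_miRNA = sum_i alpha_i h_i."""
    a = alpha.value if isinstance(alpha, ad.Tensor) else np.asarray(alpha)
    h = H.value if isinstance(H, ad.Tensor) else np.asarray(H)
    if a.shape[0] != h.shape[0]:
        raise ValueError(f"attention length {a.shape[0]} != hidden count {h.shape[0]}")
    return ad.sum_(ad.mul(ad.reshape(alpha, (-1, 1)), H), axis=0)


def pair_logits(y_mirna, y_sm, params):
    """Two classification logits Z = W_output [y_miRNA ; y_sm] + b_output."""
    joint = ad.concat([y_mirna, y_sm], axis=0)
    return ad.add(ad.matmul(params.W_output, joint), params.b_output)


def classify(y_mirna, y_sm, params):
    """(P_negative, P_positive) from the softmax over the two logits."""
    z = pair_logits(y_mirna, y_sm, params)
    zv = z.value if isinstance(z, ad.Tensor) else np.asarray(z)
    if not np.all(np.isfinite(zv)):
        raise FloatingPointError("non-finite classification logits")
    p = ad.softmax(zv)
    return float(p[0]), float(p[1])
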