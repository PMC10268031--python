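"""miRNA sequence encoder: overlapping n-mer tokens, word embeddings, a
window-concatenation convolution stack and a mean readout.

A sequence of s bases yields s - n + 1 overlapping n-mer words (n = 3 by
default, giving at most 4^3 = 64 words plus one reserved unknown token for
N-containing windows).  Each word has a learned d-dimensional embedding X_i;
window i concatenates w consecutive embeddings into c_i^0 in R^{dw}.  The
filter stack applies per-position affine + ReLU maps: the first layer takes
dw -> d, deeper layers d -> d (each layer owns its weights).  The plain
readout y_miRNA is the mean of the hidden set C = {c_i^L}; in the full model
the attention head replaces it with a weighted sum.

Token IDs are fixed by enumeration (base-4 code of the n-mer, offset by one),
so the token vocabulary needs no fitting and is identical across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad

RNA_BASES = "ACGU"
UNKNOWN_TOKEN = 0

DEFAULT_N = 3   # bases per word (stated choice: small n keeps the vocabulary informative)
DEFAULT_W = 5   # window size (words per convolution window)
DEFAULT_L = 2   # filter applications
DEFAULT_D = 32

_BASE_CODE = {b: k for k, b in enumerate(RNA_BASES)}


@dataclass
class TokenSequence:
    """A miRNA as an ordered list of overlapping n-mer token IDs."""

    mirna_id: str
    tokens: np.ndarray
    n: int
    source_length: int


@dataclass
class SequenceEncoderParams:
    word_embedding: object   # (4^n + 1, d); row 0 is the unknown token
    conv_W: list             # [ (d, d*w), (d, d), ... ]  one matrix per layer
    conv_b: list             # [ (d,), ... ]
    w: int = DEFAULT_W
    L: int = DEFAULT_L
    d: int = DEFAULT_D


def token_vocab_size(n=DEFAULT_N):
    """Number of token IDs: every RNA n-mer plus the unknown token."""
    return len(RNA_BASES) ** n + 1


def init_sequence_encoder(n=DEFAULT_N, w=DEFAULT_W, L=DEFAULT_L, d=DEFAULT_D, rng=None):
    if L < 1:
        raise ValueError("filter stack needs at least one layer")
    rng = np.random.default_rng(rng)
    s = 1.0 / np.sqrt(d)
    conv_W = [rng.uniform(-s, s, size=(d, d * w))]
    conv_b = [np.zeros(d)]
    for _ in range(1, L):
        conv_W.append(rng.uniform(-s, s, size=(d, d)))
        conv_b.append(np.zeros(d))
    return SequenceEncoderParams(
        word_embedding=rng.uniform(-s, s, size=(token_vocab_size(n), d)),
        conv_W=conv_W,
        conv_b=conv_b,
        w=w,
        L=L,
        d=d,
    )


def tokenize(sequence, n=DEFAULT_N, mirna_id=""):
    """Split an RNA sequence into overlapping n-mer token IDs (stride 1).

    T is accepted as an alias of U; any window containing N maps to the
    reserved unknown token.  Other characters are rejected.
    """
    seq = sequence.strip().upper().replace("T", "U")
    bad = set(seq) - set(RNA_BASES) - {"N"}
    if bad:
        raise ValueError(
            f"illegal character(s) {sorted(bad)} in sequence {mirna_id or sequence!r}"
        )
    if len(seq) < n:
        raise ValueError(
            f"sequence {mirna_id or sequence!r} shorter than word size n={n}"
        )
    tokens = np.empty(len(seq) - n + 1, dtype=np.intp)
    for i in range(len(tokens)):
        word = seq[i : i + n]
        if "N" in word:
            tokens[i] = UNKNOWN_TOKEN
        else:
            code = 0
            for b in word:
                code = code * 4 + _BASE_CODE[b]
            tokens[i] = code + 1
    return TokenSequence(mirna_id=mirna_id, tokens=tokens, n=n, source_length=len(seq))


def embed_windows(ts, params):
    """Concatenate w consecutive word embeddings per window -> (n_windows, dw)."""
    n_tok = len(ts.tokens)
    if n_tok == 0:
        raise ValueError("token sequence is empty")
    if n_tok < params.w:
        raise ValueError(
            f"sequence {ts.mirna_id!r}: {n_tok} words < window size w={params.w}"
        )
    X = ad.take(params.word_embedding, ts.tokens)
    n_win = n_tok - params.w + 1
    idx = np.add.outer(np.arange(n_win), np.arange(params.w))  # (n_win, w)
    flat = ad.take(X, idx.ravel())
    return ad.reshape(flat, (n_win, params.w * params.d))


def filter_stack(c0, params):
    """Per-position affine + ReLU layers: dw -> d, then d -> d, L times."""
    h = c0
    for W, b in zip(params.conv_W, params.conv_b):
        Wt = ad.Tensor(W.value.T, [(W, lambda g: g.T)]) if isinstance(W, ad.Tensor) else np.asarray(W).T
        h = ad.relu(ad.add(ad.matmul(h, Wt), b))
    return h


def sequence_readout(C):
    """Plain mean over the hidden set (the pre-attention readout)."""
    vals = C.value if isinstance(C, ad.Tensor) else np.asarray(C)
    if vals.shape[0] == 0:
        raise ValueError("empty hidden set")
    return ad.mean(C, axis=0)


def encode_sequence(ts, params):
    """Full encoder: windows -> filter stack -> hidden set C (n_windows, d)."""
    return filter_stack(embed_windows(ts, params), params)
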