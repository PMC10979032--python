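"""Sparse-attention drug encoder with convolutional distillation.

A sandwich of three top-S sparse self-attention layers interleaved with two
distillation blocks (width-3 convolution, ELU, strided max pooling that
halves the node axis). Attention logits carry the structural biases from
:mod:`dtafusion.encodings`; only the S queries with the highest
max-minus-mean sparsity score attend in full, the rest emit the mean value
vector. The final node axis is max-reduced to one global drug vector.

Because the distillation blocks operate on an ordered node axis (the
parser's atom order), this encoder — unlike the GCN drug encoder — is not
permutation invariant; the order is deterministic for a given input record.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from . import constants as C
from .autodiff import Parameter, Tensor
from .encodings import DegreeEmbeddingTable, degree_encode

#: vocabulary size per slot of the 9-slot atom feature vector
ATOM_SLOT_VOCABS = [
    C.MAX_ATOM_COUNT + 1,
    C.N_CHIRALITY,
    C.MAX_DEGREE + 1,
    C.N_CHARGE,
    C.MAX_NUM_H + 1,
    C.MAX_RADICALS + 1,
    C.N_HYBRID,
    2,
    2,
]


class AtomEmbedding:
    """Sum of per-slot embeddings of the 9 integer atom features."""

    def __init__(self, dim, rng):
        self.tables = [
            Parameter(rng.normal(0.0, 0.1, (v, dim)), name=f"atom_emb_{k}")
            for k, v in enumerate(ATOM_SLOT_VOCABS)
        ]

    def __call__(self, node_features):
        out = ad.embedding(self.tables[0], node_features[:, 0])
        for k in range(1, 9):
            out = out + ad.embedding(self.tables[k], node_features[:, k])
        return out

    def parameters(self):
        return list(self.tables)


class SparseAttentionParams:
    """Projection weights and the top-S budget of one attention layer."""

    def __init__(self, dim, top_s, rng):
        s = 1.0 / np.sqrt(dim)
        self.w_q = Parameter(rng.normal(0.0, s, (dim, dim)), name="w_q")
        self.w_k = Parameter(rng.normal(0.0, s, (dim, dim)), name="w_k")
        self.w_v = Parameter(rng.normal(0.0, s, (dim, dim)), name="w_v")
        self.top_s = int(top_s)
        self.scale = 1.0 / np.sqrt(dim)

    def parameters(self):
        return [self.w_q, self.w_k, self.w_v]


def query_sparsity_scores(q_proj, k_proj):
    """Max-minus-mean informativeness score of each query row.

    Computed exactly over all keys (molecular graphs are small enough that
    the sub-sampled estimate used for long sequences is unnecessary).
    """
    q = np.asarray(q_proj, dtype=float)
    k = np.asarray(k_proj, dtype=float)
    logits = q @ k.T / np.sqrt(q.shape[1])
    return logits.max(axis=1) - logits.mean(axis=1)


def select_top_queries(scores, top_s):
    """Indices of the top-S queries; ties resolved toward the lower index."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    return np.sort(order[: min(top_s, len(scores))])


def sparsepro_attention(h, bias, p):
    """Top-S sparse self-attention with additive structural biases.

    Logits are ``(h W_Q)(h W_K)^T / sqrt(d)`` plus the spatial and edge-path
    bias matrices (the degree signal already lives in ``h``). Selected
    queries emit the softmax-weighted sum of value vectors; unselected
    queries emit the mean value vector.
    """
    if not np.all(np.isfinite(h.data)):
        raise ValueError("non-finite node features entering attention")
    L = h.data.shape[0]
    q = h @ p.w_q
    k = h @ p.w_k
    v = h @ p.w_v
    logits = ad.scale(q @ ad.transpose(k), p.scale) + bias.spatial + bias.edge
    alpha = ad.softmax_rows(logits)
    attended = alpha @ v
    sel = select_top_queries(query_sparsity_scores(q.data, k.data), p.top_s)
    if len(sel) >= L:
        return attended
    mask = np.zeros((L, 1))
    mask[sel] = 1.0
    mean_v = ad.reshape(ad.mean_(v, axis=0), (1, -1))
    return Tensor(mask) * attended + Tensor(1.0 - mask) * mean_v


class DistillBlock:
    """Conv1d (width 3, same-padded) + ELU + max pool (window 3, stride 2)."""

    def __init__(self, dim, rng):
        s = 1.0 / np.sqrt(3 * dim)
        self.kernel = Parameter(rng.normal(0.0, s, (3, dim, dim)), name="conv_k")
        self.bias = Parameter(np.zeros(dim), name="conv_b")

    def __call__(self, x):
        return ad.maxpool1d_nodes(ad.elu(ad.conv1d_nodes(x, self.kernel, self.bias)))

    def parameters(self):
        return [self.kernel, self.bias]


def surviving_indices(length):
    """Input indices that anchor each pooled output position (stride 2)."""
    return np.arange(0, length, 2)


class ESCStack:
    """attention / distill / attention / distill / attention, with residual
    identity skips around each attention layer."""

    def __init__(self, dim, top_s, rng, use_degree=True):
        self.dim = dim
        self.use_degree = use_degree
        self.embed = AtomEmbedding(dim, rng)
        self.degree_table = DegreeEmbeddingTable(dim, rng=rng, scale=0.1 if use_degree else 0.0)
        self.attn = [SparseAttentionParams(dim, top_s, rng) for _ in range(3)]
        self.distill = [DistillBlock(dim, rng) for _ in range(2)]

    def parameters(self):
        ps = self.embed.parameters() + self.degree_table.parameters()
        for a in self.attn:
            ps += a.parameters()
        for d in self.distill:
            ps += d.parameters()
        return ps


def esc_forward(g, bias, stack):
    """Encode one drug graph into a global feature vector of length d."""
    h = stack.embed(g.node_features)
    if stack.use_degree:
        h = degree_encode(h, g.degrees, stack.degree_table)
    index = np.arange(g.n_nodes)
    cur_bias = bias
    for layer in range(3):
        h = sparsepro_attention(h, cur_bias, stack.attn[layer]) + h
        if layer < 2:
            h = stack.distill[layer](h)
            index = index[surviving_indices(len(index))]
            cur_bias = bias.subsample(index)
    return ad.max_axis(h, axis=0)
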