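"""Graph-convolution building blocks shared by the drug, protein-side and
fused-graph paths.

One GCN layer is ``H_i = ReLU(A_hat H_{i-1} W)`` with the symmetric
normalisation ``A_hat = D~^{-1/2} (A + I) D~^{-1/2}``; self-loops guarantee
every node (including isolated ones) keeps its own features. A residual block
applies an inner two-affine transform ``F`` and rectifies ``F(H) + H``.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor


def normalized_adjacency(a):
    """Symmetric GCN normalisation of a 0/1 adjacency (self-loops added)."""
    a = np.asarray(a, dtype=float)
    a_tilde = a + np.eye(a.shape[0])
    d = a_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return a_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]


class GCNLayerParams:
    def __init__(self, d_in, d_out, rng):
        s = np.sqrt(2.0 / (d_in + d_out))
        self.weight = Parameter(rng.normal(0.0, s, (d_in, d_out)), name="gcn_w")

    def parameters(self):
        return [self.weight]


def gcn_layer(h, a_hat, p):
    """One graph-convolution step; ``a_hat`` is the precomputed normalised
    adjacency (constant with respect to the parameters)."""
    return ad.relu(Tensor(a_hat) @ h @ p.weight)


class ResidualBlockParams:
    """Inner transform F(H) = W2 . ReLU(W1 H + b1); identity skip outside."""

    def __init__(self, dim, rng):
        s = np.sqrt(2.0 / (2 * dim))
        self.w1 = Parameter(rng.normal(0.0, s, (dim, dim)), name="res_w1")
        self.b1 = Parameter(np.zeros(dim), name="res_b1")
        self.w2 = Parameter(rng.normal(0.0, s, (dim, dim)), name="res_w2")

    def parameters(self):
        return [self.w1, self.b1, self.w2]


def residual_block(h, p):
    inner = ad.relu(h @ p.w1 + p.b1) @ p.w2
    return ad.relu(inner + h)


class AffineParams:
    def __init__(self, d_in, d_out, rng):
        s = np.sqrt(2.0 / (d_in + d_out))
        self.w = Parameter(rng.normal(0.0, s, (d_in, d_out)), name="aff_w")
        self.b = Parameter(np.zeros(d_out), name="aff_b")

    def parameters(self):
        return [self.w, self.b]


def affine(h, p):
    return h @ p.w + p.b
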