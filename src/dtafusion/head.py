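"""Affinity scoring head.

The drug path concatenates the global attention-encoder feature with a GCN
pass over the masked drug subgraph (a single super node, so that GCN is an
affine map); the protein path runs a GCN over the masked protein subgraph,
max-pools over residues, rectifies and projects. The concatenated vector goes
through a two-layer fully connected stack (dropout before each affine layer
during training) and ends in one real affinity score.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .gcn import AffineParams, GCNLayerParams, affine, gcn_layer, normalized_adjacency


class HeadParams:
    def __init__(self, dim, hidden, rng, dropout=0.2):
        self.dim = dim
        self.dropout = dropout
        self.drug_gcn = GCNLayerParams(dim, dim, rng)
        self.prot_gcn = GCNLayerParams(dim, dim, rng)
        self.prot_affine = AffineParams(dim, dim, rng)
        self.fc1 = AffineParams(3 * dim, hidden, rng)
        self.fc2 = AffineParams(hidden, 1, rng)

    def parameters(self):
        return (self.drug_gcn.parameters() + self.prot_gcn.parameters()
                + self.prot_affine.parameters()
                + self.fc1.parameters() + self.fc2.parameters())


def predict_affinity(x_esc, drug_masked, prot_masked, prot_adj, p,
                     rng=None, training=False, prot_a_hat=None):
    """Score one drug-protein pair.

    ``x_esc`` is the global drug feature (length d); ``drug_masked`` is the
    (1, d) masked drug row; ``prot_masked`` the (M, d) masked protein rows
    with their induced adjacency ``prot_adj``.
    """
    for name, t in (("x_esc", x_esc), ("drug_masked", drug_masked),
                    ("prot_masked", prot_masked)):
        if not np.all(np.isfinite(t.data)):
            raise ValueError(f"non-finite input at stage {name}")
    if x_esc.data.shape[-1] != p.dim or drug_masked.data.shape[-1] != p.dim:
        raise ValueError("width mismatch at stage drug-path input")
    # drug path: one-node subgraph GCN, then feature-axis concat with x_esc
    drug_refined = gcn_layer(drug_masked, np.ones((1, 1)), p.drug_gcn)
    x_d_final = ad.concat([ad.reshape(x_esc, (1, -1)), drug_refined], axis=1)
    x_d_pool = ad.max_axis(x_d_final, axis=0)  # node-axis pool (single row)
    # protein path: GCN over masked subgraph -> max pool -> ReLU -> affine
    if prot_a_hat is None:
        prot_a_hat = normalized_adjacency(prot_adj)
    prot_refined = gcn_layer(prot_masked, prot_a_hat, p.prot_gcn)
    x_p_pool = affine(ad.relu(ad.max_axis(prot_refined, axis=0)), p.prot_affine)
    joint = ad.concat([x_d_pool, x_p_pool], axis=0)
    if training and rng is not None:
        joint = ad.dropout(joint, p.dropout, rng, training)
    hidden = ad.relu(affine(joint, p.fc1))
    if training and rng is not None:
        hidden = ad.dropout(hidden, p.dropout, rng, training)
    score = affine(hidden, p.fc2)
    return score  # Tensor of shape (1,)
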