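"""GCN drug encoder: molecular graph -> drug super-node vector x_d.

This path consumes a different atom-feature slate from the attention
encoder: element, degree, position index, implicit-valence proxy, formal
charge and hybridization, one-hot embedded and projected. GCN layers and
residual blocks refine node features; a column-wise max pool collapses the
node axis; two affine layers emit the drug vector. Both the GCN layers and
the max pool are symmetric in the node order, so — unlike the attention
encoder — this encoding is permutation invariant.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from . import constants as C
from .autodiff import Parameter
from .chem import mol_encoder_features
from .gcn import AffineParams, GCNLayerParams, ResidualBlockParams, affine, gcn_layer, normalized_adjacency, residual_block

MOL_SLOT_VOCABS = [
    C.N_ELEMENTS,
    C.MAX_DEGREE + 1,
    C.MAX_ATOM_COUNT,
    C.MAX_NUM_H + 1,
    C.N_CHARGE,
    C.N_HYBRID,
]


class MolEncoder:
    """Embedding -> GCN blocks -> residual blocks -> max pool -> 2 affine."""

    def __init__(self, dim, rng, gcn_blocks=2, res_blocks=2, out_dim=None):
        out_dim = out_dim or dim
        self.dim = dim
        self.tables = [
            Parameter(rng.normal(0.0, 0.1, (v, dim)), name=f"mol_emb_{k}")
            for k, v in enumerate(MOL_SLOT_VOCABS)
        ]
        self.gcn = [GCNLayerParams(dim, dim, rng) for _ in range(gcn_blocks)]
        self.res = [ResidualBlockParams(dim, rng) for _ in range(res_blocks)]
        self.aff0 = AffineParams(dim, dim, rng)
        self.aff1 = AffineParams(dim, out_dim, rng)

    def parameters(self):
        ps = list(self.tables)
        for blk in self.gcn:
            ps += blk.parameters()
        for blk in self.res:
            ps += blk.parameters()
        return ps + self.aff0.parameters() + self.aff1.parameters()

    def embed(self, feats):
        out = ad.embedding(self.tables[0], feats[:, 0])
        for k in range(1, len(self.tables)):
            out = out + ad.embedding(self.tables[k], feats[:, k])
        return out


def encode_drug(g, enc, mol=None, feats=None):
    """Map a drug graph to its super-node vector.

    ``feats`` (the integer feature matrix from
    :func:`dtafusion.chem.mol_encoder_features`) may be precomputed; else it
    is derived from ``mol``.
    """
    if feats is None:
        if mol is None:
            raise ValueError("encode_drug needs either mol or precomputed feats")
        feats = mol_encoder_features(mol)
    h = enc.embed(np.asarray(feats))
    a_hat = normalized_adjacency(g.adjacency)
    for blk in enc.gcn:
        h = gcn_layer(h, a_hat, blk)
    for blk in enc.res:
        h = residual_block(h, blk)
    v_max = ad.max_axis(h, axis=0)
    return affine(affine(v_max, enc.aff0), enc.aff1)
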