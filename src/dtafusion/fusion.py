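"""Early fusion of drug and protein graphs and masked separation.

The drug enters the fused graph as a single super node (row 0) connected to
every residue; protein-internal edges are kept with indices shifted by one.
GCN refinement with residual blocks runs over the fused heterograph, after
which a boolean node mask splits the refined features back into the drug row
and the protein rows. The induced subgraphs are what the affinity head
consumes: the drug side is a one-node graph (its GCN reduces to an affine
map), the protein side keeps its internal contact/backbone edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .gcn import GCNLayerParams, ResidualBlockParams, gcn_layer, normalized_adjacency, residual_block


@dataclass
class DTGGraph:
    """Fused drug-target heterograph.

    Row 0 is the drug super node; protein residue i sits at row i + 1.
    ``node_mask`` is True at protein rows.
    """

    node_features: Tensor       # (1 + M, d)
    adjacency: np.ndarray       # (1 + M, 1 + M)
    node_mask: np.ndarray       # (1 + M,) bool
    protein_adjacency: np.ndarray  # (M, M) induced protein subgraph


def fused_adjacency(protein_adj):
    """Adjacency of the fused graph: cross edges (0, j) for every residue
    plus index-shifted protein edges. Depends only on the protein, so it can
    be cached per protein."""
    m = protein_adj.shape[0]
    adj = np.zeros((1 + m, 1 + m), dtype=np.int64)
    adj[0, 1:] = 1
    adj[1:, 0] = 1
    adj[1:, 1:] = protein_adj
    return adj


def fuse(x_d, prot_feats, protein_adj):
    """Stack the (already width-matched) drug super node onto the protein
    node features and attach the cross edges."""
    m = protein_adj.shape[0]
    if m == 0:
        raise ValueError("cannot fuse with an empty protein graph")
    drug_row = ad.reshape(x_d, (1, -1))
    feats = ad.concat([drug_row, prot_feats], axis=0)
    mask = np.ones(1 + m, dtype=bool)
    mask[0] = False
    return DTGGraph(node_features=feats, adjacency=fused_adjacency(protein_adj),
                    node_mask=mask, protein_adjacency=protein_adj)


class DTGRefiner:
    """GCN layer(s) + residual blocks over the fused heterograph."""

    def __init__(self, dim, rng, gcn_blocks=1, res_blocks=2):
        self.gcn = [GCNLayerParams(dim, dim, rng) for _ in range(gcn_blocks)]
        self.res = [ResidualBlockParams(dim, rng) for _ in range(res_blocks)]

    def parameters(self):
        ps = []
        for blk in self.gcn:
            ps += blk.parameters()
        for blk in self.res:
            ps += blk.parameters()
        return ps


def dtg_refine(g, refiner, a_hat=None):
    """Refine fused node features; shape is preserved."""
    if a_hat is None:
        a_hat = normalized_adjacency(g.adjacency)
    h = g.node_features
    for blk in refiner.gcn:
        h = gcn_layer(h, a_hat, blk)
    for blk in refiner.res:
        h = residual_block(h, blk)
    return h


def masked_split(g, refined):
    """Separate refined features into (drug rows, protein rows).

    The two outputs partition the node set: the drug part is the single
    super-node row, the protein part is the M residue rows in order.
    """
    prot_idx = np.flatnonzero(g.node_mask)
    drug_idx = np.flatnonzero(~g.node_mask)
    return ad.take_rows(refined, drug_idx), ad.take_rows(refined, prot_idx)
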