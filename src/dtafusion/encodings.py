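"""Structural encodings for the drug graph: degree, spatial, and edge-path.

Three complementary signals make the attention layers structure-aware:

* degree centrality — learnable embeddings of each atom's degree added to its
  node features (incoming and outgoing tables; identical keys on undirected
  molecular graphs);
* spatial — one learnable scalar per shortest-path-distance bucket, used as an
  additive logit bias for every atom pair, with a dedicated bucket for
  unreachable pairs;
* edge-path — bond features along the (deterministically chosen) shortest
  path between a pair, projected to a scalar and averaged over the path.

The shortest-path tie-break is the lexicographically smallest node sequence,
so all encodings are reproducible for a fixed atom order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_sp

from . import constants as C
from .autodiff import Parameter, Tensor, embedding, matmul, reshape as _reshape

MAX_DEGREE_BUCKET = 16
MAX_SPD_BUCKET = C.MAX_SPD_BUCKET


@dataclass
class SpatialMatrix:
    """All-pairs hop counts; -1 marks unreachable pairs; zero diagonal."""

    phi: np.ndarray

    @property
    def n(self):
        return self.phi.shape[0]


def compute_spd(g):
    """All-pairs unweighted shortest-path hop counts for a drug graph."""
    n = g.adjacency.shape[0]
    if n == 1:
        return SpatialMatrix(np.zeros((1, 1), dtype=np.int64))
    d = _csgraph_sp(g.adjacency.astype(float), method="D", unweighted=True)
    phi = np.where(np.isinf(d), -1, d).astype(np.int64)
    return SpatialMatrix(phi)


def spd_buckets(spd, max_bucket=MAX_SPD_BUCKET):
    """Bucketised hop counts; the last bucket (max_bucket + 1) = unreachable."""
    phi = spd.phi
    b = np.minimum(phi, max_bucket)
    b[phi < 0] = max_bucket + 1
    return b


# ---------------------------------------------------------------------------
# degree centrality


class DegreeEmbeddingTable:
    """Incoming/outgoing degree embedding tables, clipped at a bucket cap."""

    def __init__(self, dim, max_degree_bucket=MAX_DEGREE_BUCKET, rng=None, scale=0.0):
        self.max_degree_bucket = max_degree_bucket
        shape = (max_degree_bucket + 1, dim)
        if rng is None or scale == 0.0:
            init_in = np.zeros(shape)
            init_out = np.zeros(shape)
        else:
            init_in = rng.normal(0.0, scale, shape)
            init_out = rng.normal(0.0, scale, shape)
        self.in_table = Parameter(init_in, name="deg_in")
        self.out_table = Parameter(init_out, name="deg_out")

    def parameters(self):
        return [self.in_table, self.out_table]


def degree_encode(x, degrees, table):
    """Add degree-centrality embeddings to embedded node features.

    On an undirected graph the incoming and outgoing degrees coincide, so both
    lookups use the same key; the two tables remain distinct parameters.
    """
    degrees = np.asarray(degrees)
    if (degrees < 0).any():
        raise ValueError("negative node degree")
    buckets = np.minimum(degrees, table.max_degree_bucket)
    return x + embedding(table.in_table, buckets) + embedding(table.out_table, buckets)


# ---------------------------------------------------------------------------
# spatial bias


def make_spatial_weights(max_bucket=MAX_SPD_BUCKET):
    """One learnable scalar per SPD bucket plus an 'unreachable' bucket."""
    return Parameter(np.zeros(max_bucket + 2), name="w_phi")


def spatial_bias(spd, weights, max_bucket=MAX_SPD_BUCKET):
    """Per-pair additive attention bias from bucketised hop counts."""
    b = spd_buckets(spd, max_bucket)
    flat = embedding(weights, b.ravel())
    return _reshape(flat, b.shape)


# ---------------------------------------------------------------------------
# edge-path bias


@dataclass
class EdgePathTable:
    """Scalar projection of bond features plus a path-length cap."""

    w_edge: Parameter
    max_path_len: int = 20

    @classmethod
    def create(cls, max_path_len=20, init=None):
        w = np.zeros(C.BOND_ONEHOT_WIDTH) if init is None else np.asarray(init, float)
        return cls(w_edge=Parameter(w, name="w_edge"), max_path_len=max_path_len)

    def parameters(self):
        return [self.w_edge]


def bond_onehot(bf):
    """One-hot encode a (type, stereo, conjugated) bond feature vector."""
    v = np.zeros(C.BOND_ONEHOT_WIDTH)
    v[bf[0]] = 1.0
    v[C.N_BOND_TYPES + bf[1]] = 1.0
    v[C.N_BOND_TYPES + C.N_BOND_STEREO] = float(bf[2])
    return v


def canonical_shortest_path(g, spd, i, j):
    """Node sequence of the lexicographically smallest shortest path i -> j.

    Greedy descent: from the current node, step to the smallest-index
    neighbour whose remaining distance to ``j`` drops by one. Returns None if
    ``j`` is unreachable from ``i``.
    """
    phi = spd.phi
    if phi[i, j] < 0:
        return None
    neighbours = [np.flatnonzero(g.adjacency[v]) for v in range(phi.shape[0])]
    path = [i]
    cur = i
    while cur != j:
        nxt = min(v for v in neighbours[cur] if phi[v, j] == phi[cur, j] - 1)
        path.append(int(nxt))
        cur = nxt
    return path


def path_feature_matrix(g, spd, max_path_len=20):
    """(N, N, F) averaged bond one-hots along canonical shortest paths.

    Static per graph: diagonal and unreachable pairs are all-zero; paths
    longer than ``max_path_len`` contribute only their first
    ``max_path_len`` edges.
    """
    n = spd.n
    feat = {}
    for i, j, bf in g.edges:
        oh = bond_onehot(bf)
        feat[(i, j)] = oh
        feat[(j, i)] = oh
    out = np.zeros((n, n, C.BOND_ONEHOT_WIDTH))
    for i in range(n):
        for j in range(n):
            if i == j or spd.phi[i, j] < 0:
                continue
            path = canonical_shortest_path(g, spd, i, j)
            edges = list(zip(path[:-1], path[1:]))[:max_path_len]
            out[i, j] = np.mean([feat[e] for e in edges], axis=0)
    return out


def edge_path_bias(g, spd, table):
    """Per-pair additive attention bias from bond features along paths."""
    pf = path_feature_matrix(g, spd, table.max_path_len)
    return edge_path_bias_from_matrix(pf, table)


def edge_path_bias_from_matrix(pf, table):
    """Edge-path bias from a precomputed (N, N, F) path-feature matrix; lets
    callers cache the expensive static part across training steps."""
    n = pf.shape[0]
    flat = matmul(Tensor(pf.reshape(n * n, -1)), table.w_edge)
    return _reshape(flat, (n, n))


@dataclass
class AttentionBiasSet:
    """Spatial and edge-path bias matrices for one drug graph.

    The degree signal enters through the node features (``degree_encode``),
    not through a pair matrix.
    """

    spatial: Tensor
    edge: Tensor

    def subsample(self, index):
        """Restrict both matrices to the surviving node indices."""
        return AttentionBiasSet(
            spatial=_submatrix(self.spatial, index),
            edge=_submatrix(self.edge, index),
        )


def _submatrix(t, index):
    index = np.asarray(index, dtype=np.intp)

    def bw(g):
        full = np.zeros_like(t.data)
        np.add.at(full, np.ix_(index, index), g)
        return ((t, full),)

    return Tensor(t.data[np.ix_(index, index)], parents=(t,), backward=bw)


def build_bias_set(g, spd, w_phi, edge_table, use_spatial=True, use_edge=True):
    """Assemble the attention-bias pair matrices for one graph."""
    n = spd.n
    zero = Tensor(np.zeros((n, n)))
    sp = spatial_bias(spd, w_phi) if use_spatial else zero
    ed = edge_path_bias(g, spd, edge_table) if use_edge else zero
    return AttentionBiasSet(spatial=sp, edge=ed)
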