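"""The affinity model: network assembly, fitting, and results.

:class:`AffinityModel` is built from a :class:`~dtafusion.data.DatasetTable`
(plus a split plan and hyperparameters) and owns the full computation graph:
two drug encoders (sparse-attention global path and GCN super-node path), the
residue-level protein graph, early fusion into a heterograph, GCN refinement
with masked separation, and the scoring head. ``fit()`` minimises the mean
squared error with Adam and returns an :class:`AffinityResults` carrying the
trained parameters, the training log, per-part predictions and a ``summary()``
table. All randomness — initialisation, batch order, dropout — flows from one
seed.

Static featurization (molecular graphs, shortest-path structures, protein
node features, normalised adjacencies) is cached per drug and per protein;
within a batch each unique drug and protein is encoded once and shared across
its pairs, which is also how gradients accumulate.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .chem import build_drug_graph, mol_encoder_features, parse_molecule
from .data import make_splits, save_predictions
from .encodings import (AttentionBiasSet, EdgePathTable, compute_spd,
                        edge_path_bias_from_matrix, make_spatial_weights,
                        path_feature_matrix, spatial_bias)
from .esc import ESCStack, esc_forward
from .fusion import DTGRefiner, dtg_refine, fuse, fused_adjacency, masked_split
from .gcn import AffineParams, affine, normalized_adjacency
from .head import HeadParams, predict_affinity
from .metrics import regression_metrics
from .molenc import MolEncoder, encode_drug
from .protein import build_protein_graph
from .synth import SyntheticEmbeddingProvider

_CHOICES = {
    "res_blocks": {2, 3, 4},
    "gcn_blocks": {1, 2},
    "hidden": {256, 512},
    "train_batch": {64, 128},
    "dropout": {0.2, 0.5},
    "lr": {0.0005, 0.001, 0.01},
}


@dataclass
class Hyperparameters:
    """Training and architecture settings.

    Values outside the declared search sets are accepted with a warning, so
    desk-scale runs can shrink the network without editing the class.
    """

    res_blocks: int = 2
    gcn_blocks: int = 2
    epochs: int = 2000
    hidden: int = 256
    train_batch: int = 64
    test_batch: int = 256
    dropout: float = 0.2
    lr: float = 0.001
    top_s: int = 25
    seed: int = 0
    d_model: int = 32
    embedding_width: int = 16
    use_degree: bool = True
    use_spatial: bool = True
    use_edge: bool = True

    def __post_init__(self):
        for name, allowed in _CHOICES.items():
            if getattr(self, name) not in allowed:
                warnings.warn(f"hyperparameter {name}={getattr(self, name)} "
                              f"is outside the declared set {sorted(allowed)}",
                              stacklevel=3)

    def to_dict(self):
        return asdict(self)


class _DrugCache:
    """Static per-drug structures shared across all training steps."""

    def __init__(self, smiles, drug_id, max_path_len):
        self.mol = parse_molecule(smiles, drug_id)
        self.graph = build_drug_graph(self.mol)
        self.spd = compute_spd(self.graph)
        self.path_features = path_feature_matrix(self.graph, self.spd, max_path_len)
        self.mol_feats = mol_encoder_features(self.mol)


class _ProteinCache:
    """Static per-protein structures: node features and adjacencies."""

    def __init__(self, rec, provider):
        self.graph = build_protein_graph(rec, provider)
        self.node_features = self.graph.node_features
        self.adjacency = self.graph.adjacency
        self.a_hat = normalized_adjacency(self.adjacency)
        self.fused_a_hat = normalized_adjacency(fused_adjacency(self.adjacency))


class DTANetwork:
    """All trainable components, wired per the early-fusion architecture."""

    def __init__(self, hp, feature_width, rng):
        d = hp.d_model
        self.hp = hp
        self.esc = ESCStack(d, hp.top_s, rng, use_degree=hp.use_degree)
        self.w_phi = make_spatial_weights()
        self.edge_table = EdgePathTable.create()
        self.mol = MolEncoder(d, rng, gcn_blocks=hp.gcn_blocks,
                              res_blocks=hp.res_blocks)
        self.prot_proj = AffineParams(feature_width, d, rng)
        self.refiner = DTGRefiner(d, rng, gcn_blocks=1, res_blocks=hp.res_blocks)
        self.head = HeadParams(d, hp.hidden, rng, dropout=hp.dropout)

    def parameters(self):
        return (self.esc.parameters() + [self.w_phi]
                + self.edge_table.parameters() + self.mol.parameters()
                + self.prot_proj.parameters() + self.refiner.parameters()
                + self.head.parameters())

    def bias_set(self, dc):
        n = dc.spd.n
        zero = Tensor(np.zeros((n, n)))
        sp = spatial_bias(dc.spd, self.w_phi) if self.hp.use_spatial else zero
        ed = (edge_path_bias_from_matrix(dc.path_features, self.edge_table)
              if self.hp.use_edge else zero)
        return AttentionBiasSet(spatial=sp, edge=ed)

    def encode_drug_pair(self, dc):
        """(global attention feature, GCN super-node vector) for one drug."""
        x_esc = esc_forward(dc.graph, self.bias_set(dc), self.esc)
        x_d = encode_drug(dc.graph, self.mol, feats=dc.mol_feats)
        return x_esc, x_d

    def project_protein(self, pc):
        return affine(Tensor(pc.node_features), self.prot_proj)

    def score_pair(self, x_esc, x_d, prot_feats, pc, rng=None, training=False):
        dtg = fuse(x_d, prot_feats, pc.adjacency)
        refined = dtg_refine(dtg, self.refiner, a_hat=pc.fused_a_hat)
        drug_rows, prot_rows = masked_split(dtg, refined)
        return predict_affinity(x_esc, drug_rows, prot_rows, pc.adjacency,
                                self.head, rng=rng, training=training,
                                prot_a_hat=pc.a_hat)

    def state_arrays(self):
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint does not match network layout")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.data = a.copy()


class TrainingDiverged(RuntimeError):
    pass


class AffinityModel:
    """Early-fusion graph regression model for drug-target affinity.

    Parameters
    ----------
    table : DatasetTable
        Drugs, proteins and affinity pairs (already on model scale).
    plan : SplitPlan, optional
        Six-part split; built from ``hp.seed`` when omitted.
    hp : Hyperparameters, optional
    provider : EmbeddingProvider, optional
        Per-residue sequence embedder; defaults to the deterministic
        synthetic provider at ``hp.embedding_width``.
    """

    def __init__(self, table, plan=None, hp=None, provider=None):
        self.table = table
        self.hp = hp or Hyperparameters()
        self.plan = plan or make_splits(table, self.hp.seed)
        self.provider = provider or SyntheticEmbeddingProvider(self.hp.embedding_width)
        self._drug_cache = {}
        self._protein_cache = {}
        self.feature_width = self.provider.width + 8 + 1
        self.network = None

    @classmethod
    def from_files(cls, manifest, drugs, protein_dir, affinity_kind="pkd", **kw):
        from .data import load_dataset
        table = load_dataset(manifest, drugs, protein_dir, affinity_kind)
        return cls(table, **kw)

    # -- caches ----------------------------------------------------------
    def _drug(self, drug_id):
        if drug_id not in self._drug_cache:
            self._drug_cache[drug_id] = _DrugCache(
                self.table.drugs[drug_id], drug_id, max_path_len=20)
        return self._drug_cache[drug_id]

    def _protein(self, protein_id):
        if protein_id not in self._protein_cache:
            self._protein_cache[protein_id] = _ProteinCache(
                self.table.proteins[protein_id], self.provider)
        return self._protein_cache[protein_id]

    # -- forward ---------------------------------------------------------
    def _batch_scores(self, indices, rng=None, training=False):
        """Scores for a batch of pair indices; unique drugs/proteins are
        encoded once and shared."""
        net = self.network
        pairs = [self.table.pairs[i] for i in indices]
        drug_enc = {}
        prot_enc = {}
        for d_id, p_id, _ in pairs:
            if d_id not in drug_enc:
                drug_enc[d_id] = net.encode_drug_pair(self._drug(d_id))
            if p_id not in prot_enc:
                prot_enc[p_id] = net.project_protein(self._protein(p_id))
        scores = []
        for d_id, p_id, _ in pairs:
            x_esc, x_d = drug_enc[d_id]
            scores.append(net.score_pair(x_esc, x_d, prot_enc[p_id],
                                         self._protein(p_id),
                                         rng=rng, training=training))
        y = np.array([a for _, _, a in pairs])
        return scores, y

    def _loss(self, scores, y):
        stacked = ad.concat(scores, axis=0)
        return ad.mean_(ad.square(stacked - Tensor(y)))

    # -- fitting ---------------------------------------------------------
    def fit(self, epochs=None, seed=None, fold=None, verbose=False,
            log_every=10):
        """Train with Adam on the MSE loss and return the results object.

        ``fold`` selects a CV fold whose validation part drives best-weight
        checkpointing; with ``fold=None`` all non-test pairs train and the
        final weights are kept.
        """
        hp = self.hp
        epochs = hp.epochs if epochs is None else epochs
        seed = hp.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        self.network = DTANetwork(hp, self.feature_width, rng)
        if fold is None:
            train_idx = self.plan.train_indices()
            val_idx = None
        else:
            train_idx, val_idx = self.plan.fold_indices(fold)
        opt = Adam(self.network.parameters(), lr=hp.lr)
        log = []
        best = None
        t0 = time.time()
        for epoch in range(epochs):
            order = rng.permutation(train_idx)
            epoch_loss = 0.0
            for start in range(0, len(order), hp.train_batch):
                batch = order[start:start + hp.train_batch]
                scores, y = self._batch_scores(batch, rng=rng, training=True)
                loss = self._loss(scores, y)
                if not np.isfinite(loss.data):
                    raise TrainingDiverged(
                        f"loss became non-finite at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(batch)
            epoch_loss /= len(train_idx)
            entry = {"epoch": epoch, "train_mse": epoch_loss,
                     "wall_clock": time.time() - t0, "seed": seed}
            if val_idx is not None and (epoch % log_every == 0
                                        or epoch == epochs - 1):
                val_mse = self._eval_mse(val_idx)
                entry["val_mse"] = val_mse
                if best is None or val_mse < best[0]:
                    best = (val_mse, self.network.state_arrays())
            log.append(entry)
            if verbose and epoch % log_every == 0:
                print(f"epoch {epoch:4d}  train mse {epoch_loss:.4f}"
                      + (f"  val mse {entry.get('val_mse', float('nan')):.4f}"
                         if val_idx is not None else ""))
        if best is not None:
            self.network.load_state_arrays(best[1])
        return AffinityResults(self, log, seed=seed, fold=fold)

    def _eval_mse(self, indices):
        scores, y = self._batch_scores(indices, training=False)
        return float(np.mean((np.concatenate([s.data for s in scores]) - y) ** 2))

    def predict_indices(self, indices):
        """Deterministic (dropout-free) predictions for pair indices."""
        preds = []
        bs = self.hp.test_batch
        for start in range(0, len(indices), bs):
            batch = np.asarray(indices)[start:start + bs]
            scores, _ = self._batch_scores(batch, training=False)
            preds.extend(float(s.data[0]) for s in scores)
        return np.array(preds)


class AffinityResults:
    """Fitted-model results: training log, predictions, metrics, summary."""

    def __init__(self, model, train_log, seed, fold=None):
        self.model = model
        self.train_log = train_log
        self.seed = seed
        self.fold = fold

    @property
    def network(self):
        return self.model.network

    def predict(self, part="test"):
        """Predictions as rows (drug_id, protein_id, y_true, y_pred)."""
        idx = self._indices(part)
        preds = self.model.predict_indices(idx)
        rows = []
        for i, yp in zip(idx, preds):
            d, p, yt = self.model.table.pairs[i]
            rows.append((d, p, yt, yp))
        return rows

    def _indices(self, part):
        plan = self.model.plan
        if part == "test":
            return plan.test_indices()
        if part == "train":
            return plan.train_indices()
        if part == "all":
            return np.arange(self.model.table.n_pairs)
        raise ValueError(f"unknown part {part!r}")

    def evaluate(self, part="test", predictions_path=None):
        """Metric report for one part; optionally writes the predictions TSV."""
        rows = self.predict(part)
        if predictions_path is not None:
            save_predictions(predictions_path, rows)
        y = np.array([r[2] for r in rows])
        yhat = np.array([r[3] for r in rows])
        return regression_metrics(y, yhat)

    def summary(self, part="test"):
        """Plain-text summary table of the fit and its evaluation metrics."""
        rep = self.evaluate(part)
        hp = self.model.hp
        lines = [
            "Drug-Target Affinity Regression Results",
            "=" * 47,
            f"{'No. pairs (total)':<28}{self.model.table.n_pairs:>19}",
            f"{'No. pairs (' + part + ')':<28}{rep.n:>19}",
            f"{'Epochs run':<28}{len(self.train_log):>19}",
            f"{'Final train MSE':<28}{self.train_log[-1]['train_mse']:>19.4f}",
            f"{'Seed':<28}{self.seed:>19}",
            f"{'Hidden / d_model':<28}{f'{hp.hidden} / {hp.d_model}':>19}",
            "-" * 47,
        ]
        for name in ("mse", "rmse", "pearson", "spearman", "ci", "r2"):
            lines.append(f"{name.upper():<28}{getattr(rep, name):>19.4f}")
        lines.append("=" * 47)
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------
    def save(self, path):
        """Checkpoint parameters + config to an .npz archive."""
        arrays = {f"p{i}": a for i, a in enumerate(self.network.state_arrays())}
        arrays["config"] = np.frombuffer(
            json.dumps(self.model.hp.to_dict()).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @staticmethod
    def load_into(model, path):
        """Restore checkpointed weights into a compatible model; returns a
        results object with an empty log."""
        archive = np.load(path)
        cfg = json.loads(bytes(archive["config"]).decode())
        if model.network is None:
            rng = np.random.default_rng(model.hp.seed)
            model.network = DTANetwork(model.hp, model.feature_width, rng)
        if cfg != model.hp.to_dict():
            warnings.warn("checkpoint config differs from model config")
        n = len(model.network.parameters())
        model.network.load_state_arrays([archive[f"p{i}"] for i in range(n)])
        return AffinityResults(model, train_log=[], seed=model.hp.seed)
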