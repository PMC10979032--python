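"""Residue-level protein graphs from sequence, SS8, ASA and a contact map.

A protein record carries the amino-acid sequence, an 8-state secondary
structure string (DSSP alphabet ``HGIEBTSC``), per-residue relative solvent
accessibility in [0, 1], and either a residue-pair distance matrix (Å) or a
contact-probability matrix. Node features concatenate a per-residue sequence
embedding (behind a provider contract, so any language-model embedder can be
plugged in), the one-hot SS8 state, and the ASA scalar. Edges are contacts —
non-adjacent residues (|i - j| >= 2) closer than 8 Å, or contact probability
above 0.5 — plus backbone (i, i+1) edges that keep the chain connected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np

from . import constants as C

CONTACT_DISTANCE = 8.0        # Å, strict upper bound
CONTACT_PROBABILITY = 0.5     # strict lower bound for probability maps
MIN_SEQ_SEPARATION = 2


class ProteinValidationError(ValueError):
    pass


@dataclass
class ProteinRecord:
    protein_id: str
    sequence: str
    ss8: str
    asa: np.ndarray         # (M,) relative accessibility in [0, 1]
    distmap: np.ndarray     # (M, M)
    kind: str = "distance"  # "distance" | "probability"

    def __post_init__(self):
        self.asa = np.asarray(self.asa, dtype=float)
        self.distmap = np.asarray(self.distmap, dtype=float)
        m = len(self.sequence)
        for name, length in (("ss8", len(self.ss8)), ("asa", len(self.asa)),
                             ("distmap", self.distmap.shape[0])):
            if length != m:
                raise ProteinValidationError(
                    f"{self.protein_id}: field '{name}' has length {length}, "
                    f"sequence has {m}")
        if self.distmap.shape[0] != self.distmap.shape[1]:
            raise ProteinValidationError(f"{self.protein_id}: distmap is not square")
        if not np.allclose(self.distmap, self.distmap.T, atol=1e-6):
            raise ProteinValidationError(f"{self.protein_id}: distmap is asymmetric")
        if self.kind not in ("distance", "probability"):
            raise ProteinValidationError(f"{self.protein_id}: unknown map kind {self.kind!r}")
        bad = set(self.ss8) - set(C.SS8_ALPHABET)
        if bad:
            raise ProteinValidationError(
                f"{self.protein_id}: ss8 contains letters outside the 8-state "
                f"alphabet: {sorted(bad)}")
        # absolute ASA (Å^2) is normalised to relative accessibility at load
        if np.nanmax(self.asa) > 1.0 + 1e-9:
            maxes = np.array([C.MAX_ASA.get(aa, 200.0) for aa in self.sequence])
            self.asa = np.clip(self.asa / maxes, 0.0, 1.0)

    @property
    def length(self):
        return len(self.sequence)


@runtime_checkable
class EmbeddingProvider(Protocol):
    """Contract for per-residue sequence embedders (language models etc.)."""

    width: int

    def embed(self, sequence: str) -> np.ndarray:  # (M, width)
        ...


@dataclass
class ProteinGraph:
    protein_id: str
    node_features: np.ndarray   # (M, h + 8 + 1)
    edges: list                 # (i, j, kind) with i < j, kinds backbone|contact
    adjacency: np.ndarray       # (M, M) 0/1 symmetric

    @property
    def n_nodes(self):
        return self.node_features.shape[0]


def build_contact_edges(rec):
    """Undirected edge list: contacts plus backbone links.

    Contacts require sequence separation >= 2 and distance strictly below
    8 Å (or probability strictly above 0.5). Backbone edges (i, i+1) are
    always present so the graph stays chain-connected.
    """
    m = rec.length
    edges = [(i, i + 1, "backbone") for i in range(m - 1)]
    if rec.kind == "distance":
        hit = rec.distmap < CONTACT_DISTANCE
    else:
        hit = rec.distmap > CONTACT_PROBABILITY
    for i in range(m):
        for j in range(i + MIN_SEQ_SEPARATION, m):
            if hit[i, j]:
                edges.append((i, j, "contact"))
    return edges


def build_protein_graph(rec, provider):
    """Assemble the residue graph: embedding ⊕ one-hot SS8 ⊕ ASA per node."""
    emb = np.asarray(provider.embed(rec.sequence), dtype=float)
    if emb.shape != (rec.length, provider.width):
        raise ProteinValidationError(
            f"{rec.protein_id}: provider returned shape {emb.shape}, "
            f"expected ({rec.length}, {provider.width})")
    ss_onehot = np.zeros((rec.length, 8))
    for i, s in enumerate(rec.ss8):
        ss_onehot[i, C.SS8_ALPHABET.index(s)] = 1.0
    feats = np.hstack([emb, ss_onehot, rec.asa[:, None]])
    edges = build_contact_edges(rec)
    adj = np.zeros((rec.length, rec.length), dtype=np.int64)
    for i, j, _ in edges:
        adj[i, j] = adj[j, i] = 1
    return ProteinGraph(protein_id=rec.protein_id, node_features=feats,
                        edges=edges, adjacency=adj)


# ---------------------------------------------------------------------------
# on-disk record format


def load_protein_record(protein_id, directory):
    """Read one record from ``directory``: {id}.fasta, {id}.ss8, {id}.asa.tsv
    and {id}.map (whitespace matrix with a `# kind: distance|probability`
    header line)."""
    from Bio import SeqIO

    directory = Path(directory)
    fasta = directory / f"{protein_id}.fasta"
    seq = str(next(SeqIO.parse(str(fasta), "fasta")).seq)
    ss8 = (directory / f"{protein_id}.ss8").read_text().strip()
    asa_rows = [ln.split("\t") for ln in
                (directory / f"{protein_id}.asa.tsv").read_text().strip().splitlines()]
    asa = np.full(len(seq), np.nan)
    for idx, val in asa_rows:
        asa[int(idx)] = float(val)
    map_lines = (directory / f"{protein_id}.map").read_text().strip().splitlines()
    kind = "distance"
    if map_lines[0].lstrip().startswith("#"):
        kind = map_lines[0].split(":")[-1].strip()
        map_lines = map_lines[1:]
    dist = np.array([[float(x) for x in ln.split()] for ln in map_lines])
    return ProteinRecord(protein_id=protein_id, sequence=seq, ss8=ss8,
                         asa=asa, distmap=dist, kind=kind)


def save_protein_record(rec, directory):
    """Write a record in the four-file plain-text layout of
    :func:`load_protein_record`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / f"{rec.protein_id}.fasta").write_text(
        f">{rec.protein_id}\n{rec.sequence}\n")
    (directory / f"{rec.protein_id}.ss8").write_text(rec.ss8 + "\n")
    (directory / f"{rec.protein_id}.asa.tsv").write_text(
        "".join(f"{i}\t{v:.6f}\n" for i, v in enumerate(rec.asa)))
    body = "\n".join(" ".join(f"{x:.3f}" for x in row) for row in rec.distmap)
    (directory / f"{rec.protein_id}.map").write_text(
        f"# kind: {rec.kind}\n{body}\n")
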