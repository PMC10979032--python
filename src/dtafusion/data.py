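"""Dataset tables, on-disk manifests, and the split protocol.

A dataset is (drug id -> SMILES), (protein id -> ProteinRecord), and a list
of (drug_id, protein_id, affinity) pairs. Dissociation constants given in nM
are transformed to pKd at load. The split protocol shuffles pairs into six
equal parts, holds one out as the independent test set, and arranges the
remaining five as 5-fold cross-validation; a quadrant mode first cuts the
pair list into four seeded subsets, each split six ways independently.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .metrics import kd_to_pkd
from .protein import load_protein_record

log = logging.getLogger("dtafusion")

AFFINITY_KINDS = ("kd_nM", "pkd", "kiba")


class DatasetError(ValueError):
    pass


@dataclass
class DatasetTable:
    drugs: dict                 # drug_id -> SMILES
    proteins: dict              # protein_id -> ProteinRecord
    pairs: list                 # (drug_id, protein_id, affinity) on model scale
    affinity_kind: str = "pkd"

    def __post_init__(self):
        if self.affinity_kind not in AFFINITY_KINDS:
            raise DatasetError(f"unknown affinity kind {self.affinity_kind!r}")
        for d, p, a in self.pairs:
            if d not in self.drugs:
                raise DatasetError(f"pair references unknown drug id {d!r}")
            if p not in self.proteins:
                raise DatasetError(f"pair references unknown protein id {p!r}")
            if not math.isfinite(a):
                raise DatasetError(f"non-finite affinity for pair ({d}, {p})")

    @property
    def n_pairs(self):
        return len(self.pairs)

    def affinities(self):
        return np.array([a for _, _, a in self.pairs])


@dataclass
class SplitPlan:
    """Six-part split: part 5 is the test set, parts 0-4 rotate as CV folds."""

    part_assignment: np.ndarray     # (n_pairs,) int in 0..5
    test_part: int
    cv_folds: list                  # fold k -> validation part index
    seed: int

    def test_indices(self):
        return np.flatnonzero(self.part_assignment == self.test_part)

    def fold_indices(self, k):
        """(train, validation) pair indices for CV fold ``k``."""
        val_part = self.cv_folds[k]
        val = np.flatnonzero(self.part_assignment == val_part)
        train = np.flatnonzero((self.part_assignment != val_part)
                               & (self.part_assignment != self.test_part))
        return train, val

    def train_indices(self):
        """All non-test pairs."""
        return np.flatnonzero(self.part_assignment != self.test_part)


def make_splits(table, seed):
    """Seeded 6-way split with one test part and 5-fold CV over the rest."""
    n = table.n_pairs
    if n < 12:
        raise DatasetError(f"need at least 12 pairs to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment = np.empty(n, dtype=np.int64)
    # equal parts +-1: distribute the remainder over the leading parts
    sizes = np.full(6, n // 6)
    sizes[: n % 6] += 1
    start = 0
    for part, size in enumerate(sizes):
        assignment[order[start:start + size]] = part
        start += size
    return SplitPlan(part_assignment=assignment, test_part=5,
                     cv_folds=[0, 1, 2, 3, 4], seed=seed)


def make_quadrant_splits(table, seed):
    """KIBA-style: four seeded pair subsets, each split six ways."""
    n = table.n_pairs
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    quads = np.array_split(order, 4)
    plans = []
    for q, idx in enumerate(quads):
        sub = DatasetTable(drugs=table.drugs, proteins=table.proteins,
                           pairs=[table.pairs[i] for i in idx],
                           affinity_kind=table.affinity_kind)
        plans.append((idx, make_splits(sub, seed + q + 1)))
    return plans


def subset(table, indices):
    """A new table restricted to the given pair indices."""
    return DatasetTable(drugs=table.drugs, proteins=table.proteins,
                        pairs=[table.pairs[i] for i in indices],
                        affinity_kind=table.affinity_kind)


# ---------------------------------------------------------------------------
# loading


def load_drugs(path):
    """SMILES input: either one SMILES per line or CSV with drug_id,smiles."""
    path = Path(path)
    text = path.read_text().strip().splitlines()
    drugs = {}
    if "," in text[0]:
        rows = list(csv.reader(text))
        if rows[0][0].lower() in ("drug_id", "id"):
            rows = rows[1:]
        for row in rows:
            drugs[row[0]] = row[1]
    else:
        for i, smi in enumerate(text):
            drugs[f"drug_{i}"] = smi.strip()
    return drugs


def load_dataset(manifest_path, drug_path, protein_dir, affinity_kind="pkd"):
    """Assemble a :class:`DatasetTable` from on-disk inputs.

    The manifest is a TSV with columns drug_id, protein_id, affinity (header
    optional). ``kd_nM`` affinities are converted to pKd; rows with missing
    or NaN affinity are skipped with a logged count.
    """
    drugs = load_drugs(drug_path)
    pairs = []
    skipped = 0
    lines = Path(manifest_path).read_text().strip().splitlines()
    if lines and lines[0].lower().startswith("drug_id"):
        lines = lines[1:]
    protein_ids = set()
    for ln_no, ln in enumerate(lines, start=1):
        fields = ln.rstrip("\n").split("\t")
        if len(fields) != 3:
            raise DatasetError(f"manifest line {ln_no}: expected 3 columns, got {len(fields)}")
        d, p, a_raw = fields
        if d not in drugs:
            raise DatasetError(f"manifest line {ln_no}: unknown drug id {d!r}")
        try:
            a = float(a_raw)
        except ValueError:
            raise DatasetError(f"manifest line {ln_no}: malformed affinity {a_raw!r}")
        if math.isnan(a):
            skipped += 1
            continue
        if affinity_kind == "kd_nM":
            a = kd_to_pkd(a)
        pairs.append((d, p, a))
        protein_ids.add(p)
    if skipped:
        log.info("skipped %d pairs with missing affinity", skipped)
    proteins = {pid: load_protein_record(pid, protein_dir) for pid in sorted(protein_ids)}
    kind = "pkd" if affinity_kind == "kd_nM" else affinity_kind
    return DatasetTable(drugs=drugs, proteins=proteins, pairs=pairs, affinity_kind=kind)


def save_predictions(path, rows):
    """Write a predictions TSV: drug_id, protein_id, y_true, y_pred."""
    with open(path, "w") as fh:
        fh.write("drug_id\tprotein_id\ty_true\ty_pred\n")
        for d, p, yt, yp in rows:
            fh.write(f"{d}\t{p}\t{yt:.10g}\t{yp:.10g}\n")


def load_predictions(path):
    """Read a predictions TSV back into (rows, y_true, y_pred)."""
    lines = Path(path).read_text().strip().splitlines()[1:]
    rows = []
    for ln in lines:
        d, p, yt, yp = ln.split("\t")
        rows.append((d, p, float(yt), float(yp)))
    y = np.array([r[2] for r in rows])
    yhat = np.array([r[3] for r in rows])
    return rows, y, yhat
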