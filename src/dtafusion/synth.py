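"""Synthetic drugs, proteins and affinity labels with known structure.

Every stage of the pipeline is testable offline: drugs are drawn from a
curated list of drug-like SMILES templates with seeded halogen/methyl
decoration (all outputs are re-parsed for validity); proteins get a random
sequence, a state-persistent SS8 string, Beta-distributed relative
accessibility, and a distance map from a self-avoiding 3.8 Å-step random
walk standing in for the Cβ trace of a compact chain. Labels come from a
printed descriptor formula over *both* sides — including a drug-protein
interaction term, so neither branch alone can explain the signal — plus
Gaussian noise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from . import constants as C
from .data import DatasetTable
from .protein import ProteinRecord

# affinity formula weights: heavy-atom term, aromatic-ring term, mean-ASA
# term, helix-fraction term, ring x helix interaction
AFFINITY_WEIGHTS = (2.0, 1.5, 2.0, 3.0, 4.0)

SMILES_TEMPLATES = [
    "CC(=O)Oc1ccccc1C(=O)O",            # aspirin
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",       # ibuprofen
    "CC(=O)Nc1ccc(O)cc1",               # paracetamol
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",       # caffeine
    "c1ccc2c(c1)ccc1ccccc12",           # phenanthrene
    "c1ccc(-c2ccccc2)cc1",              # biphenyl
    "OCC1OC(O)C(O)C(O)C1O",             # glucose
    "NCCc1ccc(O)c(O)c1",                # dopamine
    "NC(Cc1ccccc1)C(=O)O",              # phenylalanine
    "OC(=O)c1ccccc1O",                  # salicylic acid
    "Nc1ccc(cc1)S(N)(=O)=O",            # sulfanilamide
    "Clc1ccccc1Cl",
    "Oc1ccc(Cl)cc1",
    "COc1ccc(CCN)cc1",
    "CCN(CC)CC(=O)Nc1c(C)cccc1C",       # lidocaine
    "CN1CCC[C@H]1c1cccnc1",             # nicotine
    "OC(=O)CCc1ccccc1",
    "NC(=O)c1ccccc1",                   # benzamide
    "CC(=O)c1ccccc1",                   # acetophenone
    "c1ccc(Oc2ccccc2)cc1",              # diphenyl ether
    "CC(C)NCC(O)COc1ccccc1",
    "O=C(O)c1ccncc1",                   # isonicotinic acid
    "Cc1ccc(S(=O)(=O)N)cc1",
    "CCOC(=O)c1ccccc1N",
    "O=C1CCCCC1",                       # cyclohexanone
    "C1CCNCC1",                         # piperidine
    "c1ccc2[nH]ccc2c1",                 # indole
    "c1ccc2ncccc2c1",                   # quinoline
    "c1ccc2c(c1)oc1ccccc12",            # dibenzofuran
    "O=c1cc[nH]c(=O)[nH]1",             # uracil
    "Nc1ncnc2[nH]cnc12",                # adenine
    "CC12CCC3c4ccc(O)cc4CCC3C1CCC2O",   # estradiol-like core
    "CN(C)CCc1c[nH]c2ccccc12",          # dimethyltryptamine
    "OCCN1CCN(CCCN2c3ccccc3Sc3ccccc32)CC1",
    "CC(N)Cc1ccccc1",                   # amphetamine
    "COc1cc2c(cc1OC)CCN(C)C2",
    "O=C(Nc1ccccc1)c1ccccc1",           # benzanilide
    "CSCCC(N)C(=O)O",                   # methionine
    "NC(CS)C(=O)O",                     # cysteine
    "OC(=O)C1CCCN1",                    # proline
    "Nc1ccccc1C(=O)O",                  # anthranilic acid
    "Oc1ccc2ccccc2c1",                  # 2-naphthol
    "CC(=O)NCCc1c[nH]c2ccc(OC)cc12",    # melatonin
    "CN1C2CCC1CC(OC(=O)C(CO)c1ccccc1)C2",  # atropine-like
    "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",    # salbutamol
    "O=C(O)Cc1ccccc1",                  # phenylacetic acid
    "ClCCN(CCCl)c1ccccc1",
    "O=S(=O)(c1ccccc1)c1ccccc1",        # diphenyl sulfone
    "CC1=CC(=O)CC(C)(C)C1",             # isophorone
    "COC(=O)c1ccc(O)cc1",               # methylparaben
]

DECORATIONS = ["F", "Cl", "Br", "C"]


@dataclass
class FixtureSpec:
    n_drugs: int = 20
    n_proteins: int = 20
    protein_length: tuple = (24, 48)
    embedding_width: int = 16
    noise_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_drugs < 1 or self.n_proteins < 1:
            raise ValueError("counts must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


def _decorate(smiles, rng):
    """Substitute one aromatic C-H with a halogen or methyl; reject and
    resample on sanitisation failure."""
    mol = Chem.MolFromSmiles(smiles)
    sites = [a.GetIdx() for a in mol.GetAtoms()
             if a.GetIsAromatic() and a.GetSymbol() == "C" and a.GetTotalNumHs() > 0]
    if not sites:
        return smiles
    for _ in range(8):
        rw = Chem.RWMol(mol)
        site = int(rng.choice(sites))
        new_idx = rw.AddAtom(Chem.Atom(str(rng.choice(DECORATIONS))))
        rw.AddBond(site, new_idx, Chem.BondType.SINGLE)
        try:
            out = rw.GetMol()
            Chem.SanitizeMol(out)
            smi = Chem.MolToSmiles(out)
            if Chem.MolFromSmiles(smi) is not None:
                return smi
        except Exception:
            continue
    return smiles


def gen_drug_set(spec):
    """Seeded list of valid drug-like SMILES (templates + decoration)."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for k in range(spec.n_drugs):
        template = SMILES_TEMPLATES[int(rng.integers(len(SMILES_TEMPLATES)))]
        smi = _decorate(template, rng) if rng.random() < 0.5 else template
        out.append(smi)
    return out


def _markov_ss8(m, rng, persistence=0.8):
    letters = C.SS8_ALPHABET
    states = [int(rng.integers(8))]
    for _ in range(m - 1):
        if rng.random() < persistence:
            states.append(states[-1])
        else:
            states.append(int(rng.integers(8)))
    return "".join(letters[s] for s in states)


def _self_avoiding_walk(m, rng, step=3.8, clash=3.4, tries=40):
    """Cβ-proxy coordinates: fixed-step 3D walk with excluded volume."""
    coords = np.zeros((m, 3))
    for i in range(1, m):
        best, best_min = None, -np.inf
        for _ in range(tries):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            cand = coords[i - 1] + step * direction
            if i >= 2:
                d = np.linalg.norm(coords[: i - 1] - cand, axis=1)
                dmin = d.min()
            else:
                dmin = np.inf
            if dmin > clash:
                best = cand
                break
            if dmin > best_min:
                best, best_min = cand, dmin
        coords[i] = best
    return coords


class SyntheticEmbeddingProvider:
    """Gaussian per-residue embeddings, deterministically seeded by the
    sequence content, standing in for a protein language model."""

    def __init__(self, width=16):
        self.width = width

    def embed(self, sequence):
        seed = zlib.crc32(sequence.encode()) & 0x7FFFFFFF
        rng = np.random.default_rng(seed)
        return rng.normal(0.0, 1.0, (len(sequence), self.width))


def gen_protein_record(spec, protein_id="prot_0", rng=None):
    """One synthetic protein record with internally consistent fields."""
    rng = rng or np.random.default_rng(spec.seed)
    lo, hi = spec.protein_length
    m = int(rng.integers(lo, hi + 1))
    seq = "".join(C.AMINO_ACIDS[int(rng.integers(20))] for _ in range(m))
    ss8 = _markov_ss8(m, rng)
    asa = rng.beta(2.0, 2.0, m)
    coords = _self_avoiding_walk(m, rng)
    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    return ProteinRecord(protein_id=protein_id, sequence=seq, ss8=ss8,
                         asa=asa, distmap=dist, kind="distance")


def drug_descriptors(smiles):
    """(scaled heavy-atom count, scaled aromatic-ring count) for the label
    formula."""
    mol = Chem.MolFromSmiles(smiles)
    heavy = mol.GetNumHeavyAtoms() / 64.0
    rings = rdMolDescriptors.CalcNumAromaticRings(mol) / 6.0
    return heavy, rings


def protein_descriptors(rec):
    """(mean relative ASA, helix fraction) for the label formula."""
    return float(np.mean(rec.asa)), rec.ss8.count("H") / rec.length


def affinity_formula(smiles, rec):
    """Noiseless descriptor affinity; the generator adds Gaussian noise."""
    w1, w2, w3, w4, w5 = AFFINITY_WEIGHTS
    heavy, rings = drug_descriptors(smiles)
    asa_mean, helix = protein_descriptors(rec)
    return (w1 * heavy + w2 * rings + w3 * asa_mean + w4 * helix
            + w5 * rings * helix)


def gen_dataset(spec):
    """Full cross of drugs x proteins with formula + noise labels."""
    rng = np.random.default_rng(spec.seed)
    smiles = gen_drug_set(spec)
    drugs = {f"drug_{k}": s for k, s in enumerate(smiles)}
    proteins = {}
    for k in range(spec.n_proteins):
        proteins[f"prot_{k}"] = gen_protein_record(spec, f"prot_{k}", rng)
    pairs = []
    for d_id, smi in drugs.items():
        for p_id, rec in proteins.items():
            a = affinity_formula(smi, rec)
            if spec.noise_sigma > 0:
                a += rng.normal(0.0, spec.noise_sigma)
            pairs.append((d_id, p_id, float(a)))
    return DatasetTable(drugs=drugs, proteins=proteins, pairs=pairs,
                        affinity_kind="pkd")


def write_dataset(table, out_dir):
    """Write a dataset in the pipeline's on-disk input formats."""
    from pathlib import Path
    from .protein import save_protein_record

    out = Path(out_dir)
    (out / "proteins").mkdir(parents=True, exist_ok=True)
    with open(out / "drugs.csv", "w") as fh:
        fh.write("drug_id,smiles\n")
        for d_id, smi in table.drugs.items():
            fh.write(f"{d_id},{smi}\n")
    for rec in table.proteins.values():
        save_protein_record(rec, out / "proteins")
    with open(out / "manifest.tsv", "w") as fh:
        fh.write("drug_id\tprotein_id\taffinity\n")
        for d, p, a in table.pairs:
            fh.write(f"{d}\t{p}\t{a:.10g}\n")
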