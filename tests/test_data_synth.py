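"""Dataset tables, splits, on-disk round trips and the synthetic generator."""

import numpy as np
import pytest
from rdkit import Chem

from dtafusion import synth
from dtafusion.data import (DatasetError, load_dataset,
                            make_quadrant_splits, make_splits, subset)
from dtafusion.metrics import kd_to_pkd
from dtafusion.protein import build_contact_edges
from dtafusion.synth import FixtureSpec, affinity_formula, gen_dataset, \
    gen_drug_set, gen_protein_record, write_dataset


@pytest.fixture(scope="module")
def table():
    return gen_dataset(FixtureSpec(n_drugs=10, n_proteins=6, seed=9))


class TestSplits:
    def test_sixty_pairs_make_six_parts_of_ten(self, table):
        plan = make_splits(table, seed=1)
        sizes = np.bincount(plan.part_assignment, minlength=6)
        assert list(sizes) == [10] * 6
        assert len(plan.test_indices()) == 10

    def test_same_seed_identical_plans(self, table):
        p1 = make_splits(table, seed=4)
        p2 = make_splits(table, seed=4)
        np.testing.assert_array_equal(p1.part_assignment, p2.part_assignment)

    def test_folds_and_test_partition_all_pairs(self, table):
        plan = make_splits(table, seed=2)
        seen = set(plan.test_indices())
        assert len(seen) == 10
        for k in range(5):
            train, val = plan.fold_indices(k)
            assert set(train) & set(val) == set()
            assert set(val) & set(plan.test_indices()) == set()
        all_vals = set()
        for k in range(5):
            _, val = plan.fold_indices(k)
            all_vals |= set(val)
        assert all_vals | set(plan.test_indices()) == set(range(table.n_pairs))

    def test_too_few_pairs_rejected(self, table):
        small = subset(table, list(range(8)))
        with pytest.raises(DatasetError):
            make_splits(small, seed=0)

    def test_quadrant_mode_partitions_pairs(self, table):
        plans = make_quadrant_splits(table, seed=3)
        assert len(plans) == 4
        all_idx = np.concatenate([idx for idx, _ in plans])
        assert sorted(all_idx) == list(range(table.n_pairs))


class TestLoadDataset:
    def _write(self, tmp_path, table, manifest_rows=None):
        write_dataset(table, tmp_path)
        if manifest_rows is not None:
            with open(tmp_path / "manifest.tsv", "w") as fh:
                fh.write("drug_id\tprotein_id\taffinity\n")
                for row in manifest_rows:
                    fh.write("\t".join(row) + "\n")

    def test_round_trip_preserves_pairs(self, tmp_path, table):
        self._write(tmp_path, table)
        back = load_dataset(tmp_path / "manifest.tsv", tmp_path / "drugs.csv",
                            tmp_path / "proteins")
        assert back.n_pairs == table.n_pairs
        np.testing.assert_allclose(back.affinities(), table.affinities(),
                                   atol=1e-9)

    def test_nan_affinity_skipped(self, tmp_path, table):
        rows = [("drug_0", "prot_0", "1.5"), ("drug_1", "prot_1", "nan"),
                ("drug_2", "prot_2", "2.0"), ("drug_3", "prot_3", "0.7")]
        self._write(tmp_path, table, rows)
        back = load_dataset(tmp_path / "manifest.tsv", tmp_path / "drugs.csv",
                            tmp_path / "proteins")
        assert back.n_pairs == 3

    def test_kd_nm_transformed_to_pkd(self, tmp_path, table):
        rows = [("drug_0", "prot_0", "1e9"), ("drug_1", "prot_1", "1.0")]
        self._write(tmp_path, table, rows)
        back = load_dataset(tmp_path / "manifest.tsv", tmp_path / "drugs.csv",
                            tmp_path / "proteins", affinity_kind="kd_nM")
        assert back.pairs[0][2] == 0.0
        assert back.pairs[1][2] == kd_to_pkd(1.0)

    def test_unknown_drug_id_rejected_with_line(self, tmp_path, table):
        rows = [("drug_0", "prot_0", "1.0"), ("no_such_drug", "prot_0", "1.0")]
        self._write(tmp_path, table, rows)
        with pytest.raises(DatasetError, match="line 2"):
            load_dataset(tmp_path / "manifest.tsv", tmp_path / "drugs.csv",
                         tmp_path / "proteins")

    def test_malformed_affinity_rejected_with_line(self, tmp_path, table):
        rows = [("drug_0", "prot_0", "abc")]
        self._write(tmp_path, table, rows)
        with pytest.raises(DatasetError, match="line 1"):
            load_dataset(tmp_path / "manifest.tsv", tmp_path / "drugs.csv",
                         tmp_path / "proteins")


class TestDrugGeneration:
    def test_requested_count_all_parseable(self):
        smiles = gen_drug_set(FixtureSpec(n_drugs=10, n_proteins=1, seed=1))
        assert len(smiles) == 10
        assert all(Chem.MolFromSmiles(s) is not None for s in smiles)

    def test_seeded_determinism(self):
        a = gen_drug_set(FixtureSpec(n_drugs=15, n_proteins=1, seed=8))
        b = gen_drug_set(FixtureSpec(n_drugs=15, n_proteins=1, seed=8))
        assert a == b

    def test_size_bound(self, fixture_smiles):
        for s in fixture_smiles:
            assert Chem.MolFromSmiles(s).GetNumHeavyAtoms() <= 64


class TestProteinGeneration:
    def test_field_lengths_consistent(self):
        rec = gen_protein_record(FixtureSpec(protein_length=(30, 30), seed=2))
        assert rec.length == 30
        assert len(rec.ss8) == 30
        assert rec.asa.shape == (30,)
        assert rec.distmap.shape == (30, 30)

    def test_contact_density_in_frozen_band(self):
        densities = []
        for seed in range(40):
            rec = gen_protein_record(FixtureSpec(seed=seed))
            m = rec.length
            contacts = sum(1 for _, _, k in build_contact_edges(rec)
                           if k == "contact")
            densities.append(contacts / (m * (m - 1) / 2 - (m - 1)))
        assert all(0.01 < d < 0.4 for d in densities)

    def test_seeded_determinism(self):
        a = gen_protein_record(FixtureSpec(seed=6))
        b = gen_protein_record(FixtureSpec(seed=6))
        assert a.sequence == b.sequence
        np.testing.assert_array_equal(a.distmap, b.distmap)


class TestAffinityLabels:
    def test_noiseless_labels_match_formula_exactly(self):
        t = gen_dataset(FixtureSpec(n_drugs=5, n_proteins=4, noise_sigma=0.0,
                                    seed=3))
        for d, p, a in t.pairs:
            assert a == affinity_formula(t.drugs[d], t.proteins[p])

    def test_noise_inflates_label_variance_as_expected(self):
        """Label = formula + N(0, sigma^2): the residual variance over 400
        pairs estimates sigma^2 = 0.01 within chi-square sampling error."""
        noisy = gen_dataset(FixtureSpec(n_drugs=20, n_proteins=20,
                                        noise_sigma=0.1, seed=13))
        resid = np.array([a - affinity_formula(noisy.drugs[d], noisy.proteins[p])
                          for d, p, a in noisy.pairs])
        assert np.var(resid) == pytest.approx(0.01, rel=0.25)
        assert abs(np.mean(resid)) < 0.02

    def test_same_spec_same_table(self):
        spec = FixtureSpec(n_drugs=4, n_proteins=4, seed=21)
        t1, t2 = gen_dataset(spec), gen_dataset(spec)
        assert t1.pairs == t2.pairs

    def test_generated_artifacts_pass_validation(self, tmp_path):
        t = gen_dataset(FixtureSpec(n_drugs=4, n_proteins=4, seed=17))
        write_dataset(t, tmp_path)
        back = load_dataset(tmp_path / "manifest.tsv", tmp_path / "drugs.csv",
                            tmp_path / "proteins")
        assert back.n_pairs == 16
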