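"""Molecule tables, scaffold splitting, and initial/pool construction."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from molal import (
    MISSING,
    ConfigurationError,
    InputError,
    MoleculeTable,
    balanced_initial_pool,
    label_composition,
    make_initial_pool,
    murcko_scaffold,
    read_molecule_table,
    scaffold_split,
    single_task_view,
    write_molecule_table,
)
from molal.synthetic import generate_multitask_labels


class TestReadMoleculeTable:
    def test_blank_cell_becomes_missing(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("smiles,a\nCCO,1\nCCN,0\nCCC,\n")
        table = read_molecule_table(path, task_columns=["a"])
        assert table.labels[:, 0].tolist() == [1, 0, MISSING]

    def test_non_binary_label_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("smiles,a\nCCO,2\n")
        with pytest.raises(InputError, match="binary"):
            read_molecule_table(path, task_columns=["a"])

    def test_invalid_smiles_dropped_and_counted(self, molecule_csv, caplog):
        with caplog.at_level("WARNING", logger="molal.mol_data"):
            table = read_molecule_table(molecule_csv, task_columns=["toxic"])
        # independent oracle: parse every row with RDKit directly
        raw = [ln.split(",")[1] for ln in molecule_csv.read_text().splitlines()[1:]]
        n_valid = sum(Chem.MolFromSmiles(s) is not None for s in raw)
        assert table.n_molecules == n_valid == 20
        assert "dropped 1" in caplog.text

    def test_missing_column_is_configuration_error(self, molecule_csv):
        with pytest.raises(ConfigurationError):
            read_molecule_table(molecule_csv, smiles_column="nope")

    def test_round_trip_preserves_labels_and_missing(self, tmp_path):
        labels = np.array([[1, MISSING], [0, 1], [MISSING, 0]])
        table = MoleculeTable(
            ids=["a", "b", "c"], smiles=["CCO", "CCN", "c1ccccc1"],
            labels=labels, task_names=["t1", "t2"],
        )
        path = tmp_path / "round.csv"
        write_molecule_table(table, path)
        back = read_molecule_table(path, task_columns=["t1", "t2"], id_column="id")
        assert np.array_equal(back.labels, table.labels)
        assert np.array_equal(back.missing_mask, table.missing_mask)
        assert back.smiles == table.smiles


class TestScaffoldSplit:
    def test_single_scaffold_is_an_error(self):
        smiles = [f"c1ccccc1{'C' * k}" for k in range(1, 11)]
        table = MoleculeTable(
            ids=[str(k) for k in range(10)], smiles=smiles,
            labels=np.zeros((10, 1), dtype=int), task_names=["t"],
        )
        with pytest.raises(InputError, match="single scaffold"):
            scaffold_split(table)

    def test_identical_scaffolds_stay_together(self, molecules):
        splits = scaffold_split(molecules, test_fraction=0.2)
        scaffolds = [murcko_scaffold(s) for s in molecules.smiles]
        train_scaffolds = {scaffolds[i] for i in splits.train}
        test_scaffolds = {scaffolds[i] for i in splits.test}
        assert not train_scaffolds & test_scaffolds

    def test_greedy_rule_matches_independent_oracle(self, molecules):
        """Apply the published greedy rule by hand with RDKit scaffolds."""
        splits = scaffold_split(molecules, test_fraction=0.2)
        groups = {}
        for i, smi in enumerate(molecules.smiles):
            scaf = MurckoScaffold.MurckoScaffoldSmiles(
                mol=Chem.MolFromSmiles(smi), includeChirality=False
            )
            groups.setdefault(scaf, []).append(i)
        assert len(groups) >= 8
        expected_train, expected_test = [], []
        for _, members in sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0])):
            (expected_train if len(expected_train) < 0.8 * 20 else expected_test).extend(members)
        assert sorted(expected_train) == splits.train.tolist()
        assert sorted(expected_test) == splits.test.tolist()
        assert 0.1 <= len(splits.test) / 20 <= 0.3

    def test_acyclic_molecules_share_one_group(self):
        # two acyclic molecules plus one ring system: acyclics never split apart
        table = MoleculeTable(
            ids=["a", "b", "c", "d"],
            smiles=["CCO", "CCCC", "c1ccccc1O", "c1ccccc1N"],
            labels=np.zeros((4, 1), dtype=int), task_names=["t"],
        )
        splits = scaffold_split(table, test_fraction=0.5)
        sides = [0 in splits.train, 1 in splits.train]
        assert sides[0] == sides[1]


class TestInitialPool:
    def _table(self, n_pos, n_neg, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
        rng.shuffle(labels)
        n = n_pos + n_neg
        return MoleculeTable(
            ids=[f"m{i}" for i in range(n)], smiles=["CCO"] * n,
            labels=labels[:, None], task_names=["t"],
        )

    def test_balanced_counts_and_pool_size(self):
        table = self._table(300, 700)
        splits = make_initial_pool(table, np.arange(1000), "t", initial_size=100, seed=1)
        y = table.task_labels("t")
        assert splits.initial.size == 100
        assert (y[splits.initial] == 1).sum() == 50
        assert (y[splits.initial] == 0).sum() == 50
        assert splits.pool.size == 900
        assert np.array_equal(
            np.sort(np.concatenate([splits.initial, splits.pool])), np.arange(1000)
        )

    def test_insufficient_positives_names_shortfall(self):
        table = self._table(30, 970)
        with pytest.raises(InputError, match="30 positives"):
            make_initial_pool(table, np.arange(1000), "t", initial_size=100, seed=1)

    def test_same_seed_reproduces_exactly(self):
        table = self._table(300, 700)
        a = make_initial_pool(table, np.arange(1000), "t", initial_size=100, seed=7)
        b = make_initial_pool(table, np.arange(1000), "t", initial_size=100, seed=7)
        assert np.array_equal(a.initial, b.initial)
        assert np.array_equal(a.pool, b.pool)

    def test_missing_labels_excluded_from_pool(self):
        labels = np.array([1] * 10 + [0] * 10 + [MISSING] * 5)[:, None]
        table = MoleculeTable(
            ids=[f"m{i}" for i in range(25)], smiles=["CCO"] * 25,
            labels=labels, task_names=["t"],
        )
        initial, pool = balanced_initial_pool(
            table.task_labels("t"), np.arange(25), initial_size=10, seed=0
        )
        assert initial.size + pool.size == 20  # the 5 unlabeled never appear


class TestSingleTaskView:
    def test_drops_missing_rows(self):
        labels = np.array([[1, 0], [MISSING, 1], [0, MISSING], [MISSING, MISSING], [1, 1]])
        table = MoleculeTable(
            ids=list("abcde"), smiles=["CCO"] * 5, labels=labels, task_names=["A", "B"],
        )
        view = single_task_view(table, "A")
        assert view.n_molecules == 3
        assert view.task_names == ["A"]
        assert not view.missing_mask.any()

    def test_unknown_task_is_configuration_error(self, molecules):
        with pytest.raises(ConfigurationError):
            single_task_view(molecules, "nope")

    def test_view_sizes_match_missing_rate(self):
        labels = generate_multitask_labels(
            5000, n_tasks=4, active_rate=0.0624, missing_rate=0.2056, seed=3
        )
        table = MoleculeTable(
            ids=[f"m{i}" for i in range(5000)], smiles=["CCO"] * 5000,
            labels=labels, task_names=["a", "b", "c", "d"],
        )
        for task in table.task_names:
            # oracle: count non-missing cells directly
            expected = int((labels[:, table.task_index(task)] != MISSING).sum())
            assert single_task_view(table, task).n_molecules == expected
            se = np.sqrt(0.2056 * (1 - 0.2056) * 5000)
            assert abs(expected - 5000 * (1 - 0.2056)) < 3 * se


def test_label_composition_counts_cells():
    labels = np.array([[1, MISSING], [0, 0], [MISSING, 1]])
    table = MoleculeTable(
        ids=list("abc"), smiles=["CCO"] * 3, labels=labels, task_names=["x", "y"],
    )
    comp = label_composition(table)
    assert comp["n_compounds"] == 3
    assert comp["active_fraction"] == pytest.approx(2 / 6)
    assert comp["missing_fraction"] == pytest.approx(2 / 6)
    assert comp["inactive_fraction"] == pytest.approx(2 / 6)
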