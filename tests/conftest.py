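import numpy as np
import pytest

from molal import MoleculeTable, fixture_molecules


@pytest.fixture(scope="session")
def molecules() -> MoleculeTable:
    """The packaged 20-molecule fixture table."""
    return fixture_molecules()


@pytest.fixture()
def molecule_csv(tmp_path, molecules):
    """The fixture table written to CSV with one invalid SMILES appended."""
    path = tmp_path / "molecules.csv"
    lines = ["id,smiles,toxic"]
    for i in range(molecules.n_molecules):
        lines.append(f"{molecules.ids[i]},{molecules.smiles[i]},{molecules.labels[i, 0]}")
    lines.append("broken,C1CC,1")  # unclosed ring: unparseable
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def separable_2d():
    """200 linearly separable points in 2-D."""
    rng = np.random.default_rng(42)
    X = np.vstack([rng.normal(-2.0, 0.5, (100, 2)), rng.normal(2.0, 0.5, (100, 2))])
    y = np.concatenate([np.zeros(100, dtype=int), np.ones(100, dtype=int)])
    return X, y
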