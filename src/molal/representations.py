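"""Feature matrices and class-separability metrics.

Molecules are represented either by extended-connectivity fingerprints
(ECFP, hashed circular substructures) computed here with RDKit, or by a
precomputed per-molecule embedding matrix loaded from disk (e.g. the pooled
output of a pretrained transformer encoder — the encoder itself is outside
this package's scope). A third ``synthetic`` kind tags matrices produced by
the synthetic-data generator.

Separability of the two label classes in a feature space is summarized by
three complementary metrics: Fisher's ratio (global mean separation over
within-class scatter), the two-cluster Davies-Bouldin index (treating the
classes as clusters), and class purity (local label agreement among k
nearest neighbors).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.metrics import davies_bouldin_score
from sklearn.neighbors import NearestNeighbors

from .mol_data import InputError, MoleculeTable

FEATURE_KINDS = ("ecfp", "embedding", "synthetic")


@dataclass
class FeatureMatrix:
    """n x d numeric feature matrix with a provenance tag."""

    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise InputError("feature matrix must be 2-D")
        if self.kind not in FEATURE_KINDS:
            raise InputError(f"kind must be one of {FEATURE_KINDS}")
        if not np.isfinite(self.values).all():
            raise InputError("feature matrix contains non-finite entries")
        if self.kind == "ecfp" and not np.isin(self.values, (0.0, 1.0)).all():
            raise InputError("ecfp features must be binary")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass
class SeparabilityReport:
    """How well the two classes separate in a feature space."""

    fisher_ratio: float
    davies_bouldin: float
    class_purity: float
    k_neighbors: int


def featurize_ecfp(
    table: MoleculeTable, radius: int = 2, n_bits: int = 1024
) -> FeatureMatrix:
    """Hashed circular-substructure fingerprints, one bit vector per molecule.

    Deterministic for identical molecules regardless of how their SMILES is
    written (RDKit canonicalizes internally). Unparseable SMILES are
    collected and reported together.
    """
    if radius < 1:
        raise InputError("radius must be >= 1")
    if n_bits < 64:
        raise InputError("n_bits must be >= 64")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    rows = np.zeros((table.n_molecules, n_bits), dtype=np.float64)
    bad: list[str] = []
    for i, smi in enumerate(table.smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            bad.append(smi)
            continue
        fp = gen.GetFingerprint(mol)
        rows[i, list(fp.GetOnBits())] = 1.0
    if bad:
        raise InputError(f"unparseable SMILES: {bad}")
    return FeatureMatrix(values=rows, kind="ecfp")


def load_embeddings(path: str | Path, expected_rows: int) -> FeatureMatrix:
    """Load a precomputed embedding matrix (.npy or CSV of numbers).

    The embedding dimension is whatever the file provides; only the row
    count is checked against the molecule table.
    """
    path = Path(path)
    if path.suffix == ".npy":
        values = np.load(path)
    else:
        values = np.loadtxt(path, delimiter=",", ndmin=2)
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2:
        raise InputError(f"{path} is not a 2-D matrix")
    if values.shape[0] != expected_rows:
        raise InputError(
            f"embedding rows ({values.shape[0]}) do not match the molecule "
            f"table ({expected_rows})"
        )
    if not np.isfinite(values).all():
        raise InputError(f"{path} contains non-finite entries")
    return FeatureMatrix(values=values, kind="embedding")


def save_fingerprints(features: FeatureMatrix, path: str | Path) -> None:
    np.savetxt(path, features.values, fmt="%d" if features.kind == "ecfp" else "%.8g",
               delimiter=",")


def separability(
    features: FeatureMatrix, labels: np.ndarray, k_neighbors: int = 10
) -> SeparabilityReport:
    """Quantify two-class separation in the feature space.

    fisher_ratio = ||mu+ - mu-||^2 / (tr(Sigma+) + tr(Sigma-)) with per-class
    sample means and covariances; davies_bouldin treats the two classes as
    clusters under Euclidean distance; class_purity is the mean fraction of a
    point's k nearest neighbors (excluding itself) that share its label.
    """
    X = features.values
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if classes.size != 2:
        raise InputError("separability needs exactly two classes present")
    if k_neighbors >= X.shape[0]:
        raise InputError("k_neighbors must be smaller than n")

    pos, neg = X[y == classes[1]], X[y == classes[0]]
    mu_diff = pos.mean(axis=0) - neg.mean(axis=0)
    scatter = 0.0
    for grp in (pos, neg):
        if grp.shape[0] > 1:
            scatter += float(np.trace(np.atleast_2d(np.cov(grp, rowvar=False, ddof=1))))
    fisher = float(mu_diff @ mu_diff) / scatter if scatter > 0 else np.inf

    db = float(davies_bouldin_score(X, y))

    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    _, idx = nn.kneighbors(X)
    neighbor_labels = y[idx[:, 1:]]  # drop self
    purity = float((neighbor_labels == y[:, None]).mean())

    return SeparabilityReport(
        fisher_ratio=fisher,
        davies_bouldin=db,
        class_purity=purity,
        k_neighbors=k_neighbors,
    )
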