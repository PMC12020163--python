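"""Synthetic feature spaces and label matrices for controlled experiments.

The generator emulates the two qualitative regimes seen when embedding a
toxicity screen into different molecular representations:

* ``structured`` — the minority (positive) class concentrates in a few tight
  Gaussian clusters displaced well away from the bulk of negatives, the way
  a pretrained embedding groups chemically similar actives;
* ``scattered`` — positives are drawn from the same mixture components as
  the negatives with only a small mean shift, producing heavy class overlap,
  the way a hashed fingerprint space often looks.

Both regimes share every other property (size, dimension, imbalance), so
experiments that contrast them isolate representation quality as the single
varying factor.

A companion generator produces multitask binary label matrices with missing
values, mimicking the cell-level composition of large toxicology screens
(about 6.24% active measurements overall and 20.56% missing cells, with
per-task active rates jittered across tasks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mol_data import MISSING, InputError, MoleculeTable
from .representations import FeatureMatrix

#: Default positive prevalence, matching the minority fraction of the
#: feature-space analyses this generator stands in for.
DEFAULT_PREVALENCE = 0.068


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic two-class feature space.

    ``separation`` is the centroid displacement of positive clusters in
    units of the within-cluster standard deviation; 0 makes the classes
    identically distributed.
    """

    n: int = 2000
    d: int = 16
    regime: str = "structured"
    n_pos_clusters: int = 6
    separation: float = 5.0
    prevalence: float = DEFAULT_PREVALENCE
    n_tasks: int = 1
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in ("structured", "scattered"):
            raise InputError("regime must be 'structured' or 'scattered'")
        if not 0 < self.prevalence < 0.5:
            raise InputError("prevalence must be in (0, 0.5)")
        if self.separation < 0:
            raise InputError("separation must be nonnegative")
        if not 0 <= self.missing_rate < 1:
            raise InputError("missing_rate must be in [0, 1)")


def generate_feature_space(spec: SyntheticSpec) -> tuple[FeatureMatrix, np.ndarray]:
    """Sample features and binary labels under ``spec``.

    Negatives come from an isotropic Gaussian mixture with a handful of
    broad components. Positives: in the structured regime, ``n_pos_clusters``
    tight clusters whose centroids sit ``separation`` within-cluster standard
    deviations away from a negative component along random orthogonal
    directions; in the scattered regime, the negative components themselves
    shifted by only ``separation / 4``, which buries the positives inside the
    negative mass. Byte-identical output for identical spec (seed included).
    """
    n_pos = int(round(spec.prevalence * spec.n))
    if n_pos < spec.n_pos_clusters:
        raise InputError(
            f"prevalence*n = {n_pos} positives cannot fill "
            f"{spec.n_pos_clusters} clusters"
        )
    n_neg = spec.n - n_pos
    rng = np.random.default_rng(spec.seed)

    n_neg_comp = 3
    neg_sd = 1.0
    neg_centers = rng.normal(0.0, 1.0, size=(n_neg_comp, spec.d))
    neg_assign = rng.integers(0, n_neg_comp, size=n_neg)
    X_neg = neg_centers[neg_assign] + rng.normal(0.0, neg_sd, size=(n_neg, spec.d))

    pos_sd = 0.5  # positive clusters half as wide as the negative components
    # random orthonormal displacement directions, one per positive cluster
    raw = rng.normal(size=(spec.d, spec.n_pos_clusters))
    q, _ = np.linalg.qr(raw)
    directions = q.T[: spec.n_pos_clusters]

    anchor = neg_centers[rng.integers(0, n_neg_comp, size=spec.n_pos_clusters)]
    if spec.regime == "structured":
        centers = anchor + spec.separation * pos_sd * directions
        sd = pos_sd
    else:
        centers = anchor + (spec.separation / 4.0) * neg_sd * directions
        sd = neg_sd
    pos_assign = rng.integers(0, spec.n_pos_clusters, size=n_pos)
    X_pos = centers[pos_assign] + rng.normal(0.0, sd, size=(n_pos, spec.d))

    X = np.vstack([X_neg, X_pos])
    y = np.concatenate([np.zeros(n_neg, dtype=np.int64), np.ones(n_pos, dtype=np.int64)])
    order = rng.permutation(spec.n)
    return FeatureMatrix(values=X[order], kind="synthetic"), y[order]


def generate_multitask_labels(
    n: int,
    n_tasks: int = 12,
    active_rate: float = 0.0624,
    missing_rate: float = 0.2056,
    seed: int = 0,
    task_rate_jitter: float = 0.5,
) -> np.ndarray:
    """Multitask binary label matrix with independent missing cells.

    Each cell is missing with probability ``missing_rate``; conditional on
    being observed, it is active with probability ``active_rate /
    (1 - missing_rate)`` so that active cells make up ``active_rate`` of ALL
    cells (the convention large toxicology screens report). Per-task active
    rates are jittered multiplicatively by up to ``task_rate_jitter`` around
    the mean, renormalized so the overall rate is preserved.
    """
    if not 0 <= active_rate < 1 or not 0 <= missing_rate < 1:
        raise InputError("rates must be in [0, 1)")
    cond_active = active_rate / (1.0 - missing_rate) if missing_rate < 1 else 0.0
    if cond_active >= 1:
        raise InputError("active_rate incompatible with missing_rate")
    rng = np.random.default_rng(seed)
    factors = 1.0 + task_rate_jitter * rng.uniform(-1, 1, size=n_tasks)
    factors *= n_tasks / factors.sum()
    task_rates = np.clip(cond_active * factors, 0.0, 1.0)

    labels = (rng.uniform(size=(n, n_tasks)) < task_rates).astype(np.int64)
    missing = rng.uniform(size=(n, n_tasks)) < missing_rate
    labels[missing] = MISSING
    return labels


#: Hand-curated drug-like molecules spanning common ring systems; used as a
#: stable fixture for scaffold splitting and fingerprint tests. One invalid
#: entry can be appended by tests to exercise the drop-and-log path.
_FIXTURE_SMILES = [
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1"),
    ("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O"),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ("theobromine", "Cn1cnc2c1c(=O)[nH]c(=O)n2C"),
    ("nicotine", "CN1CCC[C@H]1c1cccnc1"),
    ("benzamide", "NC(=O)c1ccccc1"),
    ("toluamide", "Cc1ccccc1C(N)=O"),
    ("naphthalene_ol", "Oc1ccc2ccccc2c1"),
    ("quinoline_amine", "Nc1ccc2ncccc2c1"),
    ("indole_acetic", "OC(=O)Cc1c[nH]c2ccccc12"),
    ("serotonin", "NCCc1c[nH]c2ccc(O)cc12"),
    ("piperidine_ester", "CCOC(=O)C1CCNCC1"),
    ("morpholine_amide", "O=C(N1CCOCC1)c1ccccc1"),
    ("pyrimidine_diol", "Oc1ccnc(O)n1"),
    ("cyclohexanol", "OC1CCCCC1"),
    ("glycerol", "OCC(O)CO"),
    ("octanoic_acid", "CCCCCCCC(=O)O"),
    ("imidazole_methyl", "Cc1cnc[nH]1"),
    ("furan_carboxylic", "OC(=O)c1ccco1"),
]


def fixture_molecules(seed: int = 7) -> MoleculeTable:
    """A packaged 20-molecule table with synthetic binary labels.

    Spans well over six distinct Bemis-Murcko scaffolds (benzene, xanthine,
    pyridine, naphthalene, quinoline, indole, piperidine, morpholine,
    pyrimidine, cyclohexane, imidazole, furan, plus acyclics) and is stable
    across releases; labels are reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, size=(len(_FIXTURE_SMILES), 1))
    return MoleculeTable(
        ids=[name for name, _ in _FIXTURE_SMILES],
        smiles=[smi for _, smi in _FIXTURE_SMILES],
        labels=labels,
        task_names=["toxic"],
    )
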