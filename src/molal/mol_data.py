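"""Molecule tables, scaffold-based splitting, and initial/pool construction.

A :class:`MoleculeTable` holds SMILES strings and a compound x task binary
label matrix with an explicit missing mask. Train/test splits are made at the
level of Bemis-Murcko scaffolds so no core ring system appears on both sides
of the split, which tests generalization to unseen chemotypes. Active-learning
runs start from a small class-balanced initial set drawn from the training
molecules; the remainder with a known label for the task of interest forms
the acquisition pool.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.Scaffolds import MurckoScaffold

from ._seeds import derive_seed

logger = logging.getLogger(__name__)

MISSING = -1  # sentinel in integer label matrices


class ConfigurationError(ValueError):
    """A named column, task or option does not exist."""


class InputError(ValueError):
    """The data itself violates a precondition."""


@dataclass
class MoleculeTable:
    """SMILES strings plus a compound x task binary label matrix.

    ``labels`` is an ``(n, n_tasks)`` integer array with entries in
    ``{0, 1, MISSING}``; ``missing_mask`` is the boolean view
    ``labels == MISSING``.
    """

    ids: list[str]
    smiles: list[str]
    labels: np.ndarray
    task_names: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim == 1:
            self.labels = self.labels[:, None]
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise InputError("molecule ids must be unique")
        if len(self.smiles) != n or self.labels.shape[0] != n:
            raise InputError(
                f"inconsistent table: {n} ids, {len(self.smiles)} smiles, "
                f"{self.labels.shape[0]} label rows"
            )
        if self.labels.shape[1] != len(self.task_names):
            raise InputError("label columns do not match task_names")
        valid = np.isin(self.labels, (0, 1, MISSING))
        if not valid.all():
            bad = np.unique(self.labels[~valid])
            raise InputError(f"labels must be 0, 1 or missing; found {bad.tolist()}")

    @property
    def n_molecules(self) -> int:
        return len(self.ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.labels == MISSING

    def task_index(self, task: str) -> int:
        try:
            return self.task_names.index(task)
        except ValueError:
            raise ConfigurationError(
                f"unknown task {task!r}; available: {self.task_names}"
            ) from None

    def task_labels(self, task: str) -> np.ndarray:
        """Full-length label vector for one task (missing as MISSING)."""
        return self.labels[:, self.task_index(task)]


@dataclass
class SplitIndices:
    """Index sets for one active-learning run.

    ``initial`` and ``pool`` partition the labeled-for-task part of ``train``;
    ``test`` is disjoint from ``train`` and shares no scaffold with it.
    """

    train: np.ndarray
    test: np.ndarray
    initial: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    pool: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))

    def __post_init__(self) -> None:
        self.train = np.asarray(self.train, dtype=np.int64)
        self.test = np.asarray(self.test, dtype=np.int64)
        self.initial = np.asarray(self.initial, dtype=np.int64)
        self.pool = np.asarray(self.pool, dtype=np.int64)
        if np.intersect1d(self.train, self.test).size:
            raise InputError("train and test overlap")
        if np.intersect1d(self.initial, self.pool).size:
            raise InputError("initial and pool overlap")

    def to_json(self, path: str | Path, **params: object) -> None:
        payload = {
            "train": self.train.tolist(),
            "test": self.test.tolist(),
            "initial": self.initial.tolist(),
            "pool": self.pool.tolist(),
            "params": params,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitIndices":
        payload = json.loads(Path(path).read_text())
        return cls(
            train=payload["train"],
            test=payload["test"],
            initial=payload["initial"],
            pool=payload["pool"],
        )


def _parse_label_cell(value: object) -> int:
    """Map a CSV cell to {0, 1, MISSING}; anything else is an error."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return MISSING
    text = str(value).strip()
    if text in ("", "NA", "NaN", "nan"):
        return MISSING
    num = float(text)
    if num not in (0.0, 1.0):
        raise InputError(f"label cell {value!r} is not binary or missing")
    return int(num)


def read_molecule_table(
    path: str | Path,
    smiles_column: str = "smiles",
    task_columns: list[str] | None = None,
    id_column: str | None = "id",
) -> MoleculeTable:
    """Read a molecule CSV, validating SMILES and binarity of labels.

    Rows whose SMILES fail to parse are dropped; the count is logged. Missing
    label cells (blank or "NA") map to the missing marker. A column named by
    ``id_column`` supplies identifiers when present; otherwise row-based ids
    are synthesized. Unnamed remaining columns are treated as tasks.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    if smiles_column not in df.columns:
        raise ConfigurationError(f"SMILES column {smiles_column!r} not in {path}")
    if task_columns is None:
        reserved = {smiles_column, id_column}
        task_columns = [c for c in df.columns if c not in reserved]
    for col in task_columns:
        if col not in df.columns:
            raise ConfigurationError(f"label column {col!r} not in {path}")

    RDLogger.DisableLog("rdApp.error")
    try:
        keep_rows: list[int] = []
        smiles: list[str] = []
        n_dropped = 0
        for i, smi in enumerate(df[smiles_column]):
            mol = Chem.MolFromSmiles(smi) if isinstance(smi, str) else None
            if mol is None:
                n_dropped += 1
            else:
                keep_rows.append(i)
                smiles.append(smi)
    finally:
        RDLogger.EnableLog("rdApp.error")
    if n_dropped:
        logger.warning("dropped %d rows with unparseable SMILES", n_dropped)
    if not keep_rows:
        raise InputError(f"no valid SMILES rows in {path}")

    sub = df.iloc[keep_rows]
    labels = np.array(
        [[_parse_label_cell(v) for v in sub[col]] for col in task_columns],
        dtype=np.int64,
    ).T
    if id_column is not None and id_column in df.columns:
        ids = [str(v) for v in sub[id_column]]
    else:
        ids = [f"mol{i}" for i in keep_rows]
    return MoleculeTable(ids=ids, smiles=smiles, labels=labels, task_names=list(task_columns))


def write_molecule_table(table: MoleculeTable, path: str | Path) -> None:
    """Write a table back to CSV; missing labels become empty cells."""
    data: dict[str, object] = {"id": table.ids, "smiles": table.smiles}
    for j, name in enumerate(table.task_names):
        col = table.labels[:, j].astype(object)
        col[table.labels[:, j] == MISSING] = ""
        data[name] = col
    pd.DataFrame(data).to_csv(path, index=False)


def murcko_scaffold(smiles: str) -> str:
    """Canonical Bemis-Murcko scaffold SMILES ("" for acyclic molecules)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparseable SMILES {smiles!r}")
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol, includeChirality=False)


def scaffold_split(
    table: MoleculeTable, test_fraction: float = 0.2, seed: int = 0
) -> SplitIndices:
    """Greedy scaffold split: larger scaffold groups are assigned to train
    first until train holds at least ``1 - test_fraction`` of the molecules;
    the remaining groups form the test set. Ties between equal-sized groups
    break by lexicographic scaffold string, so the split is deterministic.

    Acyclic molecules (empty scaffold string) form one shared group.
    """
    if not 0 < test_fraction < 1:
        raise ConfigurationError("test_fraction must be in (0, 1)")
    groups: dict[str, list[int]] = {}
    for i, smi in enumerate(table.smiles):
        groups.setdefault(murcko_scaffold(smi), []).append(i)
    if len(groups) < 2:
        raise InputError(
            "all molecules share a single scaffold; scaffold split impossible"
        )
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    n = table.n_molecules
    train_target = (1.0 - test_fraction) * n
    train: list[int] = []
    test: list[int] = []
    for _, members in ordered:
        if len(train) < train_target:
            train.extend(members)
        else:
            test.extend(members)
    if not test:
        raise InputError("scaffold split produced an empty test set")
    return SplitIndices(train=np.sort(train), test=np.sort(test))


def balanced_initial_pool(
    y: np.ndarray,
    train: np.ndarray,
    initial_size: int = 100,
    seed: int = 0,
    label_tag: str = "",
) -> tuple[np.ndarray, np.ndarray]:
    """Label-vector-level core of :func:`make_initial_pool`.

    ``y`` is a full-length label vector with entries in {0, 1, MISSING}.
    Returns (initial, pool) as sorted global index arrays.
    """
    if initial_size % 2:
        raise ConfigurationError("initial_size must be even for a balanced set")
    train = np.asarray(train, dtype=np.int64)
    yt = np.asarray(y)[train]
    pos = train[yt == 1]
    neg = train[yt == 0]
    half = initial_size // 2
    if pos.size < half or neg.size < half:
        raise InputError(
            f"need {half} of each class{label_tag}: "
            f"have {pos.size} positives, {neg.size} negatives"
        )
    rng = np.random.default_rng(derive_seed(seed, "initial_pool", label_tag))
    initial = np.sort(
        np.concatenate(
            [rng.choice(pos, half, replace=False), rng.choice(neg, half, replace=False)]
        )
    )
    labeled = train[(yt == 0) | (yt == 1)]
    pool = np.setdiff1d(labeled, initial)
    return initial, pool


def make_initial_pool(
    table: MoleculeTable,
    train: np.ndarray,
    task: str,
    initial_size: int = 100,
    seed: int = 0,
    test: np.ndarray | None = None,
) -> SplitIndices:
    """Draw a class-balanced initial labeled set and the acquisition pool.

    The initial set holds exactly ``initial_size/2`` positives and negatives
    for ``task``, sampled uniformly under ``seed``. The pool is the rest of
    the train molecules that carry a non-missing label for the task (a pool
    point must be labelable by the simulated oracle).
    """
    initial, pool = balanced_initial_pool(
        table.task_labels(task),
        train,
        initial_size=initial_size,
        seed=seed,
        label_tag=f" for task {task!r}",
    )
    train = np.asarray(train, dtype=np.int64)
    if test is None:
        test = np.array([], dtype=np.int64)
    return SplitIndices(train=train, test=np.asarray(test, dtype=np.int64),
                        initial=initial, pool=pool)


def label_composition(table: MoleculeTable) -> dict[str, float]:
    """Cell-level composition of a multitask label matrix.

    Returns the fraction of all cells that are active (1), inactive (0) and
    missing, plus the compound count — the summary used to characterize
    large multitask toxicity screens.
    """
    total = table.labels.size
    return {
        "n_compounds": float(table.n_molecules),
        "active_fraction": float((table.labels == 1).sum() / total),
        "inactive_fraction": float((table.labels == 0).sum() / total),
        "missing_fraction": float((table.labels == MISSING).sum() / total),
    }


def single_task_view(table: MoleculeTable, task: str) -> MoleculeTable:
    """One-column view keeping only molecules labeled for ``task``."""
    j = table.task_index(task)
    keep = np.flatnonzero(table.labels[:, j] != MISSING)
    if keep.size == 0:
        raise InputError(f"task {task!r} has no labeled molecules")
    return MoleculeTable(
        ids=[table.ids[i] for i in keep],
        smiles=[table.smiles[i] for i in keep],
        labels=table.labels[keep][:, [j]],
        task_names=[task],
    )
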