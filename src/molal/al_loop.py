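"""The pool-based active-learning loop and multi-arm orchestration.

One run starts from a class-balanced labeled initial set and an unlabeled
pool. Each iteration retrains the MC-dropout network from scratch on the
current labeled set, scores the pool with the configured acquisition
function, moves the selected candidate(s) with their revealed labels into
the labeled set, and periodically evaluates ranking quality (average
precision) and calibration (ECE) on a fixed held-out test set. Labels are
"revealed" from the ground-truth table, simulating the oracle of a
retrospective screen.

Every stage derives its seed from the single ``run_seed`` through a stable
hash of (run_seed, stage, iteration), so a run is exactly reproducible and
arms that share a run_seed share their initial sets without sharing dropout
masks.

The uniform arm's scores do not depend on the model, so it skips retraining
except at evaluation points — the acquired sequence and all recorded metrics
are identical to the naive schedule.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from ._seeds import derive_seed
from .acquisition import (
    bald_scores,
    epig_scores,
    select_next,
    uniform_scores,
)
from .bnn import BnnConfig, mc_predict, train_bnn
from .evaluation import average_precision, expected_calibration_error
from .mol_data import MISSING, InputError, MoleculeTable, SplitIndices, balanced_initial_pool
from .representations import FeatureMatrix


@dataclass
class ALConfig:
    """Configuration of one active-learning run."""

    acquisition: str = "uniform"
    feature_kind: str = "synthetic"
    n_iterations: int = 100
    batch_size: int = 1
    initial_size: int = 100
    target_sample_size: int = 100
    bnn: BnnConfig = field(default_factory=BnnConfig)
    eval_every: int = 10
    ece_bins: int = 10
    run_seed: int = 0

    def __post_init__(self) -> None:
        if self.acquisition not in ("uniform", "bald", "epig"):
            raise InputError(f"unknown acquisition {self.acquisition!r}")
        if self.n_iterations < 1:
            raise InputError("n_iterations must be >= 1")
        if self.eval_every < 1:
            raise InputError("eval_every must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ALConfig":
        d = dict(d)
        if isinstance(d.get("bnn"), dict):
            d["bnn"] = BnnConfig(**d["bnn"])
        return cls(**d)


@dataclass
class IterationRecord:
    iteration: int
    acquired_indices: list[int]
    acquired_labels: list[int]
    labeled_size: int
    scores: list[float]
    metrics: dict | None = None


@dataclass
class ALHistory:
    """Full record of one run: per-iteration acquisitions and metrics."""

    config: ALConfig
    initial: list[int]
    records: list[IterationRecord] = field(default_factory=list)
    arm: str = ""
    task: str = ""
    seed: int = 0
    truncated_at: int | None = None
    pool_size: int = 0
    pool_positives: int = 0

    @property
    def acquired_indices(self) -> np.ndarray:
        return np.array(
            [i for r in self.records if r.iteration > 0 for i in r.acquired_indices],
            dtype=np.int64,
        )

    @property
    def acquired_labels(self) -> np.ndarray:
        return np.array(
            [l for r in self.records if r.iteration > 0 for l in r.acquired_labels],
            dtype=np.int64,
        )

    def metric_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(grid, avg_precision, ece, cum_positives) at evaluated iterations."""
        grid, ap, ece, cum = [], [], [], []
        running = 0
        by_iter: dict[int, int] = {}
        for r in self.records:
            running += sum(1 for l in r.acquired_labels if l == 1)
            by_iter[r.iteration] = running
        for r in self.records:
            if r.metrics is not None:
                grid.append(r.iteration)
                ap.append(r.metrics["avg_precision"])
                ece.append(r.metrics["ece"])
                cum.append(by_iter[r.iteration])
        return (np.array(grid), np.array(ap), np.array(ece), np.array(cum))

    def to_trace(self):
        from .evaluation import MetricTrace

        grid, ap, ece, cum = self.metric_arrays()
        return MetricTrace(
            iterations=grid, avg_precision=ap, ece=ece, cum_positives=cum,
            arm=self.arm or self.config.acquisition, task=self.task, seed=self.seed,
        )

    # ---- serialization ------------------------------------------------------

    def to_jsonl(self, path: str | Path) -> None:
        """One JSON line per iteration record, preceded by a manifest line."""
        with open(path, "w") as fh:
            manifest = {
                "type": "manifest",
                "config": self.config.to_dict(),
                "initial": self.initial,
                "arm": self.arm,
                "task": self.task,
                "seed": self.seed,
                "truncated_at": self.truncated_at,
                "pool_size": self.pool_size,
                "pool_positives": self.pool_positives,
            }
            fh.write(json.dumps(manifest) + "\n")
            for r in self.records:
                fh.write(json.dumps({"type": "record", **asdict(r)}) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "ALHistory":
        lines = Path(path).read_text().splitlines()
        manifest = json.loads(lines[0])
        hist = cls(
            config=ALConfig.from_dict(manifest["config"]),
            initial=manifest["initial"],
            arm=manifest["arm"],
            task=manifest["task"],
            seed=manifest["seed"],
            truncated_at=manifest["truncated_at"],
            pool_size=manifest.get("pool_size", 0),
            pool_positives=manifest.get("pool_positives", 0),
        )
        for line in lines[1:]:
            d = json.loads(line)
            d.pop("type")
            hist.records.append(IterationRecord(**d))
        return hist


def _resolve_labels(data: MoleculeTable | np.ndarray, task: str | None) -> np.ndarray:
    if isinstance(data, MoleculeTable):
        if task is None:
            if len(data.task_names) != 1:
                raise InputError("multi-task table: specify the task to run")
            task = data.task_names[0]
        return data.task_labels(task)
    return np.asarray(data, dtype=np.int64)


def run_active_learning(
    data: MoleculeTable | np.ndarray,
    features: FeatureMatrix,
    splits: SplitIndices,
    config: ALConfig,
    task: str | None = None,
    log_path: str | Path | None = None,
) -> ALHistory:
    """Execute one seeded active-learning run.

    ``data`` is either a molecule table (with ``task`` naming the label
    column to use) or a full-length label vector aligned with ``features``.
    ``splits`` must carry non-empty ``initial``, ``pool`` and ``test``. The
    loop truncates cleanly when the pool is exhausted before
    ``n_iterations``.
    """
    y = _resolve_labels(data, task)
    if features.n != y.shape[0]:
        raise InputError("features and labels disagree in length")
    test = np.asarray(splits.test, dtype=np.int64)
    if test.size == 0:
        raise InputError("split has no test set")
    if splits.pool.size == 0:
        raise InputError("split has no pool")

    X = features.values
    labeled = list(int(i) for i in splits.initial)
    pool = [int(i) for i in splits.pool]
    test_set = set(int(i) for i in test)
    y_test = y[test]
    cfg = config
    seed = cfg.run_seed
    rng_targets_base = seed

    hist = ALHistory(
        config=cfg, initial=list(labeled), arm=cfg.acquisition,
        task=task or "", seed=seed,
        pool_size=len(pool), pool_positives=int((y[splits.pool] == 1).sum()),
    )
    log_fh = open(log_path, "a") if log_path is not None else None

    def train_current(iteration: int):
        bnn_cfg = replace(
            cfg.bnn,
            input_dim=X.shape[1],
            seed=derive_seed(seed, "train", iteration),
        )
        return train_bnn(X[labeled], y[labeled], bnn_cfg)

    def evaluate(model, iteration: int) -> dict:
        post = mc_predict(
            model, X[test], T=cfg.bnn.n_forward_passes,
            seed=derive_seed(seed, "eval", iteration),
        )
        p = post.mean_positive()
        return {
            "avg_precision": average_precision(p, y_test),
            "ece": expected_calibration_error(p, y_test, n_bins=cfg.ece_bins),
        }

    try:
        for iteration in range(cfg.n_iterations + 1):
            exhausted = len(pool) < cfg.batch_size
            last = iteration == cfg.n_iterations or exhausted
            is_eval = iteration % cfg.eval_every == 0 or last
            need_model = is_eval or cfg.acquisition != "uniform"
            model = train_current(iteration) if need_model else None
            metrics = evaluate(model, iteration) if is_eval else None
            if iteration == 0:
                hist.records.append(
                    IterationRecord(0, [], [], len(labeled), [], metrics)
                )
            elif is_eval:
                # the record appended after the previous acquisition carries
                # this iteration's number; attach the evaluation to it
                hist.records[-1].metrics = metrics
            if last:
                if exhausted:
                    hist.truncated_at = iteration
                break

            acq_seed = derive_seed(seed, "acquire", iteration)
            if cfg.acquisition == "uniform":
                scores = uniform_scores(len(pool))
            elif cfg.acquisition == "bald":
                post = mc_predict(model, X[pool], T=cfg.bnn.n_forward_passes, seed=acq_seed)
                scores = bald_scores(post)
            else:  # epig, paired pool/target draws in one pass
                rng_t = np.random.default_rng(
                    derive_seed(rng_targets_base, "targets", iteration)
                )
                m = min(cfg.target_sample_size, test.size)
                targets = rng_t.choice(test, size=m, replace=False)
                stacked = np.vstack([X[pool], X[targets]])
                post_all = mc_predict(
                    model, stacked, T=cfg.bnn.n_forward_passes, seed=acq_seed
                )
                post_pool = post_all.subset(np.arange(len(pool)))
                post_target = post_all.subset(np.arange(len(pool), len(pool) + m))
                scores = epig_scores(post_pool, post_target)

            positions = select_next(
                scores, batch_size=cfg.batch_size,
                seed=derive_seed(seed, "tiebreak", iteration),
            )
            chosen = [pool[int(p)] for p in positions]
            chosen_scores = [float(scores.scores[int(p)]) for p in positions]
            for g in chosen:
                if g in test_set:
                    raise InputError(f"leakage: test index {g} acquired")
                if y[g] == MISSING:
                    raise InputError(f"pool index {g} has no label to reveal")
            for p in sorted(positions, reverse=True):
                pool.pop(int(p))
            labeled.extend(chosen)

            hist.records.append(
                IterationRecord(
                    iteration=iteration + 1,
                    acquired_indices=[int(g) for g in chosen],
                    acquired_labels=[int(y[g]) for g in chosen],
                    labeled_size=len(labeled),
                    scores=chosen_scores,
                    metrics=None,
                )
            )
            if log_fh is not None:
                for g, s in zip(chosen, chosen_scores):
                    log_fh.write(
                        f"iteration={iteration + 1} acquisition={cfg.acquisition} "
                        f"selected={g} score={s:.6g} labeled={len(labeled)}\n"
                    )
    finally:
        if log_fh is not None:
            log_fh.close()
    return hist


def run_matrix(
    features: FeatureMatrix,
    labels_by_task: dict[str, np.ndarray],
    train: np.ndarray,
    test: np.ndarray,
    base_config: ALConfig,
    acquisitions: tuple[str, ...] = ("uniform", "bald", "epig"),
    seeds: tuple[int, ...] = (0, 1, 2),
) -> dict[tuple[str, str, int], ALHistory]:
    """Cross-product of (acquisition x task x seed) runs with shared splits.

    Within each (task, seed) cell every acquisition arm starts from the same
    balanced initial set and pool, which is what paired per-(task, seed)
    statistics require.
    """
    if not seeds:
        raise InputError("seed list is empty")
    if not acquisitions:
        raise InputError("acquisition list is empty")
    out: dict[tuple[str, str, int], ALHistory] = {}
    for task, y in labels_by_task.items():
        for s in seeds:
            initial, pool = balanced_initial_pool(
                y, train, initial_size=base_config.initial_size,
                seed=derive_seed(s, "split", task),
            )
            splits = SplitIndices(train=train, test=test, initial=initial, pool=pool)
            for acq in acquisitions:
                cfg = replace(base_config, acquisition=acq, run_seed=s)
                hist = run_active_learning(y, features, splits, cfg, task=None)
                hist.task = task
                out[(acq, task, s)] = hist
    return out
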