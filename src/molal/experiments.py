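"""Reproducible benchmark experiments on synthetic feature spaces.

These are the package's standard end-to-end studies: multi-seed active
learning on the structured synthetic space with paired acquisition arms, and
the representation study contrasting the structured and scattered regimes.
Both are deterministic given a master seed; every per-seed, per-stage random
stream is derived from it.

Problem sizes default to a desk-scale setting (2000 molecules, 16 feature
dimensions, 100 acquisitions, 30 training epochs) that keeps a ten-seed
paired benchmark within minutes on one CPU while preserving the qualitative
dynamics of interest.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from ._seeds import derive_seed
from .al_loop import ALConfig, ALHistory, run_matrix
from .bnn import BnnConfig, mc_predict, train_bnn
from .evaluation import MetricTrace, average_precision
from .mol_data import balanced_initial_pool
from .representations import SeparabilityReport, separability
from .synthetic import SyntheticSpec, generate_feature_space


def random_split(n: int, test_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random train/test index split (synthetic data has no scaffolds)."""
    rng = np.random.default_rng(derive_seed(seed, "traintest"))
    perm = rng.permutation(n)
    n_test = int(round(test_fraction * n))
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def synthetic_al_benchmark(
    master_seed: int = 0,
    n_seeds: int = 10,
    acquisitions: tuple[str, ...] = ("epig", "uniform"),
    regime: str = "structured",
    n: int = 2000,
    d: int = 16,
    n_iterations: int = 100,
    eval_every: int = 10,
    epochs: int = 30,
    initial_size: int = 100,
    test_fraction: float = 0.2,
) -> dict[tuple[str, int], ALHistory]:
    """Paired multi-seed active-learning benchmark on synthetic data.

    For each seed a fresh feature space is generated, randomly split 80:20,
    and every acquisition arm runs from the same balanced initial set. The
    returned histories are keyed by (acquisition, seed).
    """
    out: dict[tuple[str, int], ALHistory] = {}
    for k in range(n_seeds):
        seed = derive_seed(master_seed, "benchmark", k)
        spec = SyntheticSpec(n=n, d=d, regime=regime, seed=seed)
        features, y = generate_feature_space(spec)
        train, test = random_split(n, test_fraction, seed)
        cfg = ALConfig(
            n_iterations=n_iterations,
            eval_every=eval_every,
            initial_size=initial_size,
            bnn=BnnConfig(input_dim=d, epochs=epochs),
        )
        histories = run_matrix(
            features, {"synthetic": y}, train, test, cfg,
            acquisitions=acquisitions, seeds=(seed,),
        )
        for (acq, _task, _s), hist in histories.items():
            hist.seed = k  # pair arms by the benchmark replicate index
            out[(acq, k)] = hist
    return out


def traces_by_arm(
    histories: dict[tuple[str, int], ALHistory]
) -> dict[str, list[MetricTrace]]:
    """Group benchmark histories into per-arm lists of metric traces."""
    out: dict[str, list[MetricTrace]] = {}
    for (acq, _seed), hist in sorted(histories.items()):
        out.setdefault(acq, []).append(hist.to_trace())
    return out


def representation_benchmark(
    master_seed: int = 0,
    n_seeds: int = 10,
    n: int = 2000,
    d: int = 16,
    epochs: int = 30,
    initial_size: int = 100,
    test_fraction: float = 0.2,
    k_neighbors: int = 10,
) -> dict[str, list]:
    """Contrast the structured and scattered regimes at identical spec.

    For each seed and regime: separability metrics on the full space, and
    the test average precision of a network trained on a balanced initial
    set of ``initial_size`` molecules. Returns per-seed lists keyed by
    ``{regime}_separability`` and ``{regime}_ap``.
    """
    out: dict[str, list] = {
        "structured_separability": [], "scattered_separability": [],
        "structured_ap": [], "scattered_ap": [],
    }
    for k in range(n_seeds):
        seed = derive_seed(master_seed, "representation", k)
        for regime in ("structured", "scattered"):
            spec = SyntheticSpec(n=n, d=d, regime=regime, seed=seed)
            features, y = generate_feature_space(spec)
            report: SeparabilityReport = separability(features, y, k_neighbors)
            out[f"{regime}_separability"].append(report)

            train, test = random_split(n, test_fraction, seed)
            initial, _pool = balanced_initial_pool(
                y, train, initial_size=initial_size, seed=seed
            )
            model = train_bnn(
                features.values[initial], y[initial],
                BnnConfig(input_dim=d, epochs=epochs,
                          seed=derive_seed(seed, "repr-train", regime)),
            )
            post = mc_predict(
                model, features.values[test],
                seed=derive_seed(seed, "repr-eval", regime),
            )
            out[f"{regime}_ap"].append(
                average_precision(post.mean_positive(), y[test])
            )
    return out
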