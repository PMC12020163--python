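"""Acquisition functions over posterior predictive samples.

Scores quantify the expected value of labeling each pool candidate:

* ``uniform`` — the random baseline, every candidate scores 1/|pool|;
* ``bald`` — mutual information between the candidate's unknown label and
  the model parameters, estimated as the entropy of the mean predictive
  distribution minus the mean per-draw entropy (epistemic uncertainty);
* ``epig`` — expected predictive information gain: the mutual information
  between the candidate's label and the label of a random target point,
  averaged over a sample from the target input distribution. Estimated from
  the joint distribution over (candidate, target) labels under paired
  parameter draws, as a KL divergence of that joint from the product of its
  marginals.

All entropies use the natural logarithm, so scores are in nats. Selection is
an argmax (top-``batch_size``) with seeded uniform tie-breaking; the uniform
arm samples without replacement instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seeds import derive_seed
from .bnn import PosteriorSamples
from .mol_data import InputError

_CLIP = 1e-12

ACQUISITION_NAMES = ("uniform", "bald", "epig")


@dataclass
class AcquisitionScores:
    """Per-candidate scores in nats (uniform: probabilities)."""

    scores: np.ndarray
    name: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.name not in ACQUISITION_NAMES:
            raise InputError(f"name must be one of {ACQUISITION_NAMES}")
        if not np.isfinite(self.scores).all():
            raise InputError("scores must be finite")
        if self.name in ("bald", "epig") and (self.scores < -1e-9).any():
            raise InputError(f"{self.name} scores must be nonnegative")

    @property
    def n_pool(self) -> int:
        return self.scores.shape[0]


def uniform_scores(n_pool: int) -> AcquisitionScores:
    """Constant score 1/n_pool for every candidate."""
    if n_pool < 1:
        raise InputError("pool is empty")
    return AcquisitionScores(np.full(n_pool, 1.0 / n_pool), "uniform")


def _entropy(p: np.ndarray) -> np.ndarray:
    """Binary Shannon entropy along the last axis, in nats."""
    q = np.clip(p, _CLIP, 1.0 - _CLIP)
    return -(q * np.log(q)).sum(axis=-1)


def bald_scores(post: PosteriorSamples) -> AcquisitionScores:
    """H[mean predictive] - mean per-draw H, per pool point.

    Zero exactly when all T draws agree (no disagreement means the label
    carries no information about the parameters).
    """
    if post.T < 2:
        raise InputError("BALD needs at least 2 posterior draws")
    probs = post.probs  # (T, n, 2)
    mean = probs.mean(axis=0)
    scores = _entropy(mean) - _entropy(probs).mean(axis=0)
    agree = (probs == probs[:1]).all(axis=(0, 2))
    scores = np.where(agree, 0.0, np.maximum(scores, 0.0))
    return AcquisitionScores(scores, "bald")


def epig_scores(
    post_pool: PosteriorSamples, post_target: PosteriorSamples
) -> AcquisitionScores:
    """Expected predictive information gain of each pool point.

    Both sample sets must come from the SAME T parameter draws (identical
    dropout masks per pass) — compute them in one ``mc_predict`` call over
    the concatenated feature matrix and split. For pool point x and target
    x*, the joint label distribution is the average over draws of
    p(y|x, phi) p(y*|x*, phi); the score is the mean over targets of
    KL(joint || product of marginals).
    """
    if post_pool.T != post_target.T:
        raise InputError(
            f"pool and target posterior samples must share T (paired draws); "
            f"got T={post_pool.T} vs T={post_target.T}"
        )
    T = post_pool.T
    if T < 2:
        raise InputError("EPIG needs at least 2 posterior draws")
    pool = post_pool.probs  # (T, n, 2)
    target = post_target.probs  # (T, M, 2)
    joint = np.einsum("tnc,tmd->nmcd", pool, target) / T  # (n, M, 2, 2)
    marg_pool = pool.mean(axis=0)  # (n, 2)
    marg_target = target.mean(axis=0)  # (M, 2)
    product = marg_pool[:, None, :, None] * marg_target[None, :, None, :]
    jc = np.clip(joint, _CLIP, None)
    pc = np.clip(product, _CLIP, None)
    kl = np.where(joint > 0, joint * (np.log(jc) - np.log(pc)), 0.0).sum(axis=(2, 3))
    scores = np.maximum(kl.mean(axis=1), 0.0)
    return AcquisitionScores(scores, "epig")


def select_next(
    scores: AcquisitionScores, batch_size: int = 1, seed: int = 0
) -> np.ndarray:
    """Pick the next batch of pool positions to label.

    BALD/EPIG take the ``batch_size`` highest scores with uniform random
    tie-breaking under ``seed``; the uniform arm samples positions without
    replacement. Returned positions index into the score vector.
    """
    n = scores.n_pool
    if n == 0:
        raise InputError("pool is empty")
    if batch_size > n:
        raise InputError(f"batch_size {batch_size} exceeds pool size {n}")
    rng = np.random.default_rng(derive_seed(seed, "select", scores.name))
    if scores.name == "uniform":
        return np.sort(rng.choice(n, size=batch_size, replace=False))
    # random tie-break: jitter ranks by a random permutation as secondary key
    tiebreak = rng.permutation(n)
    order = np.lexsort((tiebreak, -scores.scores))
    return np.sort(order[:batch_size])
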