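"""MC-dropout Bayesian neural network for binary molecular property prediction.

The classifier is a small feed-forward network: a linear layer into a hidden
space, batch normalization, ReLU and dropout; one residual block (linear,
batch-norm, skip connection from the block input, ReLU, dropout); and a final
linear layer producing one logit. Training minimizes binary cross-entropy on
logits with Adam (L2 weight decay) under a cosine-annealing learning-rate
schedule with warm restarts.

Dropout doubles as approximate Bayesian inference: keeping it active at
prediction time and repeating T stochastic forward passes draws T parameter
realizations phi^(t) from the dropout posterior q(phi). Each pass uses ONE
dropout mask per hidden layer shared across all rows of the batch, so a pass
is a single coherent parameter draw — this pairing is what allows joint
(pool, target) probabilities to be formed for EPIG. Batch normalization runs
in inference mode (stored running statistics) during these passes.

The network and its training loop are implemented directly on NumPy arrays;
forward and backward passes, the optimizer and the schedule are all local to
this module, which keeps every source of randomness under one seeded
generator and the whole fit bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._seeds import derive_seed
from .mol_data import InputError
from .representations import FeatureMatrix

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass
class BnnConfig:
    """Architecture and training hyperparameters.

    ``dropout_p`` is the rate used during training; ``mc_dropout_p`` (if set)
    overrides it for inference-time stochastic forward passes, so the two
    rates can differ. ``lr_cycle`` is the warm-restart period of the cosine
    schedule in epochs.
    """

    input_dim: int = 16
    hidden_dim: int = 128
    n_hidden: int = 1
    dropout_p: float = 0.3
    mc_dropout_p: float | None = None
    learning_rate: float = 1e-3
    weight_decay: float = 1e-2
    epochs: int = 110
    batch_size: int = 16
    lr_cycle: int = 10
    n_forward_passes: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_p < 1:
            raise InputError("dropout_p must be in [0, 1)")
        if self.n_forward_passes < 2:
            raise InputError("n_forward_passes must be >= 2")
        for name in ("input_dim", "hidden_dim", "n_hidden", "epochs",
                     "batch_size", "lr_cycle"):
            if getattr(self, name) < 1:
                raise InputError(f"{name} must be positive")

    @property
    def inference_dropout_p(self) -> float:
        return self.dropout_p if self.mc_dropout_p is None else self.mc_dropout_p


@dataclass
class PosteriorSamples:
    """T x n x 2 predictive class probabilities from stochastic passes."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 3 or self.probs.shape[2] != 2:
            raise InputError("probs must have shape (T, n, 2)")
        if ((self.probs < 0) | (self.probs > 1)).any():
            raise InputError("probabilities must lie in [0, 1]")
        if not np.allclose(self.probs.sum(axis=2), 1.0, atol=1e-6):
            raise InputError("class probabilities must sum to 1")

    @property
    def T(self) -> int:
        return self.probs.shape[0]

    @property
    def n(self) -> int:
        return self.probs.shape[1]

    def mean_positive(self) -> np.ndarray:
        """Predictive mean p(y=1 | x) averaged over the T draws."""
        return self.probs[:, :, 1].mean(axis=0)

    def subset(self, idx: np.ndarray) -> "PosteriorSamples":
        return PosteriorSamples(self.probs[:, np.asarray(idx), :])


class _BatchNorm:
    """1-D batch normalization with running statistics."""

    def __init__(self, dim: int) -> None:
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - _BN_MOMENTUM) * self.running_mean + _BN_MOMENTUM * mu
            self.running_var = (1 - _BN_MOMENTUM) * self.running_var + _BN_MOMENTUM * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_sd = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (x - mu) * inv_sd
        if training:
            self._cache = (xhat, inv_sd)
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        xhat, inv_sd = self._cache
        B = dy.shape[0]
        dgamma = (dy * xhat).sum(axis=0)
        dbeta = dy.sum(axis=0)
        dx = (self.gamma * inv_sd / B) * (B * dy - dbeta - xhat * dgamma)
        return dx, dgamma, dbeta


class MCDropoutNet:
    """The network of the architecture above, with manual backprop."""

    def __init__(self, config: BnnConfig) -> None:
        self.config = config
        rng = np.random.default_rng(derive_seed(config.seed, "init"))
        d, h = config.input_dim, config.hidden_dim

        def he(fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.W_in, self.b_in = he(d, (d, h)), np.zeros(h)
        self.bn_in = _BatchNorm(h)
        self.W_res = [he(h, (h, h)) for _ in range(config.n_hidden)]
        self.b_res = [np.zeros(h) for _ in range(config.n_hidden)]
        self.bn_res = [_BatchNorm(h) for _ in range(config.n_hidden)]
        self.W_out, self.b_out = he(h, (h, 1)), np.zeros(1)

    # ---- parameter plumbing -------------------------------------------------

    def _params(self) -> list[np.ndarray]:
        out = [self.W_in, self.b_in, self.bn_in.gamma, self.bn_in.beta]
        for k in range(self.config.n_hidden):
            out += [self.W_res[k], self.b_res[k],
                    self.bn_res[k].gamma, self.bn_res[k].beta]
        out += [self.W_out, self.b_out]
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {
            "W_in": self.W_in, "b_in": self.b_in,
            "bn_in.gamma": self.bn_in.gamma, "bn_in.beta": self.bn_in.beta,
            "bn_in.rmean": self.bn_in.running_mean, "bn_in.rvar": self.bn_in.running_var,
            "W_out": self.W_out, "b_out": self.b_out,
        }
        for k in range(self.config.n_hidden):
            state[f"W_res{k}"] = self.W_res[k]
            state[f"b_res{k}"] = self.b_res[k]
            state[f"bn_res{k}.gamma"] = self.bn_res[k].gamma
            state[f"bn_res{k}.beta"] = self.bn_res[k].beta
            state[f"bn_res{k}.rmean"] = self.bn_res[k].running_mean
            state[f"bn_res{k}.rvar"] = self.bn_res[k].running_var
        return {k: v.copy() for k, v in state.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.W_in = state["W_in"].copy()
        self.b_in = state["b_in"].copy()
        self.bn_in.gamma = state["bn_in.gamma"].copy()
        self.bn_in.beta = state["bn_in.beta"].copy()
        self.bn_in.running_mean = state["bn_in.rmean"].copy()
        self.bn_in.running_var = state["bn_in.rvar"].copy()
        for k in range(self.config.n_hidden):
            self.W_res[k] = state[f"W_res{k}"].copy()
            self.b_res[k] = state[f"b_res{k}"].copy()
            self.bn_res[k].gamma = state[f"bn_res{k}.gamma"].copy()
            self.bn_res[k].beta = state[f"bn_res{k}.beta"].copy()
            self.bn_res[k].running_mean = state[f"bn_res{k}.rmean"].copy()
            self.bn_res[k].running_var = state[f"bn_res{k}.rvar"].copy()
        self.W_out = state["W_out"].copy()
        self.b_out = state["b_out"].copy()

    # ---- forward / backward -------------------------------------------------

    def _forward_train(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        p = self.config.dropout_p
        keep = 1.0 - p
        cache: dict[str, object] = {"X": X}

        z = X @ self.W_in + self.b_in
        a = self.bn_in.forward(z, training=True)
        relu_in = a > 0
        a = a * relu_in
        mask_in = (rng.random(a.shape) < keep) / keep if p > 0 else np.ones_like(a)
        h = a * mask_in
        cache["relu_in"], cache["mask_in"] = relu_in, mask_in

        block_caches = []
        for k in range(self.config.n_hidden):
            z_k = h @ self.W_res[k] + self.b_res[k]
            bn_k = self.bn_res[k].forward(z_k, training=True)
            r = h + bn_k
            relu_k = r > 0
            a_k = r * relu_k
            mask_k = (rng.random(a_k.shape) < keep) / keep if p > 0 else np.ones_like(a_k)
            block_caches.append((h, relu_k, mask_k))
            h = a_k * mask_k
        cache["blocks"] = block_caches
        cache["h_last"] = h
        self._train_cache = cache
        return (h @ self.W_out + self.b_out).ravel()

    def _backward(self, dlogit: np.ndarray) -> list[np.ndarray]:
        cache = self._train_cache
        h_last = cache["h_last"]
        dlogit = dlogit[:, None]
        dW_out = h_last.T @ dlogit
        db_out = dlogit.sum(axis=0)
        dh = dlogit @ self.W_out.T

        grads_blocks = []
        for k in reversed(range(self.config.n_hidden)):
            h_in, relu_k, mask_k = cache["blocks"][k]
            da = dh * mask_k
            dr = da * relu_k
            dbn, dgamma, dbeta = self.bn_res[k].backward(dr)
            dW = h_in.T @ dbn
            db = dbn.sum(axis=0)
            dh = dr + dbn @ self.W_res[k].T  # skip path + linear path
            grads_blocks.append((dW, db, dgamma, dbeta))
        grads_blocks.reverse()

        da = dh * cache["mask_in"]
        dz = da * cache["relu_in"]
        dzlin, dgamma_in, dbeta_in = self.bn_in.backward(dz)
        dW_in = cache["X"].T @ dzlin
        db_in = dzlin.sum(axis=0)

        grads = [dW_in, db_in, dgamma_in, dbeta_in]
        for dW, db, dgamma, dbeta in grads_blocks:
            grads += [dW, db, dgamma, dbeta]
        grads += [dW_out, db_out]
        return grads

    def forward_eval(
        self,
        X: np.ndarray,
        unit_masks: list[np.ndarray] | None = None,
    ) -> np.ndarray:
        """Deterministic or MC forward pass with batch-norm running stats.

        ``unit_masks`` holds one pre-scaled mask vector per dropout site,
        shared across the batch (a single dropout-posterior parameter draw).
        """
        site = 0
        z = X @ self.W_in + self.b_in
        a = np.maximum(self.bn_in.forward(z, training=False), 0.0)
        if unit_masks is not None:
            a = a * unit_masks[site]
        site += 1
        h = a
        for k in range(self.config.n_hidden):
            z_k = h @ self.W_res[k] + self.b_res[k]
            r = h + self.bn_res[k].forward(z_k, training=False)
            a_k = np.maximum(r, 0.0)
            if unit_masks is not None:
                a_k = a_k * unit_masks[site]
            site += 1
            h = a_k
        return (h @ self.W_out + self.b_out).ravel()

    @property
    def n_dropout_sites(self) -> int:
        return 1 + self.config.n_hidden


def _cosine_lr(base_lr: float, epoch: int, cycle: int) -> float:
    """Cosine annealing with warm restarts every ``cycle`` epochs."""
    phase = (epoch % cycle) / cycle
    return 0.5 * base_lr * (1.0 + np.cos(np.pi * phase))


def train_bnn(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    config: BnnConfig,
) -> MCDropoutNet:
    """Fit the network on a labeled set; reproducible from ``config.seed``.

    Minibatches of ``batch_size`` with a fresh shuffle per epoch; a final
    batch of size 1 is dropped (batch statistics would be degenerate).
    Raises :class:`DivergenceError` naming the epoch if the loss leaves the
    finite range.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    y = np.asarray(labels, dtype=np.float64).ravel()
    if X.shape[0] != y.shape[0]:
        raise InputError("features and labels disagree in length")
    if X.shape[1] != config.input_dim:
        raise InputError(
            f"feature dim {X.shape[1]} != configured input_dim {config.input_dim}"
        )
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos < 2 or n_neg < 2:
        raise InputError(
            f"need >= 2 examples per class; have {n_pos} positives, {n_neg} negatives"
        )

    model = MCDropoutNet(config)
    rng = np.random.default_rng(derive_seed(config.seed, "train"))
    params = model._params()
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    n = X.shape[0]

    for epoch in range(config.epochs):
        lr = _cosine_lr(config.learning_rate, epoch, config.lr_cycle)
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if idx.size < 2:
                continue  # a singleton batch has no usable batch statistics
            Xb, yb = X[idx], y[idx]
            logits = model._forward_train(Xb, rng)
            # stable binary cross-entropy with logits
            loss = np.mean(np.logaddexp(0.0, logits) - yb * logits)
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            probs = 1.0 / (1.0 + np.exp(-logits))
            grads = model._backward((probs - yb) / idx.size)

            step += 1
            params = model._params()
            for j, (p, g) in enumerate(zip(params, grads)):
                g = g + config.weight_decay * p  # coupled L2, Adam convention
                m[j] = beta1 * m[j] + (1 - beta1) * g
                v[j] = beta2 * v[j] + (1 - beta2) * g * g
                mhat = m[j] / (1 - beta1**step)
                vhat = v[j] / (1 - beta2**step)
                p -= lr * mhat / (np.sqrt(vhat) + eps)
    return model


def mc_predict(
    model: MCDropoutNet,
    features: FeatureMatrix | np.ndarray,
    T: int | None = None,
    dropout_active: bool = True,
    seed: int = 0,
) -> PosteriorSamples:
    """T stochastic forward passes; returns T x n x 2 class probabilities.

    With dropout active, pass t applies one mask vector per hidden layer to
    every input row, i.e. draws a single network phi^(t) per pass. To obtain
    the paired draws EPIG needs, call this once on the concatenation of pool
    and target features and split the result.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    cfg = model.config
    if T is None:
        T = cfg.n_forward_passes
    if X.shape[1] != cfg.input_dim:
        raise InputError("feature dim does not match the trained model")
    if dropout_active and T < 2:
        warnings.warn(
            "T < 2 stochastic passes gives no uncertainty estimate",
            RuntimeWarning,
            stacklevel=2,
        )
    p = cfg.inference_dropout_p if dropout_active else 0.0
    keep = 1.0 - p
    rng = np.random.default_rng(derive_seed(seed, "mc_predict"))
    h = cfg.hidden_dim
    out = np.empty((T, X.shape[0], 2))
    for t in range(T):
        if p > 0:
            masks = [
                (rng.random(h) < keep) / keep for _ in range(model.n_dropout_sites)
            ]
        else:
            masks = None
        logits = model.forward_eval(X, unit_masks=masks)
        pos = 1.0 / (1.0 + np.exp(-logits))
        out[t, :, 1] = pos
        out[t, :, 0] = 1.0 - pos
    return PosteriorSamples(out)


def save_model(model: MCDropoutNet, path: str) -> None:
    """Serialize weights (.npz) with the config as JSON alongside."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    np.savez(path, **model.state_dict())
    Path(str(path) + ".json").write_text(json.dumps(asdict(model.config)))


def load_model(path: str) -> MCDropoutNet:
    import json
    from pathlib import Path

    cfg = BnnConfig(**json.loads(Path(str(path) + ".json").read_text()))
    model = MCDropoutNet(cfg)
    with np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz") as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model


def clone_config(config: BnnConfig, **overrides: object) -> BnnConfig:
    return replace(config, **overrides)
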