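"""Single-hidden-layer sparse autoencoder trained with minibatch SGD.

Encoder and decoder both use the logistic sigmoid:

    z = sigmoid(W1 x + b1),    x_hat = sigmoid(W2 z + b2)

The training objective is the sparse mean-square-error loss

    L = (1/n) sum_i ||x_i - x_hat_i||^2
        + beta * sum_j KL(rho || rho_hat_j)
        + lambda * (||W1||_F^2 + ||W2||_F^2)

where rho_hat_j is the mean activation of hidden unit j over the batch and
KL(rho||rho_hat) = rho log(rho/rho_hat) + (1-rho) log((1-rho)/(1-rho_hat)).
The reconstruction term sums squared error over the 1024 patch entries and
averages over patches — the convention of the MATLAB-family sparse
autoencoder this loss is modelled on, and the scale at which the default
learning rate of 1e-3 is effective.

The per-patch anomaly score is the mean absolute (l1) deviation between a
patch and its reconstruction, kept separate from the training loss: the
squared error drives optimization while the l1 residual scores anomalies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from typing import NamedTuple

import numpy as np
from scipy.special import expit as sigmoid

from .errors import TrainingDivergedError

__all__ = [
    "AutoencoderModel", "TrainConfig", "LossParts",
    "initialize_model", "encode", "decode", "loss", "loss_gradients",
    "train", "patch_error", "save_model", "load_model",
]

_RHO_EPS = 1e-8


@dataclass
class AutoencoderModel:
    """Weights and biases of one sigmoid autoencoder."""

    W1: np.ndarray  # (hidden, n_inputs)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (n_inputs, hidden)
    b2: np.ndarray  # (n_inputs,)

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=np.float64)
        self.b1 = np.asarray(self.b1, dtype=np.float64)
        self.W2 = np.asarray(self.W2, dtype=np.float64)
        self.b2 = np.asarray(self.b2, dtype=np.float64)
        h, d = self.W1.shape
        if self.b1.shape != (h,) or self.W2.shape != (d, h) or self.b2.shape != (d,):
            raise ValueError("inconsistent parameter shapes")
        for p in (self.W1, self.b1, self.W2, self.b2):
            if not np.isfinite(p).all():
                raise ValueError("model parameters must be finite")

    @property
    def hidden_size(self) -> int:
        return self.W1.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[1]

    def copy(self) -> "AutoencoderModel":
        return AutoencoderModel(self.W1.copy(), self.b1.copy(),
                                self.W2.copy(), self.b2.copy())


@dataclass(frozen=True)
class TrainConfig:
    """SGD hyperparameters.

    Defaults: initial learning rate 1e-3, 4000
    maximum epochs, sparsity regularization beta=1 with target activation
    rho=0.05, and L2 weight regularization 1e-3.

    ``algorithm`` selects the optimizer:

    * ``"scg"`` (default) — full-batch scaled conjugate gradient (Moller's
      algorithm, the trainer of the MATLAB-family sparse autoencoder this
      loss is modelled on); ``max_epochs`` bounds the iterations and the
      learning-rate/batch/momentum settings are ignored.
    * ``"sgd"`` — minibatch stochastic gradient descent with classical
      momentum (0.9 by default, the sgdm convention; set 0 for plain SGD);
      the learning rate decays by ``lr_decay`` every ``max_epochs // 4``
      epochs.
    """

    learning_rate: float = 0.001
    max_epochs: int = 4000
    batch_size: int = 256
    sparsity_regularization: float = 1.0   # beta
    sparsity_proportion: float = 0.05      # rho
    l2_regularization: float = 0.001       # lambda
    lr_decay: float = 0.5
    momentum: float = 0.9
    algorithm: str = "scg"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0 < self.sparsity_proportion < 1:
            raise ValueError("sparsity_proportion must lie in (0, 1)")
        if self.sparsity_regularization < 0 or self.l2_regularization < 0:
            raise ValueError("regularization weights must be >= 0")
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("max_epochs and batch_size must be >= 1")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")
        if self.algorithm not in ("scg", "sgd"):
            raise ValueError("algorithm must be 'scg' or 'sgd'")


class LossParts(NamedTuple):
    total: float
    mse: float
    sparsity: float  # sum of KL divergences (unweighted)
    l2: float        # squared Frobenius norms (unweighted)


def initialize_model(n_inputs: int, hidden_size: int,
                     rng: np.random.Generator,
                     data_means: np.ndarray | None = None,
                     rho: float | None = None) -> AutoencoderModel:
    """Uniform +-1/sqrt(fan_in) weights.

    Biases start at the values that make the untrained network statistically
    neutral: the decoder bias at the logit of the per-feature training mean
    (so initial reconstructions match the data mean instead of 0.5) and the
    encoder bias at logit(rho) (so initial activations sit at the sparsity
    target and the KL term starts near zero). With ``data_means``/``rho``
    omitted the biases are zero.
    """
    r1 = 1.0 / np.sqrt(n_inputs)
    r2 = 1.0 / np.sqrt(hidden_size)
    b1 = np.zeros(hidden_size)
    if rho is not None:
        b1 += np.log(rho / (1.0 - rho))
    b2 = np.zeros(n_inputs)
    if data_means is not None:
        m = np.clip(np.asarray(data_means, dtype=np.float64), 1e-3, 1 - 1e-3)
        b2 = np.log(m / (1.0 - m))
    return AutoencoderModel(
        W1=rng.uniform(-r1, r1, size=(hidden_size, n_inputs)),
        b1=b1,
        W2=rng.uniform(-r2, r2, size=(n_inputs, hidden_size)),
        b2=b2,
    )


def encode(model: AutoencoderModel, patches: np.ndarray) -> np.ndarray:
    """Latent activations, one row per patch; values in (0, 1)."""
    x = np.atleast_2d(np.asarray(patches, dtype=np.float64))
    return sigmoid(x @ model.W1.T + model.b1)


def decode(model: AutoencoderModel, latent: np.ndarray) -> np.ndarray:
    """Reconstructions, one row per latent vector; values in (0, 1)."""
    z = np.atleast_2d(np.asarray(latent, dtype=np.float64))
    return sigmoid(z @ model.W2.T + model.b2)


def _rho_hat(latent: np.ndarray) -> np.ndarray:
    rho_hat = latent.mean(axis=0)
    if ((rho_hat <= _RHO_EPS) | (rho_hat >= 1 - _RHO_EPS)).any():
        warnings.warn("mean hidden activation saturated; clamping for KL term",
                      RuntimeWarning, stacklevel=3)
        rho_hat = np.clip(rho_hat, _RHO_EPS, 1 - _RHO_EPS)
    return rho_hat


def loss(model: AutoencoderModel, patches: np.ndarray,
         config: TrainConfig) -> LossParts:
    """Sparse-MSE loss and its components (components unweighted)."""
    x = np.atleast_2d(np.asarray(patches, dtype=np.float64))
    if x.shape[0] < 1:
        raise ValueError("at least one patch required")
    z = encode(model, x)
    xhat = decode(model, z)
    n = x.shape[0]
    mse = float(np.sum((xhat - x) ** 2) / n)
    rho = config.sparsity_proportion
    rho_hat = _rho_hat(z)
    kl = float(np.sum(rho * np.log(rho / rho_hat)
                      + (1 - rho) * np.log((1 - rho) / (1 - rho_hat))))
    l2 = float(np.sum(model.W1 ** 2) + np.sum(model.W2 ** 2))
    total = mse + config.sparsity_regularization * kl + config.l2_regularization * l2
    return LossParts(total=total, mse=mse, sparsity=kl, l2=l2)


def loss_gradients(model: AutoencoderModel, patches: np.ndarray,
                   config: TrainConfig) -> dict[str, np.ndarray]:
    """Analytic gradients of the total loss w.r.t. W1, b1, W2, b2."""
    x = np.atleast_2d(np.asarray(patches, dtype=np.float64))
    n = x.shape[0]
    z = encode(model, x)
    xhat = decode(model, z)
    beta = config.sparsity_regularization
    lam = config.l2_regularization
    rho = config.sparsity_proportion

    # output layer: d total / d pre-activation2
    d2 = (2.0 / n) * (xhat - x) * xhat * (1.0 - xhat)
    gW2 = d2.T @ z + 2.0 * lam * model.W2
    gb2 = d2.sum(axis=0)

    # hidden layer: backprop + sparsity penalty through rho_hat = mean(z)
    dz = d2 @ model.W2
    rho_hat = _rho_hat(z)
    dz = dz + (beta / n) * (-rho / rho_hat + (1.0 - rho) / (1.0 - rho_hat))
    d1 = dz * z * (1.0 - z)
    gW1 = d1.T @ x + 2.0 * lam * model.W1
    gb1 = d1.sum(axis=0)
    return {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2}


def _pack(model: AutoencoderModel) -> np.ndarray:
    return np.concatenate([model.W1.ravel(), model.b1,
                           model.W2.ravel(), model.b2])


def _unpack(vec: np.ndarray, hidden: int, n_inputs: int) -> AutoencoderModel:
    sizes = [hidden * n_inputs, hidden, n_inputs * hidden, n_inputs]
    offs = np.cumsum([0] + sizes)
    return AutoencoderModel(
        W1=vec[offs[0]:offs[1]].reshape(hidden, n_inputs),
        b1=vec[offs[1]:offs[2]],
        W2=vec[offs[2]:offs[3]].reshape(n_inputs, hidden),
        b2=vec[offs[3]:offs[4]],
    )


def _train_scg(x: np.ndarray, config: TrainConfig, model: AutoencoderModel,
               ) -> tuple[AutoencoderModel, list[float]]:
    """Moller's scaled conjugate gradient, full batch.

    A conjugate-gradient method with a Levenberg-Marquardt-style scale that
    replaces the line search by a one-sided finite-difference curvature
    estimate along the search direction; deterministic given the start point.
    """
    hidden, n_inputs = model.hidden_size, model.n_inputs

    def f_and_g(w: np.ndarray) -> tuple[float, np.ndarray]:
        m = _unpack(w, hidden, n_inputs)
        g = loss_gradients(m, x, config)
        return loss(m, x, config).total, np.concatenate(
            [g["W1"].ravel(), g["b1"], g["W2"].ravel(), g["b2"]])

    sigma0 = 1e-4
    lam, lam_bar = 1e-6, 0.0
    w = _pack(model)
    f_w, grad = f_and_g(w)
    r = -grad
    p = r.copy()
    success = True
    history: list[float] = []
    n_params = w.size
    delta = 0.0
    for k in range(1, config.max_epochs + 1):
        p_sq = float(p @ p)
        if p_sq == 0.0:
            history.append(f_w)
            break
        if success:
            sigma = sigma0 / np.sqrt(p_sq)
            _, grad_sigma = f_and_g(w + sigma * p)
            s = (grad_sigma - grad) / sigma
            delta = float(p @ s)
        delta += (lam - lam_bar) * p_sq
        if delta <= 0:  # make the Hessian estimate positive definite
            lam_bar = 2.0 * (lam - delta / p_sq)
            delta = -delta + lam * p_sq
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta
        w_new = w + alpha * p
        f_new, grad_new = f_and_g(w_new)
        if not np.isfinite(f_new):
            raise TrainingDivergedError(k, alpha)
        comp = 2.0 * delta * (f_w - f_new) / (mu * mu)  # comparison parameter
        if comp >= 0:  # successful step
            w, f_w = w_new, f_new
            r_new = -grad_new
            grad = grad_new
            lam_bar = 0.0
            success = True
            if k % n_params == 0:
                p = r_new.copy()  # periodic restart
            else:
                beta = float((r_new @ r_new - r_new @ r) / mu)
                p = r_new + beta * p
            r = r_new
            if comp >= 0.75:
                lam *= 0.25
        else:
            lam_bar = lam
            success = False
        if comp < 0.25:
            lam += delta * (1.0 - comp) / p_sq
        history.append(f_w)
    return _unpack(w, hidden, n_inputs), history


def train(patches: np.ndarray, config: TrainConfig,
          hidden_size: int = 128) -> tuple[AutoencoderModel, list[float]]:
    """Train one sparse autoencoder.

    Dispatches on ``config.algorithm``: full-batch scaled conjugate
    gradient, or minibatch SGD with momentum and stepwise learning-rate
    decay. Returns the trained model and one full-dataset total-loss value
    per epoch/iteration. Deterministic for a fixed config (seeded
    initialization and shuffling).
    """
    x = np.atleast_2d(np.asarray(patches, dtype=np.float64))
    n = x.shape[0]
    rng = np.random.default_rng(config.seed)
    model = initialize_model(x.shape[1], hidden_size, rng,
                             data_means=x.mean(axis=0),
                             rho=config.sparsity_proportion)
    if config.algorithm == "scg":
        return _train_scg(x, config, model)
    lr = config.learning_rate
    decay_every = max(1, config.max_epochs // 4)
    mu = config.momentum
    velocity = {k: np.zeros_like(getattr(model, k)) for k in ("W1", "b1", "W2", "b2")}
    history: list[float] = []
    for epoch in range(1, config.max_epochs + 1):
        perm = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = x[perm[start:start + config.batch_size]]
            g = loss_gradients(model, batch, config)
            for k, vel in velocity.items():
                vel *= mu
                vel += g[k]
                param = getattr(model, k)
                param -= lr * vel
        epoch_loss = loss(model, x, config).total
        if not np.isfinite(epoch_loss):
            raise TrainingDivergedError(epoch, lr)
        history.append(epoch_loss)
        if epoch % decay_every == 0:
            lr *= config.lr_decay
    return model, history


def patch_error(model: AutoencoderModel, patches: np.ndarray) -> np.ndarray:
    """Per-patch mean absolute deviation between input and reconstruction —
    the patch-level anomaly score."""
    x = np.atleast_2d(np.asarray(patches, dtype=np.float64))
    xhat = decode(model, encode(model, x))
    return np.mean(np.abs(x - xhat), axis=1)


# ---------------------------------------------------------------------------
# serialization: one-line JSON header + raw float64 parameter blocks

def save_model(model: AutoencoderModel, path,
               config: TrainConfig | None = None) -> None:
    header = {
        "hidden_size": model.hidden_size,
        "n_inputs": model.n_inputs,
        "config": None if config is None else asdict(config),
    }
    with open(path, "wb") as fh:
        fh.write(json.dumps(header).encode() + b"\n")
        for p in (model.W1, model.b1, model.W2, model.b2):
            fh.write(np.ascontiguousarray(p).tobytes())


def load_model(path) -> tuple[AutoencoderModel, TrainConfig | None]:
    with open(path, "rb") as fh:
        header = json.loads(fh.readline().decode())
        raw = fh.read()
    h, d = header["hidden_size"], header["n_inputs"]
    sizes = [h * d, h, d * h, d]
    offsets = np.cumsum([0] + sizes)
    flat = np.frombuffer(raw, dtype=np.float64)
    if flat.size != offsets[-1]:
        raise ValueError(f"corrupt model file {path}: wrong parameter count")
    W1 = flat[offsets[0]:offsets[1]].reshape(h, d).copy()
    b1 = flat[offsets[1]:offsets[2]].copy()
    W2 = flat[offsets[2]:offsets[3]].reshape(d, h).copy()
    b2 = flat[offsets[3]:offsets[4]].copy()
    config = None if header["config"] is None else TrainConfig(**header["config"])
    return AutoencoderModel(W1, b1, W2, b2), config
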