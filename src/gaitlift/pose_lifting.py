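"""2D-to-3D pose lifting with a residual fully-connected network.

The lifter learns f: R^{2n} -> R^{3n} mapping one frame of 2D keypoints to a
root-relative 3D pose on the canonical n = 17 joint skeleton.  The
architecture is the residual fully-connected family: an input linear layer
that raises the dimensionality to the hidden width, followed by residual
blocks of two (linear, batch-norm, ReLU, dropout) stages with an identity
skip, and a final linear layer producing 3n outputs.  Weights use Kaiming
initialization; training minimizes mean squared error with Adam under an
exponentially decaying learning rate.

Everything — forward pass, backpropagation (including through batch norm and
inverted dropout), and the Adam update — is implemented directly in numpy,
so training is deterministic given the seed.

2D inputs are normalized per frame (centred on the hip midpoint, scaled by
the right-hip-to-right-shoulder distance) so that synthetic and real
observations share units; targets are root-relative 3D poses in the same
dimensionless scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._errors import ConfigError, DataError, DivergenceError
from .containers import KeypointSeries2D, Pose3DSeries, canonical_2d
from .skeleton import CANONICAL_JOINTS, SkeletonMap

__all__ = ["LiftingConfig", "PoseBatch", "LiftingNetwork", "build_model",
           "train", "lift", "normalize_2d_frames", "save_checkpoint",
           "load_checkpoint"]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1

_RHIP = CANONICAL_JOINTS.index("right_hip")
_LHIP = CANONICAL_JOINTS.index("left_hip")
_RSHO = CANONICAL_JOINTS.index("right_shoulder")


@dataclass(frozen=True)
class LiftingConfig:
    """Hyperparameters of the lifting network and its training loop."""

    n_joints: int = 17
    hidden: int = 1024
    blocks: int = 2
    dropout: float = 0.5
    learning_rate: float = 1e-3
    lr_decay: float = 0.99       # multiplicative, per epoch
    epochs: int = 200
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_joints <= 0:
            raise ConfigError(f"n_joints must be positive, got {self.n_joints}")
        if self.hidden <= 0:
            raise ConfigError(f"hidden width must be positive, got {self.hidden}")
        if not 0 <= self.dropout < 1:
            raise ConfigError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.epochs < 1:
            raise ConfigError(f"epochs must be >= 1, got {self.epochs}")

    @property
    def input_dim(self) -> int:
        return 2 * self.n_joints

    @property
    def output_dim(self) -> int:
        return 3 * self.n_joints


@dataclass
class PoseBatch:
    """Aligned (2D input, 3D target) pairs in normalized units."""

    inputs: np.ndarray    # N x 2n
    targets: np.ndarray   # N x 3n

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.inputs.shape[0] != self.targets.shape[0]:
            raise DataError("PoseBatch: inputs and targets differ in length")
        if not (np.all(np.isfinite(self.inputs))
                and np.all(np.isfinite(self.targets))):
            raise DataError("PoseBatch: non-finite values")

    def __len__(self) -> int:
        return self.inputs.shape[0]


# ---------------------------------------------------------------------------
# Layers

class _Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        # Kaiming (He) initialization for ReLU networks
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [(self.W, "dW"), (self.b, "db")]


class _BatchNorm:
    def __init__(self, dim: int):
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean += _BN_MOMENTUM * (mu - self.running_mean)
            self.running_var += _BN_MOMENTUM * (var - self.running_var)
            self._istd = 1.0 / np.sqrt(var + _BN_EPS)
            self._xc = x - mu
            self._xhat = self._xc * self._istd
            return self.gamma * self._xhat + self.beta
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + _BN_EPS)
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n = dy.shape[0]
        self.dgamma = (dy * self._xhat).sum(axis=0)
        self.dbeta = dy.sum(axis=0)
        dxhat = dy * self.gamma
        # standard batch-norm gradient
        dx = (self._istd / n) * (
            n * dxhat - dxhat.sum(axis=0)
            - self._xhat * (dxhat * self._xhat).sum(axis=0))
        return dx

    def params(self):
        return [(self.gamma, "dgamma"), (self.beta, "dbeta")]


class _ReLU:
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._mask = x > 0
            return x * self._mask
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask

    def params(self):
        return []


class _Dropout:
    """Inverted dropout: active only in training, identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self._rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.p == 0.0:
            return x
        self._mask = (self._rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.p == 0.0:
            return dy
        return dy * self._mask

    def params(self):
        return []


class _Stage:
    """linear -> batch norm -> ReLU -> dropout."""

    def __init__(self, d_in: int, d_out: int, p: float,
                 rng: np.random.Generator):
        self.layers = [_Linear(d_in, d_out, rng), _BatchNorm(d_out), _ReLU(),
                       _Dropout(p, rng)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        out = []
        for layer in self.layers:
            out.extend((layer, arr, grad) for arr, grad in layer.params())
        return out


class LiftingNetwork:
    """The residual fully-connected lifter."""

    def __init__(self, config: LiftingConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        w, p = config.hidden, config.dropout
        self.input_stage = _Stage(config.input_dim, w, p, rng)
        self.res_blocks = [
            [_Stage(w, w, p, rng), _Stage(w, w, p, rng)]
            for _ in range(config.blocks)
        ]
        self.output_layer = _Linear(w, config.output_dim, rng)
        self.trained = False

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = self.input_stage.forward(x, training)
        for block in self.res_blocks:
            skip = h
            for stage in block:
                h = stage.forward(h, training)
            h = h + skip
        return self.output_layer.forward(h, training)

    def backward(self, dy: np.ndarray) -> None:
        dh = self.output_layer.backward(dy)
        for block in reversed(self.res_blocks):
            dskip = dh
            for stage in reversed(block):
                dh = stage.backward(dh)
            dh = dh + dskip
        self.input_stage.backward(dh)

    def _param_triples(self):
        triples = list(self.input_stage.params())
        for block in self.res_blocks:
            for stage in block:
                triples.extend(stage.params())
        triples.extend((self.output_layer, arr, grad)
                       for arr, grad in self.output_layer.params())
        return triples

    @property
    def parameter_count(self) -> int:
        return sum(arr.size for _, arr, _ in self._param_triples())

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All learnable and running-statistic arrays, keyed stably."""
        out: dict[str, np.ndarray] = {}
        stages = [("in", self.input_stage)]
        for i, block in enumerate(self.res_blocks):
            for s, stage in enumerate(block):
                stages.append((f"b{i}s{s}", stage))
        for name, stage in stages:
            lin: _Linear = stage.layers[0]
            bn: _BatchNorm = stage.layers[1]
            out[f"{name}.W"] = lin.W
            out[f"{name}.b"] = lin.b
            out[f"{name}.gamma"] = bn.gamma
            out[f"{name}.beta"] = bn.beta
            out[f"{name}.rmean"] = bn.running_mean
            out[f"{name}.rvar"] = bn.running_var
        out["out.W"] = self.output_layer.W
        out["out.b"] = self.output_layer.b
        return out

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        for key, target in self.state_arrays().items():
            target[...] = arrays[key]


def build_model(config: LiftingConfig) -> LiftingNetwork:
    """Construct a Kaiming-initialized lifter for ``config``."""
    return LiftingNetwork(config)


# ---------------------------------------------------------------------------
# Training

class _Adam:
    def __init__(self, triples, beta1=0.9, beta2=0.999, eps=1e-8):
        self.triples = triples
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(arr) for _, arr, _ in triples]
        self.v = [np.zeros_like(arr) for _, arr, _ in triples]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (layer, arr, gname) in enumerate(self.triples):
            g = getattr(layer, gname)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            arr -= lr * mhat / (np.sqrt(vhat) + self.eps)


def train(model: LiftingNetwork, data: PoseBatch,
          config: LiftingConfig | None = None) -> list[float]:
    """Train the lifter on (2D, 3D) pairs; returns per-epoch mean MSE.

    Mini-batches are reshuffled every epoch; the learning rate is multiplied
    by ``lr_decay`` after each epoch.  The run is reproducible bit-for-bit
    given the config seed.  A non-finite loss aborts with
    :class:`DivergenceError` naming the epoch.
    """
    config = config or model.config
    if len(data) < 1:
        raise DataError("train: need at least one sample")
    if data.inputs.shape[1] != config.input_dim:
        raise DataError(
            f"train: input dim {data.inputs.shape[1]} != {config.input_dim}")
    if data.targets.shape[1] != config.output_dim:
        raise DataError(
            f"train: target dim {data.targets.shape[1]} != {config.output_dim}")

    rng = np.random.default_rng(config.seed + 1)   # shuffling stream
    optimizer = _Adam(model._param_triples())
    n = len(data)
    history: list[float] = []
    lr = config.learning_rate
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            x, y = data.inputs[idx], data.targets[idx]
            pred = model.forward(x, training=True)
            diff = pred - y
            loss = float(np.mean(diff * diff))
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            model.backward(2.0 * diff / diff.size)
            optimizer.step(lr)
            total += loss * len(idx)
        history.append(total / n)
        lr *= config.lr_decay
    model.trained = True
    return history


# ---------------------------------------------------------------------------
# Inference

def normalize_2d_frames(coords17: np.ndarray) -> np.ndarray:
    """Normalize frames x 17 x 2 keypoints to hip-centred, unit-scale inputs.

    Each frame is centred on the midpoint of the two hips and divided by the
    right-hip-to-right-shoulder distance, then flattened to R^{2n}.
    """
    centre = 0.5 * (coords17[:, _RHIP, :] + coords17[:, _LHIP, :])
    scale = np.linalg.norm(coords17[:, _RSHO, :] - coords17[:, _RHIP, :],
                           axis=1)
    if np.any(scale <= 0):
        raise DataError("normalize_2d_frames: degenerate hip-shoulder scale")
    out = (coords17 - centre[:, None, :]) / scale[:, None, None]
    return out.reshape(out.shape[0], -1)


def lift(model: LiftingNetwork, keypoints: KeypointSeries2D,
         skel_map: SkeletonMap) -> Pose3DSeries:
    """Lift a gap-free 2D keypoint series to a root-relative 3D pose series.

    Runs the network in inference mode (dropout off, batch norm using
    running statistics), one stateless map per frame.  Output coordinates
    are in normalized (hip-to-shoulder) units with the root pinned to the
    origin.
    """
    coords17, missing = canonical_2d(keypoints, skel_map)
    if missing.any() or not np.all(np.isfinite(coords17)):
        raise DataError("lift: keypoints contain gaps or NaNs; fill gaps "
                        "before lifting")
    n = model.config.n_joints
    if n != len(CANONICAL_JOINTS):
        raise DataError(f"lift: model expects n={n}, canonical skeleton has "
                        f"{len(CANONICAL_JOINTS)} joints")
    x = normalize_2d_frames(coords17)
    pred = model.forward(x, training=False)
    coords = pred.reshape(-1, n, 3)
    coords = coords - coords[:, :1, :]   # enforce root-relative output
    return Pose3DSeries(fps=keypoints.fps, coords=coords, root_relative=True)


# ---------------------------------------------------------------------------
# Checkpoints

def save_checkpoint(model: LiftingNetwork, path) -> None:
    """Save config and all weights/statistics in one ``.npz`` archive."""
    cfg = model.config
    meta = np.array([cfg.n_joints, cfg.hidden, cfg.blocks, cfg.epochs,
                     cfg.batch_size, cfg.seed], dtype=np.int64)
    hyper = np.array([cfg.dropout, cfg.learning_rate, cfg.lr_decay])
    np.savez(path, __meta__=meta, __hyper__=hyper,
             __trained__=np.array([int(model.trained)]),
             **model.state_arrays())


def load_checkpoint(path) -> LiftingNetwork:
    with np.load(path) as archive:
        meta = archive["__meta__"]
        hyper = archive["__hyper__"]
        config = LiftingConfig(
            n_joints=int(meta[0]), hidden=int(meta[1]), blocks=int(meta[2]),
            epochs=int(meta[3]), batch_size=int(meta[4]), seed=int(meta[5]),
            dropout=float(hyper[0]), learning_rate=float(hyper[1]),
            lr_decay=float(hyper[2]))
        model = LiftingNetwork(config)
        model.load_state({k: archive[k] for k in archive.files
                          if not k.startswith("__")})
        model.trained = bool(archive["__trained__"][0])
    return model
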