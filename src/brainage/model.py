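"""The 3D convolutional age regressor and its training protocol.

Training follows the published recipe: mean-absolute-error cost, stochastic
gradient descent with learning rate 0.001, momentum 0.1 and inverse-time
learning-rate decay 5e-5, batch size 8 for 150 iterations (epochs by
default), with on-the-fly translation/rotation augmentation, evaluated with
5-fold cross-validation.  The layer layout itself is a configurable
stand-in scaled to phantom resolution: four convolution blocks
(8-16-32-64 filters, 3^3 kernels) downsampling by stride 2, global average
pooling, a fixed feature gain and a linear scalar head in years.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import nn


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the age-regression training protocol."""

    learning_rate: float = 0.001
    momentum: float = 0.1
    lr_decay: float = 5e-5
    batch_size: int = 8
    iterations: int = 150
    iteration_unit: str = "epochs"  # "epochs" | "steps"
    folds: int = 5
    max_translation: float = 2.0    # voxels, per axis
    max_rotation: float = 10.0      # degrees, about a random axis
    loss: str = "mae"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.momentum, self.lr_decay,
               self.batch_size, self.iterations) <= 0:
            raise ValueError("training hyperparameters must be strictly positive")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.max_translation < 0 or self.max_rotation < 0:
            raise ValueError("augmentation magnitudes must be >= 0")
        if self.iteration_unit not in ("epochs", "steps"):
            raise ValueError("iteration_unit must be 'epochs' or 'steps'")
        if self.loss != "mae":
            raise ValueError("only the mean-absolute-error cost is supported")


@dataclass(frozen=True)
class ConvBlock:
    filters: int
    kernel: int = 3
    stride: int = 2
    pool: int = 1  # average-pool factor applied after activation (1 = none)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer plan: conv blocks, then global average pool -> gain -> linear scalar.

    ``feature_gain`` is a fixed multiplier on the pooled features; it sets
    the scale the regression head sees so that SGD at the protocol's small
    learning rate converges within the protocol's iteration budget.
    """

    conv_blocks: tuple[ConvBlock, ...] = (
        ConvBlock(8), ConvBlock(16), ConvBlock(32), ConvBlock(64),
    )
    activation: str = "relu"
    feature_gain: float = 8.0

    def __post_init__(self) -> None:
        if self.activation != "relu":
            raise ValueError("only ReLU activation is supported")
        if not self.conv_blocks:
            raise ValueError("at least one conv block is required")


class AgeModel:
    """The convolutional age regressor: architecture + weights + history."""

    def __init__(self, architecture: ArchitectureSpec | None = None, seed: int = 0) -> None:
        self.architecture = architecture or ArchitectureSpec()
        self.training_history: list[float] = []
        rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(7,)))
        layers: list[nn.Layer] = []
        c_in = 1
        for block in self.architecture.conv_blocks:
            layers.append(nn.Conv3d(c_in, block.filters, block.kernel, block.stride, rng=rng))
            layers.append(nn.ReLU())
            if block.pool > 1:
                layers.append(nn.AvgPool3d(block.pool))
            c_in = block.filters
        layers.append(nn.GlobalAvgPool())
        layers.append(nn.Scale(self.architecture.feature_gain))
        layers.append(nn.LinearHead(c_in, rng=rng))
        self.net = nn.Sequential(layers)

    @property
    def head(self) -> nn.LinearHead:
        return self.net.layers[-1]

    def predict(self, volumes: np.ndarray) -> np.ndarray:
        """Predict ages (years) for a batch of preprocessed volumes (N, D, H, W)."""
        x = np.asarray(volumes, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        return self.net.forward(x[:, None], train=False)

    # -- checkpointing ------------------------------------------------------

    def save(self, path: str) -> None:
        """Single-file checkpoint: architecture description + weights."""
        import json

        arch = {
            "conv_blocks": [
                [b.filters, b.kernel, b.stride, b.pool] for b in self.architecture.conv_blocks
            ],
            "activation": self.architecture.activation,
            "feature_gain": self.architecture.feature_gain,
        }
        params = {f"p{i}": p for i, p in enumerate(self.net.parameters)}
        np.savez(path, _architecture=json.dumps(arch),
                 _history=np.asarray(self.training_history), **params)

    @classmethod
    def load(cls, path: str) -> "AgeModel":
        import json

        data = np.load(path, allow_pickle=False)
        arch_d = json.loads(str(data["_architecture"]))
        arch = ArchitectureSpec(
            conv_blocks=tuple(ConvBlock(*b) for b in arch_d["conv_blocks"]),
            activation=arch_d["activation"],
            feature_gain=arch_d["feature_gain"],
        )
        model = cls(architecture=arch)
        for i, p in enumerate(model.net.parameters):
            p[...] = data[f"p{i}"]
        model.training_history = list(data["_history"])
        return model


# ---------------------------------------------------------------------------
# On-the-fly augmentation


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    theta = np.deg2rad(angle_deg)
    k = axis / np.linalg.norm(axis)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * (kx @ kx)


_GRID_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _voxel_grid(shape: tuple[int, int, int]) -> np.ndarray:
    if shape not in _GRID_CACHE:
        grids = np.meshgrid(*[np.arange(s, dtype=np.float32) for s in shape], indexing="ij")
        _GRID_CACHE[shape] = np.stack([g.ravel() for g in grids])  # (3, P)
    return _GRID_CACHE[shape]


try:  # optional fused kernel; the numpy path below is the reference
    from numba import njit as _njit

    @_njit(cache=True, fastmath=True)
    def _resample_kernel(vols, mats, offs, out):  # pragma: no cover - jitted
        b, d, h, w = vols.shape
        for n in range(b):
            m = mats[n]
            o = offs[n]
            for i in range(d):
                for j in range(h):
                    for k in range(w):
                        x = m[0, 0] * i + m[0, 1] * j + m[0, 2] * k + o[0]
                        y = m[1, 0] * i + m[1, 1] * j + m[1, 2] * k + o[1]
                        z = m[2, 0] * i + m[2, 1] * j + m[2, 2] * k + o[2]
                        if x < 0 or x > d - 1 or y < 0 or y > h - 1 or z < 0 or z > w - 1:
                            out[n, i, j, k] = 0.0
                            continue
                        x0 = min(int(x), d - 2)
                        y0 = min(int(y), h - 2)
                        z0 = min(int(z), w - 2)
                        fx, fy, fz = x - x0, y - y0, z - z0
                        v = vols[n]
                        c00 = v[x0, y0, z0] * (1 - fz) + v[x0, y0, z0 + 1] * fz
                        c01 = v[x0, y0 + 1, z0] * (1 - fz) + v[x0, y0 + 1, z0 + 1] * fz
                        c10 = v[x0 + 1, y0, z0] * (1 - fz) + v[x0 + 1, y0, z0 + 1] * fz
                        c11 = v[x0 + 1, y0 + 1, z0] * (1 - fz) + v[x0 + 1, y0 + 1, z0 + 1] * fz
                        c0 = c00 * (1 - fy) + c01 * fy
                        c1 = c10 * (1 - fy) + c11 * fy
                        out[n, i, j, k] = c0 * (1 - fx) + c1 * fx

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally present
    _HAVE_NUMBA = False


def _trilinear_resample_batch(
    volumes: np.ndarray, matrices: np.ndarray, offsets: np.ndarray
) -> np.ndarray:
    """Pull-back trilinear sampling for a batch (B, D, H, W).

    ``out[b](x) = volumes[b](matrices[b] @ x + offsets[b])``; coordinates
    outside the field of view sample 0.  One fused gather pass for the whole
    batch keeps on-the-fly augmentation cheap on a single CPU.
    """
    if _HAVE_NUMBA:
        out = np.empty_like(volumes)
        _resample_kernel(
            np.ascontiguousarray(volumes, dtype=np.float32),
            matrices.astype(np.float32),
            offsets.astype(np.float32),
            out,
        )
        return out
    b = volumes.shape[0]
    shape = volumes.shape[1:]
    grid = _voxel_grid(shape)  # (3, P)
    coords = np.einsum("bij,jp->bip", matrices.astype(np.float32), grid)
    coords += offsets.astype(np.float32)[:, :, None]  # (B, 3, P)
    valid = (
        (coords[:, 0] >= 0) & (coords[:, 0] <= shape[0] - 1)
        & (coords[:, 1] >= 0) & (coords[:, 1] <= shape[1] - 1)
        & (coords[:, 2] >= 0) & (coords[:, 2] <= shape[2] - 1)
    )
    i0 = np.floor(coords).astype(np.int64)
    np.clip(i0, 0, np.array(shape, dtype=np.int64)[None, :, None] - 2, out=i0)
    frac = (coords - i0).astype(np.float32)
    fx, fy, fz = frac[:, 0], frac[:, 1], frac[:, 2]
    sy, sz = shape[1] * shape[2], shape[2]
    vol_stride = shape[0] * sy
    base = i0[:, 0] * sy + i0[:, 1] * sz + i0[:, 2]
    base += (np.arange(b, dtype=np.int64) * vol_stride)[:, None]
    flat = volumes.reshape(-1)
    c000 = flat[base]
    c001 = flat[base + 1]
    c010 = flat[base + sz]
    c011 = flat[base + sz + 1]
    c100 = flat[base + sy]
    c101 = flat[base + sy + 1]
    c110 = flat[base + sy + sz]
    c111 = flat[base + sy + sz + 1]
    gz = 1 - fz
    c00 = c000 * gz + c001 * fz
    c01 = c010 * gz + c011 * fz
    c10 = c100 * gz + c101 * fz
    c11 = c110 * gz + c111 * fz
    gy = 1 - fy
    c0 = c00 * gy + c01 * fy
    c1 = c10 * gy + c11 * fy
    out = c0 * (1 - fx) + c1 * fx
    out[~valid] = 0.0
    return out.reshape(volumes.shape)


def _draw_rigid_params(
    rng: np.random.Generator, config: TrainingConfig, shape: tuple[int, int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """One random rigid transform in pull-back form (matrix, offset)."""
    center = (np.array(shape, dtype=np.float64) - 1) / 2.0
    if config.max_rotation > 0:
        axis = rng.normal(size=3)
        while np.linalg.norm(axis) < 1e-8:  # pragma: no cover - measure-zero draw
            axis = rng.normal(size=3)
        angle = rng.uniform(-config.max_rotation, config.max_rotation)
        rot = _rotation_matrix(axis, angle)
    else:
        rot = np.eye(3)
    shift = rng.uniform(-config.max_translation, config.max_translation, size=3)
    # Pull-back: x_in = R^T (x_out - center - shift) + center
    matrix = rot.T
    offset = center - matrix @ (center + shift)
    return matrix, offset


def augment_batch(volumes: np.ndarray, rng: np.random.Generator,
                  config: TrainingConfig) -> np.ndarray:
    """Independently augment each volume of a batch (B, D, H, W)."""
    if config.max_translation == 0 and config.max_rotation == 0:
        return volumes
    volumes = np.asarray(volumes, dtype=np.float32)
    shape = volumes.shape[1:]
    mats = np.empty((len(volumes), 3, 3))
    offs = np.empty((len(volumes), 3))
    for i in range(len(volumes)):
        mats[i], offs[i] = _draw_rigid_params(rng, config, shape)
    return _trilinear_resample_batch(volumes, mats, offs)


def augment(volume: np.ndarray, rng: np.random.Generator,
            config: TrainingConfig) -> np.ndarray:
    """Random rigid jitter: rotation <= max_rotation degrees about a random
    axis followed by a translation <= max_translation voxels per axis.

    Applied to intensity volumes only, on the fly, during training.  With
    both magnitudes zero this is the identity.
    """
    return augment_batch(np.asarray(volume, dtype=np.float32)[None], rng, config)[0]


# ---------------------------------------------------------------------------
# Training


def train(model: AgeModel, volumes: np.ndarray, ages: np.ndarray,
          config: TrainingConfig | None = None) -> AgeModel:
    """Fit the regressor by SGD on the mean absolute error, in place.

    ``volumes`` is (N, D, H, W), preprocessed; ``ages`` in years.  One
    iteration (default unit: epoch) is a full shuffled pass in batches of
    ``batch_size``, each batch augmented on the fly.  The per-iteration mean
    MAE is appended to ``model.training_history``.
    """
    config = config or TrainingConfig()
    volumes = np.asarray(volumes, dtype=np.float32)
    ages = np.asarray(ages, dtype=np.float32)
    n = len(volumes)
    if n < config.batch_size:
        raise ValueError(f"need at least batch_size={config.batch_size} subjects, got {n}")

    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(config.seed), spawn_key=(11,))
    )
    # A freshly initialized head predicts near zero; recentre its bias on the
    # training-age mean so early optimization works on the residual signal.
    if not model.training_history:
        model.head.params[1][0] = float(ages.mean())

    opt = nn.SGD(model.net, config.learning_rate, config.momentum, config.lr_decay)

    if config.iteration_unit == "epochs":
        n_epochs, steps_per_epoch = config.iterations, max(1, n // config.batch_size)
    else:
        n_epochs, steps_per_epoch = 1, config.iterations

    for _ in range(n_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for step in range(steps_per_epoch):
            take = order[(step * config.batch_size) % n:][: config.batch_size]
            if len(take) < config.batch_size:  # wrap around for step-unit runs
                take = np.concatenate([take, order[: config.batch_size - len(take)]])
            batch = augment_batch(volumes[take], rng, config)
            target = ages[take]
            pred = model.net.forward(batch[:, None], train=True)
            loss, dpred = nn.mae_loss(pred, target)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at optimizer step {opt.t} "
                    f"(lr={opt.current_lr:.2e}); check input scaling"
                )
            epoch_losses.append(loss)
            model.net.zero_grad()
            model.net.backward(dpred)
            opt.step()
            if config.iteration_unit == "steps":
                model.training_history.append(loss)
        if config.iteration_unit == "epochs":
            model.training_history.append(float(np.mean(epoch_losses)))
    return model


def predict_age(model: AgeModel, volume: np.ndarray) -> float:
    """Predicted age in years for one preprocessed volume."""
    pred = model.predict(volume)
    if not np.all(np.isfinite(pred)):
        raise RuntimeError("non-finite prediction")
    return float(pred[0])


def crossvalidate(
    volumes: np.ndarray,
    ages: np.ndarray,
    config: TrainingConfig | None = None,
    architecture: ArchitectureSpec | None = None,
    predictor_factory=None,
) -> list[float]:
    """K-fold cross-validation of the training protocol; returns fold MAEs.

    Fold assignment is a deterministic shuffle from ``config.seed``; every
    subject is out-of-fold exactly once.  ``predictor_factory`` may inject an
    alternative ``(train_volumes, train_ages) -> (volumes -> predictions)``
    trainer (used in tests to validate the fold bookkeeping in isolation).
    """
    config = config or TrainingConfig()
    volumes = np.asarray(volumes, dtype=np.float32)
    ages = np.asarray(ages, dtype=np.float64)
    n = len(volumes)
    if n < config.folds * config.batch_size:
        raise ValueError(
            f"need at least folds*batch_size={config.folds * config.batch_size} subjects, got {n}"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(config.seed), spawn_key=(13,))
    )
    order = rng.permutation(n)
    folds = np.array_split(order, config.folds)

    if predictor_factory is None:
        def predictor_factory(train_v, train_a, fold_seed):
            m = AgeModel(architecture, seed=fold_seed)
            train(m, train_v, train_a, replace(config, seed=fold_seed))
            return m.predict

    maes = []
    for k, hold in enumerate(folds):
        fit = np.concatenate([f for i, f in enumerate(folds) if i != k])
        try:
            predictor = predictor_factory(volumes[fit], ages[fit], config.seed + k)
        except TypeError:
            predictor = predictor_factory(volumes[fit], ages[fit])
        preds = np.asarray(predictor(volumes[hold]), dtype=np.float64)
        maes.append(float(np.mean(np.abs(preds - ages[hold]))))
    return maes
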