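"""The hybrid CNN-LSTM BMI regressor.

Architecture: the six inertial channels are split into an accelerometer and a
gyroscope branch (``two_branch_acc_gyro``, default). Each branch stacks three
blocks of 2-D convolution (rectangular kernels running along time) -> ReLU ->
batch normalization (momentum 0.99, eps 0.001) -> max pooling. The pooled
maps keep their time axis; channel and space axes are flattened per time step
and the branches concatenated, giving the sequence a stacked LSTM consumes.
A dense head with dropout and L2 regularization ends in a single linear unit,
trained with mean-squared-error loss.

The public surface follows the model/results idiom: build a
:class:`CNNLSTMRegressor` from windows and labels, call ``fit()``, and work
with the returned :class:`CNNLSTMResults` (``predict``, ``history``,
``summary``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from . import nn
from .core import Window

ArrayLike = Union[np.ndarray, Sequence[Window]]


def windows_to_tensor(windows: ArrayLike) -> np.ndarray:
    """Stack windows into an (N, 6, w) float tensor."""
    if isinstance(windows, np.ndarray):
        x = np.asarray(windows, dtype=float)
        if x.ndim != 3 or x.shape[1] != 6:
            raise ValueError(f"expected (N, 6, w) tensor, got {x.shape}")
        return x
    if len(windows) == 0:
        return np.empty((0, 6, 0))
    return np.stack([np.asarray(w.data, dtype=float) for w in windows])


@dataclass(frozen=True)
class ModelConfig:
    """Complete description of the hybrid network and its training loop.

    Training defaults follow the grid-search optima of the original design
    space (Adam, learning rate 0.001, 200 epochs, batch 20, dropout 0.5, L2);
    architectural defaults (feature maps, rectangular kernel sizes, LSTM and
    dense widths) are this package's choices, exposed here because no method
    result should hinge on them.
    """

    branch_mode: str = "two_branch_acc_gyro"
    conv_feature_maps: tuple = (32, 64, 64)
    conv_kernels: tuple = ((1, 9), (1, 7), (1, 5))
    pool_sizes: tuple = ((1, 2), (1, 2), (1, 2))
    lstm_units: tuple = (64, 64)
    dense_units: tuple = (64,)
    dropout_rate: float = 0.5
    l2_strength: float = 1e-4
    optimizer: str = "adam"
    learning_rate: float = 0.001
    epochs: int = 200
    batch_size: int = 20
    seed: int = 0
    bn_momentum: float = 0.99
    bn_eps: float = 1e-3

    def __post_init__(self):
        if self.branch_mode not in ("two_branch_acc_gyro", "single_branch"):
            raise ValueError(f"unknown branch_mode {self.branch_mode!r}")
        n = len(self.conv_feature_maps)
        if not (len(self.conv_kernels) == len(self.pool_sizes) == n) or n < 1:
            raise ValueError("conv stack specs must align and be non-empty")
        if self.optimizer not in nn.OPTIMIZERS:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        for name in ("dropout_rate",):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("learning_rate, epochs, batch_size must be positive")
        if min(self.lstm_units) < 1 or (
            self.dense_units and min(self.dense_units) < 1
        ):
            raise ValueError("layer widths must be positive")

    @classmethod
    def desk_profile(cls, **overrides) -> "ModelConfig":
        """Lightweight profile sized for laptop-scale experiments and tests."""
        params = dict(
            conv_feature_maps=(8, 16, 16),
            lstm_units=(32,),
            dense_units=(32,),
            dropout_rate=0.2,
            epochs=12,
            batch_size=64,
            learning_rate=0.003,
        )
        params.update(overrides)
        return cls(**params)


class _Branch:
    """One conv stack ending in a time-preserving flatten."""

    def __init__(self, cfg: ModelConfig, in_height: int, in_width: int, rng):
        self.layers: list[nn.Layer] = []
        c, h, w = 1, in_height, in_width
        for fm, (kh, kw), (ph, pw) in zip(
            cfg.conv_feature_maps, cfg.conv_kernels, cfg.pool_sizes
        ):
            if h < kh or w < kw:
                raise ValueError(
                    f"conv kernel ({kh},{kw}) does not fit input plane "
                    f"({h},{w}); shrink kernels or pools"
                )
            self.layers.append(
                nn.Conv2D(
                    c, fm, kh, kw, rng, skip_input_grad=len(self.layers) == 0
                )
            )
            h, w = h - kh + 1, w - kw + 1
            self.layers.append(nn.ReLU())
            self.layers.append(nn.BatchNorm2D(fm, cfg.bn_momentum, cfg.bn_eps))
            if h // ph < 1 or w // pw < 1:
                raise ValueError(
                    f"pool ({ph},{pw}) collapses plane ({h},{w}); "
                    "shrink pools or use a longer window"
                )
            self.layers.append(nn.MaxPool2D(ph, pw))
            c, h, w = fm, h // ph, w // pw
        self.layers.append(nn.TimeFlatten())
        self.out_time = w
        self.out_features = c * h

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class _Network:
    """Branches -> merge -> LSTM stack -> dense head -> linear unit."""

    def __init__(self, cfg: ModelConfig, window_len: int, rng):
        self.cfg = cfg
        if cfg.branch_mode == "two_branch_acc_gyro":
            self.splits = [(0, 3), (3, 6)]
        else:
            self.splits = [(0, 6)]
        self.branches = [
            _Branch(cfg, hi - lo, window_len, rng) for lo, hi in self.splits
        ]
        times = {b.out_time for b in self.branches}
        assert len(times) == 1
        feat = sum(b.out_features for b in self.branches)
        self.head: list[nn.Layer] = []
        for li, units in enumerate(cfg.lstm_units):
            last = li == len(cfg.lstm_units) - 1
            self.head.append(nn.LSTM(feat, units, rng, return_sequences=not last))
            feat = units
        for units in cfg.dense_units:
            self.head.append(nn.Dense(feat, units, rng))
            self.head.append(nn.ReLU())
            self.head.append(nn.Dropout(cfg.dropout_rate))
            feat = units
        self.head.append(nn.Dense(feat, 1, rng))
        self._branch_feat = [b.out_features for b in self.branches]

    @property
    def all_layers(self) -> list[nn.Layer]:
        return [l for b in self.branches for l in b.layers] + self.head

    @property
    def n_parameters(self) -> int:
        return sum(l.n_parameters for l in self.all_layers)

    def set_dropout_rng(self, rng):
        for layer in self.head:
            if isinstance(layer, nn.Dropout):
                layer.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        outs = []
        for (lo, hi), branch in zip(self.splits, self.branches):
            xb = x[:, None, lo:hi, :]  # (N, 1, height, time)
            outs.append(branch.forward(xb, train))
        h = np.concatenate(outs, axis=2) if len(outs) > 1 else outs[0]
        for layer in self.head:
            h = layer.forward(h, train)
        return h[:, 0]

    def backward(self, gout: np.ndarray) -> None:
        g = gout[:, None]
        for layer in reversed(self.head):
            g = layer.backward(g)
        offset = 0
        for feat, branch in zip(self._branch_feat, self.branches):
            branch.backward(g[:, :, offset : offset + feat])
            offset += feat


class CNNLSTMRegressor:
    """Hybrid CNN-LSTM model of per-window BMI.

    Parameters
    ----------
    windows : sequence of Window or (N, 6, w) array
        Training windows (normalize them first; the model takes them as-is).
    labels : array-like
        One BMI value per window.
    config : ModelConfig, optional
        Architecture and training hyper-parameters.
    """

    def __init__(
        self,
        windows: ArrayLike,
        labels,
        config: Optional[ModelConfig] = None,
    ):
        self.x = windows_to_tensor(windows)
        self.y = np.asarray(labels, dtype=float)
        if self.x.shape[0] != self.y.shape[0]:
            raise ValueError("windows and labels disagree in length")
        if self.x.shape[0] < 1:
            raise ValueError("need at least one training window")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("labels must be finite")
        self.config = config or ModelConfig()

    def fit(
        self,
        val_windows: Optional[ArrayLike] = None,
        val_labels=None,
        verbose: bool = False,
    ) -> "CNNLSTMResults":
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
        net = _Network(cfg, self.x.shape[2], rng)
        net.set_dropout_rng(rng)
        # standardize labels for optimization; constants stored for inference
        y_mean = float(self.y.mean())
        y_std = float(self.y.std())
        if y_std == 0.0:
            y_std = 1.0
        yz = (self.y - y_mean) / y_std
        opt = nn.OPTIMIZERS[cfg.optimizer](
            net.all_layers, cfg.learning_rate, cfg.l2_strength
        )
        n = self.x.shape[0]
        x32 = self.x.astype(np.float32)
        xv = yv = None
        if val_windows is not None:
            xv = windows_to_tensor(val_windows).astype(np.float32)
            yv = np.asarray(val_labels, dtype=float)
        history = []
        for epoch in range(1, cfg.epochs + 1):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                if len(idx) < 2:
                    continue  # batch-norm needs at least two samples
                pred = net.forward(x32[idx], train=True)
                err = pred.astype(float) - yz[idx]
                loss = float(np.mean(err**2))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged: non-finite loss at epoch {epoch} "
                        f"(lr={cfg.learning_rate}, optimizer={cfg.optimizer})"
                    )
                net.backward((2.0 * err / len(idx)).astype(np.float32))
                opt.step()
                losses.append(loss)
            rec = {"epoch": epoch, "loss": float(np.mean(losses))}
            if xv is not None and len(xv):
                pv = _predict_net(net, xv) * y_std + y_mean
                rec["val_mae"] = float(np.mean(np.abs(pv - yv)))
            history.append(rec)
            if verbose:  # pragma: no cover
                print(rec)
        return CNNLSTMResults(self, net, y_mean, y_std, history)


def _predict_net(net: _Network, x: np.ndarray, batch: int = 256) -> np.ndarray:
    outs = [
        net.forward(x[i : i + batch], train=False)
        for i in range(0, x.shape[0], batch)
    ]
    return np.concatenate(outs) if outs else np.empty(0)


class CNNLSTMResults:
    """Fitted CNN-LSTM: predictions, training history, parameter summary."""

    def __init__(self, model, net, y_mean, y_std, history):
        self.model = model
        self.config = model.config
        self._net = net
        self.y_mean = y_mean
        self.y_std = y_std
        self.history = history

    @property
    def n_parameters(self) -> int:
        return self._net.n_parameters

    def predict(self, windows: ArrayLike) -> np.ndarray:
        x = windows_to_tensor(windows)
        if x.shape[0] == 0:
            return np.empty(0)
        if x.shape[2] != self.model.x.shape[2]:
            raise ValueError(
                f"window length {x.shape[2]} does not match the fitted "
                f"model's {self.model.x.shape[2]}"
            )
        return (
            _predict_net(self._net, x.astype(np.float32)).astype(float)
            * self.y_std
            + self.y_mean
        )

    def save(self, path_prefix: str) -> None:
        """Write a checkpoint: ``<prefix>.npz`` weights + ``<prefix>.json`` sidecar."""
        import dataclasses
        import json

        arrays = {}
        for i, layer in enumerate(self._net.all_layers):
            for j, p in enumerate(layer.params):
                arrays[f"p_{i}_{j}"] = p
            if isinstance(layer, nn.BatchNorm2D):
                arrays[f"rm_{i}"] = layer.running_mean
                arrays[f"rv_{i}"] = layer.running_var
        np.savez(path_prefix + ".npz", **arrays)
        sidecar = {
            "format": "motionbmi-model-v1",
            "config": dataclasses.asdict(self.config),
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "window_len": int(self.model.x.shape[2]),
            "history": self.history,
        }
        with open(path_prefix + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path_prefix: str) -> "CNNLSTMResults":
        import json

        with open(path_prefix + ".json") as fh:
            sidecar = json.load(fh)
        if sidecar.get("format") != "motionbmi-model-v1":
            raise ValueError("unrecognized model checkpoint format")
        cfg_dict = sidecar["config"]
        for key in ("conv_feature_maps", "lstm_units", "dense_units"):
            cfg_dict[key] = tuple(cfg_dict[key])
        for key in ("conv_kernels", "pool_sizes"):
            cfg_dict[key] = tuple(tuple(v) for v in cfg_dict[key])
        cfg = ModelConfig(**cfg_dict)
        window_len = sidecar["window_len"]
        model = CNNLSTMRegressor(
            np.zeros((1, 6, window_len)), np.zeros(1), cfg
        )
        net = _Network(cfg, window_len, np.random.default_rng(0))
        data = np.load(path_prefix + ".npz")
        for i, layer in enumerate(net.all_layers):
            for j in range(len(layer.params)):
                layer.params[j][...] = data[f"p_{i}_{j}"]
            if isinstance(layer, nn.BatchNorm2D):
                layer.running_mean = data[f"rm_{i}"]
                layer.running_var = data[f"rv_{i}"]
        return cls(
            model, net, sidecar["y_mean"], sidecar["y_std"], sidecar["history"]
        )

    def plot_history(self, ax=None):  # pragma: no cover - thin plotting shim
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot([h["epoch"] for h in self.history], [h["loss"] for h in self.history])
        ax.set_xlabel("epoch")
        ax.set_ylabel("training MSE (standardized)")
        return ax

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "CNN-LSTM BMI regressor",
            "=" * 40,
            f"branches:        {cfg.branch_mode}",
            f"conv stack:      maps {cfg.conv_feature_maps}, "
            f"kernels {cfg.conv_kernels}, pools {cfg.pool_sizes}",
            f"lstm stack:      {cfg.lstm_units}",
            f"dense head:      {cfg.dense_units} (dropout {cfg.dropout_rate})",
            f"parameters:      {self.n_parameters}",
            f"optimizer:       {cfg.optimizer} (lr {cfg.learning_rate}, "
            f"L2 {cfg.l2_strength})",
            f"epochs x batch:  {cfg.epochs} x {cfg.batch_size}",
            f"final train MSE: {self.history[-1]['loss']:.4f} (standardized)",
            f"label scaling:   mean {self.y_mean:.3f}, sd {self.y_std:.3f}",
        ]
        return "\n".join(lines)


def build_model(
    cfg: ModelConfig, window_shape: tuple[int, int]
) -> CNNLSTMRegressor:
    """Assemble an untrained model for a (channels, length) window shape.

    Provided for shape-checking and parameter counting without data; the
    returned model holds a single dummy window.
    """
    channels, length = window_shape
    if channels != 6:
        raise ValueError("window shape must have 6 channels")
    dummy = np.zeros((1, 6, length))
    model = CNNLSTMRegressor(dummy, np.zeros(1), cfg)
    # fail fast on impossible shape arithmetic
    _Network(cfg, length, np.random.default_rng(0))
    return model


def grid_search(
    cfg_space,
    train_windows: ArrayLike,
    train_labels,
    val_windows: ArrayLike,
    val_labels,
) -> tuple[ModelConfig, list[dict]]:
    """Exhaustive search over a config space; minimal validation MAE wins.

    ``cfg_space`` is either an iterable of ModelConfig or a
    ``(base_config, {field: [values, ...]})`` pair expanded as a Cartesian
    product. Ties break toward the earlier grid point. Returns the winning
    config and an audit log with one entry per candidate.
    """
    if isinstance(cfg_space, tuple) and len(cfg_space) == 2:
        base, axes = cfg_space
        keys = list(axes)
        configs = [
            replace(base, **dict(zip(keys, combo)))
            for combo in itertools.product(*(axes[k] for k in keys))
        ]
    else:
        configs = list(cfg_space)
    if not configs:
        raise ValueError("empty hyper-parameter search space")
    yv = np.asarray(val_labels, dtype=float)
    audit = []
    best_cfg, best_mae = None, np.inf
    for cfg in configs:
        try:
            res = CNNLSTMRegressor(train_windows, train_labels, cfg).fit()
            pred = res.predict(val_windows)
            mae = float(np.mean(np.abs(pred - yv)))
        except RuntimeError as exc:  # divergence counts as a failed candidate
            audit.append({"config": cfg, "val_mae": float("inf"), "error": str(exc)})
            continue
        audit.append({"config": cfg, "val_mae": mae})
        if mae < best_mae:
            best_cfg, best_mae = cfg, mae
    if best_cfg is None:
        raise RuntimeError("every grid candidate diverged")
    return best_cfg, audit
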