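"""Dense autoencoders for straightened-vessel ROI compression.

Three reference architectures share an input of 35,014 values (the row-major
flattened 854 x 41 ROI) and halve the layer width toward the bottleneck:

* AE256: 35014 -> 512 -> 256 -> 512 -> 35014
* AE128: 35014 -> 512 -> 256 -> 128 -> 256 -> 512 -> 35014
* AE64:  35014 -> 512 -> 256 -> 128 -> 64 -> 128 -> 256 -> 512 -> 35014

Hidden layers are ReLU, the bottleneck is linear (so the latent code keeps its
full range), and the output is sigmoid, matching inputs normalized to [0, 1].
Training minimizes the mean squared reconstruction error with Adam
(default max 300 epochs, batch size 48). The implementation is plain numpy
with manual backpropagation — the models are small dense stacks and CPU
training at reduced scale is the test path — and is exactly reproducible for
a given seed.

Reconstruction quality is scored with SSIM (Gaussian window, sigma 1.5,
11 x 11, data range 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

__all__ = [
    "AEConfig",
    "TrainConfig",
    "DenseAutoencoder",
    "architecture",
    "count_params",
    "ssim",
    "ARCHITECTURES",
]

#: Encoder hidden widths (excluding the latent layer) per named architecture.
ARCHITECTURES: dict[str, tuple[tuple[int, ...], int]] = {
    "AE256": ((512,), 256),
    "AE128": ((512, 256), 128),
    "AE64": ((512, 256, 128), 64),
}


@dataclass(frozen=True)
class AEConfig:
    """Architecture of a mirrored dense autoencoder."""

    input_dim: int = 35014
    encoder_widths: tuple[int, ...] = (512, 256, 128)
    latent_dim: int = 64

    def __post_init__(self) -> None:
        widths = (self.input_dim, *self.encoder_widths, self.latent_dim)
        if any(b >= a for a, b in zip(widths, widths[1:])):
            raise ValueError(
                "layer widths must strictly decrease toward the latent layer: "
                f"{widths}"
            )

    @property
    def layer_widths(self) -> tuple[int, ...]:
        """Full layer sequence: encoder, latent, mirrored decoder."""
        enc = (self.input_dim, *self.encoder_widths, self.latent_dim)
        return enc + enc[-2::-1]

    @property
    def n_encoder_layers(self) -> int:
        return len(self.encoder_widths) + 1


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam on the mean squared reconstruction error)."""

    max_epochs: int = 300
    batch_size: int = 48
    learning_rate: float = 0.001
    seed: int = 0
    validation_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("max_epochs and batch_size must be >= 1")
        if not (0.0 <= self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in [0, 1)")


def architecture(name: str, input_dim: int = 35014) -> AEConfig:
    """One of the three named architectures (AE64 / AE128 / AE256)."""
    try:
        widths, latent = ARCHITECTURES[name]
    except KeyError:
        raise ValueError(f"unknown architecture {name!r}") from None
    return AEConfig(input_dim=input_dim, encoder_widths=widths, latent_dim=latent)


def count_params(config: AEConfig | str, scope: str = "encoder") -> int:
    """Number of trainable parameters: sum over affine layers of fan_in*fan_out + fan_out.

    ``scope="encoder"`` counts the input -> ... -> latent half only (the
    convention of the reference parameter table); ``scope="full"`` counts the
    whole mirrored network.
    """
    if isinstance(config, str):
        config = architecture(config)
    widths = config.layer_widths
    if scope == "encoder":
        widths = widths[: config.n_encoder_layers + 1]
    elif scope != "full":
        raise ValueError("scope must be 'encoder' or 'full'")
    return int(sum(a * b + b for a, b in zip(widths, widths[1:])))


def _activations(config: AEConfig) -> list[str]:
    n_aff = len(config.layer_widths) - 1
    acts = ["relu"] * n_aff
    acts[config.n_encoder_layers - 1] = "linear"  # bottleneck
    acts[-1] = "sigmoid"
    return acts


class DenseAutoencoder:
    """Mirrored dense autoencoder with manual backprop, trained with Adam."""

    def __init__(self, config: AEConfig, seed: int = 0):
        self.config = config
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
        self._acts = _activations(config)
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        widths = config.layer_widths
        for fan_in, fan_out in zip(widths, widths[1:]):
            # Glorot-uniform initialization, seeded
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.weights.append(
                rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(np.float64)
            )
            self.biases.append(np.zeros(fan_out))

    # -- forward/backward -------------------------------------------------

    @staticmethod
    def _apply(act: str, z: np.ndarray) -> np.ndarray:
        if act == "relu":
            return np.maximum(z, 0.0)
        if act == "sigmoid":
            return 1.0 / (1.0 + np.exp(-z))
        return z

    def _forward(self, x: np.ndarray) -> list[np.ndarray]:
        outs = [x]
        h = x
        for w, b, act in zip(self.weights, self.biases, self._acts):
            h = self._apply(act, h @ w + b)
            outs.append(h)
        return outs

    def _backward(
        self, outs: list[np.ndarray]
    ) -> list[tuple[np.ndarray, np.ndarray]]:
        x, xhat = outs[0], outs[-1]
        n = x.shape[0]
        # d MSE / d xhat, averaged over batch and features
        delta = 2.0 * (xhat - x) / (n * x.shape[1])
        grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(self.weights)  # type: ignore
        for layer in range(len(self.weights) - 1, -1, -1):
            h = outs[layer + 1]
            act = self._acts[layer]
            if act == "sigmoid":
                delta = delta * h * (1.0 - h)
            elif act == "relu":
                delta = delta * (h > 0)
            grads[layer] = (outs[layer].T @ delta, delta.sum(axis=0))
            if layer:
                delta = delta @ self.weights[layer].T
        return grads

    # -- public API --------------------------------------------------------

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        self._check_dim(x)
        return self._forward(x)[-1]

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Latent code(s); deterministic, named ae_0..ae_{latent_dim-1} downstream."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        self._check_dim(x)
        h = x
        for layer in range(self.config.n_encoder_layers):
            h = self._apply(self._acts[layer], h @ self.weights[layer] + self.biases[layer])
        return h

    def loss(self, x: np.ndarray) -> float:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return float(np.mean((self.reconstruct(x) - x) ** 2))

    def _check_dim(self, x: np.ndarray) -> None:
        if x.shape[1] != self.config.input_dim:
            raise ValueError(
                f"input has {x.shape[1]} values, model expects {self.config.input_dim}"
            )

    def fit(self, x: np.ndarray, tc: TrainConfig) -> "DenseAutoencoder":
        """Train in place on rows of ``x`` (values in [0, 1]); returns self."""
        x = np.asarray(x, dtype=float)
        self._check_dim(np.atleast_2d(x))
        if x.shape[0] < 2 * tc.batch_size:
            raise ValueError(
                f"need >= {2 * tc.batch_size} images (2 x batch_size), got {x.shape[0]}"
            )
        rng = np.random.default_rng(tc.seed)
        n_val = int(round(tc.validation_fraction * x.shape[0]))
        order = rng.permutation(x.shape[0])
        x_val, x_tr = x[order[:n_val]], x[order[n_val:]]

        m = [np.zeros_like(w) for w in self.weights] + [
            np.zeros_like(b) for b in self.biases
        ]
        v = [np.zeros_like(g) for g in m]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        n_layers = len(self.weights)
        for epoch in range(tc.max_epochs):
            perm = rng.permutation(x_tr.shape[0])
            epoch_loss = 0.0
            for start in range(0, x_tr.shape[0], tc.batch_size):
                batch = x_tr[perm[start : start + tc.batch_size]]
                outs = self._forward(batch)
                batch_loss = float(np.mean((outs[-1] - batch) ** 2))
                if not np.isfinite(batch_loss):
                    raise RuntimeError(
                        f"loss became non-finite at epoch {epoch}; "
                        "reduce the learning rate"
                    )
                epoch_loss += batch_loss * batch.shape[0]
                grads = self._backward(outs)
                t += 1
                params = self.weights + self.biases
                gs = [g for g, _ in grads] + [g for _, g in grads]
                for k, (p, g) in enumerate(zip(params, gs)):
                    m[k] = beta1 * m[k] + (1 - beta1) * g
                    v[k] = beta2 * v[k] + (1 - beta2) * g * g
                    mhat = m[k] / (1 - beta1**t)
                    vhat = v[k] / (1 - beta2**t)
                    p -= tc.learning_rate * mhat / (np.sqrt(vhat) + eps)
            self.history["train_loss"].append(epoch_loss / x_tr.shape[0])
            self.history["val_loss"].append(
                self.loss(x_val) if n_val else float("nan")
            )
        return self

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        arrays = {f"w{k}": w for k, w in enumerate(self.weights)}
        arrays.update({f"b{k}": b for k, b in enumerate(self.biases)})
        np.savez(
            path,
            encoder_widths=np.array(self.config.encoder_widths),
            input_dim=self.config.input_dim,
            latent_dim=self.config.latent_dim,
            train_loss=np.array(self.history["train_loss"]),
            val_loss=np.array(self.history["val_loss"]),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "DenseAutoencoder":
        data = np.load(path)
        config = AEConfig(
            input_dim=int(data["input_dim"]),
            encoder_widths=tuple(int(w) for w in data["encoder_widths"]),
            latent_dim=int(data["latent_dim"]),
        )
        model = cls(config)
        model.weights = [data[f"w{k}"] for k in range(len(model.weights))]
        model.biases = [data[f"b{k}"] for k in range(len(model.biases))]
        model.history = {
            "train_loss": list(data["train_loss"]),
            "val_loss": list(data["val_loss"]),
        }
        return model


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Structural similarity of two [0, 1] images (Gaussian window, sigma 1.5).

    Scores lie in [-1, 1]; 1 means identical structure.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(
        structural_similarity(
            a, b, data_range=1.0, gaussian_weights=True, sigma=1.5, win_size=11
        )
    )
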