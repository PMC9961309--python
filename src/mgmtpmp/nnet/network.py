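"""The DLRFE network: a compact CNN whose FC-layer activations are the features.

Architecture (input 64x64 grayscale, zero-center normalized):

====  =========================================  ==============  ==========
 #    layer                                      activations     learnables
====  =========================================  ==============  ==========
 1    Conv 64@3x3 'same' + ReLU                  64 x 64 x 64       640
 2    MaxPool 2x2 /2                             32 x 32 x 64         0
 3    Conv 128@3x3 'same' + ReLU                 32 x 32 x 128     73,856
 4    MaxPool 2x2 /2                             16 x 16 x 128        0
 5    BatchNorm                                  16 x 16 x 128       256
 6    Conv 256@3x3 'valid' + ReLU                14 x 14 x 256    295,168
 7    MaxPool 2x2 /2                              7 x 7 x 256         0
 8    Dropout 20%                                 7 x 7 x 256         0
 9    Flatten                                    12,544               0
10    FC1 (512)                                  512            6,423,040
11    FC2 (64)                                   64                32,832
12    FC3 (2) + softmax                          2                    130
====  =========================================  ==============  ==========

Total learnables: 6,825,922.  Conv-3 uses VALID padding: that is the only
choice consistent with the 16x16 -> 14x14 activation drop and with FC1's
512 x 12,544 weight matrix (12,544 = 7*7*256).  FC1 and FC2 carry no
nonlinearity; their raw linear outputs are the latent features
("feature bleeding"): x_latent = [x_FC1 | x_FC2], 512 + 64 = 576 values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .layers import F32, BatchNorm, Conv2D, Dense, Dropout, Flatten, MaxPool2, ReLU


class ArchitectureError(RuntimeError):
    """Raised when a network spec does not reproduce its declared shape chain."""


#: the canonical activation-shape chain, one entry per named stage
CANONICAL_CHAIN = [
    ("conv1", (64, 64, 64)),
    ("pool1", (32, 32, 64)),
    ("conv2", (32, 32, 128)),
    ("pool2", (16, 16, 128)),
    ("conv3", (14, 14, 256)),
    ("pool3", (7, 7, 256)),
    ("flatten", 12544),
    ("fc1", 512),
    ("fc2", 64),
    ("fc3", 2),
]


@dataclass
class NetworkSpec:
    input_side: int = 64
    conv_filters: tuple = (64, 128, 256)
    conv_paddings: tuple = ("same", "same", "valid")
    kernel: int = 3
    fc_widths: tuple = (512, 64, 2)
    dropout_rate: float = 0.2
    expected_chain: list = field(default_factory=lambda: list(CANONICAL_CHAIN))

    @property
    def n_classes(self) -> int:
        return self.fc_widths[-1]

    def to_dict(self) -> dict:
        return {
            "input_side": self.input_side,
            "conv_filters": list(self.conv_filters),
            "conv_paddings": list(self.conv_paddings),
            "kernel": self.kernel,
            "fc_widths": list(self.fc_widths),
            "dropout_rate": self.dropout_rate,
            "expected_chain": [[n, s if isinstance(s, int) else list(s)]
                               for n, s in self.expected_chain],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        chain = [(n, s if isinstance(s, int) else tuple(s)) for n, s in d["expected_chain"]]
        return cls(
            input_side=d["input_side"],
            conv_filters=tuple(d["conv_filters"]),
            conv_paddings=tuple(d["conv_paddings"]),
            kernel=d["kernel"],
            fc_widths=tuple(d["fc_widths"]),
            dropout_rate=d["dropout_rate"],
            expected_chain=chain,
        )


@dataclass
class LatentFeatures:
    """FC1/FC2 activations of one image and their fixed-order concatenation."""

    x_fc1: np.ndarray
    x_fc2: np.ndarray

    @property
    def x_latent(self) -> np.ndarray:
        return np.concatenate([self.x_fc1, self.x_fc2])


class DLRFENetwork:
    """The CNN plus bookkeeping: named stages, training history, mean image."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        k = spec.kernel
        f1, f2, f3 = spec.conv_filters
        p1, p2, p3 = spec.conv_paddings
        w1, w2, w3 = spec.fc_widths

        stages: list[tuple[str, object]] = [
            ("conv1", Conv2D(1, f1, k, p1, rng=rng)),
            ("relu1", ReLU()),
            ("pool1", MaxPool2()),
            ("conv2", Conv2D(f1, f2, k, p2, rng=rng)),
            ("relu2", ReLU()),
            ("pool2", MaxPool2()),
            ("bn2", BatchNorm(f2)),
            ("conv3", Conv2D(f2, f3, k, p3, rng=rng)),
            ("relu3", ReLU()),
            ("pool3", MaxPool2()),
            ("drop3", Dropout(spec.dropout_rate)),
            ("flatten", Flatten()),
        ]
        flat_dim = self._infer_conv_chain(stages, spec)
        stages += [
            ("fc1", Dense(flat_dim, w1, rng=rng)),
            ("fc2", Dense(w1, w2, rng=rng)),
            ("fc3", Dense(w2, w3, rng=rng)),
        ]
        self.stages = stages
        self.layers = dict(stages)
        self._validate_chain()

        self.mean_image = np.zeros((spec.input_side, spec.input_side), dtype=F32)
        self.history: list[dict] = []

    # -- construction-time shape validation -------------------------------

    @staticmethod
    def _infer_conv_chain(stages, spec) -> int:
        shape = (spec.input_side, spec.input_side, 1)
        for _, layer in stages:
            shape = layer.out_shape(shape)
        return shape

    def shape_chain(self) -> list:
        """(name, activation shape) for the named stages of the chain."""
        shape = (self.spec.input_side, self.spec.input_side, 1)
        chain = []
        reported = {"conv1", "pool1", "conv2", "pool2", "conv3", "pool3",
                    "flatten", "fc1", "fc2", "fc3"}
        for name, layer in self.stages:
            shape = layer.out_shape(shape)
            if name in reported:
                chain.append((name, shape))
        return chain

    def _validate_chain(self) -> None:
        actual = dict(self.shape_chain())
        for name, expected in self.spec.expected_chain:
            if actual.get(name) != expected:
                raise ArchitectureError(
                    f"layer {name!r}: expected activations {expected}, "
                    f"got {actual.get(name)}"
                )

    def param_count(self) -> int:
        return sum(
            int(np.prod(p.shape))
            for _, layer in self.stages
            for p in layer.params.values()
        )

    # -- forward / backward -----------------------------------------------

    def _prepare(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=F32)
        if x.ndim == 2:
            x = x[None]
        side = self.spec.input_side
        if x.shape[1:] != (side, side):
            raise ValueError(
                f"expected {side}x{side} input images, got {x.shape[1:]}"
            )
        return (x - self.mean_image)[..., None]

    def forward(self, images, *, train=False, rng=None, capture=False):
        """Run the network; returns logits, or (logits, {'fc1','fc2'}) if capturing."""
        x = self._prepare(images)
        captured = {}
        for name, layer in self.stages:
            x = layer.forward(x, train=train, rng=rng)
            if capture and name in ("fc1", "fc2"):
                captured[name] = x.copy()
        return (x, captured) if capture else x

    def backward(self, dlogits):
        dy = dlogits
        for _, layer in reversed(self.stages):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        """Yield (stage-name, param-name, array, grad-array)."""
        for name, layer in self.stages:
            for key in layer.params:
                yield name, key, layer.params[key], layer.grads[key]

    # -- latent feature harvesting ----------------------------------------

    def extract_latent(self, image: np.ndarray) -> LatentFeatures:
        """Harvest FC1/FC2 activations for one image (inference mode).

        A pure function of (network parameters, image): batch-norm uses its
        running statistics and dropout is disabled.
        """
        _, cap = self.forward(image, train=False, capture=True)
        return LatentFeatures(x_fc1=cap["fc1"][0], x_fc2=cap["fc2"][0])

    def extract_latent_batch(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """(n, 576) latent matrix for a stack of images, in FC1|FC2 order."""
        chunks = []
        for start in range(0, len(images), batch_size):
            _, cap = self.forward(images[start : start + batch_size],
                                  train=False, capture=True)
            chunks.append(np.concatenate([cap["fc1"], cap["fc2"]], axis=1))
        return np.concatenate(chunks, axis=0)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {"mean_image": self.mean_image}
        for sname, pname, param, _ in self.parameters():
            arrays[f"{sname}.{pname}"] = param
        for name, layer in self.stages:
            if isinstance(layer, BatchNorm):
                arrays[f"{name}.running_mean"] = layer.running_mean
                arrays[f"{name}.running_var"] = layer.running_var
        np.savez(
            path,
            spec=json.dumps(self.to_meta()),
            **arrays,
        )

    def to_meta(self) -> dict:
        return {"spec": self.spec.to_dict(), "seed": self.seed, "history": self.history}

    @classmethod
    def load(cls, path: str | Path) -> "DLRFENetwork":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["spec"]))
            net = cls(NetworkSpec.from_dict(meta["spec"]), seed=meta["seed"])
            net.history = meta["history"]
            net.mean_image = data["mean_image"]
            for sname, pname, param, _ in net.parameters():
                param[...] = data[f"{sname}.{pname}"]
            for name, layer in net.stages:
                if isinstance(layer, BatchNorm):
                    layer.running_mean = data[f"{name}.running_mean"]
                    layer.running_var = data[f"{name}.running_var"]
        return net


def build_network(spec: NetworkSpec | None = None, seed: int = 0) -> DLRFENetwork:
    """Construct an untrained DLRFE network, validating its shape chain."""
    return DLRFENetwork(spec or NetworkSpec(), seed=seed)
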