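"""Training the DLRFE network: softmax cross-entropy + SGD with momentum.

The published training recipe is kept verbatim: SGDM with momentum 0.99,
initial learning rate 1e-4, mini-batches of 16, L2 regularization 1e-4 and
cross-entropy loss; 5 epochs is the operating point (latent features bled
at low epoch counts generalize best), up to 50 supported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .layers import F32
from .network import DLRFENetwork

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class TrainingConfig:
    momentum: float = 0.99
    learning_rate: float = 1e-4
    epochs: int = 5
    batch_size: int = 16
    l2: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.momentum < 1):
            raise ValueError("momentum must be in [0, 1)")
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.l2 < 0:
            raise ValueError("learning rate and batch size must be positive, l2 >= 0")
        if not (0 <= self.epochs <= 50):
            raise ValueError("epochs must be in [0, 50]")


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    """Normalized exponential P_k = e^{O_k} / sum_m e^{O_m}, max-shifted."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_loss(target: np.ndarray, predicted: np.ndarray) -> float:
    """L(t, p) = -sum_x t(x) log p(x) for a one-hot target.

    A predicted probability of exactly 0 at the target class is clamped by a
    small epsilon (and logged) so the loss stays finite.
    """
    t = np.asarray(target, dtype=np.float64)
    p = np.asarray(predicted, dtype=np.float64)
    if t.shape != p.shape:
        raise ValueError("target and prediction must have the same shape")
    if np.any(p[t > 0] == 0):
        logger.warning("predicted probability 0 at target class; clamping by %g", _EPS)
    return float(-(t * np.log(np.maximum(p, _EPS))).sum())


def batch_cost(labels: np.ndarray, probs: np.ndarray) -> float:
    """Mean negative log-likelihood -(1/J) sum_j ln p(t_j | x_j)."""
    p_target = probs[np.arange(len(labels)), labels]
    return float(-np.log(np.maximum(p_target, _EPS)).mean())


class SGDM:
    """Classical momentum: v <- mu*v - eta*(grad + lambda*W); W <- W + v.

    L2 regularization applies to weight matrices only (not to biases or
    batch-norm scale/offset), the usual convention.
    """

    def __init__(self, net: DLRFENetwork, cfg: TrainingConfig):
        self.cfg = cfg
        self.velocity = {
            (sname, pname): np.zeros_like(param)
            for sname, pname, param, _ in net.parameters()
        }

    def step(self, net: DLRFENetwork) -> None:
        mu, eta, lam = self.cfg.momentum, self.cfg.learning_rate, self.cfg.l2
        for sname, pname, param, grad in net.parameters():
            if not np.all(np.isfinite(grad)):
                raise FloatingPointError(
                    f"non-finite gradient in {sname}.{pname} "
                    f"(|grad|_max={np.abs(grad[np.isfinite(grad)]).max(initial=0):.3g})"
                )
            g = grad.astype(np.float64)
            if lam and param.ndim > 1:
                g = g + lam * param
            v = self.velocity[(sname, pname)]
            v[...] = (mu * v - eta * g).astype(F32)
            param += v


def train_network(
    net: DLRFENetwork,
    images: np.ndarray,
    labels: np.ndarray,
    cfg: TrainingConfig | None = None,
) -> DLRFENetwork:
    """Train in place with seeded shuffled mini-batches; returns the network.

    The input layer's zero-center normalization (mean image subtracted from
    every input) is fit here from the training set.  The per-epoch history
    records mean batch cost and training accuracy.  With ``epochs=0`` the
    initialized network is returned untouched, history empty.
    """
    cfg = cfg or TrainingConfig()
    images = np.asarray(images)
    labels = np.asarray(labels, dtype=np.int64)
    if len(images) == 0:
        raise ValueError("training set is empty")
    classes = np.unique(labels)
    if len(classes) < net.spec.n_classes:
        raise ValueError(
            f"training set covers classes {classes.tolist()} but the network "
            f"has {net.spec.n_classes} output classes"
        )
    net.mean_image = images.astype(F32).mean(axis=0)
    rng = np.random.default_rng(cfg.seed)
    opt = SGDM(net, cfg)
    n = len(images)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = images[idx], labels[idx]
            logits = net.forward(xb, train=True, rng=rng)
            probs = softmax_probs(logits)
            losses.append(batch_cost(yb, probs))
            correct += int((probs.argmax(axis=1) == yb).sum())
            dlogits = (probs - np.eye(net.spec.n_classes)[yb]) / len(yb)
            net.backward(dlogits.astype(F32))
            opt.step(net)
        entry = {
            "epoch": epoch + 1,
            "loss": float(np.mean(losses)),
            "accuracy": correct / n,
        }
        net.history.append(entry)
        logger.info("epoch %d: cost %.4f, train accuracy %.4f",
                    entry["epoch"], entry["loss"], entry["accuracy"])
    return net
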