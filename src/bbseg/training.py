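"""Optimization: equal-weighted binary cross-entropy + mean absolute error.

The class head is trained with binary cross-entropy, the distance head
with mean absolute error on raw pixel-unit targets in [0, d_max]; the two
terms are summed with equal (1:1) weighting.  MAE rather than MSE keeps
the gradient informative near small distances, which is where the
watershed valleys live.  The optimizer is Adam with learning rate 0.001
by default and no schedule: the only training knob is the presentation
budget T = round(E*F*M).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import DualHeadCNN, _sigmoid
from .params import ParamSet
from .sampling import SampleDraw, dihedral

_EPS = 1e-7


def bce(class_label, p) -> float:
    """Mean binary cross-entropy of probabilities ``p`` against 0/1 labels."""
    p = np.clip(np.asarray(p, dtype=np.float64), _EPS, 1.0 - _EPS)
    y = np.asarray(class_label, dtype=np.float64)
    return float(np.mean(-y * np.log(p) - (1.0 - y) * np.log(1.0 - p)))


def mae(dist_label, dist_pred) -> float:
    """Mean absolute error of the distance output, in pixels."""
    return float(
        np.mean(np.abs(np.asarray(dist_label, float) - np.asarray(dist_pred, float)))
    )


def loss(p, dist_pred, class_label, dist_label) -> float:
    """Combined training loss: BCE + MAE with equal weighting."""
    return bce(class_label, p) + mae(dist_label, dist_pred)


@dataclass
class TrainLog:
    """Per-interval loss trace plus final budget accounting."""

    steps: int = 0  # sample presentations completed
    records: list[dict] = field(default_factory=list)

    def log(self, step, combined, class_loss, dist_loss):
        self.records.append(
            {
                "step": int(step),
                "loss": float(combined),
                "class_loss": float(class_loss),
                "dist_loss": float(dist_loss),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    @property
    def final_loss(self) -> float:
        return self.records[-1]["loss"] if self.records else float("nan")

    @property
    def initial_loss(self) -> float:
        return self.records[0]["loss"] if self.records else float("nan")


class Adam:
    """Plain Adam (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for k, p in params.items():
            gk = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * gk
            self.v[k] = b2 * self.v[k] + (1 - b2) * gk * gk
            mhat = self.m[k] / corr1
            vhat = self.v[k] / corr2
            p -= (self.lr * mhat / (np.sqrt(vhat) + eps)).astype(p.dtype)


def fit(
    net: DualHeadCNN,
    draw: SampleDraw,
    params: ParamSet,
    rng: np.random.Generator,
    log_every: int = 20,
) -> TrainLog:
    """Train on a pixel draw for exactly T = round(E*F*M) presentations.

    Each pass over the draw is a fresh seeded shuffle; the final partial
    pass is truncated so the presentation count matches the budget exactly.
    One optimizer update is taken per mini-batch.  With augmentation on,
    every presentation sees an independently drawn symmetry of the square
    applied to its patch stack (class and distance targets are invariant
    under these symmetries).
    """
    n = len(draw)
    if n == 0:
        raise ValueError("empty sample stream")
    T = draw.budget.T
    opt = Adam(net.params, lr=params.learning_rate)
    log = TrainLog()
    batch = params.batch_size
    done = 0
    interval = {"n": 0, "bce": 0.0, "mae": 0.0}
    batches_seen = 0
    while done < T:
        order = rng.permutation(n)
        for start in range(0, n, batch):
            if done >= T:
                break
            idx = order[start : start + batch]
            if done + len(idx) > T:
                idx = idx[: T - done]
            x = draw.stacks(idx)
            if params.augment:
                ks = rng.integers(0, 8, size=len(idx))
                for i, k in enumerate(ks):
                    if k:
                        x[i] = dihedral(x[i], int(k))
            y = draw.class_label[idx].astype(np.float64)
            d = draw.dist_label[idx].astype(np.float64)
            logit, dist, cache = net.forward(x, keep_cache=True)
            p = _sigmoid(logit)
            m = float(len(idx))
            # d(BCE)/dlogit = (p - y)/m ; d(MAE)/ddist = sign(dist - d)/m
            dlogit = ((p - y) / m).astype(net.dtype)
            ddist = (np.sign(dist - d) / m).astype(net.dtype)
            grads = net.backward(dlogit, ddist, cache)
            opt.step(net.params, grads)
            done += len(idx)
            interval["n"] += 1
            interval["bce"] += bce(y, p)
            interval["mae"] += mae(d, dist)
            batches_seen += 1
            if batches_seen % log_every == 0 or done >= T:
                nb = interval["n"]
                log.log(
                    done,
                    (interval["bce"] + interval["mae"]) / nb,
                    interval["bce"] / nb,
                    interval["mae"] / nb,
                )
                interval = {"n": 0, "bce": 0.0, "mae": 0.0}
    log.steps = done
    return log
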