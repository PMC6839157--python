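"""Training protocol: SGDM optimization, stratified splitting, k-fold
cross-validation, the mini-batch loop and mask prediction.

The optimizer is stochastic gradient descent with momentum in its
two-point form

    theta_{l+1} = theta_l - lr * grad E(theta_l) + momentum * (theta_l - theta_{l-1})

with defaults lr = 0.001, momentum = 0.9, batch size 5 and a fixed stop
at 150 epochs (no schedule, no early stopping).  Data are split
60/20/20 into train/validation/test with per-class stratification
(validation and test each get round(0.2 n) items), and model selection
is followed by 5-fold cross-validation on the merged train+test pool.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .engine import TRAINABLE_KEYS, forward, loss_and_gradients
from .graph import LayerGraph

__all__ = [
    "TrainConfig",
    "SplitPlan",
    "LossTrace",
    "sgdm_step",
    "stratified_split",
    "kfold_split",
    "train",
    "predict_mask",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    momentum: float = 0.9
    batch_size: int = 5
    max_epochs: int = 150
    dropout: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must be in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass(frozen=True)
class SplitPlan:
    train: tuple[int, ...]
    val: tuple[int, ...]
    test: tuple[int, ...]
    labels: tuple


@dataclass
class LossTrace:
    """(iteration, mini-batch loss) pairs, iterations strictly increasing."""

    iterations: list[int] = field(default_factory=list)
    losses: list[float] = field(default_factory=list)

    def append(self, iteration: int, loss: float) -> None:
        if self.iterations and iteration <= self.iterations[-1]:
            raise ValueError("iterations must be strictly increasing")
        self.iterations.append(iteration)
        self.losses.append(loss)


def sgdm_step(theta, theta_prev, gradient, cfg: TrainConfig):
    """One SGDM update on a single parameter array (or scalar).

    The first step passes theta_prev = theta, reducing to plain gradient
    descent; momentum = 0 recovers plain gradient descent throughout.
    """
    theta = np.asarray(theta, dtype=float)
    theta_prev = np.asarray(theta_prev, dtype=float)
    gradient = np.asarray(gradient, dtype=float)
    if theta.shape != theta_prev.shape or theta.shape != gradient.shape:
        raise ValueError(
            f"shape mismatch: theta {theta.shape}, theta_prev {theta_prev.shape}, "
            f"gradient {gradient.shape}"
        )
    return theta - cfg.learning_rate * gradient + cfg.momentum * (theta - theta_prev)


# ---------------------------------------------------------------------------
# data splitting

def _largest_remainder_alloc(class_sizes: dict, fraction: float, target: int) -> dict:
    """Per-class counts with floors + largest remainders, summing to target."""
    base = {c: math.floor(fraction * n) for c, n in class_sizes.items()}
    remainders = sorted(
        class_sizes,
        key=lambda c: (fraction * class_sizes[c]) % 1.0,
        reverse=True,
    )
    short = target - sum(base.values())
    for c in remainders:
        if short == 0:
            break
        if base[c] < class_sizes[c]:
            base[c] += 1
            short -= 1
    return base


def stratified_split(
    labels, fractions: tuple[float, float, float] = (0.6, 0.2, 0.2), seed: int = 0
) -> SplitPlan:
    """Seeded stratified train/validation/test split.

    Validation and test sizes are round(f * n); train takes the
    remainder — the rule that maps n = 387 to (233, 77, 77) and n = 163
    to (97, 33, 33).  Each class is represented in each subset within
    one item of its global proportion.
    """
    labels = list(labels)
    n = len(labels)
    if n < 5:
        raise ValueError(f"need at least 5 items, got {n}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    classes: dict = {}
    for i, lab in enumerate(labels):
        classes.setdefault(lab, []).append(i)
    for lab, idx in classes.items():
        if len(idx) < 3:
            warnings.warn(
                f"class {lab!r} has only {len(idx)} items; stratification is best-effort",
                stacklevel=2,
            )
    rng = np.random.default_rng(seed)
    for idx in classes.values():
        rng.shuffle(idx)
    sizes = {lab: len(idx) for lab, idx in classes.items()}
    n_val = round(fractions[1] * n)
    n_test = round(fractions[2] * n)
    val_alloc = _largest_remainder_alloc(sizes, fractions[1], n_val)
    # allocate test from what remains of each class
    remaining = {lab: sizes[lab] - val_alloc[lab] for lab in sizes}
    test_alloc = _largest_remainder_alloc(remaining, n_test / max(sum(remaining.values()), 1), n_test)
    val, test, trainset = [], [], []
    for lab, idx in classes.items():
        k1 = val_alloc[lab]
        k2 = test_alloc[lab]
        val.extend(idx[:k1])
        test.extend(idx[k1 : k1 + k2])
        trainset.extend(idx[k1 + k2 :])
    return SplitPlan(
        train=tuple(sorted(trainset)),
        val=tuple(sorted(val)),
        test=tuple(sorted(test)),
        labels=tuple(labels),
    )


def kfold_split(indices, k: int = 5, seed: int = 0, labels=None):
    """Seeded k-fold partition of ``indices`` into (train, test) pairs.

    Folds are disjoint, differ in size by at most one, and cover all
    indices.  When ``labels`` is given the folds are stratified: each
    class is dealt round-robin so its items spread evenly over folds.
    """
    indices = list(indices)
    n = len(indices)
    if n < k:
        raise ValueError(f"need at least k={k} items, got {n}")
    rng = np.random.default_rng(seed)
    folds: list[list] = [[] for _ in range(k)]
    if labels is None:
        order = list(range(n))
        rng.shuffle(order)
        groups = [order]
    else:
        labels = list(labels)
        if len(labels) != n:
            raise ValueError("labels must match indices in length")
        by_class: dict = {}
        for pos, lab in enumerate(labels):
            by_class.setdefault(lab, []).append(pos)
        groups = []
        for lab in sorted(by_class, key=str):
            idx = by_class[lab]
            rng.shuffle(idx)
            groups.append(idx)
    fold_i = 0
    for group in groups:
        for pos in group:
            folds[fold_i].append(indices[pos])
            fold_i = (fold_i + 1) % k
    out = []
    for i in range(k):
        test = sorted(folds[i])
        train = sorted(x for j, f in enumerate(folds) if j != i for x in f)
        out.append((train, test))
    return out


# ---------------------------------------------------------------------------
# training loop

def _as_arrays(dataset):
    images = np.stack([np.asarray(item[0], dtype=np.float64) for item in dataset])
    masks = np.stack([np.asarray(item[1]) for item in dataset]).astype(np.int64)
    if images.shape[1:] != masks.shape[1:]:
        raise ValueError(
            f"image/mask shape mismatch: {images.shape[1:]} vs {masks.shape[1:]}"
        )
    return images, masks


def train(
    g: LayerGraph,
    params: dict,
    dataset,
    cfg: TrainConfig = TrainConfig(),
) -> tuple[dict, LossTrace]:
    """Mini-batch SGDM training of a layer graph.

    ``dataset`` is a sequence of (image, mask[, label]) items whose
    sides match the graph input.  The batch order is reshuffled every
    epoch with a seed derived from ``cfg.seed``; dropout masks are drawn
    from the same stream, so identical seeds and data give identical
    traces and parameters.  Aborts on a non-finite loss.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    images, masks = _as_arrays(dataset)
    prev = {
        name: {k: v.copy() for k, v in p.items() if k in TRAINABLE_KEYS}
        for name, p in params.items()
    }
    trace = LossTrace()
    iteration = 0
    n = len(images)
    for epoch in range(cfg.max_epochs):
        epoch_rng = np.random.default_rng((cfg.seed, epoch))
        order = epoch_rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            iteration += 1
            loss, grads = loss_and_gradients(
                g, params, images[batch], masks[batch], rng=epoch_rng
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite mini-batch loss at iteration {iteration}"
                )
            trace.append(iteration, loss)
            for name, pg in grads.items():
                for key, grad in pg.items():
                    theta = params[name][key]
                    new = (
                        theta
                        - cfg.learning_rate * grad
                        + cfg.momentum * (theta - prev[name][key])
                    ).astype(theta.dtype)
                    prev[name][key] = theta
                    params[name][key] = new
    return params, trace


def predict_mask(g: LayerGraph, params: dict, image: np.ndarray) -> np.ndarray:
    """Segment one image: per-pixel argmax over the two softmax
    channels, ties resolved to background (label 0)."""
    image = np.asarray(image)
    probs = forward(g, params, image[None])
    return (probs[0, 1] > probs[0, 0]).astype(np.uint8)
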