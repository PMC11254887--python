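"""U-Net ROI segmentation: input-stack construction, augmentation, the
four-fold rotation scheme, training, prediction and fold aggregation.

The four input channels are the four 15-second frames of the 2-3 minute
window (frames 9-12) — the minute the GFR computation uses — each upsampled
to the network grid and jointly normalised to [0,1] by the stack maximum.
A ``channel_mode="summed"`` option replicates the summed window instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .core import DynamicRenogram, RoiSet
from .nn import Adam, UNet, bce_logit_grad, soft_dice, soft_dice_grad

__all__ = [
    "TrainConfig",
    "AugmentRanges",
    "FoldPlan",
    "SegModel",
    "build_input_stack",
    "soft_dice_loss",
    "augment",
    "make_fold_plan",
    "train",
    "predict_roiset",
    "aggregate_folds",
    "roiset_to_labels",
]

_CHANNELS = ("kidney_left", "kidney_right", "bg_left", "bg_right")


@dataclass(frozen=True)
class AugmentRanges:
    translate_px: float = 4.0
    rotate_deg: float = 10.0
    scale: float = 0.1
    shear_deg: float = 5.0


@dataclass(frozen=True)
class TrainConfig:
    input_size: int = 256
    in_channels: int = 4
    out_channels: int = 4
    learning_rate: float = 1e-5
    epochs: int = 30
    batch_size: int = 8
    folds: int = 4
    seed: int = 0
    base_filters: int = 32
    levels: int = 4
    channel_mode: str = "frames"  # or "summed"
    augment: bool = False
    augment_ranges: AugmentRanges = field(default_factory=AugmentRanges)
    window_frames: tuple[int, int] = (9, 12)
    dice_epsilon: float = 1.0
    # weight of a small cross-entropy gradient added to the Dice gradient;
    # rescues sigmoid channels that saturate early (Dice gradient vanishes)
    bce_stabilizer: float = 0.05

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.input_size % 2 ** (self.levels - 1) != 0:
            raise ValueError("input_size must be divisible by 2**(levels-1)")


@dataclass
class FoldPlan:
    assignment: np.ndarray  # fold index per scan
    rotations: list[tuple[np.ndarray, np.ndarray]]  # (train_idx, test_idx)

    @property
    def folds(self) -> int:
        return len(self.rotations)


@dataclass
class SegModel:
    """A trained network plus its architecture descriptor and training log."""

    net: UNet
    descriptor: dict
    loss_history: list[float]

    def save(self, path) -> None:
        self.net.save(path)

    @classmethod
    def load(cls, path) -> "SegModel":
        net = UNet.load(path)
        return cls(net=net, descriptor=net.descriptor(), loss_history=[])


def soft_dice_loss(pred: np.ndarray, truth: np.ndarray, epsilon: float = 1.0) -> float:
    """Public soft-Dice loss (see :func:`splitgfr.nn.soft_dice`)."""
    pred = np.asarray(pred, dtype=float)
    if pred.min() < 0 or pred.max() > 1:
        raise ValueError("pred must hold probabilities in [0, 1]")
    return soft_dice(pred, truth, epsilon)


def build_input_stack(scan: DynamicRenogram, config: TrainConfig = TrainConfig()) -> np.ndarray:
    """(4, S, S) float32 network input from the window frames of a scan."""
    lo, hi = config.window_frames
    if scan.n_frames < hi:
        raise ValueError(f"scan has {scan.n_frames} frames; need >= {hi}")
    frames = scan.counts[lo - 1 : hi].astype(np.float64)
    if config.channel_mode == "summed":
        frames = np.repeat(frames.sum(axis=0, keepdims=True), config.in_channels, axis=0)
    elif config.channel_mode != "frames":
        raise ValueError(f"unknown channel_mode {config.channel_mode!r}")
    s = config.input_size
    if frames.shape[1] != s:
        frames = np.stack(
            [
                resize(f, (s, s), order=1, mode="edge", anti_aliasing=False, preserve_range=True)
                for f in frames
            ]
        )
    peak = frames.max()
    if peak <= 0:
        warnings.warn("all-zero input stack; returning zeros", stacklevel=2)
        return np.zeros((frames.shape[0], s, s), dtype=np.float32)
    return (frames / peak).astype(np.float32)


def roiset_to_labels(rois: RoiSet, input_size: int) -> np.ndarray:
    """(4, S, S) binary label stack, nearest-neighbour upsampled from 64x64."""
    out = []
    for name in _CHANNELS:
        m = rois.masks()[name]
        if m.shape[0] != input_size:
            factor = input_size / m.shape[0]
            if input_size % m.shape[0] == 0:
                m = np.kron(m, np.ones((int(factor), int(factor)), dtype=bool))
            else:
                m = resize(m.astype(float), (input_size, input_size), order=0, preserve_range=True) > 0.5
        out.append(m)
    return np.stack(out).astype(np.float32)


def labels_to_roiset(labels: np.ndarray, raw_size: int = 64) -> tuple[RoiSet, dict[str, bool]]:
    """Downsample a (4, S, S) binary stack to the raw grid by block-max."""
    s = labels.shape[-1]
    if s % raw_size != 0 and raw_size % s != 0:
        raise ValueError(f"label grid {s} incommensurate with raw grid {raw_size}")
    masks = {}
    flags = {}
    for i, name in enumerate(_CHANNELS):
        m = labels[i].astype(bool)
        if s > raw_size:
            k = s // raw_size
            m = m.reshape(raw_size, k, raw_size, k).any(axis=(1, 3))
        elif s < raw_size:
            m = np.kron(m, np.ones((raw_size // s, raw_size // s), dtype=bool))
        masks[name] = m
        flags[name] = not m.any()
    rois = RoiSet(
        masks["kidney_left"], masks["kidney_right"], masks["bg_left"], masks["bg_right"],
        provenance="deep-learning",
    )
    return rois, flags


def _affine_params(ranges: AugmentRanges, rng: np.random.Generator):
    t = rng.uniform(-ranges.translate_px, ranges.translate_px, size=2)
    rot = np.radians(rng.uniform(-ranges.rotate_deg, ranges.rotate_deg))
    sc = 1.0 + rng.uniform(-ranges.scale, ranges.scale)
    sh = np.radians(rng.uniform(-ranges.shear_deg, ranges.shear_deg))
    return t, rot, sc, sh


def augment(
    input_stack: np.ndarray,
    masks: np.ndarray,
    ranges: AugmentRanges = AugmentRanges(),
    seed: int = 0,
    max_retries: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random affine transform identically to inputs and labels.

    Masks are interpolated linearly and re-binarised at 0.5.  A draw that
    pushes any originally non-empty mask entirely off-grid is rejected and
    redrawn (bounded retries).
    """
    rng = np.random.default_rng(seed)
    size = input_stack.shape[-1]
    center = (size - 1) / 2.0
    nonempty = [i for i in range(masks.shape[0]) if masks[i].any()]

    for _ in range(max_retries):
        t, rot, sc, sh = _affine_params(ranges, rng)
        rotm = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        shear = np.array([[1.0, np.tan(sh)], [0.0, 1.0]])
        fwd = sc * rotm @ shear
        inv = np.linalg.inv(fwd)
        # output coord o maps back to input coord inv @ (o - center - t) + center
        offset = center - inv @ (np.full(2, center) + t)

        out_stack = np.stack(
            [ndimage.affine_transform(ch, inv, offset=offset, order=1, mode="constant") for ch in input_stack]
        ).astype(input_stack.dtype)
        out_masks = np.stack(
            [
                ndimage.affine_transform(m.astype(float), inv, offset=offset, order=1, mode="constant") >= 0.5
                for m in masks
            ]
        ).astype(masks.dtype)
        if all(out_masks[i].any() for i in nonempty):
            return out_stack, out_masks
    raise RuntimeError("augmentation kept pushing masks off-grid; widen the field or shrink ranges")


def make_fold_plan(n_scans: int, folds: int = 4, seed: int = 0) -> FoldPlan:
    """Random near-equal partition into folds; rotation r tests fold r."""
    if n_scans < folds:
        raise ValueError(f"need at least {folds} scans, got {n_scans}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_scans)
    assignment = np.empty(n_scans, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, folds)):
        assignment[chunk] = f
    rotations = []
    for f in range(folds):
        test = np.flatnonzero(assignment == f)
        train_idx = np.flatnonzero(assignment != f)
        rotations.append((train_idx, test))
    return FoldPlan(assignment=assignment, rotations=rotations)


def _train_one(
    stacks: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig,
    seed: int,
) -> SegModel:
    net = UNet(
        in_ch=config.in_channels,
        out_ch=config.out_channels,
        base=config.base_filters,
        levels=config.levels,
        seed=seed,
    )
    opt = Adam(net, lr=config.learning_rate)
    rng = np.random.default_rng(seed + 1)
    n = len(stacks)
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = stacks[idx], labels[idx]
            if config.augment:
                aug = [
                    augment(xb[i], yb[i], config.augment_ranges, seed=int(rng.integers(2**31)))
                    for i in range(len(idx))
                ]
                xb = np.stack([a[0] for a in aug])
                yb = np.stack([a[1] for a in aug])
            p = net.forward(xb, train=True)
            loss = soft_dice(p, yb, config.dice_epsilon)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            dz = config.bce_stabilizer * bce_logit_grad(p, yb) if config.bce_stabilizer else None
            net.backward(soft_dice_grad(p, yb, config.dice_epsilon), dloss_dz=dz)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return SegModel(net=net, descriptor=net.descriptor(), loss_history=history)


def train(
    dataset: Sequence[tuple[np.ndarray, np.ndarray]],
    plan: FoldPlan,
    config: TrainConfig = TrainConfig(),
) -> list[SegModel]:
    """Train one model per rotation, each on its own training folds only.

    ``dataset`` holds (input_stack, label_stack) pairs on the network grid.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    stacks = np.stack([d[0] for d in dataset]).astype(np.float32)
    labels = np.stack([d[1] for d in dataset]).astype(np.float32)
    models = []
    for r, (train_idx, test_idx) in enumerate(plan.rotations):
        if len(train_idx) == 0:
            raise ValueError(f"rotation {r} has an empty training fold")
        if np.intersect1d(train_idx, test_idx).size:
            raise ValueError(f"rotation {r} leaks test scans into training")
        models.append(_train_one(stacks[train_idx], labels[train_idx], config, seed=config.seed + r))
    return models


def predict_roiset(model: SegModel, stack: np.ndarray, raw_size: int = 64) -> tuple[RoiSet, dict[str, bool]]:
    """Threshold the sigmoid outputs at 0.5 and map channels to the ROI set.

    Returns the 64x64 ROI set (block-max downsampled) plus per-structure
    emptiness flags; empty masks are a valid, flagged outcome.
    """
    p = model.net.forward(stack[None], train=False)[0]
    binary = (p > 0.5).astype(np.float32)
    return labels_to_roiset(binary, raw_size)


def aggregate_folds(
    per_rotation: Sequence[dict[int, object]],
    expected_ids: Sequence[int],
) -> dict[int, object]:
    """Pool per-rotation test-fold predictions into one prediction per scan."""
    pooled: dict[int, object] = {}
    for preds in per_rotation:
        for scan_id, value in preds.items():
            if scan_id in pooled:
                raise ValueError(f"scan {scan_id} predicted by more than one rotation")
            pooled[scan_id] = value
    missing = set(expected_ids) - set(pooled)
    if missing:
        raise ValueError(f"no prediction for scans: {sorted(missing)}")
    return pooled
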