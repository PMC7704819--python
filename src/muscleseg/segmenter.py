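"""Slice-wise U-net segmentation of the four thigh muscle groups.

The network takes the preprocessed water and fat images as two input
channels, each independently min-max normalized to [0, 1] per volume, and
is trained in 2D on axial slices. Training minimizes categorical
cross-entropy over {background, ROI1..ROI4} (a per-ROI sigmoid/BCE head is
selectable). Prediction squashes each ROI score map to (0,1), binarizes at
a threshold (default 0.5, strict inequality), resolves multi-label pixels
by the highest score, and restacks slices into a label volume.

Training runs on the CPU in pure NumPy (see :mod:`muscleseg.nn`); the
default architecture (depth 3, 16 base filters) is sized for desk-scale
64 x 64 slices, with depth/width configurable up to full-resolution scans.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np

from . import nn
from .volumes import FatWaterVolume, MuscleLabelVolume

__all__ = [
    "UnetConfig",
    "SliceSample",
    "TrainedModel",
    "normalize_channels",
    "make_slice_dataset",
    "build_unet",
    "train",
    "predict_volume",
    "save_model",
    "load_model",
]


@dataclass
class UnetConfig:
    depth: int = 3
    base_filters: int = 16
    in_channels: int = 2
    out_channels: int = 4  # ROI score maps; softmax head adds a background map
    head: str = "softmax"  # "softmax" (categorical CE) or "sigmoid" (per-ROI BCE)
    norm: str = "none"  # "none" or "group" (group norm after each conv)
    batch_size: int = 6
    epochs: int = 1000
    learning_rate: float = 1e-6
    lr_schedule: str = "constant"  # "constant" or "cosine" decay per epoch
    min_lr_fraction: float = 0.05  # floor of the cosine decay
    binarize_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if not 0.0 < self.binarize_threshold < 1.0:
            raise ValueError("binarize_threshold must be in (0,1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.head not in ("softmax", "sigmoid"):
            raise ValueError("head must be 'softmax' or 'sigmoid'")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError("lr_schedule must be 'constant' or 'cosine'")
        if self.norm not in ("none", "group"):
            raise ValueError("norm must be 'none' or 'group'")

    @property
    def n_maps(self) -> int:
        return self.out_channels + (1 if self.head == "softmax" else 0)


@dataclass
class SliceSample:
    """One 2D training sample: 2-channel input in [0,1] and per-pixel class."""

    input: np.ndarray  # (2, H, W) float32
    target: np.ndarray  # (H, W) int8 in {0..4}
    volume_id: str
    slice_index: int


@dataclass
class TrainedModel:
    net: nn.UNet
    config: UnetConfig
    history: Dict[str, List[float]] = field(
        default_factory=lambda: {"train_loss": [], "val_loss": []}
    )


def normalize_channels(vol: FatWaterVolume) -> FatWaterVolume:
    """Independently min-max normalize each channel to [0, 1] volume-wide.

    A constant channel maps to all zeros. Idempotent, and invariant to a
    positive affine rescaling of the input.
    """

    def _norm(x: np.ndarray) -> np.ndarray:
        lo, hi = float(x.min()), float(x.max())
        if hi == lo:
            return np.zeros_like(x)
        return (x - lo) / (hi - lo)

    return FatWaterVolume(
        _norm(vol.water), _norm(vol.fat), vol.voxel_spacing, side_label=vol.side_label
    )


def make_slice_dataset(
    volumes: Sequence[Tuple[FatWaterVolume, MuscleLabelVolume]],
    split: float | Tuple[int, int] = 0.75,
    seed: int = 0,
    volume_ids: Sequence[str] | None = None,
    groups: Sequence[str] | None = None,
) -> Tuple[List[SliceSample], List[SliceSample]]:
    """Split volumes into train/validation slice sets at the volume level.

    All slices of a volume land in the same split (scan-level splitting).
    ``split`` is either the train fraction or explicit (n_train, n_val)
    counts. When ``groups`` is given (e.g. a subject id per volume, so that
    the two thighs of one subject never straddle the split), whole groups
    are assigned to a split and the counts refer to groups. Slices of each
    volume are emitted in acquisition order, so stacking a volume's targets
    reconstructs its label volume.
    """
    nvol = len(volumes)
    if nvol < 2:
        raise ValueError("need at least 2 volumes to split train/validation")
    if volume_ids is None:
        volume_ids = [f"vol{i:03d}" for i in range(nvol)]
    if groups is None:
        group_of = list(range(nvol))
    else:
        if len(groups) != nvol:
            raise ValueError("groups must give one group id per volume")
        group_of = list(groups)
    uniq = sorted(set(group_of), key=str)
    ngroup = len(uniq)
    if ngroup < 2:
        raise ValueError("need at least 2 groups to split train/validation")
    if isinstance(split, tuple):
        n_train, n_val = split
        if n_train + n_val > ngroup or n_train < 1 or n_val < 1:
            raise ValueError(f"split counts {split} incompatible with {ngroup} groups")
    else:
        n_train = int(round(split * ngroup))
        n_train = min(max(n_train, 1), ngroup - 1)
        n_val = ngroup - n_train
    rng = np.random.default_rng(seed)
    order = rng.permutation(ngroup)
    train_groups = {uniq[i] for i in order[:n_train]}
    val_groups = {uniq[i] for i in order[n_train : n_train + n_val]}
    train_idx = {i for i in range(nvol) if group_of[i] in train_groups}
    val_idx = {i for i in range(nvol) if group_of[i] in val_groups}

    def _slices(i: int) -> List[SliceSample]:
        vol, lab = volumes[i]
        if vol.shape != lab.shape:
            raise ValueError(f"volume/label grid mismatch for {volume_ids[i]}")
        out = []
        for z in range(vol.shape[2]):
            x = np.stack([vol.water[:, :, z], vol.fat[:, :, z]]).astype(np.float32)
            out.append(
                SliceSample(x, lab.labels[:, :, z].astype(np.int8), volume_ids[i], z)
            )
        return out

    train = [s for i in sorted(train_idx) for s in _slices(i)]
    val = [s for i in sorted(val_idx) for s in _slices(i)]
    return train, val


def build_unet(cfg: UnetConfig) -> TrainedModel:
    """Construct an untrained U-net model from a config."""
    net = nn.UNet(cfg.in_channels, cfg.n_maps, cfg.depth, cfg.base_filters, seed=cfg.seed, norm=cfg.norm)
    return TrainedModel(net=net, config=cfg)


def _batch(samples: Sequence[SliceSample], idx: Sequence[int], head: str, n_maps: int):
    x = np.stack([samples[i].input for i in idx]).astype(np.float32)
    t = np.stack([samples[i].target for i in idx]).astype(np.int64)
    if head == "softmax":
        return x, t
    onehot = np.zeros((t.shape[0], n_maps) + t.shape[1:], dtype=np.float32)
    for r in range(n_maps):
        onehot[:, r] = t == (r + 1)
    return x, onehot


def _loss_on(net: nn.UNet, samples: Sequence[SliceSample], cfg: UnetConfig, chunk: int = 8) -> float:
    total, npix = 0.0, 0
    for start in range(0, len(samples), chunk):
        idx = range(start, min(start + chunk, len(samples)))
        x, t = _batch(samples, list(idx), cfg.head, cfg.n_maps)
        logits = net.forward(x)
        if cfg.head == "softmax":
            loss, _ = nn.softmax_cross_entropy(logits, t)
        else:
            loss, _ = nn.sigmoid_bce(logits, t)
        n = x.shape[0]
        total += loss * n
        npix += n
    return total / npix


def train(
    model: TrainedModel,
    train_set: Sequence[SliceSample],
    val_set: Sequence[SliceSample],
    cfg: UnetConfig | None = None,
) -> TrainedModel:
    """Train in place; returns the model with best-validation parameters.

    Per-epoch training and validation losses are appended to
    ``model.history``. With ``epochs = 0`` the model is returned untouched.
    A non-finite loss aborts with a diagnostic naming the learning rate and
    input scale.
    """
    cfg = cfg or model.config
    if cfg.epochs == 0:
        return model
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be nonempty")
    net = model.net
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(net, cfg.learning_rate)
    best_loss = np.inf
    best_state = None
    for epoch in range(cfg.epochs):
        if cfg.lr_schedule == "cosine":
            frac = epoch / max(cfg.epochs - 1, 1)
            lo = cfg.learning_rate * cfg.min_lr_fraction
            opt.lr = lo + 0.5 * (1 + np.cos(np.pi * frac)) * (cfg.learning_rate - lo)
        order = rng.permutation(len(train_set))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            x, t = _batch(train_set, idx, cfg.head, cfg.n_maps)
            logits = net.forward(x)
            if cfg.head == "softmax":
                loss, grad = nn.softmax_cross_entropy(logits, t)
            else:
                loss, grad = nn.sigmoid_bce(logits, t)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: "
                    f"learning_rate={cfg.learning_rate}, input range "
                    f"[{x.min():.3g}, {x.max():.3g}] — check normalization/learning rate"
                )
            net.zero_grad()
            net.backward(grad)
            opt.step()
            losses.append(loss)
        val_loss = _loss_on(net, val_set, cfg)
        model.history["train_loss"].append(float(np.mean(losses)))
        model.history["val_loss"].append(float(val_loss))
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = net.state_dict()
    if best_state is not None:
        net.load_state_dict(best_state)
    return model


def _classify(logits: np.ndarray, cfg: UnetConfig) -> np.ndarray:
    """Threshold + argmax rule mapping score maps to labels {0..4}.

    Each ROI map is squashed to (0,1) — the softmax class probability for
    the softmax head, the elementwise sigmoid for the sigmoid head. Pixels
    strictly above the threshold in at least one ROI map take the
    highest-scoring ROI; all others are background. Exactly-at-threshold
    counts as below (deterministic).
    """
    if cfg.head == "softmax":
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        scores = (ez / ez.sum(axis=1, keepdims=True))[:, 1:]
    else:
        scores = nn.sigmoid(logits)
    above = (scores > cfg.binarize_threshold).any(axis=1)
    label = scores.argmax(axis=1).astype(np.int16) + 1
    label[~above] = 0
    return label


def predict_volume(
    model: TrainedModel, vol: FatWaterVolume, cfg: UnetConfig | None = None, chunk: int = 8
) -> MuscleLabelVolume:
    """Predict a label volume slice-by-slice from a normalized volume."""
    cfg = cfg or model.config
    nz = vol.shape[2]
    planes = []
    for start in range(0, nz, chunk):
        zs = range(start, min(start + chunk, nz))
        x = np.stack(
            [np.stack([vol.water[:, :, z], vol.fat[:, :, z]]) for z in zs]
        ).astype(np.float32)
        logits = model.net.forward(x)
        planes.append(_classify(logits, cfg))
    labels = np.concatenate(planes, axis=0).transpose(1, 2, 0)
    return MuscleLabelVolume(labels, vol.voxel_spacing)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Save parameters (.npz) with a JSON sidecar (config + history)."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.net.state_dict())
    sidecar = {"config": asdict(model.config), "history": model.history}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = UnetConfig(**sidecar["config"])
    model = build_unet(cfg)
    with np.load(path.with_suffix(".npz")) as state:
        model.net.load_state_dict({k: state[k] for k in state.files})
    model.history = sidecar["history"]
    return model
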