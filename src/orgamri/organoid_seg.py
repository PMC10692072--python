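"""3-D organoid segmentation: Multi-Otsu baseline and the U-Net harness.

Two segmentation routes are provided.  The deterministic baseline applies
Multi-Otsu thresholding to the whole-volume histogram and returns the
middle intensity class (tissue: brighter than background air, darker than
culture medium) restricted to its largest connected component.  The
trainable route is a small 3-D U-Net trained with Adam
(learning rate 1e-3, weight decay 1e-7), batch size 1, and a weighted
combination of binary cross-entropy and Dice loss (1:10), with the
best-validation-Dice checkpoint kept for prediction.  Inputs are expected
min–max normalized (see :func:`orgamri.volio.minmax_normalize`).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_multiotsu

from .metrics import dice
from .unet3d import Adam, UNet3D, bce_dice_loss, pad_to_multiple
from .volio import BinaryMask, VolumeImage, mask_volume_mm3

logger = logging.getLogger("orgamri")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Training protocol for the segmentation U-Net.

    Defaults follow the organoid-task protocol: Adam (lr 1e-3, weight
    decay 1e-7), 2000 iterations, batch size 1, BCE:Dice loss weights 1:10.
    The cyst task reuses the same protocol with 5000 iterations.
    ``model_scale`` multiplies the base channel width (8) so desk-scale
    tests can shrink the network.
    """

    optimizer: str = "adam"
    learning_rate: float = 1e-3
    weight_decay: float = 1e-7
    iterations: int = 2000
    batch_size: int = 1
    bce_weight: float = 1.0
    dice_weight: float = 10.0
    seed: int = 0
    model_scale: float = 1.0
    threshold: float = 0.5
    val_every: int = 25

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.bce_weight < 0 or self.dice_weight < 0:
            raise ValueError("loss weights must be non-negative")
        if self.bce_weight == 0 and self.dice_weight == 0:
            raise ValueError("at least one loss weight must be positive")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.optimizer.lower() != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")

    def base_channels(self) -> int:
        return max(2, int(round(8 * self.model_scale)))


@dataclass
class ModelArtifact:
    """A trained network: weights, config, and its validation history."""

    state: dict[str, np.ndarray]
    config: TrainConfig
    val_dice_history: list[tuple[int, float]] = field(default_factory=list)
    loss_history: list[float] = field(default_factory=list)
    best_iteration: int = -1
    best_val_dice: float = float("nan")

    def build_model(self) -> UNet3D:
        model = UNet3D(base_channels=self.config.base_channels(), seed=self.config.seed)
        model.load_state_dict(self.state)
        return model

    def save(self, path: str | os.PathLike) -> None:
        """Single-file artifact: npz of weights with an embedded JSON config."""
        meta = {
            "config": asdict(self.config),
            "val_dice_history": self.val_dice_history,
            "best_iteration": self.best_iteration,
            "best_val_dice": self.best_val_dice,
        }
        np.savez(
            str(path),
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **self.state,
        )

    @classmethod
    def load(cls, path: str | os.PathLike) -> "ModelArtifact":
        with np.load(str(path)) as npz:
            meta = json.loads(bytes(npz["__meta__"].tobytes()).decode())
            state = {k: npz[k] for k in npz.files if k != "__meta__"}
        cfg = TrainConfig(**meta["config"])
        return cls(
            state=state,
            config=cfg,
            val_dice_history=[tuple(t) for t in meta["val_dice_history"]],
            best_iteration=meta["best_iteration"],
            best_val_dice=meta["best_val_dice"],
        )


# ---------------------------------------------------------------------------
# Multi-Otsu baseline
# ---------------------------------------------------------------------------

def multi_otsu_thresholds(
    values: np.ndarray | None = None,
    n_classes: int = 3,
    nbins: int = 256,
    hist: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Thresholds maximizing between-class variance for ``n_classes`` classes.

    Either raw ``values`` (histogrammed into ``nbins``) or a pre-computed
    ``hist`` = (counts, bin_centers) may be given; an explicit histogram
    makes the search exact on already-quantized data.
    """
    if hist is not None:
        return threshold_multiotsu(classes=n_classes, hist=hist)
    values = np.asarray(values).ravel()
    if values.min() == values.max():
        raise ValueError("cannot threshold a constant volume")
    if np.unique(values).size < n_classes:
        raise ValueError(
            f"volume has fewer than {n_classes} distinct values; "
            "Multi-Otsu thresholds are degenerate"
        )
    return threshold_multiotsu(values, classes=n_classes, nbins=nbins)


def multi_otsu_segment(
    v: VolumeImage,
    n_classes: int = 3,
    largest_component: bool = True,
) -> BinaryMask:
    """Segment the organoid as the middle Multi-Otsu intensity class.

    With three classes the histogram splits into background (dark air),
    tissue (intermediate) and medium/cyst fluid (bright); the middle class
    is the organoid candidate.  By default only its largest connected
    component is kept, which removes stray tissue-intensity speckle at
    the tube wall.
    """
    thr = multi_otsu_thresholds(v.data, n_classes=n_classes)
    lo, hi = thr[0], thr[-1]
    cand = (v.data > lo) & (v.data <= hi)
    if largest_component and cand.any():
        labels, n = ndimage.label(cand)
        if n > 1:
            sizes = ndimage.sum_labels(cand, labels, index=np.arange(1, n + 1))
            cand = labels == (1 + int(np.argmax(sizes)))
    return BinaryMask(data=cand, spacing_um=v.spacing_um)


# ---------------------------------------------------------------------------
# U-Net training harness
# ---------------------------------------------------------------------------

def _prep(vol: VolumeImage) -> np.ndarray:
    arr = np.asarray(vol.data, dtype=np.float32)
    padded, _ = pad_to_multiple(arr)
    return padded[None]


def _prep_target(mask: BinaryMask) -> np.ndarray:
    arr = mask.data.astype(np.float32)
    padded, _ = pad_to_multiple(arr)
    return padded


def train_unet3d(
    train: list[tuple[VolumeImage, BinaryMask]],
    val: list[tuple[VolumeImage, BinaryMask]],
    cfg: TrainConfig,
) -> ModelArtifact:
    """Train the 3-D U-Net on (normalized volume, target mask) pairs.

    Runs ``cfg.iterations`` single-volume updates of the composite
    ``bce_weight·BCE + dice_weight·(1 − softDice)`` loss, shuffling the
    sample order each epoch.  Validation Dice (at ``cfg.threshold``) is
    evaluated every ``cfg.val_every`` iterations and the best checkpoint
    is kept; with no validation pairs the final weights are kept.
    Deterministic for a fixed ``cfg.seed``.
    """
    if not train:
        raise ValueError("empty training set")
    for v, m in train + val:
        if v.shape != m.shape:
            raise ValueError(f"volume/mask shapes differ: {v.shape} vs {m.shape}")

    xs = [_prep(v) for v, _ in train]
    ys = [_prep_target(m) for _, m in train]
    val_pairs = [(np.asarray(v.data, dtype=np.float32), m.data) for v, m in val]

    model = UNet3D(base_channels=cfg.base_channels(), seed=cfg.seed)
    opt = Adam(
        model.params,
        lr=cfg.learning_rate,
        weight_decay=cfg.weight_decay,
    )
    rng = np.random.default_rng(cfg.seed)

    order: list[int] = []
    loss_history: list[float] = []
    val_history: list[tuple[int, float]] = []
    best_state = None
    best_dice = -np.inf
    best_iter = -1

    def validate(it: int) -> None:
        nonlocal best_state, best_dice, best_iter
        if not val_pairs:
            return
        scores = []
        for vol, gt in val_pairs:
            pred = model.predict_proba(vol) >= cfg.threshold
            scores.append(dice(gt, pred) if (pred.any() or gt.any()) else 1.0)
        d = float(np.mean(scores))
        val_history.append((it, d))
        if d > best_dice:
            best_dice, best_iter = d, it
            best_state = model.state_dict()

    for it in range(1, cfg.iterations + 1):
        if not order:
            order = list(rng.permutation(len(xs)))
        i = order.pop()
        logits, cache = model.forward(xs[i], want_cache=True)
        loss, dz, _ = bce_dice_loss(logits, ys[i], cfg.bce_weight, cfg.dice_weight)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite loss ({loss}) at iteration {it}; "
                "check input normalization and learning rate"
            )
        grads = model.backward(dz, cache)
        opt.step(grads)
        loss_history.append(float(loss))
        if it % cfg.val_every == 0 or it == cfg.iterations:
            validate(it)

    if best_state is None:  # no validation set: keep final weights
        best_state = model.state_dict()
        best_iter = cfg.iterations
        best_dice = float("nan")

    return ModelArtifact(
        state=best_state,
        config=cfg,
        val_dice_history=val_history,
        loss_history=loss_history,
        best_iteration=best_iter,
        best_val_dice=float(best_dice),
    )


def predict_mask(artifact: ModelArtifact, v: VolumeImage) -> BinaryMask:
    """Binarize the voxel-wise foreground probability at the config threshold.

    Volumes whose shape is not divisible by 4 are zero-padded for the
    network and the prediction is cropped back, so the output always
    matches the input shape.  An all-empty prediction is legal and logged.
    """
    model = artifact.build_model()
    if any(s % 4 for s in v.shape):
        logger.info(
            "volume shape %s not divisible by 4: zero-padding for the network "
            "and cropping the prediction back", v.shape
        )
    probs = model.predict_proba(np.asarray(v.data, dtype=np.float32))
    mask = probs >= artifact.config.threshold
    if not mask.any():
        logger.warning("prediction is empty (all probabilities below threshold)")
    return BinaryMask(data=mask, spacing_um=v.spacing_um)


# ---------------------------------------------------------------------------
# longitudinal volume monitoring
# ---------------------------------------------------------------------------

def volume_curve(samples, masks: list[BinaryMask] | None = None) -> pd.DataFrame:
    """Organoid volume (mm³) over imaging days for one organoid.

    ``samples`` must all share one organoid id; ``masks`` defaults to each
    sample's own organoid mask.  Rows are sorted by day; duplicate days
    are rejected because one sample per organoid and day is expected.
    """
    ids = {s.organoid_id for s in samples}
    if len(ids) != 1:
        raise ValueError(f"samples must belong to one organoid, got ids {sorted(ids)}")
    if masks is None:
        masks = [s.organoid_mask for s in samples]
    days = [s.day for s in samples]
    if len(set(days)) != len(days):
        raise ValueError("duplicate imaging day for organoid")
    rows = sorted(
        ({"day": s.day, "volume_mm3": mask_volume_mm3(m)} for s, m in zip(samples, masks)),
        key=lambda r: r["day"],
    )
    return pd.DataFrame(rows, columns=["day", "volume_mm3"])
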