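"""Local cyst segmentation within organoids.

Small cysts are hard to delineate at 80 µm resolution, so samples with
less than 1000 cyst voxels (0.51 mm³ at that spacing) are excluded from
the cyst-segmentation task before training.  The segmentation itself
reuses the organoid U-Net harness with cyst masks as targets and a longer
default schedule (5000 iterations); predictions may optionally be
restricted to the organoid mask, since cysts live inside organoids by
definition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .organoid_seg import ModelArtifact, TrainConfig, predict_mask, train_unet3d
from .volio import BinaryMask, VolumeImage, mask_volume_mm3

#: minimum cyst size (voxels) for a sample to enter the cyst-segmentation task
MIN_CYST_VOXELS = 1000

#: default training schedule for the cyst task (organoid protocol, longer)
CYST_TRAIN_ITERATIONS = 5000


@dataclass
class CystSampleFilterReport:
    """Outcome of the minimum-cyst-volume inclusion rule."""

    included_ids: list[str]
    excluded_ids: list[str]
    unevaluable_ids: list[str]
    voxel_counts: dict[str, int]
    volumes_mm3: dict[str, float]
    min_voxels: int


def filter_min_cyst_voxels(samples, min_voxels: int = MIN_CYST_VOXELS) -> CystSampleFilterReport:
    """Apply the inclusion rule: keep samples with ≥ ``min_voxels`` cyst voxels.

    "Less than 1000 voxels" excludes, so a sample with exactly 1000 is
    included.  Samples without a cyst annotation are reported as
    unevaluable rather than silently dropped.  The threshold is in
    voxels; each sample's mm³ equivalent is derived from its own spacing.
    """
    included, excluded, unevaluable = [], [], []
    counts: dict[str, int] = {}
    volumes: dict[str, float] = {}
    for s in samples:
        sid = s.sample_id
        mask = getattr(s, "cyst_mask", None)
        if mask is None:
            unevaluable.append(sid)
            continue
        n = mask.count()
        counts[sid] = n
        volumes[sid] = mask_volume_mm3(mask)
        (included if n >= min_voxels else excluded).append(sid)
    return CystSampleFilterReport(
        included_ids=included,
        excluded_ids=excluded,
        unevaluable_ids=unevaluable,
        voxel_counts=counts,
        volumes_mm3=volumes,
        min_voxels=min_voxels,
    )


def default_cyst_config(**overrides) -> TrainConfig:
    """Organoid training protocol with the longer cyst-task schedule."""
    cfg = TrainConfig(iterations=CYST_TRAIN_ITERATIONS)
    return replace(cfg, **overrides) if overrides else cfg


def train_cyst_unet(
    train: list[tuple[VolumeImage, BinaryMask]],
    val: list[tuple[VolumeImage, BinaryMask]],
    cfg: TrainConfig | None = None,
) -> ModelArtifact:
    """Train the U-Net on (normalized volume, cyst mask) pairs."""
    if cfg is None:
        cfg = default_cyst_config()
    return train_unet3d(train, val, cfg)


def predict_cyst_mask(
    artifact: ModelArtifact,
    v: VolumeImage,
    organoid: BinaryMask | None = None,
    restrict_to_organoid: bool = False,
) -> BinaryMask:
    """Predict cyst voxels; optionally intersect with the organoid mask.

    Restriction is off by default; when on, no predicted cyst voxel can
    fall outside the supplied organoid mask.
    """
    pred = predict_mask(artifact, v)
    if restrict_to_organoid:
        if organoid is None:
            raise ValueError("restrict_to_organoid requires an organoid mask")
        pred = BinaryMask(data=pred.data & organoid.data, spacing_um=pred.spacing_um)
    return pred
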