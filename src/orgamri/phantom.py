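"""Synthetic MRI-like organoid phantoms with ground-truth masks.

A phantom emulates one Eppendorf tube of bright culture medium standing in
a dark background, containing a darker spherical organoid that may carry
bright fluid-filled cysts.  On a T2*-weighted contrast free fluid (medium,
cyst content) is bright while compact tissue is darker, which is exactly
the intensity topology the downstream compactness metric and the
segmentation networks rely on.  Geometry is deliberately simple — tube =
cylinder along the coronal axis, organoid = sphere, cysts = spheres —
because only the intensity populations and their spatial nesting matter
for validating the pipeline.

Intensities are drawn as population mean + noise and then multiplied by a
per-volume gain, so tests can detect any unintended dependence of the
analysis on the absolute intensity scale.
"""

from __future__ import annotations

import copy
import csv
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .volio import BinaryMask, VolumeImage, write_mask, write_volume

logger = logging.getLogger("orgamri")

Coord = tuple[float, float, float]


@dataclass
class PhantomSpec:
    """Generative parameters of one synthetic organoid sample.

    Intensities are in arbitrary units with the ordering
    ``intensity_medium > intensity_tissue > intensity_bg``; cyst fluid is
    required to sit within ±10% of the medium intensity because cysts are
    filled with fluid similar to the surrounding culture medium.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_um: float = 80.0
    tube_radius_frac: float = 0.45
    organoid_center: Coord | None = None  # defaults to grid center
    organoid_radius_vox: float = 12.0
    cysts: list[tuple[Coord, float]] = field(default_factory=list)
    intensity_bg: float = 0.05
    intensity_tissue: float = 0.30
    intensity_medium: float = 0.85
    intensity_cyst: float = 0.82
    noise_sigma: float = 0.03
    noise_model: str = "gaussian"  # or "rician"
    gain: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(self.grid_shape) != 3 or any(s < 8 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 axes of >=8 voxels, got {self.grid_shape}")
        if self.organoid_center is None:
            self.organoid_center = tuple(s / 2.0 for s in self.grid_shape)
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be positive")
        if self.tube_radius_frac <= 0 or self.organoid_radius_vox <= 0:
            raise ValueError("all radii must be positive")
        if not (self.intensity_medium > self.intensity_tissue > self.intensity_bg):
            raise ValueError(
                "intensity ordering must be medium > tissue > background, got "
                f"medium={self.intensity_medium}, tissue={self.intensity_tissue}, "
                f"bg={self.intensity_bg}"
            )
        if abs(self.intensity_cyst - self.intensity_medium) > 0.10 * self.intensity_medium:
            raise ValueError(
                "cyst fluid must be within ±10% of the medium intensity "
                f"(cyst={self.intensity_cyst}, medium={self.intensity_medium})"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

        tube_r = self.tube_radius()
        cz, cy, cx = self.organoid_center
        # tube axis runs along the coronal axis through the in-plane center
        ty, tx = self.grid_shape[1] / 2.0, self.grid_shape[2] / 2.0
        inplane = float(np.hypot(cy - ty, cx - tx))
        if inplane + self.organoid_radius_vox > tube_r:
            raise ValueError("organoid sphere does not fit inside the medium tube")
        for ccenter, crad in self.cysts:
            if crad <= 0:
                raise ValueError("all radii must be positive")
            d = float(np.linalg.norm(np.subtract(ccenter, self.organoid_center)))
            if d + crad > self.organoid_radius_vox:
                raise ValueError(
                    f"cyst at {ccenter} (r={crad}) is not fully inside the organoid"
                )

    def tube_radius(self) -> float:
        return self.tube_radius_frac * min(self.grid_shape[1], self.grid_shape[2])


@dataclass
class PhantomSample:
    """One generated sample: volume, ground-truth masks and cysticity label."""

    volume: VolumeImage
    organoid_mask: BinaryMask
    cyst_mask: BinaryMask
    cystic_label: bool
    spec: PhantomSpec
    organoid_id: str = "org0"
    day: int = 0

    @property
    def sample_id(self) -> str:
        return f"{self.organoid_id}_d{self.day:03d}"


def _sphere_mask(shape: tuple[int, int, int], center: Coord, radius: float) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    # +0.5: voxel centers
    d2 = (
        (zz + 0.5 - center[0]) ** 2
        + (yy + 0.5 - center[1]) ** 2
        + (xx + 0.5 - center[2]) ** 2
    )
    return d2 <= radius**2


def label_fields(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Boolean label fields (background / medium / tissue / cyst) by geometry.

    ``medium`` is the cyst-free tube fluid; ``tissue`` is the organoid minus
    its cysts; the four fields partition the grid.
    """
    shape = spec.grid_shape
    yy, xx = np.ogrid[: shape[1], : shape[2]]
    ty, tx = shape[1] / 2.0, shape[2] / 2.0
    tube2d = (yy + 0.5 - ty) ** 2 + (xx + 0.5 - tx) ** 2 <= spec.tube_radius() ** 2
    tube = np.broadcast_to(tube2d[None, :, :], shape)

    organoid = _sphere_mask(shape, spec.organoid_center, spec.organoid_radius_vox)
    cyst = np.zeros(shape, dtype=bool)
    for center, radius in spec.cysts:
        cyst |= _sphere_mask(shape, center, radius)
    cyst &= organoid  # geometric safety; validation already guarantees containment

    return {
        "background": ~tube,
        "medium": tube & ~organoid,
        "tissue": organoid & ~cyst,
        "cyst": cyst,
        "organoid": organoid,
    }


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom volume plus its ground-truth masks.

    Deterministic for a fixed ``spec.seed``: intensities are population
    mean + noise, then scaled by the per-volume gain.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    fields = label_fields(spec)

    mean = np.full(spec.grid_shape, spec.intensity_bg, dtype=np.float64)
    mean[fields["medium"]] = spec.intensity_medium
    mean[fields["tissue"]] = spec.intensity_tissue
    mean[fields["cyst"]] = spec.intensity_cyst

    if spec.noise_sigma > 0:
        if spec.noise_model == "rician":
            # magnitude image of a complex signal with Gaussian channel noise
            n1 = rng.normal(0.0, spec.noise_sigma, spec.grid_shape)
            n2 = rng.normal(0.0, spec.noise_sigma, spec.grid_shape)
            vol = np.sqrt((mean + n1) ** 2 + n2**2)
        else:
            vol = mean + rng.normal(0.0, spec.noise_sigma, spec.grid_shape)
    else:
        vol = mean.copy()
    vol *= spec.gain

    sp = (spec.spacing_um,) * 3
    return PhantomSample(
        volume=VolumeImage(data=vol, spacing_um=sp),
        organoid_mask=BinaryMask(data=fields["organoid"], spacing_um=sp),
        cyst_mask=BinaryMask(data=fields["cyst"], spacing_um=sp),
        cystic_label=bool(fields["cyst"].any()),
        spec=copy.deepcopy(spec),
    )


def _place_cysts(
    organoid_center: Coord,
    organoid_radius: float,
    n_cysts: int,
    radius_fracs: np.ndarray,
    directions: np.ndarray,
    offset_fracs: np.ndarray,
) -> list[tuple[Coord, float]]:
    """Scale a fixed relative cyst layout to the current organoid radius."""
    cysts = []
    for i in range(n_cysts):
        crad = float(radius_fracs[i] * organoid_radius)
        max_off = organoid_radius - crad - 0.5
        if max_off <= 0:
            continue
        off = directions[i] * offset_fracs[i] * max_off
        center = tuple(float(c + o) for c, o in zip(organoid_center, off))
        cysts.append((center, crad))
    return cysts


def generate_cohort(
    n_organoids: int,
    days: list[int],
    cystic_fraction: float,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
) -> list[PhantomSample]:
    """Generate a longitudinal cohort of phantoms.

    Each organoid keeps its identity across imaging days: its radius grows
    monotonically with day, cystic organoids keep (growing) cysts at a
    fixed relative layout, and every volume gets its own gain jitter.
    The default study design — 9 organoids over 5 imaging days — yields a
    45-sample cohort.
    """
    if n_organoids < 1:
        raise ValueError("n_organoids must be >= 1")
    if not days:
        raise ValueError("need at least one imaging day")
    if not 0.0 <= cystic_fraction <= 1.0:
        raise ValueError("cystic_fraction must be in [0, 1]")
    if base_spec is None:
        base_spec = PhantomSpec()

    rng = np.random.default_rng(seed)
    days = sorted(days)
    n_cystic = int(round(cystic_fraction * n_organoids))
    cystic_flags = np.array([i < n_cystic for i in range(n_organoids)])
    rng.shuffle(cystic_flags)

    max_radius = 0.85 * base_spec.tube_radius()
    samples: list[PhantomSample] = []
    for i in range(n_organoids):
        base_radius = rng.uniform(0.62, 0.78) * base_spec.organoid_radius_vox
        growth_per_day = rng.uniform(0.02, 0.05) * base_spec.organoid_radius_vox
        if cystic_flags[i]:
            # one dominant fluid cavity plus optional satellites: cystic
            # organoids carry a substantial cyst load, not specks
            n_cysts = int(rng.integers(1, 4))
            radius_fracs = np.concatenate(
                [rng.uniform(0.45, 0.60, 1), rng.uniform(0.25, 0.40, n_cysts - 1)]
            )
            dirs = rng.normal(size=(n_cysts, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            offset_fracs = rng.uniform(0.0, 0.9, n_cysts)
        for j, day in enumerate(days):
            radius = min(base_radius + growth_per_day * (day - days[0]), max_radius)
            cysts = []
            if cystic_flags[i]:
                cysts = _place_cysts(
                    base_spec.organoid_center,
                    radius,
                    n_cysts,
                    radius_fracs,
                    dirs,
                    offset_fracs,
                )
                if not cysts:  # degenerate tiny organoid: force one central cyst
                    cysts = [(base_spec.organoid_center, 0.3 * radius)]
            spec = replace(
                copy.deepcopy(base_spec),
                organoid_radius_vox=radius,
                cysts=cysts,
                gain=float(rng.uniform(0.8, 1.2)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            sample = generate_phantom(spec)
            sample.organoid_id = f"org{i}"
            sample.day = int(day)
            samples.append(sample)
    return samples


def write_cohort(samples: list[PhantomSample], out_dir: str | os.PathLike) -> str:
    """Write volumes + masks as NIfTI plus a CSV manifest; returns manifest path."""
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    manifest_path = os.path.join(out_dir, "manifest.csv")
    with open(manifest_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["sample_id", "organoid_id", "day", "cystic_label",
             "volume_path", "organoid_mask_path", "cyst_mask_path"]
        )
        for s in samples:
            vp = os.path.join(out_dir, f"{s.sample_id}_vol.nii.gz")
            op = os.path.join(out_dir, f"{s.sample_id}_org.nii.gz")
            cp = os.path.join(out_dir, f"{s.sample_id}_cyst.nii.gz")
            write_volume(s.volume, vp)
            write_mask(s.organoid_mask, op)
            write_mask(s.cyst_mask, cp)
            w.writerow(
                [s.sample_id, s.organoid_id, s.day, int(s.cystic_label), vp, op, cp]
            )
    return manifest_path
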