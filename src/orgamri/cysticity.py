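"""Global cysticity scoring via the *compactness* metric.

Cysts are cavities filled with fluid similar to the surrounding culture
medium, so on a T2*-weighted contrast a cystic organoid's voxels look
medium-like (bright) while a compact organoid stays darker than its
environment.  *Compactness* turns this into a scalar:

    compactness = | mean(int_org) − mean(int_medium) |

where ``int_org`` are the intensities of organoid voxels (from the
ground-truth segmentation by default) and ``int_medium`` the intensities
of medium voxels, excluding any organoid voxel.  Medium voxels are found
by applying Otsu's threshold 2-D-wise on every organoid-containing
coronal plane (bright medium vs. dark background), discarding the first
and last organoid-containing planes to filter noisy-edge artifacts.  Low
compactness means medium-like organoid signal, i.e. cystic; scoring the
cystic class with −compactness therefore feeds straight into ROC
analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.filters import threshold_otsu

from .metrics import ROCResult, roc_auc
from .volio import CORONAL_AXIS, BinaryMask, VolumeImage

logger = logging.getLogger("orgamri")


@dataclass
class CompactnessResult:
    """Compactness of one sample plus the quantities it was built from."""

    mu_org: float
    mu_medium: float
    compactness: float
    plane_first: int
    plane_last: int
    n_medium_voxels: int

    def __post_init__(self) -> None:
        assert self.n_medium_voxels >= 1


def find_organoid_planes(m: BinaryMask, axis: int = CORONAL_AXIS) -> tuple[int, int]:
    """First and last plane indices along ``axis`` containing organoid voxels."""
    if not m.data.any():
        raise ValueError("empty mask: no organoid-containing planes")
    other = tuple(i for i in range(3) if i != axis)
    occupied = np.flatnonzero(m.data.any(axis=other))
    return int(occupied[0]), int(occupied[-1])


def extract_medium_mask(
    v: VolumeImage, organoid: BinaryMask, axis: int = CORONAL_AXIS
) -> BinaryMask:
    """Medium voxels via plane-wise Otsu along the coronal axis.

    For every interior organoid-containing plane a 2-D Otsu threshold
    separates bright fluid (medium and organoid cysts) from dark
    background; the plane's medium voxels are the above-threshold voxels
    minus the organoid voxels.  The first and last organoid-containing
    planes are discarded, so the organoid must span at least 3 planes.
    """
    if v.data.shape != organoid.data.shape:
        raise ValueError("volume and organoid mask shapes differ")
    first, last = find_organoid_planes(organoid, axis=axis)
    if last - first + 1 < 3:
        raise ValueError(
            "organoid occupies fewer than 3 coronal planes; "
            "no interior plane survives discarding the first and last"
        )
    medium = np.zeros(v.data.shape, dtype=bool)
    vol = np.moveaxis(v.data, axis, 0)
    org = np.moveaxis(organoid.data, axis, 0)
    med = np.moveaxis(medium, axis, 0)  # writable view
    for p in range(first + 1, last):
        plane = vol[p]
        if plane.min() == plane.max():
            logger.warning("plane %d is constant; contributes no medium voxels", p)
            continue
        thr = threshold_otsu(plane)
        bright = plane > thr
        plane_medium = bright & ~org[p]
        if not plane_medium.any():
            logger.warning(
                "plane %d: above-threshold voxels are all organoid; "
                "contributes no medium voxels", p
            )
        med[p] = plane_medium
    return BinaryMask(data=medium, spacing_um=v.spacing_um)


def compactness(
    v: VolumeImage, organoid: BinaryMask, axis: int = CORONAL_AXIS
) -> CompactnessResult:
    """Absolute difference of mean organoid and mean medium intensity.

    ``v`` should be the min–max normalized volume so values are
    comparable across samples despite per-acquisition gain differences.
    A fully cystic organoid scores near 0 (medium-like), a compact one
    scores high.
    """
    medium = extract_medium_mask(v, organoid, axis=axis)
    n_medium = medium.count()
    if n_medium == 0:
        raise ValueError("medium extraction produced no voxels")
    first, last = find_organoid_planes(organoid, axis=axis)
    mu_org = float(v.data[organoid.data].mean())
    mu_medium = float(v.data[medium.data].mean())
    return CompactnessResult(
        mu_org=mu_org,
        mu_medium=mu_medium,
        compactness=abs(mu_org - mu_medium),
        plane_first=first + 1,
        plane_last=last - 1,
        n_medium_voxels=n_medium,
    )


def classify_cysticity(
    results: list[tuple[CompactnessResult, bool]]
) -> tuple[ROCResult, list[bool]]:
    """ROC analysis of cysticity from compactness values.

    The score for the cystic class is −compactness (the more medium-like
    the organoid, the lower its compactness, the more cystic).  Returns
    the ROC result and per-sample calls at the Youden-J operating point.
    """
    if len(results) < 2:
        raise ValueError("need at least two samples")
    scores = np.array([-r.compactness for r, _ in results])
    labels = np.array([bool(lbl) for _, lbl in results])
    roc = roc_auc(scores, labels)
    roc.score_meaning = "score = -compactness; higher = more cystic"
    calls = [bool(s >= roc.chosen_threshold) for s in scores]
    return roc, calls


def compare_groups_compactness(
    values_noncystic, values_cystic, equal_var: bool = False
) -> tuple[float, float]:
    """Two-sided t-test of compactness between the two groups.

    Welch's variant by default.  Returns (t statistic, two-sided p).
    The statistic's sign follows the (non-cystic − cystic) order of the
    arguments.
    """
    a = np.asarray(values_noncystic, dtype=float)
    b = np.asarray(values_cystic, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if np.array_equal(a, b):
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)
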