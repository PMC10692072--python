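"""Evaluation primitives: Dice score, ROC AUC and organoid-wise LOOCV splits.

The Dice score between a ground-truth voxel set A and a predicted voxel
set B is ``2·|A∩B| / (|A| + |B|)``; 1 means perfect agreement.  ROC AUC
summarizes a binary classifier over all operating points; ties are
counted 1/2, so the AUC equals the probability that a random positive
sample outscores a random negative one.  The leave-one-out protocol is
organoid-wise: all imaging time points of one organoid form the test set
of one split, which prevents leakage of organoid identity between
training and testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .volio import BinaryMask


@dataclass
class DiceReport:
    """Per-sample Dice scores with mean ± SD aggregations.

    Whether the headline mean is taken over samples or over organoids is a
    reporting choice; both aggregations are carried.
    """

    per_sample: list[tuple[str, float]]
    organoid_of: dict[str, str] = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return np.array([d for _, d in self.per_sample], dtype=float)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1)) if len(self.per_sample) > 1 else 0.0

    def mean_by_organoid(self) -> dict[str, float]:
        groups: dict[str, list[float]] = {}
        for sid, d in self.per_sample:
            groups.setdefault(self.organoid_of.get(sid, sid), []).append(d)
        return {k: float(np.mean(v)) for k, v in groups.items()}


@dataclass
class LOOCVSplit:
    test_organoid_id: str
    train_sample_ids: list[str]
    val_sample_ids: list[str]
    test_sample_ids: list[str]
    seed: int


@dataclass
class ROCResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    chosen_threshold: float  # Youden's J maximizer
    score_meaning: str = "higher score = more likely positive"


def dice(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Dice overlap ``2|A∩B|/(|A|+|B|)`` between two aligned masks.

    Symmetric in its arguments.  Raises if shapes differ or if both masks
    are empty (0/0 would silently score an empty prediction of an empty
    target as perfect).
    """
    a_arr = a.data if isinstance(a, BinaryMask) else np.asarray(a, dtype=bool)
    b_arr = b.data if isinstance(b, BinaryMask) else np.asarray(b, dtype=bool)
    if a_arr.shape != b_arr.shape:
        raise ValueError(f"mask shapes differ: {a_arr.shape} vs {b_arr.shape}")
    na, nb = int(a_arr.sum()), int(b_arr.sum())
    if na + nb == 0:
        raise ValueError("Dice undefined: both masks are empty (0/0)")
    inter = int(np.logical_and(a_arr, b_arr).sum())
    return 2.0 * inter / (na + nb)


def roc_auc(scores, labels) -> ROCResult:
    """ROC AUC with trapezoidal tie handling plus the full ROC curve.

    ``scores`` are real-valued, higher meaning more likely positive;
    ``labels`` are booleans.  Both classes must be present.  The chosen
    operating threshold maximizes Youden's J = TPR − FPR (a convenience;
    evaluation uses the AUC only).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D sequences")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present to compute ROC AUC")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thr = roc_curve(labels, scores)
    j = tpr - fpr
    chosen = float(thr[int(np.argmax(j))])
    return ROCResult(auc=auc, fpr=fpr, tpr=tpr, thresholds=thr, chosen_threshold=chosen)


def loocv_splits(samples, val_frac: float = 0.2, seed: int = 0) -> list[LOOCVSplit]:
    """Organoid-wise leave-one-out cross-validation splits.

    ``samples`` is any sequence of objects with ``sample_id`` and
    ``organoid_id`` attributes (phantom samples qualify).  One split per
    organoid: its samples form the test set; the remaining samples are
    split at random into ~(1−val_frac) training and ~val_frac validation.
    Each split shuffles with its own seed derived from the root seed, so
    the whole protocol reproduces from one integer.
    """
    if not 0.0 < val_frac < 1.0:
        raise ValueError("val_frac must be in (0, 1)")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in cohort")
    organoids = sorted({s.organoid_id for s in samples})
    if len(organoids) < 2:
        raise ValueError("need at least two organoid ids for LOOCV")

    root = np.random.SeedSequence(seed)
    child_seeds = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in root.spawn(len(organoids))]

    splits = []
    for org, child_seed in zip(organoids, child_seeds):
        test_ids = [s.sample_id for s in samples if s.organoid_id == org]
        rest = [s.sample_id for s in samples if s.organoid_id != org]
        rng = np.random.default_rng(child_seed)
        rest = list(np.array(rest)[rng.permutation(len(rest))])
        n_val = max(1, int(round(val_frac * len(rest))))
        splits.append(
            LOOCVSplit(
                test_organoid_id=org,
                train_sample_ids=[str(x) for x in rest[n_val:]],
                val_sample_ids=[str(x) for x in rest[:n_val]],
                test_sample_ids=test_ids,
                seed=child_seed,
            )
        )
    return splits
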