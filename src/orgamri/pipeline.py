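"""End-to-end orchestration: simulate → segment → classify → cyst-seg → DTI.

A run is described by a :class:`RunConfig` (round-trippable through
YAML).  Stages execute in pipeline order on a cohort loaded from a
manifest (or simulated in place), and every stage writes its per-sample
CSV next to a consolidated JSON report, so each reported number is
recomputable from the retained per-stage tables.  One root seed
deterministically derives every stage seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cyst_seg import filter_min_cyst_voxels
from .cysticity import classify_cysticity, compactness, compare_groups_compactness
from .dti_stats import compare_groups_dti
from .metrics import DiceReport, dice, loocv_splits
from .organoid_seg import TrainConfig, multi_otsu_segment, predict_mask, train_unet3d
from .phantom import PhantomSpec, generate_cohort
from .volio import BinaryMask, VolumeImage, minmax_normalize, read_mask, read_volume

logger = logging.getLogger("orgamri")

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "orgamri_run"
    manifest: str | None = None  # CSV; None -> simulate a cohort
    seed: int = 0

    # simulation stage
    n_organoids: int = 9
    days: list[int] = field(default_factory=lambda: [20, 26, 36, 42, 54])
    cystic_fraction: float = 0.5
    phantom: dict = field(default_factory=dict)  # PhantomSpec overrides

    # stage toggles
    run_segmentation: bool = True
    run_cysticity: bool = True
    run_cyst_filter: bool = True
    run_dti: bool = True

    # segmentation stage
    segmentation_method: str = "otsu"  # "otsu" (deterministic) or "unet"
    train: dict = field(default_factory=dict)  # TrainConfig overrides
    val_frac: float = 0.2

    # analysis parameters
    min_cyst_voxels: int = 1000
    alpha: float = 0.05

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        # output location does not affect the science: exclude it
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _derive_seed(root: int, stage: str) -> int:
    h = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


@dataclass
class _Sample:
    """Cohort entry as the pipeline consumes it (file-backed or in-memory)."""

    sample_id: str
    organoid_id: str
    day: int
    cystic_label: bool
    volume: VolumeImage
    organoid_mask: BinaryMask
    cyst_mask: BinaryMask | None


def load_manifest(path: str) -> list[_Sample]:
    df = pd.read_csv(path)
    base = os.path.dirname(os.path.abspath(path))

    def resolve(p):
        return p if os.path.isabs(p) else os.path.join(base, p)

    out = []
    for _, row in df.iterrows():
        cyst = None
        if isinstance(row.get("cyst_mask_path"), str) and row["cyst_mask_path"]:
            cyst = read_mask(resolve(row["cyst_mask_path"]))
        out.append(
            _Sample(
                sample_id=str(row["sample_id"]),
                organoid_id=str(row["organoid_id"]),
                day=int(row["day"]),
                cystic_label=bool(int(row["cystic_label"])),
                volume=read_volume(resolve(row["volume_path"])),
                organoid_mask=read_mask(resolve(row["organoid_mask_path"])),
                cyst_mask=cyst,
            )
        )
    return out


def _simulate(cfg: RunConfig) -> list[_Sample]:
    spec = PhantomSpec(**cfg.phantom)
    cohort = generate_cohort(
        n_organoids=cfg.n_organoids,
        days=cfg.days,
        cystic_fraction=cfg.cystic_fraction,
        base_spec=spec,
        seed=_derive_seed(cfg.seed, "simulate"),
    )
    return [
        _Sample(
            sample_id=s.sample_id,
            organoid_id=s.organoid_id,
            day=s.day,
            cystic_label=s.cystic_label,
            volume=s.volume,
            organoid_mask=s.organoid_mask,
            cyst_mask=s.cyst_mask,
        )
        for s in cohort
    ]


def _segment_stage(samples: list[_Sample], cfg: RunConfig, out_dir: str) -> dict:
    splits = loocv_splits(samples, val_frac=cfg.val_frac, seed=_derive_seed(cfg.seed, "loocv"))
    pd.DataFrame(
        [
            {
                "test_organoid_id": sp.test_organoid_id,
                "train": ";".join(sp.train_sample_ids),
                "val": ";".join(sp.val_sample_ids),
                "test": ";".join(sp.test_sample_ids),
                "seed": sp.seed,
            }
            for sp in splits
        ]
    ).to_csv(os.path.join(out_dir, "loocv_splits.csv"), index=False)

    by_id = {s.sample_id: s for s in samples}
    norm = {s.sample_id: minmax_normalize(s.volume) for s in samples}
    per_sample: list[tuple[str, float]] = []

    if cfg.segmentation_method == "otsu":
        for s in samples:
            pred = multi_otsu_segment(norm[s.sample_id])
            per_sample.append((s.sample_id, dice(s.organoid_mask, pred)))
    elif cfg.segmentation_method == "unet":
        tcfg_base = TrainConfig(**cfg.train)
        for sp in splits:
            tcfg = dataclasses.replace(tcfg_base, seed=sp.seed)
            train_pairs = [(norm[i], by_id[i].organoid_mask) for i in sp.train_sample_ids]
            val_pairs = [(norm[i], by_id[i].organoid_mask) for i in sp.val_sample_ids]
            art = train_unet3d(train_pairs, val_pairs, tcfg)
            for i in sp.test_sample_ids:
                pred = predict_mask(art, norm[i])
                per_sample.append((i, dice(by_id[i].organoid_mask, pred)))
    else:
        raise ValueError(f"unknown segmentation method {cfg.segmentation_method!r}")

    report = DiceReport(
        per_sample=per_sample,
        organoid_of={s.sample_id: s.organoid_id for s in samples},
    )
    pd.DataFrame(report.per_sample, columns=["sample_id", "dice"]).to_csv(
        os.path.join(out_dir, "segmentation_dice.csv"), index=False
    )
    return {
        "method": cfg.segmentation_method,
        "n_splits": len(splits),
        "dice_mean": report.mean,
        "dice_sd": report.sd,
        "dice_mean_by_organoid": report.mean_by_organoid(),
    }


def _cysticity_stage(samples: list[_Sample], cfg: RunConfig, out_dir: str) -> dict:
    rows = []
    results = []
    for s in samples:
        res = compactness(minmax_normalize(s.volume), s.organoid_mask)
        results.append((res, s.cystic_label))
        rows.append(
            {
                "sample_id": s.sample_id,
                "cystic_label": int(s.cystic_label),
                "mu_org": res.mu_org,
                "mu_medium": res.mu_medium,
                "compactness": res.compactness,
                "plane_first": res.plane_first,
                "plane_last": res.plane_last,
                "n_medium_voxels": res.n_medium_voxels,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(os.path.join(out_dir, "compactness.csv"), index=False)
    roc, calls = classify_cysticity(results)
    vals_nc = df.loc[df["cystic_label"] == 0, "compactness"].to_numpy()
    vals_c = df.loc[df["cystic_label"] == 1, "compactness"].to_numpy()
    t, p = compare_groups_compactness(vals_nc, vals_c)
    return {
        "roc_auc": roc.auc,
        "chosen_threshold": roc.chosen_threshold,
        "t_statistic": t,
        "p_value": p,
        "n_cystic": int(df["cystic_label"].sum()),
        "n_noncystic": int((1 - df["cystic_label"]).sum()),
    }


def _cyst_filter_stage(samples: list[_Sample], cfg: RunConfig, out_dir: str) -> dict:
    report = filter_min_cyst_voxels(samples, min_voxels=cfg.min_cyst_voxels)
    pd.DataFrame(
        [
            {
                "sample_id": sid,
                "cyst_voxels": report.voxel_counts.get(sid),
                "cyst_mm3": report.volumes_mm3.get(sid),
                "included": sid in report.included_ids,
            }
            for sid in report.voxel_counts
        ]
    ).to_csv(os.path.join(out_dir, "cyst_filter.csv"), index=False)
    return {
        "min_voxels": report.min_voxels,
        "n_included": len(report.included_ids),
        "n_excluded": len(report.excluded_ids),
        "n_unevaluable": len(report.unevaluable_ids),
    }


def _synthetic_dti_maps(sample: _Sample, seed: int) -> dict[str, VolumeImage]:
    """Simple stand-in DTI maps derived from phantom geometry.

    Trace (×10⁻³ mm²/s): free fluid diffuses fast (cysts ~2.5, medium
    ~2.9), compact tissue slowly (~1.0).  FA and eigenvalue maps are
    scaled variants; they carry the same group structure.
    """
    rng = np.random.default_rng(seed)
    shape = sample.volume.shape
    org = sample.organoid_mask.data
    cyst = sample.cyst_mask.data if sample.cyst_mask is not None else np.zeros(shape, bool)
    trace = np.full(shape, 2.9)
    trace[org] = 1.0
    trace[cyst] = 2.5
    trace += rng.normal(0, 0.05, shape)
    maps = {"Trace": VolumeImage(trace, sample.volume.spacing_um)}
    for name, scale in (("FA", 0.12), ("Eig1", 0.45), ("Eig2", 0.33), ("Eig3", 0.22)):
        maps[name] = VolumeImage(trace * scale + rng.normal(0, 0.01, shape),
                                 sample.volume.spacing_um)
    return maps


def _dti_stage(samples: list[_Sample], cfg: RunConfig, out_dir: str) -> dict:
    seed = _derive_seed(cfg.seed, "dti")
    entries = []
    for i, s in enumerate(samples):
        entries.append(
            {
                "sample_id": s.sample_id,
                "maps": _synthetic_dti_maps(s, seed + i),
                "organoid_mask": s.organoid_mask,
                "cystic_label": s.cystic_label,
            }
        )
    result = compare_groups_dti(entries, alpha=cfg.alpha)
    result.table.to_csv(os.path.join(out_dir, "dti_stats.csv"), index=False)
    return {
        "alpha": cfg.alpha,
        "rejected_maps": result.rejected_maps(),
        "table": result.table.to_dict(orient="records"),
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in order and write the consolidated report.

    Returns the report dict (also written to ``<out_dir>/report.json``).
    Any stage failure raises with a stage-tagged message; outputs of
    completed stages are retained.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    cfg.to_yaml(os.path.join(cfg.out_dir, "run_config.yaml"))

    if cfg.manifest:
        samples = load_manifest(cfg.manifest)
    else:
        samples = _simulate(cfg)

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "orgamri_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_samples": len(samples),
        "n_organoids": len({s.organoid_id for s in samples}),
        "stages": {},
    }

    stages = [
        ("segmentation", cfg.run_segmentation, _segment_stage),
        ("cysticity", cfg.run_cysticity, _cysticity_stage),
        ("cyst_filter", cfg.run_cyst_filter, _cyst_filter_stage),
        ("dti", cfg.run_dti, _dti_stage),
    ]
    for name, enabled, fn in stages:
        if not enabled:
            continue
        try:
            report["stages"][name] = fn(samples, cfg, cfg.out_dir)
        except Exception as exc:
            _write_report(report, cfg.out_dir)  # retain partial outputs
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    _write_report(report, cfg.out_dir)
    return report


def _write_report(report: dict, out_dir: str) -> None:
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=str)
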