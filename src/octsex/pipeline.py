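"""End-to-end orchestration: simulate → select → split → train → evaluate.

A run is fully described by a :class:`RunConfig`; every stage's randomness
derives from the single global seed, so re-running an identical config
reproduces identical manifests and metrics on the same backend.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import __version__
from .cnn import CNNClassifier
from .engine import ScanConfig, SourceSpectrum, scan_bscan
from .evaluation import (
    confusion_matrix,
    learning_curves,
    metrics,
    plot_learning_curves,
    size_ablation,
)
from .phantom import CohortSpec, make_cohort, rasterize
from .preprocess import (
    PreprocessConfig,
    augment,
    enhance,
    quality_select,
    resize,
    split_dataset,
    write_manifest,
)

__all__ = [
    "RunConfig",
    "RunRecord",
    "simulate_cohort",
    "run_all",
    "load_images",
    "well_separated_config",
    "high_noise_config",
]

log = logging.getLogger("octsex")


@dataclass(frozen=True)
class RunConfig:
    """Complete, serializable description of one experiment.

    Defaults reproduce the full-scale study design (30 chicks × 50 frames
    at 1000×1000 acquisition).  :meth:`desk_scale` returns a reduced
    variant — coarser scan grid, smaller cohort — for CPU-budget runs;
    the dataset bookkeeping (counts, splits) is unaffected by resolution.
    """

    cohort: CohortSpec = field(default_factory=CohortSpec)
    source: SourceSpectrum = field(default_factory=SourceSpectrum)
    scan: ScanConfig = field(default_factory=ScanConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    noise_floor: float = 0.02
    n_augment: int = 1
    train_fraction: float = 0.8
    split_mode: str = "by_chick"
    learning_rate: float = 1e-4
    batch_size: int = 128
    max_epochs: int = 1000
    patience: int = 50
    val_fraction: float = 0.1
    tau: float = 0.6
    ablate_sizes: tuple[tuple[int, int], ...] = ()
    out_dir: str = "runs/run0"
    seed: int = 0

    @classmethod
    def desk_scale(cls, **overrides) -> "RunConfig":
        """Reduced-resolution, reduced-cohort configuration for one CPU."""
        defaults = dict(
            cohort=CohortSpec(n_chicks=12, frames_per_chick=15, keep_per_chick=12),
            source=SourceSpectrum(n_spectral_samples=512),
            scan=ScanConfig(n_alines=200, depth_pixels=200, depth_crop=120, depth_pitch_um=20.0),
            learning_rate=1e-3,
            batch_size=16,
            max_epochs=40,
            patience=10,
        )
        defaults.update(overrides)
        return cls(**defaults)

    # ------------------------------------------------------------- serialization
    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_as_plain(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return _from_plain(cls, yaml.safe_load(Path(path).read_text()))

    def stage_seeds(self) -> dict[str, int]:
        """Per-stage seeds, all derived from the global seed."""
        names = ("cohort", "scan", "split", "train", "augment")
        state = np.random.SeedSequence(self.seed).generate_state(len(names)) % (2**31)
        return dict(zip(names, (int(s) for s in state)))


def well_separated_config(seed: int = 1, out_dir: str = "runs/recovery_clean", **overrides) -> RunConfig:
    """Parameter-recovery conditions: bright low-speckle cones, 16 chicks.

    A working pipeline must classify this cohort nearly perfectly from a
    leakage-safe by-chick split; the reduced cohort and scan grid keep one
    run within a desk-scale CPU budget.
    """
    from .phantom import WELL_SEPARATED_PARAMS

    defaults = dict(
        cohort=CohortSpec(
            n_chicks=16, frames_per_chick=10, keep_per_chick=8,
            ambiguous_rate=0.0, params=WELL_SEPARATED_PARAMS,
        ),
        noise_floor=0.02,
        max_epochs=50,
        patience=49,
        tau=0.0,  # pure argmax: binary sex accuracy is the quantity of interest
        out_dir=out_dir,
        seed=seed,
    )
    defaults.update(overrides)
    return RunConfig.desk_scale(**defaults)


def high_noise_config(seed: int = 1, out_dir: str = "runs/recovery_noisy", **overrides) -> RunConfig:
    """Negative-control conditions: cone contrast buried under heavy speckle.

    Identical pipeline and budget as :func:`well_separated_config`; because
    the by-chick split leaves no side channel, accuracy should fall toward
    chance here — a pipeline that still scored well would be leaking labels.
    """
    from .phantom import HIGH_NOISE_PARAMS

    defaults = dict(
        cohort=CohortSpec(
            n_chicks=16, frames_per_chick=10, keep_per_chick=8,
            ambiguous_rate=0.0, params=HIGH_NOISE_PARAMS,
        ),
        noise_floor=0.3,
        max_epochs=50,
        patience=49,
        tau=0.0,
        out_dir=out_dir,
        seed=seed,
    )
    defaults.update(overrides)
    return RunConfig.desk_scale(**defaults)


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_as_plain(v) for v in obj]
    return obj


def _from_plain(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            v = _from_plain(f.type, v)
        kwargs[f.name] = v
    # nested dataclasses (types are strings under future annotations)
    nested = {
        "cohort": CohortSpec, "source": SourceSpectrum,
        "scan": ScanConfig, "preprocess": PreprocessConfig,
    }
    for name, sub in nested.items():
        if name in kwargs and isinstance(kwargs[name], dict):
            sub_kwargs = dict(kwargs[name])
            if name == "cohort" and isinstance(sub_kwargs.get("params"), dict):
                from .phantom import PhantomParams

                pk = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in sub_kwargs["params"].items()
                }
                sub_kwargs["params"] = PhantomParams(**pk)
            for key, val in sub_kwargs.items():
                if isinstance(val, list):
                    sub_kwargs[key] = tuple(val)
            kwargs[name] = sub(**sub_kwargs)
    for key in ("ablate_sizes",):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(tuple(v) for v in kwargs[key])
    return cls(**kwargs)


@dataclass
class RunRecord:
    config: dict
    version: str
    seeds: dict[str, int]
    timings: dict[str, float]
    outputs: dict[str, str]
    report: dict

    def write(self, path) -> None:
        """Atomic write: the record appears complete or not at all."""
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(asdict(self), indent=2, default=str))
        os.replace(tmp, path)


def simulate_cohort(
    config: RunConfig,
    out_dir: str | Path | None = None,
    select: bool = True,
    in_memory: bool = False,
):
    """Generate phantoms, scan B-scans, optionally select and write them.

    Writes ``chick{ID}_frame{N}.png`` files plus a CSV manifest, or (with
    ``in_memory=True``) returns the images as arrays alongside the
    manifest without touching disk.
    """
    seeds = config.stage_seeds()
    cohort_spec = dataclasses.replace(config.cohort, seed=seeds["cohort"])
    records = make_cohort(cohort_spec)
    log.info("cohort: %d chicks × %d frames", config.cohort.n_chicks, config.cohort.frames_per_chick)

    geometry = config.scan.geometry()
    scan_rng = np.random.default_rng(seeds["scan"])
    images: list[np.ndarray] = []
    rows = []
    from .preprocess import quality_score

    for rec in records:
        rmap = rasterize(rec.phantom, geometry)
        bscan = scan_bscan(
            rmap,
            config.source,
            config.scan,
            speckle_scale=rec.phantom.speckle_scale,
            noise_floor=config.noise_floor,
            rng=scan_rng,
            chick_id=rec.chick_id,
            frame_index=rec.frame_index,
            label=rec.label,
        )
        images.append(bscan.pixels)
        rows.append(
            {
                "path": f"chick{rec.chick_id}_frame{rec.frame_index}.png",
                "chick_id": rec.chick_id,
                "frame_index": rec.frame_index,
                "label": rec.label,
                "quality": quality_score(bscan.pixels),
                "split": "",
            }
        )
    manifest = pd.DataFrame(rows)

    if select:
        keep_idx: list[int] = []
        for chick_id, group in manifest.groupby("chick_id"):
            idx = group.index.to_list()
            kept = quality_select(
                [images[i] for i in idx],
                config.cohort.keep_per_chick,
                frame_indices=group["frame_index"].to_list(),
            )
            keep_idx.extend(idx[i] for i in kept)
        keep_idx = sorted(keep_idx)
        manifest = manifest.loc[keep_idx].reset_index(drop=True)
        images = [images[i] for i in keep_idx]
        log.info("selection: kept %d of %d frames", len(manifest), len(records))

    if not in_memory:
        out_dir = Path(out_dir or config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for img, path in zip(images, manifest["path"]):
            Image.fromarray(img).save(out_dir / path)
        write_manifest(manifest, out_dir / "manifest.csv")
    return manifest, images


def load_images(manifest: pd.DataFrame, image_dir: str | Path) -> list[np.ndarray]:
    image_dir = Path(image_dir)
    return [np.asarray(Image.open(image_dir / p).convert("L")) for p in manifest["path"]]


def prepare_arrays(
    manifest: pd.DataFrame,
    images: list[np.ndarray],
    config: RunConfig,
):
    """Enhance, resize, split and augment into training/test arrays.

    Enhancement and resizing apply to every frame.  Augmentation applies
    to the training split only (augmenting before splitting would leak
    augmented copies of test frames into training).  Ambiguous frames are
    excluded from training; in the test split their true class is
    not_detect.
    """
    seeds = config.stage_seeds()
    pp = config.preprocess
    processed = [resize(enhance(im, pp), pp.target_width, pp.target_height) for im in images]

    manifest = split_dataset(
        manifest, train_fraction=config.train_fraction, mode=config.split_mode, seed=seeds["split"]
    )
    is_train = (manifest["split"] == "train").to_numpy()
    labels = manifest["label"].to_numpy()

    train_mask = is_train & (labels != "ambiguous")
    Xtr = [processed[i] for i in np.flatnonzero(train_mask)]
    ytr = [labels[i] for i in np.flatnonzero(train_mask)]
    if config.n_augment > 0:
        aug_rng = np.random.default_rng(seeds["augment"])
        extra_X, extra_y = [], []
        for img, lab in zip(list(Xtr), list(ytr)):
            for a in augment(img, aug_rng, pp, n=config.n_augment):
                extra_X.append(a)
                extra_y.append(lab)
        Xtr += extra_X
        ytr += extra_y

    test_idx = np.flatnonzero(~is_train)
    Xte = [processed[i] for i in test_idx]
    yte = ["not_detect" if labels[i] == "ambiguous" else labels[i] for i in test_idx]
    return manifest, (np.stack(Xtr), np.asarray(ytr)), (np.stack(Xte), np.asarray(yte))


def run_all(config: RunConfig, in_memory_images: bool = False) -> RunRecord:
    """Execute the whole pipeline and write a complete run record."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    outputs: dict[str, str] = {}
    seeds = config.stage_seeds()

    t0 = time.perf_counter()
    img_dir = out_dir / "images"
    manifest, images = simulate_cohort(
        config, out_dir=img_dir, select=True, in_memory=in_memory_images
    )
    timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    manifest, (Xtr, ytr), (Xte, yte) = prepare_arrays(manifest, images, config)
    write_manifest(manifest, out_dir / "manifest.csv")
    outputs["manifest"] = str(out_dir / "manifest.csv")
    timings["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    clf = CNNClassifier(
        input_height=config.preprocess.target_height,
        input_width=config.preprocess.target_width,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        patience=config.patience,
        val_fraction=config.val_fraction,
        tau=config.tau,
        random_state=seeds["train"],
    )
    clf.fit(Xtr, ytr)
    timings["train"] = time.perf_counter() - t0
    clf.save(out_dir / "model")
    outputs["model"] = str(out_dir / "model.npz")
    curves = learning_curves(clf.history_)
    curves.to_csv(out_dir / "history.csv", index=False)
    plot_learning_curves(clf.history_, out_dir / "learning_curves.png")
    outputs["history"] = str(out_dir / "history.csv")

    t0 = time.perf_counter()
    y_pred = clf.predict_with_reject(Xte)
    cm = confusion_matrix(yte, y_pred)
    report = metrics(cm)
    timings["evaluate"] = time.perf_counter() - t0
    cm.to_frame().to_csv(out_dir / "confusion_matrix.csv")
    (out_dir / "metrics.json").write_text(json.dumps(report.to_dict(), indent=2))
    outputs["metrics"] = str(out_dir / "metrics.json")

    if config.ablate_sizes:
        # the sweep resizes from the stored full-resolution frames, not from
        # the already-downscaled training arrays; augmentation is not applied
        t0 = time.perf_counter()
        labels = manifest["label"].to_numpy()
        is_train = (manifest["split"] == "train").to_numpy()
        enhanced = [enhance(im, config.preprocess) for im in images]
        tr_idx = np.flatnonzero(is_train & (labels != "ambiguous"))
        te_idx = np.flatnonzero(~is_train)
        ab = size_ablation(
            [enhanced[i] for i in tr_idx],
            labels[tr_idx],
            [enhanced[i] for i in te_idx],
            ["not_detect" if labels[i] == "ambiguous" else labels[i] for i in te_idx],
            sizes=config.ablate_sizes,
            clf_params=dict(
                learning_rate=config.learning_rate,
                batch_size=config.batch_size,
                max_epochs=config.max_epochs,
                patience=config.patience,
                val_fraction=config.val_fraction,
            ),
            seeds=(seeds["train"],),
            tau=config.tau,
        )
        ab.to_csv(out_dir / "ablation.csv", index=False)
        outputs["ablation"] = str(out_dir / "ablation.csv")
        timings["ablate"] = time.perf_counter() - t0

    record = RunRecord(
        config=_as_plain(config),
        version=__version__,
        seeds=seeds,
        timings=timings,
        outputs=outputs,
        report={
            "accuracy": report.accuracy,
            "stopped_epoch": clf.stopped_epoch_,
            "n_train": int(len(Xtr)),
            "n_test": int(len(Xte)),
            "confusion_matrix": cm.array.tolist(),
            "metrics": report.to_dict(),
        },
    )
    record.write(out_dir / "run_record.json")
    return record
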