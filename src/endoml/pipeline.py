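"""End-to-end orchestration: enhance -> segment -> embed -> select -> classify.

``run`` executes the full chain on a frame set (generated from a
:class:`~endoml.synthdata.FrameRecipe` or loaded from disk) under a
single global seed: every stage draws its randomness from a stream
derived from that seed, so a rerun with the same config reproduces
the report bit-for-bit (timings aside). ``ablation`` mirrors the
four-experiment design - raw frames, enhanced frames, segmented
crops, and the full pipeline with feature selection - on one shared
train/test split.
"""

from __future__ import annotations

import time
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .backbone import BackboneFeatureExtractor
from .elm import ELMClassifier, evaluate
from .enhancement import ContrastEnhancer
from .saliency import SaliencySegmenter
from .selection import HybridWOAHHOSelector
from .synthdata import FrameRecipe, make_frames
from . import io as eio

__all__ = ["PipelineConfig", "RunReport", "run", "ablation", "VARIANTS"]

VARIANTS = ("raw", "enhanced", "segmented", "full")


def _stage_seed(global_seed: int, stage: str) -> int:
    """Independent per-stage seed stream derived from the global seed."""
    tag = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence([int(global_seed), int(tag)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Global configuration; nested stage settings with study defaults."""

    recipe: FrameRecipe = field(default_factory=lambda: FrameRecipe(n_frames=60))
    data_dir: str | None = None          # overrides the recipe when set
    seed: int = 0
    split: str = "holdout"               # "holdout" (50:50) | "kfold10"
    out_dir: str | None = None

    enhance: bool = True
    segment: bool = True
    select: bool = True
    tune_bo: bool = False                # BO over (lr, momentum, L2)

    selem_radius: int = 5
    denoiser: str = "median"

    saliency_epochs: int = 100
    saliency_lr: float = 0.05
    saliency_momentum: float = 0.6
    top_k: int | None = None
    min_area: int = 64

    architecture: str = "tiny_cnn"
    embedding_width: int | None = None
    finetune_epochs: int = 20
    learning_rate: float = 0.01
    momentum: float = 0.7
    l2: float = 1e-5
    tune_budget: tuple[int, int] = (4, 4)

    population: int = 10
    iterations: int = 20
    hho_iterations: int = 10
    fitness_hidden: int = 100

    elm_hidden: int = 500
    elm_ridge: float = 1e-6


@dataclass
class RunReport:
    accuracy: float
    confusion_matrix: list
    classes: list
    n_train: int
    n_test: int
    dim_before_selection: int
    dim_after_selection: int
    selected_indices: list
    stage_timings: dict
    selection_history: list
    seed: int
    config: dict

    def to_dict(self) -> dict:
        return asdict(self)

    def comparable(self) -> dict:
        """Report content with the wall-clock timings stripped."""
        d = self.to_dict()
        d.pop("stage_timings")
        return d


def _load_frames(config: PipelineConfig):
    if config.data_dir is not None:
        images, names = eio.load_image_dir(Path(config.data_dir) / "frames")
        _, labels = eio.load_features(Path(config.data_dir) / "labels.csv") \
            if (Path(config.data_dir) / "labels.csv").exists() else (None, None)
        if labels is None:
            raise FileNotFoundError("labels.csv required next to frames/")
        return images, None, np.asarray(labels, dtype=int)
    recipe = replace(config.recipe, seed=_stage_seed(config.seed, "frames"))
    return make_frames(recipe)


def _crop_frames(segmenter: SaliencySegmenter, images, enhanced):
    """Best-scoring localized region per frame; whole frame as fallback."""
    crops = []
    for img, enh in zip(images, enhanced):
        regions = segmenter.localize_regions(img, enh)
        if regions:
            crops.append(max(regions, key=lambda r: r.score).crop)
        else:
            crops.append(img)
    return crops


def _classify(train_feats, ytr, test_feats, yte, config: PipelineConfig):
    clf = ELMClassifier(hidden_units=config.elm_hidden, ridge=config.elm_ridge,
                        random_state=_stage_seed(config.seed, "elm"))
    clf.fit(train_feats, ytr)
    return evaluate(yte, clf.predict(test_feats), clf.classes_)


def run(config: PipelineConfig | None = None) -> RunReport:
    """Execute the enabled stages in order and return the report."""
    config = config or PipelineConfig()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    images, _, labels = _load_frames(config)
    timings["data"] = time.perf_counter() - t0

    if config.split == "kfold10":
        return _run_kfold(config, images, labels, timings)
    idx = np.arange(len(images))
    train_idx, test_idx = train_test_split(
        idx, test_size=0.5, random_state=_stage_seed(config.seed, "split"),
        stratify=labels)

    t0 = time.perf_counter()
    if config.enhance:
        enhancer = ContrastEnhancer(selem_radius=config.selem_radius,
                                    denoiser=config.denoiser)
        enhanced = enhancer.transform(images)
    else:
        enhanced = images
    timings["enhance"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if config.segment:
        segmenter = SaliencySegmenter(
            learning_rate=config.saliency_lr, epochs=config.saliency_epochs,
            momentum=config.saliency_momentum, top_k=config.top_k,
            min_area=config.min_area,
            random_state=_stage_seed(config.seed, "saliency"))
        segmenter.fit(images[train_idx], labels[train_idx])
        crops = _crop_frames(segmenter, images, enhanced)
    else:
        crops = list(enhanced)
    timings["segment"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    extractor = BackboneFeatureExtractor(
        architecture=config.architecture, embedding_width=config.embedding_width,
        learning_rate=config.learning_rate, momentum=config.momentum,
        l2=config.l2, epochs=config.finetune_epochs, tune=config.tune_bo,
        tune_budget=config.tune_budget,
        random_state=_stage_seed(config.seed, "backbone"))
    train_crops = [crops[i] for i in train_idx]
    extractor.fit(train_crops, labels[train_idx])
    feats = {
        "train": extractor.transform(train_crops),
        "test": extractor.transform([crops[i] for i in test_idx]),
    }
    timings["features"] = time.perf_counter() - t0
    dim_before = feats["train"].shape[1]

    t0 = time.perf_counter()
    history: list[float] = []
    if config.select:
        selector = HybridWOAHHOSelector(
            population=config.population, iterations=config.iterations,
            hho_iterations=config.hho_iterations,
            fitness_hidden=config.fitness_hidden,
            random_state=_stage_seed(config.seed, "selection"))
        selector.fit(feats["train"], labels[train_idx])
        feats = {k: selector.transform(v) for k, v in feats.items()}
        selected = np.flatnonzero(selector.support_).tolist()
        history = list(selector.history_)
    else:
        selected = list(range(dim_before))
    timings["select"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    metrics = _classify(feats["train"], labels[train_idx],
                        feats["test"], labels[test_idx], config)
    timings["classify"] = time.perf_counter() - t0

    report = RunReport(
        accuracy=metrics["accuracy"],
        confusion_matrix=metrics["confusion_matrix"],
        classes=metrics["classes"],
        n_train=len(train_idx), n_test=len(test_idx),
        dim_before_selection=dim_before,
        dim_after_selection=feats["train"].shape[1],
        selected_indices=selected,
        stage_timings=timings,
        selection_history=history,
        seed=config.seed,
        config=_config_dict(config),
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        eio.save_json(out / "report.json", report.to_dict())
        eio.save_features(out / "train_features.csv", feats["train"],
                          labels[train_idx])
        eio.save_features(out / "test_features.csv", feats["test"],
                          labels[test_idx])
    return report


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["recipe"] = asdict(config.recipe)
    return d


def _run_kfold(config, images, labels, timings):
    """10-fold variant: mean accuracy over folds, pooled confusion."""
    skf = StratifiedKFold(n_splits=10, shuffle=True,
                          random_state=_stage_seed(config.seed, "split"))
    accs, cms = [], None
    for fold, (tr, te) in enumerate(skf.split(images, labels)):
        sub = replace(config, split="holdout", out_dir=None)
        # reuse the holdout machinery on this fold by slicing up front
        rep = _run_on_split(sub, images, labels, tr, te)
        accs.append(rep["accuracy"])
        cm = np.asarray(rep["confusion_matrix"])
        cms = cm if cms is None else cms + cm
    return RunReport(
        accuracy=float(np.mean(accs)), confusion_matrix=cms.tolist(),
        classes=sorted(set(labels.tolist())), n_train=len(images) * 9 // 10,
        n_test=len(images) // 10, dim_before_selection=-1,
        dim_after_selection=-1, selected_indices=[], stage_timings=timings,
        selection_history=[], seed=config.seed, config=_config_dict(config))


def _run_on_split(config, images, labels, train_idx, test_idx) -> dict:
    """Single split execution used by k-fold and ablation runs."""
    if config.enhance:
        enhanced = ContrastEnhancer(selem_radius=config.selem_radius,
                                    denoiser=config.denoiser).transform(images)
    else:
        enhanced = images
    if config.segment:
        segmenter = SaliencySegmenter(
            learning_rate=config.saliency_lr, epochs=config.saliency_epochs,
            momentum=config.saliency_momentum, top_k=config.top_k,
            min_area=config.min_area,
            random_state=_stage_seed(config.seed, "saliency"))
        segmenter.fit(images[train_idx], labels[train_idx])
        crops = _crop_frames(segmenter, images, enhanced)
    else:
        crops = list(enhanced)
    extractor = BackboneFeatureExtractor(
        architecture=config.architecture, embedding_width=config.embedding_width,
        learning_rate=config.learning_rate, momentum=config.momentum,
        l2=config.l2, epochs=config.finetune_epochs, tune=config.tune_bo,
        tune_budget=config.tune_budget,
        random_state=_stage_seed(config.seed, "backbone"))
    train_crops = [crops[i] for i in train_idx]
    extractor.fit(train_crops, labels[train_idx])
    ftr = extractor.transform(train_crops)
    fte = extractor.transform([crops[i] for i in test_idx])
    if config.select:
        selector = HybridWOAHHOSelector(
            population=config.population, iterations=config.iterations,
            hho_iterations=config.hho_iterations,
            fitness_hidden=config.fitness_hidden,
            random_state=_stage_seed(config.seed, "selection"))
        selector.fit(ftr, labels[train_idx])
        ftr, fte = selector.transform(ftr), selector.transform(fte)
    return _classify(ftr, labels[train_idx], fte, labels[test_idx], config)


def ablation(config: PipelineConfig | None = None,
             variants: tuple[str, ...] = VARIANTS) -> dict:
    """Run the requested pipeline variants on one shared split."""
    config = config or PipelineConfig()
    bad = set(variants) - set(VARIANTS)
    if bad:
        raise ValueError(f"unknown variants: {sorted(bad)}")
    images, _, labels = _load_frames(config)
    idx = np.arange(len(images))
    train_idx, test_idx = train_test_split(
        idx, test_size=0.5, random_state=_stage_seed(config.seed, "split"),
        stratify=labels)
    toggles = {
        "raw": dict(enhance=False, segment=False, select=False),
        "enhanced": dict(enhance=True, segment=False, select=False),
        "segmented": dict(enhance=True, segment=True, select=False),
        "full": dict(enhance=True, segment=True, select=True),
    }
    reports = {}
    for name in variants:
        variant_cfg = replace(config, **toggles[name])
        metrics = _run_on_split(variant_cfg, images, labels, train_idx, test_idx)
        reports[name] = metrics
    out = {
        "variants": list(variants),
        "train_indices": train_idx.tolist(),
        "test_indices": test_idx.tolist(),
        "seed": config.seed,
        "reports": reports,
    }
    if config.out_dir:
        outdir = Path(config.out_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        eio.save_json(outdir / "ablation.json", out)
    return out
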