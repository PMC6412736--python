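"""Cohort-level experiment orchestration.

Glue between the synthetic generator, the pre-processing chain, the
learnable components, and the validation harness: train all three models
on a set of scenes, evaluate the full framework on held-out scenes, and
run the leave-one-patient-out study end to end.

The default problem sizes here are desk-scale: 64x64 scenes, narrow
vessel/segmentation nets, reduced epochs, an 11-px vessel patch and a
5-px parenchyma morphology disk (the full-resolution pipeline uses 41 px
and 35 px; both scale with image size and are plain configuration).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from hsibrain import hsio
from hsibrain.evalstats import dice, lopo_cv
from hsibrain.framework import FrameworkConfig, run_framework, synthesize_grayscale
from hsibrain.nets import (
    TrainConfig,
    balance_classes,
    extract_patches,
    train_cnn2d,
    train_dnn1d,
    train_parenchyma_net,
)
from hsibrain.preprocess import PreprocessParams, ProcessedCube, preprocess_chain
from hsibrain.synthetic import RawScene

__all__ = [
    "ExperimentConfig",
    "preprocess_scene",
    "train_models",
    "evaluate_models",
    "run_lopo_experiment",
    "load_manifest",
]


@dataclass
class ExperimentConfig:
    """Desk-scale study conditions for the synthetic end-to-end runs."""

    seed: int = 0
    dnn_epochs: int = 40
    vessel_epochs: int = 16
    parenchyma_epochs: int = 8
    vessel_patch: int = 11
    vessel_filters: tuple[int, int, int] = (6, 8, 12)
    vessel_fc: int = 48
    vessel_activation: str = "relu"  # sigmoid convs stall at this scale
    parenchyma_base_filters: int = 8
    vessel_samples_per_scene: int = 50  # per class (vessel / non-vessel)
    max_spectra_per_class: int = 4000
    parenchyma_radius: int = 5
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)

    def framework_config(self) -> FrameworkConfig:
        return FrameworkConfig(parenchyma_morph_radius=self.parenchyma_radius)


def preprocess_scene(scene: RawScene, params: PreprocessParams | None = None) -> ProcessedCube:
    return preprocess_chain(scene.cube, scene.refs, params or PreprocessParams())


def _processed(scene: RawScene, cfg: ExperimentConfig, cache: dict) -> ProcessedCube:
    key = (scene.patient_id, scene.image_id)
    if key not in cache:
        cache[key] = preprocess_scene(scene, cfg.preprocess)
    return cache[key]


def train_models(
    scenes: list[RawScene],
    epochs: int | None = None,
    seed: int = 0,
    config: ExperimentConfig | None = None,
    cache: dict | None = None,
) -> dict:
    """Train the spectral DNN, the binary vessel CNN, and the parenchyma
    segmenter on fully-labeled scenes."""
    cfg = config or ExperimentConfig(seed=seed)
    if epochs is not None:
        cfg.dnn_epochs = epochs
    cache = cache if cache is not None else {}
    rng = np.random.default_rng([cfg.seed, 101])

    # --- spectral DNN ------------------------------------------------------
    spectra_by_class: dict[int, list[np.ndarray]] = {1: [], 2: [], 3: [], 4: []}
    for scene in scenes:
        cube = _processed(scene, cfg, cache)
        flat = cube.data.reshape(-1, cube.n_bands)
        labels = scene.truth.labels.ravel()
        for c in spectra_by_class:
            idx = np.flatnonzero(labels == c)
            if idx.size > cfg.max_spectra_per_class:
                idx = rng.choice(idx, cfg.max_spectra_per_class, replace=False)
            spectra_by_class[c].append(flat[idx])
    stacked = {c: np.concatenate(v) for c, v in spectra_by_class.items() if len(v)}
    balanced = balance_classes(stacked, rng)
    x = np.concatenate(list(balanced.values()))
    y = np.concatenate([np.full(len(v), c) for c, v in balanced.items()])
    dnn = train_dnn1d(
        x, y,
        TrainConfig(epochs=cfg.dnn_epochs, learning_rate=0.1, batch_size=128, seed=cfg.seed),
    )

    # --- vessel CNN --------------------------------------------------------
    patches, plabels = [], []
    for scene in scenes:
        cube = _processed(scene, cfg, cache)
        gray = synthesize_grayscale(cube)
        vessels = scene.vessel_truth
        if not vessels.any():  # e.g. cohorts loaded from disk without masks
            vessels = scene.truth.labels == hsio.CLASS_HYPERVASCULAR
        pos = np.argwhere(vessels)
        n = min(cfg.vessel_samples_per_scene, len(pos))
        if n == 0:
            continue
        # Half the negatives come from a ring near the vessels (hard
        # negatives that teach center discrimination), half from anywhere.
        from scipy.ndimage import binary_dilation

        near = binary_dilation(vessels, iterations=6) & ~vessels
        neg_near = np.argwhere(near)
        neg_far = np.argwhere(~vessels & ~near)
        pos = pos[rng.choice(len(pos), n, replace=False)]
        neg = np.vstack(
            [
                neg_near[rng.choice(len(neg_near), n - n // 2, replace=False)],
                neg_far[rng.choice(len(neg_far), n // 2, replace=False)],
            ]
        )
        patches.append(extract_patches(gray, np.vstack([pos, neg]), cfg.vessel_patch))
        plabels.append(np.r_[np.ones(n, dtype=int), np.zeros(n, dtype=int)])
    vessel = train_cnn2d(
        np.concatenate(patches),
        np.concatenate(plabels),
        TrainConfig(
            optimizer_name="adadelta",
            learning_rate=1.0,
            dropout_rate=0.4,
            epochs=cfg.vessel_epochs,
            patch_size=cfg.vessel_patch,
            conv_filters=cfg.vessel_filters,
            fc_width=cfg.vessel_fc,
            conv_activation=cfg.vessel_activation,
            seed=cfg.seed,
        ),
    )

    # --- parenchyma segmenter ----------------------------------------------
    grays = np.stack(
        [synthesize_grayscale(_processed(s, cfg, cache)) for s in scenes]
    )
    masks = np.stack([s.parenchyma_truth for s in scenes]).astype(float)
    paren = train_parenchyma_net(
        grays,
        masks,
        TrainConfig(
            optimizer_name="adadelta",
            learning_rate=1.0,
            epochs=cfg.parenchyma_epochs,
            base_filters=cfg.parenchyma_base_filters,
            batch_size=12,
            seed=cfg.seed,
        ),
    )
    return {"dnn": dnn, "vessel": vessel, "parenchyma": paren, "config": cfg}


def evaluate_models(
    models: dict, scenes: list[RawScene], cache: dict | None = None
) -> dict:
    """Run the full framework on each scene; report pixel accuracy against
    the truth map and the parenchyma Dice coefficient."""
    cfg: ExperimentConfig = models["config"]
    cache = cache if cache is not None else {}
    accs, dices, maps = [], [], []
    for scene in scenes:
        cube = _processed(scene, cfg, cache)
        fused, inter = run_framework(
            cube, models["dnn"], models["vessel"], models["parenchyma"],
            cfg.framework_config(),
        )
        accs.append(float((fused == scene.truth.labels).mean()))
        dices.append(dice(inter["parenchyma_mask"], scene.parenchyma_truth))
        maps.append((fused, inter))
    return {
        "accuracy": float(np.mean(accs)),
        "parenchyma_dice": float(np.mean(dices)),
        "per_scene": maps,
    }


def run_lopo_experiment(
    cohort: list[RawScene], config: ExperimentConfig | None = None
) -> dict:
    """Leave-one-patient-out study over a cohort of labeled scenes.

    Returns per-patient framework pixel accuracy and parenchyma Dice plus
    their cross-fold means.
    """
    cfg = config or ExperimentConfig()
    cache: dict = {}
    results = lopo_cv(
        cohort,
        train_fn=lambda scenes: train_models(scenes, config=cfg, cache=cache),
        eval_fn=lambda models, scenes: evaluate_models(models, scenes, cache=cache),
    )
    return {
        "per_patient": {pid: {"accuracy": r["accuracy"],
                              "parenchyma_dice": r["parenchyma_dice"]}
                        for pid, r in results},
        "mean_accuracy": float(np.mean([r["accuracy"] for _, r in results])),
        "mean_parenchyma_dice": float(np.mean([r["parenchyma_dice"] for _, r in results])),
    }


def load_manifest(manifest_dir: str) -> list[RawScene]:
    """Load a cohort written by the ``synth`` CLI command."""
    import csv

    from hsibrain.hsio import GoldStandardMap, ReferencePair

    path = os.path.join(manifest_dir, "manifest.tsv")
    scenes: list[RawScene] = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            cube = hsio.read_envi(os.path.join(manifest_dir, row["cube"]))
            white = hsio.read_portable(os.path.join(manifest_dir, row["white"])).data
            dark = hsio.read_portable(os.path.join(manifest_dir, row["dark"])).data
            truth = hsio.read_label_map(os.path.join(manifest_dir, row["truth"]))
            labels = truth.labels
            scenes.append(
                RawScene(
                    cube=cube,
                    refs=ReferencePair(white, dark),
                    truth=truth,
                    parenchyma_truth=np.isin(labels, (1, 2, 3)),
                    vessel_truth=np.zeros_like(labels, dtype=bool),
                    patient_id=row["patient_id"],
                    image_id=row["image_id"],
                    signatures={},
                )
            )
    return scenes
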