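"""Shared fixtures: desk-scale trained networks.

The trained-pipeline tests need all four network modules.  Training is
done once per session at deliberately reduced scale (width multiplier
1/8, a few hundred batches) so the whole suite fits a CPU-only CI
budget; the sizes are fixed here, and the resulting bundle is cached on
disk (keyed by a hash of the sizes) so local re-runs skip retraining.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pytest

# desk-scale training recipe (see docs/methods.md for the rationale)
TRAIN_SIZES = {
    "class": {"n_per_class": 24, "n_batches": 800, "batch_size": 8,
              "decay_step": 300, "val_fraction": 0.25, "seed": 11},
    "uniseg": {"n_samples": 16, "n_batches": 200, "batch_size": 16,
               "crop": [96, 64], "seed": 11},
    "biseg": {"n_samples": 20, "n_batches": 300, "batch_size": 8,
              "crop": [96, 64], "seed": 21},
    "decision": {"n_movies": 10, "n_batches": 100, "batch_size": 16,
                 "seed": 31},
    "width_multiplier": 0.125,
}

CACHE_DIR = Path(__file__).resolve().parent.parent / "scratch" / "model_cache"


def _train_all():
    from kymotrace.nets.data import (make_class_dataset,
                                     make_decision_dataset,
                                     make_segmentation_dataset)
    from kymotrace.nets.modules import ModelBundle, TrainConfig, train_module

    wm = TRAIN_SIZES["width_multiplier"]
    histories = {}

    sz = TRAIN_SIZES["class"]
    ds = make_class_dataset(sz["n_per_class"], sz["seed"])
    clf, histories["class"] = train_module(
        "class", ds, TrainConfig(n_batches=sz["n_batches"],
                                 batch_size=sz["batch_size"],
                                 decay_step=sz["decay_step"],
                                 val_fraction=sz["val_fraction"],
                                 width_multiplier=wm, n_restarts=1,
                                 seed=sz["seed"]))

    sz = TRAIN_SIZES["uniseg"]
    ds = make_segmentation_dataset("uni", sz["n_samples"], sz["seed"])
    uniseg, histories["uniseg"] = train_module(
        "uniseg", ds, TrainConfig(n_batches=sz["n_batches"],
                                  batch_size=sz["batch_size"],
                                  width_multiplier=wm, n_restarts=1,
                                  crop=tuple(sz["crop"]), seed=sz["seed"]))

    sz = TRAIN_SIZES["biseg"]
    ds = make_segmentation_dataset("bi", sz["n_samples"], sz["seed"])
    biseg, histories["biseg"] = train_module(
        "biseg", ds, TrainConfig(n_batches=sz["n_batches"],
                                 batch_size=sz["batch_size"],
                                 width_multiplier=wm, n_restarts=1,
                                 crop=tuple(sz["crop"]), seed=sz["seed"]))

    sz = TRAIN_SIZES["decision"]
    ds = make_decision_dataset(sz["n_movies"], sz["seed"])
    decision, histories["decision"] = train_module(
        "decision", ds, TrainConfig(n_batches=sz["n_batches"],
                                    batch_size=sz["batch_size"],
                                    width_multiplier=wm, n_restarts=1,
                                    seed=sz["seed"]))

    bundle = ModelBundle(classifier=clf, uniseg=uniseg, biseg=biseg,
                         decision=decision, width_multiplier=wm)
    return bundle, histories


@pytest.fixture(scope="session")
def trained():
    """(ModelBundle, training histories) at the desk-scale recipe."""
    from kymotrace.nets.modules import load_bundle, save_bundle

    key = hashlib.sha256(
        json.dumps(TRAIN_SIZES, sort_keys=True).encode()).hexdigest()[:16]
    cache = CACHE_DIR / f"bundle_{key}.npz"
    hist_cache = CACHE_DIR / f"history_{key}.json"
    if cache.exists() and hist_cache.exists():
        return (load_bundle(cache),
                json.loads(hist_cache.read_text()))
    bundle, histories = _train_all()
    CACHE_DIR.mkdir(parents=True, exist_ok=True)
    save_bundle(bundle, cache)
    hist_cache.write_text(json.dumps(histories))
    return bundle, histories


@pytest.fixture(scope="session")
def uni_benchmark_set(trained):
    """Fresh seeded unidirectional benchmark samples with their
    segmentation maps (computed once; reused by the benchmark and the
    threshold-sweep tests)."""
    from kymotrace.simgen import UniSimConfig, simulate_unidirectional

    bundle, _ = trained
    samples, maps = [], []
    for seed in range(3000, 3010):
        s = simulate_unidirectional(UniSimConfig(), seed, render_movie=False)
        samples.append(s)
        maps.append(bundle.segment_unidirectional(s.kymograph))
    return samples, maps


@pytest.fixture(scope="session")
def bi_benchmark_samples():
    from kymotrace.simgen import BiSimConfig, simulate_bidirectional

    return [simulate_bidirectional(BiSimConfig(), seed, render_movie=False)
            for seed in range(3100, 3110)]
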