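"""Desk-scale benchmark runs of the full grading pipeline.

These functions reproduce the pipeline's self-contained quantities on
synthetic data at sizes a single CPU handles in minutes: the dataset
split/augmentation bookkeeping at archive scale (630 images, 8:1:1,
augmented to 4500 sheets) and a learning-sanity run of the width-shrunk
network on a trivially separable gland-texture set.
"""

from __future__ import annotations

import dataclasses

from .metrics import attach_auc, compute_metrics
from .model import BackboneConfig, HCCANetConfig, build_hccanet
from .preprocessing import ImageStandardizer
from .synthetic import (
    SEPARABLE_INTERVALS,
    AugmentSpec,
    SplitSpec,
    SyntheticDatasetSpec,
    augment_to,
    generate_dataset,
    split_dataset,
)
from .training import TrainConfig, train

__all__ = ["pipeline_counts", "learning_sanity"]


def pipeline_counts(seed: int = 0, image_size: tuple[int, int] = (64, 64)) -> dict:
    """Archive-scale dataset bookkeeping: 630 images split 8:1:1, training
    split augmented to 4500 sheets.

    Image size is kept small; the split and augmentation counts do not
    depend on it.
    """
    spec = SyntheticDatasetSpec(n_per_class=210, image_size=image_size, seed=seed)
    ds = generate_dataset(spec)
    tr, va, te = split_dataset(ds, SplitSpec(seed=seed))
    aug = augment_to(tr, AugmentSpec(target_count=4500, seed=seed))
    return {
        "n_total": len(ds),
        "n_per_class": ds.class_counts,
        "n_train": len(tr),
        "n_val": len(va),
        "n_test": len(te),
        "n_augmented": len(aug),
        "augmented_per_class": aug.class_counts,
    }


def learning_sanity(seed: int = 0, *, n_train_per_class: int = 20,
                    n_test_per_class: int = 30, image_size: tuple[int, int] = (64, 64),
                    augment_target: int = 600, epochs: int = 10,
                    batch_size: int = 16, width_multiplier: float = 0.125) -> dict:
    """Train the width-shrunk network on a trivially separable 60-image set.

    The training split uses the generator's wide-margin coverage
    sub-intervals, is augmented by the pipeline's rotation/crop/scale
    stage, and is standardized before training.  Per-epoch accuracy is
    tracked on the 60 original training images (the best such epoch is
    checkpointed); generalisation is measured on a fresh 90-image set.
    """
    spec = SyntheticDatasetSpec(classes=dict(SEPARABLE_INTERVALS),
                                n_per_class=n_train_per_class,
                                image_size=image_size, seed=seed)
    train_ds = generate_dataset(spec)
    aug = augment_to(train_ds, AugmentSpec(target_count=augment_target, seed=seed))
    test_ds = generate_dataset(dataclasses.replace(
        spec, n_per_class=n_test_per_class, seed=seed + 1000))

    Xa, ya = aug.to_arrays()
    Xo, yo = train_ds.to_arrays()
    Xt, yt = test_ds.to_arrays()
    std = ImageStandardizer().fit(Xa)
    Xa, Xo, Xt = std.transform(Xa), std.transform(Xo), std.transform(Xt)

    model = build_hccanet(HCCANetConfig(
        backbone=BackboneConfig(input_size=(*image_size, 3),
                                width_multiplier=width_multiplier, seed=seed),
        seed=seed,
    ))
    history = train(model, (Xa, ya), (Xo, yo),
                    TrainConfig(epochs=epochs, batch_size=batch_size, seed=seed))

    probs = model.predict_proba(Xt)
    rep = compute_metrics(yt, probs.argmax(axis=1), labels=[0, 1, 2])
    attach_auc(rep, yt, probs)
    return {
        "train_accuracy": max(history.val_accuracy),
        "train_accuracy_per_epoch": history.val_accuracy,
        "best_epoch": history.best_epoch,
        "test_accuracy": rep.accuracy,
        "test_macro_auc": rep.macro_auc,
        "n_train": len(Xo),
        "n_test": len(Xt),
        "epochs": epochs,
    }
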