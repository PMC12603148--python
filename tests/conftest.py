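"""Shared fixtures.

The two expensive end-to-end fixtures (segmentation training, classifier
training) are session-scoped and shared between the module tests and the
acceptance tests so each trains exactly once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from lucent.phantom import PhantomSpec, make_cohort
from lucent.preprocess import PreprocessConfig, preprocess_volume


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def small_cohort(default_spec):
    """Six phantoms (3 FBA / 3 NFBA) for structural tests."""
    return make_cohort(3, 3, default_spec, seed=101)


@pytest.fixture(scope="session")
def seg_training_run(default_spec):
    """Tiny segmentation network trained on 20 phantoms, validated on 5.

    Returns (model, history, val_pairs).
    """
    from lucent.segnet import (FocalParams, SegAugmentConfig, SegNetConfig,
                               train_segnet)

    recs = make_cohort(0, 25, default_spec, seed=11)
    pairs = []
    for r in recs:
        v, m = preprocess_volume(r.volume, r.mask, PreprocessConfig())
        pairs.append((v.voxels, m))
    train, val = pairs[:20], pairs[20:]
    model, hist = train_segnet(train, SegNetConfig(), FocalParams(),
                               SegAugmentConfig(), val_pairs=val, epochs=8,
                               lr=3e-3, crop_size=32, seed=5)
    return model, hist, val


@pytest.fixture(scope="session")
def clf_training_run(default_spec):
    """Tiny multi-view classifier trained on a 40/40 phantom cohort.

    Returns (model, cfg, test_items, history).
    """
    from lucent.classifier import (AugmentConfig2D, ClassifierConfig,
                                   train_classifier)
    from lucent.render import render_viewset

    recs = make_cohort(40, 40, default_spec, seed=21)
    items = []
    for r in recs:
        vs = render_viewset(r.mask, r.volume.spacing_mm, n_views=12,
                            radius_mm=150.0, size=64, frame_half_mm=70.0)
        items.append((r.patient_id, vs.images, r.label))
    fba = [i for i in items if i[2] == "FBA"]
    nfba = [i for i in items if i[2] == "NFBA"]
    train = fba[:24] + nfba[:24]
    val = fba[24:32] + nfba[24:32]
    test = fba[32:] + nfba[32:]
    cfg = ClassifierConfig(input_size=64, lr0=1e-3, max_epochs=30, seed=3)
    # phantom renders are geometrically standardized by construction, so the
    # 2D augmentation menu (which models real-world heterogeneity) is off here
    model, hist = train_classifier(train, val, cfg, AugmentConfig2D.disabled())
    return model, cfg, test, hist
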