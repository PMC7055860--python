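"""Shared fixtures: synthetic sections and trained classifiers.

The heavier fixtures are session-scoped so the boundary classifiers are
trained once and the full-scale recovery experiment runs once.
"""

from __future__ import annotations

import numpy as np
import pytest

from myoseg.io import AnnotationMask, RunConfig
from myoseg.synth import SynthSpec, generate_section, score_detection, score_typing
from myoseg import pipeline


SMALL = dict(shape=(512, 512), n_fibers=70)


@pytest.fixture(scope="session")
def small_section():
    """A 512x512 good-quality section with ~70 fibers (ground truth attached)."""
    return generate_section(SynthSpec(seed=0, **SMALL))


@pytest.fixture(scope="session")
def classifiers():
    """Primary + iterative classifiers trained on a small annotated section."""
    cfg = RunConfig(seed=0)
    img, gt = generate_section(SynthSpec(seed=1200, **SMALL))
    ann = AnnotationMask(labels=gt.annotation_mask(n_per_class=300, seed=5))
    primary, iterative = pipeline.train_classifiers(img, ann, cfg)
    return primary, iterative, cfg


@pytest.fixture(scope="session")
def recovery():
    """Full-scale parameter-recovery experiment.

    Classifiers are trained on one 1024x1024 synthetic section and the full
    pipeline is run on three held-out good-quality sections (stain ratio 6)
    and one poor-quality section (ratio 3); detection, typing and CSA
    metrics are scored against the generator's ground truth.
    """
    cfg = RunConfig(seed=0)
    train_img, train_gt = generate_section(SynthSpec(seed=1000))
    ann = AnnotationMask(labels=train_gt.annotation_mask(n_per_class=400, seed=5))
    primary, iterative = pipeline.train_classifiers(train_img, ann, cfg)

    def _run(spec):
        img, gt = generate_section(spec)
        res = pipeline.run_pipeline(img, primary, iterative, cfg)
        det = score_detection(res.records, gt)
        acc = score_typing(res.records, res.calls, gt, det)
        return {"det": det, "type_accuracy": acc, "result": res, "gt": gt}

    good = [_run(SynthSpec(seed=s)) for s in (0, 2, 5)]
    poor = [_run(SynthSpec(seed=3, stain_ratio=3.0))]

    def _agg(runs):
        n_truth = sum(r["det"].n_truth for r in runs)
        fp = sum(len(r["det"].false_positives) for r in runs)
        fn = sum(len(r["det"].false_negatives) for r in runs)
        errs = np.concatenate([r["det"].csa_errors for r in runs])
        n_match = sum(len(r["det"].matches) for r in runs)
        n_ok = sum(r["type_accuracy"] * len(r["det"].matches) for r in runs)
        return {
            "fp_rate": fp / n_truth,
            "fn_rate": fn / n_truth,
            "type_accuracy": n_ok / n_match if n_match else 0.0,
            "median_csa_error": float(np.median(np.abs(errs))),
            "n_truth": n_truth,
        }

    return {"good": good, "poor": poor,
            "good_agg": _agg(good), "poor_agg": _agg(poor)}
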